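time,recovery
0.0,0.0
1.0,0.2960315800417462
2.0,0.48251978960598724
3.0,0.599999999999662
4.0,0.6740078950102456
5.0,0.7206299474013985
6.0,0.7499999999998757
7.0,0.7685019737525584
8.0,0.7801574868503698
9.0,0.7875000000000036
10.0,0.7921254934381835
11.0,0.7950393717126422
12.0,0.7968750000000543
13.0,0.7980313733596015
14.0,0.7987598429282176
15.0,0.7992187500000716
16.0,0.7995078433399591
17.0,0.7996899607321134
18.0,0.799804687500077
19.0,0.799876960835049
20.0,0.7999224901830878
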