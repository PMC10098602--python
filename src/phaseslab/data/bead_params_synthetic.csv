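# Synthetic per-bead parameter table for the residue-resolution model.
# SYNTHETIC: this is NOT a transcription of any published pair table. Sigma
# values are the standard residue van der Waals diameters used throughout
# this model family; masses are standard residue masses (Da); charges are
# integer formal charges at simulated conditions (D,E=-1; K,R=+1; H=0;
# phosphoserine SEP=-2; DNA bp BP=-2). "stickiness" is a declared
# dimensionless scale (aromatics high) from which pair interaction depths
# are built via the combination rules documented in phaseslab.params.
# "cls" tags drive cation-pi / pi-pi enhancement of pair depths.
name,code,kind,charge,sigma,mass,stickiness,cls
ALA,A,protein,0,5.04,71.08,0.45,aliphatic
ARG,R,protein,1,6.56,156.19,0.55,cation
ASN,N,protein,0,5.68,114.10,0.40,polar
ASP,D,protein,-1,5.58,115.09,0.30,anion
CYS,C,protein,0,5.48,103.14,0.60,aliphatic
GLN,Q,protein,0,6.02,128.13,0.42,polar
GLU,E,protein,-1,5.92,129.12,0.30,anion
GLY,G,protein,0,4.50,57.05,0.40,polar
HIS,H,protein,0,6.08,137.14,0.55,aromatic
ILE,I,protein,0,6.18,113.16,0.62,aliphatic
LEU,L,protein,0,6.18,113.16,0.65,aliphatic
LYS,K,protein,1,6.36,128.17,0.40,cation
MET,M,protein,0,6.18,131.19,0.73,aliphatic
PHE,F,protein,0,6.36,147.18,0.90,aromatic
PRO,P,protein,0,5.56,97.12,0.50,aliphatic
SER,S,protein,0,5.18,87.08,0.42,polar
THR,T,protein,0,5.62,101.10,0.44,polar
TRP,W,protein,0,6.78,186.21,0.95,aromatic
TYR,Y,protein,0,6.46,163.18,0.92,aromatic
VAL,V,protein,0,5.86,99.07,0.58,aliphatic
SEP,J,protein,-2,5.70,167.06,0.42,anion
BP,B,dna,-2,10.00,650.00,0.35,anion
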