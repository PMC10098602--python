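# Methods

This note documents the models, parameters, numerical choices and known
limitations of `phaseslab`, in the package's own words.

## Coarse-grained representation

Each protein residue is a single spherical bead with a type-specific
charge, diameter and mass; consecutive beads are joined by harmonic bonds
U = k (r − r0)² with k = 19.1 kcal/mol/Å² and r0 = 3.81 Å (the Cα–Cα
virtual bond length). Protein chains are fully flexible. Each DNA base pair
is reduced to a single bead carrying −2 e (the two backbone phosphates)
with an effective interaction diameter of 10 Å, bonded at the canonical
helical rise of 3.4 Å; a duplex is propagated as a rigid body, justified at
the 12–24 bp lengths used here, which are far below the ~150 bp persistence
length of double-stranded DNA. Phosphoserine beads carry −2 e with the
serine diameter scaled by +10 %.

### Pair parameters (synthetic table)

The per-type table (`data/bead_params_synthetic.csv`) is a synthetic,
self-documented parameterization, not a transcription of any published
pair matrix: diameters are the standard residue van der Waals values used
across this model family, masses are standard residue masses, and charges
are integer formal charges at simulated conditions (Asp/Glu −1, Lys/Arg +1,
His 0). Pair interaction depths are built from a declared per-type
"stickiness" scale s (aromatics high) as ε_ij = ε₀ √(s_i s_j) · boost with
ε₀ = 0.55 kcal/mol, boosting cation–π pairs ×1.6 and π–π pairs ×1.5 to
mimic the interaction hierarchy that residue-resolution LLPS force fields
encode. The code treats the table purely as data: any CSV with the same
columns (for example a published force-field transcription) can be swapped
in without code changes, and all property-based tests in this repository
are independent of the literal values.

### Energy model

- **Wang–Frenkel**: U(r) = ε α ((σ/r)^2μ − 1)((r_c/r)^2μ − 1)^2ν with
  μ = 2, ν = 1, r_c = 3σ, and α chosen so the minimum is exactly −ε. The
  potential is identically zero at and beyond r_c, so no shift is needed.
  Below 0.6σ the repulsive core is continued linearly (C¹, constant
  force): U(0.6σ) is already hundreds of kcal/mol and is never visited in
  equilibrium, but the unmodified core reaches ~10⁶ kcal/mol, enough for a
  single accidental overlap (for example from a barostat move) to inject
  unintegrable kinetic energy. The zero at σ, the cutoff and the −ε
  minimum (near 1.19σ) all lie outside the modified region.
- **Debye–Hückel**: (q_i q_j e² / 4πε₀ε_r r)·exp(−r/λ_D), truncated and
  shifted at 35 Å; ε_r = 80, temperature-independent. λ_D is derived from
  ionic strength (default 150 mM monovalent), temperature and ε_r; at
  (150 mM, 300 K, 80) λ_D = 7.95 Å.
- **Exclusions**: directly bonded (1–2) pairs, and all intra-chain pairs of
  rigid chains (their internal energy is constant and the stacked bp beads
  of a rigid duplex would otherwise overlap by construction).

Internal units are Å, Da, kcal/mol, fs, elementary charges; conversions are
derived from CODATA constants via `scipy.constants`.

## Dynamics and the Direct Coexistence protocol

The integrator is BAOAB Langevin with default dt = 10 fs and friction
0.01 /fs (10 /ps); with zero friction it reduces exactly to velocity
Verlet, which the energy-conservation tests exploit (<0.1 % drift over 10⁴
frictionless 1 fs steps of a harmonic dimer). Rigid duplexes translate and
rotate about their centers of mass; torques use the world-frame inertia
tensor, rotations use the rotation-vector exponential map, and each bead
contributes its own solid-sphere inertia so rotation about the duplex axis
is well defined. Rotational friction and noise match the translational
thermostat, and sampled kinetic temperatures are unbiased within 2 %.

The Berendsen barostat rescales per-chain centers of mass isotropically
with coupling time 1 ps and an effective compressibility parameter of
4.5×10⁻³ /bar — far above water's, reflecting how soft these coarse-grained
fluids are and giving useful compression rates at desk scale; per-step
volume changes are clamped to ±3 % regardless. Pressure is the standard
kinetic-plus-pair-virial estimator (verified against the exact ideal-gas
law under barostatting).

The Direct Coexistence protocol is: random overlap-free insertion in a
cubic box (persistent-random-walk protein conformations, straight rigid
duplexes, seeded and bit-reproducible), NPT compression at 25 bar to a
dense liquid, elongation of the z axis by a fixed factor (default 3), then
NVT production. The LLPS flag is read from the time-averaged,
slab-recentred density profile of the second half of production.

### Desk-scale problem sizes

Defaults run minutes on one CPU: 0.05 ns NPT, 0.2 ns production,
~200 beads in the demonstration system, frames every 0.01 ns. These are
configuration values, not code limits — paper-scale studies of this kind
use tens of chains of ~100 residues for microseconds, and the same
`ProtocolConfig` expresses that directly. Temperatures may be given in K;
the reduced-temperature convention T/T_c(wildtype) uses a configurable
conversion constant (default 160 K).

### Scaled-down coexistence demonstration

The monotonicity fixture is a charge-complementary mixture: eight
lysine-bearing 20-mers ("KGGSG"×4, +4 e each) against two flexible 16-mer
polyglutamate strands (−16 e each), exactly neutral overall, so
condensation is driven by electrostatic complementarity as in the
protein/DNA systems this package targets. Strand choice matters at desk
scale: a −2 e DNA-bp bead binds several protein beads at once
(~10 kcal/mol per strand), putting the critical temperature of any
DNA-glued mixture far above every usable demo temperature, whereas
single-charge polyglutamate beads keep per-chain cohesion at ≈7 kT at
300 K but only ≈2.4 kT at 900 K — condensed at 300 K, one-phase at 3×
that temperature. (A separate K-peptide + short-duplex system,
`polyampholyte_dna_system`, exercises the protein–DNA contact, valency
and contact-energy analyses on real dynamics, where persistent binding is
exactly what is wanted.)

The demonstration uses production friction 0.0005 /fs (0.5 /ps) — much
lighter than the simulation default — because dispersal is
diffusion-limited (D ∝ 1/γ) and the flag should reflect thermodynamics,
not drag; the NPT compression stage keeps heavy damping (0.01 /fs), which
suppresses the rare close approaches a shrinking box can generate. The
interface flag for this system uses desk-scale dials, declared in the
protocol configuration: the plateau requirement is disabled (a ~200-bead
condensate is only a few interface widths thick, so a slab-geometry
plateau cannot exist at any temperature), the contrast ratio is raised
from 10 to 15, and the mass must be localized along the slab axis
(mass-weighted σ_z ≤ 0.15 of the box; condensed states measure
0.06–0.10, a spreading one-phase cloud 0.2 or more). The localization
requirement exists because a supercritical cloud expanding from the
compressed slab keeps near-empty box edges for hundreds of picoseconds,
which a pure contrast criterion misreads as coexistence. Three seeds per
temperature are run and majority flags compared.

## Phase analysis

Density profiles recentre each frame by the mass-weighted circular mean
along the slab axis before averaging, so a drifting slab accumulates
coherently; per-species (protein/DNA) channels sum to the total, and the
profile integral conserves total mass to machine precision.

Coexistence densities come from least-squares fits of
ρ(z) = (ρ_l+ρ_v)/2 − (ρ_l−ρ_v)/2 · tanh((|z−z0|−w)/d). Initial guesses are
taken from a lightly smoothed profile (half-maximum width of the dense
region), several interface-width starts are tried and the lowest-residual
solution kept — small-system, few-frame profiles are lumpy and a single
start is not reliable. A "well-defined interface" (the LLPS indicator)
requires a fitted dense/dilute contrast ≥ 10 and a dense plateau at least
3 interface widths wide; fit failure yields "no interface" with
diagnostics rather than an exception.

Critical points are fitted simultaneously to the law of rectilinear
diameters (ρ_l+ρ_v)/2 = ρ_c + A(T_c−T) and the scaling law
ρ_l−ρ_v = B(1−T/T_c)^β with β fixed at the 3-D Ising value 0.325 (standard
for this model class; fitting β from a handful of binodal points is not
identifiable). T_c is initialised by linearising the scaling law
(Δρ^{1/β} is linear in T) and constrained above every input temperature.
Closed-loop tests recover a generated T_c = 160 K within 1 % at 1 %
density noise and ρ_c within 5 %.

## Contact analysis

Two beads are in contact when their minimum-image distance is below
1.13 × the mean of their diameters; pairs within one chain separated by two
or fewer bonds are never counted, and a bp bead's "molecular diameter" is
its model σ. Maps are averaged per chain pair per frame, so homotypic maps
from different system sizes are directly comparable, and entries lie in
[0, 1]. DNA valency counts, per frame and strand, the protein chains with
at least 3 bead contacts — each such chain is +1 recruit — and averages
over frames. Per-contact energies sum the Wang–Frenkel and Debye–Hückel
terms over contacting pairs divided by the contact count, expressed in kT
at the thermostat setpoint (not the instantaneous temperature).

## Sequence profiling

Sequences are scanned by sliding fragments (default 30 residues, step 1);
each fragment score is assigned to the fragment's central residue
(start + 15 for length 30) and the series is smoothed by a centered running
mean (default window 7) whose window shrinks symmetrically at the track
edges. Shipped scorers: mean Kyte–Doolittle hydropathy, Shannon entropy in
bits (a low-complexity proxy; fragments under 2.9 bits are flagged),
Henderson–Hasselbalch net charge and bisection isoelectric point using a
vendored Lehninger-style pKa set (termini 9.69/2.34; phosphoserine pKa
2.19 and 5.96, so its charge is ≈ −2 at pH 7.4). Any callable mapping a
fragment to a number plugs into the same windowing, which is how an
external propensity predictor would be attached; no disorder predictor is
re-implemented, and the entropy track is a declared proxy rather than a
reconstruction of any particular low-complexity detector.

## FRAP quantification

Recovery is the bleached/unbleached intensity ratio — which cancels
acquisition photobleaching that affects both regions multiplicatively —
rescaled so prebleach is 1 and the first post-bleach point (the ratio
minimum) is 0. The model I(t) = M(1 − 2^(−t/t½)) parameterises the
half-time directly; both the fitted t½ and a direct half-plateau reading
are reported, and the immobile fraction is reported both as 1 − M and
empirically as the signal unrecovered at 20 s (the headline number). At
the default sampling (1 s intervals, 20 s) a 1.5 s half-time is recovered
exactly on noiseless traces, with <5 % mean bias and ~10 % per-trace
scatter at 5 % multiplicative noise.

## What the synthetic generators do and do not emulate

The generators produce slab configurations by inhomogeneous Poisson
sampling of a known tanh profile, binodals from a known critical point
with multiplicative Gaussian noise, FRAP traces with known t½/mobile
fraction and optional matched drift, and random sequences of controlled
composition. They reproduce the *geometry and statistics* the analysis
modules must invert — not the physics: synthetic slabs carry no
correlations between beads, no interfacial fluctuations beyond Poisson
noise, and no dynamics. Passing closed-loop tests therefore demonstrates
that the analysis chain is an unbiased inverse of its own data model at
realistic noise levels, not that the simulator reproduces any particular
experimental system.

## Known limitations

- The pair table is a constructed stand-in; quantitative phase diagrams of
  specific proteins require a published force-field transcription in its
  place.
- All-pairs energy evaluation is exact but O(N²); it is the right choice
  at desk scale (hundreds of beads) and becomes the bottleneck for
  paper-scale systems, where a neighbour-listed kernel would be swapped in
  behind the same `EnergyModel` interface.
- Rigid-body dynamics use a simple exponential-map rotation update; it is
  stable and statistically correct here but is not a symplectic rigid-body
  integrator.
- The Berendsen barostat does not sample a true NPT ensemble (it is used
  only to prepare dense configurations, as intended).
- Electrostatics are mean-field Debye–Hückel with fixed integer charges;
  titration, ion condensation and divalent-salt effects are out of scope.
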