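# phaseslab

Residue-resolution coarse-grained simulation and analysis of protein
liquid–liquid phase separation (LLPS), built around the chromatin
architectural protein **HMGA1a** (human HMGA1 isoform a, UniProt P17096, 107
residues) and its condensation with short double-stranded DNA.

HMGA1a is an intrinsically disordered, strongly basic protein (three
DNA-binding AT hooks, an acidic C-terminal tail) whose phase behaviour is
modulated by DNA and by CK2 phosphorylation of Ser99/Ser102/Ser103. This
package provides the computational machinery to study such systems at desk
scale:

- **Sequence profiling** — sliding 30-residue fragments scored for
  Kyte–Doolittle hydropathy, Shannon-entropy sequence complexity, net charge
  (Henderson–Hasselbalch) and isoelectric point, smoothed with a centered
  running mean (window 7), plus a pluggable per-fragment scorer interface.
- **Coarse-grained models** — one bead per protein residue (one bead per DNA
  base pair carrying −2 e, rigid duplexes), with Wang–Frenkel short-range
  pair potentials, Debye–Hückel screened electrostatics (150 mM, λ_D ≈ 8 Å)
  and harmonic bonds. Phosphoserine is a modified bead (−2 e, +10 %
  diameter).
- **Direct Coexistence simulation** — BAOAB Langevin dynamics; Berendsen
  NPT compression (>20 bar) of a cubic box into a dense liquid, elongation
  of one axis (3–10×), NVT slab production with density/energy monitors.
- **Phase analysis** — mass-density profiles along the slab axis, tanh
  interface fits for coexistence densities ρ_v and ρ_l, binodal assembly
  (absolute K and reduced T/T_c units), and critical-point estimation from
  the law of rectilinear diameters plus the scaling relation
  ρ_l − ρ_v = B(1 − T/T_c)^β with β = 0.325.
- **Contact analysis** — two beads are in contact when closer than
  1.13 × the mean of their diameters; time-averaged homotypic and
  protein–DNA contact maps, per-contact energies in kT, and DNA valency
  (a protein counts toward a strand's valency only with ≥ 3 bead contacts).
- **FRAP quantification** — bleached/unbleached ratio normalisation,
  single-exponential recovery I(t) = M·(1 − 2^(−t/t½)), mobile fraction,
  and the immobile fraction read at 20 s.
- **Synthetic data** — seeded generators for every input (sequences of
  controlled composition, tanh-profile slab configurations, binodals from a
  known critical point, noisy FRAP traces) that return their ground truth,
  so the whole pipeline is testable closed-loop without long simulations.

## Worked example

```python
import numpy as np
from phaseslab import (hmga1a, net_charge, isoelectric_point, hydropathy_score,
                       fit_critical_point, assemble_binodal,
                       normalize_trace, fit_recovery)
from phaseslab.synth import synthetic_binodal, synthetic_frap

seq = hmga1a()
print(f"net charge at pH 7.4: {net_charge(seq, 7.4):+.2f} e")
print(f"isoelectric point:    {isoelectric_point(seq):.2f}")
print(f"mean hydropathy:      {hydropathy_score(seq):+.2f}")

points, _ = synthetic_binodal(t_c=160.0, rho_c=0.30, noise=0.01, seed=1)
cp = fit_critical_point(assemble_binodal(points, tc_wildtype=160.0))
print(f"critical point: T_c = {cp.t_c:.1f} K, rho_c = {cp.rho_c:.3f} g/cm3")

trace, _ = synthetic_frap(t_half=1.5, mobile=0.80, noise=0.0)
fit = fit_recovery(normalize_trace(trace))
print(f"FRAP: t_half = {fit.t_half:.2f} s, mobile = {fit.mobile_fraction:.2f}, "
      f"immobile at 20 s = {fit.immobile_fraction_20s:.2f}")
```

prints

```
net charge at pH 7.4: +11.99 e
isoelectric point:    10.85
mean hydropathy:      -1.81
critical point: T_c = 160.3 K, rho_c = 0.300 g/cm3
FRAP: t_half = 1.50 s, mobile = 0.80, immobile at 20 s = 0.20
```

The HMGA1a chain is strongly net-positive at physiological pH with a basic
pI and negative mean hydropathy — the sequence signature of a
DNA-attracted, polar, disordered scaffold. The critical-point fit recovers
the generating (T_c, ρ_c) from a 1 %-noise binodal, and the FRAP fit
returns the generating recovery half-time and mobile fraction exactly on a
noiseless trace.

A command-line interface mirrors the library:

```bash
phaseslab profile --fasta hmga1a.fasta --tracks hydropathy,entropy,charge
phaseslab build --fasta hmga1a.fasta --phospho 99,102,103 --dna-bp 24 --copies 48:12
phaseslab simulate --topology topology.json --temperature 300 --seed 7
phaseslab analyze-phase --traj run/trajectory.xyz --topology topology.json
phaseslab contacts --traj run/trajectory.xyz --topology topology.json --mode protein-dna
phaseslab frap --trace trace.csv
phaseslab synth --kind binodal --seed 3
```

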