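"""Seeded synthetic-data generators with known ground truth.

Every generator is deterministic for a fixed seed and returns its
ground-truth parameters alongside the data, enabling closed-loop recovery
tests of the analysis modules (slab -> density profile -> coexistence
densities; binodal -> critical point; FRAP trace -> recovery fit) without
running any molecular dynamics. Defaults mirror the study conditions:
107-residue chains, 24-bp strands, a 48:12 protein:DNA copy ratio, a
wildtype critical temperature of 160 K, and FRAP with t_half = 1.5 s and an
80 % mobile fraction.
"""

from __future__ import annotations

import numpy as np

from .constants import DA_PER_A3_TO_G_CM3
from .frap import FRAPTrace
from .md import SimulationFrame
from .params import load_bead_table
from .phase import BinodalPoint, ISING_BETA
from .sequences import CANONICAL, ProteinSequence
from .topology import (
    BeadTopology,
    build_dna_duplex,
    build_protein_topology,
    replicate_topologies,
)

#: residue composition with HMGA1a-like charge content
#: (K+R fraction 0.25, D+E fraction 0.15, remainder polar/small)
HMGA1A_LIKE_COMPOSITION: dict[str, float] = {
    "K": 0.15, "R": 0.10, "D": 0.02, "E": 0.13, "G": 0.10, "S": 0.12,
    "P": 0.10, "T": 0.08, "A": 0.08, "Q": 0.04, "V": 0.04, "N": 0.02,
    "L": 0.02,
}


def random_sequence(length: int, composition: dict[str, float],
                    seed: int = 0) -> ProteinSequence:
    """I.i.d. residue draws from ``composition`` (probabilities sum to 1)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    codes = list(composition)
    probs = np.array([composition[c] for c in codes], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition probabilities sum to {probs.sum()}, not 1")
    if any(c not in CANONICAL for c in codes):
        raise ValueError("composition contains non-canonical residue codes")
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(codes, size=length, p=probs))
    return ProteinSequence(f"synthetic-{seed}", residues)


def synthetic_slab(
    rho_dense: float,
    rho_dilute: float,
    box: tuple[float, float, float] = (60.0, 60.0, 240.0),
    interface_width: float = 8.0,
    slab_half_width: float | None = None,
    bead_mass: float = 110.0,
    bead_sigma: float = 6.0,
    n_frames: int = 1,
    seed: int = 0,
):
    """Slab-geometry frames sampled from a tanh density profile along z.

    Beads are placed by inhomogeneous Poisson sampling of the profile
    rho(z) = (rho_l+rho_v)/2 - (rho_l-rho_v)/2 * tanh((|z-z0|-w)/d) with the
    slab centred in the box. Returns ``(frames, topology, truth)`` where
    ``truth`` holds the generating parameters.
    """
    if not rho_dense > rho_dilute >= 0:
        raise ValueError("require rho_dense > rho_dilute >= 0")
    if rho_dense > 1.5:
        raise ValueError("dense-phase density exceeds close packing for "
                         "residue-sized beads")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    lz = box[2]
    w = slab_half_width if slab_half_width is not None else lz / 6.0
    d = interface_width
    z0 = lz / 2.0

    zgrid = np.linspace(0.0, lz, 4001)
    rho = (0.5 * (rho_dense + rho_dilute)
           - 0.5 * (rho_dense - rho_dilute)
           * np.tanh((np.abs(zgrid - z0) - w) / d))
    number_density = rho / (bead_mass * DA_PER_A3_TO_G_CM3)  # beads / A^3
    area = box[0] * box[1]
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (number_density[1:] + number_density[:-1]) * np.diff(zgrid))])
    expected = cdf[-1] * area
    # fixed total at the profile's expectation: positions are i.i.d. draws
    # from the tanh profile, so per-bin counts fluctuate (sub-)Poisson while
    # the realized total density carries no coherent seed-to-seed offset
    n_beads = int(round(expected))
    cdf /= cdf[-1]

    frames = []
    for _ in range(n_frames):
        u = rng.uniform(size=n_beads)
        z = np.interp(u, cdf, zgrid)
        xy = rng.uniform(size=(n_beads, 2)) * box[:2]
        coords = np.column_stack([xy, z])
        frames.append(SimulationFrame(coordinates=coords, box=box.copy()))

    topo = BeadTopology(
        type_names=["ALA"] * n_beads,
        charges=np.zeros(n_beads),
        sigmas=np.full(n_beads, bead_sigma),
        masses=np.full(n_beads, bead_mass),
        bonds=np.zeros((0, 2), dtype=int),
        bond_r0=np.zeros(0),
        bond_k=np.zeros(0),
        chain_id=np.arange(n_beads),
        chain_kinds=["protein"] * n_beads,
        chain_rigid=[False] * n_beads,
    )
    truth = {"rho_dense": rho_dense, "rho_dilute": rho_dilute,
             "slab_half_width": w, "interface_width": d, "z0": z0,
             "n_beads": n_beads}
    return frames, topo, truth


def synthetic_binodal(
    t_c: float = 160.0,
    rho_c: float = 0.30,
    slope_A: float = 1.5e-3,
    amplitude_B: float = 0.55,
    beta: float = ISING_BETA,
    temperatures: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
):
    """Binodal points from a known critical point, with multiplicative noise.

    rho_{l,v}(T) = rho_c + A (T_c - T) +/- (B/2) (1 - T/T_c)^beta, each
    density multiplied by (1 + noise * N(0,1)). Returns ``(points, truth)``.
    """
    if temperatures is None:
        temperatures = t_c * np.linspace(0.70, 0.97, 8)
    temperatures = np.asarray(temperatures, dtype=float)
    if (temperatures >= t_c).any():
        raise ValueError("all temperatures must be below t_c")
    rng = np.random.default_rng(seed)
    points = []
    for T in temperatures:
        mid = rho_c + slope_A * (t_c - T)
        half = 0.5 * amplitude_B * (1.0 - T / t_c) ** beta
        rv = (mid - half) * (1.0 + noise * rng.normal())
        rl = (mid + half) * (1.0 + noise * rng.normal())
        rv, rl = max(min(rv, rl), 0.0), max(rv, rl)
        points.append(BinodalPoint(float(T), float(rv), float(rl)))
    truth = {"t_c": t_c, "rho_c": rho_c, "slope_A": slope_A,
             "amplitude_B": amplitude_B, "beta": beta, "noise": noise}
    return points, truth


def synthetic_frap(
    t_half: float = 1.5,
    mobile: float = 0.80,
    noise: float = 0.0,
    n_points: int = 21,
    dt: float = 1.0,
    bleach_depth: float = 0.2,
    drift_rate: float = 0.0,
    seed: int = 0,
):
    """Noisy exponential FRAP trace with known t_half and mobile fraction.

    The unbleached channel optionally decays by ``drift_rate`` per second
    (matched multiplicative acquisition bleaching in both channels, which
    ratio normalisation must cancel). Returns ``(trace, truth)``.
    """
    if not 0.0 <= mobile <= 1.0:
        raise ValueError("mobile fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt
    recovery = mobile * (1.0 - 2.0 ** (-t / t_half)) if t_half > 0 \
        else np.full_like(t, mobile)
    ratio = bleach_depth + (1.0 - bleach_depth) * recovery
    unbleached = np.exp(-drift_rate * t)
    bleached = ratio * unbleached
    if noise > 0:
        bleached = bleached * (1.0 + noise * rng.normal(size=n_points))
        bleached = np.clip(bleached, 0.0, None)
    trace = FRAPTrace(time=t, bleached=bleached, unbleached=unbleached,
                      prebleach_bleached=1.0, prebleach_unbleached=1.0)
    truth = {"t_half": t_half, "mobile": mobile, "noise": noise,
             "bleach_depth": bleach_depth, "drift_rate": drift_rate}
    return trace, truth


def random_bead_frame(n_beads: int, box: float = 40.0, seed: int = 0,
                      charged_fraction: float = 0.5):
    """Random single-bead chains in a periodic box, for oracle tests.

    Bead types are drawn from the 20 canonical residues with at least
    ``charged_fraction`` of draws taken from charged types, so both energy
    terms are exercised. Returns ``(frame, topology)``.
    """
    rng = np.random.default_rng(seed)
    table = load_bead_table()
    charged = ["ARG", "LYS", "ASP", "GLU"]
    neutral = ["ALA", "SER", "GLY", "PHE", "LEU", "TYR", "GLN"]
    names = [
        str(rng.choice(charged)) if rng.uniform() < charged_fraction
        else str(rng.choice(neutral))
        for _ in range(n_beads)
    ]
    types = [table[n] for n in names]
    box3 = np.array([box] * 3, dtype=float)
    coords = rng.uniform(size=(n_beads, 3)) * box3
    topo = BeadTopology(
        type_names=names,
        charges=np.array([t.charge for t in types]),
        sigmas=np.array([t.sigma for t in types]),
        masses=np.array([t.mass for t in types]),
        bonds=np.zeros((0, 2), dtype=int),
        bond_r0=np.zeros(0),
        bond_k=np.zeros(0),
        chain_id=np.arange(n_beads),
        chain_kinds=["protein"] * n_beads,
        chain_rigid=[False] * n_beads,
    )
    frame = SimulationFrame(coordinates=coords, box=box3)
    return frame, topo


#: K-containing 20-mer used by the scaled-down coexistence demonstration.
#: Four lysines per chain keep the mixture's critical temperature at a few
#: hundred kelvin — low enough that tripling a condensed-state temperature
#: lands clearly in the one-phase region.
POLYAMPHOLYTE_SEQUENCE = "KGGSG" * 4


#: flexible polyanion strand complementing the K-bearing chains
POLYANION_SEQUENCE = "E" * 16


def polyampholyte_mixture(n_chains: int = 8, n_strands: int = 2,
                          strand_length: int = 16) -> BeadTopology:
    """Charge-complementary demo mixture: K-bearing 20-mers + poly-E strands.

    Eight +4 e peptides against two flexible -16 e polyglutamate strands
    give an exactly neutral mixture whose condensation is driven by
    electrostatic complementarity. Per-bead binding is weak (single-charge
    beads, modest pair depths), so the mixture's critical temperature sits
    at a few hundred kelvin — condensed at 300 K, one-phase at 900 K —
    which makes it the fixture for the scaled-down direct-coexistence
    monotonicity demonstration.
    """
    pep = build_protein_topology(ProteinSequence("K-rich20", POLYAMPHOLYTE_SEQUENCE))
    anion = build_protein_topology(
        ProteinSequence("polyE", POLYANION_SEQUENCE[:strand_length].ljust(
            strand_length, "E")))
    return replicate_topologies([(pep, n_chains), (anion, n_strands)])


def polyampholyte_dna_system(n_chains: int = 8, n_strands: int = 2,
                             strand_bp: int = 8, seed: int = 0) -> BeadTopology:
    """Small charge-complementary test system: K-bearing 20-mers + duplexes.

    Eight +4 e peptides against two -16 e rigid DNA strands give an exactly
    neutral mixture whose condensation is driven by protein-DNA
    electrostatics — a desk-scale analogue of the protein/DNA
    direct-coexistence setup, used for contact-map, valency and
    contact-energy analyses on real dynamics.
    """
    pep = build_protein_topology(ProteinSequence("K-rich20", POLYAMPHOLYTE_SEQUENCE))
    dna = build_dna_duplex(strand_bp, sequence="random", seed=seed)
    return replicate_topologies([(pep, n_chains), (dna, n_strands)])
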