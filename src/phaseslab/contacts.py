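"""Contact-frequency maps, DNA valency, and per-contact energies.

Two beads are in contact when their minimum-image distance is below 1.13
times the mean of their diameters. Pairs within the same chain separated by
two or fewer bonds are never counted (this keeps trivially bonded neighbours
out of the maps). A protein chain counts toward a DNA strand's valency only
when it makes at least ``min_contacts`` (default 3) bead-level contacts with
that strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB
from .energy import ElectrostaticsSpec, debye_huckel_energy, wang_frenkel_energy
from .params import PairTable
from .topology import BeadTopology

CONTACT_FACTOR = 1.13
MIN_BOND_SEPARATION = 3          # same-chain pairs need > 2 bonds between them


@dataclass
class ContactMap:
    row_labels: np.ndarray           # 1-based residue / bp positions
    col_labels: np.ndarray
    frequency: np.ndarray            # contacts per frame per chain pair
    n_frames: int
    selection: str
    temperature_reduced: float | None = None


@dataclass
class ValencyResult:
    per_strand: np.ndarray           # time-averaged recruited-protein counts
    mean_valency: float
    min_contacts: int
    contact_energy_kT: float | None = None

    def __post_init__(self) -> None:
        if (self.per_strand < 0).any():
            raise ValueError("valency counts must be non-negative")


@dataclass
class ContactEnergy:
    mean_kT: float                   # signed (negative = attractive)
    magnitude_kT: float
    n_contacts: int
    temperature: float


def _eligibility(topo: BeadTopology) -> np.ndarray:
    """Boolean (N, N) matrix of pairs allowed to form contacts."""
    chain = topo.chain_id
    pos = topo.bead_position_in_chain()
    same = chain[:, None] == chain[None, :]
    sep = np.abs(pos[:, None] - pos[None, :])
    ok = (~same) | (sep >= MIN_BOND_SEPARATION)
    np.fill_diagonal(ok, False)
    return ok


def _distance_matrix(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = coords[:, None, :] - coords[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=2))


def contact_matrix(frame, topo: BeadTopology,
                   factor: float = CONTACT_FACTOR) -> np.ndarray:
    """Symmetric boolean contact matrix for one frame (1.13 rule)."""
    coords = np.asarray(frame.coordinates, dtype=float)
    box = np.asarray(frame.box, dtype=float)
    r = _distance_matrix(coords, box)
    thresh = factor * 0.5 * (topo.sigmas[:, None] + topo.sigmas[None, :])
    return (r < thresh) & _eligibility(topo)


def _chains_of_kind(topo: BeadTopology, kind: str) -> list[np.ndarray]:
    return [topo.chain_beads(c) for c in range(topo.n_chains)
            if topo.chain_kinds[c] == kind]


def aggregate_contact_map(traj, topo: BeadTopology,
                          selection: str = "protein-protein") -> ContactMap:
    """Time- and chain-pair-averaged contact frequencies.

    ``selection`` is "protein-protein" (symmetric, residue x residue) or
    "protein-dna" (residue x base pair). Frequencies are normalised per
    chain pair per frame, so maps from different system sizes compare
    directly; entries lie in [0, 1].
    """
    prot = _chains_of_kind(topo, "protein")
    dna = _chains_of_kind(topo, "dna")
    if selection == "protein-protein":
        if len(prot) < 2:
            raise ValueError("selection needs at least two protein chains")
        pairs = [(a, b) for i, a in enumerate(prot) for b in prot[i + 1:]]
    elif selection == "protein-dna":
        if not prot or not dna:
            raise ValueError("selection needs protein and DNA chains")
        pairs = [(a, b) for a in prot for b in dna]
    else:
        raise ValueError(f"unknown selection {selection!r}")
    lens = {(len(a), len(b)) for a, b in pairs}
    if len(lens) != 1:
        raise ValueError("all chains of a kind must share one length")
    n_rows, n_cols = lens.pop()
    acc = np.zeros((n_rows, n_cols))
    frames = traj.frames
    for frame in frames:
        cm = contact_matrix(frame, topo)
        for a, b in pairs:
            block = cm[np.ix_(a, b)].astype(float)
            if selection == "protein-protein":
                # average the two chain orderings -> symmetric homotypic map
                block = 0.5 * (block + block.T)
            acc += block
    acc /= len(frames) * len(pairs)
    return ContactMap(np.arange(1, n_rows + 1), np.arange(1, n_cols + 1),
                      acc, len(frames), selection)


def dna_valency(traj, topo: BeadTopology, min_contacts: int = 3) -> ValencyResult:
    """Per-strand protein recruitment under the >=3-bead-contact rule.

    For every frame and DNA strand, a protein chain contributes +1 to that
    strand's valency when it makes at least ``min_contacts`` bead contacts;
    counts are averaged over frames.
    """
    prot = _chains_of_kind(topo, "protein")
    dna = _chains_of_kind(topo, "dna")
    if not dna:
        raise ValueError("topology contains no DNA strands")
    counts = np.zeros(len(dna))
    frames = traj.frames
    for frame in frames:
        cm = contact_matrix(frame, topo)
        for s, strand in enumerate(dna):
            for chain in prot:
                if cm[np.ix_(chain, strand)].sum() >= min_contacts:
                    counts[s] += 1
    counts /= len(frames)
    return ValencyResult(counts, float(counts.mean()), min_contacts)


def mean_contact_energy(traj, topo: BeadTopology, spec: ElectrostaticsSpec,
                        selection: str = "protein-dna",
                        temperature: float | None = None,
                        pair_table: PairTable | None = None) -> ContactEnergy:
    """Mean Wang-Frenkel + Debye-Huckel energy per contact, in kT.

    The kT conversion uses the trajectory's thermostat setpoint (or an
    explicit ``temperature``). Attractive contacts give a negative signed
    mean; the magnitude is reported alongside.
    """
    table = pair_table if pair_table is not None else PairTable.from_table()
    t_idx = np.array([table.index[name] for name in topo.type_names])
    kind = np.array([topo.chain_kinds[c] for c in topo.chain_id])
    if selection == "protein-dna":
        sel_rows, sel_cols = kind == "protein", kind == "dna"
    elif selection == "protein-protein":
        sel_rows = sel_cols = kind == "protein"
    else:
        raise ValueError(f"unknown selection {selection!r}")
    temp = temperature if temperature is not None else traj.temperature
    total = 0.0
    n_contacts = 0
    for frame in traj.frames:
        coords = np.asarray(frame.coordinates, dtype=float)
        box = np.asarray(frame.box, dtype=float)
        cm = contact_matrix(frame, topo)
        cm &= sel_rows[:, None] & sel_cols[None, :]
        iu, ju = np.nonzero(np.triu(cm | cm.T, k=1))
        if len(iu) == 0:
            continue
        d = coords[iu] - coords[ju]
        d -= box * np.round(d / box)
        r = np.sqrt((d * d).sum(axis=1))
        for k in range(len(iu)):
            ti, tj = t_idx[iu[k]], t_idx[ju[k]]
            e = wang_frenkel_energy(r[k], table.eps[ti, tj],
                                    table.sigma[ti, tj], table.mu[ti, tj],
                                    table.nu[ti, tj])
            e += debye_huckel_energy(r[k], topo.charges[iu[k]],
                                     topo.charges[ju[k]], spec)
            total += e
        n_contacts += len(iu)
    if n_contacts == 0:
        raise ValueError("no contacts observed in the selection")
    mean = total / n_contacts / (KB * temp)
    return ContactEnergy(float(mean), float(abs(mean)), n_contacts, temp)
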