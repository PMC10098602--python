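"""Coarse-grained bead topologies: one bead per protein residue, one per DNA bp.

A :class:`BeadTopology` is a flat, array-backed description of all chains in a
system: per-bead type names, charges, diameters and masses, harmonic bonds
between consecutive beads of a chain, and per-chain kind/rigidity flags. DNA
duplexes are flagged rigid (at 24 bp a duplex is much shorter than its
persistence length, so bending is neglected and each duplex moves as a rigid
body).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import (
    BeadType,
    DNA_RISE,
    K_BOND_DNA,
    K_BOND_PROTEIN,
    R0_PROTEIN,
    load_bead_table,
)
from .sequences import PHOSPHOSERINE, ProteinSequence

DNA_BASES = "ACGT"


@dataclass
class BeadTopology:
    """Chains of typed beads with harmonic bonds.

    Arrays are indexed by global bead index; ``chain_id`` maps each bead to
    its chain, and chain-level metadata lives in the ``chain_*`` lists.
    """

    type_names: list[str]                 # per bead
    charges: np.ndarray                   # e
    sigmas: np.ndarray                    # A
    masses: np.ndarray                    # Da
    bonds: np.ndarray                     # (n_bonds, 2) int
    bond_r0: np.ndarray                   # A
    bond_k: np.ndarray                    # kcal/mol/A^2
    chain_id: np.ndarray                  # per bead, int
    chain_kinds: list[str]                # "protein" | "dna", per chain
    chain_rigid: list[bool]               # per chain
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.type_names)
        for arr, name in ((self.charges, "charges"), (self.sigmas, "sigmas"),
                          (self.masses, "masses"), (self.chain_id, "chain_id")):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != bead count {n}")
        for a, b in self.bonds:
            if self.chain_id[a] != self.chain_id[b] or abs(int(a) - int(b)) != 1:
                raise ValueError("bonds may only join consecutive beads of one chain")

    @property
    def n_beads(self) -> int:
        return len(self.type_names)

    @property
    def n_chains(self) -> int:
        return len(self.chain_kinds)

    def total_charge(self) -> float:
        return float(self.charges.sum())

    def chain_beads(self, chain: int) -> np.ndarray:
        return np.flatnonzero(self.chain_id == chain)

    def bead_position_in_chain(self) -> np.ndarray:
        """1-based position of every bead within its own chain."""
        pos = np.zeros(self.n_beads, dtype=int)
        for c in range(self.n_chains):
            idx = self.chain_beads(c)
            pos[idx] = np.arange(1, len(idx) + 1)
        return pos

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "type_names": self.type_names,
            "charges": self.charges.tolist(),
            "sigmas": self.sigmas.tolist(),
            "masses": self.masses.tolist(),
            "bonds": self.bonds.tolist(),
            "bond_r0": self.bond_r0.tolist(),
            "bond_k": self.bond_k.tolist(),
            "chain_id": self.chain_id.tolist(),
            "chain_kinds": self.chain_kinds,
            "chain_rigid": self.chain_rigid,
            "metadata": self.metadata,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BeadTopology":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        return cls(
            type_names=list(doc["type_names"]),
            charges=np.array(doc["charges"], dtype=float),
            sigmas=np.array(doc["sigmas"], dtype=float),
            masses=np.array(doc["masses"], dtype=float),
            bonds=np.array(doc["bonds"], dtype=int).reshape(-1, 2),
            bond_r0=np.array(doc["bond_r0"], dtype=float),
            bond_k=np.array(doc["bond_k"], dtype=float),
            chain_id=np.array(doc["chain_id"], dtype=int),
            chain_kinds=list(doc["chain_kinds"]),
            chain_rigid=[bool(x) for x in doc["chain_rigid"]],
            metadata=dict(doc.get("metadata", {})),
        )


def build_protein_topology(
    seq: ProteinSequence,
    table: dict[str, BeadType] | None = None,
) -> BeadTopology:
    """One bead per residue, N-1 backbone bonds at r0 = 3.81 A."""
    table = table if table is not None else load_bead_table()
    try:
        types = [table[aa] for aa in seq.residues]
    except KeyError as exc:
        raise ValueError(f"unknown residue code {exc.args[0]!r}") from exc
    n = len(types)
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)]) if n > 1 \
        else np.zeros((0, 2), dtype=int)
    return BeadTopology(
        type_names=[t.name for t in types],
        charges=np.array([t.charge for t in types]),
        sigmas=np.array([t.sigma for t in types]),
        masses=np.array([t.mass for t in types]),
        bonds=bonds.astype(int),
        bond_r0=np.full(len(bonds), R0_PROTEIN),
        bond_k=np.full(len(bonds), K_BOND_PROTEIN),
        chain_id=np.zeros(n, dtype=int),
        chain_kinds=["protein"],
        chain_rigid=[False],
        metadata={"sequence": seq.residues, "identifier": seq.identifier},
    )


def apply_phosphorylation(
    topo: BeadTopology,
    sites: list[int],
    table: dict[str, BeadType] | None = None,
) -> BeadTopology:
    """Retype serine beads at 1-based ``sites`` to phosphoserine (SEP).

    Bead count and bonds are unchanged; each site must currently be a serine.
    Sites index residues within the (single-protein-chain) topology.
    """
    table = table if table is not None else load_bead_table()
    sep = table["SEP"]
    new = BeadTopology.from_json(topo.to_json())  # deep copy via round-trip
    for site in sites:
        i = site - 1
        if i < 0 or i >= topo.n_beads:
            raise ValueError(f"site {site} out of range")
        if topo.type_names[i] != "SER":
            raise ValueError(
                f"site {site} is {topo.type_names[i]}, not SER; cannot phosphorylate")
        new.type_names[i] = sep.name
        new.charges[i] = sep.charge
        new.sigmas[i] = sep.sigma
        new.masses[i] = sep.mass
    seq = new.metadata.get("sequence")
    if seq:
        chars = list(seq)
        for site in sites:
            chars[site - 1] = PHOSPHOSERINE
        new.metadata["sequence"] = "".join(chars)
    new.metadata["phosphosites"] = sorted(int(s) for s in sites)
    return new


def build_dna_duplex(
    n_bp: int,
    sequence: str = "random",
    seed: int = 0,
    table: dict[str, BeadType] | None = None,
) -> BeadTopology:
    """Rigid duplex of ``n_bp`` beads, one per base pair, -2 e each.

    The base-pair sequence is metadata only (all bp beads share the BP type);
    ``sequence="random"`` draws it reproducibly from ``seed``.
    """
    if n_bp < 2:
        raise ValueError("a duplex needs at least 2 base pairs")
    table = table if table is not None else load_bead_table()
    bp = table["BP"]
    if sequence == "random":
        rng = np.random.default_rng(seed)
        sequence = "".join(rng.choice(list(DNA_BASES), size=n_bp))
    elif len(sequence) != n_bp:
        raise ValueError("explicit sequence length must equal n_bp")
    bonds = np.column_stack([np.arange(n_bp - 1), np.arange(1, n_bp)]).astype(int)
    return BeadTopology(
        type_names=[bp.name] * n_bp,
        charges=np.full(n_bp, bp.charge),
        sigmas=np.full(n_bp, bp.sigma),
        masses=np.full(n_bp, bp.mass),
        bonds=bonds,
        bond_r0=np.full(len(bonds), DNA_RISE),
        bond_k=np.full(len(bonds), K_BOND_DNA),
        chain_id=np.zeros(n_bp, dtype=int),
        chain_kinds=["dna"],
        chain_rigid=[True],
        metadata={"sequence": sequence},
    )


def replicate_topologies(parts: list[tuple[BeadTopology, int]]) -> BeadTopology:
    """Concatenate ``copies`` of each component topology into one system.

    ``parts`` is a list of (single- or multi-chain topology, copy count).
    """
    type_names: list[str] = []
    charges, sigmas, masses = [], [], []
    bonds, bond_r0, bond_k = [], [], []
    chain_id: list[int] = []
    chain_kinds: list[str] = []
    chain_rigid: list[bool] = []
    bead_offset = 0
    chain_offset = 0
    for topo, copies in parts:
        for _ in range(copies):
            type_names.extend(topo.type_names)
            charges.append(topo.charges)
            sigmas.append(topo.sigmas)
            masses.append(topo.masses)
            if len(topo.bonds):
                bonds.append(topo.bonds + bead_offset)
                bond_r0.append(topo.bond_r0)
                bond_k.append(topo.bond_k)
            chain_id.extend((topo.chain_id + chain_offset).tolist())
            chain_kinds.extend(topo.chain_kinds)
            chain_rigid.extend(topo.chain_rigid)
            bead_offset += topo.n_beads
            chain_offset += topo.n_chains
    return BeadTopology(
        type_names=type_names,
        charges=np.concatenate(charges),
        sigmas=np.concatenate(sigmas),
        masses=np.concatenate(masses),
        bonds=np.concatenate(bonds) if bonds else np.zeros((0, 2), dtype=int),
        bond_r0=np.concatenate(bond_r0) if bond_r0 else np.zeros(0),
        bond_k=np.concatenate(bond_k) if bond_k else np.zeros(0),
        chain_id=np.array(chain_id, dtype=int),
        chain_kinds=chain_kinds,
        chain_rigid=chain_rigid,
    )
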