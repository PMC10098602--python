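"""Bead types and the pair-interaction parameter table.

The per-type table ships as a versioned CSV (``data/bead_params_synthetic.csv``;
a synthetic, self-documented parameterization — see the file header). Pairwise
Wang-Frenkel parameters are built from it with declared combination rules:

* contact distance ``sigma_ij`` — arithmetic mean of the bead diameters;
* depth ``eps_ij = EPS0 * sqrt(s_i * s_j) * boost`` where ``s`` is the
  per-type stickiness and ``boost`` enhances cation-pi (x1.6) and pi-pi
  (x1.5) pairs, mimicking the interaction hierarchy of residue-resolution
  LLPS force fields;
* exponents ``mu = 2``, ``nu = 1`` for every pair.

The table is data, not code: an alternative CSV with the same columns can be
swapped in via :func:`load_bead_table`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: overall energy scale of the pair-depth combination rule, kcal/mol
EPS0 = 0.55
CATION_PI_BOOST = 1.6
PI_PI_BOOST = 1.5
#: Wang-Frenkel exponents (per pair; uniform in the shipped table)
MU_DEFAULT = 2
NU_DEFAULT = 1

#: harmonic bond constant U = k (r - r0)^2, kcal/mol/A^2 (protein backbone)
K_BOND_PROTEIN = 19.1
#: protein backbone pseudo-bond length, A
R0_PROTEIN = 3.81
#: canonical helical rise per base pair, A
DNA_RISE = 3.4
#: nominal bond constant stored for DNA (duplexes are propagated rigidly)
K_BOND_DNA = 100.0


@dataclass(frozen=True)
class BeadType:
    name: str       # three-letter-ish type name (ALA ... SEP, BP)
    code: str       # one-letter sequence code
    kind: str       # "protein" | "dna"
    charge: float   # elementary charges
    sigma: float    # A
    mass: float     # Da
    stickiness: float
    cls: str        # aliphatic | aromatic | cation | anion | polar

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.mass <= 0:
            raise ValueError(f"{self.name}: sigma and mass must be positive")


def default_table_path() -> Path:
    return Path(str(resources.files("phaseslab").joinpath(
        "data/bead_params_synthetic.csv")))


def table_checksum(path: str | Path | None = None) -> str:
    path = Path(path) if path is not None else default_table_path()
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_bead_table(path: str | Path | None = None) -> dict[str, BeadType]:
    """Load bead types keyed by both type name and one-letter code."""
    path = Path(path) if path is not None else default_table_path()
    df = pd.read_csv(path, comment="#")
    table: dict[str, BeadType] = {}
    for row in df.itertuples(index=False):
        bt = BeadType(row.name, row.code, row.kind, float(row.charge),
                      float(row.sigma), float(row.mass),
                      float(row.stickiness), row.cls)
        table[bt.name] = bt
        table[bt.code] = bt
    return table


def pair_epsilon(a: BeadType, b: BeadType) -> float:
    """Combined Wang-Frenkel depth for a type pair (symmetric)."""
    boost = 1.0
    classes = {a.cls, b.cls}
    if classes == {"cation", "aromatic"}:
        boost = CATION_PI_BOOST
    elif classes == {"aromatic"}:
        boost = PI_PI_BOOST
    return EPS0 * float(np.sqrt(a.stickiness * b.stickiness)) * boost


def pair_sigma(a: BeadType, b: BeadType) -> float:
    return 0.5 * (a.sigma + b.sigma)


class PairTable:
    """Dense symmetric pair-parameter matrices over an ordered type list."""

    def __init__(self, types: list[BeadType]):
        self.types = types
        self.index = {t.name: i for i, t in enumerate(types)}
        n = len(types)
        self.eps = np.zeros((n, n))
        self.sigma = np.zeros((n, n))
        self.mu = np.full((n, n), float(MU_DEFAULT))
        self.nu = np.full((n, n), float(NU_DEFAULT))
        for i, a in enumerate(types):
            for j, b in enumerate(types):
                self.eps[i, j] = pair_epsilon(a, b)
                self.sigma[i, j] = pair_sigma(a, b)

    @classmethod
    def from_table(cls, table: dict[str, BeadType] | None = None) -> "PairTable":
        table = table if table is not None else load_bead_table()
        uniq = sorted({bt.name for bt in table.values()})
        return cls([table[name] for name in uniq])
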