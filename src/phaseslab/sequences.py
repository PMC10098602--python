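"""Protein sequences and per-fragment physicochemical scorers.

The sequence alphabet is the 20 canonical one-letter amino-acid codes plus
``"J"`` for phosphoserine (unassigned in the IUPAC alphabet, so round-trips
safely through FASTA). Scorers operate on :class:`ProteinSequence` fragments
and are the building blocks of the windowed profiles in
:mod:`phaseslab.profiles`.

Charge handling follows Henderson-Hasselbalch titration with a vendored
Lehninger-style pKa set; phosphoserine carries two acidic pKa values so its
side chain titrates toward -2 e around physiological pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHOSERINE = "J"
ALPHABET = frozenset(CANONICAL + PHOSPHOSERINE)

#: Full-length human HMGA1a (canonical UniProt P17096, 107 residues).
HMGA1A_SEQUENCE = (
    "MSESSSKSSQPLASKQEKDGTEKRGRGRPRKQPPVSPGTALVGSQKEPSE"
    "VPTPKRPRGRPKGSKNKGAAKTRKTTTTPGRKPRGRPKKLEKEEEEGISQ"
    "ESSEEEQ"
)

#: CK2 phosphorylation sites in the acidic C-terminal tail (1-based).
HMGA1A_PHOSPHOSITES = (99, 102, 103)

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Lehninger-style pKa values. Termini use the glycine alpha-amino/alpha-
# carboxyl values; phosphoserine's second phosphate pKa of 5.96 puts its
# charge near -2 at pH 7.4.
PKA_NTERM = 9.69
PKA_CTERM = 2.34
PKA_ACIDIC = {"D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07}
PKA_BASIC = {"K": 10.53, "R": 12.48, "H": 6.00}
PKA_PHOSPHOSERINE = (2.19, 5.96)  # two acidic protons of the phosphate

#: Entropy threshold (bits) below which a fragment is flagged low-complexity.
LOW_COMPLEXITY_ENTROPY_BITS = 2.9


@dataclass(frozen=True)
class ProteinSequence:
    """An identified protein chain over the 21-letter alphabet."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"{self.identifier!r}: empty sequence")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in ALPHABET:
                raise ValueError(
                    f"{self.identifier!r}: invalid residue code {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def fragment(self, start: int, length: int) -> "ProteinSequence":
        """Sub-sequence of ``length`` residues starting at 1-based ``start``."""
        if start < 1 or start + length - 1 > len(self):
            raise ValueError("fragment out of range")
        return ProteinSequence(
            f"{self.identifier}[{start}:{start + length - 1}]",
            self.residues[start - 1: start - 1 + length],
        )


def hmga1a(phosphorylated: bool = False) -> ProteinSequence:
    """The wildtype (or Ser99/102/103-phosphorylated) HMGA1a chain."""
    residues = HMGA1A_SEQUENCE
    name = "HMGA1a"
    if phosphorylated:
        chars = list(residues)
        for site in HMGA1A_PHOSPHOSITES:
            assert chars[site - 1] == "S"
            chars[site - 1] = PHOSPHOSERINE
        residues = "".join(chars)
        name = "HMGA1a-3P"
    return ProteinSequence(name, residues)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file.

    Residues are uppercased; record order is preserved. Raises ``ValueError``
    for an empty file or for any residue outside the alphabet (the error
    names the offending record and position).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return [ProteinSequence(rec.id, str(rec.seq).upper()) for rec in records]


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="")
        for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# scorers
# ---------------------------------------------------------------------------

def hydropathy_score(fragment: ProteinSequence) -> float:
    """Mean Kyte-Doolittle hydropathy; phosphoserine scored as serine."""
    vals = [KYTE_DOOLITTLE["S" if aa == PHOSPHOSERINE else aa]
            for aa in fragment.residues]
    return sum(vals) / len(vals)


def shannon_entropy(fragment: ProteinSequence) -> float:
    """Shannon entropy (bits) of the residue composition.

    Phosphoserine counts as serine so the value is bounded by log2(20)
    regardless of modification state.
    """
    counts: dict[str, int] = {}
    for aa in fragment.residues:
        aa = "S" if aa == PHOSPHOSERINE else aa
        counts[aa] = counts.get(aa, 0) + 1
    n = len(fragment.residues)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def is_low_complexity(fragment: ProteinSequence,
                      threshold_bits: float = LOW_COMPLEXITY_ENTROPY_BITS) -> bool:
    return shannon_entropy(fragment) < threshold_bits


def _titratable_groups(seq: ProteinSequence) -> list[tuple[float, int]]:
    """(pKa, sign) for every ionizable group of the chain, termini included."""
    groups: list[tuple[float, int]] = [(PKA_NTERM, +1), (PKA_CTERM, -1)]
    for aa in seq.residues:
        if aa in PKA_BASIC:
            groups.append((PKA_BASIC[aa], +1))
        elif aa in PKA_ACIDIC:
            groups.append((PKA_ACIDIC[aa], -1))
        elif aa == PHOSPHOSERINE:
            groups.extend((pka, -1) for pka in PKA_PHOSPHOSERINE)
    return groups


def net_charge(seq: ProteinSequence, pH: float) -> float:
    """Henderson-Hasselbalch net charge (elementary charges) at ``pH``.

    Basic groups contribute +1/(1+10^(pH-pKa)), acidic groups
    -1/(1+10^(pKa-pH)); strictly decreasing in pH.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    q = 0.0
    for pka, sign in _titratable_groups(seq):
        if sign > 0:
            q += 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            q -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return q


def isoelectric_point(seq: ProteinSequence, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    q_lo, q_hi = net_charge(seq, lo), net_charge(seq, hi)
    if q_lo < 0 or q_hi > 0:
        raise ValueError("net charge does not change sign on [0, 14]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
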