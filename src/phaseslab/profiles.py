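"""Windowed per-fragment sequence profiling.

A sequence of length L is scanned with sliding fragments (step 1, default
length 30); each fragment is reduced to one number by a pluggable scorer and
the raw fragment series is smoothed by a centered running mean (default
window 7). Each smoothed score is assigned to the fragment's central residue,
so a track covers positions ``1+fragment_length//2`` through
``L-fragment_length+1+fragment_length//2``.

At track edges the running-mean window shrinks symmetrically: position i
averages over the ``min(i, n-1-i, (window-1)//2)`` neighbours available on
both sides, which preserves track length and keeps a window of 1 a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .sequences import (
    ProteinSequence,
    hydropathy_score,
    isoelectric_point,
    net_charge,
    shannon_entropy,
)

FragmentScorer = Callable[[ProteinSequence], float]

#: Scorers addressable by name from the CLI / profile_tracks.
NAMED_SCORERS: dict[str, FragmentScorer] = {
    "hydropathy": hydropathy_score,
    "entropy": shannon_entropy,
    "charge": lambda frag: net_charge(frag, 7.4),
    "pi": isoelectric_point,
}


@dataclass(frozen=True)
class ProfileTrack:
    positions: np.ndarray        # 1-based central-residue indices
    values: np.ndarray
    fragment_length: int
    smoothing_window: int
    scorer_name: str

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")


def running_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with symmetric edge shrinkage."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    n = len(values)
    half = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h: i + h + 1].mean()
    return out


def windowed_profile(
    seq: ProteinSequence,
    scorer: FragmentScorer,
    fragment_length: int = 30,
    smoothing_window: int = 7,
    scorer_name: str = "custom",
) -> ProfileTrack:
    """Sliding-fragment profile of ``seq`` under ``scorer``.

    One raw score per fragment start (step 1), smoothed by a centered running
    mean, mapped to fragment centers.
    """
    if fragment_length < 1 or fragment_length > len(seq):
        raise ValueError(
            f"fragment_length {fragment_length} exceeds sequence length {len(seq)}"
        )
    n_frag = len(seq) - fragment_length + 1
    raw = np.array([
        scorer(seq.fragment(start, fragment_length))
        for start in range(1, n_frag + 1)
    ])
    smoothed = running_mean(raw, smoothing_window)
    centers = np.arange(1, n_frag + 1) + fragment_length // 2
    return ProfileTrack(centers, smoothed, fragment_length, smoothing_window,
                        scorer_name)


def profile_tracks(
    seq: ProteinSequence,
    tracks: Sequence[str] = ("hydropathy", "entropy", "charge"),
    fragment_length: int = 30,
    smoothing_window: int = 7,
) -> pd.DataFrame:
    """Tidy per-position table (position, residue, track, value) of named tracks."""
    rows = []
    for name in tracks:
        try:
            scorer = NAMED_SCORERS[name]
        except KeyError:
            raise ValueError(f"unknown track {name!r}; choose from {sorted(NAMED_SCORERS)}")
        track = windowed_profile(seq, scorer, fragment_length, smoothing_window,
                                 scorer_name=name)
        for pos, val in zip(track.positions, track.values):
            rows.append({
                "position": int(pos),
                "residue": seq.residues[int(pos) - 1],
                "track": name,
                "value": float(val),
            })
    return pd.DataFrame(rows, columns=["position", "residue", "track", "value"])


def write_profile_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
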