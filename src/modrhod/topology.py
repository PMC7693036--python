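"""Transmembrane topology validation by hydropathy.

A candidate microbial rhodopsin must show seven transmembrane helices and a
retinal-binding lysine (the Schiff-base lysine) inside the seventh helix.
Helices are delimited by Kyte–Doolittle hydropathy: a sliding-window mean is
thresholded, near-adjacent super-threshold runs are merged, and short runs
are discarded.  The window/threshold/min-length defaults are the canonical
Kyte–Doolittle settings for transmembrane detection (window 19, threshold
1.6, minimum helix length 15); the source analysis names no segmentation
parameters, so these are free, overridable parameters rather than claims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ProteinRecord, ValidationError

#: Kyte–Doolittle hydropathy scale; X (unknown) scores 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MIN_LEN = 15
DEFAULT_MAX_GAP = 3


@dataclass(frozen=True)
class HydropathyProfile:
    """Per-residue smoothed hydropathy scores for one sequence."""

    scores: np.ndarray
    window: int

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class TMTopology:
    """Ordered transmembrane helix intervals, 1-based inclusive."""

    helices: tuple[tuple[int, int], ...]
    retinal_lysine_position: int | None = None

    @property
    def n_helices(self) -> int:
        return len(self.helices)

    def covered(self) -> int:
        """Total number of residues inside helices."""
        return sum(e - s + 1 for s, e in self.helices)


def hydropathy_profile(record: ProteinRecord, window: int = DEFAULT_WINDOW) -> HydropathyProfile:
    """Sliding-window mean Kyte–Doolittle hydropathy.

    ``window`` must be odd and no longer than the sequence; positions within
    half a window of either terminus are scored with a shrunken window so
    every residue carries a defined score.
    """
    n = len(record.sequence)
    if window % 2 == 0 or window < 5:
        raise ValidationError(f"window must be odd and >= 5, got {window}")
    if window > n:
        raise ValidationError(f"window {window} exceeds sequence length {n}")
    raw = np.array([KYTE_DOOLITTLE[ch] for ch in record.sequence])
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(raw)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    scores = (csum[hi] - csum[lo]) / (hi - lo)
    return HydropathyProfile(scores=scores, window=window)


def segment_helices(
    profile: HydropathyProfile,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    max_gap: int = DEFAULT_MAX_GAP,
) -> TMTopology:
    """Delimit helices as maximal super-threshold runs.

    Runs separated by at most ``max_gap`` sub-threshold residues are merged
    (the gap residues are absorbed into the helix); merged runs shorter than
    ``min_len`` are discarded.  Deterministic; an empty helix list is a valid
    result for hydrophilic sequences.
    """
    above = profile.scores >= threshold
    runs: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= max_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    helices = tuple(
        (s + 1, e + 1) for s, e in merged if e - s + 1 >= min_len
    )
    return TMTopology(helices=helices)


def validate_rhodopsin(
    record: ProteinRecord, topology: TMTopology
) -> tuple[bool, list[str]]:
    """Apply the rhodopsin candidacy criterion.

    True iff exactly seven helices were found and at least one lysine lies
    within the seventh (last) helix interval; the reasons list enumerates
    every failed criterion.
    """
    reasons: list[str] = []
    if topology.n_helices != 7:
        reasons.append(f"helix count {topology.n_helices} != 7")
    else:
        start, end = topology.helices[-1]
        if "K" not in record.sequence[start - 1:end]:
            reasons.append("no retinal lysine in helix 7")
    return (not reasons, reasons)


def detect(
    record: ProteinRecord,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[TMTopology, bool, list[str]]:
    """Profile, segment and validate one record in a single call."""
    topo = segment_helices(
        hydropathy_profile(record, window), threshold, min_len, max_gap
    )
    ok, reasons = validate_rhodopsin(record, topo)
    if ok:
        start, end = topo.helices[-1]
        k_off = record.sequence.index("K", start - 1, end)
        topo = TMTopology(helices=topo.helices, retinal_lysine_position=k_off + 1)
    return topo, ok, reasons
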