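"""Heart-rate series post-processing: HR-RAW and HR-CLEAN.

The per-window estimates from the two cheeks are merged into a single
trend (HR-RAW) by element-wise averaging followed by a 5-point moving
average, then cleaned (HR-CLEAN) by (1) dropping sentinel zeros — the
first interval of a recording is always 0 — and (2) iteratively removing
any interval deviating by more than 10% from the mean of its retained
neighbours.  The 10% rule reflects the physiological bound of roughly
10 bpm beat-to-beat fluctuation in a resting subject: larger jumps between
3.3 s windows indicate a lost or corrupted region of interest, not a real
heart-rate change.  Values are removed, never replaced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import InputError, TooShortSeriesError

#: Relative deviation from the adjacent-interval mean above which an
#: interval is discarded.
CLEAN_THRESHOLD = 0.10
#: Moving-average length in intervals.
MA_WINDOW = 5


@dataclass
class HRRaw:
    """Left/right-averaged, moving-averaged HR trend for one subject."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class HRClean:
    """Cleaned HR series plus the positions retained from the raw trend."""

    values: np.ndarray
    kept_indices: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        if np.any(self.values == 0):
            raise InputError("cleaned series must contain no zeros")
        if np.any(np.diff(self.kept_indices) <= 0):
            raise InputError("kept_indices must be strictly increasing")


def average_cheeks(left: Sequence[float], right: Sequence[float]
                   ) -> np.ndarray:
    """Element-wise mean of the two cheek series.

    A sentinel 0 on exactly one side means that cheek's ROI was unusable;
    the valid side's value is used alone.  Both sides 0 stays 0.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise InputError(f"length mismatch: {left.shape} vs {right.shape}")
    both = (left != 0) & (right != 0)
    out = left + right          # covers the one-sided and both-zero cases
    out[both] = (left[both] + right[both]) / 2.0
    return out


def moving_average5(values: Sequence[float], subject_id: str = "",
                    window: int = MA_WINDOW) -> HRRaw:
    """Centred 5-point moving average, truncated at the edges.

    Position i averages values[max(0, i-2) : i+3], so the output has the
    same length as the input and edge positions use the part of the window
    that exists.  Sentinel zeros are missing measurements, not values:
    they are excluded from every window mean, and a position that is
    itself 0 stays 0 in the trend (the trend of a recording therefore
    starts with the 0 of its first, warm-up window).  Without this, one
    dropout window would drag five trend values below their neighbours
    and the 10% cleaning rule would discard all of them.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise InputError("input must be a non-empty 1-D series")
    half = window // 2
    out = np.empty_like(v)
    for i in range(v.size):
        if v[i] == 0:
            out[i] = 0.0
            continue
        w = v[max(0, i - half): i + half + 1]
        w = w[w != 0]
        out[i] = w.mean()
    return HRRaw(values=out, subject_id=subject_id)


def _neighbour_mean(vals: List[float], i: int) -> float:
    """Mean of the retained neighbours of position i (single neighbour at
    the boundaries)."""
    if 0 < i < len(vals) - 1:
        return (vals[i - 1] + vals[i + 1]) / 2.0
    if i == 0:
        return vals[1]
    return vals[-2]


def clean_hr(hr_raw, subject_id: str = "",
             threshold: float = CLEAN_THRESHOLD) -> HRClean:
    """Remove sentinel zeros and >10%-deviating intervals from a raw trend.

    After zero removal the series is scanned left to right: an interior
    interval i is removed when |v_i - m| > threshold * m, where m is the
    mean of the previous retained and next surviving neighbour; after a
    removal the new occupant of position i is re-examined with its new
    neighbours.  Boundary intervals are then checked against their single
    neighbour with the same rule.  Scans repeat until a full pass removes
    nothing, so the result is a fixpoint (re-cleaning changes nothing).
    """
    values = hr_raw.values if isinstance(hr_raw, HRRaw) else hr_raw
    if isinstance(hr_raw, HRRaw) and not subject_id:
        subject_id = hr_raw.subject_id
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise InputError("series must be 1-D")
    keep = v != 0
    vals = list(v[keep])
    idxs = list(np.nonzero(keep)[0])
    if len(vals) < 3:
        raise TooShortSeriesError(
            f"only {len(vals)} nonzero intervals; need >= 3")

    def deviates(i: int) -> bool:
        m = _neighbour_mean(vals, i)
        return abs(vals[i] - m) > threshold * m

    changed = True
    while changed:
        changed = False
        # interior scan with in-place re-evaluation after each removal
        i = 1
        while i < len(vals) - 1:
            if deviates(i):
                del vals[i], idxs[i]
                changed = True
                if len(vals) < 3:
                    raise TooShortSeriesError(
                        "cleaning left fewer than 3 intervals")
            else:
                i += 1
        # boundary intervals against their single neighbour
        for b in (len(vals) - 1, 0):
            if len(vals) >= 2 and deviates(b):
                del vals[b], idxs[b]
                changed = True
                if len(vals) < 3:
                    raise TooShortSeriesError(
                        "cleaning left fewer than 3 intervals")
    return HRClean(values=np.array(vals), kept_indices=np.array(idxs),
                   subject_id=subject_id)


def postprocess(left: Sequence[float], right: Sequence[float],
                subject_id: str = "") -> Tuple[HRRaw, HRClean]:
    """Full chain: cheek averaging -> 5-point trend -> cleaning."""
    merged = average_cheeks(left, right)
    raw = moving_average5(merged, subject_id=subject_id)
    return raw, clean_hr(raw)
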