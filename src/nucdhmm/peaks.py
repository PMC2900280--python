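"""Read-coverage peak machinery for nucleosome-map evaluation.

From a mononucleosome read set one builds the *reads-occupancy* track (the
number of reads covering each position), smooths it with a 147-bp moving
average, and calls "well-defined" nucleosomes: sharp peaks whose height is
at least 1.9 (at least two well-overlapping reads; the overlap can be under
147 bp, hence 1.9 rather than 2.0) and whose flanks drop with absolute
slope above 0.01 per bp over a 20-bp span (20 bp being the average yeast
linker length).

A second caller turns any occupancy-score track (e.g. the posterior
occupancy from the duration HMM) into predicted nucleosome centers: local
maxima of the 147-bp moving average, greedily thinned so that no two
surviving centers lie within a minimum separation (127 bp).
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np


def reads_occupancy(intervals: Sequence[Tuple[int, int]],
                    genome_length: int) -> np.ndarray:
    """Per-position read-coverage counts (1-based closed intervals in)."""
    diff = np.zeros(genome_length + 2, dtype=np.int64)
    for s, e in intervals:
        if s < 1 or e > genome_length or s > e:
            raise ValueError(f"interval ({s}, {e}) outside [1, {genome_length}]")
        diff[s] += 1
        diff[e + 1] -= 1
    return np.cumsum(diff[:genome_length + 1])[1:]


def moving_average(vec: np.ndarray, window: int = 147) -> np.ndarray:
    """Centered moving average; edges average over the truncated window."""
    vec = np.asarray(vec, dtype=float)
    n = len(vec)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > n:
        raise ValueError("window exceeds vector length")
    half = window // 2
    cs = np.concatenate([[0.0], np.cumsum(vec)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def local_maxima(vec: np.ndarray) -> List[Tuple[int, float]]:
    """(0-based position, value) of local maxima.

    A point qualifies if it is >= both neighbors with at least one strict
    inequality; a flat plateau flanked by lower values collapses to its
    midpoint (leftmost midpoint for even plateaus).  Sequence boundaries act
    as "missing" neighbors: a plateau touching a boundary qualifies if its
    one real flank is lower.
    """
    vec = np.asarray(vec, dtype=float)
    n = len(vec)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and vec[j + 1] == vec[i]:
            j += 1
        left_lower = i == 0 or vec[i - 1] < vec[i]
        right_lower = j == n - 1 or vec[j + 1] < vec[j]
        strict = (i > 0 and vec[i - 1] < vec[i]) or (j < n - 1 and vec[j + 1] < vec[j])
        if left_lower and right_lower and strict:
            out.append(((i + j) // 2, float(vec[i])))
        i = j + 1
    return out


def well_defined_nucleosomes(avg: np.ndarray, slope_min: float = 0.01,
                             height_min: float = 1.9,
                             flank: int = 20) -> List[int]:
    """Centers (0-based) of sharp, high peaks in a smoothed coverage track.

    A local maximum at p with height >= ``height_min`` is kept when the
    absolute slopes (avg[p] - avg[p -/+ flank]) / flank both exceed
    ``slope_min``.  Peaks within ``flank`` of either end are skipped.
    """
    avg = np.asarray(avg, dtype=float)
    n = len(avg)
    out = []
    for p, h in local_maxima(avg):
        if h < height_min or p - flank < 0 or p + flank >= n:
            continue
        slope_up = (avg[p] - avg[p - flank]) / flank
        slope_down = (avg[p] - avg[p + flank]) / flank
        if abs(slope_up) > slope_min and abs(slope_down) > slope_min:
            out.append(p)
    return out


def occupancy_peak_caller(occ: np.ndarray, min_sep: int = 127,
                          window: int = 147) -> List[int]:
    """Predicted nucleosome centers (0-based) from an occupancy-score track.

    The track is smoothed with a 147-bp moving average; local maxima become
    candidate centers; then, repeatedly, of two surviving centers strictly
    closer than ``min_sep`` the one with the smaller smoothed value is
    discarded (value ties discard the rightmost).  Centers exactly
    ``min_sep`` apart both survive.
    """
    occ = np.asarray(occ, dtype=float)
    if len(occ) == 0:
        return []
    if len(occ) < window:
        window = len(occ) if len(occ) % 2 == 1 else len(occ) - 1
        if window < 1:
            return []
    avg = moving_average(occ, window)
    return thin_peaks(local_maxima(avg), min_sep)


def thin_peaks(candidates: Sequence[Tuple[int, float]],
               min_sep: int = 127) -> List[int]:
    """Greedy conflict resolution among (position, value) candidates.

    Processing by decreasing value (leftmost first on ties) realizes the
    discard-the-smaller-of-a-conflicting-pair rule deterministically; a
    candidate survives iff no surviving higher-ranked candidate lies
    strictly within ``min_sep``.
    """
    order = sorted(candidates, key=lambda pv: (-pv[1], pv[0]))
    kept: List[int] = []
    for p, _v in order:
        if all(abs(p - q) >= min_sep for q in kept):
            kept.append(p)
    return sorted(kept)
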