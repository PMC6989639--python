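"""Shift-tolerant similarity between signature signals across experiments.

Wavenumber calibration differs slightly between experiments, shifting the same
analyte's peaks by a few (typically fewer than ten) frequency channels and
ruining a naive Pearson correlation.  The similarity metric here translates one
signal by every integer shift in ``[-max_shift, +max_shift]`` and takes the
largest Pearson correlation, computed only over the *informative section* — the
union of the channel ranges the two signals occupy — so that the vast
signal-free remainder of the spectrum cannot dilute the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import DegenerateDataError, ParameterError

Interval = Tuple[int, int]


def coalesce_intervals(intervals: Sequence[Interval]) -> List[Interval]:
    """Sort inclusive intervals and merge any that overlap or are adjacent."""
    items = sorted((int(a), int(b)) for a, b in intervals)
    for a, b in items:
        if b < a:
            raise ParameterError(f"invalid interval ({a}, {b})")
    merged: List[Interval] = []
    for a, b in items:
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def informative_section(
    support_a: Sequence[Interval], support_b: Sequence[Interval]
) -> List[Interval]:
    """Union of the channel ranges two signals occupy.

    Overlapping or adjacent intervals are coalesced; disjoint ranges remain
    separate intervals.  E.g. supports (400, 600) and (500, 650) give the
    single section (400, 650).
    """
    if not support_a or not support_b:
        raise DegenerateDataError("informative section requires two non-empty supports")
    return coalesce_intervals(list(support_a) + list(support_b))


@dataclass
class MatchResult:
    """Best alignment of a signal pair under the shift search.

    ``best_shift`` is the signed channel offset applied to the second signal
    (positive = toward higher channels); ``best_correlation`` the Pearson
    correlation over the informative section at that shift;
    ``correlation_at_zero`` the unshifted value for reference (None when the
    unshifted section was too short to score).
    """

    best_shift: int
    best_correlation: float
    informative_section: List[Interval]
    correlation_at_zero: Optional[float]


def _section_channels(section: Sequence[Interval], width: int) -> np.ndarray:
    parts = [np.arange(max(a, 0), min(b, width - 1) + 1) for a, b in section]
    parts = [p for p in parts if p.size]
    if not parts:
        return np.empty(0, dtype=int)
    return np.concatenate(parts)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        import logging

        logging.getLogger(__name__).warning(
            "zero variance on informative section; correlation defined as 0"
        )
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def shifted_similarity(sig_a, sig_b, max_shift: int = 10) -> MatchResult:
    """Score a signal pair over all channel shifts in ``[-max_shift, max_shift]``.

    For each candidate shift ``s`` the second signal's support is translated by
    ``s`` and clipped to the channel range, the informative section is formed
    from the first support and the translated second support, and the Pearson
    correlation of the two signals is computed over the section (the second
    signal read at ``channel - s``).  Sections shorter than 3 channels are
    skipped.  The shift with the largest correlation wins; ties prefer the
    smallest ``|s|``, then the smaller ``s``.
    """
    a = np.asarray(sig_a.spectrum, dtype=float)
    b = np.asarray(sig_b.spectrum, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("signals must share one channel grid")
    w = a.size
    if not 0 <= max_shift < w / 2:
        raise ParameterError(f"max_shift={max_shift} must lie in [0, W/2)")
    if not sig_a.support or not sig_b.support:
        raise DegenerateDataError("both signals need a non-empty support")
    best: Optional[Tuple[float, int, List[Interval]]] = None
    corr_at_zero: Optional[float] = None
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda v: (abs(v), v)):
        shifted_b = [
            (max(lo + s, 0), min(hi + s, w - 1))
            for lo, hi in sig_b.support
            if lo + s <= w - 1 and hi + s >= 0
        ]
        if not shifted_b:
            continue
        section = coalesce_intervals(list(sig_a.support) + shifted_b)
        channels = _section_channels(section, w)
        channels = channels[(channels - s >= 0) & (channels - s < w)]
        if channels.size < 3:
            continue
        r = _corr(a[channels], b[channels - s])
        if s == 0:
            corr_at_zero = r
        if best is None or r > best[0]:
            best = (r, s, section)
    if best is None:
        raise DegenerateDataError(
            f"no shift in [-{max_shift}, {max_shift}] yields an informative "
            "section of at least 3 channels"
        )
    return MatchResult(
        best_shift=best[1],
        best_correlation=best[0],
        informative_section=best[2],
        correlation_at_zero=corr_at_zero,
    )


def match_signatures(
    list_a: Sequence,
    list_b: Sequence,
    max_shift: int = 10,
    min_similarity: float = 0.5,
) -> List[Tuple[int, int, MatchResult]]:
    """Score all signature pairs across two experiments.

    Returns ``(index_a, index_b, MatchResult)`` for every pair whose best
    correlation reaches ``min_similarity``, sorted descending by correlation.
    Pairs that cannot be scored (no overlap at any shift) are skipped.
    """
    if not list_a or not list_b:
        raise ParameterError("both signature lists must be non-empty")
    out: List[Tuple[int, int, MatchResult]] = []
    for i, sa in enumerate(list_a):
        for j, sb in enumerate(list_b):
            try:
                res = shifted_similarity(sa, sb, max_shift=max_shift)
            except DegenerateDataError:
                continue
            if res.best_correlation >= min_similarity:
                out.append((i, j, res))
    out.sort(key=lambda item: -item[2].best_correlation)
    return out


def matches_to_table(matches, list_a, list_b):
    """1-based match table for reporting/CLI output."""
    import pandas as pd

    from .merging import format_support

    rows = [
        {
            "a_time": list_a[i].time_index + 1,
            "b_time": list_b[j].time_index + 1,
            "best_shift": r.best_shift,
            "best_correlation": r.best_correlation,
            "correlation_at_zero": r.correlation_at_zero,
            "section": format_support(r.informative_section),
        }
        for i, j, r in matches
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "a_time",
            "b_time",
            "best_shift",
            "best_correlation",
            "correlation_at_zero",
            "section",
        ],
    )
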