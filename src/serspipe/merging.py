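"""Merging runs of consecutive detections into signature signals.

One analyte event usually spans several consecutive acquisitions whose spectra
share a shape but first intensify and then fade.  Walking the sorted detected
times, each time is compared with its immediate predecessor: if they are
consecutive and their full corrected spectra correlate above ``phi``, they
belong to the same event and only the stronger one (median absolute corrected
intensity over the row's bump support) survives; otherwise a new signature
starts.  The result is one signature signal per analyte event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .detection import DetectionResult
from .exceptions import DegenerateDataError, ParameterError
from .io import CorrectedSpectra
from .matching import coalesce_intervals

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]


@dataclass
class SignatureSignal:
    """The retained spectrum of one analyte event.

    ``time_index`` is the 0-based row kept; ``spectrum`` its corrected row;
    ``support`` the union of the row's bump intervals (0-based, inclusive);
    ``strength`` the median absolute corrected intensity over the support.
    """

    time_index: int
    spectrum: np.ndarray
    support: List[Interval]
    strength: float


def signal_strength(row: np.ndarray, support: Sequence[Interval]) -> float:
    """Median of |corrected intensity| over the support channels."""
    row = np.asarray(row, dtype=float)
    channels = support_channels(support, row.size)
    if channels.size == 0:
        raise DegenerateDataError("empty support: a detected signal must occupy channels")
    return float(np.median(np.abs(row[channels])))


def support_channels(support: Sequence[Interval], width: int) -> np.ndarray:
    """0-based channel indices covered by a list of inclusive intervals."""
    if not support:
        return np.empty(0, dtype=int)
    parts = [np.arange(max(a, 0), min(b, width - 1) + 1) for a, b in support]
    return np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=int)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; defined as 0 (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        logger.warning("zero-variance vector in correlation; treating as dissimilar (r=0)")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def merge_signals(
    cs: CorrectedSpectra, det: DetectionResult, phi: float = 0.9
) -> List[SignatureSignal]:
    """Collapse consecutive, mutually similar detections into signature signals.

    The walk follows the detected times in order, comparing each with its
    immediate predecessor only (pairwise along the chain).  When two are
    consecutive in time and their full-row Pearson correlation exceeds ``phi``,
    the later time replaces the earlier one in the signature set only if it is
    strictly stronger (ties keep the earlier time); otherwise the later time
    opens a new signature.  High ``phi`` avoids merging distinct co-eluting
    analytes.
    """
    if not -1 < phi < 1:
        raise ParameterError(f"phi={phi} must lie in (-1, 1)")
    times = [int(t) for t in det.detected_times]
    if times != sorted(times):
        raise ParameterError("detected_times must be sorted ascending")
    if not times:
        return []
    y = cs.values
    supports = {
        t: coalesce_intervals([(b.start, b.end) for b in det.bumps[t]]) for t in times
    }
    strengths = {t: signal_strength(y[t], supports[t]) for t in times}
    kept = [times[0]]
    for prev, cur in zip(times, times[1:]):
        if cur == prev + 1 and pearson(y[prev], y[cur]) > phi:
            # same event: the stronger of the adjacent pair survives
            if strengths[cur] > strengths[prev] and prev in kept:
                kept[kept.index(prev)] = cur
        else:
            kept.append(cur)
    return [
        SignatureSignal(
            time_index=t,
            spectrum=y[t].copy(),
            support=supports[t],
            strength=strengths[t],
        )
        for t in sorted(kept)
    ]


def signatures_to_table(signatures: Sequence[SignatureSignal]):
    """1-based metadata table: signature_index, time_index, strength, support."""
    import pandas as pd

    rows = [
        {
            "signature_index": k + 1,
            "time_index": s.time_index + 1,
            "strength": s.strength,
            "support": format_support(s.support),
        }
        for k, s in enumerate(signatures)
    ]
    return pd.DataFrame(rows, columns=["signature_index", "time_index", "strength", "support"])


def format_support(support: Sequence[Interval]) -> str:
    """Render 0-based inclusive intervals as 1-based closed 'a-b;c-d'."""
    return ";".join(f"{a + 1}-{b + 1}" for a, b in support)


def parse_support(text: str) -> List[Interval]:
    """Inverse of :func:`format_support` (back to 0-based inclusive)."""
    out = []
    for part in str(text).split(";"):
        a, b = part.split("-")
        out.append((int(a) - 1, int(b) - 1))
    return out
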