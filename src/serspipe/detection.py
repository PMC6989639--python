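"""Signal detection on background-corrected spectra.

After background removal a spectrum is noise plus, occasionally, analyte
signal.  Noise alternates rapidly in sign with modest magnitude; signal is a
positive *bump* — a consecutive run of channels of high magnitude.  Detection
therefore combines three cutoffs per spectrum:

* practical significance: corrected intensity above ``alpha`` noise standard
  deviations (the noise SD is estimated robustly per spectrum via the median
  absolute value scaled by 1/Phi^-1(0.75), the MAD rule, which tolerates up to
  about half the channels carrying signal);
* statistical significance: a one-sided normal p-value per channel, converted
  to Benjamini-Hochberg false-discovery-rate values within the spectrum, below
  ``beta``;
* persistence along frequency: a run of at least ``gamma`` consecutive
  qualifying channels, which rejects single-channel cosmic-ray spikes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
from scipy.stats import norm

from .exceptions import ParameterError, ValidationError
from .io import CorrectedSpectra

logger = logging.getLogger(__name__)

#: MAD-to-SD scaling for Gaussian noise, 1 / Phi^-1(0.75)
MAD_SCALE = 1.0 / float(norm.ppf(0.75))

#: lower clamp applied to p-values before FDR conversion, guarding underflow
P_FLOOR = 1e-300


def estimate_noise_sd(row: np.ndarray) -> float:
    """Robust per-spectrum noise SD: ``MAD_SCALE * median(|Y_ij|)``.

    Returns 0.0 for an all-zero (degenerate) row; downstream p-values for such
    a row are defined as 1.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or row.size < 2:
        raise ParameterError("row must be a 1-D vector with at least 2 channels")
    return MAD_SCALE * float(np.median(np.abs(row)))


def channel_pvalues(row: np.ndarray, sigma: float) -> np.ndarray:
    """One-sided per-channel p-values ``2*Phi(-Y/sigma)`` for positive values.

    Non-positive corrected values get p = 1 (signals are positive bumps).  A
    degenerate row (sigma = 0) gets p = 1 everywhere.  Values are clamped below
    at ``P_FLOOR`` so extreme signals cannot underflow to exact zero.
    """
    row = np.asarray(row, dtype=float)
    if sigma < 0:
        raise ParameterError(f"sigma={sigma} must be non-negative")
    if sigma == 0:
        return np.ones_like(row)
    p = np.where(row > 0, 2.0 * norm.sf(row / sigma), 1.0)
    return np.clip(p, P_FLOOR, 1.0)


def fdr_convert(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment along the last axis.

    Accepts a length-W vector (one spectrum) or a T x W matrix (row-wise).
    Adjusted values are ``min_{k>=rank}(p_(k) * m / k)`` clipped at 1; the map
    is order-preserving in the raw p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value vector")
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.shape[-1]
    order = np.argsort(p, axis=-1, kind="stable")
    ranked = np.take_along_axis(p, order, axis=-1) * (m / np.arange(1, m + 1))
    adj = np.minimum.accumulate(ranked[..., ::-1], axis=-1)[..., ::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    np.put_along_axis(out, order, adj, axis=-1)
    return out


@dataclass(frozen=True)
class Bump:
    """A maximal consecutive run of channels passing both cutoffs.

    ``start``/``end`` are 0-based inclusive channel indices; ``length`` is the
    run width; ``peak_value`` the maximum corrected intensity on the run;
    ``min_fdr`` the smallest FDR value on the run.  ``time_index`` is the
    0-based spectrum row (None when found outside a matrix context).
    """

    start: int
    end: int
    length: int
    peak_value: float
    min_fdr: float
    time_index: int | None = None


def _qualifying(row, sigma, fdr_row, alpha, beta, absolute_alpha):
    threshold = alpha if absolute_alpha else alpha * sigma
    return (row > threshold) & (fdr_row < beta)


def _runs(mask: np.ndarray):
    """(start, stop) half-open runs of True in a boolean vector."""
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    stops = np.nonzero(padded == -1)[0]
    return zip(starts, stops)


def find_bumps(
    row: np.ndarray,
    sigma: float,
    fdr_row: np.ndarray,
    alpha: float = 3.0,
    beta: float = 0.05,
    gamma: int = 3,
    absolute_alpha: bool = False,
    time_index: int | None = None,
) -> List[Bump]:
    """All maximal runs of channels with ``Y > alpha*sigma`` and ``FDR < beta``.

    ``alpha`` is interpreted in noise-SD units by default (the magnitude cutoff
    is relative to the spectrum's own noise level); pass ``absolute_alpha=True``
    for an absolute intensity cutoff.  The spectrum contains signal iff the
    longest bump has length >= ``gamma``; bumps shorter than ``gamma`` are still
    reported (length-1 bumps are typically cosmic-ray spikes).
    """
    if gamma < 1:
        raise ParameterError(f"gamma={gamma} must be >= 1")
    row = np.asarray(row, dtype=float)
    fdr_row = np.asarray(fdr_row, dtype=float)
    if row.shape != fdr_row.shape:
        raise ParameterError("row and fdr_row must have equal length")
    mask = _qualifying(row, sigma, fdr_row, alpha, beta, absolute_alpha)
    return [
        Bump(
            start=int(a),
            end=int(b - 1),
            length=int(b - a),
            peak_value=float(row[a:b].max()),
            min_fdr=float(fdr_row[a:b].min()),
            time_index=time_index,
        )
        for a, b in _runs(mask)
    ]


@dataclass
class DetectionResult:
    """Row-wise detection over a corrected matrix.

    ``detected_times`` are the 0-based rows owning at least one bump of length
    >= gamma, sorted ascending; ``bumps`` maps each detected row to all of its
    bumps.  ``pvalues``/``fdr_values`` are the full T x W matrices and ``sigma``
    the per-row noise SDs.  ``degenerate_rows`` are rows with sigma = 0.
    """

    detected_times: np.ndarray
    bumps: Dict[int, List[Bump]]
    pvalues: np.ndarray
    fdr_values: np.ndarray
    sigma: np.ndarray
    alpha: float
    beta: float
    gamma: int
    absolute_alpha: bool = False
    degenerate_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def detect_signals(
    cs: CorrectedSpectra,
    alpha: float = 3.0,
    beta: float = 0.05,
    gamma: int = 3,
    absolute_alpha: bool = False,
) -> DetectionResult:
    """Apply noise estimation, p-value/FDR conversion and bump finding row-wise.

    Degenerate rows (all-zero, sigma = 0) are logged and never detected.
    """
    if gamma < 1:
        raise ParameterError(f"gamma={gamma} must be >= 1")
    y = cs.values
    sigma = MAD_SCALE * np.median(np.abs(y), axis=1)
    degenerate = np.nonzero(sigma == 0)[0]
    if degenerate.size:
        logger.warning(
            "%d degenerate spectra (zero noise estimate) at rows %s; "
            "their p-values are defined as 1",
            degenerate.size,
            (degenerate + 1).tolist()[:10],
        )
    safe_sigma = np.where(sigma > 0, sigma, 1.0)
    p = np.where((y > 0) & (sigma[:, None] > 0), 2.0 * norm.sf(y / safe_sigma[:, None]), 1.0)
    p = np.clip(p, P_FLOOR, 1.0)
    fdr = fdr_convert(p)
    thresholds = alpha if absolute_alpha else (alpha * sigma)[:, None]
    qual = (y > thresholds) & (fdr < beta)
    detected: List[int] = []
    bumps: Dict[int, List[Bump]] = {}
    candidate_rows = np.nonzero(qual.any(axis=1))[0]
    for i in candidate_rows:
        row_bumps = [
            Bump(
                start=int(a),
                end=int(b - 1),
                length=int(b - a),
                peak_value=float(y[i, a:b].max()),
                min_fdr=float(fdr[i, a:b].min()),
                time_index=int(i),
            )
            for a, b in _runs(qual[i])
        ]
        if max(b.length for b in row_bumps) >= gamma:
            detected.append(int(i))
            bumps[int(i)] = row_bumps
    return DetectionResult(
        detected_times=np.asarray(detected, dtype=int),
        bumps=bumps,
        pvalues=p,
        fdr_values=fdr,
        sigma=sigma,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        absolute_alpha=absolute_alpha,
        degenerate_rows=degenerate,
    )


def detections_to_table(det: DetectionResult):
    """Flatten a detection result into a 1-based table (one row per bump).

    Columns: time_index, bump_start, bump_end, bump_length, peak_value, min_fdr.
    """
    import pandas as pd

    rows = [
        {
            "time_index": t + 1,
            "bump_start": b.start + 1,
            "bump_end": b.end + 1,
            "bump_length": b.length,
            "peak_value": b.peak_value,
            "min_fdr": b.min_fdr,
        }
        for t in det.detected_times
        for b in det.bumps[int(t)]
    ]
    return pd.DataFrame(
        rows,
        columns=["time_index", "bump_start", "bump_end", "bump_length", "peak_value", "min_fdr"],
    )
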