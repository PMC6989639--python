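"""Time-frequency block background removal.

SERS acquisitions carry a continuum background that is much stronger than the
analyte signal.  Its overall strength fluctuates arbitrarily from spectrum to
spectrum while its *shape* along the frequency axis drifts only slowly in time,
and the shape itself may be arbitrarily rough — so no smoothing along frequency
is admissible.  This module removes the background by exploiting the slow shape
drift: the matrix is tiled into time x frequency blocks, within each block every
spectrum fragment is scaled to unit mean, the block's background shape is the
pointwise (per-channel) median of the scaled fragments, and for each fragment a
robust per-spectrum projection coefficient — a low percentile of the pointwise
ratios fragment/shape — rescales the shape before subtraction.

The median across time makes the shape estimate immune to transient signals
occupying fewer than half of the block's time points, and the low percentile of
the ratio vector makes the projection coefficient immune to signals occupying
less than (100-q)% of the block's channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .exceptions import DegenerateDataError, ParameterError
from .io import CorrectedSpectra, SpectraMatrix

#: relative floor under which a background-shape channel is considered vanished
_SHAPE_FLOOR = 1e-12


@dataclass(frozen=True)
class BlockGrid:
    """An exact tiling of a T x W matrix into time-frequency blocks.

    ``time_segments`` and ``freq_segments`` are 0-based half-open ``(start, stop)``
    intervals; the final segment of each axis absorbs the division remainder, so
    segment counts are ``floor(T/w_T)`` and ``floor(W/w_F)``.
    """

    T: int
    W: int
    window_time: int
    window_freq: int
    time_segments: Tuple[Tuple[int, int], ...]
    freq_segments: Tuple[Tuple[int, int], ...]

    @property
    def n_time(self) -> int:
        return len(self.time_segments)

    @property
    def n_freq(self) -> int:
        return len(self.freq_segments)

    @property
    def blocks(self) -> List[Tuple[Tuple[int, int], Tuple[int, int]]]:
        """All (time-interval, frequency-interval) pairs, row-major."""
        return [(ts, fs) for ts in self.time_segments for fs in self.freq_segments]


def _segments(n: int, w: int) -> Tuple[Tuple[int, int], ...]:
    k = n // w
    edges = [i * w for i in range(k)] + [n]
    return tuple((edges[i], edges[i + 1]) for i in range(k))


def partition_blocks(T: int, W: int, window_time: int, window_freq: int) -> BlockGrid:
    """Tile a ``T x W`` matrix into time-frequency blocks.

    Segment counts are ``floor(T/window_time) x floor(W/window_freq)`` — e.g.
    5,000 x 1,600 with windows 100/100 gives 50 x 16 blocks — and indices left
    over by the integer division are absorbed into the last segment of each
    axis, so final segments may be up to twice the window size minus one.
    """
    for name, w, n in (("window_time", window_time, T), ("window_freq", window_freq, W)):
        if not 1 <= w <= n:
            raise ParameterError(f"{name}={w} must lie in [1, {n}]")
    return BlockGrid(
        T=T,
        W=W,
        window_time=window_time,
        window_freq=window_freq,
        time_segments=_segments(T, window_time),
        freq_segments=_segments(W, window_freq),
    )


@dataclass
class BlockBackground:
    """Background estimate for one block.

    ``shape`` is the unit-mean-scale background profile ``B`` (per-channel
    median of the mean-scaled fragments); ``scaled_fragments`` are the rows of
    the block each divided by its own mean; ``row_means`` are those means.
    """

    shape: np.ndarray
    scaled_fragments: np.ndarray
    row_means: np.ndarray


def estimate_block_background(fragment: np.ndarray) -> BlockBackground:
    """Estimate the background shape of one time-frequency block.

    Each spectrum fragment (row) is divided by its mean intensity, discarding
    per-spectrum overall strength; the shape ``B_j`` is then the median over
    time of the scaled values, taken independently per channel so that no
    smoothing is introduced along frequency.
    """
    x = np.asarray(fragment, dtype=float)
    if x.ndim != 2:
        raise ParameterError("fragment must be 2-D")
    means = x.mean(axis=1)
    bad = np.nonzero(means <= 0)[0]
    if bad.size:
        raise DegenerateDataError(
            f"fragment row {bad[0] + 1} has non-positive mean ({means[bad[0]]!r}); "
            "background scaling requires positive intensities"
        )
    scaled = x / means[:, None]
    shape = np.median(scaled, axis=0)
    return BlockBackground(shape=shape, scaled_fragments=scaled, row_means=means)


def remove_block_background(
    fragment: np.ndarray, bb: BlockBackground, percentile: float = 40.0
) -> np.ndarray:
    """Remove the estimated background from one block.

    For each row the pointwise ratio ``P_ij = X*_ij / B_j`` is formed; its
    ``percentile``-th percentile (linear interpolation) is the row's projection
    coefficient ``Q_i``; the corrected row is ``X*_i - Q_i * B``.  A percentile
    well below the fraction of signal-free channels keeps ``Q_i`` unaffected by
    signals sitting on top of the background.
    """
    if not 0 < percentile < 100:
        raise ParameterError(f"percentile={percentile} must lie in (0, 100)")
    x = np.asarray(fragment, dtype=float)
    shape = bb.shape
    floor = _SHAPE_FLOOR * shape.mean()
    tiny = np.nonzero(shape <= floor)[0]
    if tiny.size:
        raise DegenerateDataError(
            f"background shape vanishes at channel {tiny[0] + 1} "
            f"(B={shape[tiny[0]]!r}); cannot form projection ratios"
        )
    ratios = x / shape[None, :]
    q = np.percentile(ratios, percentile, axis=1)
    return x - q[:, None] * shape[None, :]


def remove_background(
    m: SpectraMatrix,
    window_time: int = 50,
    window_freq: int = 50,
    percentile: float = 40.0,
) -> CorrectedSpectra:
    """Background-remove a whole spectra matrix block by block.

    Blocks are processed independently — no blending across block edges — and
    reassembled in the original index order.  Window-size guidance: the faster
    the background shape drifts in time, the smaller the windows should be;
    overly large windows leave residual background, overly small ones start to
    absorb signal into the shape estimate.  Defaults of 50/50 suit slowly
    drifting backgrounds; results are typically insensitive over 50-200.
    """
    grid = partition_blocks(m.T, m.W, window_time, window_freq)
    x = m.intensities
    y = np.empty_like(x)
    for (t0, t1) in grid.time_segments:
        for (f0, f1) in grid.freq_segments:
            frag = x[t0:t1, f0:f1]
            try:
                bb = estimate_block_background(frag)
                y[t0:t1, f0:f1] = remove_block_background(frag, bb, percentile)
            except DegenerateDataError as exc:
                raise DegenerateDataError(
                    f"block time [{t0 + 1}, {t1}] x channels [{f0 + 1}, {f1}]: {exc}"
                ) from exc
    return CorrectedSpectra(
        values=y,
        wavenumber=m.wavenumber,
        provenance={
            "window_time": window_time,
            "window_freq": window_freq,
            "percentile": percentile,
        },
    )
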