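"""Seeded generator of SERS-like spectra matrices with known ground truth.

The generator reproduces the statistical structure the analysis assumes, not
the plasmonic physics: a strong multiplicative background whose overall
strength varies arbitrarily per acquisition (log-normal multiplier) and whose
shape drifts slowly in time (a convex combination of two fixed smooth profiles
with a monotone mixing weight, so one frequency region decays while another
grows); transient analyte signals occupying a few consecutive acquisitions and
a limited channel range (sums of Gaussian peaks with a triangular
rise-then-fade temporal profile); additive i.i.d. Gaussian channel noise; and
occasional single-channel cosmic-ray spikes.  Intensities are clipped at zero
after summation (the background level is chosen high enough that the clip is
inactive in practice).

Structure (shapes, strengths, signal placement) and noise (channel noise,
cosmic rays) are drawn from separate streams, so a replicate can share the
structure of another while drawing fresh noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ParameterError, ValidationError
from .io import SpectraMatrix
from .matching import coalesce_intervals

Interval = Tuple[int, int]


@dataclass(frozen=True)
class SignalSpec:
    """One injected analyte event.

    ``onset`` (0-based acquisition) and ``duration`` fix the time window;
    ``centers``/``widths`` place Gaussian peaks on the channel axis (channel
    units); ``amplitude`` is the event's peak maximum in noise-SD units;
    ``heights`` optionally weight the peaks (relative, max-normalized away).
    """

    onset: int
    duration: int
    centers: Tuple[float, ...]
    widths: Tuple[float, ...]
    amplitude: float
    heights: Optional[Tuple[float, ...]] = None


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic acquisition run.

    Defaults describe a 600-acquisition, 400-channel run with three analyte
    events of peak amplitude 6 noise-SD lasting 3 acquisitions each, a slowly
    drifting two-profile background about 100x stronger than the noise, and on
    average two cosmic-ray spikes per matrix.
    """

    T: int = 600
    W: int = 400
    background_shapes: Optional[Tuple[np.ndarray, np.ndarray]] = None
    drift: float = 0.3
    background_level: float = 100.0
    strength_sigma: float = 0.3
    signals: Optional[List[SignalSpec]] = None
    noise_sd: float = 1.0
    cosmic_ray_rate: float = 2.0
    seed: int = 0
    noise_seed: Optional[int] = None

    def validate(self) -> None:
        problems = []
        if self.T < 1 or self.W < 1:
            problems.append(f"T={self.T}, W={self.W} must be >= 1")
        if not 0 <= self.drift <= 1:
            problems.append(f"drift={self.drift} must lie in [0, 1]")
        if self.noise_sd < 0:
            problems.append(f"noise_sd={self.noise_sd} must be >= 0")
        if self.background_level <= 0:
            problems.append(f"background_level={self.background_level} must be > 0")
        if self.strength_sigma < 0:
            problems.append(f"strength_sigma={self.strength_sigma} must be >= 0")
        if self.cosmic_ray_rate < 0:
            problems.append(f"cosmic_ray_rate={self.cosmic_ray_rate} must be >= 0")
        if self.background_shapes is not None:
            for k, s in enumerate(self.background_shapes):
                s = np.asarray(s, float)
                if s.shape != (self.W,) or (s <= 0).any() or not np.isfinite(s).all():
                    problems.append(f"background shape {k} must be positive, finite, length W")
        for k, sig in enumerate(self.signals or []):
            if sig.duration < 1:
                problems.append(f"signal {k}: duration={sig.duration} must be >= 1")
            if sig.amplitude < 0:
                problems.append(f"signal {k}: amplitude={sig.amplitude} must be >= 0")
            if len(sig.centers) != len(sig.widths) or not sig.centers:
                problems.append(f"signal {k}: centers and widths must be non-empty, equal length")
            if any(w <= 0 for w in sig.widths):
                problems.append(f"signal {k}: widths must be > 0")
            if not 0 <= sig.onset < self.T:
                problems.append(f"signal {k}: onset={sig.onset} outside [0, T)")
        if problems:
            raise ValidationError("invalid simulation config: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Everything the generator knows, for stage-by-stage verification.

    Indices are 0-based (internal convention); ``signal_supports`` are inclusive
    channel intervals, ``signal_windows`` inclusive time intervals, and
    ``signal_shapes`` the full-width noiseless peak profiles at event maximum
    (intensity units).  ``config`` is the materialized configuration (concrete
    shapes and signals), sufficient to regenerate the matrix.
    """

    signal_times: np.ndarray
    signal_windows: List[Interval]
    signal_supports: List[List[Interval]]
    signal_shapes: List[np.ndarray]
    background_truth: np.ndarray
    cosmic_rays: List[Tuple[int, int, float]]
    noise_sd: float
    config: SimulationConfig = field(repr=False, default=None)


def _default_shapes(W: int, level: float) -> Tuple[np.ndarray, np.ndarray]:
    """Two smooth positive profiles: the first dominant at low frequency, the
    second at mid-to-high frequency, so drift lowers one region and raises the
    other."""
    j = np.arange(W, dtype=float)

    def g(center, width):
        return np.exp(-0.5 * ((j - center * W) / (width * W)) ** 2)

    s1 = 1.0 + 0.9 * g(0.18, 0.10) + 0.35 * g(0.70, 0.20)
    s2 = 1.0 + 0.30 * g(0.18, 0.10) + 0.9 * g(0.65, 0.14) + 0.25 * g(0.45, 0.05)
    return level * s1, level * s2


def _triangular_profile(duration: int) -> np.ndarray:
    """Rise-then-fade weights peaking at 1 in the middle of the window."""
    half = (duration - 1) // 2
    k = np.arange(duration)
    return (1.0 + np.minimum(k, duration - 1 - k)) / (1.0 + half)


def _signal_shape(spec: SignalSpec, W: int, noise_sd: float) -> np.ndarray:
    j = np.arange(W, dtype=float)
    heights = spec.heights or tuple(1.0 for _ in spec.centers)
    g = np.zeros(W)
    for c, w, h in zip(spec.centers, spec.widths, heights):
        g += h * np.exp(-0.5 * ((j - c) / w) ** 2)
    peak = g.max()
    if peak > 0:
        g *= spec.amplitude * noise_sd / peak
    return g


def _signal_support(spec: SignalSpec, W: int) -> List[Interval]:
    """Inclusive channel intervals occupied by the event: +-3 peak widths."""
    intervals = []
    for c, w in zip(spec.centers, spec.widths):
        lo = max(int(np.floor(c - 3 * w)), 0)
        hi = min(int(np.ceil(c + 3 * w)), W - 1)
        if lo <= hi:
            intervals.append((lo, hi))
    return coalesce_intervals(intervals)


def default_signals(
    T: int,
    W: int,
    n_signals: int = 3,
    amplitude: float = 6.0,
    duration: int = 3,
    seed: int = 0,
) -> List[SignalSpec]:
    """Evenly spaced events with one or two Gaussian peaks of width ~2.5
    channels (support about 15 channels per peak), placed away from the
    channel edges."""
    rng = np.random.default_rng(seed)
    specs = []
    for k in range(n_signals):
        onset = int((k + 1) * T / (n_signals + 1))
        n_peaks = 1 + int(rng.integers(0, 2))
        base = float(rng.uniform(0.12 * W, 0.82 * W))
        centers = tuple(base + 18.0 * p for p in range(n_peaks))
        widths = tuple(float(rng.uniform(2.0, 3.0)) for _ in range(n_peaks))
        heights = tuple(float(rng.uniform(0.6, 1.0)) for _ in range(n_peaks))
        specs.append(
            SignalSpec(
                onset=onset,
                duration=duration,
                centers=centers,
                widths=widths,
                amplitude=amplitude,
                heights=heights,
            )
        )
    return specs


def default_config(
    T: int = 600,
    W: int = 400,
    n_signals: int = 3,
    amplitude: float = 6.0,
    duration: int = 3,
    noise_sd: float = 1.0,
    drift: float = 0.3,
    cosmic_ray_rate: float = 2.0,
    seed: int = 0,
) -> SimulationConfig:
    """Standard study conditions (see :class:`SimulationConfig`)."""
    return SimulationConfig(
        T=T,
        W=W,
        drift=drift,
        signals=default_signals(T, W, n_signals, amplitude, duration, seed=seed),
        noise_sd=noise_sd,
        cosmic_ray_rate=cosmic_ray_rate,
        seed=seed,
    )


def generate_dataset(cfg: SimulationConfig) -> Tuple[SpectraMatrix, GroundTruth]:
    """Draw one spectra matrix and its ground truth.

    ``X_tj = c_t * B_t(j) + sum_s a_s(t) g_s(j) + eps_tj`` clipped at 0, where
    ``B_t`` mixes the two background profiles with a monotone weight
    ``drift * t/(T-1)``, ``c_t`` is a log-normal strength multiplier, ``a_s`` a
    triangular rise-fall profile, ``g_s`` a sum of Gaussian peaks, and ``eps``
    i.i.d. N(0, noise_sd^2).  Cosmic rays are single-channel positive spikes at
    random positions.  Identical configuration (including seeds) gives
    bit-identical output.
    """
    cfg.validate()
    T, W = cfg.T, cfg.W
    rng_struct = np.random.default_rng(cfg.seed)
    noise_seed = cfg.noise_seed if cfg.noise_seed is not None else cfg.seed + 1
    rng_noise = np.random.default_rng(noise_seed)

    if cfg.background_shapes is None:
        s1, s2 = _default_shapes(W, cfg.background_level)
    else:
        s1 = np.asarray(cfg.background_shapes[0], float)
        s2 = np.asarray(cfg.background_shapes[1], float)
    mix = cfg.drift * (np.arange(T) / max(T - 1, 1))
    shape_t = (1 - mix)[:, None] * s1[None, :] + mix[:, None] * s2[None, :]
    strength = np.exp(rng_struct.normal(0.0, cfg.strength_sigma, size=T))
    background = strength[:, None] * shape_t

    signals = cfg.signals if cfg.signals is not None else []
    signal_total = np.zeros((T, W))
    windows: List[Interval] = []
    supports: List[List[Interval]] = []
    shapes: List[np.ndarray] = []
    for spec in signals:
        g = _signal_shape(spec, W, cfg.noise_sd)
        profile = _triangular_profile(spec.duration)
        t_hi = min(spec.onset + spec.duration, T)
        for k, t in enumerate(range(spec.onset, t_hi)):
            signal_total[t] += profile[k] * g
        windows.append((spec.onset, t_hi - 1))
        supports.append(_signal_support(spec, W))
        shapes.append(g)

    noise = rng_noise.normal(0.0, cfg.noise_sd, size=(T, W))
    x = background + signal_total + noise

    cosmic: List[Tuple[int, int, float]] = []
    n_rays = int(rng_noise.poisson(cfg.cosmic_ray_rate))
    for _ in range(n_rays):
        t = int(rng_noise.integers(0, T))
        j = int(rng_noise.integers(0, W))
        mag = float(rng_noise.uniform(20.0, 50.0) * cfg.noise_sd)
        x[t, j] += mag
        cosmic.append((t, j, mag))

    np.clip(x, 0.0, None, out=x)

    materialized = dataclasses.replace(
        cfg,
        background_shapes=(s1.copy(), s2.copy()),
        signals=list(signals),
        noise_seed=noise_seed,
    )
    signal_times = np.unique(
        np.concatenate([np.arange(a, b + 1) for a, b in windows])
        if windows
        else np.empty(0, dtype=int)
    ).astype(int)
    gt = GroundTruth(
        signal_times=signal_times,
        signal_windows=windows,
        signal_supports=supports,
        signal_shapes=shapes,
        background_truth=background,
        cosmic_rays=cosmic,
        noise_sd=cfg.noise_sd,
        config=materialized,
    )
    return SpectraMatrix(intensities=x), gt


def _translate_edge_extend(profile: np.ndarray, shift: int) -> np.ndarray:
    """Translate a channel profile, filling exposed edges with the edge value."""
    W = profile.size
    idx = np.clip(np.arange(W) - shift, 0, W - 1)
    return profile[idx]


def generate_shifted_replicate(
    m: SpectraMatrix, gt: GroundTruth, shift: int, seed: int
) -> Tuple[SpectraMatrix, GroundTruth]:
    """A technical replicate of ``(m, gt)`` whose channel axis is miscalibrated.

    Background profiles and signal peak centers are translated by ``shift``
    channels (positive = toward higher channels, edges extended), the structure
    stream (strengths, placement) is reused, and fresh noise and cosmic rays
    are drawn from ``seed``.  With ``shift=0`` the replicate differs from the
    original only in noise.
    """
    cfg = gt.config
    if cfg is None:
        raise ParameterError("ground truth carries no configuration to regenerate from")
    if abs(shift) >= cfg.W / 4:
        raise ParameterError(f"|shift|={abs(shift)} must be < W/4 = {cfg.W / 4}")
    s1, s2 = cfg.background_shapes
    shifted_signals = [
        dataclasses.replace(spec, centers=tuple(c + shift for c in spec.centers))
        for spec in cfg.signals
    ]
    cfg2 = dataclasses.replace(
        cfg,
        background_shapes=(
            _translate_edge_extend(s1, shift),
            _translate_edge_extend(s2, shift),
        ),
        signals=shifted_signals,
        noise_seed=int(seed),
    )
    return generate_dataset(cfg2)
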