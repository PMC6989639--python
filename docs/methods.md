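# Methods

## Data model and assumptions

The pipeline operates on a T × W matrix of non-negative intensities — one
spectrum of W frequency channels per acquisition time. The working model is

    X_tj = c_t · B_t(j) + Σ_s a_s(t) · g_s(j) + ε_tj,

with `c_t > 0` an arbitrary per-acquisition background strength, `B_t` a
background shape that drifts *slowly* in time but may be arbitrarily rough
along frequency, `g_s` a non-negative analyte peak profile confined to a
limited channel range, `a_s` a transient temporal profile (rise then fade over
a few acquisitions), and `ε` zero-mean noise, treated as Gaussian for the
detection p-values. Two structural assumptions matter:

1. within one time window the background shape is approximately constant
   (only its strength varies), and
2. at any time point, signals occupy a minority of time points within the
   window and a minority of channels within each frequency window.

Assumption 1 justifies the per-block multiplicative model; assumption 2 is
what the median (over time) and the low percentile (over channels) exploit.

## Background removal

Within each block, rows are scaled to unit mean, the shape `B` is the
per-channel median of the scaled rows, and each row sheds `Q_i · B`, where
`Q_i` is the q-th percentile of the pointwise ratios `X*_ij/B_j`. The block
where `X*_ij = c_i B_j` exactly is annihilated identically: the ratio vector
is constant, so any percentile of it equals the constant, and the subtraction
cancels. The operation is positively homogeneous — scaling the input by λ > 0
scales the output by λ.

Numerical conventions: percentiles use linear interpolation between closest
ranks (q on the 0–100 scale, default 40); the median of an even count is the
mean of the two central order statistics; a shape channel below 1e-12 of the
mean shape raises an error (it indicates a dead channel, which should be
diagnosed rather than silently clipped); a row with non-positive mean raises
an error naming the row. Blocks are processed independently, with no blending
across edges — cross-block smoothing would reintroduce exactly the kind of
frequency smoothing the method is designed to avoid.

Remainder handling: with window sizes `w_T`/`w_F`, the axis is cut into
`floor(T/w_T)` (resp. `floor(W/w_F)`) segments and the division remainder is
absorbed into the last segment (sizes up to `2w−1`). This keeps the block
count of the 5,000 × 1,600, 100/100 case at 50 × 16 and avoids slivers of a
few time points, whose medians would be unstable.

Window-size guidance: the faster the background shape drifts, the smaller the
windows must be; overly large windows leave residual background (the residual
energy grows monotonically with drift speed at fixed window — reproduced as a
generator property test), while overly small time windows let a long-lasting
signal occupy the majority of a block and leak into the median. Two presets
encode the published parameterizations this pipeline targets: `vitamin`
(50/50, short-lived analytes) and `tumor` (w_T = 150, long-lasting signals).

## Signal detection

Per spectrum: `σ̂_i = median_j |Y_ij| / Φ⁻¹(0.75)`. Using the median absolute
value rather than a standard deviation keeps the estimate stable in the
presence of signal; quantitatively, corrupting a fraction f of channels moves
the estimate to the `0.5/(1−f)` quantile of the absolute noise distribution —
a 6% inflation at f = 0.05, and bounded (never dragged toward the signal
amplitude) for any f < 0.5.

P-values are one-sided normal, `p_ij = 2Φ(−Y_ij/σ̂_i)` for `Y_ij > 0` and 1
otherwise (signals are positive; negative excursions are never candidates),
clamped below at 1e-300 so extreme peaks cannot underflow to zero. FDR
conversion is the Benjamini–Hochberg step-up applied within each spectrum
across its W channels (row-wise, vectorized over the whole matrix). The
magnitude cutoff α is interpreted in noise-SD units (`Y_ij > α·σ̂_i`), which
transfers across datasets of different gain; an absolute-intensity reading is
available via `absolute_alpha=True`. Defaults α = 3, β = 0.05, γ = 3 are
conservative and overridable. A spectrum is reported when its longest
qualifying run spans ≥ γ channels; shorter runs are still reported as bumps
(a length-1 bump at high amplitude is the fingerprint of a cosmic ray).
Degenerate rows (σ̂ = 0) get p ≡ 1, are never detected, and are logged.

## Merging

The detected times are walked in order, each compared only with its immediate
predecessor: consecutive in time *and* full-row Pearson correlation above φ
(default 0.9 — high, so that distinct co-eluting analytes are not merged)
means same event, and the later time replaces the earlier in the signature set
only when strictly stronger (ties keep the earlier time, making the output
deterministic). Strength is the median of |Y| over the row's bump support —
the signal's own channels — because a median over all W channels would be
noise-dominated. For the intended unimodal (rise-then-fade) intensity
profiles this pairwise walk leaves exactly the strongest time of each run; for
a non-unimodal run (e.g. two interleaved events of oscillating strength that
still correlate above φ) the pairwise rule can retain a locally- rather than
globally-strongest time. Correlations involving a zero-variance row are
defined as 0 (dissimilar) with a warning.

## Cross-experiment matching

The similarity of two signature signals is the maximum, over integer channel
shifts `s ∈ [−max_shift, +max_shift]` applied to the second signal, of the
Pearson correlation computed over the *informative section*: the union of the
first signal's support and the translated second support, coalescing
overlapping or adjacent intervals. The section is recomputed per shift (it is
defined by where the signals occupy, which moves with the shift) and clipped
to the channel range; channels where the translated signal is undefined are
dropped. Sections shorter than 3 channels are skipped (Pearson correlation on
fewer points is degenerate); if every shift is skipped the pair is reported as
unmatchable. Ties prefer the smallest |s|, then the smaller s — the
no-miscalibration hypothesis wins ties. `max_shift` defaults to 10 channels,
the scale of wavenumber miscalibration actually observed between replicate
experiments; an unbounded search would invite spurious maxima on noise.

Positive shift means the second signal is moved toward higher channel
indices; a replicate whose axis is miscalibrated by +k channels is therefore
matched at best shift −k.

## Synthetic data

The generator draws from the working model above, with: background shape
drift as a convex combination of two fixed smooth profiles with a monotone
mixing weight (`drift · t/(T−1)`), chosen so one frequency region decays while
another grows over the run; log-normal per-acquisition strength; signals as
sums of Gaussian peaks (normalized so the stated amplitude, in noise-SD units,
is the event's peak maximum) with a triangular rise-then-fade profile;
i.i.d. Gaussian channel noise; Poisson-count single-channel cosmic-ray spikes
of 20–50 noise-SD; and a clip at zero (inactive in practice because the
background level, 100× the noise SD, dominates). Defaults — T = 600, W = 400,
three events of amplitude 6σ lasting 3 acquisitions with peak widths ~2–3
channels (support ≈ 15 channels per peak), drift 0.3, 2 expected cosmic rays —
describe a short, clean acquisition run. Structure (shapes, strengths, signal
placement) and noise are drawn from separate seeded streams so that
`generate_shifted_replicate` can translate the structure by a chosen number of
channels (edge values extended) while drawing fresh noise: a technical
replicate with a known wavenumber miscalibration.

What the generator does *not* emulate: Poisson/heteroscedastic detector
noise, correlated noise along frequency, photobleaching trends, overlapping
co-eluting analytes, and rough (non-smooth) background shapes. Passing tests
on this synthetic data therefore demonstrate the pipeline's behavior under
its own model assumptions — exact background cancellation, calibrated false
positives, shift recovery — not performance on any particular instrument's
data. Conversely the drift violation of the per-block constancy assumption
*is* emulated, which is what makes the residual-energy and detection tests
informative.

## Signal-to-noise ceiling on shape recovery

A corrected row at an event's peak is `g + ε` with `ε` of SD σ. The Pearson
correlation with the true shape over the support is
`sd(g)/sqrt(sd(g)² + σ²)`, and since a non-negative shape with maximum A has
`sd(g) ≤ A/2`, the correlation cannot exceed `(A/2)/sqrt((A/2)² + σ²)` no
matter the peak shape — ≈ 0.949 at A = 6σ, and ≈ 0.90 for realistic Gaussian
peaks (for which `sd(g) ≈ 0.35·A` over a ±3-width support). Recovered-shape
correlations in the 0.88–0.93 range at 6σ are therefore the expected
behavior, not a deficiency of the background removal; correlations above 0.95
require peak amplitudes of roughly 9σ and up.

## Problem sizes used in the test suite

Unit and property tests run on matrices from 20 × 20 up to 600 × 400 (the
generator default); the false-positive control uses fifty 200 × 400 noise
matrices; the smoke test runs the full chain once at the full acquisition
scale of 5,000 × 1,600, where the block decomposition keeps the whole
analysis to a few seconds of vectorized numpy.
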