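import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc, erfinv
from statsmodels.stats.multitest import multipletests

from serspipe import (
    CorrectedSpectra,
    ParameterError,
    ValidationError,
    channel_pvalues,
    default_config,
    detect_signals,
    estimate_noise_sd,
    fdr_convert,
    find_bumps,
    generate_dataset,
    remove_background,
)


class TestNoiseSd:
    def test_alternating_unit_row_equals_mad_constant(self):
        """median|Y| = 1, so the estimate equals 1/Phi^-1(0.75), computed here
        independently through the inverse error function."""
        row = np.tile([-1.0, 1.0], 400)
        k_independent = 1.0 / (np.sqrt(2.0) * erfinv(0.5))
        assert estimate_noise_sd(row) == pytest.approx(k_independent, rel=1e-12)
        assert estimate_noise_sd(row) == pytest.approx(1.4826, rel=1e-3)

    def test_median_consistent_for_gaussian_noise(self):
        sd_true = 2.5
        errs = []
        for seed in range(100):
            row = np.random.default_rng(seed).normal(0, sd_true, 1600)
            errs.append(abs(estimate_noise_sd(row) - sd_true) / sd_true)
        assert np.median(errs) < 0.05

    def test_relative_bias_small_at_full_width(self):
        ests = [
            estimate_noise_sd(np.random.default_rng(1000 + s).normal(0, 1, 1600))
            for s in range(200)
        ]
        assert abs(np.median(ests) - 1.0) < 0.02

    def test_all_zero_row_degenerate(self):
        assert estimate_noise_sd(np.zeros(10)) == 0.0

    def test_robust_to_signal_on_few_channels(self, rng):
        """A realistic signal (5% of channels, 20 sigma) moves the estimate
        < 10%; even 40% corrupted channels inflate it only to another noise
        quantile rather than toward the signal amplitude (median breakdown)."""
        row = rng.normal(0, 1, 1600)
        clean = estimate_noise_sd(row)
        spiked = row.copy()
        spiked[:80] += 20.0
        assert abs(estimate_noise_sd(spiked) - clean) / clean < 0.10
        heavy = row.copy()
        heavy[:640] += 20.0
        assert estimate_noise_sd(heavy) < 3.0 * clean

    def test_too_short_row_rejected(self):
        with pytest.raises(ParameterError):
            estimate_noise_sd(np.array([1.0]))


class TestPvalues:
    def test_nonpositive_values_get_p_one(self):
        p = channel_pvalues(np.array([-3.0, 0.0, 2.0]), sigma=1.0)
        assert p[0] == 1.0 and p[1] == 1.0 and p[2] < 0.05

    def test_continuity_at_zero(self):
        p = channel_pvalues(np.array([1e-12]), sigma=1.0)
        assert p[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_normal_tail(self):
        """2*Phi(-z) cross-checked through the complementary error function."""
        z = 1.959964
        p = channel_pvalues(np.array([z]), sigma=1.0)[0]
        assert p == pytest.approx(erfc(z / np.sqrt(2.0)), rel=1e-12)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_degenerate_sigma_gives_all_ones(self):
        np.testing.assert_array_equal(
            channel_pvalues(np.array([5.0, -1.0, 0.3]), sigma=0.0), np.ones(3)
        )

    def test_extreme_signal_clamped_not_zero(self):
        p = channel_pvalues(np.array([100.0]), sigma=1.0)
        assert p[0] >= 1e-300

    def test_negative_sigma_rejected(self):
        with pytest.raises(ParameterError):
            channel_pvalues(np.array([1.0, 2.0]), sigma=-1.0)


class TestFdrConvert:
    def test_single_pvalue_identity(self):
        assert fdr_convert(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_ties_saturate(self):
        np.testing.assert_allclose(fdr_convert(np.full(20, 0.3)), 0.3)

    def test_small_example_against_literal_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        # literal step-up: sort, multiply by m/rank, cumulative min from largest
        expected = np.array([0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(fdr_convert(p), expected, rtol=1e-12)

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, int(rng.integers(1, 60)))
            want = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(fdr_convert(p), want, rtol=1e-10)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_dominates_and_preserves_order(self, plist):
        p = np.array(plist)
        f = fdr_convert(p)
        assert (f >= p - 1e-15).all() and (f <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(f[order]) >= -1e-15).all()

    def test_rowwise_matrix_equals_per_row(self, rng):
        p = rng.uniform(0, 1, size=(5, 30))
        rows = np.vstack([fdr_convert(p[i]) for i in range(5)])
        np.testing.assert_allclose(fdr_convert(p), rows, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_convert(np.array([0.5, 1.5]))


class TestFindBumps:
    def test_quiet_row_has_no_bumps(self, rng):
        row = rng.normal(0, 1, 200)
        sigma = estimate_noise_sd(row)
        fdr = fdr_convert(channel_pvalues(row, sigma))
        assert find_bumps(row, sigma, fdr, alpha=5, beta=1e-4, gamma=3) == []

    def test_cosmic_ray_spike_is_short_bump(self):
        row = np.zeros(100)
        row[50] = 50.0
        noise = np.tile([-1.0, 1.0], 50)
        row += 0.1 * noise
        sigma = estimate_noise_sd(row)
        fdr = fdr_convert(channel_pvalues(row, sigma))
        bumps = find_bumps(row, sigma, fdr, alpha=3, beta=0.01, gamma=2)
        long_enough = [b for b in bumps if b.length >= 2]
        assert any(b.start == b.end == 50 for b in bumps)
        assert not long_enough  # row is NOT signal-positive at gamma=2

    def test_two_runs_reported_with_exact_lengths(self):
        row = np.tile([-0.5, 0.5], 50).astype(float)
        row[10:15] = 10.0  # 5-channel run
        row[40:42] = 10.0  # 2-channel run
        sigma = estimate_noise_sd(row)
        fdr = fdr_convert(channel_pvalues(row, sigma))
        bumps = find_bumps(row, sigma, fdr, alpha=3, beta=0.01, gamma=3)
        assert [(b.start, b.end, b.length) for b in bumps] == [(10, 14, 5), (40, 41, 2)]
        assert max(b.length for b in bumps) >= 3  # signal-positive via the 5-run

    def test_bumps_are_maximal_and_disjoint(self, rng):
        row = rng.normal(0, 1, 300)
        row[100:130] += 8.0
        sigma = estimate_noise_sd(row)
        fdr = fdr_convert(channel_pvalues(row, sigma))
        bumps = find_bumps(row, sigma, fdr)
        for a, b in zip(bumps, bumps[1:]):
            assert b.start > a.end + 1

    def test_gamma_below_one_rejected(self):
        with pytest.raises(ParameterError):
            find_bumps(np.zeros(5), 1.0, np.ones(5), gamma=0)


class TestDetectSignals:
    def test_all_zero_matrix_yields_no_detections(self):
        det = detect_signals(CorrectedSpectra(values=np.zeros((5, 10))))
        assert det.detected_times.size == 0
        assert det.degenerate_rows.tolist() == [0, 1, 2, 3, 4]
        assert (det.pvalues == 1).all()

    def test_pure_noise_rarely_detected(self):
        hits = 0
        for seed in range(10):
            y = np.random.default_rng(seed).normal(0, 1, size=(200, 400))
            det = detect_signals(CorrectedSpectra(values=y), alpha=3, beta=0.01, gamma=3)
            hits += det.detected_times.size > 0
        assert hits == 0

    def test_synthetic_events_recovered_within_windows(self, analyzed):
        m, gt, cs, det, sigs = analyzed
        windows = gt.signal_windows
        for t0, t1 in windows:
            assert any(t0 <= t <= t1 for t in det.detected_times)
        for t in det.detected_times:
            assert any(t0 <= t <= t1 for t0, t1 in windows)

    def test_detected_times_sorted_and_bumps_long_enough(self, analyzed):
        det = analyzed[3]
        assert (np.diff(det.detected_times) > 0).all()
        for t in det.detected_times:
            assert max(b.length for b in det.bumps[int(t)]) >= det.gamma

    @pytest.mark.parametrize(
        "loose,strict",
        [
            (dict(alpha=2), dict(alpha=4)),
            (dict(beta=0.1), dict(beta=0.001)),
            (dict(gamma=2), dict(gamma=6)),
        ],
    )
    def test_detection_monotone_in_cutoffs(self, rng, loose, strict):
        y = rng.normal(0, 1, size=(80, 120))
        y[20:24, 40:60] += 5.0
        y[50:52, 80:95] += 3.5
        cs = CorrectedSpectra(values=y)
        base = dict(alpha=3, beta=0.05, gamma=3)
        t_loose = set(detect_signals(cs, **{**base, **loose}).detected_times.tolist())
        t_strict = set(detect_signals(cs, **{**base, **strict}).detected_times.tolist())
        assert t_strict <= t_loose

    def test_absolute_alpha_flag_changes_threshold_scale(self, rng):
        y = rng.normal(0, 1, size=(30, 100))
        y[10, 40:50] += 4.0
        cs = CorrectedSpectra(values=y)
        relative = detect_signals(cs, alpha=3.0, beta=0.1, gamma=3)
        absolute = detect_signals(cs, alpha=3.0, beta=0.1, gamma=3, absolute_alpha=True)
        # sigma ~ 1, so both modes agree on this input
        assert relative.detected_times.tolist() == absolute.detected_times.tolist()
        # a huge absolute cutoff kills detection regardless of sigma
        none = detect_signals(cs, alpha=50.0, beta=0.1, gamma=3, absolute_alpha=True)
        assert none.detected_times.size == 0

    def test_noise_sd_recovered_on_signal_free_rows(self, analyzed):
        m, gt, cs, det, sigs = analyzed
        free = np.setdiff1d(np.arange(m.T), gt.signal_times)
        sig = det.sigma[free]
        assert abs(np.median(sig) - gt.noise_sd) / gt.noise_sd < 0.15
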