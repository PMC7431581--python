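"""Sample Entropy kernel, sliding series and EMA smoothing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from cpvi import (
    InputError,
    SEParams,
    SESeries,
    chebyshev_distance,
    compute_se,
    ema_smooth,
    sample_entropy,
    sample_entropy_profile,
    se_sliding_series,
)
from conftest import naive_sample_entropy


class TestChebyshevDistance:
    def test_identity_and_mixed_signs(self):
        assert chebyshev_distance([1, 2, 3], [1, 2, 3]) == 0.0
        assert chebyshev_distance([0, 0], [3, -4]) == 4.0

    def test_matches_elementwise_loop(self, rng):
        for _ in range(20):
            u = rng.normal(size=6)
            v = rng.normal(size=6)
            assert chebyshev_distance(u, v) == pytest.approx(
                max(abs(a - b) for a, b in zip(u, v)))

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            chebyshev_distance([1, 2], [1, 2, 3])


class TestSampleEntropy:
    def test_constant_vector_zero(self):
        # every template matches at m and m+1, so A/B = 1 exactly
        assert sample_entropy(np.full(100, 3.7), 2, 0.1) == 0.0

    def test_alternating_sequence_matches_oracle(self):
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], dtype=float)
        assert sample_entropy(x, 2, 0.5) == pytest.approx(
            naive_sample_entropy(x, 2, 0.5), abs=1e-12)

    def test_equals_naive_oracle_on_random_series(self, rng):
        for _ in range(30):
            n = int(rng.integers(30, 200))
            m = int(rng.integers(1, 5))
            x = rng.normal(size=n)
            r = float(rng.choice([0.1, 0.2, 0.3, 0.4])) * x.std()
            ours = sample_entropy(x, m, r)
            ref = naive_sample_entropy(x, m, r)
            if math.isnan(ref):
                assert math.isnan(ours)
            else:
                assert ours == pytest.approx(ref, abs=1e-10)

    def test_profile_consistent_with_single_m(self, rng):
        x = rng.normal(size=150)
        prof = sample_entropy_profile(x, 5, 0.3)
        for m in range(1, 6):
            single = sample_entropy(x, m, 0.3)
            if math.isnan(single):
                assert math.isnan(prof[m - 1])
            else:
                assert prof[m - 1] == pytest.approx(single, abs=1e-12)

    def test_gaussian_analytic_limit(self):
        # for iid Gaussians, P(|X-Y| <= r sigma) = 2 Phi(r/sqrt 2) - 1 and
        # SampEn tends to -ln of that conditional step probability
        expected = -math.log(2 * norm.cdf(0.2 / math.sqrt(2)) - 1)
        vals = []
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(10_000)
            vals.append(sample_entropy(x, 2, 0.2 * x.std()))
        assert np.mean(vals) == pytest.approx(expected, abs=0.05)

    def test_nonincreasing_in_tolerance(self, rng):
        x = rng.normal(size=200)
        rs = [0.1, 0.2, 0.3, 0.5, 1.0]
        vals = [sample_entropy(x, 2, r) for r in rs]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_nonnegative_whenever_defined(self, rng):
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(20, 120)))
            v = sample_entropy(x, int(rng.integers(1, 4)), 0.2 * x.std())
            assert math.isnan(v) or v >= 0.0

    def test_shuffling_a_sine_raises_entropy(self):
        t = np.arange(600)
        x = np.sin(2 * np.pi * t / 40.0)
        base = sample_entropy(x, 2, 0.2 * x.std())
        for seed in range(20):
            shuffled = np.random.default_rng(seed).permutation(x)
            assert sample_entropy(shuffled, 2, 0.2 * shuffled.std()) >= base

    def test_short_series_rejected(self):
        with pytest.raises(InputError):
            sample_entropy(np.zeros(4), 2, 0.1)

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            sample_entropy(np.array([1.0, np.nan] * 30), 2, 0.1)


class TestSlidingSeries:
    def test_window_count_for_15_minutes(self):
        x = np.random.default_rng(0).normal(size=900 * 40)
        series = se_sliding_series(x, 40.0, SEParams())
        assert len(series) == 59  # floor((900-30)/15) + 1
        steps = np.diff(series.times)
        np.testing.assert_allclose(steps, 15.0)

    def test_constant_channel_all_undefined(self):
        x = np.full(40 * 120, 2.0)
        series = se_sliding_series(x, 40.0, SEParams())
        assert np.isnan(series.values).all()

    def test_rate_transition_steps_upward(self):
        # concatenate slow and fast quasi-periodic breathing: SampEn of the
        # fast irregular half exceeds the slow regular half
        rng = np.random.default_rng(3)
        t1 = np.arange(0, 120, 1 / 40)
        slow = np.sin(2 * np.pi * t1 / 4.0) + 0.02 * rng.normal(size=t1.size)
        phase = np.cumsum(1.4 + 0.3 * rng.normal(size=t1.size)) / 40
        fast = np.sin(2 * np.pi * phase) + 0.02 * rng.normal(size=t1.size)
        series = se_sliding_series(np.concatenate([slow, fast]), 40.0, SEParams())
        n_half = len(series) // 2
        assert np.nanmean(series.values[n_half + 1:]) > np.nanmean(series.values[:n_half])

    def test_too_short_signal_rejected(self):
        with pytest.raises(InputError):
            se_sliding_series(np.zeros(100), 40.0, SEParams())


class TestEmaSmooth:
    def _series(self, values):
        values = np.asarray(values, dtype=float)
        return SESeries(times=np.arange(values.size, dtype=float), values=values,
                        channel="flow", params=SEParams(), smoothed=False)

    def test_constant_fixed_point(self):
        out = ema_smooth(self._series(np.full(20, 1.3)), span=8)
        np.testing.assert_allclose(out.values, 1.3)

    def test_span_one_identity(self, rng):
        x = rng.normal(size=30)
        out = ema_smooth(self._series(x), span=1)
        np.testing.assert_allclose(out.values, x)

    def test_impulse_decays_geometrically(self):
        # initialized at the first value, the response to [1, 0, 0, ...]
        # decays geometrically with ratio (1 - alpha)
        x = np.zeros(10)
        x[0] = 1.0
        span = 8
        alpha = 2.0 / (span + 1)
        out = ema_smooth(self._series(x), span=span)
        expected = (1 - alpha) ** np.arange(1, 10)
        np.testing.assert_allclose(out.values[1:], expected, atol=1e-12)
        assert out.values[0] == 1.0

    def test_nan_skipped_and_preserved(self):
        x = np.array([1.0, np.nan, 2.0, np.nan, 2.0])
        out = ema_smooth(self._series(x), span=3)
        assert np.isnan(out.values[[1, 3]]).all()
        # state carried across the gap: y2 = a*2 + (1-a)*1 with a = 0.5
        assert out.values[2] == pytest.approx(1.5)

    def test_empty_series_rejected(self):
        with pytest.raises(InputError):
            ema_smooth(self._series(np.array([])), span=8)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False),
                    min_size=1, max_size=40),
           st.integers(min_value=1, max_value=12))
    def test_output_bounded_by_defined_inputs(self, values, span):
        out = ema_smooth(self._series(values), span=span)
        defined = out.values[np.isfinite(out.values)]
        assert defined.size == len(values)
        assert defined.min() >= min(values) - 1e-9
        assert defined.max() <= max(values) + 1e-9


def test_compute_se_applies_smoothing(quiet_recording):
    from cpvi import decimate_to_40hz

    rec = decimate_to_40hz(quiet_recording)
    raw = se_sliding_series(rec.flow, rec.rate, SEParams())
    smoothed = compute_se(rec.flow, rec.rate, SEParams())
    assert smoothed.smoothed and not raw.smoothed
    # smoothing reduces dispersion but preserves the mean level
    assert np.nanstd(smoothed.values) <= np.nanstd(raw.values)
    assert np.nanmean(smoothed.values) == pytest.approx(np.nanmean(raw.values), rel=0.1)
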