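"""Segment features, personal baseline, percent change and CP-VI flagging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpvi import (
    BaselineState,
    InputError,
    SegmentFeature,
    SEParams,
    SESeries,
    Segment,
    detect_cpvi,
    percent_change,
    percent_changes,
    segment_features,
    update_baseline,
)


def _feat(value, index=0, kind="max", n_defined=59):
    return SegmentFeature(segment_index=index, feature_kind=kind, channel="flow",
                          value=value, n_defined=n_defined)


def _feats(values):
    return [_feat(v, index=i) for i, v in enumerate(values)]


class TestSegmentFeatures:
    def _series(self, times, values):
        return SESeries(times=np.asarray(times, float), values=np.asarray(values, float),
                        channel="flow", params=SEParams(), smoothed=True)

    def _segments(self, n, seg_s=900.0):
        return [Segment(index=k, start_s=k * seg_s, end_s=(k + 1) * seg_s)
                for k in range(n)]

    def test_mean_and_max(self):
        times = np.arange(15.0, 900.0, 15.0)
        values = np.full(times.size, 1.2)
        values[:3] = [0.5, 1.0, 1.5]
        series = self._series(times, values)
        segs = self._segments(1)
        assert segment_features(series, segs, "max")[0].value == pytest.approx(1.5)
        sub = self._series(times[:3], [0.5, 1.0, 1.5])
        feat = segment_features(sub, segs, "mean", min_defined=1)[0]
        assert feat.value == pytest.approx(1.0)
        assert feat.n_defined == 3
        # at the default minimum the 3-point segment is unevaluable
        assert not segment_features(sub, segs, "mean")[0].evaluable

    def test_spiked_segment_has_unique_max(self):
        times = np.arange(15.0, 2700.0, 15.0)
        rng = np.random.default_rng(0)
        values = 1.0 + 0.01 * rng.normal(size=times.size)
        spike = (times >= 900) & (times < 1800)
        values[spike] += 0.5
        series = self._series(times, values)
        feats = segment_features(series, self._segments(3), "max")
        assert np.argmax([f.value for f in feats]) == 1

    def test_undefined_points_excluded(self):
        times = np.arange(15.0, 900.0, 15.0)
        values = np.full(times.size, 2.0)
        values[::2] = np.nan
        feat = segment_features(self._series(times, values), self._segments(1), "mean")[0]
        assert feat.value == pytest.approx(2.0)
        assert feat.n_defined == times.size // 2

    def test_window_center_assignment_half_open(self):
        # a window centered exactly on the boundary belongs to the later segment
        series = self._series([899.9999, 900.0], [1.0, 5.0])
        feats = segment_features(series, self._segments(2), "max")
        assert feats[0].n_defined == 1 and feats[1].n_defined == 1


class TestBaselineAndPercentChange:
    def test_initialization(self):
        state = update_baseline(BaselineState(), _feat(1.4))
        assert state.initialized and state.baseline == 1.4

    def test_running_minimum(self):
        state = BaselineState(baseline=1.4, initialized=True)
        assert update_baseline(state, _feat(1.6)).baseline == 1.4
        assert update_baseline(state, _feat(1.1)).baseline == 1.1

    def test_unevaluable_leaves_state(self):
        state = BaselineState(baseline=1.4, initialized=True)
        bad = _feat(float("nan"), n_defined=2)
        assert update_baseline(state, bad).baseline == 1.4

    def test_percent_change_arithmetic(self):
        state = BaselineState(baseline=1.0, initialized=True)
        assert percent_change(_feat(1.3), state) == pytest.approx(30.0)
        assert percent_change(_feat(1.0), state) == 0.0
        assert percent_change(_feat(0.8), state) == pytest.approx(-20.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(InputError):
            percent_change(_feat(1.0), BaselineState(baseline=0.0, initialized=True))


class TestDetectCpvi:
    def test_flat_series_never_flagged(self):
        results = detect_cpvi(_feats([1.0, 1.0, 1.0]), th=25.0)
        assert [r.cpvi for r in results] == [False, False, False]

    def test_single_excursion_flagged(self):
        results = detect_cpvi(_feats([1.0, 1.3, 1.0]), th=25.0)
        assert [r.cpvi for r in results] == [False, True, False]
        assert results[1].pc == pytest.approx(30.0)

    def test_tie_at_threshold_is_negative(self):
        results = detect_cpvi(_feats([1.0, 1.25]), th=25.0)
        assert results[1].pc == pytest.approx(25.0)
        assert results[1].cpvi is False

    def test_first_segment_defines_baseline_never_flagged(self):
        results = detect_cpvi(_feats([5.0, 1.0]), th=15.0)
        assert results[0].pc == 0.0 and results[0].cpvi is False

    def test_baseline_updated_after_scoring(self):
        # the low segment 2 lowers the baseline for segment 3, not itself
        results = detect_cpvi(_feats([1.0, 0.5, 0.7]), th=25.0)
        assert results[1].baseline_used == 1.0 and results[1].cpvi is False
        assert results[2].baseline_used == 0.5
        assert results[2].pc == pytest.approx(40.0)

    def test_warmup_seeds_from_first_k(self):
        results = detect_cpvi(_feats([2.0, 1.0, 2.0]), th=25.0, baseline_warmup=2)
        assert results[0].baseline_used == 1.0
        assert results[0].cpvi is True  # first segment is 100 % above the warmup min

    def test_unevaluable_segment_returns_none(self):
        feats = [_feat(1.0, 0), _feat(float("nan"), 1, n_defined=0), _feat(1.5, 2)]
        results = detect_cpvi(feats, th=25.0)
        assert results[1].cpvi is None and math.isnan(results[1].pc)
        assert results[2].cpvi is True

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            detect_cpvi([], th=25.0)

    def test_matches_straight_line_recomputation(self, rng):
        values = 1.0 + 0.3 * rng.random(24)
        results = detect_cpvi(_feats(values), th=20.0)
        baseline = values[0]
        for v, res in zip(values, results):
            pc = 100.0 * (v - baseline) / baseline
            assert res.pc == pytest.approx(pc)
            assert res.cpvi == (pc > 20.0)
            baseline = min(baseline, v)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.1, max_value=5.0), min_size=2, max_size=30))
    def test_flag_count_nonincreasing_in_threshold(self, values):
        feats = _feats(values)
        counts = [sum(1 for r in detect_cpvi(feats, th=th) if r.cpvi)
                  for th in range(15, 55, 5)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.1, max_value=5.0), min_size=2, max_size=30),
           st.floats(min_value=0.01, max_value=100.0))
    def test_detection_is_scale_free(self, values, scale):
        base = detect_cpvi(_feats(values), th=25.0)
        scaled = detect_cpvi(_feats([v * scale for v in values]), th=25.0)
        for a, b in zip(base, scaled):
            assert a.cpvi == b.cpvi
            assert a.pc == pytest.approx(b.pc, rel=1e-9, abs=1e-6)


class TestPercentChanges:
    def test_agrees_with_detect_cpvi(self, rng):
        values = 1.0 + rng.random(15)
        values[4] = np.nan
        pcs = percent_changes(values)
        results = detect_cpvi(_feats(values), th=25.0)
        for pc, res in zip(pcs, results):
            if math.isnan(pc):
                assert math.isnan(res.pc)
            else:
                assert pc == pytest.approx(res.pc)

    def test_baseline_is_running_minimum(self, rng):
        values = 1.0 + rng.random(20)
        pcs = percent_changes(values)
        run_min = np.minimum.accumulate(values)
        expected = 100.0 * (values - np.concatenate([[values[0]], run_min[:-1]])) \
            / np.concatenate([[values[0]], run_min[:-1]])
        np.testing.assert_allclose(pcs, expected)
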