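"""Per-segment SE features, personal baseline tracking and CP-VI flagging.

A complex patient-ventilator interaction (CP-VI) — a >50 % respiratory-rate
change and/or >30 % asynchronous breaths over 3 min — raises the irregularity
of the flow and pressure waveforms, and with it their Sample Entropy.  The
detector therefore summarises the smoothed SE series per 15-min segment (mean
or maximum over the windows whose centres fall in the segment), tracks the
patient's personal baseline as the running minimum of those features, and
flags a segment when its percent change from baseline exceeds a threshold Th.

The baseline is initialised with the first evaluable segment and updated
*after* each segment is scored, so detection is causal: a quiet segment
lowers the baseline for later segments but never re-labels itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .entropy import Channel, SEParams, SESeries, compute_se
from .exceptions import InputError
from .waveform_io import ANALYSIS_RATE, Segment, WaveformRecording, decimate_to_40hz, partition_segments

logger = logging.getLogger(__name__)

FeatureKind = Literal["mean", "max"]

#: minimum number of defined SE points for a segment feature to be evaluable
MIN_DEFINED_POINTS = 10


@dataclass
class SegmentFeature:
    """Aggregate of the SE series over one segment (mean or max, nats)."""

    segment_index: int
    feature_kind: FeatureKind
    channel: Channel
    value: float  # NaN when unevaluable
    n_defined: int

    @property
    def evaluable(self) -> bool:
        # the value is NaN exactly when the defined-point minimum was not met
        return math.isfinite(self.value)


@dataclass(frozen=True)
class BaselineState:
    """Running-minimum personal baseline of an SE feature."""

    baseline: float = math.nan
    initialized: bool = False


@dataclass
class DetectionResult:
    """Outcome of CP-VI evaluation for one segment."""

    segment_index: int
    pc: float  # percent change from baseline (%); NaN if unevaluable
    th: float  # threshold applied (%)
    cpvi: Optional[bool]  # None when the segment could not be evaluated
    baseline_used: float


def segment_features(series: SESeries, segments: Sequence[Segment],
                     kind: FeatureKind,
                     min_defined: int = MIN_DEFINED_POINTS) -> list[SegmentFeature]:
    """Aggregate an SE series into one feature per segment.

    A window contributes to the segment containing its centre timestamp
    (half-open [start, end)).  Undefined SE points are excluded; a segment
    with fewer than ``min_defined`` defined points is marked unevaluable
    (NaN value) rather than raising.
    """
    if kind not in ("mean", "max"):
        raise InputError(f"unknown feature kind {kind!r}")
    feats = []
    for seg in segments:
        in_seg = (series.times >= seg.start_s) & (series.times < seg.end_s)
        vals = series.values[in_seg]
        vals = vals[np.isfinite(vals)]
        n_def = int(vals.size)
        if n_def >= min_defined:
            value = float(vals.mean() if kind == "mean" else vals.max())
        else:
            value = math.nan
        feats.append(SegmentFeature(segment_index=seg.index, feature_kind=kind,
                                    channel=series.channel, value=value, n_defined=n_def))
    return feats


def update_baseline(state: BaselineState, feature: SegmentFeature) -> BaselineState:
    """Lower the baseline if the new segment's feature is lower (running min)."""
    if not feature.evaluable:
        logger.info("segment %d unevaluable; baseline unchanged", feature.segment_index)
        return state
    if not state.initialized:
        return BaselineState(baseline=feature.value, initialized=True)
    return BaselineState(baseline=min(state.baseline, feature.value), initialized=True)


def percent_change(feature: SegmentFeature, state: BaselineState) -> float:
    """Percent change of a segment feature from the personal baseline."""
    if not state.initialized:
        raise InputError("baseline not initialized")
    if state.baseline == 0:
        raise InputError("baseline is zero; percent change undefined")
    return 100.0 * (feature.value - state.baseline) / state.baseline


def detect_cpvi(features: Sequence[SegmentFeature], th: float,
                baseline_warmup: int = 1) -> list[DetectionResult]:
    """Flag CP-VI segments by strict percent-change thresholding.

    Iterates segments in order; each evaluable segment's percent change (PC)
    against the current baseline is compared with ``th`` (CP-VI iff PC > th,
    ties negative), after which the baseline absorbs the segment's value.
    ``baseline_warmup`` seeds the baseline from the minimum over the first k
    evaluable segments before any segment is scored (k=1 reproduces plain
    first-segment initialisation, under which the first segment always has
    PC = 0 and can never be flagged).
    """
    if len(features) == 0:
        raise InputError("empty feature list")
    if baseline_warmup < 1:
        raise InputError("baseline_warmup must be >= 1")
    state = BaselineState()
    if baseline_warmup > 1:
        for feat in features[:baseline_warmup]:
            state = update_baseline(state, feat)
    results = []
    for feat in features:
        if feat.evaluable and not state.initialized:
            # the first evaluable segment defines the baseline and scores PC = 0
            state = update_baseline(state, feat)
        if not feat.evaluable or not state.initialized or state.baseline == 0:
            results.append(DetectionResult(segment_index=feat.segment_index, pc=math.nan,
                                           th=th, cpvi=None,
                                           baseline_used=state.baseline))
            state = update_baseline(state, feat)
            continue
        pc = percent_change(feat, state)
        results.append(DetectionResult(segment_index=feat.segment_index, pc=pc, th=th,
                                       cpvi=bool(pc > th), baseline_used=state.baseline))
        state = update_baseline(state, feat)
    return results


def percent_changes(feature_values: Sequence[float], baseline_warmup: int = 1) -> np.ndarray:
    """Percent-change series for an ordered array of segment feature values.

    Vector form of :func:`detect_cpvi` without a threshold: PC does not
    depend on Th, so grid searches cache PC once and compare against every
    threshold afterwards.  NaN inputs (unevaluable segments) yield NaN and
    leave the baseline untouched.
    """
    x = np.asarray(feature_values, dtype=float)
    if x.size == 0:
        raise InputError("empty feature list")
    pc = np.full_like(x, np.nan)
    baseline = math.nan
    if baseline_warmup > 1:
        head = x[:baseline_warmup]
        head = head[np.isfinite(head)]
        if head.size:
            baseline = float(head.min())
    for t in range(x.size):
        v = x[t]
        if not math.isfinite(v):
            continue
        if math.isnan(baseline):
            baseline = v
        if baseline != 0:
            pc[t] = 100.0 * (v - baseline) / baseline
        baseline = min(baseline, v)
    return pc


def detect_recording(rec: WaveformRecording, channel: Channel = "flow",
                     params: SEParams | None = None, th: float = 25.0,
                     feature_kind: FeatureKind = "max", segment_minutes: float = 15.0,
                     baseline_warmup: int = 1) -> list[DetectionResult]:
    """End-to-end CP-VI detection on a raw recording.

    Decimates to 40 Hz, computes the smoothed SE series of the requested
    channel, aggregates per segment and applies percent-change detection.
    Defaults are the flow-channel operating point (m=2, r=0.2, Th=25 %, max
    feature); for the pressure channel use ``SEParams(m=4)`` with ``th=30``.
    """
    params = params or SEParams()
    rec40 = decimate_to_40hz(rec) if rec.rate != ANALYSIS_RATE else rec
    segments = partition_segments(rec40, segment_minutes)
    series = compute_se(rec40.channel(channel), rec40.rate, params, channel=channel,
                        start_time=rec40.start_time)
    feats = segment_features(series, segments, feature_kind)
    return detect_cpvi(feats, th, baseline_warmup=baseline_warmup)
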