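"""Synthetic labelled ventilator waveforms for end-to-end testing.

Generates two-channel (flow, paw) recordings from single-compartment breath
templates under pressure-support (PSV) and assist-control (ACV) morphologies:
PSV delivers a pressure plateau with decelerating inspiratory flow, ACV a
near-square inspiratory flow with a ramping pressure; expiration is passive
(exponential) in both, with the expiratory amplitude chosen so inhaled and
exhaled volumes balance.  Breath-to-breath timing and amplitude jitter make
the signal quasi-periodic.

Two kinds of scripted events perturb the recording:

* ``rr_change`` — the instantaneous respiratory rate moves to a multiple of
  the baseline rate (with increased breath-to-breath variability, as seen in
  distressed breathing);
* ``asynchrony_cluster`` — a fraction of breaths is replaced by asynchronous
  morphologies (ineffective expiratory effort, double cycling, premature
  cycling, prolonged cycling, reverse triggering).

Ground truth follows the clinical CP-VI definition: a 3-min window is
positive iff its mean respiratory rate differs from the recording's baseline
rate by more than 50 % and/or more than 30 % of its breaths are asynchronous;
a 15-min segment is positive iff it contains a positive 3-min window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .waveform_io import Segment, VentMode, WaveformRecording, write_csv

ASYNC_TYPES = (
    "ineffective_effort",
    "double_cycling",
    "premature_cycling",
    "prolonged_cycling",
    "reverse_triggering",
)

#: CP-VI definition constants: 3-min evaluation window, >50 % rate change,
#: >30 % asynchronous breaths
TRUTH_WINDOW_S = 180.0
RR_CHANGE_LIMIT = 0.50
ASYNC_FRACTION_LIMIT = 0.30


@dataclass
class SimEvent:
    """A scripted disturbance within a recording (times in minutes)."""

    kind: str  # "rr_change" | "asynchrony_cluster"
    start_min: float
    end_min: float
    rr_multiplier: float = 1.0
    asynchrony_fraction: float = 0.0
    asynchrony_type: str = "mixed"  # one of ASYNC_TYPES or "mixed"
    rr_jitter_sd: float = 0.06  # breath-timing variability during rr_change

    def __post_init__(self) -> None:
        if self.kind not in ("rr_change", "asynchrony_cluster"):
            raise InputError(f"unknown event kind {self.kind!r}")
        if self.end_min <= self.start_min:
            raise InputError("event must have positive duration")
        if not 0.0 <= self.asynchrony_fraction <= 1.0:
            raise InputError("asynchrony_fraction must lie in [0, 1]")
        if self.asynchrony_type != "mixed" and self.asynchrony_type not in ASYNC_TYPES:
            raise InputError(f"unknown asynchrony type {self.asynchrony_type!r}")


@dataclass
class SimConfig:
    """Recording-level simulation settings."""

    mode: VentMode = VentMode.PSV
    base_rr: float = 16.0  # breaths/min
    duration_min: float = 60.0
    rate: float = 200.0  # Hz
    noise_sd: float = 0.02  # fraction of channel amplitude
    events: list[SimEvent] = field(default_factory=list)
    seed: int = 0
    subject_id: str = "sim"
    rr_jitter_sd: float = 0.03  # baseline breath-timing variability
    peep: float = 6.0  # cmH2O
    pressure_support: float = 10.0  # cmH2O above PEEP (PSV)
    driving_pressure: float = 12.0  # cmH2O above PEEP at end-inspiration (ACV)
    peak_flow: float = 50.0  # L/min

    def __post_init__(self) -> None:
        if not 5.0 <= self.base_rr <= 60.0:
            raise InputError("base_rr must lie in [5, 60] breaths/min")
        if self.duration_min <= 0 or self.rate <= 0:
            raise InputError("duration and rate must be positive")
        for ev in self.events:
            if ev.end_min > self.duration_min:
                raise InputError(
                    f"event [{ev.start_min}, {ev.end_min}] min exceeds the "
                    f"{self.duration_min}-min recording"
                )


@dataclass
class BreathParams:
    """Parameters of a single breath cycle."""

    rr: float = 16.0  # instantaneous rate -> cycle length 60/rr
    ti_frac: float = 0.33  # inspiratory fraction of the cycle
    peep: float = 6.0
    pressure_support: float = 10.0
    driving_pressure: float = 12.0
    peak_flow: float = 50.0
    tau_exp: float = 0.55  # expiratory time constant, s
    asynchrony: Optional[str] = None

    def __post_init__(self) -> None:
        if not 3.0 <= self.rr <= 90.0:
            raise InputError(f"rr out of physiological range: {self.rr}")
        if not 0.1 <= self.ti_frac <= 0.7:
            raise InputError("ti_frac out of range")
        if self.peep < 0 or self.peak_flow <= 0 or self.tau_exp <= 0:
            raise InputError("invalid breath parameters")
        if self.asynchrony is not None and self.asynchrony not in ASYNC_TYPES:
            raise InputError(f"unknown asynchrony {self.asynchrony!r}")


def _insp_psv(n: int, t: np.ndarray, p: BreathParams):
    """Pressure-support inspiration: plateau pressure, decelerating flow."""
    paw = p.peep + p.pressure_support * (1.0 - np.exp(-t / 0.05))
    flow = p.peak_flow * (1.0 - np.exp(-t / 0.04)) * np.exp(-t / 0.5)
    return flow, paw


def _insp_acv(n: int, t: np.ndarray, p: BreathParams):
    """Volume-control inspiration: near-square flow, ramping pressure."""
    ti = t[-1] if t.size else 1.0
    flow = p.peak_flow * (1.0 - np.exp(-t / 0.025))
    resistive = 0.35 * p.driving_pressure
    paw = p.peep + resistive * (1.0 - np.exp(-t / 0.025)) \
        + (p.driving_pressure - resistive) * (t / max(ti, 1e-9))
    return flow, paw


def _expiration(n_exp: int, fs: float, v_insp: float, p: BreathParams):
    """Passive expiration whose integrated volume matches inspiration."""
    t = np.arange(n_exp) / fs
    te = n_exp / fs
    shape = np.exp(-t / p.tau_exp)
    # scale so that integral of flow (L/min over seconds -> L) equals v_insp
    denom = p.tau_exp * (1.0 - np.exp(-te / p.tau_exp))
    peak = (v_insp * 60.0) / max(denom, 1e-9)
    flow = -peak * shape * (1.0 - np.exp(-t / 0.03))
    paw = p.peep + 0.0 * t
    return flow, paw


def _segments_insp(mode: VentMode, ti: float, fs: float, p: BreathParams):
    n_i = max(int(round(ti * fs)), 2)
    t = np.arange(n_i) / fs
    if mode == VentMode.PSV:
        return _insp_psv(n_i, t, p)
    return _insp_acv(n_i, t, p)


def simulate_breath(mode: VentMode, params: BreathParams, rate: float,
                    rng: Optional[np.random.Generator] = None):
    """One breath cycle (flow L/min, paw cmH2O) at the given sampling rate.

    Asynchronous morphologies perturb both the waveform shape and the breath
    timing, as their clinical counterparts do: an ineffective effort is a
    missed trigger (expiratory flow/pressure deflection and a prolonged
    interval before the next delivered breath), double cycling stacks two
    inspirations, premature cycling shortens the inspiratory time and hastens
    the next cycle, prolonged cycling stretches both, and reverse triggering
    adds a large mid-expiratory effort with jittered timing.  With the same
    parameters and rng state the output is deterministic.
    """
    if rate <= 0:
        raise InputError("rate must be positive")
    rng = rng or np.random.default_rng(0)
    p = params
    t_tot = 60.0 / p.rr
    kind = p.asynchrony

    if kind == "ineffective_effort":
        if mode == VentMode.PSV:
            # missed trigger: the patient-cycled ventilator waits
            t_tot *= rng.uniform(1.25, 1.7)
    elif kind == "reverse_triggering":
        t_tot *= rng.uniform(0.85, 1.15)
    elif kind == "double_cycling":
        t_tot *= rng.uniform(0.9, 1.1)
    elif kind == "premature_cycling":
        t_tot *= rng.uniform(0.6, 0.85)
    elif kind == "prolonged_cycling":
        t_tot *= rng.uniform(1.1, 1.4)

    ti = p.ti_frac * (60.0 / p.rr)
    if kind == "premature_cycling":
        ti *= 0.45
    elif kind == "prolonged_cycling":
        ti *= 1.8
    ti = min(ti, 0.8 * t_tot)

    if kind == "double_cycling":
        # two stacked inspirations separated by a brief expiratory gap
        f1, pw1 = _segments_insp(mode, ti * 0.9, rate, p)
        gap_n = max(int(round(0.15 * rate)), 1)
        f2, pw2 = _segments_insp(mode, ti * 0.8, rate, p)
        v1 = (np.sum(f1) + np.sum(f2)) / 60.0 / rate
        n_exp = max(int(round(t_tot * rate)) - f1.size - gap_n - f2.size, 2)
        fg = -0.2 * p.peak_flow * np.ones(gap_n)
        pg = np.full(gap_n, p.peep + 0.3 * p.pressure_support)
        fe, pe = _expiration(n_exp, rate, v1 + np.sum(fg) / 60.0 / rate, p)
        flow = np.concatenate([f1, fg, f2, fe])
        paw = np.concatenate([pw1, pg, pw2, pe])
    else:
        fi, pwi = _segments_insp(mode, ti, rate, p)
        v_insp = np.sum(fi) / 60.0 / rate
        n_exp = max(int(round(t_tot * rate)) - fi.size, 2)
        fe, pe = _expiration(n_exp, rate, v_insp, p)
        flow = np.concatenate([fi, fe])
        paw = np.concatenate([pwi, pe])

        if kind in ("ineffective_effort", "reverse_triggering"):
            # patient effort during expiration: flow bump and pressure dip
            strong = kind == "reverse_triggering"
            amp_f = (0.6 if strong else 0.4) * p.peak_flow * rng.uniform(0.7, 1.3)
            amp_p = (0.6 if strong else 0.3) * p.pressure_support * rng.uniform(0.7, 1.3)
            width = rng.uniform(0.25, 0.5)  # s
            n = flow.size
            t0 = fi.size / rate + rng.uniform(0.2, 0.7) * (n - fi.size) / rate
            tt = np.arange(n) / rate
            bump = np.exp(-0.5 * ((tt - t0) / (width / 2.355)) ** 2)
            flow = flow + amp_f * bump
            paw = paw - amp_p * bump
        elif kind == "premature_cycling":
            # continued effort after early cycling distorts early expiration
            n = flow.size
            tt = np.arange(n) / rate
            t0 = fi.size / rate + 0.15
            bump = np.exp(-0.5 * ((tt - t0) / 0.12) ** 2)
            flow = flow + 0.25 * p.peak_flow * bump
            paw = paw - 0.1 * p.pressure_support * bump

    return flow, paw


@dataclass
class BreathLog:
    """Realized per-breath bookkeeping used by the pure labelling function."""

    table: pd.DataFrame  # columns: start_s, duration_s, rr_inst, asynchronous, kind


def label_windows(breaths: pd.DataFrame, duration_s: float, base_rr: float,
                  window_s: float = TRUTH_WINDOW_S) -> pd.DataFrame:
    """CP-VI ground truth per contiguous 3-min window (pure function).

    A window is positive iff the mean instantaneous rate of the breaths
    starting in it deviates from ``base_rr`` by more than 50 %, and/or more
    than 30 % of those breaths are asynchronous.
    """
    n_win = int(duration_s // window_s)
    rows = []
    for k in range(n_win):
        lo, hi = k * window_s, (k + 1) * window_s
        sel = breaths[(breaths.start_s >= lo) & (breaths.start_s < hi)]
        if len(sel) == 0:
            rr_mean, frac = 0.0, 0.0
        else:
            rr_mean = float(sel.rr_inst.mean())
            frac = float(sel.asynchronous.mean())
        rate_dev = abs(rr_mean - base_rr) / base_rr
        rows.append(
            {
                "window": k,
                "start_s": lo,
                "end_s": hi,
                "rr_mean": rr_mean,
                "rate_change": rate_dev,
                "async_fraction": frac,
                "positive": bool(rate_dev > RR_CHANGE_LIMIT or frac > ASYNC_FRACTION_LIMIT),
            }
        )
    return pd.DataFrame(rows)


def label_segments(truth: pd.DataFrame, segment_minutes: float = 15.0) -> list[int]:
    """Per-segment labels: positive iff any overlapping 3-min window is."""
    seg_s = segment_minutes * 60.0
    n_seg = int((truth.end_s.max() if len(truth) else 0) // seg_s)
    labels = []
    for k in range(n_seg):
        lo, hi = k * seg_s, (k + 1) * seg_s
        overlap = truth[(truth.end_s > lo) & (truth.start_s < hi)]
        labels.append(int(overlap.positive.any()))
    return labels


def _rr_target(t_s: float, config: SimConfig):
    """Instantaneous target rate and jitter SD, honouring rr_change events."""
    rr = config.base_rr
    jitter = config.rr_jitter_sd
    for ev in config.events:
        if ev.kind == "rr_change" and ev.start_min * 60.0 <= t_s < ev.end_min * 60.0:
            rr = config.base_rr * ev.rr_multiplier
            jitter = max(jitter, ev.rr_jitter_sd)
    return rr, jitter


def _cluster_jitter(fraction: float) -> float:
    """Breath-timing variability during an asynchrony cluster.

    Clusters accompany patient distress, so every breath in the cluster (not
    only the asynchronous ones) carries elevated timing variability, scaling
    with cluster severity.
    """
    return 0.03 + 0.30 * fraction


def _cluster_rate_boost(fraction: float) -> float:
    """Elevated respiratory drive during a cluster: mean rate rises with severity."""
    return 1.0 + 0.55 * fraction


def _active_cluster(t_s: float, config: SimConfig) -> Optional[SimEvent]:
    for ev in config.events:
        if ev.kind == "asynchrony_cluster" and ev.start_min * 60.0 <= t_s < ev.end_min * 60.0:
            return ev
    return None


def simulate_recording(config: SimConfig):
    """Synthesize a labelled recording.

    Returns ``(recording, truth, segments)``: the 200-Hz (by default)
    two-channel recording with additive Gaussian noise, the per-3-min truth
    table and the per-15-min :class:`Segment` list with labels filled in.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.rate
    duration_s = config.duration_min * 60.0
    n_total = int(round(duration_s * fs))

    flow_parts, paw_parts, rows = [], [], []
    t = 0.0
    n_done = 0
    cluster_tally: dict = {}  # id(event) -> [breaths seen, asynchronous]
    while n_done < n_total:
        rr_tgt, jitter = _rr_target(t, config)
        cluster = _active_cluster(t, config)
        if cluster is not None:
            jitter = max(jitter, _cluster_jitter(cluster.asynchrony_fraction))
            rr_tgt *= _cluster_rate_boost(cluster.asynchrony_fraction)
        rr_inst = float(np.clip(rr_tgt * np.exp(rng.normal(0.0, jitter)), 3.0, 90.0))
        kind = None
        if cluster is not None:
            # adaptive thinning keeps the realized asynchronous fraction close
            # to the event's target, so labels match the intended severity
            seen, hits = cluster_tally.setdefault(id(cluster), [0, 0])
            target = cluster.asynchrony_fraction
            p = float(np.clip(target + 0.8 * (target * seen - hits), 0.0, 1.0))
            if rng.random() < p:
                kind = (cluster.asynchrony_type if cluster.asynchrony_type != "mixed"
                        else ASYNC_TYPES[rng.integers(len(ASYNC_TYPES))])
            cluster_tally[id(cluster)] = [seen + 1, hits + (kind is not None)]
        amp_jit = float(rng.normal(1.0, 0.03))
        params = BreathParams(
            rr=rr_inst,
            peep=config.peep,
            pressure_support=config.pressure_support * amp_jit,
            driving_pressure=config.driving_pressure * amp_jit,
            peak_flow=config.peak_flow * amp_jit,
            asynchrony=kind,
        )
        flow_b, paw_b = simulate_breath(config.mode, params, fs, rng)
        flow_parts.append(flow_b)
        paw_parts.append(paw_b)
        duration_b = flow_b.size / fs
        rows.append(
            {
                "start_s": t,
                "duration_s": duration_b,
                # realized rate: morphologies may stretch or shorten the cycle
                "rr_inst": 60.0 / duration_b,
                "asynchronous": kind is not None,
                "kind": kind or "",
            }
        )
        t += flow_b.size / fs
        n_done += flow_b.size

    flow = np.concatenate(flow_parts)[:n_total]
    paw = np.concatenate(paw_parts)[:n_total]
    # additive sensor noise scaled to each channel's half peak-to-peak amplitude
    for x in (flow, paw):
        amp = 0.5 * (np.max(x) - np.min(x))
        x += rng.normal(0.0, config.noise_sd * amp, size=x.size)

    rec = WaveformRecording(flow=flow, paw=paw, rate=fs, subject_id=config.subject_id,
                            mode=config.mode)
    breaths = pd.DataFrame(rows)
    truth = label_windows(breaths, duration_s, config.base_rr)
    seg_labels = label_segments(truth)
    segments = [
        Segment(index=k, start_s=k * 900.0, end_s=(k + 1) * 900.0,
                label=lab, mode=config.mode)
        for k, lab in enumerate(seg_labels)
    ]
    return rec, truth, segments


# --- benchmark corpus -------------------------------------------------------

def _corpus_configs(n_recordings: int, balance: float, seed: int,
                    duration_min: float = 60.0) -> list[SimConfig]:
    """Recording configurations for the detection benchmark corpus.

    Positive recordings carry one or two CP-VI events in segments 2-4 with
    graded severity (weak clusters just above the 30 % asynchrony limit up to
    strong clusters and large rate shifts); negative recordings may carry
    sub-threshold disturbances (mild clusters / small rate drifts) so that
    negatives are not trivially quiet.  Event severities are graded so the
    entropy percent-change margin between classes brackets the 25 % detection
    threshold; the first segment is always event-free to provide a clean
    personal baseline.  All events are aligned to the 3-min truth grid.
    """
    if n_recordings < 2:
        raise InputError("need at least two recordings")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_recordings * 4).reshape(n_recordings, 4)
    n_pos = int(round(balance * n_recordings))
    configs = []
    for i in range(n_recordings):
        rng = np.random.default_rng(child_seeds[i, 0])
        mode = VentMode.PSV if i % 2 == 0 else VentMode.ACV
        base_rr = float(rng.uniform(13.0, 20.0))
        positive = i < n_pos
        events: list[SimEvent] = []
        # events sit on the 3-min truth grid, interior to segments 2..4 and
        # ending >= 3 min before the next boundary so that straddling SE
        # windows and EMA memory cannot leak an event into the next segment
        def _place(seg: int, dur_min: float) -> tuple[float, float]:
            k_max = int((12.0 - dur_min) // 3.0)
            start = seg * 15.0 + 3.0 * int(rng.integers(0, k_max + 1))
            return start, start + dur_min

        n_seg = int(duration_min // 15.0)
        if n_seg < 2:
            raise InputError("corpus recordings need at least two 15-min segments")
        seg_choices = rng.permutation(np.arange(1, n_seg))
        if positive:
            n_ev = min(1 + int(rng.random() < 0.4), len(seg_choices))
            for j in range(n_ev):
                seg = int(seg_choices[j])
                severity = rng.random()
                if severity < 0.40:  # brief weak cluster: just above the 30 % limit
                    start, end = _place(seg, float(rng.choice([3.0, 6.0])))
                    events.append(SimEvent("asynchrony_cluster", start, end,
                                           asynchrony_fraction=float(rng.uniform(0.38, 0.46))))
                elif severity < 0.75:  # strong cluster
                    start, end = _place(seg, float(rng.choice([6.0, 9.0])))
                    events.append(SimEvent("asynchrony_cluster", start, end,
                                           asynchrony_fraction=float(rng.uniform(0.55, 0.85))))
                elif severity < 0.92:  # large rate rise
                    start, end = _place(seg, float(rng.choice([6.0, 9.0])))
                    events.append(SimEvent("rr_change", start, end,
                                           rr_multiplier=float(rng.uniform(1.7, 2.2))))
                else:  # large rate fall: a positive the entropy rise cannot see
                    start, end = _place(seg, 9.0)
                    events.append(SimEvent("rr_change", start, end,
                                           rr_multiplier=float(rng.uniform(0.35, 0.45))))
        else:
            # every negative recording carries one sub-threshold rate drift
            # (a hard negative), plus sometimes a mild asynchrony cluster
            start, end = _place(int(seg_choices[0]), 6.0)
            events.append(SimEvent("rr_change", start, end,
                                   rr_multiplier=float(rng.uniform(1.16, 1.28)),
                                   rr_jitter_sd=0.04))
            if len(seg_choices) > 1 and rng.random() < 0.45:
                start, end = _place(int(seg_choices[1]), 6.0)
                events.append(SimEvent("asynchrony_cluster", start, end,
                                       asynchrony_fraction=float(rng.uniform(0.06, 0.12))))
        configs.append(
            SimConfig(mode=mode, base_rr=base_rr, duration_min=duration_min,
                      events=events, seed=int(child_seeds[i, 1]),
                      subject_id=f"sim{i:03d}")
        )
    return configs


def build_corpus(n_recordings: int = 30, balance: float = 0.5, seed: int = 0,
                 duration_min: float = 60.0):
    """In-memory benchmark corpus: list of (recording, truth, segments)."""
    return [simulate_recording(cfg)
            for cfg in _corpus_configs(n_recordings, balance, seed, duration_min)]


def make_benchmark_corpus(n_recordings: int, balance: float, seed: int, out_dir,
                          duration_min: float = 60.0) -> pd.DataFrame:
    """Write a benchmark corpus to disk: CSV waveforms plus a manifest.

    The manifest has one row per 15-min segment: path, subject, segment
    index, gold label and ventilation mode.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cfg in _corpus_configs(n_recordings, balance, seed, duration_min):
        rec, truth, segments = simulate_recording(cfg)
        path = out_dir / f"{cfg.subject_id}.csv"
        write_csv(rec, path)
        for seg in segments:
            rows.append(
                {
                    "path": path.name,
                    "subject_id": cfg.subject_id,
                    "segment_index": seg.index,
                    "label": seg.label,
                    "mode": cfg.mode.value,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
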