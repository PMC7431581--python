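"""Reading, validation, decimation and segmentation of ventilator waveforms.

A recording is a pair of synchronously sampled channels: airway flow (L/min)
and airway pressure (cmH2O).  Bedside acquisition systems typically store them
at 200 Hz; entropy analysis runs at 40 Hz, so recordings are decimated with an
anti-aliasing low-pass before downsampling.  Recordings are partitioned into
contiguous fixed-length segments (15 min by default) which are the unit of
labelling and detection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import FormatError, InputError, SamplingError, UnsupportedRateError

logger = logging.getLogger(__name__)

#: canonical CSV column names (written by :func:`write_csv`)
CSV_COLUMNS = ("time_s", "flow_lpm", "paw_cmh2o")

#: analysis sampling rate in Hz
ANALYSIS_RATE = 40.0


class VentMode(str, Enum):
    """Ventilation mode of a recording or segment."""

    PSV = "PSV"
    ACV = "ACV"
    UNKNOWN = "UNKNOWN"


@dataclass
class WaveformRecording:
    """Two-channel ventilator recording.

    Parameters
    ----------
    flow : ndarray
        Airway flow samples (L/min).
    paw : ndarray
        Airway pressure samples (cmH2O).
    rate : float
        Sampling frequency (Hz).
    start_time : float
        Offset of the first sample, seconds.
    subject_id : str
        Opaque identifier.
    mode : VentMode
        Ventilation mode, if known.
    """

    flow: np.ndarray
    paw: np.ndarray
    rate: float
    start_time: float = 0.0
    subject_id: str = ""
    mode: VentMode = VentMode.UNKNOWN

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=np.float64)
        self.paw = np.asarray(self.paw, dtype=np.float64)
        if self.flow.ndim != 1 or self.paw.ndim != 1:
            raise InputError("flow and paw must be 1-D sample arrays")
        if self.flow.size == 0 or self.flow.size != self.paw.size:
            raise InputError(
                f"flow and paw must have equal nonzero length "
                f"(got {self.flow.size} and {self.paw.size})"
            )
        if not self.rate > 0:
            raise InputError(f"sampling rate must be positive (got {self.rate})")
        if not (np.isfinite(self.flow).all() and np.isfinite(self.paw).all()):
            raise InputError("recording contains NaN/inf samples; gaps are rejected, not imputed")

    @property
    def n_samples(self) -> int:
        return int(self.flow.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds from recording start."""
        return self.start_time + np.arange(self.n_samples) / self.rate

    def channel(self, name: str) -> np.ndarray:
        if name == "flow":
            return self.flow
        if name == "paw":
            return self.paw
        raise InputError(f"unknown channel {name!r}; expected 'flow' or 'paw'")


@dataclass
class Segment:
    """Half-open time interval [start_s, end_s) within a recording."""

    index: int
    start_s: float
    end_s: float
    label: Optional[int] = None
    mode: VentMode = VentMode.UNKNOWN

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _map_columns(columns: Sequence[str]) -> dict:
    """Map CSV header names onto time/flow/paw roles by prefix, case-insensitive."""
    roles = {}
    for col in columns:
        low = col.strip().lower()
        for role in ("time", "flow", "paw"):
            if low.startswith(role) and role not in roles:
                roles[role] = col
    return roles


def load_recording(path, fmt: Optional[str] = None, subject_id: str = "",
                   mode: VentMode = VentMode.UNKNOWN) -> WaveformRecording:
    """Load and validate a two-channel recording from CSV/TSV or EDF.

    The format is inferred from the file suffix unless ``fmt`` ("csv" or
    "edf") is given.  CSV/TSV must carry time, flow and paw columns (matched
    by name prefix, e.g. ``time_s, flow_lpm, paw_cmh2o``); EDF channels are
    matched by case-insensitive label substring.  Sampling uniformity is
    verified: the maximum timestamp jitter must stay below half a sample
    period.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "edf":
        return _load_edf(path, subject_id=subject_id, mode=mode)
    if fmt != "csv":
        raise InputError(f"unsupported format {fmt!r}")

    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty file: {path}") from exc
    if df.empty:
        raise InputError(f"no samples in {path}")
    roles = _map_columns(df.columns)
    missing = [r for r in ("time", "flow", "paw") if r not in roles]
    if missing:
        raise FormatError(f"{path}: missing column(s) for {missing}; header was {list(df.columns)}")

    t = df[roles["time"]].to_numpy(dtype=np.float64)
    if t.size < 2:
        raise InputError(f"{path}: need at least 2 samples to establish a rate")
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise SamplingError(f"{path}: non-increasing timestamps")
    rate = 1.0 / dt
    # uniformity check against the ideal grid anchored at the first sample
    ideal = t[0] + np.arange(t.size) * dt
    jitter = np.max(np.abs(t - ideal))
    if jitter >= 0.5 * dt:
        raise SamplingError(
            f"{path}: non-uniform sampling (max jitter {jitter:.4g} s "
            f"exceeds half the {dt:.4g} s sample period)"
        )
    return WaveformRecording(
        flow=df[roles["flow"]].to_numpy(dtype=np.float64),
        paw=df[roles["paw"]].to_numpy(dtype=np.float64),
        rate=float(round(rate, 6)),
        start_time=float(t[0]),
        subject_id=subject_id or path.stem,
        mode=mode,
    )


def _load_edf(path: Path, subject_id: str = "",
              mode: VentMode = VentMode.UNKNOWN) -> WaveformRecording:
    """Read an EDF file, mapping channels by label substring (flow / paw)."""
    import mne  # deferred: only needed for EDF input

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = raw.ch_names
    picks = {}
    for role in ("flow", "paw"):
        match = [name for name in labels if role in name.lower()]
        if not match:
            raise FormatError(f"{path}: no EDF channel label contains {role!r}; labels: {labels}")
        picks[role] = match[0]
    data = raw.get_data(picks=[picks["flow"], picks["paw"]])
    return WaveformRecording(
        flow=data[0],
        paw=data[1],
        rate=float(raw.info["sfreq"]),
        subject_id=subject_id or path.stem,
        mode=mode,
    )


def write_csv(rec: WaveformRecording, path) -> None:
    """Write a recording to CSV with canonical columns time_s, flow_lpm, paw_cmh2o."""
    df = pd.DataFrame(
        {
            CSV_COLUMNS[0]: rec.times(),
            CSV_COLUMNS[1]: rec.flow,
            CSV_COLUMNS[2]: rec.paw,
        }
    )
    df.to_csv(path, index=False)


def decimate_to_40hz(rec: WaveformRecording, target_rate: float = ANALYSIS_RATE) -> WaveformRecording:
    """Decimate a recording to the 40 Hz analysis rate.

    A zero-phase FIR low-pass (cutoff 0.8 x the target Nyquist) is applied
    before picking every ``rate/target``-th sample, so breath landmarks keep
    their timing.  A recording already at the target rate is returned as-is.
    """
    if math.isclose(rec.rate, target_rate):
        return rec
    factor = rec.rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise UnsupportedRateError(
            f"rate {rec.rate} Hz is not an integer multiple of {target_rate} Hz"
        )
    q = int(round(factor))
    cutoff = 0.8 * (target_rate / 2.0)
    numtaps = 20 * q + 1  # odd length -> symmetric FIR
    taps = signal.firwin(numtaps, cutoff, fs=rec.rate)
    n_out = rec.n_samples // q
    out = {}
    for name in ("flow", "paw"):
        x = signal.filtfilt(taps, [1.0], rec.channel(name))
        out[name] = x[: n_out * q : q]
    return replace(rec, flow=out["flow"], paw=out["paw"], rate=target_rate)


def partition_segments(rec: WaveformRecording, segment_minutes: float = 15.0,
                       mode: Optional[VentMode] = None) -> list[Segment]:
    """Partition a recording into contiguous fixed-length segments.

    Returns ``floor(duration / segment)`` half-open segments anchored at the
    recording start; a trailing remainder shorter than one segment is
    discarded (and logged).
    """
    if segment_minutes <= 0:
        raise InputError("segment_minutes must be positive")
    seg_s = segment_minutes * 60.0
    n_seg = int(rec.duration_s // seg_s)
    if n_seg < 1:
        raise InputError(
            f"recording of {rec.duration_s:.1f} s is shorter than one "
            f"{seg_s:.0f} s segment"
        )
    remainder = rec.duration_s - n_seg * seg_s
    if remainder > 1.0 / rec.rate:
        logger.info("discarding %.1f s trailing remainder after %d segments", remainder, n_seg)
    seg_mode = mode if mode is not None else rec.mode
    return [
        Segment(index=k, start_s=rec.start_time + k * seg_s,
                end_s=rec.start_time + (k + 1) * seg_s, mode=seg_mode)
        for k in range(n_seg)
    ]
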