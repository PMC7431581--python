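"""Sample Entropy of sliding waveform windows.

Sample Entropy (SampEn) of a series x(1..N) with embedding dimension m and
tolerance r is -ln(A/B), where B counts pairs of m-sample templates whose
Chebyshev distance is <= r and A counts the same pairs still matching when
extended to m+1 samples.  Template starts run over i = 1..N-m for both counts
and self-matches are excluded (Richman-Moorman convention), so the
normalisation constants cancel and SampEn = -ln(sum A_i / sum B_i).

The optimised kernel walks each diagonal j - i = d of the distance matrix
once, tracking run lengths of consecutive sample matches; a run of matching
samples of length g starting at i yields template matches at every dimension
m <= g (and m+1 extensions at every m <= g-1), so a single O(N^2) pass
produces the match counts for all dimensions 1..m_max simultaneously.

Entropy is evaluated on 30-s sliding windows (50 % overlap by default) with a
per-window tolerance r = r_factor x SD(window), and the resulting series is
denoised with an 8-period exponential moving average.  Windows where no
template pair matches, or whose SD is zero, carry an undefined value (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from numba import njit

from .exceptions import InputError

Channel = Literal["flow", "paw"]


@dataclass(frozen=True)
class SEParams:
    """Settings for sliding-window Sample Entropy.

    m : embedding dimension (template length).
    r_factor : tolerance as a multiple of each window's SD.
    window_s : window length, seconds (default 30).
    overlap_frac : fractional overlap between consecutive windows in [0, 1).
    ema_span : span of the exponential moving average applied to the series.
    smoothing_on : whether the EMA is applied.
    """

    m: int = 2
    r_factor: float = 0.2
    window_s: float = 30.0
    overlap_frac: float = 0.5
    ema_span: int = 8
    smoothing_on: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InputError(f"m must be >= 1 (got {self.m})")
        if not self.r_factor > 0:
            raise InputError(f"r_factor must be positive (got {self.r_factor})")
        if not self.window_s > 0:
            raise InputError("window_s must be positive")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise InputError("overlap_frac must lie in [0, 1)")
        if self.ema_span < 1:
            raise InputError("ema_span must be >= 1")

    @property
    def stride_s(self) -> float:
        return self.window_s * (1.0 - self.overlap_frac)


@dataclass
class SESeries:
    """Time-stamped Sample Entropy values for one channel and one setting.

    ``times`` are window-centre timestamps (s); ``values`` are SampEn in nats
    with NaN marking undefined windows.
    """

    times: np.ndarray
    values: np.ndarray
    channel: Channel
    params: SEParams
    smoothed: bool = False

    def __len__(self) -> int:
        return int(self.times.size)


def chebyshev_distance(u, v) -> float:
    """Maximum absolute componentwise difference between two vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InputError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.max(np.abs(u - v)))


@njit(cache=False)
def _match_histograms(x, m_max, r):  # pragma: no cover - exercised via wrappers
    """Histogram of maximal template-match lengths over all sample pairs.

    For each diagonal d = j - i >= 1 the run length g of consecutive sample
    matches (|x[k] - x[k+d]| <= r) starting at i is tracked backwards.  The
    pair (i, i+d) is an m-template match for every m <= min(g, N-1-d-i); the
    second bound enforces the template-start range i, j <= N-m (1-indexed).
    Counts are capped at m_max+1 and returned as histograms whose suffix sums
    give B_m (matches at length m) and A_m (matches at length m+1).
    """
    n = x.shape[0]
    cap = m_max + 1
    hist_b = np.zeros(cap + 1, dtype=np.int64)
    hist_a = np.zeros(cap + 1, dtype=np.int64)
    for d in range(1, n):
        g = 0
        for i in range(n - 1 - d, -1, -1):
            if abs(x[i] - x[i + d]) <= r:
                g += 1
            else:
                g = 0
            if g > 0:
                lim = n - 1 - d - i
                b = g if g < lim else lim
                if b > cap:
                    b = cap
                if b >= 1:
                    hist_b[b] += 1
                a = g - 1 if g - 1 < lim else lim
                if a > m_max:
                    a = m_max
                if a >= 1:
                    hist_a[a] += 1
    return hist_b, hist_a


def _match_counts(x: np.ndarray, m_max: int, r_abs: float):
    """Unordered pair match counts B_m, A_m for all m = 1..m_max."""
    hist_b, hist_a = _match_histograms(np.ascontiguousarray(x, dtype=np.float64),
                                       m_max, float(r_abs))
    b = np.cumsum(hist_b[::-1])[::-1][1:]  # suffix sums, index m = 1..cap
    a = np.cumsum(hist_a[::-1])[::-1][1:]
    return b[:m_max], a[:m_max]


def sample_entropy_profile(x, m_max: int, r_abs: float) -> np.ndarray:
    """SampEn for every embedding dimension m = 1..m_max in one pass.

    Returns an array of length ``m_max`` (entry k-1 holds SampEn at m=k);
    dimensions with no m- or (m+1)-template match are NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise InputError("x must be 1-D")
    if not np.isfinite(x).all():
        raise InputError("x contains non-finite samples")
    if m_max < 1:
        raise InputError("m_max must be >= 1")
    if x.size <= m_max + 2:
        raise InputError(f"need N > m + 2 (N={x.size}, m_max={m_max})")
    if not r_abs > 0:
        raise InputError("r_abs must be positive")
    b, a = _match_counts(x, m_max, r_abs)
    out = np.full(m_max, np.nan)
    ok = (b > 0) & (a > 0)
    out[ok] = -np.log(a[ok] / b[ok])
    return out


def sample_entropy(x, m: int, r_abs: float) -> float:
    """Sample Entropy of a single series; NaN when no template pair matches."""
    return float(sample_entropy_profile(x, m, r_abs)[m - 1])


def _window_starts(n_samples: int, rate: float, window_s: float, stride_s: float) -> np.ndarray:
    """Start indices of all complete windows (anchored at sample 0)."""
    w = int(round(window_s * rate))
    s = int(round(stride_s * rate))
    if s < 1:
        raise InputError("stride shorter than one sample")
    if n_samples < w:
        raise InputError(f"signal of {n_samples} samples shorter than one {w}-sample window")
    n_win = (n_samples - w) // s + 1
    return np.arange(n_win) * s


def se_sliding_series(x, rate: float, params: SEParams, channel: Channel = "flow",
                      start_time: float = 0.0) -> SESeries:
    """Raw sliding-window SampEn series for one channel.

    Each complete window of ``params.window_s`` seconds (stepping by the
    stride implied by ``overlap_frac``) yields one value with tolerance
    ``r_factor x SD(window)``; zero-SD windows are undefined (NaN).
    """
    x = np.asarray(x, dtype=np.float64)
    starts = _window_starts(x.size, rate, params.window_s, params.stride_s)
    w = int(round(params.window_s * rate))
    values = np.empty(starts.size)
    for k, s0 in enumerate(starts):
        win = x[s0 : s0 + w]
        sd = win.std()
        if sd == 0.0:
            values[k] = np.nan
        else:
            values[k] = sample_entropy(win, params.m, params.r_factor * sd)
    times = start_time + (starts + w / 2.0) / rate
    return SESeries(times=times, values=values, channel=channel, params=params, smoothed=False)


def se_profile_matrix(x, rate: float, m_max: int, r_factors: Sequence[float],
                      window_s: float = 30.0, overlap_frac: float = 0.5,
                      start_time: float = 0.0):
    """Raw SampEn for every (r_factor, m) setting over the sliding windows.

    One O(N^2) kernel pass per (window, r) covers all m at once, which is what
    makes the full optimisation grid affordable.  Returns ``(times, se)``
    where ``se`` has shape (n_r, m_max, n_windows).
    """
    x = np.asarray(x, dtype=np.float64)
    stride_s = window_s * (1.0 - overlap_frac)
    starts = _window_starts(x.size, rate, window_s, stride_s)
    w = int(round(window_s * rate))
    se = np.full((len(r_factors), m_max, starts.size), np.nan)
    for k, s0 in enumerate(starts):
        win = np.ascontiguousarray(x[s0 : s0 + w])
        sd = win.std()
        if sd == 0.0:
            continue
        for j, rf in enumerate(r_factors):
            b, a = _match_counts(win, m_max, rf * sd)
            ok = (b > 0) & (a > 0)
            se[j, ok, k] = -np.log(a[ok] / b[ok])
    times = start_time + (starts + w / 2.0) / rate
    return times, se


def ema_smooth(series: SESeries, span: int | None = None) -> SESeries:
    """Exponential moving average of an SE series.

    Recursive y_t = alpha x_t + (1 - alpha) y_{t-1} with alpha = 2/(span+1),
    initialised at the first defined value.  Undefined (NaN) inputs carry the
    previous smoothed state forward and stay NaN in the output.
    """
    if span is None:
        span = series.params.ema_span
    if span < 1:
        raise InputError("span must be >= 1")
    x = np.asarray(series.values, dtype=float)
    if x.size == 0:
        raise InputError("empty series")
    alpha = 2.0 / (span + 1.0)
    y = np.full_like(x, np.nan)
    state = np.nan
    for t in range(x.size):
        if np.isnan(x[t]):
            continue
        state = x[t] if np.isnan(state) else alpha * x[t] + (1.0 - alpha) * state
        y[t] = state
    return replace(series, values=y, smoothed=True)


def compute_se(x, rate: float, params: SEParams, channel: Channel = "flow",
               start_time: float = 0.0) -> SESeries:
    """Sliding-window SampEn with the configured smoothing applied."""
    raw = se_sliding_series(x, rate, params, channel=channel, start_time=start_time)
    if params.smoothing_on:
        return ema_smooth(raw, params.ema_span)
    return raw
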