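"""Repeated-holdout optimisation of SE settings (m, r) and threshold Th.

The labelled 15-min segments are repeatedly split at random into a 70 %
optimisation subset and a 30 % validation subset.  For every combination of
channel, feature (mean/max), embedding dimension m, tolerance factor r and
threshold Th, the Matthews correlation coefficient of the detector against
the gold labels is computed on each repetition's optimisation subset; the
combination with the maximum mean MCC across repetitions is selected (ties
broken towards the smaller m, then r, then Th), and its performance is then
reported per repetition on the held-out validation subsets.

Because the detector's percent change from baseline does not depend on Th,
the expensive part — sliding-window Sample Entropy for every (channel, m, r)
— is computed once per recording and cached as a per-segment percent-change
table; every split and threshold is then evaluated on cached values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detection import FeatureKind, percent_changes, segment_features
from .entropy import Channel, SEParams, SESeries, ema_smooth, se_profile_matrix
from .exceptions import InputError, SelectionError, SplitError
from .metrics import PerformanceMetrics, confusion, mcc, performance
from .waveform_io import ANALYSIS_RATE, Segment, WaveformRecording, decimate_to_40hz

COMBO_COLS = ["channel", "feature", "m", "r", "th"]


@dataclass(frozen=True)
class GridSpec:
    """Search grids and holdout settings for the optimisation procedure."""

    m_values: tuple = tuple(range(1, 21))
    r_values: tuple = (0.1, 0.2, 0.3, 0.4)
    th_values: tuple = (15, 20, 25, 30, 35, 40, 45, 50)
    features: tuple = ("mean", "max")
    channels: tuple = ("flow", "paw")
    n_repeats: int = 15
    opt_fraction: float = 0.70
    seed: int = 0
    window_s: float = 30.0
    overlap_frac: float = 0.5
    ema_span: int = 8
    smoothing_on: bool = True
    segment_minutes: float = 15.0
    baseline_warmup: int = 1

    def __post_init__(self) -> None:
        for name in ("m_values", "r_values", "th_values", "features", "channels"):
            if len(getattr(self, name)) == 0:
                raise InputError(f"{name} must be non-empty")
        if not 0.0 < self.opt_fraction < 1.0:
            raise InputError("opt_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise InputError("n_repeats must be >= 1")


@dataclass
class FeatureCache:
    """Pooled per-segment gold labels and cached percent changes.

    ``pc[(channel, feature, m, r)]`` is an array aligned with ``labels``
    holding each segment's percent change from its recording's evolving
    baseline under that setting (NaN for unevaluable segments).
    """

    labels: np.ndarray
    modes: np.ndarray
    recording_ids: np.ndarray
    segment_indices: np.ndarray
    pc: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class SelectedSetting:
    channel: Channel
    feature: FeatureKind
    m: int
    r: float
    th: float
    mean_mcc: float
    n_repetitions_at_max: int


@dataclass
class GridResult:
    """Per-repetition and mean MCC for every grid combination, plus splits."""

    table: pd.DataFrame  # columns COMBO_COLS + mcc_rep_<k> ... + mean_mcc
    splits: list  # [(opt_idx, val_idx)] per repetition
    grid: GridSpec
    cache: FeatureCache

    @property
    def n_repeats(self) -> int:
        return len(self.splits)


def build_feature_cache(
    corpus: Sequence[tuple[WaveformRecording, Sequence[Segment]]],
    grid: GridSpec,
    r_values: Optional[Sequence[float]] = None,
    channels: Optional[Sequence[Channel]] = None,
) -> FeatureCache:
    """Compute and cache percent changes for every grid setting.

    ``corpus`` pairs each recording with its labelled segments.  One
    all-dimensions entropy pass per (recording, channel, r) covers every m,
    so the grid costs no more entropy work than its largest m.
    """
    r_values = tuple(r_values if r_values is not None else grid.r_values)
    channels = tuple(channels if channels is not None else grid.channels)
    m_max = max(grid.m_values)
    labels, modes, rec_ids, seg_idx = [], [], [], []
    pc: dict = {(ch, feat, m, r): []
                for ch in channels for feat in grid.features
                for m in grid.m_values for r in r_values}
    for rec_no, (rec, segments) in enumerate(corpus):
        if any(s.label is None for s in segments):
            raise InputError("all segments must carry gold labels")
        rec40 = decimate_to_40hz(rec) if rec.rate != ANALYSIS_RATE else rec
        labels.extend(int(s.label) for s in segments)
        modes.extend(s.mode.value for s in segments)
        rec_ids.extend([rec.subject_id or str(rec_no)] * len(segments))
        seg_idx.extend(s.index for s in segments)
        for ch in channels:
            times, se = se_profile_matrix(rec40.channel(ch), rec40.rate, m_max, r_values,
                                          window_s=grid.window_s,
                                          overlap_frac=grid.overlap_frac,
                                          start_time=rec40.start_time)
            for j, r in enumerate(r_values):
                for m in grid.m_values:
                    params = SEParams(m=m, r_factor=r, window_s=grid.window_s,
                                      overlap_frac=grid.overlap_frac,
                                      ema_span=grid.ema_span,
                                      smoothing_on=grid.smoothing_on)
                    series = SESeries(times=times, values=se[j, m - 1].copy(),
                                      channel=ch, params=params, smoothed=False)
                    if grid.smoothing_on:
                        series = ema_smooth(series, grid.ema_span)
                    for feat in grid.features:
                        feats = segment_features(series, segments, feat)
                        vals = [f.value for f in feats]
                        pc[(ch, feat, m, r)].extend(
                            percent_changes(vals, baseline_warmup=grid.baseline_warmup))
    return FeatureCache(
        labels=np.asarray(labels, dtype=int),
        modes=np.asarray(modes, dtype=object),
        recording_ids=np.asarray(rec_ids, dtype=object),
        segment_indices=np.asarray(seg_idx, dtype=int),
        pc={k: np.asarray(v, dtype=float) for k, v in pc.items()},
    )


def holdout_split(labels: Sequence[int], fraction: float,
                  rng: np.random.Generator | int) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint exhaustive split into round(fraction*n) / remainder.

    The split unit is the segment; the dataset must contain both classes
    (92 segments at fraction 0.70 split 64/28).
    """
    y = np.asarray(labels)
    n = y.size
    if n < 4:
        raise SplitError("need at least 4 segments to split")
    if len(np.unique(y)) < 2:
        raise SplitError("single-class dataset cannot be split meaningfully")
    if not 0.0 < fraction < 1.0:
        raise InputError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    perm = rng.permutation(n)
    n_opt = int(round(fraction * n))
    n_opt = min(max(n_opt, 1), n - 1)
    return np.sort(perm[:n_opt]), np.sort(perm[n_opt:])


def _mcc_on_subset(pred_pc: np.ndarray, labels: np.ndarray, th: float,
                   idx: np.ndarray) -> float:
    pc = pred_pc[idx]
    y = labels[idx]
    ok = np.isfinite(pc)
    if not ok.any():
        return np.nan
    return mcc(confusion((pc[ok] > th).astype(int), y[ok]))


def grid_search(cache: FeatureCache, grid: GridSpec) -> GridResult:
    """Mean MCC per (channel, feature, m, r, Th) across holdout repetitions.

    One master seed spawns the repetition seeds deterministically; every
    combination is evaluated on identical splits for comparability.
    """
    ss = np.random.SeedSequence(grid.seed)
    rep_rngs = [np.random.default_rng(s) for s in ss.spawn(grid.n_repeats)]
    splits = [holdout_split(cache.labels, grid.opt_fraction, rng) for rng in rep_rngs]

    rows = []
    for ch in grid.channels:
        for feat in grid.features:
            for m in grid.m_values:
                for r in grid.r_values:
                    key = (ch, feat, m, r)
                    if key not in cache.pc:
                        raise InputError(f"cache is missing setting {key}")
                    pc = cache.pc[key]
                    for th in grid.th_values:
                        reps = [_mcc_on_subset(pc, cache.labels, th, opt)
                                for opt, _ in splits]
                        row = {"channel": ch, "feature": feat, "m": m, "r": r, "th": th}
                        row.update({f"mcc_rep_{k}": v for k, v in enumerate(reps)})
                        row["mean_mcc"] = float(np.nanmean(reps)) if np.isfinite(reps).any() else np.nan
                        rows.append(row)
    return GridResult(table=pd.DataFrame(rows), splits=splits, grid=grid, cache=cache)


def select_optimal(result: GridResult) -> SelectedSetting:
    """Argmax of mean MCC; ties prefer smaller m, then r, then Th.

    Also reports in how many repetitions the winner attained that
    repetition's maximum MCC (a stability diagnostic).
    """
    df = result.table
    valid = df[np.isfinite(df.mean_mcc)]
    if valid.empty:
        raise SelectionError("no grid combination could be evaluated")
    best_val = valid.mean_mcc.max()
    # exact-tie candidates, then parsimony order
    tied = valid[valid.mean_mcc == best_val].sort_values(
        ["m", "r", "th", "channel", "feature"], kind="mergesort")
    row = tied.iloc[0]
    rep_cols = [c for c in df.columns if c.startswith("mcc_rep_")]
    winner_reps = row[rep_cols].to_numpy(dtype=float)
    rep_max = valid[rep_cols].to_numpy(dtype=float)
    per_rep_max = np.nanmax(rep_max, axis=0)
    n_at_max = int(np.sum(np.isclose(winner_reps, per_rep_max)))
    return SelectedSetting(channel=row.channel, feature=row.feature, m=int(row.m),
                           r=float(row.r), th=float(row.th),
                           mean_mcc=float(row.mean_mcc), n_repetitions_at_max=n_at_max)


def validate_selected(result: GridResult, selected: SelectedSetting) -> pd.DataFrame:
    """Per-repetition validation-subset performance of the selected setting.

    Returns one row per repetition with MCC, sensitivity, specificity,
    accuracy, PPV and NPV on both subsets; summarise with
    :func:`summarize_validation`.
    """
    pc = result.cache.pc[(selected.channel, selected.feature, selected.m, selected.r)]
    y = result.cache.labels
    rows = []
    for k, (opt, val) in enumerate(result.splits):
        for subset_name, idx in (("optimization", opt), ("validation", val)):
            sel_pc = pc[idx]
            sel_y = y[idx]
            ok = np.isfinite(sel_pc)
            perf = performance(confusion((sel_pc[ok] > selected.th).astype(int), sel_y[ok]))
            rows.append({"repetition": k, "subset": subset_name,
                         "mcc": perf.mcc, "sensitivity": perf.sensitivity,
                         "specificity": perf.specificity, "accuracy": perf.accuracy,
                         "ppv": perf.ppv, "npv": perf.npv})
    return pd.DataFrame(rows)


def summarize_validation(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range of each metric, per subset."""
    metrics = ["mcc", "sensitivity", "specificity", "accuracy", "ppv", "npv"]
    out = []
    for subset, sub in per_rep.groupby("subset"):
        for metric in metrics:
            vals = sub[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            q1, med, q3 = np.percentile(vals, [25, 50, 75]) if vals.size else (np.nan,) * 3
            out.append({"subset": subset, "metric": metric,
                        "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(out)


def r_sensitivity(
    corpus: Sequence[tuple[WaveformRecording, Sequence[Segment]]],
    selected: SelectedSetting,
    grid: GridSpec,
    step: float = 0.01,
    halfwidth: float = 0.05,
) -> pd.DataFrame:
    """Mean MCC over a fine r grid around the selected tolerance.

    Scans r in [r* - halfwidth, r* + halfwidth] at the given step on the same
    repetition splits (same master seed), holding channel, feature, m and Th
    fixed; used to check that r* is a robust local maximum.
    """
    if selected.r - halfwidth <= 0:
        raise InputError("r - halfwidth must stay positive")
    n_steps = int(round(halfwidth / step))
    r_list = [round(selected.r + k * step, 10) for k in range(-n_steps, n_steps + 1)]
    fine = GridSpec(m_values=(selected.m,), r_values=tuple(r_list),
                    th_values=(selected.th,), features=(selected.feature,),
                    channels=(selected.channel,), n_repeats=grid.n_repeats,
                    opt_fraction=grid.opt_fraction, seed=grid.seed,
                    window_s=grid.window_s, overlap_frac=grid.overlap_frac,
                    ema_span=grid.ema_span, smoothing_on=grid.smoothing_on,
                    segment_minutes=grid.segment_minutes,
                    baseline_warmup=grid.baseline_warmup)
    cache = build_feature_cache(corpus, fine)
    result = grid_search(cache, fine)
    df = result.table[["r", "mean_mcc"]].sort_values("r").reset_index(drop=True)
    df["is_selected"] = np.isclose(df.r, selected.r)
    return df


def heatmap_tables(result: GridResult, channel: Channel,
                   feature: FeatureKind) -> dict[float, pd.DataFrame]:
    """Mean-MCC matrices (m x Th), one per r value, for heatmap export."""
    sub = result.table[(result.table.channel == channel)
                       & (result.table.feature == feature)]
    return {r: block.pivot(index="m", columns="th", values="mean_mcc")
            for r, block in sub.groupby("r")}


def export_heatmaps(result: GridResult, out_dir, channel: Channel = "flow",
                    feature: FeatureKind = "max") -> list:
    """Write the m x Th mean-MCC heatmaps (CSV + PNG) for one channel/feature."""
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = heatmap_tables(result, channel, feature)
    fig, axes = plt.subplots(1, len(tables), figsize=(4 * len(tables), 4),
                             squeeze=False)
    for ax, (r, tab) in zip(axes[0], sorted(tables.items())):
        csv_path = out_dir / f"mean_mcc_{channel}_{feature}_r{r:g}.csv"
        tab.to_csv(csv_path)
        written.append(csv_path)
        im = ax.imshow(tab.to_numpy(), aspect="auto", origin="lower",
                       vmin=-1, vmax=1, cmap="viridis",
                       extent=(min(tab.columns), max(tab.columns),
                               min(tab.index), max(tab.index)))
        ax.set_xlabel("Th (%)")
        ax.set_ylabel("m")
        ax.set_title(f"{channel} {feature}, r={r:g}")
        fig.colorbar(im, ax=ax, label="mean MCC")
    png_path = out_dir / f"mean_mcc_{channel}_{feature}.png"
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    written.append(png_path)
    return written
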