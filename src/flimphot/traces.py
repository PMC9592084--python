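"""Quantification of stimulus-evoked transients in ROI time series.

Each ROI yields per-sensor time series: fluorescence lifetime (ns) for
Peredox/RCaMP, photon intensity for SBFI.  Sampling is irregular —
10-60 s between frames at rest, ~0.25 s during the stimulation window.
This module computes dF/F, transient metrics (baseline, peak change,
half-decay time), applies the recording exclusion rules (RCaMP
half-decay < 35 s; |dRCaMP| >= 0.2 ns for ratio computations), builds
interpolated cohort averages, and runs normality-gated two-group
comparisons (Shapiro-Wilk gate; t-tests if normal, Wilcoxon /
Mann-Whitney otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ROITrace",
    "TransientMetrics",
    "AnalysisThresholds",
    "AveragedTrace",
    "ExclusionRecord",
    "GroupComparison",
    "BoxSummary",
    "delta_f_over_f",
    "transient_metrics",
    "peredox_rcamp_ratio",
    "bin_and_average",
    "compare_groups",
    "summarize_box",
]

LIFETIME_SENSORS = frozenset({"Peredox", "RCaMP", "mito-RCaMP"})
INTENSITY_SENSORS = frozenset({"SBFI"})


@dataclass
class ROITrace:
    """Time series of one sensor in one ROI."""

    roi_id: str
    sensor: str
    times_s: np.ndarray
    values: np.ndarray
    units: str = "ns"
    stim_time_s: float | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.sensor in LIFETIME_SENSORS and np.any(self.values <= 0):
            raise ValueError("lifetime values must be > 0")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class TransientMetrics:
    """Summary of one stimulus-evoked transient."""

    baseline: float
    delta_peak: float  # signed extremum of (value - baseline) after stimulus
    time_to_peak_s: float
    half_decay_time_s: float | None  # None if no halfway return observed
    polarity: str  # "up" | "down"
    dff_peak: float | None = None  # intensity sensors only

    def __post_init__(self) -> None:
        if self.polarity not in ("up", "down"):
            raise ValueError("polarity must be 'up' or 'down'")
        if self.half_decay_time_s is not None and not self.half_decay_time_s > 0:
            raise ValueError("half_decay_time_s must be > 0 when defined")


@dataclass(frozen=True)
class AnalysisThresholds:
    """Recording-quality rules applied before ratio computations."""

    min_delta_rcamp_ns: float = 0.2
    max_half_decay_s: float = 35.0
    baseline_window_s: float = 60.0

    def __post_init__(self) -> None:
        for name in ("min_delta_rcamp_ns", "max_half_decay_s", "baseline_window_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ExclusionRecord:
    """A recording that failed a quality rule (a result, not an error)."""

    roi_id: str
    rule: str
    detail: str


@dataclass
class AveragedTrace:
    """Cohort mean trace on a merged, binned time axis."""

    common_times_s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    sem: np.ndarray
    n_per_point: np.ndarray


@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float
    pvalue: float
    normal_a: bool
    normal_b: bool
    n_a: int
    n_b: int


@dataclass(frozen=True)
class BoxSummary:
    """Box-plot summary: mean, median, and the 5-95 percentile range."""

    mean: float
    median: float
    p5: float
    p95: float
    n: int


def _baseline(trace: ROITrace, stim_time: float, window_s: float) -> float:
    mask = (trace.times_s >= stim_time - window_s) & (trace.times_s < stim_time)
    if mask.sum() < 1:
        raise ValueError(
            f"no samples in the {window_s} s baseline window before t={stim_time}"
        )
    return float(trace.values[mask].mean())


def delta_f_over_f(
    trace: ROITrace, baseline_window_s: float = 60.0
) -> ROITrace:
    """Convert an intensity trace to dF/F relative to the pre-stimulus
    baseline mean.  Requires >= 3 baseline samples and a positive
    baseline."""
    if trace.stim_time_s is None:
        raise ValueError("trace needs stim_time_s to define the baseline window")
    mask = (trace.times_s >= trace.stim_time_s - baseline_window_s) & (
        trace.times_s < trace.stim_time_s
    )
    if mask.sum() < 3:
        raise ValueError("need >= 3 samples in the baseline window")
    f0 = float(trace.values[mask].mean())
    if f0 <= 0:
        raise ValueError(f"baseline mean must be > 0, got {f0}")
    return ROITrace(
        roi_id=trace.roi_id,
        sensor=trace.sensor,
        times_s=trace.times_s.copy(),
        values=(trace.values - f0) / f0,
        units="dF/F",
        stim_time_s=trace.stim_time_s,
    )


def transient_metrics(
    trace: ROITrace,
    stim_time_s: float | None = None,
    polarity: str = "up",
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    peak_window_s: float | None = None,
) -> TransientMetrics:
    """Baseline, signed peak change, and half-decay of one transient.

    The peak is the extremum of (value - baseline) after the stimulus
    (minimum for ``polarity="down"``, e.g. SBFI quench; maximum for
    ``"up"``).  The half-decay time is measured from the peak to the
    first linearly interpolated crossing of the halfway-to-baseline
    level; ``None`` if the trace never returns halfway.
    """
    stim = stim_time_s if stim_time_s is not None else trace.stim_time_s
    if stim is None:
        raise ValueError("stimulus time required")
    if not trace.times_s[0] <= stim <= trace.times_s[-1]:
        raise ValueError("stim_time outside the trace time span")
    base = _baseline(trace, stim, thresholds.baseline_window_s)

    post = trace.times_s >= stim
    if peak_window_s is not None:
        post &= trace.times_s <= stim + peak_window_s
    if post.sum() < 3:
        raise ValueError("need >= 3 post-stimulus samples")
    t_post = trace.times_s[post]
    dv = trace.values[post] - base

    idx = int(np.argmin(dv)) if polarity == "down" else int(np.argmax(dv))
    delta_peak = float(dv[idx])
    t_peak = float(t_post[idx])

    half = delta_peak / 2.0
    half_decay: float | None = None
    if delta_peak != 0.0:
        seg_t = trace.times_s[trace.times_s >= t_peak]
        seg_v = trace.values[trace.times_s >= t_peak] - base
        for i in range(1, seg_t.size):
            crossed = (
                seg_v[i] <= half if polarity == "up" else seg_v[i] >= half
            )
            if crossed:
                v0, v1 = seg_v[i - 1], seg_v[i]
                if v1 == v0:
                    t_cross = seg_t[i]
                else:
                    t_cross = seg_t[i - 1] + (half - v0) / (v1 - v0) * (
                        seg_t[i] - seg_t[i - 1]
                    )
                half_decay = float(t_cross - t_peak)
                if half_decay <= 0:
                    half_decay = None
                break

    dff_peak = delta_peak / base if trace.units != "dF/F" and base != 0 else None
    if trace.units == "dF/F":
        dff_peak = delta_peak
    return TransientMetrics(
        baseline=base,
        delta_peak=delta_peak,
        time_to_peak_s=t_peak - stim,
        half_decay_time_s=half_decay,
        polarity=polarity,
        dff_peak=dff_peak if trace.sensor in INTENSITY_SENSORS or trace.units == "dF/F" else None,
    )


def peredox_rcamp_ratio(
    peredox: TransientMetrics,
    rcamp: TransientMetrics,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    roi_id: str = "",
) -> float | ExclusionRecord:
    """dPeredox/dRCaMP for one recording, or an exclusion record.

    Excluded when |dRCaMP| < 0.2 ns (noisy denominators) or when the
    RCaMP half-decay is >= 35 s (slow, poorly stimulus-locked Ca2+
    transients); exactly one of ratio/exclusion is returned.
    """
    if abs(rcamp.delta_peak) < thresholds.min_delta_rcamp_ns:
        return ExclusionRecord(
            roi_id=roi_id,
            rule="min_delta_rcamp",
            detail=(
                f"|dRCaMP|={abs(rcamp.delta_peak):.3f} ns < "
                f"{thresholds.min_delta_rcamp_ns} ns"
            ),
        )
    if (
        rcamp.half_decay_time_s is None
        or rcamp.half_decay_time_s >= thresholds.max_half_decay_s
    ):
        shown = (
            "undefined"
            if rcamp.half_decay_time_s is None
            else f"{rcamp.half_decay_time_s:.1f} s"
        )
        return ExclusionRecord(
            roi_id=roi_id,
            rule="max_half_decay",
            detail=f"RCaMP half-decay {shown} not < {thresholds.max_half_decay_s} s",
        )
    return peredox.delta_peak / rcamp.delta_peak


def bin_and_average(
    traces: list[ROITrace],
    coarse_bin_s: float = 1.0,
    fine_bin_s: float = 0.01,
    stim_window_s: tuple[float, float] = (0.0, 2.0),
) -> AveragedTrace:
    """Merge stimulus-aligned traces onto one binned time axis.

    Times are shifted so the stimulus is at 0, rounded to the nearest
    second outside ``stim_window_s`` and the nearest 10 ms inside it
    (matching the coarse/fine acquisition cadence), then each trace is
    linearly interpolated onto the union grid.  No extrapolation:
    points outside a trace's span contribute nothing and
    ``n_per_point`` records how many traces cover each grid point.
    """
    if len(traces) < 2:
        raise ValueError("need >= 2 traces to average")
    binned = []
    for tr in traces:
        if tr.stim_time_s is None:
            raise ValueError(f"trace {tr.roi_id} has no stim_time_s")
        t = tr.times_s - tr.stim_time_s
        in_stim = (t >= stim_window_s[0]) & (t <= stim_window_s[1])
        tb = np.where(
            in_stim,
            np.round(t / fine_bin_s) * fine_bin_s,
            np.round(t / coarse_bin_s) * coarse_bin_s,
        )
        # average duplicates landing in one bin
        uniq, inv = np.unique(np.round(tb, 9), return_inverse=True)
        vals = np.zeros_like(uniq)
        cnt = np.zeros_like(uniq)
        np.add.at(vals, inv, tr.values)
        np.add.at(cnt, inv, 1.0)
        binned.append((uniq, vals / cnt))

    grid = np.unique(np.round(np.concatenate([b[0] for b in binned]), 9))
    stack = np.full((len(binned), grid.size), np.nan)
    for i, (tb, vb) in enumerate(binned):
        inside = (grid >= tb[0]) & (grid <= tb[-1])
        stack[i, inside] = np.interp(grid[inside], tb, vb)

    n = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.zeros_like(mean)
        multi = n > 1
        sd[multi] = np.nanstd(stack[:, multi], axis=0, ddof=1)
    sem = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return AveragedTrace(
        common_times_s=grid, mean=mean, sd=sd, sem=sem, n_per_point=n
    )


def compare_groups(
    a,
    b,
    paired: bool = False,
    alpha_normality: float = 0.05,
) -> GroupComparison:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Both groups normal (and, if paired, the differences testable) ->
    paired/two-sample t-test; otherwise paired Wilcoxon / Mann-Whitney.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal group sizes")

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:  # Shapiro-Wilk undefined for constant data
            return True
        return stats.shapiro(x).pvalue > alpha_normality

    norm_a, norm_b = _normal(a), _normal(b)

    if paired:
        diffs = a - b
        if np.all(diffs == 0):  # identical samples: null exactly true
            name = "paired t-test" if (norm_a and norm_b) else "paired Wilcoxon"
            return GroupComparison(name, 0.0, 1.0, norm_a, norm_b, a.size, b.size)
        if norm_a and norm_b:
            res = stats.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = stats.wilcoxon(a, b)
            name = "paired Wilcoxon"
    else:
        if norm_a and norm_b:
            res = stats.ttest_ind(a, b)
            name = "two-sample t-test"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney"
    return GroupComparison(
        test_name=name,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        normal_a=norm_a,
        normal_b=norm_b,
        n_a=a.size,
        n_b=b.size,
    )


def summarize_box(values) -> BoxSummary:
    """Mean, median, and 5-95 % range (linear-interpolation percentiles)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("summarize_box needs at least one value")
    p5, p95 = np.percentile(v, [5, 95], method="linear")
    return BoxSummary(
        mean=float(v.mean()),
        median=float(np.median(v)),
        p5=float(p5),
        p95=float(p95),
        n=v.size,
    )
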