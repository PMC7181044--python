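"""SUVR curves, windowed SUVR, and static-window optimization.

The standardized uptake value ratio (SUVR) is the target/reference
activity ratio; averaged over a late static window it approximates the
DVR without a dynamic scan. The window scan regresses windowed SUVR on
Logan DVR across the cohort, per region and candidate window, and selects
the window whose regression is both tight (r^2 above threshold in every
non-excluded region) and unbiased (mean |slope - 1| minimal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .frames import FrameSchedule, TimeActivityCurve

__all__ = [
    "AnalysisWindow",
    "suvr_curve",
    "windowed_suvr",
    "window_grid",
    "regress_suvr_on_dvr",
    "window_scan",
    "select_optimal_window",
    "cohort_windowed_suvr",
    "NoQualifyingWindowError",
]

DEFAULT_WINDOW = (40.0, 70.0)
DEFAULT_R2_THRESHOLD = 0.90
#: regions excluded from the window-selection criterion: the midbrain signal
#: emerges late and weakly, so its regression never clears the threshold
DEFAULT_EXCLUDED_REGIONS = frozenset({"MB"})


@dataclass(frozen=True)
class AnalysisWindow:
    """Static acquisition window [start, end] in minutes post-injection."""

    start: float
    end: float

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end}]")

    def contains(self, mid_times: np.ndarray) -> np.ndarray:
        t = np.asarray(mid_times, dtype=float)
        return (t >= self.start - 1e-12) & (t <= self.end + 1e-12)

    def label(self) -> str:
        return f"{self.start:g}-{self.end:g}"


def suvr_curve(target: TimeActivityCurve, ref: TimeActivityCurve) -> TimeActivityCurve:
    """Frame-wise target/reference ratio; frames with non-positive reference
    activity are masked out."""
    if len(target.values) != len(ref.values):
        raise ValueError("target and reference TACs differ in frame count")
    keep = ref.y > 0
    if not keep.any():
        raise ValueError("reference TAC has no positive frames")
    t = target.t[keep]
    vals = target.y[keep] / ref.y[keep]
    return TimeActivityCurve(f"{target.region}:{ref.region}", tuple(t), tuple(vals))


def windowed_suvr(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    schedule: FrameSchedule,
    window: "AnalysisWindow | tuple[float, float]" = DEFAULT_WINDOW,
) -> float:
    """Windowed SUVR: duration-weighted mean target activity over frames
    whose mid-time falls in the (closed) window, divided by the same for
    the reference. Equivalent to the ratio of static images summed over
    the window."""
    if not isinstance(window, AnalysisWindow):
        window = AnalysisWindow(*window)
    if window.end > schedule.end_min + 1e-9:
        raise ValueError(
            f"window end {window.end} min exceeds scan end {schedule.end_min} min"
        )
    mids = schedule.mid_times_min()
    sel = window.contains(mids)
    if not sel.any():
        raise ValueError(f"window {window.label()} min contains no frame mid-time")
    w = schedule.durations_min[sel]
    denom = float(np.sum(ref.y[sel] * w))
    if denom <= 0:
        raise ValueError("reference activity is zero over the window")
    return float(np.sum(target.y[sel] * w) / denom)


def window_grid(
    schedule: FrameSchedule,
    duration: float = 30.0,
    step: float = 10.0,
    include_full_scan: bool = True,
) -> list[AnalysisWindow]:
    """Stepwise candidate windows: fixed-duration windows sliding by ``step``
    from t = 0, plus the full-scan window. Defaults give 30-min windows
    starting at 0, 10, ..., 60 min on the 90-min schedule."""
    if duration <= 0 or step <= 0:
        raise ValueError("duration and step must be positive")
    end = schedule.end_min
    if duration > end + 1e-9:
        raise ValueError(f"window duration {duration} min exceeds scan length {end} min")
    windows = []
    start = 0.0
    while start + duration <= end + 1e-9:
        windows.append(AnalysisWindow(start, start + duration))
        start += step
    if include_full_scan and not any(
        w.start == 0.0 and abs(w.end - end) < 1e-9 for w in windows
    ):
        windows.append(AnalysisWindow(0.0, end))
    return windows


def cohort_windowed_suvr(
    cohort_tacs: dict[str, dict[str, TimeActivityCurve]],
    schedule: FrameSchedule,
    window: "AnalysisWindow | tuple[float, float]" = DEFAULT_WINDOW,
    ref_region: str = "CB",
) -> pd.DataFrame:
    """Windowed SUVR for every animal x target region: columns animal,
    region, suvr."""
    rows = []
    for animal, tacs in cohort_tacs.items():
        ref = tacs[ref_region]
        for region, tac in tacs.items():
            if region == ref_region:
                continue
            rows.append((animal, region, windowed_suvr(tac, ref, schedule, window)))
    return pd.DataFrame(rows, columns=["animal", "region", "suvr"])


def regress_suvr_on_dvr(
    suvr: np.ndarray, dvr: np.ndarray
) -> tuple[float, float, float]:
    """OLS of SUVR (y) on DVR (x) pooled across animals and age groups.

    Returns (r2, slope, intercept); r2 is the squared Pearson correlation.
    """
    suvr = np.asarray(suvr, dtype=float)
    dvr = np.asarray(dvr, dtype=float)
    if suvr.size != dvr.size:
        raise ValueError("SUVR and DVR vectors differ in length")
    if suvr.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {suvr.size}")
    if np.ptp(dvr) == 0:
        raise ValueError("zero DVR variance; regression undefined")
    res = stats.linregress(dvr, suvr)
    return float(res.rvalue**2), float(res.slope), float(res.intercept)


def window_scan(
    cohort_tacs: dict[str, dict[str, TimeActivityCurve]],
    dvr_table: pd.DataFrame,
    schedule: FrameSchedule,
    windows: "list[AnalysisWindow] | None" = None,
    ref_region: str = "CB",
) -> pd.DataFrame:
    """Per region x candidate window regression of windowed SUVR on DVR.

    ``dvr_table`` needs columns animal, region, dvr (e.g. from
    :func:`taupet.kinetics.cohort_logan`). Returns columns region,
    win_start, win_end, r2, slope, intercept, n.
    """
    windows = windows if windows is not None else window_grid(schedule)
    dvr_idx = dvr_table.set_index(["animal", "region"])["dvr"]
    rows = []
    for win in windows:
        suvr_df = cohort_windowed_suvr(cohort_tacs, schedule, win, ref_region)
        for region, grp in suvr_df.groupby("region", sort=True):
            paired = [
                (dvr_idx.get((a, region)), s)
                for a, s in zip(grp["animal"], grp["suvr"])
            ]
            paired = [(d, s) for d, s in paired if d is not None]
            if len(paired) < 3:
                continue
            d, s = map(np.asarray, zip(*paired))
            r2, slope, intercept = regress_suvr_on_dvr(s, d)
            rows.append((region, win.start, win.end, r2, slope, intercept, len(paired)))
    return pd.DataFrame(
        rows,
        columns=["region", "win_start", "win_end", "r2", "slope", "intercept", "n"],
    )


class NoQualifyingWindowError(RuntimeError):
    """No window met the r^2 criterion; carries the best near-miss."""

    def __init__(self, best_window, min_r2):
        self.best_window = best_window
        self.min_r2 = min_r2
        super().__init__(
            f"no window met the r2 criterion in every region; best near-miss "
            f"{best_window} with min r2 = {min_r2:.3f}"
        )


def select_optimal_window(
    table: pd.DataFrame,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    excluded_regions: frozenset = DEFAULT_EXCLUDED_REGIONS,
) -> tuple[AnalysisWindow, pd.DataFrame]:
    """Pick the static window from a window-scan table.

    A window qualifies when every non-excluded region reaches
    r2 >= ``r2_threshold``; among qualifying windows the one minimizing the
    mean |slope - 1| across non-excluded regions wins, earliest start
    breaking ties. Returns the winner and a per-window report with
    columns win_start, win_end, min_r2, mean_abs_slope_dev, qualifies.
    """
    if table.empty:
        raise ValueError("window-scan table is empty")
    sub = table[~table["region"].isin(excluded_regions)]
    if sub.empty:
        raise ValueError("every region is excluded from selection")
    report = (
        sub.groupby(["win_start", "win_end"])
        .agg(
            min_r2=("r2", "min"),
            mean_abs_slope_dev=("slope", lambda s: float(np.mean(np.abs(s - 1.0)))),
        )
        .reset_index()
    )
    report["qualifies"] = report["min_r2"] >= r2_threshold
    qual = report[report["qualifies"]]
    if qual.empty:
        best = report.loc[report["min_r2"].idxmax()]
        raise NoQualifyingWindowError(
            (float(best["win_start"]), float(best["win_end"])), float(best["min_r2"])
        )
    qual = qual.sort_values(["mean_abs_slope_dev", "win_start"], kind="stable")
    top = qual.iloc[0]
    return AnalysisWindow(float(top["win_start"]), float(top["win_end"])), report
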