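"""Reference-tissue kinetic estimation: SRTM fits and reference Logan DVR.

The distribution volume ratio (DVR) is estimated as the slope of the
reference Logan plot

    int_0^T C_voi dt / C_voi(T) =
        DVR * [int_0^T C_ref dt + C_ref(T)/k2ref] / C_voi(T) + intercept

fitted by ordinary least squares over frames with mid-time >= t*. The
reference efflux constant k2ref is taken from a simplified reference
tissue model (SRTM) fit, by default of the highest-binding target region
(cortex) of each animal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .frames import FrameSchedule, TimeActivityCurve, cumulative_integral
from .synth import SRTMParams, srtm_forward

__all__ = [
    "LoganFit",
    "SRTMFit",
    "SRTMFitError",
    "logan_dvr",
    "fit_srtm",
    "select_tstar",
    "estimate_k2ref",
    "cohort_logan",
]

DEFAULT_T_STAR = 40.0  # minutes; uptake plateaus roughly 30-40 min in

#: SRTM parameter bounds: R1 in (0, 5], k2 in (0, 2] 1/min, BPnd in [0, 10]
SRTM_LOWER = np.array([1e-3, 1e-4, 0.0])
SRTM_UPPER = np.array([5.0, 2.0, 10.0])

#: fixed multi-start grid (R1, k2, BPnd) for the nonlinear fit
SRTM_STARTS = (
    (1.0, 0.10, 0.10),
    (0.8, 0.20, 0.60),
    (1.2, 0.05, 1.50),
)


class SRTMFitError(RuntimeError):
    """No SRTM start point converged; carries per-start diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = diagnostics
        super().__init__(f"SRTM fit failed from all starts: {diagnostics}")


@dataclass(frozen=True)
class LoganFit:
    """Reference Logan regression result for one target region."""

    dvr: float
    intercept: float  # minutes
    t_star: float  # minutes
    r2_linear: float
    n_points: int
    k2ref_used: float  # 1/min


@dataclass(frozen=True)
class SRTMFit:
    params: SRTMParams
    residual_rms: float  # kBq/mL
    converged: bool

    @property
    def k2ref(self) -> float:
        return self.params.k2ref


def _logan_coordinates(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    schedule: FrameSchedule,
    k2ref: float,
) -> tuple[np.ndarray, np.ndarray]:
    """y(T) and x(T) of the reference Logan linearization at all frame
    mid-times (integrals by the rectangular frame rule)."""
    ct = target.y
    cr = ref.y
    int_ct = cumulative_integral(target, schedule)
    int_cr = cumulative_integral(ref, schedule)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = int_ct / ct
        x = (int_cr + cr / k2ref) / ct
    return x, y


def logan_dvr(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    schedule: FrameSchedule,
    k2ref: float,
    t_star: float = DEFAULT_T_STAR,
) -> LoganFit:
    """Reference Logan graphical analysis: OLS slope = DVR.

    Only frames with mid-time >= ``t_star`` (the linear portion of the plot)
    enter the regression. Requires at least 3 such frames and positive
    target activity at each of them.
    """
    if k2ref <= 0:
        raise ValueError(f"k2ref must be positive, got {k2ref}")
    mids = schedule.mid_times_min()
    if t_star >= schedule.end_min:
        raise ValueError(
            f"t* = {t_star} min is not before scan end {schedule.end_min} min"
        )
    sel = mids >= t_star - 1e-12
    if int(sel.sum()) < 3:
        raise ValueError(
            f"only {int(sel.sum())} frames at or after t* = {t_star} min; "
            "need at least 3"
        )
    if np.any(target.y[sel] <= 0):
        raise ValueError("target activity is zero at a frame after t*")
    x, y = _logan_coordinates(target, ref, schedule, k2ref)
    x, y = x[sel], y[sel]
    slope, intercept, r, _, _ = stats.linregress(x, y)
    return LoganFit(
        dvr=float(slope),
        intercept=float(intercept),
        t_star=float(t_star),
        r2_linear=float(r**2),
        n_points=int(sel.sum()),
        k2ref_used=float(k2ref),
    )


def select_tstar(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    schedule: FrameSchedule,
    k2ref: float,
    max_rel_dev: float = 0.10,
) -> float:
    """Earliest frame mid-time from which the Logan plot is linear.

    A candidate start qualifies when, fitting the line from there to scan
    end, every included point deviates from the fit by at most
    ``max_rel_dev`` relative to the fitted value. Falls back to 40 min if
    no candidate qualifies.
    """
    if not (0 < max_rel_dev < 0.5):
        raise ValueError(f"max_rel_dev must be in (0, 0.5), got {max_rel_dev}")
    mids = schedule.mid_times_min()
    x_all, y_all = _logan_coordinates(target, ref, schedule, k2ref)
    for i in range(len(mids) - 2):  # need >= 3 points
        x, y = x_all[i:], y_all[i:]
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            continue
        if np.ptp(x) == 0:
            continue
        slope, intercept = np.polyfit(x, y, 1)
        fitted = slope * x + intercept
        if np.any(fitted == 0):
            continue
        rel = np.abs(y - fitted) / np.abs(fitted)
        if np.max(rel) <= max_rel_dev:
            return float(mids[i])
    return DEFAULT_T_STAR


def fit_srtm(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    schedule: FrameSchedule,
) -> SRTMFit:
    """Weighted nonlinear least-squares SRTM fit of a target TAC.

    Residuals are weighted by sqrt(frame duration), the usual proxy for
    count statistics. The fit is restarted from a fixed three-point grid
    and the best converged solution is returned; k2ref follows as k2/R1.
    """
    if np.all(ref.y == 0):
        raise ValueError("reference TAC is identically zero")
    if len(target.values) != schedule.n_frames or len(ref.values) != schedule.n_frames:
        raise ValueError("target and reference TACs must be on the schedule")
    w = np.sqrt(schedule.durations_min)
    yobs = target.y

    def residuals(theta):
        model = srtm_forward(
            ref, SRTMParams(R1=theta[0], k2=theta[1], BPnd=theta[2]), schedule
        )
        return w * (model.y - yobs)

    best = None
    diagnostics = []
    for start in SRTM_STARTS:
        try:
            res = least_squares(
                residuals,
                np.asarray(start, dtype=float),
                bounds=(SRTM_LOWER, SRTM_UPPER),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failures
            diagnostics.append((start, repr(exc)))
            continue
        if not res.success:
            diagnostics.append((start, res.message))
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise SRTMFitError(diagnostics)
    r1, k2, bpnd = best.x
    params = SRTMParams(R1=float(r1), k2=float(k2), BPnd=float(bpnd))
    model = srtm_forward(ref, params, schedule)
    rms = float(np.sqrt(np.mean((model.y - yobs) ** 2)))
    return SRTMFit(params=params, residual_rms=rms, converged=True)


def estimate_k2ref(
    tacs: dict[str, TimeActivityCurve],
    schedule: FrameSchedule,
    target_region: str = "CX",
    ref_region: str = "CB",
) -> float:
    """Animal-level k2ref from an SRTM fit of the highest-binding region.

    Fitting the cortex (largest specific signal) gives the most stable
    k2 and R1 estimates; k2ref = k2/R1 is a property of the reference
    tissue and is then shared across that animal's regions.
    """
    fit = fit_srtm(tacs[target_region], tacs[ref_region], schedule)
    return fit.k2ref


def cohort_logan(
    cohort_tacs: dict[str, dict[str, TimeActivityCurve]],
    schedule: FrameSchedule,
    t_star: float = DEFAULT_T_STAR,
    k2ref: "float | None" = None,
    ref_region: str = "CB",
    k2ref_region: str = "CX",
) -> pd.DataFrame:
    """Per-animal, per-region Logan DVR table.

    ``k2ref=None`` (default) estimates k2ref per animal by SRTM on the
    cortex; a float fixes it to a population value. Returns columns
    animal, region, dvr, intercept, t_star, r2_linear, k2ref_used.
    """
    rows = []
    for animal, tacs in cohort_tacs.items():
        k2r = k2ref if k2ref is not None else estimate_k2ref(
            tacs, schedule, target_region=k2ref_region, ref_region=ref_region
        )
        for region, tac in tacs.items():
            if region == ref_region:
                continue
            fit = logan_dvr(tac, tacs[ref_region], schedule, k2r, t_star)
            rows.append(
                (
                    animal,
                    region,
                    fit.dvr,
                    fit.intercept,
                    fit.t_star,
                    fit.r2_linear,
                    fit.k2ref_used,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "animal",
            "region",
            "dvr",
            "intercept",
            "t_star",
            "r2_linear",
            "k2ref_used",
        ],
    )
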