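"""Parameter-recovery and calibration studies on the synthetic cohort.

These are the validation experiments the package is scored by: noiseless
Logan recovery across binding levels, percent-change recovery of the
calibrated cortical age effects, absolute-scale calibration of the
hippocampal group mean, and type-I error control of the group-comparison
engine. They are used by the analysis drivers, the test suite, and the
acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .frames import default_schedule
from .kinetics import logan_dvr
from .stats import compare_groups, percent_change
from .suvr import cohort_windowed_suvr
from .synth import (
    CohortSpec,
    SRTMParams,
    default_cohort_spec,
    reference_tac,
    simulate_cohort,
    srtm_forward,
)

__all__ = [
    "replicate_seed",
    "dvr_recovery_grid",
    "pct_change_replicates",
    "group_mean_suvr_replicates",
    "type_one_error_rate",
]

PAPER_WINDOW = (40.0, 70.0)


def replicate_seed(seed: int, rep: int) -> int:
    """Well-mixed per-replicate substream seed (< 2**31)."""
    return int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))


def dvr_recovery_grid(
    bpnd_values=(0.0, 0.25, 0.35, 0.55, 0.75),
    t_star: float = 40.0,
    params: "SRTMParams | None" = None,
) -> pd.DataFrame:
    """Noiseless Logan recovery of DVR across binding levels.

    Simulates one target TAC per BPnd from the default reference model with
    the true k2ref, runs reference Logan at ``t_star``, and reports true vs
    estimated DVR. Columns: bpnd, dvr_true, dvr_est, rel_err.
    """
    schedule = default_schedule()
    base = params or SRTMParams()
    spec = default_cohort_spec(seed=0)
    cb = reference_tac(spec.reference_model, schedule)
    rows = []
    for b in bpnd_values:
        p = SRTMParams(R1=base.R1, k2=base.k2, BPnd=float(b))
        tgt = srtm_forward(cb, p, schedule)
        fit = logan_dvr(tgt, cb, schedule, p.k2ref, t_star)
        rows.append((b, p.dvr, fit.dvr, (fit.dvr - p.dvr) / p.dvr))
    return pd.DataFrame(rows, columns=["bpnd", "dvr_true", "dvr_est", "rel_err"])


def _subset_spec(base: CohortSpec, groups, regions, seed: int) -> CohortSpec:
    return CohortSpec(
        group_labels=tuple(groups),
        n_per_group=base.n_per_group,
        true_dvr={r: base.true_dvr[r] for r in regions},
        dvr_sd={r: base.dvr_sd.get(r, {}) for r in regions},
        reference_model=base.reference_model,
        R1=base.R1,
        k2=base.k2,
        r1_sd=base.r1_sd,
        k2_sd=base.k2_sd,
        noise_scale=base.noise_scale,
        seed=seed,
    )


def pct_change_replicates(
    groups=("4", "6", "9", "11"),
    baseline: str = "2",
    region: str = "CX",
    n_replicates: int = 200,
    seed: int = 0,
    window=PAPER_WINDOW,
) -> pd.DataFrame:
    """Percent change of group-mean windowed SUVR vs baseline, replicated.

    Each replicate simulates an independent calibrated cohort (baseline +
    requested groups, n = 3 each by default), computes the windowed SUVR
    per animal, and records 100*(mean_group - mean_baseline)/mean_baseline.
    Returns one row per replicate x group: columns replicate, group,
    pct_change.
    """
    schedule = default_schedule()
    base = default_cohort_spec(seed=0)
    rows = []
    for rep in range(n_replicates):
        spec = _subset_spec(
            base, (baseline,) + tuple(groups), [region], replicate_seed(seed, rep)
        )
        tacs, truth = simulate_cohort(spec, schedule)
        sv = cohort_windowed_suvr(tacs, schedule, window)
        sv = sv.merge(truth[["animal", "group"]].drop_duplicates(), on="animal")
        means = sv[sv["region"] == region].groupby("group")["suvr"].mean()
        for g in groups:
            rows.append((rep, g, percent_change(float(means[g]), float(means[baseline]))))
    return pd.DataFrame(rows, columns=["replicate", "group", "pct_change"])


def group_mean_suvr_replicates(
    region: str = "HIP",
    group: str = "11",
    n_replicates: int = 25,
    seed: int = 0,
    window=PAPER_WINDOW,
) -> np.ndarray:
    """Windowed-SUVR group means for one region/group over replicate cohorts.

    Used to check the absolute scale of the calibration (an n = 3 group mean
    from a single cohort has sampling SE ~0.09, so replicates are averaged).
    """
    schedule = default_schedule()
    base = default_cohort_spec(seed=0)
    means = []
    for rep in range(n_replicates):
        spec = _subset_spec(base, (group,), [region], replicate_seed(seed, rep))
        tacs, _ = simulate_cohort(spec, schedule)
        sv = cohort_windowed_suvr(tacs, schedule, window)
        means.append(float(sv[sv["region"] == region]["suvr"].mean()))
    return np.asarray(means)


def type_one_error_rate(
    n_replicates: int = 1000,
    seed: int = 0,
    n_groups: int = 6,
    n_per_group: int = 3,
    sd: float = 0.05,
    engine: str = "anova_tukey",
    alpha: float = 0.05,
) -> float:
    """Baseline-contrast false-rejection rate under zero group effect.

    Each replicate draws all groups from the same normal distribution
    (mean 1, the given SD) and counts a rejection when any adjusted
    baseline contrast falls below ``alpha``. With a multiplicity-adjusted
    engine this family-wise rate should stay at or below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    labels = [f"g{i}" for i in range(n_groups)]
    rejections = 0
    for _ in range(n_replicates):
        df = pd.DataFrame(
            {
                "group": np.repeat(labels, n_per_group),
                "suvr": rng.normal(1.0, sd, n_groups * n_per_group),
            }
        )
        cmp = compare_groups(df, baseline=labels[0], engine=engine)
        base = cmp.pairwise[cmp.pairwise["is_baseline_contrast"]]
        if (base["p_adj"] < alpha).any():
            rejections += 1
    return rejections / n_replicates
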