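"""Cross-sectional group comparison of windowed SUVR.

Default engine: one-way ANOVA with Tukey's HSD for all pairwise contrasts
(the baseline contrasts are what the summary table reports). Alternative
engine: Kruskal-Wallis omnibus with Dunn's rank-based pairwise test and
Bonferroni adjustment, for small groups whose normality is in doubt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "percent_change",
    "compare_groups",
    "build_group_table",
    "significance_stars",
    "GroupComparison",
]

ENGINES = ("anova_tukey", "kruskal_dunn")


def percent_change(group_mean: float, baseline_mean: float) -> float:
    """100 * (group - baseline) / baseline."""
    if baseline_mean == 0:
        raise ZeroDivisionError("baseline mean is zero; percent change undefined")
    if baseline_mean < 0:
        raise ValueError(f"baseline mean must be positive, got {baseline_mean}")
    return 100.0 * (group_mean - baseline_mean) / baseline_mean


def significance_stars(p: float) -> str:
    """Stars at the conventional thresholds: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus + pairwise results for one region."""

    omnibus_p: float
    omnibus_stat: float
    engine: str
    pairwise: pd.DataFrame  # columns: group1, group2, p_adj, is_baseline_contrast


def _dunn_bonferroni(values: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's post-hoc z-test on pooled ranks, Bonferroni-adjusted.

    Standard large-sample form with the tie correction to the rank
    variance; adequate for the handful of groups used here.
    """
    pooled = np.concatenate(values)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction factor
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    correction = 1.0 - tie_term / (n**3 - n) if n > 1 else 1.0
    split = np.cumsum([v.size for v in values])[:-1]
    group_ranks = np.split(ranks, split)
    mean_ranks = [r.mean() for r in group_ranks]
    sizes = [v.size for v in values]
    m = len(values) * (len(values) - 1) // 2
    rows = []
    for i in range(len(values)):
        for j in range(i + 1, len(values)):
            se = np.sqrt(
                (n * (n + 1) / 12.0) * correction * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append((labels[i], labels[j], min(1.0, p * m)))
    return pd.DataFrame(rows, columns=["group1", "group2", "p_adj"])


def compare_groups(
    df: pd.DataFrame,
    value_col: str = "suvr",
    group_col: str = "group",
    baseline: "str | None" = None,
    engine: str = "anova_tukey",
    include_pairwise: bool = True,
) -> GroupComparison:
    """Omnibus test plus all pairwise contrasts with adjusted p-values.

    ``df`` holds one row per animal. ``baseline`` (default: first group in
    sorted order) flags which pairwise contrasts are against the baseline
    group. Engines: "anova_tukey" (one-way ANOVA + Tukey HSD, default) or
    "kruskal_dunn" (Kruskal-Wallis + Dunn with Bonferroni).
    ``include_pairwise=False`` skips the post-hoc contrasts (the omnibus
    alone is much cheaper, e.g. inside permutation studies).
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    labels = sorted(df[group_col].astype(str).unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    values = [
        df.loc[df[group_col].astype(str) == g, value_col].to_numpy(dtype=float)
        for g in labels
    ]
    small = [g for g, v in zip(labels, values) if v.size < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    baseline = str(baseline) if baseline is not None else labels[0]
    if baseline not in labels:
        raise ValueError(f"baseline group {baseline!r} not present in {labels}")

    if engine == "anova_tukey":
        stat, p = sps.f_oneway(*values)
        if not np.isfinite(p):  # zero within-group variance everywhere
            p, stat = 1.0, 0.0
        if not include_pairwise:
            return GroupComparison(
                omnibus_p=float(p), omnibus_stat=float(stat), engine=engine,
                pairwise=pd.DataFrame(
                    columns=["group1", "group2", "p_adj", "is_baseline_contrast"]
                ),
            )
        tuk = pairwise_tukeyhsd(
            endog=np.concatenate(values),
            groups=np.concatenate([[g] * v.size for g, v in zip(labels, values)]),
            alpha=0.05,
        )
        uniq = [str(g) for g in tuk.groupsunique]
        pairs = [
            (uniq[i], uniq[j])
            for i in range(len(uniq))
            for j in range(i + 1, len(uniq))
        ]
        pair = pd.DataFrame(pairs, columns=["group1", "group2"])
        pair["p_adj"] = np.asarray(tuk.pvalues, dtype=float)
    else:
        stat, p = sps.kruskal(*values)
        if not include_pairwise:
            return GroupComparison(
                omnibus_p=float(p), omnibus_stat=float(stat), engine=engine,
                pairwise=pd.DataFrame(
                    columns=["group1", "group2", "p_adj", "is_baseline_contrast"]
                ),
            )
        pair = _dunn_bonferroni(values, labels)

    pair["is_baseline_contrast"] = (pair["group1"] == baseline) | (
        pair["group2"] == baseline
    )
    return GroupComparison(
        omnibus_p=float(p), omnibus_stat=float(stat), engine=engine, pairwise=pair
    )


def build_group_table(
    suvr_df: pd.DataFrame,
    baseline: str,
    engine: str = "anova_tukey",
) -> pd.DataFrame:
    """Per-region group summary: mean +/- SD, percent change vs baseline,
    baseline-contrast adjusted p-value and stars.

    ``suvr_df`` needs columns animal, group, region, suvr with one row per
    animal x region; every animal must carry every region it is compared
    in. Percent changes are computed from unrounded group means. Returns a
    tidy table with columns region, group, n, mean_suvr, sd_suvr,
    pct_change_vs_baseline, p_adj_vs_baseline, stars.
    """
    required = {"animal", "group", "region", "suvr"}
    if not required.issubset(suvr_df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(suvr_df.columns))}")
    counts = suvr_df.groupby("animal")["region"].nunique()
    if counts.nunique() > 1:
        bad = counts[counts != counts.max()].index.tolist()
        raise ValueError(f"animals missing regions: {bad}")
    baseline = str(baseline)
    rows = []
    for region, grp in suvr_df.groupby("region", sort=True):
        cmp = compare_groups(grp, baseline=baseline, engine=engine)
        base_mean = grp.loc[grp["group"].astype(str) == baseline, "suvr"].mean()
        padj = {}
        for _, r in cmp.pairwise.iterrows():
            if r["is_baseline_contrast"]:
                other = r["group2"] if r["group1"] == baseline else r["group1"]
                padj[str(other)] = float(r["p_adj"])
        for g, gg in grp.groupby(grp["group"].astype(str), sort=True):
            mean = float(gg["suvr"].mean())
            sd = float(gg["suvr"].std(ddof=1))
            if g == baseline:
                pct, p = 0.0, np.nan
            else:
                pct, p = percent_change(mean, float(base_mean)), padj.get(g, np.nan)
            rows.append(
                (
                    region,
                    g,
                    int(len(gg)),
                    mean,
                    sd,
                    pct,
                    p,
                    significance_stars(p) if np.isfinite(p) else "",
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region",
            "group",
            "n",
            "mean_suvr",
            "sd_suvr",
            "pct_change_vs_baseline",
            "p_adj_vs_baseline",
            "stars",
        ],
    )
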