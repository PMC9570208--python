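"""Group-comparison statistics and report generation.

One-way ANOVA across the three study groups, followed by post-hoc pairwise
comparisons: Welch two-sample t-tests with Holm step-down adjustment by
default, or Tukey's HSD. Categorical covariates (sex, smoking) are
compared with Pearson's chi-square on the contingency table, without
continuity correction. Normality is reported, not tested: a
quantile-quantile table against the normal distribution is emitted for
visual inspection. The statistical unit is the subject for the GP index
and the cell for domain morphometrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("laurdangp")

__all__ = [
    "GroupComparison",
    "PairwiseResult",
    "anova_oneway",
    "anova_from_summary",
    "posthoc_pairwise",
    "chi_square_categorical",
    "qq_report",
    "compare_feature",
    "significance_stars",
    "full_report",
]

#: smallest positive float; stands in for p-values that underflow to 0
_P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    raw_p: float
    adj_p: float
    statistic: float = np.nan


@dataclass
class GroupComparison:
    """ANOVA + adjusted post-hoc results for one feature."""

    feature_name: str
    group_means_sds: dict[str, tuple[float, float, int]]  # group -> (mean, sd, n)
    anova_F: float
    anova_p: float
    pairwise: list[PairwiseResult]
    adjust_method: str

    def __post_init__(self) -> None:
        if self.adjust_method == "holm":
            for pw in self.pairwise:
                if pw.adj_p + 1e-12 < pw.raw_p:
                    raise ValueError("Holm-adjusted p below raw p")


def _check_groups(values_by_group: Mapping[str, Sequence[float]], min_n: int = 2) -> dict:
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < min_n:
            raise ValueError(f"group {name!r} has fewer than {min_n} observations")
    return groups


def anova_oneway(values_by_group: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classic one-way ANOVA F statistic and p-value.

    Degenerate inputs are handled explicitly: identical groups give
    (F=0, p=1); zero within-group variance with distinct means gives
    (F=inf, p = smallest positive float) rather than NaN.
    """
    groups = _check_groups(values_by_group)
    samples = list(groups.values())
    within_var = sum(v.var(ddof=1) for v in samples)
    means = [v.mean() for v in samples]
    if within_var == 0:
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return np.inf, _P_FLOOR
    with np.errstate(invalid="ignore"):
        F, p = sps.f_oneway(*samples)
    if not np.isfinite(p):
        p = _P_FLOOR if np.isinf(F) else 1.0
    return float(F), float(p)


def anova_from_summary(
    ns: Sequence[int], means: Sequence[float], sds: Sequence[float]
) -> tuple[float, float]:
    """One-way ANOVA from per-group n/mean/SD via the standard decomposition.

    Useful when only summary statistics are available (published tables);
    algebraically identical to :func:`anova_oneway` on the raw samples.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    k = len(ns)
    n_tot = ns.sum()
    grand = float((ns * means).sum() / n_tot)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, n_tot - k
    if ss_within == 0:
        return (0.0, 1.0) if ss_between == 0 else (np.inf, _P_FLOOR)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), p


def posthoc_pairwise(
    values_by_group: Mapping[str, Sequence[float]],
    method: str = "holm",
) -> list[PairwiseResult]:
    """All pairwise group comparisons with multiplicity adjustment.

    ``holm``: Welch two-sample t-tests, Holm step-down adjusted.
    ``tukey``: Tukey's honestly-significant-difference test (its p-values
    are already family-wise, so raw and adjusted coincide).
    """
    groups = _check_groups(values_by_group)
    names = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    if method == "holm":
        raw = []
        stats = []
        for a, b in pairs:
            t = sps.ttest_ind(groups[a], groups[b], equal_var=False)
            raw.append(float(t.pvalue))
            stats.append(float(t.statistic))
        adj = multipletests(raw, method="holm")[1] if raw else []
        return [
            PairwiseResult(pair=p, raw_p=r, adj_p=float(a), statistic=s)
            for p, r, a, s in zip(pairs, raw, adj, stats)
        ]
    if method == "tukey":
        res = sps.tukey_hsd(*(groups[n] for n in names))
        out = []
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                p = float(res.pvalue[i, j])
                out.append(
                    PairwiseResult(
                        pair=(a, names[j]),
                        raw_p=p,
                        adj_p=p,
                        statistic=float(res.statistic[i, j]),
                    )
                )
        return out
    raise ValueError(f"unknown post-hoc method {method!r} (use 'holm' or 'tukey')")


def chi_square_categorical(counts_table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-square on a contingency table (no continuity correction).

    Returns (chi2, p, low_expected) where ``low_expected`` flags expected
    counts below 5 (the classic validity warning).
    """
    table = np.asarray(counts_table)
    if (table < 0).any() or not np.issubdtype(table.dtype, np.number):
        raise ValueError("counts must be non-negative numbers")
    chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
    low = bool((expected < 5).any())
    if low:
        logger.warning("chi-square: expected counts below 5, test may be unreliable")
    return float(chi2), float(p), low


def qq_report(values: Sequence[float]) -> pd.DataFrame:
    """Normal quantile-quantile pairs for visual normality checks.

    Returns a table of (theoretical, empirical) quantiles with the fitted
    line's slope/intercept as attributes; a constant sample is flagged
    degenerate instead of fitted. No automatic rejection is performed.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 observations for a Q-Q report")
    (theo, emp), (slope, intercept, r) = sps.probplot(vals, dist="norm")
    df = pd.DataFrame({"theoretical": theo, "empirical": emp})
    degenerate = bool(np.ptp(vals) == 0)
    df.attrs.update(slope=float(slope), intercept=float(intercept), r=float(r),
                    degenerate=degenerate)
    if degenerate:
        logger.warning("qq_report: constant sample, Q-Q line is degenerate")
    return df


def compare_feature(
    values_by_group: Mapping[str, Sequence[float]],
    feature_name: str,
    method: str = "holm",
) -> GroupComparison:
    """ANOVA plus adjusted pairwise comparisons for one feature."""
    groups = _check_groups(values_by_group)
    F, p = anova_oneway(groups)
    pairwise = posthoc_pairwise(groups, method=method)
    return GroupComparison(
        feature_name=feature_name,
        group_means_sds={
            g: (float(v.mean()), float(v.std(ddof=1)), len(v)) for g, v in groups.items()
        },
        anova_F=F,
        anova_p=p,
        pairwise=pairwise,
        adjust_method=method,
    )


def significance_stars(p: float) -> str:
    """Star convention: **** <1e-4, ** <0.01, * <0.05, else ''."""
    if p < 1e-4:
        return "****"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _comparison_frame(cmp: GroupComparison) -> pd.DataFrame:
    rows = []
    for g, (m, s, n) in cmp.group_means_sds.items():
        rows.append({"kind": "group", "label": g, "mean": m, "sd": s, "n": n,
                     "p": np.nan, "adj_p": np.nan, "stars": ""})
    rows.append({"kind": "anova", "label": "F=%.4g" % cmp.anova_F, "mean": np.nan,
                 "sd": np.nan, "n": np.nan, "p": cmp.anova_p, "adj_p": np.nan,
                 "stars": significance_stars(cmp.anova_p)})
    for pw in cmp.pairwise:
        rows.append({"kind": "pairwise", "label": f"{pw.pair[0]} vs {pw.pair[1]}",
                     "mean": np.nan, "sd": np.nan, "n": np.nan, "p": pw.raw_p,
                     "adj_p": pw.adj_p, "stars": significance_stars(pw.adj_p)})
    return pd.DataFrame(rows)


def full_report(
    subject_df: pd.DataFrame,
    cell_df: pd.DataFrame,
    outdir: str | Path,
    method: str = "holm",
    covariates: Sequence[str] = (),
    make_plots: bool = True,
) -> dict[str, GroupComparison]:
    """Study-level report: one CSV per feature, a JSON summary, and plots.

    ``subject_df`` needs columns ``group`` and ``mean_gp`` (subject rows);
    ``cell_df`` needs ``group``, ``n_domains``, ``mean_feret_um``,
    ``mean_circularity`` (cell rows). Features missing a group are skipped
    with a logged warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features: list[tuple[str, pd.DataFrame, str]] = [("mean_gp", subject_df, "gp")]
    for col in ("n_domains", "mean_feret_um", "mean_circularity"):
        features.append((col, cell_df, col))
    for cov in covariates:
        features.append((cov, subject_df, cov))
    comparisons: dict[str, GroupComparison] = {}
    for col, df, name in features:
        if col not in df.columns:
            logger.warning("full_report: feature %r missing, skipped", col)
            continue
        sub = df[["group", col]].dropna()
        groups = {g: v[col].to_numpy() for g, v in sub.groupby("group")}
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            logger.warning("full_report: feature %r lacks groups/observations, skipped", col)
            continue
        cmp = compare_feature(groups, feature_name=name, method=method)
        comparisons[name] = cmp
        _comparison_frame(cmp).to_csv(outdir / f"{name}.csv", index=False, encoding="utf-8")
    summary = {
        name: {
            "anova_F": c.anova_F,
            "anova_p": c.anova_p,
            "groups": {g: {"mean": m, "sd": s, "n": n}
                       for g, (m, s, n) in c.group_means_sds.items()},
            "pairwise": [
                {"pair": list(pw.pair), "raw_p": pw.raw_p, "adj_p": pw.adj_p,
                 "stars": significance_stars(pw.adj_p)}
                for pw in c.pairwise
            ],
            "adjust_method": c.adjust_method,
        }
        for name, c in comparisons.items()
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")
    if make_plots:
        _plot_features(comparisons, subject_df, cell_df, outdir)
    return comparisons


def _plot_features(
    comparisons: Mapping[str, GroupComparison],
    subject_df: pd.DataFrame,
    cell_df: pd.DataFrame,
    outdir: Path,
) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plot_spec = {
        "gp": ("mean_gp", subject_df, "box", "per-subject mean GP"),
        "n_domains": ("n_domains", cell_df, "box", "LC domains per cell"),
        "mean_feret_um": ("mean_feret_um", cell_df, "violin", "Feret diameter (µm)"),
        "mean_circularity": ("mean_circularity", cell_df, "violin", "circularity"),
    }
    for name, (col, df, kind, ylabel) in plot_spec.items():
        if name not in comparisons or col not in df.columns:
            continue
        sub = df[["group", col]].dropna()
        order = sorted(sub["group"].unique())
        data = [sub.loc[sub["group"] == g, col].to_numpy() for g in order]
        fig, ax = plt.subplots(figsize=(4, 3))
        if kind == "box":
            ax.boxplot(data, tick_labels=order)
        else:
            ax.violinplot(data, showmeans=True)
            ax.set_xticks(range(1, len(order) + 1), order)
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        fig.savefig(outdir / f"{name}.png", dpi=120)
        plt.close(fig)
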