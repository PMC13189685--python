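"""Cohort statistics: Pearson correlations, one-way ANOVA with LSD-t
post-hoc comparisons, and the predefined group analyses.

The analysis set mirrors a clinical angiogenesis-validation design:
perfusion-parameter vs. microvascular-density correlations, repeat-reading
(session 1 vs session 2) correlations, and comparisons of Ktrans, Ve and MVD
across histology, tumor-size (>3 vs <=3 cm) and nodal-status groups.  LSD-t
pairwise comparisons use the pooled within-group mean square with n - k
degrees of freedom and are deliberately unadjusted for multiplicity, as the
named procedure implies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "AnovaResult",
    "pearson_r",
    "anova_lsd",
    "build_cohort_table",
    "run_paper_analyses",
]

logger = logging.getLogger(__name__)

SIZE_GROUPS = (">3cm", "<=3cm")
NODAL_GROUPS = ("positive", "negative")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its t-test p-value and Fisher-z 95% CI."""

    r: float
    p: float
    n: int
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n": self.n,
                "ci_low": self.ci_low, "ci_high": self.ci_high}


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA with LSD-t pairwise comparisons.

    ``pairwise`` holds ``(group_a, group_b, mean_diff, lsd_t, p)`` for every
    unordered pair of groups.
    """

    f_stat: float
    p: float
    df_between: int
    df_within: int
    group_means: dict
    group_sds: dict
    group_ns: dict
    pairwise: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "p": self.p,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "group_means": self.group_means,
            "group_sds": self.group_sds,
            "group_ns": self.group_ns,
            "pairwise": [
                {"group_a": a, "group_b": b, "mean_diff": d, "lsd_t": t, "p": p}
                for (a, b, d, t, p) in self.pairwise
            ],
        }


def pearson_r(x, y) -> CorrelationResult:
    """Product-moment correlation with two-sided p and Fisher-z interval.

    The p-value uses the exact t transform ``t = r sqrt((n-2)/(1-r^2))`` on
    n - 2 degrees of freedom; the 95% interval is ``tanh(atanh(r) +/-
    1.96/sqrt(n-3))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = np.sum(xd**2)
    syy = np.sum(yd**2)
    if sxx == 0 or syy == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(np.sum(xd * yd) / np.sqrt(sxx * syy))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = sps.norm.ppf(0.975) / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
    else:
        ci_low = ci_high = r
    return CorrelationResult(r=r, p=p, n=n, ci_low=ci_low, ci_high=ci_high)


def anova_lsd(values, group_labels) -> AnovaResult:
    """One-way ANOVA followed by LSD-t pairwise comparisons.

    Classical between/within sum-of-squares decomposition; the LSD-t
    statistic for groups a, b is ``(mean_a - mean_b) / sqrt(MSW (1/n_a +
    1/n_b))`` on the within-group degrees of freedom, with unadjusted
    two-sided p-values.  Group summaries use the sample SD (n - 1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValueError("values and group_labels must align")
    groups = list(dict.fromkeys(labels.tolist()))  # preserve first-seen order
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n = values.size
    k = len(groups)
    if n <= k:
        raise ValueError("need more observations than groups")
    grand = values.mean()
    means, sds, ns = {}, {}, {}
    ss_between = 0.0
    ss_within = 0.0
    for g in groups:
        v = values[labels == g]
        ns[g] = int(v.size)
        means[g] = float(v.mean())
        sds[g] = float(v.std(ddof=1)) if v.size > 1 else float("nan")
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += float(np.sum((v - v.mean()) ** 2))
    df_b, df_w = k - 1, n - k
    msw = ss_within / df_w
    if ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_b) / msw
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    pairwise = []
    for a, b in combinations(groups, 2):
        diff = means[a] - means[b]
        se = np.sqrt(msw * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            t_ab = np.inf if diff != 0 else 0.0
        else:
            t_ab = diff / se
        p_ab = float(2.0 * sps.t.sf(abs(t_ab), df=df_w)) if np.isfinite(t_ab) else 0.0
        pairwise.append((a, b, float(diff), float(t_ab), p_ab))
    return AnovaResult(
        f_stat=float(f),
        p=p,
        df_between=df_b,
        df_within=df_w,
        group_means=means,
        group_sds=sds,
        group_ns=ns,
        pairwise=pairwise,
    )


def build_cohort_table(records, fitted: dict | None = None) -> pd.DataFrame:
    """Join lesion records with fitted per-session and final parameters.

    ``fitted`` maps lesion_id -> dict with keys ``ktrans_s1, ve_s1,
    ktrans_s2, ve_s2, ktrans_final, ve_final``; omitted when only truth-level
    analyses are wanted.  Adds the size (> 3 vs <= 3 cm, boundary inclusive
    on the small side) and nodal grouping columns.
    """
    rows = []
    for rec in records:
        row = {
            "lesion_id": rec.lesion_id,
            "histology": rec.histology,
            "size_cm": rec.size_cm,
            "nodal_positive": rec.nodal_positive,
            "mvd": rec.mvd,
            "ktrans_true": rec.ktrans_true,
            "ve_true": rec.ve_true,
        }
        if fitted is not None:
            row.update(fitted[rec.lesion_id])
        rows.append(row)
    df = pd.DataFrame(rows)
    df["size_group"] = np.where(df["size_cm"] > 3.0, SIZE_GROUPS[0], SIZE_GROUPS[1])
    df["nodal_group"] = np.where(df["nodal_positive"], NODAL_GROUPS[0], NODAL_GROUPS[1])
    return df


def _safe_anova(df, value_col, group_col):
    try:
        return anova_lsd(df[value_col].to_numpy(), df[group_col].to_numpy()).to_dict()
    except ValueError as exc:
        logger.warning("skipping %s by %s: %s", value_col, group_col, exc)
        return None


def run_paper_analyses(table: pd.DataFrame) -> dict:
    """Run the full predefined analysis set on a cohort table.

    Emits Ktrans-MVD and Ve-MVD correlations (final values), session-1 vs
    session-2 repeatability correlations where both sessions are present,
    ANOVA + LSD-t across histology, the two predefined two-group comparisons
    (size, nodal status), and mean +/- SD summaries per group.  Comparisons
    whose groups are missing or degenerate are skipped with a logged warning.
    """
    report: dict = {"n": int(len(table)), "correlations": {}, "group_comparisons": {}}
    kt_col = "ktrans_final" if "ktrans_final" in table else "ktrans_true"
    ve_col = "ve_final" if "ve_final" in table else "ve_true"
    report["parameter_columns"] = {"ktrans": kt_col, "ve": ve_col}

    report["correlations"]["ktrans_vs_mvd"] = pearson_r(
        table[kt_col], table["mvd"]
    ).to_dict()
    report["correlations"]["ve_vs_mvd"] = pearson_r(table[ve_col], table["mvd"]).to_dict()
    if {"ktrans_s1", "ktrans_s2"}.issubset(table.columns):
        report["correlations"]["repeatability_ktrans"] = pearson_r(
            table["ktrans_s1"], table["ktrans_s2"]
        ).to_dict()
        report["correlations"]["repeatability_ve"] = pearson_r(
            table["ve_s1"], table["ve_s2"]
        ).to_dict()

    for group_col in ("histology", "size_group", "nodal_group"):
        comp = {}
        for label, col in (("ktrans", kt_col), ("ve", ve_col), ("mvd", "mvd")):
            res = _safe_anova(table, col, group_col)
            if res is not None:
                comp[label] = res
        report["group_comparisons"][group_col] = comp
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`run_paper_analyses` output."""
    lines = [f"Cohort analyses (n = {report['n']})", "=" * 40, "", "Correlations:"]
    for name, c in report["correlations"].items():
        lines.append(
            f"  {name}: r = {c['r']:.3f} (95% CI {c['ci_low']:.3f}..{c['ci_high']:.3f}), "
            f"P = {c['p']:.4g}, n = {c['n']}"
        )
    for group_col, comp in report["group_comparisons"].items():
        lines += ["", f"By {group_col}:"]
        for param, res in comp.items():
            lines.append(
                f"  {param}: F({res['df_between']},{res['df_within']}) = "
                f"{res['f_stat']:.3f}, P = {res['p']:.4g}"
            )
            for g in res["group_means"]:
                lines.append(
                    f"    {g}: {res['group_means'][g]:.3f} +/- "
                    f"{res['group_sds'][g]:.3f} (n = {res['group_ns'][g]})"
                )
            for pw in res["pairwise"]:
                lines.append(
                    f"    {pw['group_a']} vs {pw['group_b']}: diff = "
                    f"{pw['mean_diff']:.3f}, LSD-t = {pw['lsd_t']:.3f}, P = {pw['p']:.4g}"
                )
    return "\n".join(lines)
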