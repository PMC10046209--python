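"""Statistical analysis of threshold tables.

Implements the study's analysis from the standard formulas: one-way
between-groups ANOVA (from raw data or from group summary statistics),
the paired two-sample t-test for means, and the Bonferroni-adjusted
alpha (0.05 / 3 = 0.017 for the three pairwise comparisons of a
family).  p-values come from the F and t distribution functions
(regularized incomplete-beta routines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False  # zero-variance differences with nonzero mean


@dataclass(frozen=True)
class MultipleComparisonPolicy:
    family_alpha: float = 0.05
    m: int = 3

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("number of comparisons m must be >= 1")
        if not 0.0 < self.family_alpha < 1.0:
            raise ValueError("family_alpha must be in (0, 1)")

    @property
    def adjusted_alpha(self) -> float:
        return self.family_alpha / self.m


def bonferroni(policy: MultipleComparisonPolicy) -> float:
    """Bonferroni-adjusted per-comparison alpha: family_alpha / m."""
    return policy.adjusted_alpha


def one_way_anova(groups) -> AnovaResult:
    """Between-groups one-way ANOVA from raw data.

    ``F = MSB / MSW`` with the standard sums of squares; the upper-tail
    p comes from the F(df_between, df_within) distribution.  If both the
    between- and within-group variability vanish, F is defined as 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA requires at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0 and ssb == 0.0:
        return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
    if ssw == 0.0:
        return AnovaResult(F=np.inf, df_between=df_b, df_within=df_w, p=0.0)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def one_way_anova_from_summary(means, sds, n_per_group: int) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group means and SDs.

    Assumes equal group sizes: ``SSB = n * sum((m_i - grand)^2)`` and
    ``MSW = mean(sd_i^2)``.  Agrees with the raw-data ANOVA exactly when
    the summaries come from the same data.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != sds.shape or means.ndim != 1 or means.size < 2:
        raise ValueError("means and sds must be matching vectors of length >= 2")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    k = means.size
    df_b, df_w = k - 1, k * (n_per_group - 1)
    ssb = n_per_group * ((means - means.mean()) ** 2).sum()
    msw = (sds ** 2).mean()
    if msw == 0.0 and ssb == 0.0:
        return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
    if msw == 0.0:
        return AnovaResult(F=np.inf, df_between=df_b, df_within=df_w, p=0.0)
    F = (ssb / df_b) / msw
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def paired_t(a, b) -> PairedTResult:
    """Paired two-sample t-test for means on differences ``a - b``.

    Two-sided p from the t distribution with n - 1 degrees of freedom.
    Zero-variance differences give t = 0 (p = 1) when the mean
    difference is zero, and an infinite t reported as p = 0 with the
    ``degenerate`` flag otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t requires two equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired_t requires n >= 2 pairs")
    d = a - b
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return PairedTResult(t=0.0, df=df, p=1.0, mean_diff=0.0)
        t = np.inf if md > 0 else -np.inf
        return PairedTResult(t=float(t), df=df, p=0.0, mean_diff=float(md), degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PairedTResult(t=float(t), df=df, p=p, mean_diff=float(md))


@dataclass
class AnalysisReport:
    """Omnibus + pairwise analysis of an aggregated threshold table."""

    anova: pd.DataFrame
    ttests: pd.DataFrame
    summary: pd.DataFrame
    policy: MultipleComparisonPolicy

    def to_text(self) -> str:
        lines = ["Summary (mean +/- SE per condition)"]
        for _, r in self.summary.iterrows():
            lines.append(
                f"  {r['task']:>8} @ {r['eccentricity']:>4.0f} deg: "
                f"{r['mean']:6.1f} +/- {r['se']:4.1f} noise dots (n={int(r['n'])})"
            )
        if not self.anova.empty:
            lines.append("")
            lines.append("One-way ANOVA per family")
            for _, r in self.anova.iterrows():
                lines.append(
                    f"  {r['family']}: F({int(r['df_between'])}, {int(r['df_within'])}) = "
                    f"{r['F']:.4f}, p = {r['p']:.4g}"
                )
        if not self.ttests.empty:
            lines.append("")
            lines.append(
                f"Pairwise paired t-tests (Bonferroni alpha = "
                f"{self.policy.adjusted_alpha:.3f})"
            )
            for _, r in self.ttests.iterrows():
                flag = "*" if r["significant"] else " "
                lines.append(
                    f"  {r['family']}: {r['a']} vs {r['b']}: t({int(r['df'])}) = "
                    f"{r['t']:.3f}, p = {r['p']:.4g} {flag}"
                )
        return "\n".join(lines)

    def write_csv(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(d / "summary.csv", index=False)
        self.anova.to_csv(d / "anova.csv", index=False)
        self.ttests.to_csv(d / "ttests.csv", index=False)


def _paired_frame(agg: pd.DataFrame, task_ecc_a, task_ecc_b):
    a = agg[(agg["task"] == task_ecc_a[0]) & (agg["eccentricity"] == task_ecc_a[1])]
    b = agg[(agg["task"] == task_ecc_b[0]) & (agg["eccentricity"] == task_ecc_b[1])]
    merged = a.merge(b, on="observer_id", suffixes=("_a", "_b"))
    return merged["value_a"].to_numpy(), merged["value_b"].to_numpy()


def report(agg: pd.DataFrame, policy: MultipleComparisonPolicy | None = None) -> AnalysisReport:
    """Analyse a best-size aggregated table the way the study does.

    One family compares the three tasks in the central field; one family
    per task compares the three eccentricities.  Each family gets an
    omnibus between-groups ANOVA and all pairwise paired t-tests with
    significance flags at the Bonferroni-adjusted alpha.  Families with
    fewer than two levels present are summarized only.
    """
    policy = policy or MultipleComparisonPolicy()
    if agg["observer_id"].nunique() < 2:
        raise ValueError("the analysis requires at least two observers")
    from .experiment import summarize

    summary = summarize(agg)

    anova_rows, t_rows = [], []

    def add_family(name: str, members: list[tuple]):
        present = [
            m for m in members
            if ((agg["task"] == m[0]) & (agg["eccentricity"] == m[1])).any()
        ]
        if len(present) < 2:
            return
        groups = [
            agg[(agg["task"] == m[0]) & (agg["eccentricity"] == m[1])]["value"].to_numpy()
            for m in present
        ]
        res = one_way_anova(groups)
        anova_rows.append({
            "family": name, "F": res.F, "df_between": res.df_between,
            "df_within": res.df_within, "p": res.p,
        })
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                x, y = _paired_frame(agg, present[i], present[j])
                if x.size < 2:
                    continue
                r = paired_t(x, y)
                t_rows.append({
                    "family": name,
                    "a": f"{present[i][0]}@{present[i][1]:g}",
                    "b": f"{present[j][0]}@{present[j][1]:g}",
                    "t": r.t, "df": r.df, "p": r.p,
                    "mean_diff": r.mean_diff,
                    "significant": r.p < policy.adjusted_alpha,
                })

    tasks = sorted(agg["task"].unique())
    eccs = sorted(agg["eccentricity"].unique())
    if len(tasks) > 1 and 0.0 in eccs:
        add_family("tasks@central", [(t, 0.0) for t in tasks])
    for t in tasks:
        if len(eccs) > 1:
            add_family(f"eccentricity@{t}", [(t, e) for e in eccs])

    return AnalysisReport(
        anova=pd.DataFrame(anova_rows),
        ttests=pd.DataFrame(t_rows),
        summary=summary,
        policy=policy,
    )
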