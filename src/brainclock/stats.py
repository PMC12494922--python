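"""Group comparisons, effect sizes and multiple-testing control.

Covers the comparison battery used throughout the analyses: independent and
paired t-tests with 95% confidence intervals and Cohen's D, one-sided
Mann-Whitney U for small samples, chi-square for categorical covariates,
Cohen's f^2 = r^2/(1-r^2) for correlations, Benjamini-Hochberg FDR, an
ANCOVA of BAGs on group plus covariates, a percentile split of BAGs into
younger/older subgroups, and the pooled within-domain-standardized
expertise-BAG association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass
class StatResult:
    statistic: float
    p: float
    ci_low: float
    ci_high: float
    df: float
    effect_size: float
    method: str

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if self.ci_low > self.ci_high:
                raise ValueError("ci_low must not exceed ci_high")


def _cohens_d_independent(a, b):
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return (a.mean() - b.mean()) / pooled


def compare_groups(a, b, method: str = "independent_t",
                   paired: bool = None, alternative: str = "less") -> StatResult:
    """Compare two samples.

    method: 'independent_t', 'paired_t' or 'mannwhitney' (one-sided; the
    direction must be given via ``alternative``, 'less' meaning a < b).
    Returns the test statistic, p-value, 95% CI of the mean difference
    (t methods), and Cohen's D (a minus b over pooled sd; paired designs use
    the sd of the differences).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if paired is not None:
        method = "paired_t" if paired and method.endswith("_t") else method
    if method == "independent_t":
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            raise ValueError("zero variance in both samples")
        res = stats.ttest_ind(a, b)
        df = len(a) + len(b) - 2
        diff = a.mean() - b.mean()
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        tcrit = stats.t.ppf(0.975, df)
        return StatResult(float(res.statistic), float(res.pvalue),
                          diff - tcrit * se, diff + tcrit * se, float(df),
                          float(_cohens_d_independent(a, b)), "independent_t")
    if method == "paired_t":
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance of paired differences")
        res = stats.ttest_rel(a, b)
        df = len(d) - 1
        se = sd / np.sqrt(len(d))
        tcrit = stats.t.ppf(0.975, df)
        return StatResult(float(res.statistic), float(res.pvalue),
                          d.mean() - tcrit * se, d.mean() + tcrit * se,
                          float(df), float(d.mean() / sd), "paired_t")
    if method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative=alternative)
        return StatResult(float(res.statistic), float(res.pvalue),
                          np.nan, np.nan, np.nan,
                          float(_cohens_d_independent(a, b)),
                          "mannwhitney_one_sided")
    raise ValueError(f"unknown method {method!r}")


def chi_square_counts(table) -> StatResult:
    """Chi-square test of independence on a contingency table."""
    table = np.asarray(table, float)
    chi2, p, df, _ = stats.chi2_contingency(table)
    # Cramer's V as the effect size for contingency tables
    n = table.sum()
    k = min(table.shape) - 1
    v = np.sqrt(chi2 / (n * k)) if n > 0 and k > 0 else np.nan
    return StatResult(float(chi2), float(p), np.nan, np.nan, float(df),
                      float(v), "chi_square")


def effect_size_f2(r: float) -> float:
    """Cohen's f^2 for a correlation: r^2 / (1 - r^2)."""
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return r**2 / (1.0 - r**2)


def fdr_bh(pvals, alpha: float = 0.05) -> dict:
    """Benjamini-Hochberg step-up FDR control.

    Returns q-values (monotone nondecreasing in sorted p order, capped at 1)
    and rejection flags at level ``alpha``.
    """
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    reject = q <= alpha
    return {"qvals": q, "reject": reject}


def ancova_group_effect(outcome, group, covariates: dict) -> StatResult:
    """Least-squares ANCOVA: outcome ~ group + covariates.

    ``group`` is binary (0/1 or two labels); categorical covariates (object
    or non-numeric dtype) enter as indicator codes. Reports the group
    coefficient, its two-sided p, 95% CI, and partial Cohen's f^2 from the
    nested-model R^2 comparison.
    """
    y = np.asarray(outcome, float)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError("group must have exactly two levels")
    gnum = (g == levels[-1]).astype(float)
    cols = [gnum]
    for name, vals in covariates.items():
        v = np.asarray(vals)
        if v.dtype.kind in "OUS":
            cats = np.unique(v)
            cols.extend((v == c).astype(float) for c in cats[1:])
        else:
            cols.append(v.astype(float))
    X = np.column_stack(cols)
    if len(y) <= X.shape[1] + 2:
        raise ValueError("too few observations for the requested model")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("singular design (group confounded with a covariate?)")
    fit = sm.OLS(y, Xc).fit()
    reduced = sm.OLS(y, sm.add_constant(X[:, 1:], has_constant="add")).fit()
    r2f, r2r = fit.rsquared, reduced.rsquared
    f2 = (r2f - r2r) / (1.0 - r2f) if r2f < 1 else np.inf
    ci = fit.conf_int()[1]
    return StatResult(float(fit.params[1]), float(fit.pvalues[1]),
                      float(ci[0]), float(ci[1]), float(fit.df_resid),
                      float(f2), "ancova")


def percentile_split(bags, lo: float = 35.0, hi: float = 65.0) -> np.ndarray:
    """Label BAGs strictly below the lo-th percentile 'younger', strictly
    above the hi-th 'older', the rest 'excluded' (linear-interpolated
    percentiles)."""
    v = np.asarray(bags, float)
    if lo >= hi:
        raise ValueError("lo must be < hi")
    if np.unique(v).size < 3:
        raise ValueError("need at least 3 distinct values")
    plo, phi = np.percentile(v, [lo, hi])
    labels = np.full(v.size, "excluded", dtype=object)
    labels[v < plo] = "younger"
    labels[v > phi] = "older"
    return labels


def expertise_bag_association(bags_by_domain: dict, scores_by_domain: dict) -> dict:
    """Pooled within-domain-standardized BAG-expertise correlation.

    BAGs and expertise scores are z-scored within each domain, pooled across
    domains, and correlated (Pearson, two-sided p, Cohen's f^2). Domains with
    constant scores are dropped with a warning.
    """
    zb, zs = [], []
    for d in bags_by_domain:
        b = np.asarray(bags_by_domain[d], float)
        s = np.asarray(scores_by_domain[d], float)
        if b.size != s.size:
            raise ValueError(f"domain {d!r}: bags and scores must align")
        if s.std(ddof=1) == 0 or b.std(ddof=1) == 0:
            warnings.warn(f"domain {d!r} dropped (constant scores or BAGs)")
            continue
        zb.append((b - b.mean()) / b.std(ddof=1))
        zs.append((s - s.mean()) / s.std(ddof=1))
    if not zb:
        raise ValueError("no domain with nonconstant scores")
    zb = np.concatenate(zb)
    zs = np.concatenate(zs)
    if zb.size < 3:
        raise ValueError("need at least 3 pooled subjects")
    r, p = stats.pearsonr(zb, zs)
    f2 = np.inf if abs(r) >= 1 else effect_size_f2(float(r))
    return {"r": float(r), "p": float(p), "f2": f2, "n": int(zb.size)}
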