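"""Inferential machinery: t-tests with noncentral-t effect-size CIs,
Wilcoxon signed-rank with matched rank-biserial correlation, a Shapiro-Wilk
normality gate, Bonferroni-Holm correction, repeated-measures ANOVA with
Mauchly's sphericity test and Greenhouse-Geisser correction, Fisher's z,
and a noncentral-t sensitivity (minimum detectable effect) solver.

Conventions: one- and two-way designs are fully within-participant; cell
replicates are averaged before the ANOVA; the Greenhouse-Geisser corrected
p-value is *reported* only for effects whose Mauchly test has p < 0.05
(both corrected and uncorrected values are always emitted).  Effect-size
confidence intervals for t-tests are obtained by inverting the noncentral-t
distribution; one-sided intervals are reported as (lower, +inf) or
(-inf, upper).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "TestResult",
    "paired_or_one_sample_t",
    "wilcoxon_signed_rank",
    "normality_gate",
    "holm_adjust",
    "rm_anova",
    "fisher_z",
    "sensitivity_min_effect",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float  # n of non-zero differences for Wilcoxon
    p: float
    effect_size: float  # d / d_z, or matched rank-biserial r
    ci: tuple[float, float]
    sidedness: str
    method: str
    n: int


def _nct_inverse(t_obs: float, df: int, prob: float) -> float:
    """Noncentrality nc with P(T_{df,nc} >= t_obs) = prob (monotone in nc)."""

    def f(nc):
        return stats.nct.sf(t_obs, df, nc) - prob

    lo, hi = t_obs - 2.0, t_obs + 2.0
    while f(lo) > 0 and lo > t_obs - 500:
        lo -= 5.0
    while f(hi) < 0 and hi < t_obs + 500:
        hi += 5.0
    return optimize.brentq(f, lo, hi, xtol=1e-10)


def paired_or_one_sample_t(
    x,
    y=None,
    popmean: float = 0.0,
    alternative: str = "two-sided",
) -> TestResult:
    """Paired (x vs y) or one-sample (x vs popmean) t-test with Cohen's
    d_z and its noncentral-t CI.

    ``d_z = mean(diff) / sd(diff)`` on the difference scores (for a
    one-sample test the differences are ``x - popmean``).
    """
    x = np.asarray(x, dtype=float)
    diff = x - (np.asarray(y, dtype=float) if y is not None else popmean)
    n = diff.size
    if n < 2:
        raise ValueError("need at least two observations")
    sd = diff.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(diff).max())):
        raise ValueError("zero variance in differences")
    df = n - 1
    t = diff.mean() / (sd / math.sqrt(n))
    d = diff.mean() / sd
    # sf(t_obs; nc) is increasing in nc: a small upper-tail probability
    # pins the smallest plausible noncentrality (the lower limit)
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df)
        lo = _nct_inverse(t, df, 0.025) / math.sqrt(n)
        hi = _nct_inverse(t, df, 0.975) / math.sqrt(n)
        ci = (lo, hi)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
        ci = (_nct_inverse(t, df, 0.05) / math.sqrt(n), math.inf)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
        ci = (-math.inf, _nct_inverse(t, df, 0.95) / math.sqrt(n))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(
        statistic=float(t),
        df=df,
        p=float(p),
        effect_size=float(d),
        ci=ci,
        sidedness=alternative,
        method="paired-t" if y is not None else "one-sample-t",
        n=n,
    )


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test with matched rank-biserial correlation.

    Zero differences are dropped; the p-value uses the normal approximation
    with continuity correction; ``r_rb = (T+ - T-) / (T+ + T-)``.  The CI
    for r_rb is a normal-approximation interval on the signed-rank statistic
    (labelled as such via the method tag) -- not an exact interval.
    """
    x = np.asarray(x, dtype=float)
    diff = x - (np.asarray(y, dtype=float) if y is not None else 0.0)
    diff = diff[diff != 0.0]
    n = diff.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = stats.rankdata(np.abs(diff))
    t_plus = float(ranks[diff > 0].sum())
    t_minus = float(ranks[diff < 0].sum())
    total = t_plus + t_minus
    r_rb = (t_plus - t_minus) / total
    res = stats.wilcoxon(diff, alternative=alternative, method="approx", correction=True)
    var_t = n * (n + 1) * (2 * n + 1) / 24.0
    half = 1.959963984540054 * 2.0 * math.sqrt(var_t) / total
    ci = (max(-1.0, r_rb - half), min(1.0, r_rb + half))
    return TestResult(
        statistic=t_plus,
        df=n,
        p=float(res.pvalue),
        effect_size=float(r_rb),
        ci=ci,
        sidedness=alternative,
        method="wilcoxon-signed-rank (normal approx; r_rb CI normal approx)",
        n=n,
    )


def normality_gate(differences, alpha: float = 0.05) -> str:
    """Route to "t" or "wilcoxon" by a Shapiro-Wilk test on the differences.

    Deterministic for identical data: Wilcoxon when Shapiro-Wilk p < alpha.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 observations")
    p = stats.shapiro(d).pvalue
    return "wilcoxon" if p < alpha else "t"


def holm_adjust(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-Holm step-down correction.

    Returns a table in the input order with the per-test threshold
    ``alpha / (m - rank + 1)`` and the step-down rejection flag; the
    attribute ``df.attrs['min_threshold']`` carries the smallest threshold
    ``alpha / m`` (the one applied to the smallest p-value).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = np.empty(m)
    reject = np.zeros(m, dtype=bool)
    still_rejecting = True
    for rank, idx in enumerate(order):
        thr = alpha / (m - rank)
        thresholds[idx] = thr
        if still_rejecting and p[idx] <= thr:
            reject[idx] = True
        else:
            still_rejecting = False
    out = pd.DataFrame({"p": p, "threshold": thresholds, "reject": reject})
    out.attrs["min_threshold"] = alpha / m
    return out


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform, ``z = atanh(r)``."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1")
    return math.atanh(r)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


def _helmert(k: int) -> np.ndarray:
    """Orthonormal contrast matrix, shape (k-1, k), rows orthogonal to 1."""
    return linalg.helmert(k, full=False)


def _sphericity(t: np.ndarray) -> tuple[float, float, float]:
    """Mauchly W and p plus GG epsilon from contrast-transformed scores.

    ``t`` has shape (n_subjects, d) where d is the effect's contrast
    dimension.  For d == 1 sphericity holds trivially.
    """
    n, d = t.shape
    if d == 1:
        return 1.0, 1.0, 1.0
    s = np.cov(t, rowvar=False, ddof=1)
    tr = np.trace(s)
    eps = tr**2 / (d * np.sum(s * s))
    det = np.linalg.det(s)
    if det <= 0 or n - 1 <= d:
        # singular covariance: W undefined; report epsilon only
        return np.nan, np.nan, float(eps)
    w = det / (tr / d) ** d
    c = 1.0 - (2 * d * d + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * c * math.log(w)
    df_m = d * (d + 1) // 2 - 1
    p = stats.chi2.sf(chi2, df_m)
    return float(w), float(p), float(eps)


def _effect_row(name, ss_eff, ss_err, df1, df2, t_scores):
    f = (ss_eff / df1) / (ss_err / df2)
    p = stats.f.sf(f, df1, df2)
    w, p_m, eps = _sphericity(t_scores)
    p_gg = stats.f.sf(f, eps * df1, eps * df2)
    corrected = (not np.isnan(p_m)) and p_m < 0.05
    return {
        "effect": name,
        "F": float(f),
        "df1": float(df1),
        "df2": float(df2),
        "p": float(p),
        "np2": float(ss_eff / (ss_eff + ss_err)),
        "mauchly_W": w,
        "mauchly_p": p_m,
        "eps": eps,
        "df1_gg": float(eps * df1),
        "df2_gg": float(eps * df2),
        "p_gg": float(p_gg),
        "sphericity_corrected": bool(corrected),
        "p_reported": float(p_gg if corrected else p),
    }


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str] | str,
    subject: str = "participant_id",
) -> pd.DataFrame:
    """One- or two-way fully within-participant ANOVA on cell means.

    Participants with any missing cell are excluded listwise; replicates
    within a cell are averaged.  Returns one row per effect with F,
    uncorrected and Greenhouse-Geisser corrected dfs and p, partial eta
    squared, Mauchly's W and p, and ``p_reported`` following the rule
    "apply GG only when Mauchly p < 0.05".
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("within must name one or two factors")
    cells = data.groupby([subject, *within], sort=True)[dv].mean().unstack(within)
    cells = cells.dropna(axis=0, how="any")
    n = len(cells)
    if n < 3:
        raise ValueError(f"need at least 3 complete participants, got {n}")

    if len(within) == 1:
        y = cells.to_numpy()  # (n, a)
        a = y.shape[1]
        if a < 2:
            raise ValueError("factor needs at least two levels")
        m = y.mean()
        m_a = y.mean(axis=0)
        m_s = y.mean(axis=1)
        ss_a = n * np.sum((m_a - m) ** 2)
        resid = y - m_a[None, :] - m_s[:, None] + m
        ss_err = np.sum(resid**2)
        t_scores = y @ _helmert(a).T
        row = _effect_row(within[0], ss_a, ss_err, a - 1, (a - 1) * (n - 1), t_scores)
        return pd.DataFrame([row])

    fa, fb = within
    a_levels = cells.columns.get_level_values(0).unique()
    b_levels = cells.columns.get_level_values(1).unique()
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("both factors need at least two levels")
    if cells.shape[1] != a * b:
        raise ValueError("unbalanced design: missing factor-level combinations")
    # reshape to (n, a, b) in sorted level order
    d3 = np.empty((n, a, b))
    for i, la in enumerate(a_levels):
        for j, lb in enumerate(b_levels):
            d3[:, i, j] = cells[(la, lb)].to_numpy()
    m = d3.mean()
    m_s = d3.mean(axis=(1, 2))
    m_a = d3.mean(axis=(0, 2))
    m_b = d3.mean(axis=(0, 1))
    m_ab = d3.mean(axis=0)
    m_as = d3.mean(axis=2)
    m_bs = d3.mean(axis=1)

    rows = []
    # main effect A from data collapsed over B
    ss_a = n * b * np.sum((m_a - m) ** 2)
    resid_as = m_as - m_a[None, :] - m_s[:, None] + m
    ss_as = b * np.sum(resid_as**2)
    rows.append(
        _effect_row(fa, ss_a, ss_as, a - 1, (a - 1) * (n - 1), m_as @ _helmert(a).T)
    )
    # main effect B
    ss_b = n * a * np.sum((m_b - m) ** 2)
    resid_bs = m_bs - m_b[None, :] - m_s[:, None] + m
    ss_bs = a * np.sum(resid_bs**2)
    rows.append(
        _effect_row(fb, ss_b, ss_bs, b - 1, (b - 1) * (n - 1), m_bs @ _helmert(b).T)
    )
    # interaction
    inter = m_ab - m_a[:, None] - m_b[None, :] + m
    ss_ab = n * np.sum(inter**2)
    resid_abs = (
        d3
        - m_as[:, :, None]
        - m_bs[:, None, :]
        - m_ab[None, :, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - m
    )
    ss_abs = np.sum(resid_abs**2)
    c_ab = np.kron(_helmert(a), _helmert(b))  # ((a-1)(b-1), a*b)
    flat = d3.reshape(n, a * b)
    rows.append(
        _effect_row(
            f"{fa} * {fb}",
            ss_ab,
            ss_abs,
            (a - 1) * (b - 1),
            (a - 1) * (b - 1) * (n - 1),
            flat @ c_ab.T,
        )
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sensitivity analysis


def _t_power(d: float, n: int, alpha: float, tails: int) -> float:
    """Exact power of a one-sample / paired t-test at effect size d."""
    df = n - 1
    nc = d * math.sqrt(n)
    if tails == 2:
        tc = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))
    tc = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(tc, df, nc))


def sensitivity_min_effect(
    n: int,
    alpha: float = 0.05,
    power: float = 0.80,
    tails: int = 2,
    design: str = "one_sample",
) -> float:
    """Smallest Cohen's d detectable at the given n, alpha and power.

    Solves ``power(d) = power`` for a one-sample (or paired, on difference
    scores -- the two are formally identical with n = number of pairs)
    t-test using exact noncentral-t tail probabilities; bisection to
    |delta d| < 1e-6.
    """
    if design not in ("one_sample", "paired"):
        raise ValueError(f"unknown design {design!r}")
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if not alpha < power < 1.0:
        raise ValueError("power must lie in (alpha, 1): below alpha it is unreachable")
    lo, hi = 0.0, 0.1
    while _t_power(hi, n, alpha, tails) < power:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("requested power unreachable")
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if _t_power(mid, n, alpha, tails) < power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
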