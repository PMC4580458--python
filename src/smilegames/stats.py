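"""Statistical summaries used by the smile-game analyses.

Exact binomial tail tests against chance, one-way repeated-measures
ANOVA with the Greenhouse-Geisser sphericity correction and (partial)
eta-squared, paired two-tailed t-tests, and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    df: float
    p_two_tailed: float


@dataclass
class RMAnovaResult:
    """One-way within-subjects ANOVA with GG-corrected degrees of freedom."""

    F: float
    df1: float
    df2: float
    epsilon_gg: float
    p: float
    eta_sq: float  # partial eta squared by default
    eta_sq_classical: float


def binom_tail(k_successes: int, n: int, p0: float) -> float:
    """Exact probability of >= k successes in n Bernoulli(p0) trials.

    Computed as the explicit upper-tail sum of binomial pmf terms.
    """
    if not 0 <= k_successes <= n:
        raise ValueError("k_successes must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    ks = np.arange(k_successes, n + 1)
    return float(sps.binom.pmf(ks, n, p0).sum())


def rm_anova_gg(data: np.ndarray, correction: str = "always") -> RMAnovaResult:
    """One-way repeated-measures ANOVA over an n-subjects x k-conditions table.

    The Greenhouse-Geisser epsilon is estimated from the sample
    covariance of the conditions and applied to both degrees of freedom
    before evaluating the F distribution.  ``correction`` may be
    "always" (default), "never", or "mauchly" (apply only when
    Mauchly's sphericity test rejects at .05; with k = 2 epsilon is 1
    and the test reduces to the paired t-test with F = t**2).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D subjects x conditions array")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.isnan(X).any():
        raise ValueError("missing cells are not supported")

    grand = X.mean()
    subj_means = X.mean(axis=1)
    cond_means = X.mean(axis=0)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    # degenerate decompositions: identical conditions give F = 0, p = 1;
    # a fully constant table has no defined F at all
    if np.isclose(ss_total, 0.0):
        raise ValueError("constant data: F is undefined")
    if np.isclose(ms_err, 0.0):
        if np.isclose(ss_cond, 0.0):
            ms_cond = 0.0
        ms_err = np.finfo(float).tiny
    F = ms_cond / ms_err

    eps = _gg_epsilon(X)
    apply_gg = k > 2 and (
        correction == "always"
        or (correction == "mauchly" and _mauchly_p(X) < 0.05)
    )
    eps_used = eps if apply_gg else 1.0
    df1 = df_cond * eps_used
    df2 = df_err * eps_used
    p = float(sps.f.sf(F, df1, df2))
    eta_partial = ss_cond / (ss_cond + ss_err) if ss_cond + ss_err > 0 else 0.0
    eta_classical = ss_cond / ss_total
    return RMAnovaResult(
        F=float(F),
        df1=float(df1),
        df2=float(df2),
        epsilon_gg=float(eps if k > 2 else 1.0),
        p=p,
        eta_sq=float(eta_partial),
        eta_sq_classical=float(eta_classical),
    )


def _gg_epsilon(X: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    k = X.shape[1]
    S = np.cov(X, rowvar=False, ddof=1)
    row_mean = S.mean(axis=0)
    Sc = S - row_mean[:, None] - row_mean[None, :] + S.mean()
    num = np.trace(Sc) ** 2
    den = (k - 1) * (Sc**2).sum()
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def _mauchly_p(X: np.ndarray) -> float:
    """Mauchly's test of sphericity (chi-square approximation)."""
    n, k = X.shape
    # orthonormal contrasts of the condition space
    C = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    S = C.T @ np.cov(X, rowvar=False, ddof=1) @ C
    d = k - 1
    eig = np.linalg.eigvalsh(S)
    if (eig <= 0).any():
        return 0.0
    W = np.prod(eig) / (eig.mean() ** d)
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    df = d * (d + 1) / 2 - 1
    return float(sps.chi2.sf(chi2, df))


def paired_t(x, y) -> TestResult:
    """Two-tailed paired t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with >= 3 pairs")
    if np.std(x - y) == 0:
        if np.allclose(x, y):
            return TestResult(statistic=0.0, df=float(x.size - 1), p_two_tailed=1.0)
        raise ValueError("zero variance of the paired differences")
    res = sps.ttest_rel(x, y)
    return TestResult(
        statistic=float(res.statistic),
        df=float(x.size - 1),
        p_two_tailed=float(res.pvalue),
    )


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with a two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with >= 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        df=float(x.size - 2),
        p_two_tailed=float(res.pvalue),
    )
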