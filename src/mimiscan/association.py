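"""Cohort association statistics: logistic diagnosis models, group-mean tests,
contingency chi-square, Kaplan-Meier / log-rank survival, and stratified
Spearman correlation.

All tests are two-sided.  No multiple-testing correction is applied by
default; a Benjamini-Hochberg utility is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "TTestResult",
    "ChiSquareResult",
    "SurvivalStratumResult",
    "SpearmanResult",
    "fit_diagnosis_logistic",
    "compare_group_means",
    "arb_category_chisq",
    "km_logrank",
    "stratified_spearman",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit of a binary diagnosis on one predictor.

    ``odds_ratio`` is per 1 unit of the predictor; ``odds_ratio_per_sd`` the
    same effect re-expressed per sample standard deviation of the predictor.
    """

    coefficient: float
    odds_ratio: float
    odds_ratio_per_sd: float
    standard_error: float
    p_value: float
    conf_int_or: tuple[float, float]
    converged: bool
    n_used: int
    separation: bool = False


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    df: float
    mean_diff: float
    equal_var: bool


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    df: int
    expected: np.ndarray = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class SurvivalStratumResult:
    strata: tuple[str, ...]
    curves: dict[str, pd.DataFrame] = field(repr=False)
    logrank_statistic: float = float("nan")
    logrank_p: float = float("nan")
    n_per_stratum: dict[str, int] = field(default_factory=dict)
    n_dropped: int = 0


@dataclass(frozen=True)
class SpearmanResult:
    stratum: str
    rho: float
    p_value: float
    n: int


def fit_diagnosis_logistic(
    predictor,
    diagnosis,
    covariates: pd.DataFrame | None = None,
) -> LogisticFit:
    """Logistic regression of binary diagnosis (1 = case) on an EBS summary.

    Rows with missing predictor/outcome are dropped (count logged).
    Non-convergence and complete separation are flagged on the result rather
    than silently returned; a constant predictor raises.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(diagnosis, dtype=float)
    if x.shape != y.shape:
        raise ValueError("predictor and diagnosis lengths differ")
    keep = ~(np.isnan(x) | np.isnan(y))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d rows with missing values", n_dropped)
    x, y = x[keep], y[keep]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("diagnosis must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("need at least one case and one non-case")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; logistic model unidentified")

    design = pd.DataFrame({"const": 1.0, "ebs": x})
    if covariates is not None:
        cov = covariates.reset_index(drop=True).loc[keep[: len(covariates)]]
        for c in cov.columns:
            design[c] = np.asarray(cov[c], dtype=float)

    separation = False
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        separation = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
        converged = bool(res.mle_retvals.get("converged", True))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separation = True
        res = sm.Logit(y, design).fit_regularized(disp=0, alpha=1e-8, maxiter=500)
        converged = False
    # quasi-separation escapes both routes but inflates the standard error
    if not separation and np.isfinite(res.bse["ebs"]) and res.bse["ebs"] > 50:
        separation = True
    if separation:
        logger.warning("complete separation detected; estimates unreliable")
    beta = float(res.params["ebs"])
    se = float(res.bse["ebs"]) if hasattr(res, "bse") else float("nan")
    pval = float(res.pvalues["ebs"]) if hasattr(res, "pvalues") else float("nan")
    sd = float(np.std(x, ddof=1))
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return LogisticFit(
        coefficient=beta,
        odds_ratio=float(np.exp(beta)),
        odds_ratio_per_sd=float(np.exp(beta * sd)),
        standard_error=se,
        p_value=pval,
        conf_int_or=(float(np.exp(lo)), float(np.exp(hi))),
        converged=converged,
        n_used=int(len(x)),
        separation=separation,
    )


def compare_group_means(a, b, *, equal_var: bool = True) -> TTestResult:
    """Two-sided independent-samples t-test (Student by default, Welch option)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    res = st.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df) if hasattr(res, "df") else (
        len(a) + len(b) - 2 if equal_var else float("nan")
    )
    return TTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
        mean_diff=float(a.mean() - b.mean()),
        equal_var=equal_var,
    )


def arb_category_chisq(table) -> ChiSquareResult:
    """Pearson chi-square on an r x c contingency table, no continuity correction.

    All expected counts must be strictly positive (zero row/column margins
    raise).  df = (r-1)(c-1).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin gives expected counts of 0")
    chi2, p, dof, expected = st.chi2_contingency(tab, correction=False)
    return ChiSquareResult(
        statistic=float(chi2), p_value=float(p), df=int(dof), expected=expected
    )


def km_logrank(
    durations,
    events,
    strata,
) -> SurvivalStratumResult:
    """Kaplan-Meier curves per stratum plus a k-sample log-rank test.

    Rows with missing duration/event/stratum are dropped with a logged count.
    Ties use the standard hypergeometric log-rank variance.  When no events
    occur anywhere the statistic is 0 with a warning.
    """
    df = pd.DataFrame(
        {"t": np.asarray(durations, dtype=float),
         "e": np.asarray(events, dtype=float),
         "g": pd.Series(list(strata), dtype=object)}
    )
    before = len(df)
    df = df.dropna()
    dropped = before - len(df)
    if dropped:
        logger.warning("dropping %d subjects with missing survival metadata", dropped)
    if (df["t"] < 0).any():
        raise ValueError("durations must be >= 0")
    labels = sorted(str(lab) for lab in df["g"].astype(str).unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 strata with >= 1 subject each")

    curves: dict[str, pd.DataFrame] = {}
    n_per: dict[str, int] = {}
    for lab in labels:
        sub = df[df["g"].astype(str) == lab]
        n_per[lab] = len(sub)
        kmf = KaplanMeierFitter()
        kmf.fit(sub["t"], event_observed=sub["e"], label=lab)
        ev = kmf.event_table
        curves[lab] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "at_risk": ev["at_risk"].to_numpy(dtype=float),
                "events": ev["observed"].to_numpy(dtype=float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            }
        )

    if df["e"].sum() == 0:
        logger.warning("all subjects censored; log-rank statistic set to 0")
        stat, p = 0.0, 1.0
    else:
        res = multivariate_logrank_test(df["t"], df["g"].astype(str), df["e"])
        stat, p = float(res.test_statistic), float(res.p_value)
    return SurvivalStratumResult(
        strata=tuple(labels),
        curves=curves,
        logrank_statistic=stat,
        logrank_p=p,
        n_per_stratum=n_per,
        n_dropped=dropped,
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for Spearman rho at very small n."""
    from itertools import permutations

    ry = st.rankdata(y)
    rx = st.rankdata(x)
    n = len(x)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = st.spearmanr(rx, ry[list(perm)]).statistic
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return count / total


def stratified_spearman(
    x,
    y,
    strata,
    *,
    exact_small_n: bool = False,
) -> list[SpearmanResult]:
    """Spearman rank correlation of (x, y) within each stratum, mid-rank ties.

    p-values use the t-approximation; with ``exact_small_n`` strata of n <= 8
    use exact permutation enumeration instead.  Strata with n < 3 or a
    constant variable yield NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = pd.Series(list(strata), dtype=object).astype(str)
    out: list[SpearmanResult] = []
    for lab in sorted(g.unique()):
        mask = (g == lab).to_numpy()
        xs, ys = x[mask], y[mask]
        n = len(xs)
        if n < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            logger.warning("stratum %s: correlation undefined (n=%d)", lab, n)
            out.append(SpearmanResult(lab, float("nan"), float("nan"), n))
            continue
        res = st.spearmanr(xs, ys)
        rho, p = float(res.statistic), float(res.pvalue)
        if exact_small_n and n <= 8:
            p = _spearman_exact_p(xs, ys, rho)
        out.append(SpearmanResult(lab, rho, p, n))
    return out


def benjamini_hochberg(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg FDR adjustment (a convenience; off by default
    everywhere else in the package, which reports unadjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({"p": p, "p_adjusted": p_adj, "reject": reject})
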