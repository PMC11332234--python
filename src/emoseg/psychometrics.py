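"""Reliability and validity statistics for per-trial metric scores.

* ``omega_total`` — McDonald's omega-total from a one-factor minres fit to
  the trial correlation matrix: with standardized loadings lambda_i and
  uniquenesses psi_i, omega = (sum lambda)^2 / ((sum lambda)^2 + sum psi).
* ``icc_single_twoway`` — ICC(A,1): two-way random effects, absolute
  agreement, single measurement, from the two-way ANOVA mean squares; the
  convention reported as "ICC2" by the psych R package.
* ``spearman_bonferroni`` — Spearman rho with a Fisher-z confidence interval
  (variance 1.06/(n-3)) and Bonferroni-adjusted p.
* ``partial_spearman`` — rank-transform x, y, z; residualize z out of the
  ranks by least squares; Pearson-correlate the residuals.

Missing data: correlations use pairwise-complete observations (consistent
with per-cell MAD screening upstream); omega and ICC use listwise-complete
rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float
    n_pairs: int
    method: str

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and not -1.0 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho out of [-1, 1]")


def _complete_rows(m: np.ndarray) -> np.ndarray:
    return m[np.isfinite(m).all(axis=1)]


def fit_one_factor_minres(corr: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Standardized loadings of a one-factor model by minimum residual.

    Minimizes the sum of squared off-diagonal residuals of R - lambda lambda'.
    Loadings are sign-fixed so their sum is non-negative.
    """
    p = corr.shape[0]
    off = ~np.eye(p, dtype=bool)

    def objective(lam: np.ndarray) -> float:
        resid = corr - np.outer(lam, lam)
        return float(np.sum(resid[off] ** 2))

    # first principal component as the start
    w, v = np.linalg.eigh(corr)
    start = v[:, -1] * np.sqrt(max(w[-1], 0.0))
    res = optimize.minimize(objective, start, method="L-BFGS-B", tol=tol)
    if not res.success and res.fun > 1e-6:
        logger.warning("one-factor minres fit did not converge: %s", res.message)
    lam = res.x
    if lam.sum() < 0:
        lam = -lam
    return np.clip(lam, -1.0, 1.0)


def omega_total(trials: pd.DataFrame | np.ndarray) -> float:
    """Omega-total internal consistency of a participants x trials matrix.

    Rows with any missing trial are dropped (listwise). Returns NaN, with a
    log message, when fewer than 3 trials or 10 complete rows remain or the
    correlation matrix is degenerate.
    """
    m = np.asarray(trials, dtype=float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValueError("omega_total needs a 2-D matrix with >= 3 trial columns")
    m = _complete_rows(m)
    if m.shape[0] < 10:
        logger.warning("omega_total: only %d complete rows (<10) -> NaN", m.shape[0])
        return float("nan")
    sds = m.std(axis=0, ddof=1)
    if np.any(sds == 0):
        logger.warning("omega_total: zero-variance trial column -> NaN")
        return float("nan")
    corr = np.corrcoef(m, rowvar=False)
    lam = fit_one_factor_minres(corr)
    psi = np.clip(1.0 - lam**2, 0.0, None)
    s = lam.sum()
    return float(s * s / (s * s + psi.sum()))


def omega_from_loadings(loadings, uniquenesses) -> float:
    """Closed-form omega given loadings and uniquenesses (for known models)."""
    s = float(np.sum(loadings))
    return s * s / (s * s + float(np.sum(uniquenesses)))


def icc_single_twoway(week1, week2) -> tuple[float, float]:
    """ICC(A,1) and paired Pearson r for two measurement occasions.

    Two-way random effects, absolute agreement, single measurement:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` with k = 2
    occasions and n paired subjects. Pairs with a missing value are dropped.
    """
    x = np.asarray(week1, dtype=float)
    y = np.asarray(week2, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise ValueError("icc_single_twoway requires >= 5 complete pairs")
    m = np.column_stack([x, y])
    k = 2
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((m - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(msr, 0):
        logger.warning("icc_single_twoway: no between-subject variance -> NaN")
        return float("nan"), float("nan")
    icc = float((msr - mse) / denom)
    if np.std(x) == 0 or np.std(y) == 0:
        pearson = float("nan")
    else:
        pearson = float(stats.pearsonr(x, y).statistic)
    return icc, pearson


def _fisher_ci(rho: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if abs(rho) >= 1.0:
        return rho, rho
    z = np.arctanh(rho)
    se = np.sqrt(1.06 / (n - 3))
    zc = stats.norm.ppf(1 - alpha / 2)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def spearman_bonferroni(x, y, n_comparisons: int = 1) -> CorrelationResult:
    """Spearman rho with Fisher-z CI and Bonferroni-adjusted p (pairwise-complete)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("spearman_bonferroni requires >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    res = stats.spearmanr(x, y)
    rho, p = float(res.statistic), float(res.pvalue)
    lo, hi = _fisher_ci(rho, n)
    return CorrelationResult(rho, lo, hi, p, min(1.0, p * n_comparisons), n, "spearman")


def partial_spearman(x, y, z, n_comparisons: int = 1) -> CorrelationResult:
    """Rank-based partial correlation of x and y controlling for z.

    All three vectors are rank-transformed; z's ranks are regressed out of
    x's and y's ranks (with intercept) and the residuals Pearson-correlated.
    The p-value uses the t reference with n - 3 degrees of freedom.
    """
    arrs = [np.asarray(v, dtype=float) for v in (x, y, z)]
    ok = np.logical_and.reduce([np.isfinite(v) for v in arrs])
    x, y, z = (v[ok] for v in arrs)
    n = len(x)
    if n < 5:
        raise ValueError("partial_spearman requires >= 5 complete triples")
    if np.ptp(z) == 0:
        raise ValueError("control variable is constant")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    design = np.column_stack([np.ones(n), rz])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    if np.allclose(res_x, 0) or np.allclose(res_y, 0):
        # a variable identical (in ranks) to the control has nothing left to
        # correlate: no remaining association
        logger.info("partial_spearman: zero residual variance, rho defined as 0")
        return CorrelationResult(0.0, 0.0, 0.0, 1.0, 1.0, n, "partial_spearman")
    rho = float(np.corrcoef(res_x, res_y)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df))
    lo, hi = _fisher_ci(rho, n - 1)  # one df spent on the control
    return CorrelationResult(rho, lo, hi, p, min(1.0, p * n_comparisons), n, "partial_spearman")


def correlation_report(
    metrics: pd.DataFrame, external: pd.DataFrame, n_comparisons: int | None = None
) -> pd.DataFrame:
    """Metric x external-score Spearman matrix with raw and adjusted p.

    ``metrics`` and ``external`` are participant-indexed frames; the
    Bonferroni family size defaults to the number of metric/external pairs.
    """
    joined = metrics.join(external, how="inner")
    pairs = [(m, e) for m in metrics.columns for e in external.columns]
    m_total = n_comparisons if n_comparisons is not None else len(pairs)
    rows = []
    for m, e in pairs:
        try:
            r = spearman_bonferroni(joined[m], joined[e], m_total)
        except ValueError as err:
            logger.warning("correlation %s ~ %s skipped: %s", m, e, err)
            continue
        rows.append(
            {
                "metric": m,
                "external": e,
                "rho": r.rho,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "n": r.n_pairs,
            }
        )
    return pd.DataFrame(rows)
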