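"""Transcriptome-wide selection scan (TWSS).

For each gene, predicted expression is regressed on sample date (ordinary
least squares with intercept; *t* in years before present, so a positive
slope means higher expression in the past). Raw two-sided P-values are
deflated by genomic control — λ is the median of the χ²₁-transformed test
statistics over the null χ²₁ median — and Benjamini–Hochberg q-values are
computed on the GC-adjusted P-values. A date-randomization scan (one global
permutation of dates, all genes) provides the empirical null for QQ
diagnostics.

No ancestry covariates are used; genomic control absorbs inflation from
drift or residual structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549364...


@dataclass
class GcReport:
    lam: float
    n_tests: int


@dataclass
class RegressionResult:
    beta: float
    se: float
    p_raw: float
    degenerate: bool


def fit_time_regression(expr: np.ndarray, dates: np.ndarray) -> RegressionResult:
    """OLS slope of expression on date (years BP) with two-sided t-test P.

    Constant expression yields a degenerate record (beta 0, p 1); constant
    dates are fatal since the design is singular for every gene.
    """
    expr = np.asarray(expr, float)
    dates = np.asarray(dates, float)
    if expr.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(dates) == 0:
        raise ValueError("all dates identical: time regression undefined")
    if np.ptp(expr) == 0:
        return RegressionResult(0.0, np.nan, 1.0, True)
    beta, se, p = _ols_many(expr[None, :], dates)
    return RegressionResult(float(beta[0]), float(se[0]), float(p[0]), False)


def _ols_many(Y: np.ndarray, t: np.ndarray):
    """Closed-form simple OLS for many responses sharing one regressor."""
    n = t.size
    tc = t - t.mean()
    sxx = float(tc @ tc)
    beta = Y @ tc / sxx
    alpha = Y.mean(axis=1) - beta * t.mean()
    resid = Y - alpha[:, None] - beta[:, None] * t
    sigma2 = (resid ** 2).sum(axis=1) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero residual variance with a nonzero slope is a perfect fit
        tstat = np.where(se > 0, beta / se,
                         np.where(beta != 0, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def scan(expression: pd.DataFrame, dates: np.ndarray,
         tissues: dict[str, str] | None = None) -> tuple[pd.DataFrame, GcReport]:
    """Run the full TWSS: per-gene OLS, genomic control, BH-FDR.

    ``expression`` is a genes × samples frame aligned with ``dates``.
    Returns the per-gene table (beta, se, p_raw, p_gc, q, degenerate flag)
    and the genomic-control report.
    """
    dates = np.asarray(dates, float)
    if expression.shape[1] != dates.size:
        raise ValueError("expression columns and dates differ in length")
    if np.ptp(dates) == 0:
        raise ValueError("all dates identical: time regression undefined")

    Y = expression.to_numpy(dtype=float)
    degenerate = np.ptp(Y, axis=1) == 0
    beta, se, p_raw = _ols_many(Y, dates)
    beta = np.where(degenerate, 0.0, beta)
    se = np.where(degenerate, np.nan, se)
    p_raw = np.where(degenerate, 1.0, p_raw)

    live = ~degenerate
    p_gc = np.ones_like(p_raw)
    report, p_gc_live = genomic_control(p_raw[live])
    p_gc[live] = p_gc_live
    q = np.ones_like(p_gc)
    q[live] = bh_fdr(p_gc[live])

    out = pd.DataFrame({
        "gene_id": expression.index,
        "tissue": [tissues.get(g, "") if tissues else "" for g in expression.index],
        "beta": beta,
        "se": se,
        "p_raw": p_raw,
        "p_gc": p_gc,
        "q": q,
        "degenerate": degenerate,
    }).set_index("gene_id")
    return out, report


def genomic_control(p_raw: np.ndarray) -> tuple[GcReport, np.ndarray]:
    """Deflate P-values by the inflation factor λ.

    Each P is mapped to a 1-df χ² statistic; λ is the observed median over
    the χ²₁ median (0.4549); adjusted P-values come from the upper tail of
    χ²/λ. λ < 1 is reported as-is, not clipped.
    """
    p_raw = np.asarray(p_raw, float)
    if p_raw.size and (p_raw.min() <= 0 or p_raw.max() > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if p_raw.size < 20:
        import logging
        logging.getLogger("paleotwas").warning(
            "genomic control on only %d tests; lambda is unstable", p_raw.size)
    chi2 = stats.chi2.isf(p_raw, 1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    p_gc = stats.chi2.sf(chi2 / lam, 1)
    return GcReport(lam, p_raw.size), np.clip(p_gc, np.finfo(float).tiny, 1.0)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if p.min() <= 0 or p.max() > 1:
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def randomized_scan(expression: pd.DataFrame, dates: np.ndarray,
                    seed: int) -> tuple[pd.DataFrame, GcReport, np.ndarray]:
    """Re-run the scan with sample dates permuted once, globally.

    One permutation is shared by all genes, preserving inter-gene
    correlation; the permuted scan feeds QQ diagnostics against the
    observed scan. Returns (table, GC report, permutation used).
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dates))
    table, report = scan(expression, np.asarray(dates, float)[perm])
    return table, report, perm
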