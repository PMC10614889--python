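"""SNP-based genome-wide selection scan.

Stages, in pipeline order:

1. SNP filtering — drop variants with overall MAF < 0.1 (computed from mean
   dosage/2 on the combined panel), missingness > 90%, or MAF = 0 among the
   ancient samples.
2. Per-SNP selection-coefficient estimation from the dated allele-frequency
   series. The default estimator fits a binomial logistic regression of
   effect-allele counts (each diploid contributes 2 trials; fractional
   dosages enter as fractional successes) on generations before present and
   reports ŝ = exp(−slope) − 1, so positive ŝ means the ALT allele rose
   toward the present. This is a constant-s maximum-likelihood stand-in for
   full time-varying trajectory inference; the interface is pluggable so a
   heavier backend can be substituted.
3. 20-SNP sliding windows advancing by 10 SNPs; the window statistic is the
   root mean square of the converged ŝ values.
4. A two-parameter gamma null (location 0) fitted genome-wide to the window
   RMS values by maximum likelihood; per-window P is the upper tail.
5. Significant windows < 5 Mb apart are merged into peaks and padded with a
   0.1 Mb buffer on each side.

A per-allele OLS of frequency (dosage/2) on date is also provided for
describing individual trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_store import GenotypePanel, Variant

log = logging.getLogger("paleotwas")

WINDOW_SIZE = 20
WINDOW_STEP = 10
_ETA_CLIP = 30.0


@dataclass
class SnpSelectionEstimate:
    variant: Variant
    s_hat: float
    converged: bool


@dataclass
class WindowRecord:
    chrom: str
    start: int       # first SNP position, 1-based closed
    end: int         # last SNP position
    n_snps: int
    rms_s: float
    p: float = np.nan


@dataclass
class AlleleSlope:
    variant: Variant
    slope: float     # allele-frequency change per year
    p: float
    degenerate: bool


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    n_windows: int


# ---------------------------------------------------------------------------
# SNP filters
# ---------------------------------------------------------------------------

def filter_snps(panel: GenotypePanel, maf_min: float = 0.1,
                max_missing: float = 0.9) -> np.ndarray:
    """Indices of variants passing the scan filters.

    Drops variants with combined-panel MAF < ``maf_min``, with a missing
    fraction above ``max_missing``, and variants monomorphic among the
    ancient samples.
    """
    D = panel.dosage
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(D, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    missingness = np.isnan(D).mean(axis=0)

    anc = panel.is_ancient
    if anc.any():
        with np.errstate(invalid="ignore"):
            f_anc = np.nanmean(D[anc], axis=0) / 2.0
        anc_poly = (f_anc > 0) & (f_anc < 1)
    else:
        anc_poly = np.zeros(D.shape[1], bool)

    keep = (maf >= maf_min) & (missingness <= max_missing) & anc_poly
    keep &= ~np.isnan(maf)
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# Selection-coefficient estimation (constant-s binomial logistic MLE)
# ---------------------------------------------------------------------------

def _logistic_irls(Y: np.ndarray, W: np.ndarray, g: np.ndarray,
                   tol: float = 1e-8, max_iter: int = 100):
    """Batched 2-parameter binomial logistic regression.

    Y: per-sample success fractions (dosage/2), shape (n, S);
    W: per-sample trial counts (2, or 0 where missing), shape (n, S);
    g: shared regressor (generations before present), shape (n,).
    Returns (intercepts, slopes, converged) over the S series.
    """
    n, S = Y.shape
    a = np.zeros(S)
    # moment start: logit of the overall mean frequency
    with np.errstate(divide="ignore", invalid="ignore"):
        ybar = (Y * W).sum(0) / W.sum(0)
    ybar = np.clip(ybar, 1e-6, 1 - 1e-6)
    a = np.log(ybar / (1 - ybar))
    b = np.zeros(S)
    converged = np.zeros(S, bool)
    active = np.ones(S, bool)

    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.clip(a[None, :] + b[None, :] * g[:, None], -_ETA_CLIP, _ETA_CLIP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = W * mu * (1.0 - mu)          # IRLS weights
        r = W * (Y - mu)                 # score contributions
        # normal equations for X = [1, g]
        s0 = w.sum(0)
        s1 = (w * g[:, None]).sum(0)
        s2 = (w * (g ** 2)[:, None]).sum(0)
        u0 = r.sum(0)
        u1 = (r * g[:, None]).sum(0)
        det = s0 * s2 - s1 * s1
        bad = ~np.isfinite(det) | (det <= 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (s2 * u0 - s1 * u1) / det
            db = (s0 * u1 - s1 * u0) / det
        da = np.where(active & ~bad, da, 0.0)
        db = np.where(active & ~bad, db, 0.0)
        a = a + da
        b = b + db
        step = np.maximum(np.abs(da), np.abs(db))
        newly = active & ~bad & (step < tol) & np.isfinite(a) & np.isfinite(b)
        converged |= newly
        active &= ~newly & ~bad & np.isfinite(a) & np.isfinite(b)

    return a, b, converged


def estimate_s_batch(dosages: np.ndarray, dates_bp: np.ndarray,
                     gen_time: float = 28.0, tol: float = 1e-8,
                     max_iter: int = 100):
    """Vectorized constant-s estimates for many SNPs sharing one design.

    ``dosages``: samples × SNPs ALT dosages (NaN = missing).
    Returns (s_hat, converged) arrays; ŝ = exp(−slope per generation) − 1.
    """
    dosages = np.asarray(dosages, float)
    if dosages.ndim == 1:
        dosages = dosages[:, None]
    g = np.asarray(dates_bp, float) / gen_time
    missing = np.isnan(dosages)
    W = np.where(missing, 0.0, 2.0)
    Y = np.where(missing, 0.0, dosages / 2.0)
    _, b, converged = _logistic_irls(Y, W, g, tol=tol, max_iter=max_iter)
    with np.errstate(over="ignore"):
        s_hat = np.expm1(-b)
    ok = converged & np.isfinite(s_hat) & (np.abs(s_hat) < 1)
    s_hat = np.where(np.isfinite(s_hat), s_hat, 0.0)
    return s_hat, ok


def estimate_s(dosages: np.ndarray, dates_bp: np.ndarray, variant: Variant | None = None,
               gen_time: float = 28.0, **kw) -> SnpSelectionEstimate:
    """Single-SNP wrapper around :func:`estimate_s_batch`.

    Requires ≥2 distinct dates with data and a polymorphic allele; a
    monomorphic series returns ŝ = 0, unconverged (excluded downstream).
    """
    dosages = np.asarray(dosages, float)
    present = ~np.isnan(dosages)
    if np.unique(np.asarray(dates_bp, float)[present]).size < 2:
        raise ValueError("need data at >= 2 distinct dates")
    mean = dosages[present].mean()
    if mean == 0.0 or mean == 2.0:
        return SnpSelectionEstimate(variant, 0.0, False)
    s, ok = estimate_s_batch(dosages[:, None], dates_bp, gen_time=gen_time, **kw)
    return SnpSelectionEstimate(variant, float(s[0]), bool(ok[0]))


# ---------------------------------------------------------------------------
# Windows, gamma null, peaks
# ---------------------------------------------------------------------------

def window_rms(chrom: str, positions: np.ndarray, s_hat: np.ndarray,
               size: int = WINDOW_SIZE, step: int = WINDOW_STEP) -> list[WindowRecord]:
    """RMS of ŝ in sliding windows of ``size`` SNPs advancing by ``step``.

    SNPs must already be position-sorted converged estimates on one
    chromosome; a trailing remainder shorter than ``size`` is discarded.
    """
    positions = np.asarray(positions)
    s_hat = np.asarray(s_hat, float)
    n = s_hat.size
    if n < size:
        log.warning("chromosome %s: %d SNPs < window size %d — no windows", chrom, n, size)
        return []
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    records = []
    for i in range(0, n - size + 1, step):
        block = s_hat[i:i + size]
        records.append(WindowRecord(
            chrom=chrom,
            start=int(positions[i]),
            end=int(positions[i + size - 1]),
            n_snps=size,
            rms_s=float(np.sqrt(np.mean(block ** 2))),
        ))
    return records


def gamma_pvalues(rms: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Upper-tail P-values from a genome-wide gamma null (location 0).

    The two-parameter gamma is fitted by ML to the strictly positive RMS
    values; zero-RMS windows get P = 1. All-equal inputs are degenerate
    and fatal. Returns (p, (shape, scale)).
    """
    rms = np.asarray(rms, float)
    if rms.size < 30:
        log.warning("gamma null fitted on only %d windows", rms.size)
    if np.any(rms < 0):
        raise ValueError("RMS values must be non-negative")
    if rms.size and np.ptp(rms) == 0:
        raise ValueError("all window RMS values identical: gamma null undefined")
    pos = rms[rms > 0]
    shape, _, scale = stats.gamma.fit(pos, floc=0)
    p = np.ones_like(rms)
    p[rms > 0] = stats.gamma.sf(rms[rms > 0], shape, loc=0, scale=scale)
    return np.clip(p, np.finfo(float).tiny, 1.0), (float(shape), float(scale))


def allele_slope(dosages: np.ndarray, dates_bp: np.ndarray,
                 variant: Variant | None = None) -> AlleleSlope:
    """OLS of allele frequency (dosage/2) on date, per year."""
    dosages = np.asarray(dosages, float)
    dates = np.asarray(dates_bp, float)
    present = ~np.isnan(dosages)
    y = dosages[present] / 2.0
    t = dates[present]
    if y.size < 3:
        raise ValueError("need at least 3 samples with data")
    if np.ptp(y) == 0:
        return AlleleSlope(variant, 0.0, 1.0, True)
    res = stats.linregress(t, y)
    return AlleleSlope(variant, float(res.slope), float(res.pvalue), False)


def merge_peaks(windows: list[WindowRecord], gap: float = 5e6,
                buffer: float = 1e5) -> list[Peak]:
    """Merge significant windows < ``gap`` bp apart; pad peaks by ``buffer``.

    Windows must be significant ones only; they are grouped per chromosome,
    consecutive windows whose inter-window distance is below ``gap`` are
    merged, and each resulting peak is extended by ``buffer`` bp on both
    sides (floored at position 1).
    """
    peaks: list[Peak] = []
    by_chrom: dict[str, list[WindowRecord]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: (w.start, w.end))
        cur_start, cur_end, n = ws[0].start, ws[0].end, 1
        for w in ws[1:]:
            if w.start - cur_end < gap:
                cur_end = max(cur_end, w.end)
                n += 1
            else:
                peaks.append(Peak(chrom, max(1, int(cur_start - buffer)),
                                  int(cur_end + buffer), n))
                cur_start, cur_end, n = w.start, w.end, 1
        peaks.append(Peak(chrom, max(1, int(cur_start - buffer)),
                          int(cur_end + buffer), n))
    return peaks
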