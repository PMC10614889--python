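"""Gene-level aggregation of SNP-level selection statistics (SDS / iHS).

Per-SNP scores are first aligned to each weight entry's effect allele: a
score polarized to the other allele of the pair is negated, and a score
whose allele pair cannot be matched leaves the SNP unscored. The gene-level
statistic is then

    score_gene = Σ_i β_i S_i / sqrt(Σ_i β_i²)

with both sums over the scored SNPs only, so the statistic stays a
calibrated z-score under missingness. Genes with scores for fewer than half
of their model SNPs are removed (exactly half is retained). Two-sided
normal P-values, genomic control, and BH q-values follow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_store import SnpScoreTable, WeightEntry, WeightModel
from .scan_time import GcReport, bh_fdr, genomic_control

log = logging.getLogger("paleotwas")


@dataclass
class GeneScoreRecord:
    gene_id: str
    statistic_name: str
    score: float
    n_snps_model: int
    n_snps_scored: int
    p: float = np.nan
    p_gc: float = np.nan
    q: float = np.nan


def align_score(entry: WeightEntry, score: float, polarized_allele: str,
                score_ref: str, score_alt: str) -> Optional[float]:
    """Express a per-SNP score relative to the entry's effect allele.

    The score table's allele pair may be in swapped orientation relative to
    the weight model; any other mismatch leaves the SNP unscored (None).
    """
    ev = entry.variant
    if {score_ref, score_alt} != {ev.ref, ev.alt}:
        return None
    if polarized_allele not in (score_ref, score_alt):
        return None
    return score if polarized_allele == entry.effect_allele else -score


def gene_score(model: WeightModel, scores: SnpScoreTable,
               statistic_name: str = "SDS",
               min_score_fraction: float = 0.5) -> Optional[GeneScoreRecord]:
    """Weight-aligned, re-normalized gene-level statistic.

    Returns None when fewer than ``min_score_fraction`` of the model's
    SNPs have scores (the gene is removed); exactly the fraction is
    retained.
    """
    aligned: list[tuple[float, float]] = []  # (beta, aligned score)
    for entry in model.entries:
        rec = scores.get(entry.variant.key)
        if rec is None:
            continue
        s = align_score(entry, rec.score, rec.polarized_allele,
                        rec.variant.ref, rec.variant.alt)
        if s is None:
            continue
        aligned.append((entry.weight, s))

    n_model = model.n_snps
    n_scored = len(aligned)
    if n_scored < n_model * min_score_fraction:
        return None
    beta = np.array([b for b, _ in aligned])
    s = np.array([x for _, x in aligned])
    value = float(beta @ s / math.sqrt(float(beta @ beta)))
    return GeneScoreRecord(model.gene_id, statistic_name, value, n_model, n_scored)


def score_pvalues(records: Sequence[GeneScoreRecord]) -> tuple[pd.DataFrame, GcReport]:
    """Two-sided N(0,1) P-values, genomic control, BH q-values."""
    scores = np.array([r.score for r in records], float)
    p = np.clip(2.0 * stats.norm.sf(np.abs(scores)), np.finfo(float).tiny, 1.0)
    report, p_gc = genomic_control(p)
    q = bh_fdr(p_gc)
    for r, pi, pg, qi in zip(records, p, p_gc, q):
        r.p, r.p_gc, r.q = float(pi), float(pg), float(qi)
    df = pd.DataFrame({
        "gene_id": [r.gene_id for r in records],
        "statistic": [r.statistic_name for r in records],
        "score": scores,
        "n_model": [r.n_snps_model for r in records],
        "n_scored": [r.n_snps_scored for r in records],
        "p": p,
        "p_gc": p_gc,
        "q": q,
    }).set_index("gene_id")
    return df, report


def direction_concordance(twss: pd.DataFrame, scores: pd.DataFrame,
                          fdr: float = 0.05,
                          orient_beta_to_present: bool = True) -> dict:
    """Compare signs of TWSS slopes and gene-level scores.

    TWSS betas are per year BP (positive = higher expression in the past);
    with ``orient_beta_to_present`` they are negated so positive means
    rising toward the present, matching the polarity of SDS-like scores.
    Sign agreement is counted on TWSS-significant genes (q < ``fdr``);
    Spearman ρ is computed over all shared genes.
    """
    shared = twss.index.intersection(scores.index)
    if len(shared) == 0:
        return {"n_same_sign": 0, "n_compared": 0, "rho": np.nan, "rho_p": np.nan}
    beta = twss.loc[shared, "beta"].to_numpy(float)
    if orient_beta_to_present:
        beta = -beta
    sc = scores.loc[shared, "score"].to_numpy(float)

    sig = twss.loc[shared, "q"].to_numpy(float) < fdr
    n_compared = int(sig.sum())
    n_same = int((np.sign(beta[sig]) == np.sign(sc[sig])).sum())
    rho, rho_p = stats.spearmanr(beta, sc)
    return {"n_same_sign": n_same, "n_compared": n_compared,
            "rho": float(rho), "rho_p": float(rho_p)}
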