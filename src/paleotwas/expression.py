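"""Predicted expression and gene-level imputation quality.

A gene's predicted normalized expression for sample *j* is the linear score
``Σ_i β_i d_ij`` over harmonized effect-allele dosages, the standard
TWAS/JTI convention. Each gene also gets an imputation-quality score

    R²_gene = Σ_i |β_i| R²_i / Σ_i |β_i|

— a |β|-weighted average of the per-SNP imputation R² values — and the 20%
of genes with the lowest R²_gene are removed before any scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_store import GenotypePanel, WeightModel, harmonize_dosage

log = logging.getLogger("paleotwas")


@dataclass
class GeneQuality:
    gene_id: str
    r2_gene: float
    n_snps_used: int


@dataclass
class GenePrediction:
    """Per-sample predicted expression for one gene, with bookkeeping."""

    gene_id: str
    tissue: str
    values: np.ndarray  # one value per panel sample
    n_snps_model: int
    n_snps_used: int    # model SNPs found in the panel after harmonization


def predict_expression(model: WeightModel, panel: GenotypePanel) -> Optional[GenePrediction]:
    """Linear score of harmonized dosages; None when no model SNP overlaps
    the panel (the gene is unmodeled and excluded downstream).

    Missing dosages are mean-imputed per variant at prediction time; model
    SNPs absent from the panel shrink the model with a logged count.
    """
    index = panel.variant_index
    values = np.zeros(len(panel.samples))
    n_used = 0
    for entry in model.entries:
        col = index.get(entry.variant.key)
        if col is None:
            continue
        dosage = harmonize_dosage(entry, panel.variants[col], panel.dosage[:, col])
        if dosage is None:
            continue
        dosage = np.asarray(dosage, dtype=float)
        missing = np.isnan(dosage)
        if missing.all():
            continue
        if missing.any():
            dosage = np.where(missing, dosage[~missing].mean(), dosage)
        values += entry.weight * dosage
        n_used += 1
    if n_used == 0:
        log.warning("gene %s: no model SNPs in panel — unmodeled", model.gene_id)
        return None
    if n_used < model.n_snps:
        log.debug("gene %s: %d of %d model SNPs in panel",
                  model.gene_id, n_used, model.n_snps)
    return GenePrediction(model.gene_id, model.tissue, values, model.n_snps, n_used)


def predict_many(models: Sequence[WeightModel], panel: GenotypePanel) -> pd.DataFrame:
    """Expression matrix (genes × samples) for all modeled genes."""
    rows, genes = [], []
    for model in models:
        pred = predict_expression(model, panel)
        if pred is None:
            continue
        rows.append(pred.values)
        genes.append(pred.gene_id)
    sample_ids = [s.sample_id for s in panel.samples]
    return pd.DataFrame(np.array(rows) if rows else np.empty((0, len(sample_ids))),
                        index=genes, columns=sample_ids)


def gene_quality(model: WeightModel, panel: GenotypePanel) -> Optional[GeneQuality]:
    """R²_gene = Σ|β_i| R²_i / Σ|β_i| over model SNPs whose panel variant
    carries an imputation R²; None when no such SNP exists (the gene is
    then excluded by the quality filter)."""
    index = panel.variant_index
    num = den = 0.0
    n_used = 0
    for entry in model.entries:
        col = index.get(entry.variant.key)
        if col is None:
            continue
        r2 = panel.variants[col].imputation_r2
        if r2 is None:
            continue
        w = abs(entry.weight)
        num += w * r2
        den += w
        n_used += 1
    if n_used == 0:
        return None
    return GeneQuality(model.gene_id, num / den, n_used)


def filter_low_quality(qualities: Sequence[GeneQuality], fraction: float = 0.20) -> set[str]:
    """Drop the ⌊fraction·N⌋ genes with the smallest R²_gene.

    Ties at the cutoff are broken by gene_id ascending (smallest ids
    dropped first) so the retained set is deterministic.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must be in [0,1), got {fraction}")
    n_drop = int(np.floor(fraction * len(qualities)))
    ranked = sorted(qualities, key=lambda q: (q.r2_gene, q.gene_id))
    return {q.gene_id for q in ranked[n_drop:]}
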