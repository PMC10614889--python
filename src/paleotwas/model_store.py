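"""Readers, validators and harmonization for the pipeline's external tables.

Three kinds of inputs are consumed:

* eQTL weight models — per gene×tissue linear predictors of normalized
  expression (flat TSV dialect; columns ``gene_id tissue chrom pos ref alt
  effect_allele weight training_r2``),
* diploid genotypes — VCF with FORMAT/DS dosages (or GT fallback) plus
  per-variant imputation quality in INFO/R2 or INFO/DR2, paired with a
  sample-metadata TSV giving each sample's date in years before present,
* per-SNP selection-score tables (SDS or normalized iHS) with the allele
  each score is polarized to.

Everything is harmonized onto the VCF's ALT-dosage convention; weight
entries whose allele pair is swapped relative to the panel are re-oriented,
and strand-ambiguous (A/T, C/G) swapped pairs are dropped as unresolvable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("paleotwas")

WEIGHT_DB_COLUMNS = [
    "gene_id", "tissue", "chrom", "pos", "ref", "alt",
    "effect_allele", "weight", "training_r2",
]

SCORE_TABLE_COLUMNS = ["chrom", "pos", "ref", "alt", "polarized_allele", "score"]

#: allele pairs that are their own reverse complement; a swapped orientation
#: cannot be distinguished from a strand flip, so such entries are dropped.
STRAND_AMBIGUOUS_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})


class FormatError(ValueError):
    """A file does not conform to its declared dialect (missing columns...)."""


class ValidationError(ValueError):
    """A row violates a domain invariant (bad allele, zero weight...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A biallelic site; ``imputation_r2`` is the per-SNP imputation quality."""

    chrom: str
    pos: int
    ref: str
    alt: str
    imputation_r2: Optional[float] = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValidationError(f"non-positive position {self.pos}")
        if self.imputation_r2 is not None and not (0.0 <= self.imputation_r2 <= 1.0):
            raise ValidationError(
                f"imputation_r2 {self.imputation_r2} outside [0,1] at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class WeightEntry:
    """One SNP's contribution to a gene's expression model (effect size β)."""

    variant: Variant
    effect_allele: str
    weight: float

    def __post_init__(self):
        if self.effect_allele not in (self.variant.ref, self.variant.alt):
            raise ValidationError(
                f"effect allele {self.effect_allele} not in "
                f"{{{self.variant.ref},{self.variant.alt}}} at "
                f"{self.variant.chrom}:{self.variant.pos}"
            )
        if not np.isfinite(self.weight) or self.weight == 0.0:
            raise ValidationError(
                f"weight must be finite and nonzero at {self.variant.chrom}:{self.variant.pos}"
            )


@dataclass
class WeightModel:
    """A gene's eQTL prediction model in one tissue."""

    gene_id: str
    tissue: str
    training_r2: float
    entries: list[WeightEntry] = field(default_factory=list)

    def __post_init__(self):
        if not self.entries:
            raise ValidationError(f"{self.gene_id}/{self.tissue}: model has no entries")
        if not (0.0 <= self.training_r2 <= 1.0):
            raise ValidationError(
                f"{self.gene_id}/{self.tissue}: training_r2 {self.training_r2} outside [0,1]"
            )
        keys = [e.variant.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValidationError(f"{self.gene_id}/{self.tissue}: duplicate variant keys")

    @property
    def n_snps(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    date_bp: float  # years before present; 0 for modern samples

    def __post_init__(self):
        if self.date_bp < 0:
            raise ValidationError(f"{self.sample_id}: negative date_bp")

    @property
    def cohort(self) -> str:
        return "ancient" if self.date_bp > 0 else "modern"


@dataclass
class GenotypePanel:
    """Sample × variant ALT-dosage matrix (NaN = missing) with metadata."""

    samples: list[SampleMeta]
    variants: list[Variant]
    dosage: np.ndarray  # shape (n_samples, n_variants), values in [0,2] or NaN

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        present = self.dosage[~np.isnan(self.dosage)]
        if present.size and (present.min() < 0 or present.max() > 2):
            raise ValidationError("dosage values outside [0,2]")

    @property
    def dates(self) -> np.ndarray:
        return np.array([s.date_bp for s in self.samples], dtype=float)

    @property
    def is_ancient(self) -> np.ndarray:
        return self.dates > 0

    @property
    def variant_index(self) -> dict:
        return {v.key: i for i, v in enumerate(self.variants)}


@dataclass(frozen=True)
class ScoreRecord:
    variant: Variant
    score: float
    polarized_allele: str

    def __post_init__(self):
        if self.polarized_allele not in (self.variant.ref, self.variant.alt):
            raise ValidationError(
                f"polarized allele {self.polarized_allele} not in "
                f"{{{self.variant.ref},{self.variant.alt}}} at "
                f"{self.variant.chrom}:{self.variant.pos}"
            )
        if not np.isfinite(self.score):
            raise ValidationError(f"non-finite score at {self.variant.chrom}:{self.variant.pos}")


class SnpScoreTable:
    """Per-SNP selection scores (pre-normalized; nominally N(0,1) under the null)."""

    def __init__(self, records: Iterable[ScoreRecord]):
        self.records = list(records)
        self._by_key = {r.variant.key: r for r in self.records}

    def get(self, key: tuple) -> Optional[ScoreRecord]:
        return self._by_key.get(key)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Weight DB I/O
# ---------------------------------------------------------------------------

def read_weight_db(path) -> dict[str, list[WeightModel]]:
    """Read a flat-TSV weight database into models grouped by gene.

    Returns ``{gene_id: [WeightModel per tissue, ...]}``. Malformed rows
    raise with the offending row number; a missing column is a FormatError.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in WEIGHT_DB_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    models: dict[str, list[WeightModel]] = {}
    for (gene_id, tissue), grp in df.groupby(["gene_id", "tissue"], sort=True):
        entries = []
        r2_values = grp["training_r2"].unique()
        if len(r2_values) != 1:
            raise ValidationError(f"{gene_id}/{tissue}: inconsistent training_r2 values")
        for row in grp.itertuples():
            try:
                variant = Variant(str(row.chrom), int(row.pos), row.ref, row.alt)
                entries.append(WeightEntry(variant, row.effect_allele, float(row.weight)))
            except ValidationError as exc:
                raise ValidationError(
                    f"{path} row {row.Index + 2}: gene {gene_id}: {exc}"
                ) from exc
        model = WeightModel(str(gene_id), str(tissue), float(r2_values[0]), entries)
        models.setdefault(str(gene_id), []).append(model)
    return models


def write_weight_db(models: Mapping[str, Sequence[WeightModel]], path) -> None:
    """Inverse of :func:`read_weight_db` (row order: gene, tissue, entry order)."""
    rows = []
    for gene_id in sorted(models):
        for model in models[gene_id]:
            for e in model.entries:
                rows.append({
                    "gene_id": model.gene_id,
                    "tissue": model.tissue,
                    "chrom": e.variant.chrom,
                    "pos": e.variant.pos,
                    "ref": e.variant.ref,
                    "alt": e.variant.alt,
                    "effect_allele": e.effect_allele,
                    "weight": e.weight,
                    "training_r2": model.training_r2,
                })
    pd.DataFrame(rows, columns=WEIGHT_DB_COLUMNS).to_csv(path, sep="\t", index=False)


def select_best_tissue(models: Sequence[WeightModel]) -> WeightModel:
    """Pick the tissue with highest training R²; ties go to the
    lexicographically smallest tissue name."""
    if not models:
        raise ValueError("select_best_tissue: no models given")
    return min(models, key=lambda m: (-m.training_r2, m.tissue))


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def harmonize_dosage(entry: WeightEntry, variant: Variant,
                     dosage_alt: np.ndarray | float):
    """Convert panel ALT dosage to effect-allele dosage for a weight entry.

    Handles ref/alt orientation swaps between the weight DB and the panel.
    Returns None (entry must be dropped) when the allele pairs do not match
    or when a swapped orientation is strand-ambiguous (A/T or C/G).
    """
    ev, pv = entry.variant, variant
    if (ev.ref, ev.alt) == (pv.ref, pv.alt):
        swapped = False
    elif (ev.ref, ev.alt) == (pv.alt, pv.ref):
        if frozenset({ev.ref, ev.alt}) in STRAND_AMBIGUOUS_PAIRS:
            log.warning(
                "dropping strand-ambiguous swapped variant %s:%d (%s/%s)",
                pv.chrom, pv.pos, pv.ref, pv.alt,
            )
            return None
        swapped = True
    else:
        log.warning(
            "allele mismatch at %s:%d: model %s/%s vs panel %s/%s — dropped",
            pv.chrom, pv.pos, ev.ref, ev.alt, pv.ref, pv.alt,
        )
        return None

    # effect allele expressed in the panel's orientation
    effect_is_panel_alt = (entry.effect_allele == ev.alt) != swapped
    if effect_is_panel_alt:
        return dosage_alt
    return 2.0 - np.asarray(dosage_alt) if isinstance(dosage_alt, np.ndarray) else 2.0 - dosage_alt


# ---------------------------------------------------------------------------
# Genotype + metadata readers
# ---------------------------------------------------------------------------

def read_sample_metadata(path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "date_bp"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    return {
        str(r.sample_id): SampleMeta(str(r.sample_id), float(r.date_bp))
        for r in df.itertuples()
    }


def read_genotypes(vcf_path, metadata_path, on_multiallelic: str = "drop") -> GenotypePanel:
    """Load a VCF + metadata TSV into a :class:`GenotypePanel`.

    Dosage comes from FORMAT/DS when present, otherwise from the GT
    ALT-allele count; imputation quality from INFO/R2 or INFO/DR2.
    Every VCF sample must appear in the metadata. Multiallelic records
    are dropped with a warning (``on_multiallelic="drop"``) or raise
    (``"error"``); non-diploid GT records are skipped with a warning.
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("drop", "error"):
        raise ValueError(f"on_multiallelic must be 'drop' or 'error', got {on_multiallelic!r}")

    meta = read_sample_metadata(metadata_path)
    vcf = VCF(str(vcf_path))
    missing_meta = [s for s in vcf.samples if s not in meta]
    if len(missing_meta) == len(vcf.samples):
        raise FormatError(f"{vcf_path}: no overlap between VCF samples and metadata")
    if missing_meta:
        raise FormatError(f"{vcf_path}: samples missing from metadata: {missing_meta[:5]}")

    samples = [meta[s] for s in vcf.samples]
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if on_multiallelic == "error":
                raise ValidationError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
            log.warning("dropping multiallelic record at %s:%d", rec.CHROM, rec.POS)
            continue
        ds = rec.format("DS")
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            dos = np.where((dos < 0) | (dos > 2), np.nan, dos)
        else:
            gts = np.asarray(rec.genotypes, dtype=float)
            if gts.shape[1] - 1 != 2:  # last column is the phasing flag
                log.warning("skipping non-diploid record at %s:%d", rec.CHROM, rec.POS)
                continue
            alleles = gts[:, :2]
            alleles[alleles < 0] = np.nan
            dos = alleles.sum(axis=1)
        r2 = rec.INFO.get("R2")
        if r2 is None:
            r2 = rec.INFO.get("DR2")
        variants.append(Variant(rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                                float(r2) if r2 is not None else None))
        columns.append(dos)

    dosage = (np.column_stack(columns) if columns
              else np.empty((len(samples), 0)))
    return GenotypePanel(samples, variants, dosage)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def score_table_from_frame(df: pd.DataFrame, source: str = "<frame>") -> SnpScoreTable:
    missing = [c for c in SCORE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    records = []
    for row in df.itertuples():
        variant = Variant(str(row.chrom), int(row.pos), row.ref, row.alt)
        records.append(ScoreRecord(variant, float(row.score), row.polarized_allele))
    return SnpScoreTable(records)


def read_score_table(path) -> SnpScoreTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return score_table_from_frame(df, source=str(path))
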