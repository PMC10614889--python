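"""Synthetic inputs with the statistical structure the scans assume.

The generator emulates the study design end-to-end: biallelic allele
frequencies evolve under a Wright–Fisher model with genic selection
(deterministic update p* = p(1+s)/(1+ps), then binomial resampling of 2Ne
gametes, absorbing at 0 and 1); dated diploid samples draw genotypes from
Hardy–Weinberg proportions at the generation nearest their date; ancient
reads follow a Poisson-coverage binomial model with a 1% sequencing error
rate and an extra 5% deamination flip at damage-prone (C/T, G/A) sites;
weight models mimic published cis-eQTL predictors (median 12 SNPs per
gene, several tissues with distinct training R²); per-variant imputation
R² is Beta-distributed; and score tables are standard normal under the
null with a configurable mean shift on selected variants, polarized to the
simulated favored allele.

SNPs are simulated independently (no linkage); dosages default to exact
genotypes so downstream truth is unambiguous, with optional jitter to
mimic imputation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model_store import (GenotypePanel, SampleMeta, Variant, WeightEntry,
                          WeightModel, write_weight_db)

_NUCS = np.array(list("ACGT"))
DAMAGE_PRONE_PAIRS = frozenset({frozenset({"C", "T"}), frozenset({"G", "A"})})


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-design parameters for a complete synthetic scenario.

    Defaults emulate the analysis design: Ne = 10^4, a 150-generation
    transect at 28 years/generation (4200 years), 600 dated ancient
    samples plus 90 modern ones, and the 1%/5% error/deamination rates.
    """

    Ne: int = 10_000
    generations: int = 150
    gen_time: float = 28.0
    n_genes: int = 200
    snps_per_gene: int = 12          # Poisson mean (clipped >= 1); median 12
    n_tissues: int = 2
    n_selected: int = 0
    s_selected: float = 0.02         # per-generation coefficient of the favored allele
    score_shift: float = 2.0         # mean score of selected variants
    p0_range: tuple[float, float] = (0.1, 0.9)
    sampling: list[tuple[float, int]] = field(default_factory=list)
    coverage: float = 1.0            # mean reads per site (read-level ops only)
    error: float = 0.01
    deamination: float = 0.05
    weight_sd: float = 0.1
    r2_beta: tuple[float, float] = (8.0, 2.0)
    dosage_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.sampling:
            self.sampling = default_sampling(self.generations * self.gen_time)

    def validate(self) -> None:
        """Raise ValueError listing every violated constraint."""
        span = self.generations * self.gen_time
        problems = []
        if self.Ne <= 0:
            problems.append("Ne must be positive")
        if self.generations <= 0:
            problems.append("generations must be positive")
        if not (0 <= self.error < 1 and 0 <= self.deamination < 1):
            problems.append("error/deamination rates must lie in [0,1)")
        if abs(self.s_selected) >= 1:
            problems.append("|s_selected| must be < 1")
        lo, hi = self.p0_range
        if not (0 < lo <= hi < 1):
            problems.append("p0_range must satisfy 0 < lo <= hi < 1")
        if self.n_selected > self.n_genes:
            problems.append("n_selected exceeds n_genes")
        for date, n in self.sampling:
            if not (0 <= date <= span):
                problems.append(f"sampling date {date} outside simulated span [0, {span}]")
            if n <= 0:
                problems.append(f"non-positive sample count at date {date}")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))


def default_sampling(span_years: float, n_ancient: int = 600,
                     n_modern: int = 90) -> list[tuple[float, int]]:
    """Evenly spaced ancient dates across the transect plus modern samples."""
    dates = np.linspace(span_years / n_ancient, span_years, n_ancient)
    scheme = [(float(d), 1) for d in dates]
    if n_modern:
        scheme.append((0.0, n_modern))
    return scheme


# ---------------------------------------------------------------------------
# Wright–Fisher trajectories
# ---------------------------------------------------------------------------

def simulate_trajectory(p0: float, s: float, Ne: int, generations: int,
                        rng=None, deterministic: bool = False) -> np.ndarray:
    """One allele-frequency path of length ``generations + 1``."""
    return simulate_trajectories(
        np.array([p0]), np.array([s]), Ne, generations,
        rng=rng, deterministic=deterministic)[:, 0]


def simulate_trajectories(p0: np.ndarray, s: np.ndarray, Ne: int,
                          generations: int, rng=None,
                          deterministic: bool = False) -> np.ndarray:
    """Independent Wright–Fisher paths, shape (generations+1, n_snps).

    Each generation applies the genic-selection update
    p* = p(1+s)/(1+ps), then (unless ``deterministic``) binomial sampling
    of 2Ne gametes. Frequencies absorb at 0 and 1.
    """
    p0 = np.asarray(p0, float)
    s = np.broadcast_to(np.asarray(s, float), p0.shape)
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("p0 must lie strictly in (0,1)")
    if not deterministic and rng is None:
        raise ValueError("stochastic simulation needs an rng")
    path = np.empty((generations + 1, p0.size))
    p = p0.copy()
    path[0] = p
    for g in range(1, generations + 1):
        pstar = p * (1 + s) / (1 + p * s)
        if deterministic:
            p = pstar
        else:
            p = rng.binomial(2 * Ne, pstar) / (2 * Ne)
        path[g] = p
    return path


# ---------------------------------------------------------------------------
# Sampling dated diploids
# ---------------------------------------------------------------------------

def generation_of_date(date_bp: float, generations: int, gen_time: float) -> int:
    """Nearest simulated generation for a date (generation ``generations``
    is the present)."""
    g = generations - int(round(date_bp / gen_time))
    if not (0 <= g <= generations):
        raise ValueError(f"date {date_bp} y BP outside simulated span")
    return g


def sample_panel(freqs: np.ndarray, variants: list[Variant],
                 sampling: list[tuple[float, int]], gen_time: float,
                 rng, dosage_jitter: float = 0.0) -> tuple[GenotypePanel, np.ndarray]:
    """Draw dated diploid samples from HWE at each date's generation.

    ``freqs`` is (generations+1, n_variants) of ALT frequencies. Returns
    the panel (dosage = genotype, optionally jittered) and the true
    genotype matrix.
    """
    generations = freqs.shape[0] - 1
    dates, gens = [], []
    for date, n in sampling:
        g = generation_of_date(date, generations, gen_time)
        dates.extend([date] * n)
        gens.extend([g] * n)
    gens = np.asarray(gens)
    p = freqs[gens, :]                       # (n_samples, n_variants)
    genotypes = rng.binomial(2, p)
    dosage = genotypes.astype(float)
    if dosage_jitter > 0:
        dosage = np.clip(dosage + rng.normal(0, dosage_jitter, dosage.shape), 0, 2)
    samples = [SampleMeta(f"S{i:05d}", float(d)) for i, d in enumerate(dates)]
    return GenotypePanel(samples, variants, dosage), genotypes


# ---------------------------------------------------------------------------
# Read counts and genotype likelihoods
# ---------------------------------------------------------------------------

def is_damage_prone(ref: str, alt: str) -> bool:
    """C/T and G/A allele pairs pick up deamination flips."""
    return frozenset({ref, alt}) in DAMAGE_PRONE_PAIRS


def _flip_rate(damage_prone: bool, error: float, deamination: float) -> float:
    if damage_prone:
        return 1.0 - (1.0 - error) * (1.0 - deamination)
    return error


def simulate_reads(alt_count: int, coverage: float, damage_prone: bool,
                   error: float = 0.01, deamination: float = 0.05,
                   rng=None) -> tuple[int, int]:
    """(n_ref, n_alt) for one sample×site: Poisson total, per-read ALT
    probability (a/2)(1−ε) + (1−a/2)ε with ε the site-class flip rate."""
    if rng is None:
        raise ValueError("simulate_reads needs an rng")
    eps = _flip_rate(damage_prone, error, deamination)
    n = rng.poisson(coverage)
    p_alt = (alt_count / 2) * (1 - eps) + (1 - alt_count / 2) * eps
    n_alt = rng.binomial(n, p_alt) if n else 0
    return int(n - n_alt), int(n_alt)


def genotype_likelihood(n_ref: int, n_alt: int, damage_prone: bool,
                        error: float = 0.01, deamination: float = 0.05) -> np.ndarray:
    """Normalized binomial read-count likelihoods over ALT count a ∈ {0,1,2}.

    Zero reads give the uninformative (1/3, 1/3, 1/3).
    """
    n = n_ref + n_alt
    if n == 0:
        return np.full(3, 1.0 / 3.0)
    eps = _flip_rate(damage_prone, error, deamination)
    a = np.array([0.0, 1.0, 2.0])
    p_alt = (a / 2) * (1 - eps) + (1 - a / 2) * eps
    lik = stats.binom.pmf(n_alt, n, p_alt)
    return lik / lik.sum()


# ---------------------------------------------------------------------------
# Weight models, score tables, full scenarios
# ---------------------------------------------------------------------------

def _draw_allele_pair(rng) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_NUCS[ref]), str(_NUCS[alt])


def _make_weight_models(n_genes: int, snps_per_gene: int, n_tissues: int,
                        weight_sd: float, rng) -> dict[str, list[WeightModel]]:
    """Gene models on chromosome 1; a gene's tissues share SNPs but have
    tissue-specific weights and training R²."""
    models: dict[str, list[WeightModel]] = {}
    for i in range(n_genes):
        gene_id = f"G{i:05d}"
        n_snps = max(1, int(rng.poisson(snps_per_gene)))
        base = 1 + i * 100_000
        variants = []
        for j in range(n_snps):
            ref, alt = _draw_allele_pair(rng)
            variants.append(Variant("1", base + j * 1_000, ref, alt))
        r2s = np.sort(rng.uniform(0.05, 0.6, size=n_tissues))[::-1]
        tissue_models = []
        for k in range(n_tissues):
            entries = []
            for v in variants:
                w = 0.0
                while w == 0.0:
                    w = rng.normal(0.0, weight_sd)
                effect = v.alt if rng.random() < 0.5 else v.ref
                entries.append(WeightEntry(v, effect, float(w)))
            tissue_models.append(
                WeightModel(gene_id, f"tissue{k}", float(r2s[k]), entries))
        models[gene_id] = tissue_models
    return models


def make_weight_db(path, n_genes: int = 200, snps_per_gene: int = 12,
                   n_tissues: int = 2, weight_sd: float = 0.1,
                   seed: int = 0) -> dict[str, list[WeightModel]]:
    """Write a synthetic weight DB TSV; returns the models by gene."""
    rng = np.random.default_rng(seed)
    models = _make_weight_models(n_genes, snps_per_gene, n_tissues, weight_sd, rng)
    write_weight_db(models, path)
    return models


def make_score_table(variants: list[Variant], favored: dict[tuple, str],
                     shift: float, rng, path=None) -> pd.DataFrame:
    """Per-SNP score table: null variants are N(0,1) with random
    polarization; selected variants (keys of ``favored``) are
    N(shift, 1) polarized to the simulated favored allele."""
    rows = []
    for v in variants:
        if v.key in favored:
            pol = favored[v.key]
            score = rng.normal(shift, 1.0)
        else:
            pol = v.alt if rng.random() < 0.5 else v.ref
            score = rng.normal(0.0, 1.0)
        rows.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                     "polarized_allele": pol, "score": score})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def write_vcf(panel: GenotypePanel, genotypes: np.ndarray, path) -> None:
    """Emit a minimal VCF v4.2 with GT + DS and INFO/R2 per variant."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({v.chrom for v in panel.variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation accuracy">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(s.sample_id for s in panel.samples) + "\n")
        order = sorted(range(len(panel.variants)),
                       key=lambda j: (panel.variants[j].chrom, panel.variants[j].pos))
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in order:
            v = panel.variants[j]
            info = f"R2={v.imputation_r2:.4f}" if v.imputation_r2 is not None else "."
            fields = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS",
                      info, "GT:DS"]
            for i in range(len(panel.samples)):
                d = panel.dosage[i, j]
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_strings[int(genotypes[i, j])]}:{d:.4f}")
            fh.write("\t".join(fields) + "\n")


def write_metadata(panel: GenotypePanel, path) -> None:
    pd.DataFrame({
        "sample_id": [s.sample_id for s in panel.samples],
        "date_bp": [s.date_bp for s in panel.samples],
    }).to_csv(path, sep="\t", index=False)


@dataclass
class Scenario:
    """In-memory handles plus the file paths of a generated fixture set."""

    config: SimulationConfig
    models: dict[str, list[WeightModel]]
    panel: GenotypePanel
    truth: pd.DataFrame
    scores: pd.DataFrame
    paths: dict[str, Path]


def make_scenario(config: SimulationConfig, outdir=None) -> Scenario:
    """Generate a complete, self-consistent input set plus truth labels.

    Selected genes alternate direction (expression up/down toward the
    present); within a selected gene, every model SNP's expression-moving
    allele for that direction is favored with ``s_selected``. The
    best-tissue model defines the causal weights. With an ``outdir``,
    emits weight DB, VCF, metadata, score table and ``truth.tsv``;
    without one, everything stays in memory.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    models = _make_weight_models(config.n_genes, config.snps_per_gene,
                                 config.n_tissues, config.weight_sd, rng)
    gene_ids = sorted(models)
    selected = gene_ids[:config.n_selected]
    directions = {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(selected)}

    # causal model per gene = highest-training-R² tissue
    from .model_store import select_best_tissue
    best = {g: select_best_tissue(ms) for g, ms in models.items()}

    variants: list[Variant] = []
    s_alt: list[float] = []
    p0: list[float] = []
    favored: dict[tuple, str] = {}
    truth_rows = []
    for g in gene_ids:
        direction = directions.get(g, 0)
        for entry in best[g].entries:
            v = entry.variant
            if direction != 0:
                raises_expr = entry.effect_allele if entry.weight > 0 else (
                    v.alt if entry.effect_allele == v.ref else v.ref)
                fav = raises_expr if direction > 0 else (
                    v.alt if raises_expr == v.ref else v.ref)
                favored[v.key] = fav
                s = config.s_selected
                s_alt.append(s if fav == v.alt else 1.0 / (1.0 + s) - 1.0)
            else:
                s_alt.append(0.0)
            variants.append(v)
            p0.append(rng.uniform(*config.p0_range))
        truth_rows.append({"gene_id": g, "selected": int(direction != 0),
                           "direction": direction,
                           "s": config.s_selected if direction != 0 else 0.0})

    freqs = simulate_trajectories(np.array(p0), np.array(s_alt), config.Ne,
                                  config.generations, rng=rng)

    # attach per-variant imputation R² before building the panel
    r2 = rng.beta(*config.r2_beta, size=len(variants))
    variants = [Variant(v.chrom, v.pos, v.ref, v.alt, float(r2[j]))
                for j, v in enumerate(variants)]
    # propagate the R²-carrying variants into the weight models' keys domain
    panel, genotypes = sample_panel(freqs, variants, config.sampling,
                                    config.gen_time, rng,
                                    dosage_jitter=config.dosage_jitter)

    scores = make_score_table(variants, favored, config.score_shift, rng)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")

    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "weights": outdir / "weights.tsv",
            "vcf": outdir / "panel.vcf",
            "metadata": outdir / "samples.tsv",
            "scores": outdir / "scores.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_weight_db(models, paths["weights"])
        write_vcf(panel, genotypes, paths["vcf"])
        write_metadata(panel, paths["metadata"])
        scores.to_csv(paths["scores"], sep="\t", index=False)
        truth.to_csv(paths["truth"], sep="\t")
    return Scenario(config, models, panel, truth, scores, paths)
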