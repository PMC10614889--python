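import numpy as np
import pytest

from paleotwas.model_store import (GenotypePanel, SampleMeta, Variant,
                                   WeightEntry, WeightModel)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_variant(pos=100, ref="A", alt="G", r2=None, chrom="1"):
    return Variant(chrom, pos, ref, alt, r2)


def make_model(weights, gene_id="GENE1", tissue="Liver", training_r2=0.3,
               start_pos=100, effect="alt", r2s=None):
    """Tiny weight model; effect allele is ALT for every entry by default."""
    entries = []
    for i, w in enumerate(weights):
        r2 = None if r2s is None else r2s[i]
        v = make_variant(pos=start_pos + i, r2=r2)
        entries.append(WeightEntry(v, v.alt if effect == "alt" else v.ref, w))
    return WeightModel(gene_id, tissue, training_r2, entries)


def make_panel(dosage, dates, start_pos=100, r2s=None, ref="A", alt="G"):
    """Panel whose variants line up with make_model's positions."""
    dosage = np.asarray(dosage, float)
    n_samples, n_variants = dosage.shape
    variants = [
        Variant("1", start_pos + j, ref, alt,
                None if r2s is None else r2s[j])
        for j in range(n_variants)
    ]
    samples = [SampleMeta(f"S{i}", float(d)) for i, d in enumerate(dates)]
    return GenotypePanel(samples, variants, dosage)


@pytest.fixture
def small_scenario(tmp_path):
    from paleotwas.synthetic_data import SimulationConfig, make_scenario
    cfg = SimulationConfig(n_genes=30, n_selected=4, seed=7)
    return make_scenario(cfg, tmp_path / "scenario")
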