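"""Weight-DB, genotype and score-table readers plus allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from paleotwas import model_store as ms

from conftest import make_variant


def write_weight_tsv(path, rows):
    pd.DataFrame(rows, columns=ms.WEIGHT_DB_COLUMNS).to_csv(path, sep="\t", index=False)


def wrow(gene="G1", tissue="Liver", chrom="1", pos=100, ref="A", alt="G",
         effect="G", weight=0.5, r2=0.3):
    return dict(gene_id=gene, tissue=tissue, chrom=chrom, pos=pos, ref=ref,
                alt=alt, effect_allele=effect, weight=weight, training_r2=r2)


class TestWeightDb:
    def test_round_trip_identity(self, tmp_path):
        rows = [wrow(pos=100), wrow(pos=200, ref="C", alt="A", effect="C", weight=-0.2)]
        f = tmp_path / "w.tsv"
        write_weight_tsv(f, rows)
        models = ms.read_weight_db(f)
        assert set(models) == {"G1"}
        assert models["G1"][0].n_snps == 2
        f2 = tmp_path / "w2.tsv"
        ms.write_weight_db(models, f2)
        a = pd.read_csv(f, sep="\t").sort_values(["pos"]).reset_index(drop=True)
        b = pd.read_csv(f2, sep="\t").sort_values(["pos"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)

    def test_three_tissues_give_three_models(self, tmp_path):
        rows = [wrow(tissue=t, r2=r) for t, r in
                [("Liver", 0.1), ("Brain", 0.3), ("Lung", 0.2)]]
        f = tmp_path / "w.tsv"
        write_weight_tsv(f, rows)
        models = ms.read_weight_db(f)
        # independent count: one model per distinct tissue in the raw file
        n_expected = pd.read_csv(f, sep="\t")["tissue"].nunique()
        assert len(models["G1"]) == n_expected == 3

    def test_effect_allele_outside_pair_rejected(self, tmp_path):
        f = tmp_path / "w.tsv"
        write_weight_tsv(f, [wrow(ref="A", alt="T", effect="G")])
        with pytest.raises(ms.ValidationError, match="G1"):
            ms.read_weight_db(f)

    def test_zero_weight_rejected(self, tmp_path):
        f = tmp_path / "w.tsv"
        write_weight_tsv(f, [wrow(weight=0.0)])
        with pytest.raises(ms.ValidationError):
            ms.read_weight_db(f)

    def test_missing_column_is_format_error(self, tmp_path):
        f = tmp_path / "w.tsv"
        pd.DataFrame([{"gene_id": "G1"}]).to_csv(f, sep="\t", index=False)
        with pytest.raises(ms.FormatError, match="missing columns"):
            ms.read_weight_db(f)


class TestSelectBestTissue:
    def _model(self, tissue, r2):
        v = make_variant()
        return ms.WeightModel("G1", tissue, r2, [ms.WeightEntry(v, v.alt, 0.5)])

    def test_single_model_identity(self):
        m = self._model("Liver", 0.4)
        assert ms.select_best_tissue([m]) is m

    def test_max_r2_wins(self):
        models = [self._model(t, r) for t, r in
                  [("A", 0.10), ("B", 0.30), ("C", 0.25)]]
        assert ms.select_best_tissue(models).training_r2 == 0.30

    def test_tie_broken_lexicographically(self):
        models = [self._model("Thyroid", 0.2), self._model("Liver", 0.2)]
        assert ms.select_best_tissue(models).tissue == "Liver"

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ms.select_best_tissue([])


class TestHarmonizeDosage:
    def _entry(self, ref="A", alt="G", effect="G", w=0.5):
        v = make_variant(ref=ref, alt=alt)
        return ms.WeightEntry(v, effect, w)

    def test_effect_alt_passthrough(self):
        e = self._entry(effect="G")
        assert ms.harmonize_dosage(e, e.variant, 1.3) == 1.3

    def test_effect_ref_complements(self):
        e = self._entry(effect="A")
        assert ms.harmonize_dosage(e, e.variant, 0.4) == pytest.approx(1.6)

    def test_swapped_orientation(self):
        # weight DB says A/G with effect G; panel stores G/A, so its ALT
        # dosage counts A and the effect dosage is the complement
        e = self._entry(ref="A", alt="G", effect="G")
        panel_v = make_variant(ref="G", alt="A")
        assert ms.harmonize_dosage(e, panel_v, 0.5) == pytest.approx(1.5)

    def test_strand_ambiguous_swap_dropped(self):
        e = self._entry(ref="A", alt="T", effect="T")
        panel_v = make_variant(ref="T", alt="A")
        assert ms.harmonize_dosage(e, panel_v, 0.5) is None

    def test_allele_mismatch_dropped(self):
        e = self._entry(ref="A", alt="G", effect="G")
        panel_v = make_variant(ref="A", alt="C")
        assert ms.harmonize_dosage(e, panel_v, 0.5) is None

    @settings(deadline=None)
    @given(st_.floats(0, 2), st_.booleans())
    def test_effect_flip_is_involution(self, dosage, swapped):
        ref, alt = ("C", "A") if not swapped else ("A", "C")
        v = make_variant(ref=ref, alt=alt)
        e_alt = ms.WeightEntry(v, alt, 0.5)
        e_ref = ms.WeightEntry(v, ref, 0.5)
        d1 = ms.harmonize_dosage(e_alt, v, dosage)
        d2 = ms.harmonize_dosage(e_ref, v, dosage)
        assert d1 + d2 == pytest.approx(2.0)


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=R2,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def write_vcf(path, body):
    path.write_text(VCF_HEADER + body)


def write_meta(path, ids_dates):
    pd.DataFrame(ids_dates, columns=["sample_id", "date_bp"]).to_csv(
        path, sep="\t", index=False)


class TestReadGenotypes:
    def test_gt_allele_counting(self, tmp_path):
        vcf, meta = tmp_path / "a.vcf", tmp_path / "m.tsv"
        write_vcf(vcf, "1\t100\t.\tA\tG\t.\tPASS\tR2=0.9\tGT\t0/1\t1/1\n")
        write_meta(meta, [("S1", 1000.0), ("S2", 0.0)])
        panel = ms.read_genotypes(vcf, meta)
        assert panel.dosage.tolist() == [[1.0], [2.0]]
        assert panel.variants[0].imputation_r2 == pytest.approx(0.9)
        assert panel.samples[0].cohort == "ancient"
        assert panel.samples[1].cohort == "modern"

    def test_ds_takes_precedence_over_gt(self, tmp_path):
        vcf, meta = tmp_path / "a.vcf", tmp_path / "m.tsv"
        write_vcf(vcf, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DS\t0/1:0.87\t1/1:1.92\n")
        write_meta(meta, [("S1", 1000.0), ("S2", 0.0)])
        panel = ms.read_genotypes(vcf, meta)
        assert panel.dosage[:, 0] == pytest.approx([0.87, 1.92])

    def test_missing_metadata_sample_is_fatal(self, tmp_path):
        vcf, meta = tmp_path / "a.vcf", tmp_path / "m.tsv"
        write_vcf(vcf, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n")
        write_meta(meta, [("S1", 1000.0)])
        with pytest.raises(ms.FormatError, match="missing from metadata"):
            ms.read_genotypes(vcf, meta)

    def test_multiallelic_dropped_or_rejected(self, tmp_path):
        vcf, meta = tmp_path / "a.vcf", tmp_path / "m.tsv"
        write_vcf(vcf, "1\t100\t.\tA\tG,C\t.\tPASS\t.\tGT\t0/1\t1/1\n"
                       "1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\n")
        write_meta(meta, [("S1", 1000.0), ("S2", 0.0)])
        panel = ms.read_genotypes(vcf, meta)
        assert [v.pos for v in panel.variants] == [200]
        with pytest.raises(ms.ValidationError):
            ms.read_genotypes(vcf, meta, on_multiallelic="error")

    def test_missing_gt_is_nan(self, tmp_path):
        vcf, meta = tmp_path / "a.vcf", tmp_path / "m.tsv"
        write_vcf(vcf, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\n")
        write_meta(meta, [("S1", 1000.0), ("S2", 0.0)])
        panel = ms.read_genotypes(vcf, meta)
        assert np.isnan(panel.dosage[0, 0]) and panel.dosage[1, 0] == 1.0


class TestScoreTable:
    def test_read_and_lookup(self, tmp_path):
        f = tmp_path / "s.tsv"
        pd.DataFrame([{"chrom": "1", "pos": 100, "ref": "A", "alt": "G",
                       "polarized_allele": "G", "score": 1.2}]).to_csv(
            f, sep="\t", index=False)
        table = ms.read_score_table(f)
        rec = table.get(("1", 100))
        assert rec.score == pytest.approx(1.2)
        assert table.get(("1", 999)) is None

    def test_bad_polarized_allele_rejected(self, tmp_path):
        f = tmp_path / "s.tsv"
        pd.DataFrame([{"chrom": "1", "pos": 100, "ref": "A", "alt": "G",
                       "polarized_allele": "T", "score": 1.2}]).to_csv(
            f, sep="\t", index=False)
        with pytest.raises(ms.ValidationError):
            ms.read_score_table(f)


class TestInvariants:
    def test_variant_invariants(self):
        with pytest.raises(ms.ValidationError):
            ms.Variant("1", 100, "A", "A")
        with pytest.raises(ms.ValidationError):
            ms.Variant("1", 0, "A", "G")
        with pytest.raises(ms.ValidationError):
            ms.Variant("1", 100, "A", "G", 1.5)

    def test_panel_rejects_out_of_range_dosage(self):
        with pytest.raises(ms.ValidationError):
            ms.GenotypePanel([ms.SampleMeta("S1", 0.0)],
                             [make_variant()], np.array([[2.5]]))

    def test_panel_rejects_shape_mismatch(self):
        with pytest.raises(ms.ValidationError):
            ms.GenotypePanel([ms.SampleMeta("S1", 0.0)],
                             [make_variant()], np.zeros((2, 1)))
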