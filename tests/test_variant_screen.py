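import numpy as np
import pandas as pd
import pytest

from vegwas.regions import VqtlRegion
from vegwas.variant_screen import (
    Annotation,
    VariantRecord,
    classify_segregation,
    hard_filter,
    map_to_genes,
    parse_ann,
    read_gff3_genes,
    select_relevant,
)


def variant(chrom="1", pos=100, ref="A", alt="G", stats=None, terms=("missense_variant",),
            gene_id="G1", depths=None):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        stats=stats or {},
        annotations=[Annotation(terms=list(terms), gene_name=gene_id, gene_id=gene_id,
                                transcript=f"{gene_id}.t1")],
        depths=depths or {"low": (10, 5), "high": (12, 0)},
    )


PASSING = {"QD": 20.0, "FS": 5.0, "MQ": 60.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0}


class TestHardFilter:
    def test_snv_low_qd_rejected(self):
        v = variant(stats={**PASSING, "QD": 1.5})
        retained, rejected, counts = hard_filter([v])
        assert not retained and rejected[0].filter_rule == "QD"
        assert counts == {"QD": 1}

    def test_indel_fs_between_bounds_retained(self):
        v = variant(ref="AT", alt="A", stats={"QD": 20.0, "FS": 100.0, "ReadPosRankSum": 0.0})
        retained, _, _ = hard_filter([v])
        assert len(retained) == 1  # INDEL FS bound is 200

    def test_snv_exact_boundaries_retained(self):
        v = variant(stats={"QD": 2.0, "FS": 60.0, "MQ": 40.0, "MQRankSum": -12.5,
                           "ReadPosRankSum": -8.0})
        retained, _, _ = hard_filter([v])
        assert len(retained) == 1

    def test_absent_stats_never_trigger(self):
        retained, _, _ = hard_filter([variant(stats={})])
        assert len(retained) == 1

    @pytest.mark.parametrize(
        "stats,expected_rule",
        [
            ({"FS": 61.0}, "FS"),
            ({"MQ": 39.9}, "MQ"),
            ({"MQRankSum": -12.6}, "MQRankSum"),
            ({"ReadPosRankSum": -8.1}, "ReadPosRankSum"),
        ],
    )
    def test_each_snv_rule(self, stats, expected_rule):
        _, rejected, _ = hard_filter([variant(stats=stats)])
        assert rejected[0].filter_rule == expected_rule

    def test_indel_rules(self):
        bad = variant(ref="ATT", alt="A", stats={"FS": 250.0})
        _, rejected, _ = hard_filter([bad])
        assert rejected[0].filter_rule == "FS"


REGION = VqtlRegion("1", 1_000, 100_000, [], "x")


class TestSelectRelevant:
    def test_synonymous_counted_not_relevant(self):
        v = variant(pos=5_000, terms=("synonymous_variant",))
        relevant, table = select_relevant([v], [REGION])
        assert relevant == []
        assert table.loc["synonymous"].iloc[0] == 1

    def test_missense_outside_region_excluded(self):
        v = variant(pos=500_000)
        relevant, table = select_relevant([v], [REGION])
        assert relevant == []
        assert table["total"].sum() == 0

    def test_constructed_counts(self):
        vs = (
            [variant(pos=2_000 + i, terms=("missense_variant",)) for i in range(5)]
            + [variant(pos=3_000 + i, terms=("3_prime_UTR_variant",)) for i in range(3)]
            + [variant(pos=4_000 + i, terms=("intron_variant",)) for i in range(2)]
        )
        relevant, table = select_relevant(vs, [REGION])
        assert len(relevant) == 8
        col = table.iloc[:, 0]
        assert col["missense"] == 5 and col["three_prime_utr"] == 3 and col["intron"] == 2

    def test_class_counts_conserve_total(self):
        rng = np.random.default_rng(0)
        terms = ["missense_variant", "intron_variant", "synonymous_variant",
                 "5_prime_UTR_variant", "intergenic_variant"]
        vs = [variant(pos=int(p), terms=(t,))
              for p, t in zip(rng.integers(1_000, 100_000, 30), rng.choice(terms, 30))]
        _, table = select_relevant(vs, [REGION])
        assert table.iloc[:, 0].sum() == 30

    def test_most_severe_class_single_count(self):
        v = variant(pos=2_000, terms=("missense_variant", "splice_region_variant"))
        _, table = select_relevant([v], [REGION])
        col = table.iloc[:, 0]
        assert col["missense"] == 1 and col["splicing"] == 0


class TestClassifySegregation:
    def test_segregating_high_absent_low(self):
        v = variant(depths={"low": (12, 0), "high": (10, 6)})
        out = classify_segregation(v)
        assert out.per_line == {"low": "absent", "high": "segregating"}
        assert out.pattern == "segregating-in-high/absent-in-low"

    def test_fixed_low_segregating_high(self):
        v = variant(depths={"low": (0, 20), "high": (7, 5)})
        out = classify_segregation(v)
        assert out.per_line == {"low": "fixed", "high": "segregating"}

    def test_low_depth_no_call(self):
        v = variant(depths={"low": (2, 1), "high": (10, 5)})
        out = classify_segregation(v)
        assert out.per_line["low"] == "no_call"

    def test_depth_scaling_invariance(self):
        base = {"low": (6, 3), "high": (8, 0)}
        scaled = {"low": (18, 9), "high": (24, 0)}
        a = classify_segregation(variant(depths=base))
        b = classify_segregation(variant(depths=scaled))
        assert a.per_line == b.per_line

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            classify_segregation(variant(depths={"low": (-1, 3), "high": (5, 5)}))


class TestMapToGenes:
    def _genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["G1", "G2", "G3"],
                "gene_name": ["A", "B", "C"],
                "chrom": ["1", "1", "1"],
                "start": [1_000, 10_000, 20_000],
                "end": [4_999, 14_999, 24_999],
            }
        )

    def test_first_bp_inclusive(self):
        out = map_to_genes([variant(pos=1_000, gene_id="G1")], self._genes())
        assert out["gene_id"].tolist() == ["G1"]

    def test_gene_without_variants_not_candidate(self):
        out = map_to_genes([variant(pos=1_500, gene_id="G1")], self._genes())
        assert "G3" not in set(out["gene_id"])

    def test_three_genes_two_candidates(self):
        vs = [variant(pos=1_500, gene_id="G1"), variant(pos=12_000, gene_id="G2"),
              variant(pos=13_000, gene_id="G2")]
        out = map_to_genes(vs, self._genes())
        assert out["gene_id"].tolist() == ["G1", "G2"]
        assert out.set_index("gene_id")["n_variants"].to_dict() == {"G1": 1, "G2": 2}

    def test_empty_relevant_list(self):
        out = map_to_genes([], self._genes())
        assert len(out) == 0 and "gene_id" in out.columns


class TestAnnParsing:
    def test_parse_multi_annotation(self):
        ann = "G|missense_variant|MODERATE|NM|G1|transcript|G1.t1|protein_coding|1/1|||||||,G|intron_variant|MODIFIER|NM|G1|transcript|G1.t2|protein_coding|1/1|||||||"
        anns = parse_ann(ann)
        assert len(anns) == 2
        assert anns[0].terms == ["missense_variant"]
        assert anns[1].transcript == "G1.t2"

    def test_joint_terms_split(self):
        anns = parse_ann("G|missense_variant&splice_region_variant|.|N|G1|t|G1.t1|")
        assert set(anns[0].terms) == {"missense_variant", "splice_region_variant"}


class TestGff3Reader:
    def test_reads_gene_records(self, tmp_path):
        from vegwas.simulate import SimConfig, gene_grid, write_gff3

        genes = gene_grid(SimConfig(n_chrom=1, snps_per_chrom=10))
        path = tmp_path / "genes.gff3"
        write_gff3(genes, path)
        back = read_gff3_genes(path)
        assert len(back) == len(genes)
        pd.testing.assert_series_equal(
            back["start"], genes["start"], check_names=False
        )
        assert back["gene_id"].tolist() == genes["gene_id"].tolist()


class TestEndToEndTruthOracle:
    def test_screen_reproduces_truth(self, tmp_path):
        from vegwas.simulate import SimConfig, SimTruth, simulate_all

        cfg = SimConfig(n_base=10, n_high=10, n_low=10, n_chrom=2, snps_per_chrom=30, seed=17)
        paths = simulate_all(cfg, tmp_path / "sim")
        truth = SimTruth.from_json(paths["truth"])
        from vegwas.variant_screen import read_vcf

        records = read_vcf(paths["vcf"])
        retained, rejected, _ = hard_filter(records)
        assert {(v.chrom, v.pos) for v in retained} == {
            (s["chrom"], s["pos"]) for s in truth.vcf_sites if s["pass_filter"]
        }
        regions = [VqtlRegion(c, s, e, [], "") for c, s, e in truth.screen_regions]
        relevant, _ = select_relevant(retained, regions)
        assert {(v.chrom, v.pos) for v in relevant} == {
            (s["chrom"], s["pos"]) for s in truth.vcf_sites if s["relevant"]
        }
        by_pos = {(s["chrom"], s["pos"]): s for s in truth.vcf_sites}
        for v in relevant:
            seg = classify_segregation(v)
            site = by_pos[(v.chrom, v.pos)]
            assert seg.per_line["low"] == site["low_class"]
            assert seg.per_line["high"] == site["high_class"]
        genes = read_gff3_genes(paths["gff3"])
        cand = map_to_genes(relevant, genes)
        expected_genes = {
            s["gene_id"] for s in truth.vcf_sites if s["relevant"] and s["gene_id"]
        }
        assert set(cand["gene_id"]) == expected_genes
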