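import numpy as np
import pandas as pd
import pytest

from _oracles import per_base_domain_oracle, per_base_feature_oracle
from tissueclock import (
    CpGLocus,
    FeatureAnnotation,
    GeneModel,
    binomial_region_enrichment,
    build_regulatory_domains,
    classify_cpg,
    derive_promoters,
    derive_shores,
    feature_distribution,
    read_bed_features,
)


def islands_ann(intervals, chrom="chr1"):
    return FeatureAnnotation(pd.DataFrame(
        [{"chrom": chrom, "start": s, "end": e, "feature_class": "cpg_island",
          "name": f"isl{i}"} for i, (s, e) in enumerate(intervals)]
    ))


class TestShores:
    def test_single_island_flanks(self):
        out = derive_shores(islands_ann([(10_000, 11_000)]))
        got = sorted(map(tuple, out.table[["start", "end"]].to_numpy()))
        assert got == [(8_000, 10_000), (11_000, 13_000)]
        assert set(out.table["feature_class"]) == {"shore"}

    def test_close_islands_subtracting_both(self):
        # islands 1 kb apart: the inter-island gap is shore, both islands cut out
        out = derive_shores(islands_ann([(10_000, 11_000), (12_000, 13_000)]))
        bases = np.zeros(20_000, dtype=bool)
        for r in out.table.itertuples():
            bases[r.start:r.end] = True
        oracle = per_base_feature_oracle([(10_000, 11_000), (12_000, 13_000)],
                                         chrom_len=20_000)
        np.testing.assert_array_equal(bases, oracle)

    def test_clipped_at_chromosome_start(self):
        out = derive_shores(islands_ann([(500, 1_500)]), {"chr1": 100_000})
        got = sorted(map(tuple, out.table[["start", "end"]].to_numpy()))
        assert got == [(0, 500), (1_500, 3_500)]

    def test_random_islands_match_per_base_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            starts = np.sort(rng.integers(0, 90_000, size=6))
            iv = [(int(s), int(s + rng.integers(200, 3_000))) for s in starts]
            out = derive_shores(islands_ann(iv), {"chr1": 100_000})
            bases = np.zeros(100_000, dtype=bool)
            for r in out.table.itertuples():
                bases[r.start:r.end] = True
            # oracle treats overlapping islands as their union
            np.testing.assert_array_equal(
                bases, per_base_feature_oracle(iv, chrom_len=100_000))


class TestPromoters:
    def test_plus_strand_window(self):
        out = derive_promoters([GeneModel("g", "chr1", "+", 50_001)])
        assert tuple(out.table.iloc[0][["start", "end"]]) == (49_000, 50_000)

    def test_minus_strand_mirrored(self):
        out = derive_promoters([GeneModel("g", "chr1", "-", 50_001)])
        assert tuple(out.table.iloc[0][["start", "end"]]) == (50_001, 51_001)

    def test_tss_at_one_clipped(self):
        out = derive_promoters([GeneModel("g", "chr1", "+", 1)])
        assert len(out.table) == 0  # fully upstream of the chromosome


class TestClassify:
    def _ann(self):
        return FeatureAnnotation(pd.DataFrame([
            {"chrom": "chr1", "start": 1_000, "end": 2_000,
             "feature_class": "cpg_island", "name": "isl"},
            {"chrom": "chr1", "start": 500, "end": 5_000,
             "feature_class": "intron", "name": "int"},
        ]))

    def test_priority_island_over_intron(self):
        classes, primary = classify_cpg(CpGLocus("chr1:1500", "chr1", 1_500), self._ann())
        assert classes == {"cpg_island", "intron"}
        assert primary == "cpg_island"

    def test_no_overlap_is_intergenic(self):
        classes, primary = classify_cpg(CpGLocus("chr1:9999", "chr1", 9_999), self._ann())
        assert classes == {"intergenic"} and primary == "intergenic"

    def test_half_open_end_excluded(self):
        # 1-based position 2000 is 0-based 1999 (inside); 2001 is 2000 (outside)
        ann = self._ann()
        assert "cpg_island" in classify_cpg(CpGLocus("x", "chr1", 2_000), ann)[0]
        assert "cpg_island" not in classify_cpg(CpGLocus("x", "chr1", 2_001), ann)[0]

    def test_stable_under_reordering(self):
        ann = self._ann()
        shuffled = FeatureAnnotation(ann.table.iloc[::-1].reset_index(drop=True))
        locus = CpGLocus("chr1:1500", "chr1", 1_500)
        assert classify_cpg(locus, ann)[1] == classify_cpg(locus, shuffled)[1]


class TestFeatureDistribution:
    def test_all_in_one_island(self):
        ann = islands_ann([(1_000, 2_000)])
        loci = [CpGLocus(f"chr1:{p}", "chr1", p) for p in range(1_100, 1_110)]
        df = feature_distribution(loci, ann)
        assert df.iloc[0]["feature_class"] == "cpg_island"
        assert df.iloc[0]["count"] == 10 and df.iloc[0]["fraction"] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(17)
        ann = islands_ann([(1_000, 2_000), (5_000, 6_000)])
        loci = [CpGLocus(f"chr1:{p}", "chr1", int(p))
                for p in rng.integers(1, 10_000, size=50)]
        df = feature_distribution(loci, ann)
        assert df["fraction"].sum() == pytest.approx(1.0)

    def test_counts_match_known_placement(self):
        ann = islands_ann([(1_000, 2_000)])
        inside = [CpGLocus(f"i{k}", "chr1", p) for k, p in enumerate(range(1_001, 1_031))]
        outside = [CpGLocus(f"o{k}", "chr1", p) for k, p in enumerate(range(9_001, 9_071))]
        df = feature_distribution(inside + outside, ann).set_index("feature_class")
        assert df.loc["cpg_island", "count"] == 30
        assert df.loc["intergenic", "count"] == 70

    def test_empty_locus_list(self):
        assert len(feature_distribution([], islands_ann([(0, 10)]))) == 0


class TestRegulatoryDomains:
    def test_lone_gene_full_extension(self):
        d = build_regulatory_domains([GeneModel("g", "chr1", "+", 2_000_001)],
                                     {"chr1": 10_000_000})
        row = d.table.iloc[0]
        assert (row["basal_start"], row["basal_end"]) == (1_995_000, 2_001_000)
        assert (row["ext_start"], row["ext_end"]) == (995_000, 3_001_000)

    def test_neighbors_meet_at_basal_boundaries(self):
        genes = [GeneModel("gL", "chr1", "+", 1_000_001),
                 GeneModel("gR", "chr1", "+", 1_016_001)]  # basal 10 kb apart
        d = build_regulatory_domains(genes, {"chr1": 50_000_000}).table.set_index("gene_id")
        assert d.loc["gL", "ext_end"] == d.loc["gR", "basal_start"]
        assert d.loc["gR", "ext_start"] == d.loc["gL", "basal_end"]

    def test_clipped_near_chromosome_start(self):
        d = build_regulatory_domains([GeneModel("g", "chr1", "+", 2_001)],
                                     {"chr1": 100_000})
        row = d.table.iloc[0]
        assert row["basal_start"] == 0 and row["ext_start"] == 0
        assert row["ext_end"] == 100_000

    def test_duplicate_gene_ids_rejected(self):
        genes = [GeneModel("g", "chr1", "+", 1_000),
                 GeneModel("g", "chr1", "-", 9_000)]
        with pytest.raises(ValueError, match="duplicate"):
            build_regulatory_domains(genes, {"chr1": 100_000})

    def test_invariants_and_per_base_oracle(self):
        rng = np.random.default_rng(19)
        chrom_len = 100_000
        for _ in range(10):
            n = int(rng.integers(2, 6))
            spec = [(f"g{i}", int(rng.integers(1, chrom_len)),
                     str(rng.choice(["+", "-"]))) for i in range(n)]
            genes = [GeneModel(gid, "chr1", strand, tss) for gid, tss, strand in spec]
            d = build_regulatory_domains(genes, {"chr1": chrom_len})
            t = d.table.set_index("gene_id")
            oracle = per_base_domain_oracle(spec, chrom_len)
            for gid in t.index:
                # basal within extended, all within bounds
                assert t.loc[gid, "ext_start"] <= t.loc[gid, "basal_start"]
                assert t.loc[gid, "basal_end"] <= t.loc[gid, "ext_end"]
                assert 0 <= t.loc[gid, "ext_start"] <= t.loc[gid, "ext_end"] <= chrom_len
                got = np.zeros(chrom_len, dtype=bool)
                got[t.loc[gid, "ext_start"]:t.loc[gid, "ext_end"]] = True
                np.testing.assert_array_equal(got, oracle[gid], err_msg=gid)


class TestBinomialEnrichment:
    def _setup(self, n_bg=40, n_in=20):
        genes = [GeneModel("g", "chr1", "+", 1_000_000)]
        domains = build_regulatory_domains(genes, {"chr1": 50_000_000})
        inside = [CpGLocus(f"in{k}", "chr1", 1_000_000 + k) for k in range(n_in)]
        outside = [CpGLocus(f"out{k}", "chr1", 40_000_000 + k)
                   for k in range(n_bg - n_in)]
        return domains, inside, outside

    def test_no_hits_gives_p_one(self):
        domains, inside, outside = self._setup()
        res = binomial_region_enrichment(outside[:5], inside + outside, domains)
        assert res["k"] == 0 and res["p_value"] == 1.0

    def test_closed_form_tail(self):
        domains, inside, outside = self._setup(n_bg=40, n_in=20)  # p_hit = 0.5
        res = binomial_region_enrichment(inside[:10], inside + outside, domains)
        assert res["p_hit"] == pytest.approx(0.5)
        assert res["p_value"] == pytest.approx(2.0**-10, rel=1e-9)

    def test_selection_equals_background(self):
        domains, inside, outside = self._setup()
        bg = inside + outside
        res = binomial_region_enrichment(bg, bg, domains)
        assert res["k"] / res["n"] == pytest.approx(res["p_hit"])
        assert res["p_value"] >= 0.5

    def test_inconsistent_background_errors(self):
        domains, inside, outside = self._setup()
        with pytest.raises(ValueError, match="background"):
            binomial_region_enrichment(inside[:2], outside, domains)


def test_read_bed_features(tmp_path):
    p = tmp_path / "islands.bed"
    p.write_text("chr1\t100\t500\tisl1\nchr2\t0\t50\tisl2\n")
    ann = read_bed_features(p, "cpg_island")
    assert list(ann.table["feature_class"]) == ["cpg_island", "cpg_island"]
    p2 = tmp_path / "mixed.bed"
    p2.write_text("chr1\t100\t500\texon\nchr1\t600\t900\tintron\n")
    ann2 = read_bed_features(p2)
    assert list(ann2.table["feature_class"]) == ["exon", "intron"]
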