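import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicpipe import somatic as so
from omicpipe import synthetic as sy


def vc(chrom="chr1", pos=100, ref="A", alt="T", caller="MuSE", **kw):
    return so.VariantCall(sample_id="s1", caller=caller, chrom=chrom, pos=pos,
                          ref=ref, alt=alt, **kw)


variant_strategy = (
    st.tuples(
        st.sampled_from(["chr1", "chr2"]),
        st.integers(1, 50),
        st.sampled_from(["A", "C", "AT", "ATT", "G"]),
        st.sampled_from(["T", "G", "TA", "C"]),
    )
    .filter(lambda t: t[2] != t[3])
    .map(lambda t: vc(chrom=t[0], pos=t[1], ref=t[2], alt=t[3]))
)


class TestVcfReading:
    def test_roundtrip_counts_and_filters(self, tmp_path):
        calls = [
            vc(pos=100, ssc=40),
            vc(pos=200, ref="C", alt="G", filter={"PASS"}, tumor_depths=(10, 10, 5, 5)),
            vc(pos=300, ref="G", alt="A", filter={"bias", "lowqual"}),
        ]
        path = tmp_path / "test.vcf"
        sy.write_vcf(calls, str(path))
        read = so.read_somatic_vcf(str(path), caller="MuSE", sample_id="s1")
        assert len(read) == 3
        by_pos = {c.pos: c for c in read}
        assert by_pos[100].ssc == 40
        assert by_pos[200].tumor_depths == (10, 10, 5, 5)
        assert by_pos[300].filter == {"bias", "lowqual"}
        assert by_pos[100].filter == {"PASS"}

    def test_multiallelic_record_split(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FILTER=<ID=PASS,Description="ok">\n'
            "##contig=<ID=chr1,length=1000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tG\tA,T\t.\tPASS\t.\n"
        )
        read = so.read_somatic_vcf(str(path), caller="MuTect2", sample_id="s1")
        assert [(c.pos, c.alt) for c in read] == [(100, "A"), (100, "T")]

    def test_gdc_filter_labels_parsed(self, tmp_path):
        calls = [vc(pos=100, gdc_filter={"panel_of_normals", "strand_bias"})]
        path = tmp_path / "gdc.vcf"
        sy.write_vcf(calls, str(path))
        read = so.read_somatic_vcf(str(path), caller="MuSE", sample_id="s1")
        assert read[0].gdc_filter == {"panel_of_normals", "strand_bias"}


class TestSscFilter:
    def test_strict_threshold(self):
        calls = [vc(pos=p, ssc=s) for p, s in [(1, 10), (2, 25), (3, 40)]]
        kept = so.apply_ssc_filter(calls)
        assert [c.ssc for c in kept] == [25, 40]  # "< 25" removed, 25 survives

    def test_calls_without_score_untouched(self):
        calls = [vc(pos=1), vc(pos=2, ssc=1)]
        kept = so.apply_ssc_filter(calls)
        assert [c.pos for c in kept] == [1]

    def test_threshold_zero_keeps_all(self):
        calls = [vc(pos=p, ssc=s) for p, s in [(1, 0), (2, 5)]]
        assert len(so.apply_ssc_filter(calls, threshold=0)) == 2

    def test_empty_input(self):
        assert so.apply_ssc_filter([]) == []


class TestPonTagging:
    def test_present_and_absent(self):
        calls = [vc(pos=100), vc(pos=200, ref="C", alt="G")]
        tagged = so.tag_pon(calls, pon={("chr1", 100, "T")})
        assert so.PON_LABEL in tagged[0].gdc_filter
        assert so.PON_LABEL not in tagged[1].gdc_filter
        assert len(tagged) == 2  # tagging never removes

    def test_matches_bruteforce_intersection(self):
        rng = np.random.default_rng(21)
        calls = [vc(pos=int(p), ref="A", alt="T") for p in rng.integers(1, 60, size=100)]
        pon_pos = set(int(p) for p in rng.integers(1, 60, size=30))
        pon = {("chr1", p, "T") for p in pon_pos}
        tagged = so.tag_pon(calls, pon)
        for c in tagged:
            assert (so.PON_LABEL in c.gdc_filter) == (c.pos in pon_pos)


def fisher_two_sided_enumeration(rf, rr, af, ar):
    """Independent oracle: enumerate the hypergeometric support directly."""
    n = rf + rr + af + ar
    row1, col1 = rf + rr, rf + af
    p_obs = (math.comb(row1, rf) * math.comb(n - row1, col1 - rf)) / math.comb(n, col1)
    total = 0.0
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        p_k = (math.comb(row1, k) * math.comb(n - row1, col1 - k)) / math.comb(n, col1)
        if p_k <= p_obs * (1 + 1e-9):
            total += p_k
    return total


class TestStrandBias:
    def test_balanced_table_not_tagged(self):
        calls = so.tag_strand_bias([vc(tumor_depths=(50, 50, 25, 25))], alpha=0.05)
        assert so.BIAS_LABEL not in calls[0].gdc_filter

    def test_one_sided_support_tagged(self):
        calls = so.tag_strand_bias([vc(tumor_depths=(50, 50, 30, 0))], alpha=0.05)
        assert so.BIAS_LABEL in calls[0].gdc_filter

    @pytest.mark.parametrize("table", [(50, 50, 30, 0), (50, 50, 25, 25), (12, 3, 2, 9)])
    def test_pvalue_matches_enumeration_oracle(self, table):
        assert so.strand_bias_pvalue(table) == pytest.approx(
            fisher_two_sided_enumeration(*table), rel=1e-6
        )

    def test_alpha_zero_never_tags(self):
        calls = so.tag_strand_bias([vc(tumor_depths=(100, 0, 50, 0))], alpha=0.0)
        assert so.BIAS_LABEL not in calls[0].gdc_filter

    def test_all_zero_table_skipped(self):
        calls = so.tag_strand_bias([vc(tumor_depths=(0, 0, 0, 0))], alpha=0.05)
        assert so.BIAS_LABEL not in calls[0].gdc_filter


class TestMatching:
    def test_strict_examples(self):
        assert so.strict_match(vc(), vc())
        assert not so.strict_match(vc(alt="T"), vc(alt="G"))

    def test_loose_span_overlap(self):
        # SNV at chr1:100 vs deletion anchored at 99 spanning 99-100
        snv = vc(pos=100, ref="A", alt="T")
        deletion = vc(pos=99, ref="CA", alt="C")
        assert so.loose_match(snv, deletion)
        assert not so.loose_match(vc(pos=100), vc(pos=102))

    @given(v1=variant_strategy, v2=variant_strategy)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_strict_implies_loose_and_loose_symmetric(self, v1, v2):
        if so.strict_match(v1, v2):
            assert so.loose_match(v1, v2)
        assert so.loose_match(v1, v2) == so.loose_match(v2, v1)
        assert so.loose_match(v1, v1)


class TestCallerPartition:
    def test_small_enumeration(self):
        a, b = vc(pos=10), vc(pos=20, ref="C", alt="G")
        sets = {"c1": [a, b], "c2": [a], "c3": [a], "c4": [a]}
        part = so.caller_partition(sets)
        assert part.loc[4, "count"] == 1 and part.loc[1, "count"] == 1
        assert part.loc[4, "fraction"] == pytest.approx(0.5)

    def test_identical_sets_all_at_n(self):
        calls = [vc(pos=p) for p in (1, 2, 3)]
        part = so.caller_partition({"a": calls, "b": calls, "c": calls})
        assert list(part.index) == [3] and part.loc[3, "count"] == 3

    def test_disjoint_sets_all_singletons(self):
        part = so.caller_partition({"a": [vc(pos=1)], "b": [vc(pos=50)]})
        assert list(part.index) == [1] and part.loc[1, "count"] == 2

    def test_fractions_sum_to_one_and_top_bin_is_intersection(self):
        rng = np.random.default_rng(22)
        sets = {
            f"c{i}": [vc(pos=int(p)) for p in rng.choice(np.arange(1, 201), size=80, replace=False)]
            for i in range(4)
        }
        part = so.caller_partition(sets, matching="strict")
        assert part["fraction"].sum() == pytest.approx(1.0)
        inter = set.intersection(*({c.pos for c in calls} for calls in sets.values()))
        assert part.loc[4, "count"] == len(inter)


class TestRecall:
    def test_small_enumeration(self):
        a, b, c = vc(pos=1), vc(pos=2, ref="C", alt="G"), vc(pos=3, ref="G", alt="C")
        truth = {"s1": [a, b, c]}
        call_sets = {"c1": {"s1": [a, b]}, "c2": {"s1": [a]}}
        res = so.recall_analysis(truth, call_sets)
        pooled = res["per_caller"].query("sample_id == '__pooled__'").set_index("caller")
        assert pooled.loc["c1", "recall"] == pytest.approx(2 / 3)
        assert pooled.loc["c2", "recall"] == pytest.approx(1 / 3)
        assert res["by_k"].loc[0, "fraction"] == pytest.approx(1 / 3)
        assert res["by_k"]["fraction"].sum() == pytest.approx(1.0)

    def test_supersets_give_perfect_recall(self):
        truth = {"s1": [vc(pos=p) for p in (1, 2)]}
        calls = {"c1": {"s1": [vc(pos=p) for p in (1, 2, 3)]},
                 "c2": {"s1": [vc(pos=p) for p in (1, 2)]}}
        res = so.recall_analysis(truth, calls)
        assert (res["per_caller"]["recall"] == 1.0).all()
        assert res["combinations"]["recall"].eq(1.0).all()

    def test_union_recall_monotone_in_k(self):
        cfg = sy.SimConfig(seed=23, n_truth_variants=500)
        truth, call_sets = sy.simulate_caller_calls(cfg)
        res = so.recall_analysis(truth, call_sets)
        best_by_k = res["combinations"].groupby("k")["recall"].max()
        assert best_by_k.is_monotonic_increasing

    def test_empty_truth_sample_excluded(self):
        truth = {"s1": [vc(pos=1)], "s2": []}
        res = so.recall_analysis(truth, {"c1": {"s1": [vc(pos=1)]}, "c2": {"s1": []}})
        assert set(res["per_caller"]["sample_id"]) == {"s1", "__pooled__"}


class TestMaf:
    def test_single_snp_row(self):
        maf = so.build_maf([vc()], project="P")
        assert len(maf) == 1 and maf.loc[0, "variant_class"] == "SNP"
        assert maf.attrs["access"] == "controlled"

    @pytest.mark.parametrize(
        "ref, alt, expected",
        [("C", "CA", "INS"), ("CA", "C", "DEL"), ("A", "T", "SNP"), ("ATG", "A", "DEL")],
    )
    def test_variant_classes(self, ref, alt, expected):
        assert so.variant_class(ref, alt) == expected

    def test_mixed_batch_class_counts_match_rule_oracle(self):
        rng = np.random.default_rng(24)
        alleles = [("A", "T"), ("C", "CAT"), ("GGT", "G"), ("G", "C")]
        picks = [alleles[i] for i in rng.integers(0, 4, size=50)]
        calls = [vc(pos=i + 1, ref=r, alt=a) for i, (r, a) in enumerate(picks)]
        maf = so.build_maf(calls, project="P")
        expected = pd.Series([so.variant_class(r, a) for r, a in picks]).value_counts()
        assert maf["variant_class"].value_counts().to_dict() == expected.to_dict()

    def test_select_clean(self):
        calls = [
            vc(pos=1),
            vc(pos=2, ref="C", alt="G", filter={"lowqual"}),
            vc(pos=3, ref="G", alt="A", gdc_filter={so.PON_LABEL}),
        ]
        clean = so.select_clean(so.build_maf(calls, "P"))
        assert list(clean["start"]) == [1]


class TestGermlineMasking:
    def test_pon_tagged_rows_removed(self):
        calls = [vc(pos=1), vc(pos=2, ref="C", alt="G", gdc_filter={so.PON_LABEL})]
        open_maf = so.mask_germline(so.build_maf(calls, "P"))
        assert list(open_maf["start"]) == [1]
        assert open_maf.attrs["access"] == "open"

    def test_empty_rules_identity(self):
        maf = so.build_maf([vc(pos=1, filter={"bad"})], "P")
        assert len(so.mask_germline(maf, rules={})) == len(maf)

    def test_normal_alt_depth_threshold(self):
        calls = [vc(pos=1, normal_alt_depth=0), vc(pos=2, ref="C", alt="G", normal_alt_depth=2)]
        open_maf = so.mask_germline(so.build_maf(calls, "P"))
        assert list(open_maf["start"]) == [1]

    def test_output_always_subset(self):
        rng = np.random.default_rng(25)
        calls = [
            vc(pos=i + 1, ssc=int(rng.integers(0, 60)),
               normal_alt_depth=int(rng.integers(0, 4)),
               filter={"PASS"} if rng.random() < 0.7 else {"x"})
            for i in range(60)
        ]
        maf = so.build_maf(calls, "P")
        open_maf = so.mask_germline(maf)
        assert set(open_maf.index).issubset(set(maf.index))


class TestClassRatios:
    def test_simple_ratio(self):
        calls = [vc(pos=i + 1) for i in range(10)] + [vc(pos=100, ref="C", alt="CA")]
        ratios = so.variant_class_ratios(so.build_maf(calls, "P"))
        assert ratios.loc[0, "ins_snp_ratio"] == pytest.approx(0.1)

    def test_zero_snp_flagged(self):
        ratios = so.variant_class_ratios(so.build_maf([vc(ref="C", alt="CA")], "P"))
        assert bool(ratios.loc[0, "undefined"]) and np.isnan(ratios.loc[0, "ins_snp_ratio"])

    def test_wga_artifact_inflates_ins_snp_ratio(self):
        """A library with a 10x insertion rate shows a ~10x INS/SNP ratio."""
        rng = np.random.default_rng(26)

        def sample_calls(sample, ins_rate, n=400):
            calls = []
            for i in range(n):
                if rng.random() < ins_rate:
                    calls.append(so.VariantCall(sample, "MuTect2", "chr1", i + 1, "C", "CAT"))
                else:
                    calls.append(so.VariantCall(sample, "MuTect2", "chr1", i + 1, "A", "T"))
            return calls

        maf = so.build_maf(sample_calls("normal", 0.03) + sample_calls("wga", 0.3), "P")
        ratios = so.variant_class_ratios(maf).set_index("sample_id")
        fold = ratios.loc["wga", "ins_snp_ratio"] / ratios.loc["normal", "ins_snp_ratio"]
        assert fold > 5
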