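import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_variant, random_catalog
from mutevo.variants import (
    FilterConfig,
    LineageTree,
    Variant,
    VariantCatalog,
    VariantError,
    af_binomial_filter,
    annotate_consequence,
    apply_filters,
    binomial_pvalue,
    database_filter,
    filter_reasons,
    lineage_subtract,
    ns_s_ratio,
    strand_filter,
    subtract,
    tmb,
)


class TestVariant:
    def test_vclass_inference(self):
        assert make_variant(ref="C", alt="T").vclass == "SNV"
        assert make_variant(ref="C", alt="CAT").vclass == "INS"
        assert make_variant(ref="CAT", alt="C").vclass == "DEL"

    def test_af(self):
        assert make_variant(depth=100, alt_count=30).af == pytest.approx(0.30)

    def test_identity_variant_rejected(self):
        with pytest.raises(VariantError):
            make_variant(ref="C", alt="C")

    def test_alt_count_exceeding_depth_rejected(self):
        with pytest.raises(VariantError):
            make_variant(depth=10, alt_count=11, alt_fwd=5, alt_rev=5)

    def test_strand_sum_exceeding_alt_rejected(self):
        with pytest.raises(VariantError):
            make_variant(alt_count=5, alt_fwd=4, alt_rev=4)

    def test_position_must_be_positive(self):
        with pytest.raises(VariantError):
            make_variant(pos=0)


class TestStrandFilter:
    def test_both_strands_kept(self):
        assert strand_filter(make_variant(alt_fwd=5, alt_rev=3, alt_count=10))

    def test_single_strand_discarded(self):
        assert not strand_filter(make_variant(alt_fwd=8, alt_rev=0, alt_count=10))

    def test_no_support_discarded(self):
        assert not strand_filter(make_variant(alt_fwd=0, alt_rev=0, alt_count=10))

    def test_missing_counts_error(self):
        v = make_variant(alt_fwd=None, alt_rev=None)
        with pytest.raises(VariantError, match="strand"):
            strand_filter(v)


class TestAfBinomialFilter:
    def test_high_af_low_p_kept(self):
        v = make_variant(depth=100, alt_count=20, alt_fwd=10, alt_rev=10)
        assert af_binomial_filter(v, FilterConfig(error_rate=0.01))

    def test_low_af_discarded_regardless_of_p(self):
        v = make_variant(depth=100, alt_count=5, alt_fwd=2, alt_rev=2)
        assert not af_binomial_filter(v, FilterConfig())

    def test_borderline_af_high_p_discarded(self):
        # af = 0.10 passes the AF bound but p = 1 - 0.95^10 ~ 0.401 > 0.05
        v = make_variant(depth=10, alt_count=1, alt_fwd=1, alt_rev=0)
        cfg = FilterConfig(error_rate=0.05, min_af=0.10)
        assert math.isclose(
            binomial_pvalue(1, 10, 0.05), 1 - 0.95**10, rel_tol=1e-12
        )
        assert not af_binomial_filter(v, cfg)

    def test_zero_depth_error(self):
        v = make_variant(depth=0, alt_count=0, alt_fwd=0, alt_rev=0)
        with pytest.raises(VariantError):
            af_binomial_filter(v, FilterConfig())

    @pytest.mark.parametrize("depth", [1, 10, 100, 500])
    def test_exact_tail_matches_naive_summation(self, depth):
        p = 0.01
        for alt in {0, 1, 2, depth // 2, depth}:
            naive = sum(
                math.comb(depth, k) * p**k * (1 - p) ** (depth - k)
                for k in range(alt, depth + 1)
            )
            assert binomial_pvalue(alt, depth, p) == pytest.approx(naive, abs=1e-12)


class TestDatabaseFilter:
    def test_pon_hit_discarded(self):
        v = make_variant()
        cfg = FilterConfig(pon_keys={v.key})
        assert not database_filter(v, cfg)

    def test_dbsnp_hit_discarded(self):
        v = make_variant()
        cfg = FilterConfig(dbsnp_keys={v.key})
        assert not database_filter(v, cfg)

    def test_novel_kept(self):
        assert database_filter(make_variant(), FilterConfig())


class TestApplyFilters:
    def test_empty_catalog(self, default_filter_config):
        cat = VariantCatalog("S")
        assert len(apply_filters(cat, default_filter_config)) == 0

    def test_idempotence_when_all_pass(self, default_filter_config):
        cat = VariantCatalog("S", "T0", [make_variant(pos=p) for p in (1, 2, 3)])
        out = apply_filters(cat, default_filter_config)
        assert out.keys() == cat.keys()
        assert apply_filters(out, default_filter_config).keys() == out.keys()

    def test_matches_brute_force_conjunction(self):
        rng = np.random.default_rng(7)
        cat = random_catalog(rng, 200)
        some_keys = sorted(cat.keys())[:10]
        cfg = FilterConfig(
            dbsnp_keys=set(some_keys[:5]), pon_keys=set(some_keys[5:])
        )
        expected = {
            v.key
            for v in cat
            if strand_filter(v)
            and af_binomial_filter(v, cfg)
            and database_filter(v, cfg)
        }
        assert apply_filters(cat, cfg).keys() == expected

    def test_error_names_variant_key(self):
        cat = VariantCatalog("S", "T0", [make_variant(alt_fwd=None, alt_rev=None)])
        with pytest.raises(VariantError, match=r"chr1"):
            apply_filters(cat, FilterConfig())


class TestSubtract:
    def test_identical_catalogs(self):
        a = VariantCatalog("S", "T0", [make_variant(pos=p) for p in (1, 2)])
        b = VariantCatalog("S", "T90", [make_variant(pos=p) for p in (1, 2)])
        res = subtract(b, a)
        assert len(res.gained) == 0 and len(res.lost) == 0
        assert set(res.shared_afs) == a.keys()

    def test_disjoint_catalogs(self):
        a = VariantCatalog("S", "T0", [make_variant(pos=p) for p in (1, 2)])
        b = VariantCatalog("S", "T90", [make_variant(pos=p) for p in (3, 4)])
        res = subtract(b, a)
        assert res.gained.keys() == b.keys()
        assert res.lost.keys() == a.keys()

    def test_partial_overlap(self):
        earlier = VariantCatalog("S", "T0", [make_variant(pos=p) for p in (1, 2, 3, 4, 5)])
        later = VariantCatalog("S", "T90", [make_variant(pos=p) for p in (3, 4, 5, 6, 7, 8)])
        res = subtract(later, earlier)
        assert len(res.gained) == 3 and len(res.lost) == 2

    @given(
        earlier=st.sets(st.integers(1, 40), max_size=25),
        later=st.sets(st.integers(1, 40), max_size=25),
    )
    @settings(max_examples=50, deadline=None)
    def test_set_conservation(self, earlier, later):
        a = VariantCatalog("S", "T0", [make_variant(pos=p) for p in earlier])
        b = VariantCatalog("S", "T90", [make_variant(pos=p) for p in later])
        res = subtract(b, a)
        shared = set(res.shared_afs)
        assert res.gained.keys() & res.lost.keys() == set()
        assert res.gained.keys() | shared == b.keys()
        assert res.lost.keys() | shared == a.keys()

    def test_shared_keeps_both_afs(self):
        a = VariantCatalog("S", "T0", [make_variant(depth=100, alt_count=50, alt_fwd=25, alt_rev=25)])
        b = VariantCatalog("S", "T90", [make_variant(depth=100, alt_count=20, alt_fwd=10, alt_rev=10)])
        res = subtract(b, a)
        assert list(res.shared_afs.values()) == [(0.5, 0.2)]


class TestLineageSubtract:
    def _cat(self, node, positions):
        return VariantCatalog(node, node, [make_variant(pos=p) for p in positions])

    def test_identical_child(self):
        tree = LineageTree()
        tree.add_node("F1", self._cat("F1", [1, 2]))
        tree.add_node("F2", self._cat("F2", [1, 2]), parent="F1")
        res = lineage_subtract(tree)
        assert res["F1"].baseline and res["F1"].gained.keys() == tree.catalog("F1").keys()
        assert len(res["F2"].gained) == 0

    def test_branching_private_sets(self):
        tree = LineageTree()
        tree.add_node("F1", self._cat("F1", [1, 2]))
        tree.add_node("F2a", self._cat("F2a", [1, 2, 10]), parent="F1")
        tree.add_node("F2b", self._cat("F2b", [1, 2, 20, 21]), parent="F1")
        res = lineage_subtract(tree)
        assert {v.pos for v in res["F2a"].gained} == {10}
        assert {v.pos for v in res["F2b"].gained} == {20, 21}

    def test_persisting_variant_gained_once(self):
        tree = LineageTree()
        tree.add_node("F1", self._cat("F1", [1]))
        tree.add_node("F2", self._cat("F2", [1, 5]), parent="F1")
        tree.add_node("F3", self._cat("F3", [1, 5]), parent="F2")
        res = lineage_subtract(tree)
        assert {v.pos for v in res["F2"].gained} == {5}
        assert len(res["F3"].gained) == 0

    def test_cycle_detected(self):
        tree = LineageTree()
        tree.add_node("A", self._cat("A", [1]), parent="B")
        tree.add_node("B", self._cat("B", [1]), parent="A")
        with pytest.raises(VariantError):
            lineage_subtract(tree)

    def test_two_roots_rejected(self):
        tree = LineageTree()
        tree.add_node("A", self._cat("A", [1]))
        tree.add_node("B", self._cat("B", [1]))
        with pytest.raises(VariantError, match="root"):
            lineage_subtract(tree)

    def test_linear_chain_telescopes(self):
        rng = np.random.default_rng(3)
        sets = {"F1": set(rng.integers(1, 500, 40).tolist())}
        sets["F2"] = (sets["F1"] - set(list(sets["F1"])[:5])) | set(rng.integers(500, 900, 20).tolist())
        sets["F3"] = (sets["F2"] - set(list(sets["F2"])[:3])) | set(rng.integers(900, 1200, 15).tolist())
        tree = LineageTree()
        tree.add_node("F1", self._cat("F1", sets["F1"]))
        tree.add_node("F2", self._cat("F2", sets["F2"]), parent="F1")
        tree.add_node("F3", self._cat("F3", sets["F3"]), parent="F2")
        res = lineage_subtract(tree)
        reconstructed = set(tree.catalog("F1").keys())
        for node in ("F2", "F3"):
            reconstructed |= res[node].gained.keys()
            reconstructed -= res[node].lost.keys()
        assert reconstructed == tree.catalog("F3").keys()


class TestTmb:
    def test_arithmetic(self):
        cat = VariantCatalog(
            "S", "T0", [make_variant(pos=p, consequence="missense") for p in range(1, 381)]
        )
        assert tmb(cat, 38.0) == pytest.approx(10.0)

    def test_zero_coding(self):
        cat = VariantCatalog("S", "T0", [make_variant(consequence="noncoding")])
        assert tmb(cat, 38.0) == 0.0

    def test_mixed_consequences(self):
        coding = [make_variant(pos=p, consequence="missense") for p in range(1, 6)]
        noncoding = [make_variant(pos=p, consequence="noncoding") for p in range(10, 13)]
        cat = VariantCatalog("S", "T0", coding + noncoding)
        assert tmb(cat, 1.0) == pytest.approx(5.0)

    def test_bad_denominator(self):
        with pytest.raises(VariantError):
            tmb(VariantCatalog("S"), 0.0)


class TestAnnotateConsequence:
    def test_synonymous_third_position(self):
        # GAA -> GAG, both glutamate
        v = make_variant(ref="A", alt="G")
        assert annotate_consequence(v, "GAATAA", cds_pos=3) == "synonymous"

    def test_missense(self):
        # GAA -> GTA, E -> V
        v = make_variant(ref="A", alt="T")
        assert annotate_consequence(v, "GAATAA", cds_pos=2) == "missense"

    def test_nonsense(self):
        # TAC -> TAA
        v = make_variant(ref="C", alt="A")
        assert annotate_consequence(v, "TACTAA", cds_pos=3) == "nonsense"

    def test_frameshift_deletion(self):
        v = make_variant(ref="AA", alt="A")
        assert annotate_consequence(v, "ATGAAATAA", cds_pos=4) == "frameshift"

    def test_inframe_deletion(self):
        v = make_variant(ref="GAAA", alt="G")
        assert annotate_consequence(v, "ATGAAATAA", cds_pos=3) == "inframe_indel"

    def test_noncoding(self):
        assert annotate_consequence(make_variant(), None) == "noncoding"

    def test_reference_mismatch(self):
        v = make_variant(ref="G", alt="T")
        with pytest.raises(VariantError, match="mismatch"):
            annotate_consequence(v, "AAATAA", cds_pos=1)


class TestNsSRatio:
    def test_three_to_one(self):
        ns = [make_variant(pos=p, consequence="missense") for p in range(1, 31)]
        s = [make_variant(pos=p, consequence="synonymous") for p in range(100, 110)]
        assert ns_s_ratio(VariantCatalog("S", "T0", ns + s)) == pytest.approx(3.0)

    def test_undefined_when_no_synonymous(self):
        cat = VariantCatalog("S", "T0", [make_variant(consequence="missense")])
        assert ns_s_ratio(cat) is None

    def test_exhaustive_cds_enumeration(self, cds_50):
        """All possible SNVs of a CDS: ratio matches an independent translation oracle."""
        from itertools import count

        from Bio.Seq import Seq

        wt_protein = str(Seq(cds_50).translate())
        variants = []
        counter = count(1)
        expected_ns = expected_s = 0
        for pos in range(1, len(cds_50) + 1):
            ref = cds_50[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = Variant(chrom="chr1", pos=next(counter), ref=ref, alt=alt)
                v.consequence = annotate_consequence(v, cds_50, cds_pos=pos)
                variants.append(v)
                mutant = cds_50[: pos - 1] + alt + cds_50[pos:]
                if str(Seq(mutant).translate()) == wt_protein:
                    expected_s += 1
                else:
                    expected_ns += 1
        cat = VariantCatalog("S", "T0", variants)
        assert ns_s_ratio(cat) == pytest.approx(expected_ns / expected_s)


class TestOrderInvariance:
    def test_filter_output_order_invariant(self):
        rng = np.random.default_rng(11)
        cat = random_catalog(rng, 100)
        cfg = FilterConfig()
        reversed_cat = VariantCatalog("S", "T0", list(cat)[::-1])
        assert apply_filters(cat, cfg).keys() == apply_filters(reversed_cat, cfg).keys()
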