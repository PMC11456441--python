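"""Exclusivity screening, prevalence, category summaries, set overlap."""

import numpy as np
import pytest

from conftest import build_matrix
from harmburden.data_model import VariantRecord, load_default_catalog
from harmburden.screens import (
    FAMILY_ZERO_GROUPS,
    ExclusivityPolicy,
    carrier_prevalence,
    category_summary,
    cross_reference,
    exclusivity_screen,
    exclusivity_screen_counts,
    load_exclusive_variant_fixture,
    load_susceptibility_catalog,
    set_overlap,
)


def _records(matrix, gene="IGF1R"):
    out = []
    for vid in matrix.variant_ids:
        chrom, pos, ref, alt = vid.split(":")
        out.append(VariantRecord(vid, chrom, int(pos), ref, alt, gene))
    return out


class TestExclusivityScreen:
    def test_control_carrier_excluded(self):
        m = build_matrix([[1, 1]], [[0, 1]])
        recs = _records(m)
        rep = exclusivity_screen(m, recs, m.variant_ids)
        assert rep.rows.variant_id.tolist() == [m.variant_ids[0]]

    def test_family_policy_excludes_parent_carriers(self):
        m = build_matrix(
            [[1, 1]], [[0, 0]], extra_groups=[("father", [[0, 1]]), ("mother", [[0, 0]]),
                                              ("sibling", [[0, 0]])]
        )
        recs = _records(m)
        rep = exclusivity_screen(
            m, recs, m.variant_ids, ExclusivityPolicy(zero_groups=FAMILY_ZERO_GROUPS)
        )
        assert rep.rows.variant_id.tolist() == [m.variant_ids[0]]

    def test_policy_naming_absent_group_errors(self):
        m = build_matrix([[1]], [[0]])
        with pytest.raises(ValueError, match="sibling"):
            exclusivity_screen(
                m, _records(m), m.variant_ids,
                ExclusivityPolicy(zero_groups=("control", "sibling")),
            )

    def test_output_subset_and_order_invariant(self):
        m = build_matrix([[1, 0, 1]], [[0, 0, 0]])
        recs = _records(m)
        fwd = exclusivity_screen(m, recs, m.variant_ids)
        rev = exclusivity_screen(m, recs, list(reversed(m.variant_ids)))
        assert fwd.rows.variant_id.tolist() == rev.rows.variant_id.tolist()
        assert set(fwd.rows.variant_id) <= set(m.variant_ids)


class TestFixtureReplay:
    def test_full_fixture_retains_16_rows(self):
        df = load_exclusive_variant_fixture()
        out = exclusivity_screen_counts(df, ["n_han_asd", "n_spark_asd"])
        assert len(out) == 16

    def test_igf1r_spark_subset_is_9(self):
        df = load_exclusive_variant_fixture()
        out = exclusivity_screen_counts(df, ["n_spark_asd"], gene="IGF1R")
        assert len(out) == 9

    def test_absent_count_column_errors(self):
        df = load_exclusive_variant_fixture()
        with pytest.raises(ValueError):
            exclusivity_screen_counts(df, ["n_missing_cohort"])


class TestCarrierPrevalence:
    def test_hand_counted_fractions(self):
        case = [[1]] * 4 + [[0]] * 12
        control = [[1]] * 2 + [[0]] * 18
        m = build_matrix(case, control)
        prev, p = carrier_prevalence(m, m.variant_ids)
        assert prev["case"] == pytest.approx(0.25)
        assert prev["control"] == pytest.approx(0.10)

    def test_identical_groups_not_significant(self):
        rows = [[1]] * 3 + [[0]] * 7
        m = build_matrix(rows, rows)
        _, p = carrier_prevalence(m, m.variant_ids)
        assert p >= 0.5

    def test_empty_qualifying_set(self, toy_matrix):
        prev, p = carrier_prevalence(toy_matrix, [])
        assert all(v == 0.0 for v in prev.values()) and p == 1.0


class TestCategorySummary:
    def test_pathway_proportions(self):
        catalog = load_default_catalog()
        reps = {"IGFBPs": "IGFBP5", "IGFs": "IGF1", "IGF-Rs": "IGF1R",
                "PI3K/AKT": "AKT1", "MAPK": "MAP2K2"}
        counts = {"IGFBPs": 3, "IGFs": 2, "IGF-Rs": 13, "PI3K/AKT": 4, "MAPK": 4}
        variants = []
        i = 0
        for cat, n in counts.items():
            for _ in range(n):
                i += 1
                variants.append(VariantRecord.build("chr1", i, "A", "G", reps[cat]))
        summary = category_summary(variants, catalog)
        assert summary.counts == counts
        assert summary.percentages == {
            "IGFBPs": 11.5, "IGFs": 7.7, "IGF-Rs": 50.0, "PI3K/AKT": 15.4, "MAPK": 15.4,
        }
        assert sum(summary.percentages.values()) == pytest.approx(100, abs=0.2)

    def test_single_variant_is_100(self):
        catalog = load_default_catalog()
        s = category_summary([VariantRecord.build("chr1", 1, "A", "G", "IGF2")], catalog)
        assert s.percentages == {"IGFs": 100.0}

    def test_empty_input_no_division(self):
        s = category_summary([], load_default_catalog())
        assert s.counts == {} and s.total == 0

    def test_unknown_gene_errors(self):
        with pytest.raises(KeyError, match="BRCA1"):
            category_summary(
                [VariantRecord.build("chr1", 1, "A", "G", "BRCA1")], load_default_catalog()
            )

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        catalog = load_default_catalog()
        symbols = list(catalog)
        for trial in range(20):
            variants = [
                VariantRecord.build("chr1", i + 1, "A", "G", rng.choice(symbols))
                for i in range(rng.integers(1, 40))
            ]
            s = category_summary(variants, catalog)
            assert sum(s.percentages.values()) == pytest.approx(100, abs=0.2)


class TestSetOverlap:
    def test_knockout_overlap_counts(self):
        a = {f"g{i}" for i in range(161)}
        b = {f"g{i}" for i in range(74, 182)}
        s = set_overlap(a, b)
        assert (s.size_a, s.size_b, s.size_intersection) == (161, 108, 87)
        assert s.pct_of_b == pytest.approx(80.6, abs=0.1)

    def test_disjoint_p_is_one(self):
        s = set_overlap({"A"}, {"B"}, universe=10)
        assert s.size_intersection == 0 and s.hypergeometric_p == pytest.approx(1.0)

    def test_identical_sets(self):
        s = set_overlap({"a", "b"}, {"A", "B"})
        assert s.pct_of_a == s.pct_of_b == 100.0

    def test_symmetry(self):
        a, b = {"x", "y", "z"}, {"y", "z", "w", "v"}
        ab, ba = set_overlap(a, b), set_overlap(b, a)
        assert (ab.size_a, ab.size_b) == (ba.size_b, ba.size_a)
        assert (ab.pct_of_a, ab.pct_of_b) == (ba.pct_of_b, ba.pct_of_a)

    def test_universe_smaller_than_union_errors(self):
        with pytest.raises(ValueError):
            set_overlap({"a", "b"}, {"c"}, universe=2)


class TestCrossReference:
    def test_catalog_self_query_matches_all_18(self):
        cat = load_susceptibility_catalog()
        out = cross_reference(cat.gene, cat)
        assert len(out) == 18

    def test_no_overlap_empty(self):
        cat = load_susceptibility_catalog()
        assert len(cross_reference({"NOTAGENE"}, cat)) == 0

    def test_case_insensitive(self):
        cat = load_susceptibility_catalog()
        out = cross_reference({"nlgn1"}, cat)
        assert out.gene.tolist() == ["NLGN1"]
        assert out.sfari_score.tolist() == ["2"]
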