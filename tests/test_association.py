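"""Burden testing, Fisher association and multiple-testing correction."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_matrix
from harmburden.association import (
    ContingencyTable,
    adjust_pvalues,
    burden_test,
    carrier_table,
    fisher_one_tailed,
    individual_burden,
    run_association,
    select_burden_test,
)
from harmburden.data_model import MISSING


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(table: ContingencyTable) -> float:
    """P(X >= case_carriers) by exact rational enumeration of the
    hypergeometric pmf with fixed margins."""
    N, K, n = table.total, table.case_carriers + table.control_carriers, table.n_cases
    lo = max(0, K + n - N)
    hi = min(K, n)
    total = Fraction(0)
    for k in range(max(table.case_carriers, lo), hi + 1):
        total += Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))
    return float(min(total, Fraction(1)))


def bh_stepup_oracle(ps):
    """Hand step-up: sort, multiply by m/rank, enforce monotonicity, cap at 1."""
    ps = np.asarray(ps, dtype=float)
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, ps[idx] * m / rank)
        adj[idx] = min(running, 1.0)
    return adj


# ---------------------------------------------------------------------------
# individual burden
# ---------------------------------------------------------------------------

class TestIndividualBurden:
    def test_modes(self):
        m = build_matrix([[1, 2, 0]], [[0, 0, 0]])
        assert individual_burden(m, m.variant_ids, "variants")[0] == 2
        assert individual_burden(m, m.variant_ids, "alleles")[0] == 3

    def test_empty_qualifying_set(self, toy_matrix):
        assert individual_burden(toy_matrix, []).tolist() == [0] * 6

    def test_missing_counts_zero(self):
        m = build_matrix([[MISSING, 1]], [[0, 0]])
        assert individual_burden(m, m.variant_ids)[0] == 1

    def test_unknown_variant_errors(self, toy_matrix):
        with pytest.raises(KeyError):
            individual_burden(toy_matrix, ["chr9:9:A:G"])

    def test_planted_mean_shift_recovered(self):
        # cases get delta extra qualifying carriers on average
        rng = np.random.default_rng(5)
        n, nv, delta = 500, 40, 1.5
        base = (rng.random((2 * n, nv)) < 0.02).astype(np.int8)
        extra = rng.random((n, nv)) < delta / nv
        case = np.clip(base[:n] + extra, 0, 2)
        m = build_matrix(case.tolist(), base[n:].tolist())
        b = individual_burden(m, m.variant_ids)
        diff = b[: n].mean() - b[n:].mean()
        # Monte-Carlo error ~ sqrt(2 * var / n) ~ 0.09 at these sizes
        assert diff == pytest.approx(delta * (1 - 0.02), abs=0.3)


# ---------------------------------------------------------------------------
# adaptive test selection
# ---------------------------------------------------------------------------

class TestSelection:
    @staticmethod
    def _normal(rng, n, sd=1.0):
        return rng.normal(10, sd, n)

    def test_normal_equal_variances_student(self):
        rng = np.random.default_rng(1)
        sel = select_burden_test(self._normal(rng, 80), self._normal(rng, 80))
        assert sel.chosen == "student_t"
        assert sel.normality_p_case > 0.05 and sel.variance_p > 0.05

    def test_normal_unequal_variances_welch(self):
        rng = np.random.default_rng(2)
        sel = select_burden_test(self._normal(rng, 80, 1.0), self._normal(rng, 80, 5.0))
        assert sel.chosen == "welch_t"

    def test_nonnormal_mann_whitney(self):
        rng = np.random.default_rng(3)
        sel = select_burden_test(rng.exponential(1, 100), self._normal(rng, 100))
        assert sel.chosen == "mann_whitney"

    def test_degenerate_zero_variance(self):
        sel = select_burden_test([1, 1, 1, 1], [1, 1, 1, 1])
        assert sel.chosen == "mann_whitney"

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            select_burden_test([1, 2], [1, 2, 3])


class TestBurdenTest:
    def test_identical_groups_no_evidence(self):
        x = [1, 2, 3, 4, 5, 6, 7, 8]
        res = burden_test(x, x)
        assert res.p_one_tailed >= 0.5

    def test_large_shift_detected(self):
        rng = np.random.default_rng(7)
        control = rng.normal(0, 1, 50)
        res = burden_test(control + 3.0, control)
        assert res.p_one_tailed < 0.001

    def test_all_tied_p_is_one(self):
        res = burden_test([2, 2, 2, 2], [2, 2, 2, 2])
        assert res.p_one_tailed == 1.0
        assert res.selection.chosen == "mann_whitney"

    def test_direction_is_cases_greater(self):
        rng = np.random.default_rng(8)
        control = rng.normal(0, 1, 50)
        res = burden_test(control - 3.0, control)
        assert res.p_one_tailed > 0.999


# ---------------------------------------------------------------------------
# carrier tables and Fisher
# ---------------------------------------------------------------------------

class TestCarrierTable:
    def test_variant_level(self):
        m = build_matrix([[1], [0], [0]], [[0], [0], [0]])
        t = carrier_table(m, m.variant_ids)
        assert (t.case_carriers, t.case_noncarriers, t.control_carriers,
                t.control_noncarriers) == (1, 2, 0, 3)

    def test_gene_collapsing_counts_once(self):
        m = build_matrix([[1, 1]], [[0, 0]])
        t = carrier_table(m, m.variant_ids, mode="carriers")
        assert t.case_carriers == 1

    def test_empty_unit_errors(self, toy_matrix):
        with pytest.raises(ValueError):
            carrier_table(toy_matrix, [])


class TestFisher:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((0, 5, 0, 7), 1.0),
            ((1, 262, 0, 294), 263 / 557),
            ((5, 5, 0, 10), 3003 / 184756),
        ],
    )
    def test_known_values(self, cells, expected):
        assert fisher_one_tailed(ContingencyTable(*cells)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 0, 3)

    @settings(derandomize=True, max_examples=300)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        assert fisher_one_tailed(t) == pytest.approx(hypergeom_tail_oracle(t), abs=1e-9)


class TestAdjustment:
    def test_bonferroni_by_hand(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bonferroni").tolist() == pytest.approx(
            [0.03, 0.06, 0.09]
        )

    def test_bh_by_hand(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bh").tolist() == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        for method in ("bh", "bonferroni"):
            assert adjust_pvalues([0.2], method).tolist() == [0.2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200), st.randoms())
    def test_bh_oracle_permutation_and_ordering(self, ps, rnd):
        bh = adjust_pvalues(ps, "bh")
        assert bh == pytest.approx(bh_stepup_oracle(ps), abs=1e-12)
        assert np.all(bh <= adjust_pvalues(ps, "bonferroni") + 1e-15)
        assert np.all(bh <= 1.0)
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        bh_perm = adjust_pvalues([ps[i] for i in perm], "bh")
        assert bh_perm == pytest.approx([bh[i] for i in perm], abs=1e-12)


# ---------------------------------------------------------------------------
# run_association
# ---------------------------------------------------------------------------

class TestRunAssociation:
    def test_single_unit_adjustments_equal_raw(self):
        m = build_matrix([[1], [0]], [[1], [0]])
        gene_of = {m.variant_ids[0]: "IGF1R"}
        (res,) = run_association(m, gene_of, level="variant")
        assert res.p_bh == res.p_bonf == res.p_fisher

    def test_gene_collapse_beats_single_variants_on_disjoint_carriers(self):
        # two case-exclusive variants of one gene with disjoint carriers
        case = [[1, 0], [0, 1], [0, 0], [0, 0]]
        control = [[0, 0]] * 4
        m = build_matrix(case, control)
        gene_of = {v: "IGF1R" for v in m.variant_ids}
        variant_res = run_association(m, gene_of, level="variant")
        (gene_res,) = run_association(m, gene_of, level="gene")
        assert gene_res.p_fisher < min(r.p_fisher for r in variant_res)

    def test_empty_input(self, toy_matrix):
        assert run_association(toy_matrix, {}, level="variant", qualifying_variants=[]) == []

    def test_planted_enrichment_ranks_first(self):
        """A strongly enriched variant attains the minimum adjusted p among
        nulls in nearly every replicate."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep, n_case, n_control, nv = 60, 150, 150, 20
        for _ in range(n_rep):
            geno = (rng.random((n_case + n_control, nv)) < 0.01).astype(np.int8)
            carriers = rng.choice(n_case, size=12, replace=False)
            geno[carriers, 0] = 1
            m = build_matrix(geno[:n_case].tolist(), geno[n_case:].tolist())
            res = run_association(m, {v: "G" for v in m.variant_ids}, level="variant")
            best = min(res, key=lambda r: r.p_bh)
            hits += best.unit_id == m.variant_ids[0]
        assert hits / n_rep >= 0.9

    def test_power_nondecreasing_in_carrier_count(self):
        """More planted case carriers never makes the enrichment p larger."""
        n_case = n_control = 200
        ps = []
        for k in (4, 8, 16):
            t = ContingencyTable(k, n_case - k, 0, n_control)
            ps.append(fisher_one_tailed(t))
        assert ps[0] > ps[1] > ps[2]
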