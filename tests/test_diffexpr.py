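"""Rank-sum DE vs exact enumeration, BH, hypergeometric tails, consensus rule."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from mpkit.diffexpr import (
    DiffExprError,
    bh_adjust,
    consensus_counts,
    consensus_malignancy,
    hypergeom_enrich,
    wilcoxon_deg,
)


def exact_rank_sum_p(a, b):
    """Enumerate all C(na+nb, na) group assignments; two-sided p as twice the
    smaller tail of the U distribution (capped at 1), matching the exact test."""
    from scipy.stats import rankdata

    pooled = np.array(list(a) + list(b), dtype=float)
    na = len(a)
    n = len(pooled)
    ranks = rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2

    us = []
    for idx in combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        us.append(u)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def deg_matrix(a_values, b_values):
    """One-gene matrix whose cells split into groups A and B."""
    values = np.array(list(a_values) + list(b_values), dtype=float).reshape(1, -1)
    m = make_matrix(values)
    ga = [f"c{i}" for i in range(len(a_values))]
    gb = [f"c{i}" for i in range(len(a_values), len(a_values) + len(b_values))]
    return m, ga, gb


class TestWilcoxon:
    @pytest.mark.parametrize(
        "a, b",
        [
            ((1, 2, 3), (4, 5, 6)),        # fully separated, 20 arrangements
            ((1, 4, 2, 7), (3, 5, 6)),     # interleaved
            ((10, 3, 8, 1), (2, 9, 5, 6)), # larger, still exact
            ((1, 2, 7, 8, 3), (4, 5, 6, 9)),
        ],
    )
    def test_matches_exact_enumeration(self, a, b):
        m, ga, gb = deg_matrix(a, b)
        res = wilcoxon_deg(m, ga, gb)[0]
        u, p = exact_rank_sum_p(a, b)
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p)

    def test_separated_triples_give_p_point_one(self):
        """(1,2,3) vs (4,5,6): the 2 extreme arrangements out of 20 → p = 0.1."""
        m, ga, gb = deg_matrix((1, 2, 3), (4, 5, 6))
        res = wilcoxon_deg(m, ga, gb)[0]
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_are_null(self):
        m, ga, gb = deg_matrix((1, 2, 3, 4), (4, 3, 2, 1))
        res = wilcoxon_deg(m, ga, gb)[0]
        assert res.p_value == pytest.approx(1.0)
        assert res.log_fold_change == pytest.approx(0.0)

    def test_label_swap_reflects_statistic(self):
        a, b = (1, 5, 3, 9), (2, 8, 7, 4)
        m, ga, gb = deg_matrix(a, b)
        r_ab = wilcoxon_deg(m, ga, gb)[0]
        r_ba = wilcoxon_deg(m, gb, ga)[0]
        assert r_ab.p_value == pytest.approx(r_ba.p_value)
        assert r_ab.statistic == pytest.approx(len(a) * len(b) - r_ba.statistic)

    def test_constant_gene_p_is_one(self):
        m, ga, gb = deg_matrix((2, 2, 2), (2, 2, 2))
        assert wilcoxon_deg(m, ga, gb)[0].p_value == 1.0

    def test_overlapping_groups_error(self):
        m, ga, gb = deg_matrix((1, 2, 3), (4, 5, 6))
        with pytest.raises(DiffExprError, match="overlap"):
            wilcoxon_deg(m, ga, ga)

    def test_small_groups_error(self):
        m, ga, gb = deg_matrix((1, 2), (4, 5, 6))
        with pytest.raises(DiffExprError, match="at least 3"):
            wilcoxon_deg(m, ga[:2], gb)

    def test_ties_fall_back_to_corrected_normal_close_to_enumeration(self):
        a, b = (1, 1, 2, 5, 3), (2, 2, 4, 5)
        m, ga, gb = deg_matrix(a, b)
        res = wilcoxon_deg(m, ga, gb)[0]
        _, p_exact = exact_rank_sum_p(a, b)
        assert res.p_value == pytest.approx(p_exact, abs=0.12)


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.04] * 5), [0.04] * 5)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        fdr = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()
        assert (fdr >= p).all()

    def test_out_of_range_errors(self):
        with pytest.raises(DiffExprError):
            bh_adjust([0.5, 1.5])


class TestHypergeom:
    def test_full_overlap_closed_form(self):
        """All 5 of 5 drawn from a 5-gene term in a 20-gene universe: 1/C(20,5)."""
        universe = [f"g{i}" for i in range(20)]
        term = set(universe[:5])
        res = hypergeom_enrich(universe[:5], {"t": term}, universe)[0]
        assert res.p_value == pytest.approx(1 / comb(20, 5))
        assert res.overlap_count == 5

    def test_zero_overlap_is_not_enriched(self):
        universe = [f"g{i}" for i in range(50)]
        res = hypergeom_enrich(universe[:10], {"t": set(universe[45:])}, universe)[0]
        assert res.p_value > 0.5

    def test_term_equal_to_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(15)]
        res = hypergeom_enrich(universe[:4], {"t": set(universe)}, universe)[0]
        assert res.p_value == pytest.approx(1.0)

    def test_matches_direct_tail_summation(self):
        N, K, n = 30, 8, 10
        universe = [f"g{i}" for i in range(N)]
        term = set(universe[:K])
        query = universe[:4] + universe[K:K + (n - 4)]  # overlap k = 4
        res = hypergeom_enrich(query, {"t": term}, universe)[0]
        tail = sum(
            comb(K, k) * comb(N - K, n - k) / comb(N, n)
            for k in range(4, min(K, n) + 1)
        )
        assert res.p_value == pytest.approx(tail)

    def test_upper_tail_from_zero_is_one(self):
        universe = [f"g{i}" for i in range(12)]
        res = hypergeom_enrich([], {"t": set(universe[:3])}, universe)
        assert res[0].p_value == pytest.approx(1.0)

    def test_query_outside_universe_warned_and_dropped(self):
        universe = [f"g{i}" for i in range(10)]
        with pytest.warns(UserWarning, match="outside universe"):
            res = hypergeom_enrich(universe[:3] + ["alien"],
                                   {"t": set(universe[:3])}, universe)[0]
        assert res.query_size == 3

    def test_empty_universe_errors(self):
        with pytest.raises(DiffExprError, match="universe"):
            hypergeom_enrich(["g1"], {"t": {"g1"}}, [])


class TestConsensus:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("malignant", "malignant", "malignant"),
            ("nonmalignant", "nonmalignant", "nonmalignant"),
            ("malignant", "nonmalignant", "ambiguous"),
            ("nonmalignant", "malignant", "ambiguous"),
            ("uncallable", "malignant", "ambiguous"),
            ("malignant", "uncallable", "ambiguous"),
            ("uncallable", "uncallable", "ambiguous"),
        ],
    )
    def test_intersection_rule(self, a, b, expected):
        calls_a = pd.Series([a], index=["c1"])
        calls_b = pd.Series([b], index=["c1"])
        assert consensus_malignancy(calls_a, calls_b)[0].consensus == expected

    def test_counts_partition_all_cells(self):
        rng = np.random.default_rng(1)
        ids = [f"c{i}" for i in range(200)]
        opts = ["malignant", "nonmalignant", "uncallable"]
        calls_a = pd.Series(rng.choice(opts, 200), index=ids)
        calls_b = pd.Series(rng.choice(opts, 200), index=ids)
        labels = consensus_malignancy(calls_a, calls_b)
        assert sum(consensus_counts(labels).values()) == 200

    def test_mismatched_cells_error_lists_ids(self):
        calls_a = pd.Series(["malignant"], index=["c1"])
        calls_b = pd.Series(["malignant"], index=["c2"])
        with pytest.raises(DiffExprError, match="c1"):
            consensus_malignancy(calls_a, calls_b)

    def test_invalid_call_rejected(self):
        calls = pd.Series(["tumourish"], index=["c1"])
        with pytest.raises(DiffExprError, match="invalid call"):
            consensus_malignancy(calls, calls)
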