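from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from callseq.markov import (
    TransitionTable,
    build_transitions,
    chi_square_mc,
    expected_counts,
    filter_min_count,
    possible_transition_count,
    posthoc_residuals,
)
from callseq.records import ParameterError, DegenerateTableError

from conftest import make_call


def table_from_counts(counts, categories=None):
    counts = np.asarray(counts)
    if categories is None:
        categories = [f"c{i}" for i in range(counts.shape[0])]
    return TransitionTable(categories=list(categories), counts=counts)


class TestBuildTransitions:
    def test_hand_trace_of_gate(self):
        # A -(0.5)- A -(2.0)- B -(1.0)- B with bci=1.72 -> A->A and B->B only
        calls = {"t1": [
            make_call("a1", 0.0, 1.0, "A"),
            make_call("a2", 1.5, 2.5, "A"),
            make_call("b1", 4.5, 5.5, "B"),
            make_call("b2", 6.5, 7.5, "B"),
        ]}
        table = build_transitions(calls, bci_s=1.72)
        assert table.n_total == 2
        pairs = {(e.from_cat, e.to_cat) for e in table.events}
        assert pairs == {("A", "A"), ("B", "B")}
        # event is timestamped by the first call of the pair
        assert {e.time_s for e in table.events} == {0.0, 4.5}

    def test_no_cross_tag_transitions(self):
        calls = {
            "t1": [make_call("a", 0, 1, "A")],
            "t2": [make_call("b", 1.1, 2, "B", tag_id="t2")],
        }
        table = build_transitions(calls, bci_s=5.0)
        assert table.n_total == 0

    def test_empty_gate(self):
        calls = {"t1": [make_call("a", 0, 1, "A"), make_call("b", 10, 11, "B")]}
        table = build_transitions(calls, bci_s=1.72)
        assert table.n_total == 0
        assert table.categories == []

    def test_bci_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            build_transitions({"t1": []}, bci_s=0.0)

    def test_axis_is_square_and_covers_events(self):
        calls = {"t1": [
            make_call("a", 0, 1, "A"),
            make_call("b", 1.2, 2, "B"),
            make_call("c", 2.1, 3, "C"),
        ]}
        table = build_transitions(calls, bci_s=1.0)
        assert table.categories == ["A", "B", "C"]
        assert table.counts.shape == (3, 3)

    def test_variable_excluded(self):
        calls = {"t1": [
            make_call("a", 0, 1, "A"),
            make_call("v", 1.2, 1.6, "VARIABLE"),
            make_call("b", 1.8, 2.5, "B"),
        ]}
        table = build_transitions(calls, bci_s=1.0)
        assert [(e.from_cat, e.to_cat) for e in table.events] == [("A", "B")]


class TestExpectedCounts:
    def test_symmetric_margins(self):
        e = expected_counts(table_from_counts([[10, 0], [0, 10]]))
        np.testing.assert_allclose(e, 5.0)

    def test_conserves_total(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(5, 5))
        table = table_from_counts(counts)
        assert expected_counts(table).sum() == pytest.approx(table.n_total)

    def test_matches_bruteforce_margin_products(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 30, size=(3, 3))
        table = table_from_counts(counts)
        e = expected_counts(table)
        n = counts.sum()
        for i in range(3):
            for j in range(3):
                assert e[i, j] == pytest.approx(
                    counts[i].sum() * counts[:, j].sum() / n, abs=1e-12
                )


class TestChiSquareMc:
    def test_diagonal_2x2(self):
        res = chi_square_mc(table_from_counts([[10, 0], [0, 10]]),
                            n_sim=200, seed=0)
        assert res.statistic == pytest.approx(20.0, abs=1e-9)

    def test_null_table(self):
        res = chi_square_mc(table_from_counts([[4, 4], [4, 4]]),
                            n_sim=500, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_mc > 0.99

    def test_statistic_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            counts = rng.integers(0, 15, size=(4, 4))
            if counts.sum() == 0:
                continue
            table = table_from_counts(counts)
            try:
                res = chi_square_mc(table, n_sim=1, seed=0)
            except DegenerateTableError:
                continue
            e = expected_counts(table)
            brute = 0.0
            for i in range(4):
                for j in range(4):
                    if e[i, j] > 0:
                        brute += (counts[i, j] - e[i, j]) ** 2 / e[i, j]
            assert res.statistic == pytest.approx(brute, abs=1e-9)

    def test_null_tables_preserve_margins(self):
        counts = np.array([[8, 2, 0], [1, 5, 4], [0, 3, 7]])
        rows, cols = counts.sum(axis=1), counts.sum(axis=0)
        sampler = stats.random_table(rows, cols)
        sims = sampler.rvs(200, method="patefield",
                           random_state=np.random.default_rng(0))
        np.testing.assert_array_equal(sims.sum(axis=2),
                                      np.tile(rows, (200, 1)))
        np.testing.assert_array_equal(sims.sum(axis=1),
                                      np.tile(cols, (200, 1)))

    def test_p_never_zero(self):
        res = chi_square_mc(table_from_counts([[50, 0], [0, 50]]),
                            n_sim=100, seed=1)
        assert res.p_mc == pytest.approx(1 / 101)

    def test_seed_reproducible(self):
        table = table_from_counts([[9, 3], [2, 8]])
        a = chi_square_mc(table, n_sim=300, seed=5)
        b = chi_square_mc(table, n_sim=300, seed=5)
        assert a.p_mc == b.p_mc

    def test_degenerate_margins_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_mc(table_from_counts([[5, 5], [0, 0]]), n_sim=10, seed=0)

    def test_multinomial_null_available(self):
        table = table_from_counts([[9, 3], [2, 8]])
        res = chi_square_mc(table, n_sim=300, seed=5, null="multinomial")
        assert 0 < res.p_mc <= 1

    def test_matches_exact_enumeration_2x2(self):
        # For a 2x2 table with both margins fixed the null is hypergeometric;
        # enumerate it exactly and check the MC p within a binomial 99% CI.
        counts = np.array([[7, 3], [2, 8]])
        table = table_from_counts(counts)
        e = expected_counts(table)
        obs = ((counts - e) ** 2 / e).sum()

        r1, c1, n = counts[0].sum(), counts[:, 0].sum(), counts.sum()
        p_exact = 0.0
        for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
            t = np.array([[a, r1 - a], [c1 - a, n - r1 - c1 + a]])
            stat = ((t - e) ** 2 / e).sum()
            if stat >= obs - 1e-12:
                p_exact += stats.hypergeom.pmf(a, n, r1, c1)

        n_sim = 2000
        res = chi_square_mc(table, n_sim=n_sim, seed=42)
        se = math.sqrt(p_exact * (1 - p_exact) / n_sim)
        assert abs(res.p_mc - p_exact) < 2.58 * se + 1 / n_sim


class TestPosthocResiduals:
    def test_null_table_all_zero(self):
        cells = posthoc_residuals(table_from_counts([[4, 4], [4, 4]]))
        assert all(c.residual == pytest.approx(0.0, abs=1e-12) for c in cells)
        assert not any(c.significant_over for c in cells)

    def test_diagonal_2x2_formula_oracle(self):
        # independent evaluation of the margin-adjusted residual for
        # [[30,0],[0,30]]: n=60, E=15, denom=15*(1-0.5)*(1-0.5)=3.75
        cells = posthoc_residuals(table_from_counts([[30, 0], [0, 30]],
                                                    ["A", "B"]))
        z_expect = 15.0 / math.sqrt(3.75)
        by_pair = {(c.from_cat, c.to_cat): c for c in cells}
        aa = by_pair[("A", "A")]
        assert aa.residual == pytest.approx(z_expect, abs=1e-12)
        assert aa.direction == "over"
        assert aa.significant_over
        ab = by_pair[("A", "B")]
        assert ab.residual == pytest.approx(-z_expect, abs=1e-12)
        assert ab.direction == "under"
        assert not ab.significant_over

    def test_bonferroni_family_is_c_squared(self):
        cells = posthoc_residuals(table_from_counts([[30, 0], [0, 30]]))
        for c in cells:
            assert c.p_adj == pytest.approx(min(1.0, c.p_raw * 4))

    def test_custom_family_size(self):
        cells = posthoc_residuals(table_from_counts([[30, 0], [0, 30]]),
                                  family_size=100)
        for c in cells:
            assert c.p_adj == pytest.approx(min(1.0, c.p_raw * 100))

    def test_zero_expectation_cells_excluded(self):
        # category appearing only as a target: its row margin is 0
        counts = np.array([[5, 5, 2], [4, 6, 3], [0, 0, 0]])
        cells = posthoc_residuals(table_from_counts(counts))
        pairs = {(c.from_cat, c.to_cat) for c in cells}
        assert all(a != "c2" for a, _ in pairs)


class TestFilterMinCount:
    def test_boundary_strict(self):
        cells = posthoc_residuals(table_from_counts([[11, 10], [10, 11]]))
        kept = filter_min_count(cells, min_count=10)
        assert {c.observed for c in kept} == {11}

    def test_empty_input(self):
        assert filter_min_count([]) == []


def test_possible_transition_count():
    labels = [f"I{i}" for i in range(62)]
    assert possible_transition_count(labels) == 3844
    assert possible_transition_count(["A", "A", "B"]) == 4  # dedup
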