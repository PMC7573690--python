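"""Synthetic proteome and network generators: determinism, convergence to the
specified state weights, degree-sequence structure, stub matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligodist.errors import InvalidParameterError
from oligodist.synthetic import (
    NetworkSimParams,
    ProteomeSimParams,
    assign_categories,
    generate_degree_sequence,
    generate_proteome,
    oligomer_state_weights,
    realize_edges,
)


class TestProteome:
    def test_empty(self):
        assert generate_proteome(ProteomeSimParams(n_proteins=0)) == []

    def test_invalid_params(self):
        with pytest.raises(InvalidParameterError):
            ProteomeSimParams(n_proteins=-1)
        with pytest.raises(InvalidParameterError):
            ProteomeSimParams(n_proteins=10, known_fraction=1.5)
        with pytest.raises(InvalidParameterError):
            ProteomeSimParams(n_proteins=10, k_support=(3, 2))

    def test_seed_determinism(self):
        p = ProteomeSimParams(n_proteins=500, seed=7)
        assert generate_proteome(p) == generate_proteome(p)

    def test_even_only_frequencies_match_multinomial(self):
        """With known_fraction=1, rho=0, no monomers, support {2,4,6,8}, the
        empirical f_s(2) is within 3 binomial SEs of 4/7."""
        n = 50_000
        params = ProteomeSimParams(
            n_proteins=n, known_fraction=1.0, odd_suppression=0.0,
            monomer_weight=0.0, k_support=(2, 4, 6, 8), seed=42,
        )
        records = generate_proteome(params)
        p_true = 4 / 7
        f2 = sum(r.oligomer_k == 2 for r in records) / n
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(f2 - p_true) < 3 * se

    def test_total_variation_convergence(self):
        """With full annotation and rho=1, empirical frequencies converge to
        the normalized weights (TV < 0.02 at n=100 000)."""
        params = ProteomeSimParams(
            n_proteins=100_000, known_fraction=1.0, odd_suppression=1.0, seed=11,
        )
        records = generate_proteome(params)
        weights = oligomer_state_weights(params)
        n = len(records)
        emp = {k: sum(r.oligomer_k == k for r in records) / n for k in weights}
        tv = 0.5 * sum(abs(emp[k] - weights[k]) for k in weights)
        assert tv < 0.02

    def test_known_fraction_and_lengths(self):
        params = ProteomeSimParams(n_proteins=20_000, known_fraction=0.3, seed=3)
        records = generate_proteome(params)
        share = sum(r.oligomer_k is not None for r in records) / len(records)
        assert share == pytest.approx(0.3, abs=0.02)
        lengths = np.array([r.length_aa for r in records])
        assert lengths.min() >= 1
        assert lengths.mean() == pytest.approx(270, rel=0.05)


class TestDegreeSequence:
    def test_truncation_boundary(self):
        params = NetworkSimParams(
            n_nodes=10_000, gamma=2.5, k_min=5, head_mean=0.0, tail_fraction=1.0,
            seed=1,
        )
        degrees = generate_degree_sequence(params)
        assert degrees.min() == 5
        assert degrees.sum() % 2 == 0

    def test_seed_determinism(self):
        p = NetworkSimParams(n_nodes=1000, seed=9)
        assert np.array_equal(generate_degree_sequence(p), generate_degree_sequence(p))

    def test_invalid_gamma(self):
        with pytest.raises(InvalidParameterError):
            NetworkSimParams(n_nodes=10, gamma=1.0)

    def test_tail_mean_matches_zeta_ratio(self):
        """At gamma=3, k_min=1 the tail mean is zeta(2)/zeta(3); the oracle is
        direct summation of k * k^-3 / sum k^-3."""
        ks = np.arange(1, 10_001, dtype=float)
        oracle = np.sum(ks * ks**-3) / np.sum(ks**-3)  # ~1.3684 up to truncation
        params = NetworkSimParams(
            n_nodes=10_000, gamma=3.0, k_min=1, head_mean=0.0, tail_fraction=1.0,
            k_max=10_000, seed=21,
        )
        degrees = generate_degree_sequence(params).astype(float)
        # correct the forced-even +1 on one entry before comparing means
        se = degrees.std() / np.sqrt(degrees.size)
        assert abs(degrees.mean() - oracle) < 3 * se
        assert oracle == pytest.approx(1.3684, abs=1e-3)


class TestRealizeEdges:
    def test_two_stubs_single_edge(self):
        g = realize_edges([1, 1], seed=0)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1

    def test_triangle_unique_realization(self):
        g = realize_edges([2, 2, 2], seed=0)
        assert g.number_of_edges() == 3
        assert sorted(d for _, d in g.degree()) == [2, 2, 2]

    def test_odd_sum_rejected(self):
        with pytest.raises(InvalidParameterError):
            realize_edges([1, 1, 1])

    def test_degree_multiset_preserved_when_no_discards(self):
        params = NetworkSimParams(n_nodes=300, gamma=3.0, k_min=2, head_mean=1.0,
                                  tail_fraction=0.3, seed=13)
        degrees = generate_degree_sequence(params)
        g = realize_edges(degrees, seed=14)
        if g.graph["discarded_stubs"] == 0:
            realized = np.array([g.degree(i) for i in range(len(degrees))])
            assert np.array_equal(np.sort(realized), np.sort(degrees))

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.integers(0, 6), min_size=2, max_size=40))
    def test_output_always_simple(self, degrees):
        if sum(degrees) % 2 == 1:
            degrees[0] += 1
        g = realize_edges(degrees, seed=0)
        assert all(a != b for a, b in g.edges)
        # degrees never exceed requested
        for node in g.nodes:
            assert g.degree(node) <= degrees[node]


class TestAssignCategories:
    def test_single_category(self, ten_records):
        out = assign_categories(ten_records, {"only": 1.0}, seed=0)
        assert all("only" in r.go_terms for r in out)

    def test_two_equal_weights_balance(self):
        from oligodist.io import ProteinRecord

        records = [ProteinRecord(f"P{i}", length_aa=10) for i in range(20_000)]
        out = assign_categories(records, {"a": 1.0, "b": 1.0}, seed=5)
        share = sum("a" in r.go_terms for r in out) / len(out)
        se = np.sqrt(0.25 / len(out))
        assert abs(share - 0.5) < 3 * se

    def test_seed_determinism(self, ten_records):
        a = assign_categories(ten_records, {"x": 1.0, "y": 2.0}, seed=7)
        b = assign_categories(ten_records, {"x": 1.0, "y": 2.0}, seed=7)
        assert a == b

    def test_empty_weights_rejected(self, ten_records):
        with pytest.raises(InvalidParameterError):
            assign_categories(ten_records, {}, seed=0)
        with pytest.raises(InvalidParameterError):
            assign_categories(ten_records, {"a": 0.0}, seed=0)
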