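"""Correlations, rank ratios, the order-statistic joint CDF and pruning."""

import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, strategies as st

from crossherd.coexpression import (
    build_network,
    build_pair_table,
    joint_cdf,
    pair_count,
    pearson_pairs,
    phenotype_network,
    prune_pairs,
    rank_ratios,
)
from crossherd.preprocess import PhenotypeSet
from conftest import make_matrix


def monte_carlo_joint_cdf(ratios, n_draws, rng):
    """Independent oracle: fraction of uniform samples whose order statistics
    are dominated by the sorted ratios."""
    r = np.sort(np.asarray(ratios))
    draws = np.sort(rng.random((n_draws, r.size)), axis=1)
    return float(np.all(draws <= r, axis=1).mean())


def symbolic_joint_cdf(ratios):
    """Second oracle: literal nested symbolic integration (exact rationals)."""
    r = sorted(sympy.Rational(x) for x in ratios)
    n = len(r)
    s = sympy.symbols(f"s0:{n}")
    expr = sympy.Integer(1)
    for i in range(n - 1, -1, -1):
        lower = 0 if i == 0 else s[i - 1]
        expr = sympy.integrate(expr, (s[i], lower, r[i]))
    return float(sympy.factorial(n) * expr)


class TestPearsonPairs:
    def test_identical_and_negated_profiles(self):
        m = make_matrix([[1.0, 2, 3], [1, 2, 3], [-1, -2, -3]])
        pairs = pearson_pairs(m)
        lookup = {(a, b): r for a, b, r in pairs.itertuples(index=False)}
        assert lookup[("g0", "g1")] == pytest.approx(1.0)
        assert lookup[("g0", "g2")] == pytest.approx(-1.0)

    def test_pair_count_formula(self):
        assert pair_count(7693) == 29587278
        m = make_matrix(np.random.default_rng(0).normal(size=(10, 5)))
        assert len(pearson_pairs(m)) == pair_count(10)

    def test_zero_variance_genes_dropped(self):
        m = make_matrix([[1.0, 2, 3], [5, 5, 5], [3, 1, 2]])
        pairs = pearson_pairs(m)
        genes = set(pairs["gene_a"]) | set(pairs["gene_b"])
        assert "g1" not in genes

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="samples"):
            pearson_pairs(make_matrix([[1.0, 2], [3, 4]]))

    def test_block_size_does_not_change_result(self):
        m = make_matrix(np.random.default_rng(1).normal(size=(30, 8)))
        a = pearson_pairs(m, block_size=4)
        b = pearson_pairs(m, block_size=1024)
        assert np.allclose(a["r"], b["r"])


class TestRankRatios:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.1, 0.5, 0.9], [1 / 3, 2 / 3, 1.0]),
            ([0.4, 0.4], [0.75, 0.75]),
            ([-0.9, 0.1], [1.0, 0.5]),
        ],
    )
    def test_definition_and_tie_rule(self, values, expected):
        assert rank_ratios(np.array(values)) == pytest.approx(expected)

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=50))
    def test_rank_sum_and_range(self, values):
        ratios = rank_ratios(np.array(values))
        n = len(values)
        assert np.all(ratios > 0) and np.all(ratios <= 1)
        # average ranks always sum to n(n+1)/2
        assert ratios.sum() * n == pytest.approx(n * (n + 1) / 2)

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=30, unique_by=abs))
    def test_monotone_in_absolute_value(self, values):
        arr = np.array(values)
        ratios = rank_ratios(arr)
        order = np.argsort(np.abs(arr))
        assert np.all(np.diff(ratios[order]) > 0)


class TestJointCdf:
    @pytest.mark.parametrize(
        "ratios,expected",
        [
            ([0.3], 0.3),
            ([0.5, 0.5], 0.25),
            ([0.2, 0.5, 0.9], 0.290),
            ([1.0, 1.0, 1.0, 1.0], 1.0),
            ([0.0, 0.5], 0.0),
        ],
    )
    def test_exact_values(self, ratios, expected):
        assert joint_cdf(ratios) == pytest.approx(expected, abs=1e-9)

    def test_matches_symbolic_integration(self):
        rng = np.random.default_rng(42)
        for n in (2, 3, 4):
            for _ in range(3):
                # exact dyadic inputs so both routes see the same numbers
                r = rng.integers(1, 1024, size=n) / 1024.0
                assert joint_cdf(r) == pytest.approx(symbolic_joint_cdf(r), abs=1e-9)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        for n in (2, 3):
            r = rng.random(n)
            exact = joint_cdf(r)
            mc = monte_carlo_joint_cdf(r, 200_000, rng)
            se = max(np.sqrt(exact * (1 - exact) / 200_000), 1e-6)
            assert abs(mc - exact) < 4 * se

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=5),
        st.data(),
    )
    def test_monotone_in_each_coordinate(self, ratios, data):
        base = joint_cdf(ratios)
        i = data.draw(st.integers(0, len(ratios) - 1))
        bumped = list(ratios)
        bumped[i] = min(1.0, bumped[i] + data.draw(st.floats(0, 1)))
        assert joint_cdf(bumped) >= base - 1e-12

    def test_input_validation(self):
        with pytest.raises(ValueError):
            joint_cdf([1.2])
        with pytest.raises(ValueError):
            joint_cdf([])
        with pytest.raises(ValueError):
            joint_cdf([0.5] * 11)


class TestPruneAndNetwork:
    @staticmethod
    def _table(rows):
        recs = []
        for i, (r1, r2, r3) in enumerate(rows):
            recs.append(
                {
                    "gene_a": f"a{i}",
                    "gene_b": f"b{i}",
                    "r_d1": r1,
                    "r_d2": r2,
                    "r_d3": r3,
                    "ratio_d1": 0.9,
                    "ratio_d2": 0.9,
                    "ratio_d3": 0.9,
                }
            )
        return pd.DataFrame(recs)

    def test_retention_rules(self):
        table = self._table(
            [(0.6, 0.7, 0.55), (0.6, 0.7, 0.50), (0.9, -0.2, 0.8)]
        )
        kept = prune_pairs(table, threshold=0.5)
        assert list(kept["gene_a"]) == ["a0"]

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        table = self._table(rng.uniform(-1, 1, size=(200, 3)))
        sizes = [len(prune_pairs(table, t)) for t in (0.0, 0.25, 0.5, 0.75)]
        assert sizes == sorted(sizes, reverse=True)

    def test_build_network_shapes(self):
        table = self._table([(0.6, 0.7, 0.55)] * 3)
        table.loc[1, "gene_a"] = "a0"  # reuse a node
        net = build_network(table, "LA")
        assert net.number_of_edges() == 3
        assert net.number_of_nodes() <= 6
        for _, _, data in net.edges(data=True):
            assert {"cor_d1", "cor_d2", "cor_d3", "joint_cdf", "weight"} <= set(data)

    def test_empty_pair_list_gives_empty_network(self):
        net = build_network(self._table([]), "HA")
        assert net.number_of_nodes() == 0 and net.number_of_edges() == 0

    def test_phenotype_network_counts_consistent(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(1, 12))
        shared = np.repeat(base, 6, axis=0) + 0.3 * rng.normal(size=(6, 12))
        noise = rng.normal(size=(14, 12))
        mats = [
            make_matrix(
                np.vstack([shared, noise]) + 0.01 * rng.normal(size=(20, 12)),
                dataset_id=f"d{i}",
            )
            for i in range(2)
        ]
        pset = PhenotypeSet("LA", mats)
        net, counts = phenotype_network(pset, threshold=0.5)
        assert counts["pairs_computed"] == pair_count(20)
        assert counts["pairs_retained"] == net.number_of_edges()
        assert counts["pairs_retained"] <= counts["pairs_computed"]
        # the co-regulated block should be connected in the network
        assert set(f"g{i}" for i in range(6)) <= set(net.nodes)
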