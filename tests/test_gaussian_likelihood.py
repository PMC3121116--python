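import math

import numpy as np
import pytest
from scipy import stats

from netscreen.gaussian_likelihood import (
    factorize,
    fit_node,
    network_log_likelihood,
)
from netscreen.reference_builder import CycleError, RegulatoryNetwork

from conftest import make_single_strain


def net(name, edges, extra_nodes=()):
    nodes = frozenset(n for e in edges for n in e) | frozenset(extra_nodes)
    return RegulatoryNetwork(name, nodes, frozenset(edges))


def random_dag(rng, n):
    """Random DAG over n labelled nodes via a random order."""
    labels = [chr(ord("A") + i) for i in range(n)]
    order = rng.permutation(n)
    edges = [
        (labels[order[i]], labels[order[j]])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < 0.4
    ]
    return labels, edges


class TestFactorize:
    def test_edgeless_network_all_roots(self):
        n = RegulatoryNetwork("S", frozenset("ABC"), frozenset())
        fact = factorize(n)
        assert len(fact) == 3
        assert all(parents == () for _, parents in fact)

    def test_chain_parentage(self):
        n = net("S", [("A", "B"), ("B", "C")])
        fact = dict(factorize(n))
        assert fact == {"A": (), "B": ("A",), "C": ("B",)}

    def test_cyclic_input_raises(self):
        n = net("S", [("A", "B"), ("B", "A")])
        with pytest.raises(CycleError):
            factorize(n)

    def test_random_dags_match_adjacency_oracle(self, rng):
        for _ in range(50):
            labels, edges = random_dag(rng, int(rng.integers(2, 8)))
            if not edges:
                continue
            n = net("S", edges, extra_nodes=labels)
            fact = dict(factorize(n))
            # independent adjacency scan
            for node in labels:
                expected = tuple(sorted(u for u, v in edges if v == node))
                assert fact[node] == expected
            # topological: every parent precedes its child
            order = [node for node, _ in factorize(n)]
            pos = {node: i for i, node in enumerate(order)}
            assert all(pos[u] < pos[v] for u, v in edges)


class TestFitNode:
    def test_root_node_closed_form(self):
        # mean 0, MLE variance 1 on (-1, +1): ll = -(2/2)(ln 2pi + 1)
        factor = fit_node(np.array([-1.0, 1.0]), None)
        expected = -(math.log(2 * math.pi) + 1.0)
        assert factor.log_likelihood == pytest.approx(expected, abs=1e-9)
        assert factor.log_likelihood == pytest.approx(-2.837877, abs=1e-6)
        assert factor.intercept == 0.0
        assert factor.residual_variance == 1.0

    def test_perfect_fit_hits_variance_floor(self):
        x = np.linspace(-1, 1, 6)
        factor = fit_node(x, x[:, None])
        assert math.isfinite(factor.log_likelihood)
        assert factor.residual_variance >= 1e-12
        assert factor.log_likelihood > 0  # floored variance, huge density

    def test_matches_density_evaluation_oracle(self, rng):
        """Contribution equals sum_k ln N(x_k; fitted mean, sigma2hat)."""
        for _ in range(20):
            m, n_i = 20, 3
            X = rng.normal(size=(m, n_i))
            y = X @ rng.normal(size=n_i) + rng.normal(0, 0.5, m)
            factor = fit_node(y, X)
            mean = factor.intercept + X @ np.array(factor.coefficients)
            oracle = stats.norm.logpdf(
                y, loc=mean, scale=math.sqrt(factor.residual_variance)
            ).sum()
            assert factor.log_likelihood == pytest.approx(oracle, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_node(np.array([1.0]), None)

    def test_rank_deficient_design_is_finite(self, rng):
        # more parents than samples: minimum-norm solve, floored variance
        X = rng.normal(size=(4, 6))
        y = rng.normal(size=4)
        factor = fit_node(y, X)
        assert math.isfinite(factor.log_likelihood)


def implied_gaussian_oracle(fit, node_order):
    """Joint N(mu, Sigma) implied by fitted structural equations.

    x = B x + c + e, e ~ N(0, D)  =>  mu = (I-B)^{-1} c,
    Sigma = (I-B)^{-1} D (I-B)^{-T}.
    """
    idx = {n: i for i, n in enumerate(node_order)}
    p = len(node_order)
    B = np.zeros((p, p))
    c = np.zeros(p)
    D = np.zeros((p, p))
    for f in fit.factors:
        i = idx[f.node]
        c[i] = f.intercept
        D[i, i] = f.residual_variance
        for parent, coef in zip(f.parents, f.coefficients):
            B[i, idx[parent]] = coef
    inv = np.linalg.inv(np.eye(p) - B)
    return inv @ c, inv @ D @ inv.T


class TestNetworkLogLikelihood:
    def test_edgeless_decomposition_identity(self, rng):
        genes = ["A", "B", "C"]
        V = rng.normal(size=(3, 8))
        expr = make_single_strain(V, genes)
        n = RegulatoryNetwork("S", frozenset(genes), frozenset())
        fit = network_log_likelihood(n, expr)
        per_gene = 0.0
        for row in V:
            s2 = row.var()
            per_gene += stats.norm.logpdf(row, row.mean(), math.sqrt(s2)).sum()
        assert fit.log_likelihood == pytest.approx(per_gene, abs=1e-9)

    def test_missing_gene_named_in_error(self, rng):
        n = net("S", [("A", "B")])
        expr = make_single_strain(rng.normal(size=(1, 6)), ["A"])
        with pytest.raises(KeyError, match="B"):
            network_log_likelihood(n, expr)

    def test_structure_matching_data_scores_higher(self, rng):
        """A -> B fits better when B really follows A (>= 99/100 seeds)."""
        n = net("S", [("A", "B")])
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = r.normal(size=10)
            b_noise = r.normal(size=10)
            b_signal = 0.9 * a + r.normal(0, 0.3, 10)
            ll_noise = network_log_likelihood(
                n, make_single_strain(np.vstack([a, b_noise]), ["A", "B"])
            ).log_likelihood
            ll_signal = network_log_likelihood(
                n, make_single_strain(np.vstack([a, b_signal]), ["A", "B"])
            ).log_likelihood
            wins += ll_signal > ll_noise
        assert wins >= 99

    def test_chain_matches_multivariate_gaussian_oracle(self):
        """Factorized ll == log-density of the implied joint Gaussian."""
        r = np.random.default_rng(42)
        a = r.normal(size=10)
        b = 0.8 * a + r.normal(0, 0.5, 10)
        c = -0.6 * b + r.normal(0, 0.4, 10)
        V = np.vstack([a, b, c])
        expr = make_single_strain(V, ["A", "B", "C"])
        n = net("S", [("A", "B"), ("B", "C")])
        fit = network_log_likelihood(n, expr)
        mu, Sigma = implied_gaussian_oracle(fit, ["A", "B", "C"])
        oracle = stats.multivariate_normal.logpdf(V.T, mean=mu, cov=Sigma).sum()
        assert fit.log_likelihood == pytest.approx(oracle, abs=1e-8)

    def test_likelihood_invariant_to_sample_order(self, rng):
        V = rng.normal(size=(3, 9))
        n = net("S", [("A", "B"), ("A", "C")])
        ll1 = network_log_likelihood(
            n, make_single_strain(V, ["A", "B", "C"])
        ).log_likelihood
        perm = rng.permutation(9)
        ll2 = network_log_likelihood(
            n, make_single_strain(V[:, perm], ["A", "B", "C"])
        ).log_likelihood
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_adding_edge_never_decreases_likelihood(self, rng):
        """Nested OLS: a superset of parents cannot fit worse."""
        for _ in range(20):
            V = rng.normal(size=(3, 12))
            expr = make_single_strain(V, ["A", "B", "C"])
            small = net("S", [("A", "C")], extra_nodes=["B"])
            large = net("S", [("A", "C"), ("B", "C")])
            ll_small = network_log_likelihood(small, expr).log_likelihood
            ll_large = network_log_likelihood(large, expr).log_likelihood
            assert ll_large >= ll_small - 1e-9
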