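"""Linear-Gaussian network likelihood of a DAG against expression data.

The joint density of the genes in a candidate network is factorized by
parentage: f(X_1, ..., X_n) = prod_i f(X_i | pa{X_i}).  Under the Gaussian
network model each conditional is Normal(b_0 + sum_j b_j * pa_j, sigma_i^2),
with coefficients fitted per node by ordinary least squares on the m observed
samples and the residual variance taken at its maximum-likelihood value
SSR/m.  Substituting the MLE back into the Gaussian log-density gives each
node's contribution in closed form,

    ll_i = -(m/2) * (ln(2*pi*sigma_i^2) + 1),

and the network log-likelihood is the sum over nodes.

Rank-deficient designs (more parents than samples, or collinear parents) are
solved with the minimum-norm pseudoinverse; a perfectly interpolating fit is
kept finite by flooring the residual variance at
max(eps_abs, eps_rel * var(child)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import ExpressionMatrix
from .reference_builder import CycleError, RegulatoryNetwork

logger = logging.getLogger(__name__)

#: Absolute and relative floors on the per-node residual variance.
EPS_ABS = 1e-12
EPS_REL = 1e-8

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class NodeFactor:
    """One fitted conditional: a node regressed on its (possibly empty) parents."""

    node: str
    parents: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    residual_variance: float
    log_likelihood: float


@dataclass(frozen=True)
class NetworkFit:
    """A network's factorized Gaussian fit and total log-likelihood."""

    network_name: str
    factors: tuple[NodeFactor, ...]
    m: int
    log_likelihood: float


def factorize(network: RegulatoryNetwork) -> list[tuple[str, tuple[str, ...]]]:
    """Return (node, sorted-parent-tuple) pairs in a topological order.

    Parentage alone determines the factorization; the topological order is
    only a convenient deterministic presentation (lexicographic tie-break).
    """
    g = network.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        raise CycleError(f"network {network.name!r} is not acyclic")
    order = nx.lexicographical_topological_sort(g)
    return [(n, tuple(sorted(g.predecessors(n)))) for n in order]


def node_contribution(m: int, residual_variance: float) -> float:
    """Closed-form Gaussian log-likelihood at the MLE residual variance."""
    return -(m / 2.0) * (math.log(2.0 * math.pi * residual_variance) + 1.0)


def _floored_variance(ssr: float, m: int, child_var: float) -> float:
    return max(ssr / m, EPS_ABS, EPS_REL * child_var)


def fit_node(
    child_values: np.ndarray,
    parent_matrix: np.ndarray | None,
    node: str = "X",
    parents: tuple[str, ...] = (),
) -> NodeFactor:
    """OLS fit of a child on its parents (with intercept).

    Parameters
    ----------
    child_values : shape (m,)
    parent_matrix : shape (m, n_i), or None for a root node
        (an intercept-only fit).
    node, parents : optional names recorded on the returned factor.
    """
    y = np.asarray(child_values, dtype=float)
    m = y.shape[0]
    if m < 2:
        raise ValueError(f"need at least 2 samples, got {m}")
    if parent_matrix is None or parent_matrix.size == 0:
        mean = float(y.mean())
        ssr = float(((y - mean) ** 2).sum())
        s2 = _floored_variance(ssr, m, ssr / m)
        return NodeFactor(node, (), (), mean, s2, node_contribution(m, s2))
    X = np.asarray(parent_matrix, dtype=float)
    if X.shape[0] != m:
        raise ValueError("child and parent rows are not sample-aligned")
    design = np.column_stack([np.ones(m), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.debug("rank-deficient design (m=%d, p=%d)", m, design.shape[1])
    resid = y - design @ beta
    ssr = float(resid @ resid)
    s2 = _floored_variance(ssr, m, float(np.var(y)))
    return NodeFactor(
        node,
        tuple(parents) if parents else tuple(f"p{i}" for i in range(X.shape[1])),
        tuple(float(b) for b in beta[1:]),
        float(beta[0]),
        s2,
        node_contribution(m, s2),
    )


def network_log_likelihood(
    network: RegulatoryNetwork, expr: ExpressionMatrix
) -> NetworkFit:
    """Fit every node's conditional and sum the contributions (full API)."""
    missing = [n for n in sorted(network.nodes) if n not in expr]
    if missing:
        raise KeyError(
            f"network {network.name!r}: genes not in expression matrix: {missing}"
        )
    V = expr.values
    idx = {g: i for i, g in enumerate(expr.genes)}
    m = expr.n_samples
    factors = []
    total = 0.0
    for node, parents in factorize(network):
        y = V[idx[node]]
        X = V[[idx[p] for p in parents]].T if parents else None
        factor = fit_node(y, X, node=node, parents=parents)
        factors.append(factor)
        total += factor.log_likelihood
    return NetworkFit(network.name, tuple(factors), m, total)


def fast_log_likelihood(
    V: np.ndarray, factors: list[tuple[int, list[int]]]
) -> float:
    """Log-likelihood from row indices into a genes x samples value matrix.

    Lean inner loop for the empirical null, where thousands of random
    networks are fitted on the same sample subset.  ``factors`` maps each
    child row index to its parent row indices; parentage need not be in
    topological order (the total is order-invariant).
    """
    m = V.shape[1]
    half_m = m / 2.0
    total = 0.0
    ones = np.ones(m)
    for child, parents in factors:
        y = V[child]
        if parents:
            design = np.column_stack([ones, V[parents].T])
            beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ beta
            ssr = float(resid @ resid)
            s2 = max(ssr / m, EPS_ABS, EPS_REL * float(np.var(y)))
        else:
            mu = y.mean()
            ssr = float(((y - mu) ** 2).sum())
            s2 = max(ssr / m, EPS_ABS, EPS_REL * ssr / m)
        total -= half_m * (math.log(2.0 * math.pi * s2) + 1.0)
    return total


def network_factors_as_indices(
    network: RegulatoryNetwork, expr: ExpressionMatrix
) -> list[tuple[int, list[int]]]:
    """Index-based parent map for :func:`fast_log_likelihood`."""
    idx = {g: i for i, g in enumerate(expr.genes)}
    g = network.to_networkx()
    return [
        (idx[n], [idx[p] for p in sorted(g.predecessors(n))])
        for n in sorted(network.nodes)
    ]
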