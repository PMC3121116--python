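"""Graph consistency probability: an empirical null for network likelihoods.

A raw network log-likelihood has no absolute scale, so a candidate network
is compared against N_r random networks that share its node and edge counts,
fitted on the same samples.  The graph consistency probability is the
empirical tail fraction

    GCP = N_s / N_r,

where N_s counts random networks whose log-likelihood strictly exceeds the
candidate's.  A small GCP means the candidate's structure fits the data
unusually well relative to size-matched chance; the screening threshold is
GCP <= 0.05 with N_r = 2000 by default.

Two null strategies are available: ``random_dag`` (default) draws node
labels from the measured-gene universe, imposes a uniformly random total
order and samples order-respecting edges — guaranteeing a DAG with exactly
the required counts; ``label_permutation`` keeps the candidate's topology
and only redraws the node labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix
from .gaussian_likelihood import (
    fast_log_likelihood,
    network_factors_as_indices,
    network_log_likelihood,
)
from .reference_builder import RegulatoryNetwork

RANDOM_DAG = "random_dag"
LABEL_PERMUTATION = "label_permutation"
STRATEGIES = (RANDOM_DAG, LABEL_PERMUTATION)

#: Default number of random networks in the empirical null.
DEFAULT_N_R = 2000

#: Screening significance threshold on the GCP.
GCP_THRESHOLD = 0.05


@dataclass(frozen=True)
class GcpResult:
    """Empirical null summary for one network on one sample subset."""

    network_name: str
    log_likelihood: float
    n_r: int
    n_s: int
    gcp: float
    seed: int | None
    strategy: str

    def __post_init__(self) -> None:
        if not (0 <= self.n_s <= self.n_r):
            raise ValueError("need 0 <= n_s <= n_r")
        if self.gcp != self.n_s / self.n_r:
            raise ValueError("gcp must equal n_s / n_r exactly")

    @property
    def significant(self) -> bool:
        return self.gcp <= GCP_THRESHOLD


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_random_network(
    n_v: int,
    n_e: int,
    gene_universe: list[str],
    rng: np.random.Generator | int | None = None,
    strategy: str = RANDOM_DAG,
    template: RegulatoryNetwork | None = None,
) -> RegulatoryNetwork:
    """Draw one random network with exactly n_v nodes and n_e edges.

    ``random_dag``: n_v distinct genes, a uniformly random total order, and
    n_e distinct order-respecting pairs — acyclic by construction.
    ``label_permutation``: the template's topology relabelled with n_v
    distinct random genes.
    """
    rng = _as_rng(rng)
    if n_v > len(gene_universe):
        raise ValueError(f"n_v={n_v} exceeds universe size {len(gene_universe)}")
    max_edges = n_v * (n_v - 1) // 2
    if n_e < 1 or n_e > max_edges:
        raise ValueError(f"n_e={n_e} infeasible for n_v={n_v} (max {max_edges})")
    genes = [gene_universe[i] for i in rng.choice(len(gene_universe), n_v, replace=False)]
    if strategy == RANDOM_DAG:
        order = rng.permutation(n_v)
        pair_idx = rng.choice(max_edges, n_e, replace=False)
        edges = []
        for q in pair_idx:
            i, j = _pair_from_index(int(q), n_v)
            edges.append((genes[order[i]], genes[order[j]]))
        return RegulatoryNetwork("random", frozenset(genes), frozenset(edges))
    if strategy == LABEL_PERMUTATION:
        if template is None:
            raise ValueError("label_permutation requires a template network")
        if template.n_v != n_v or template.n_e != n_e:
            raise ValueError("template node/edge counts disagree with n_v/n_e")
        relabel = dict(zip(sorted(template.nodes), genes))
        edges = [(relabel[u], relabel[v]) for u, v in template.edges]
        return RegulatoryNetwork("random", frozenset(genes), frozenset(edges))
    raise ValueError(f"unknown strategy {strategy!r}")


def _pair_from_index(q: int, n_v: int) -> tuple[int, int]:
    """Map a flat index in [0, C(n_v,2)) to the ordered pair (i, j), i < j."""
    i = 0
    row = n_v - 1
    while q >= row:
        q -= row
        i += 1
        row -= 1
    return i, i + 1 + q


def _random_factor_indices(
    n_v: int, n_e: int, universe_size: int, rng: np.random.Generator
) -> list[tuple[int, list[int]]]:
    """Index-level random_dag draw feeding the fast likelihood path."""
    max_edges = n_v * (n_v - 1) // 2
    genes = rng.choice(universe_size, n_v, replace=False)
    order = rng.permutation(n_v)
    pair_idx = rng.choice(max_edges, n_e, replace=False)
    parents: dict[int, list[int]] = {int(g): [] for g in genes}
    for q in pair_idx:
        i, j = _pair_from_index(int(q), n_v)
        parents[int(genes[order[j]])].append(int(genes[order[i]]))
    return list(parents.items())


def graph_consistency_probability(
    network: RegulatoryNetwork,
    expr: ExpressionMatrix,
    n_r: int = DEFAULT_N_R,
    rng: np.random.Generator | int | None = None,
    strategy: str = RANDOM_DAG,
) -> GcpResult:
    """GCP of *network* against *expr* (all samples in the matrix).

    The gene universe for random draws is the full measured-gene list of
    *expr*.  Ties in log-likelihood count as "not larger" (strict
    comparison), so a network is never penalized by an exact tie.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if n_r < 1:
        raise ValueError("n_r must be >= 1")
    seed = rng if isinstance(rng, int) else None
    rng = _as_rng(rng)
    fit = network_log_likelihood(network, expr)
    V = expr.values
    n_genes = len(expr.genes)
    n_s = 0
    if strategy == RANDOM_DAG:
        for _ in range(n_r):
            factors = _random_factor_indices(network.n_v, network.n_e, n_genes, rng)
            if fast_log_likelihood(V, factors) > fit.log_likelihood:
                n_s += 1
    else:
        template_idx = network_factors_as_indices(network, expr)
        local = sorted({i for i, ps in template_idx} | {
            p for _, ps in template_idx for p in ps
        })
        pos = {g: k for k, g in enumerate(local)}
        compact = [(pos[i], [pos[p] for p in ps]) for i, ps in template_idx]
        for _ in range(n_r):
            genes = rng.choice(n_genes, network.n_v, replace=False)
            factors = [
                (int(genes[c]), [int(genes[p]) for p in ps]) for c, ps in compact
            ]
            if fast_log_likelihood(V, factors) > fit.log_likelihood:
                n_s += 1
    return GcpResult(
        network_name=network.name,
        log_likelihood=fit.log_likelihood,
        n_r=n_r,
        n_s=n_s,
        gcp=n_s / n_r,
        seed=seed,
        strategy=strategy,
    )
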