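"""Construction of the reference set of candidate regulatory networks.

Each functional gene set defines one candidate network: every TF->target
relation whose *target* belongs to the set is collected, and if at least one
relation matches, the collected relations form a directed network named after
the set.  Networks are required to be acyclic (the likelihood factorization
assumes a DAG); cycles found in real relation tables can either abort the run
or be broken deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .data_io import BinaryRelation, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


class CycleError(ValueError):
    """Raised in strict mode when a network contains a directed cycle."""


@dataclass(frozen=True)
class RegulatoryNetwork:
    """A named directed graph of TF->target edges derived from one gene set."""

    name: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) references a missing node")

    @property
    def n_v(self) -> int:
        return len(self.nodes)

    @property
    def n_e(self) -> int:
        return len(self.edges)

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(u for u, _ in self.edges)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(v for _, v in self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def is_dag(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())


@dataclass(frozen=True)
class SkipMarker:
    """Records why a network was excluded from screening."""

    name: str
    reason: str


def build_reference(
    relations: list[BinaryRelation], gene_sets: list[GeneSet]
) -> list[RegulatoryNetwork]:
    """Build one candidate network per gene set with >=1 matching relation.

    A relation matches a set when its *target* is a member; the TF is pulled
    in as a node but its own membership is irrelevant.  Sets matching no
    relation yield no network.  Output order follows gene-set input order.
    """
    if not gene_sets:
        raise ValueError("gene_sets must be non-empty")
    networks: list[RegulatoryNetwork] = []
    for gs in gene_sets:
        edges = [(r.tf, r.target) for r in relations if r.target in gs.members]
        if not edges:
            continue
        nodes = frozenset(n for e in edges for n in e)
        networks.append(RegulatoryNetwork(gs.name, nodes, frozenset(edges)))
    logger.info(
        "built %d networks from %d gene sets and %d relations",
        len(networks), len(gene_sets), len(relations),
    )
    return networks


def resolve_cycles(network: RegulatoryNetwork, mode: str = "break") -> RegulatoryNetwork:
    """Return an acyclic version of *network*.

    mode='strict' raises :class:`CycleError` listing one offending cycle.
    mode='break' removes every back edge found by a depth-first traversal
    that starts from nodes in lexicographic order and visits successors in
    lexicographic order — deterministic, and each removal is logged.
    """
    g = network.to_networkx()
    if nx.is_directed_acyclic_graph(g):
        return network
    if mode == "strict":
        cycle = nx.find_cycle(g)
        raise CycleError(f"network {network.name!r} contains a cycle: {cycle}")
    if mode != "break":
        raise ValueError(f"unknown cycle mode {mode!r}")

    removed: list[tuple[str, str]] = []
    color: dict[str, int] = {}  # 0 absent, 1 on stack, 2 done
    for root in sorted(g.nodes):
        if color.get(root):
            continue
        stack: list[tuple[str, list[str]]] = [(root, sorted(g.successors(root)))]
        color[root] = 1
        while stack:
            node, succs = stack[-1]
            advanced = False
            while succs:
                nxt = succs.pop(0)
                if (node, nxt) in removed:
                    continue
                c = color.get(nxt, 0)
                if c == 1:  # back edge: closes a cycle through the stack
                    removed.append((node, nxt))
                elif c == 0:
                    color[nxt] = 1
                    stack.append((nxt, sorted(g.successors(nxt))))
                    advanced = True
                    break
            if not advanced and not succs:
                color[node] = 2
                stack.pop()
    for e in removed:
        logger.info("network %s: removed back edge %s->%s", network.name, *e)
    edges = network.edges - set(removed)
    result = RegulatoryNetwork(network.name, network.nodes, frozenset(edges))
    assert result.is_dag(), "cycle breaking left a cycle"
    return result


def restrict_to_measured(
    network: RegulatoryNetwork, expr: ExpressionMatrix, min_nodes: int = 3
) -> RegulatoryNetwork | SkipMarker:
    """Drop nodes absent from the expression matrix (and incident edges).

    Returns a :class:`SkipMarker` when fewer than *min_nodes* nodes or zero
    edges survive: such networks cannot be screened meaningfully.
    """
    if min_nodes < 2:
        raise ValueError("min_nodes must be >= 2")
    nodes = frozenset(n for n in network.nodes if n in expr)
    edges = frozenset(
        (u, v) for u, v in network.edges if u in nodes and v in nodes
    )
    if len(nodes) < min_nodes:
        return SkipMarker(
            network.name, f"only {len(nodes)} measured nodes (< {min_nodes})"
        )
    if not edges:
        return SkipMarker(network.name, "no measured edges")
    if nodes == network.nodes:
        return network
    return RegulatoryNetwork(network.name, nodes, edges)
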