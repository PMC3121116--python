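"""Screening orchestration: strains x segments, thresholds, combined graphs.

For every (candidate network, strain, time segment) the pipeline computes
the graph consistency probability on that strain's segment samples and the
hypergeometric enrichment of the segment's cross-strain expression
signature.  A network is called *active* in a cell when both probabilities
fall at or below their thresholds (0.05 each by default), and
*differentially active* for a segment when it is active in exactly one
strain.  Active networks sharing genes within a functional category are
merged into combined graphs annotated with per-segment activity and
up/down regulation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    CASE,
    CONTROL,
    DEFAULT_SEGMENTS,
    ExpressionMatrix,
    TimeSegment,
    read_expression,
    read_gmt,
    read_relations,
    select_samples,
    validate_segments,
    write_graph,
)
from .gcp_screen import DEFAULT_N_R, RANDOM_DAG, graph_consistency_probability
from .reference_builder import (
    RegulatoryNetwork,
    SkipMarker,
    build_reference,
    resolve_cycles,
    restrict_to_measured,
)
from .signature_enrichment import (
    SignatureResult,
    expression_signature,
    network_enrichment,
)

logger = logging.getLogger(__name__)

DEFAULT_GCP_THRESHOLD = 0.05
DEFAULT_ENRICH_THRESHOLD = 0.05


@dataclass(frozen=True)
class ScreeningRecord:
    """One (network, strain, segment) screening outcome."""

    network_name: str
    strain: str
    segment: str
    gcp: float  # NaN when skipped
    p_enrich: float  # NaN when skipped
    log_likelihood: float
    active: bool
    differential: bool
    skip_reason: str | None = None


def derive_seed(master_seed: int, *key_parts: str) -> int:
    """Deterministic per-record substream seed from the master seed.

    Hashing (master seed, record key) keeps parallel and serial execution in
    agreement and decouples records from each other's draw counts.
    """
    digest = hashlib.sha256(
        ("|".join([str(master_seed), *key_parts])).encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def screening_universe(
    networks: list[RegulatoryNetwork], expr: ExpressionMatrix
) -> frozenset[str]:
    """N: genes appearing in any reference network and measured on the array."""
    return frozenset(g for n in networks for g in n.nodes if g in expr)


def screen_all(
    ref: list[RegulatoryNetwork],
    expr: ExpressionMatrix,
    segments: tuple[TimeSegment, ...] = DEFAULT_SEGMENTS,
    n_r: int = DEFAULT_N_R,
    seed: int = 0,
    strategy: str = RANDOM_DAG,
    min_nodes: int = 3,
    gcp_threshold: float = DEFAULT_GCP_THRESHOLD,
    enrich_threshold: float = DEFAULT_ENRICH_THRESHOLD,
    signatures: dict[str, SignatureResult] | None = None,
) -> list[ScreeningRecord]:
    """Screen every (network, strain, segment) cell.

    GCP is computed per strain on that strain's segment samples; enrichment
    uses the segment's cross-strain signature, so it is shared between the
    two strains of a cell.  Pass precomputed ``signatures`` (label -> result)
    to avoid refitting them.
    """
    if not ref:
        raise ValueError("reference network list is empty")
    validate_segments(segments)
    universe = screening_universe(ref, expr)
    if signatures is None:
        signatures = {
            seg.label: expression_signature(expr, seg) for seg in segments
        }

    subsets = {
        (strain, seg.label): select_samples(expr, strain, seg)
        for strain in (CASE, CONTROL)
        for seg in segments
    }

    rows: list[dict] = []
    for network in ref:
        restricted = restrict_to_measured(network, expr, min_nodes=min_nodes)
        for seg in segments:
            if isinstance(restricted, SkipMarker):
                for strain in (CASE, CONTROL):
                    rows.append(
                        dict(
                            network_name=network.name,
                            strain=strain,
                            segment=seg.label,
                            gcp=math.nan,
                            p_enrich=math.nan,
                            log_likelihood=math.nan,
                            active=False,
                            skip_reason=restricted.reason,
                        )
                    )
                continue
            enrich = network_enrichment(restricted, signatures[seg.label], universe)
            for strain in (CASE, CONTROL):
                sub = subsets[(strain, seg.label)]
                record_seed = derive_seed(seed, network.name, strain, seg.label)
                gcp = graph_consistency_probability(
                    restricted, sub, n_r=n_r, rng=record_seed, strategy=strategy
                )
                rows.append(
                    dict(
                        network_name=network.name,
                        strain=strain,
                        segment=seg.label,
                        gcp=gcp.gcp,
                        p_enrich=enrich.p_enrich,
                        log_likelihood=gcp.log_likelihood,
                        active=(
                            gcp.gcp <= gcp_threshold
                            and enrich.p_enrich <= enrich_threshold
                        ),
                        skip_reason=None,
                    )
                )

    active_count: dict[tuple[str, str], int] = {}
    for r in rows:
        if r["active"]:
            key = (r["network_name"], r["segment"])
            active_count[key] = active_count.get(key, 0) + 1
    records = [
        ScreeningRecord(
            differential=(
                r["active"]
                and active_count.get((r["network_name"], r["segment"]), 0) == 1
            ),
            **r,
        )
        for r in rows
    ]
    n_active = sum(r.active for r in records)
    logger.info("screened %d cells, %d active", len(records), n_active)
    return records


def records_to_frame(records: list[ScreeningRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.network_name,
                r.strain,
                r.segment,
                r.gcp,
                r.p_enrich,
                r.log_likelihood,
                r.active,
                r.differential,
                r.skip_reason or "",
            )
            for r in records
        ],
        columns=[
            "network_name",
            "strain",
            "segment",
            "gcp",
            "p_enrich",
            "log_likelihood",
            "active",
            "differential",
            "skip_reason",
        ],
    )


def combine_by_category(
    records: list[ScreeningRecord],
    networks: list[RegulatoryNetwork],
    category_map: dict[str, set[str] | frozenset[str] | list[str]],
) -> list[nx.DiGraph]:
    """Merge gene-sharing active networks within each (category, strain).

    Within one functional category and strain, active networks that share at
    least one gene (directly or through a chain of sharing networks) are
    merged into one combined graph whose edge set is the union of the
    members' edges.  Each edge is annotated with the set of segments in
    which any contributing network was active; each node's segments are the
    union over its incident edges.
    """
    by_name = {n.name: n for n in networks}
    active_segments: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.active:
            active_segments.setdefault((r.network_name, r.strain), set()).add(
                r.segment
            )
    for (name, _), _segs in active_segments.items():
        if name not in category_map:
            raise KeyError(f"active network {name!r} missing from category_map")

    graphs: list[nx.DiGraph] = []
    categories = sorted({c for cats in category_map.values() for c in cats})
    for category in categories:
        for strain in (CASE, CONTROL):
            members = sorted(
                name
                for (name, s) in active_segments
                if s == strain and category in set(category_map[name])
            )
            if not members:
                continue
            sharing = nx.Graph()
            sharing.add_nodes_from(members)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    if by_name[a].nodes & by_name[b].nodes:
                        sharing.add_edge(a, b)
            for comp_idx, comp in enumerate(
                sorted(nx.connected_components(sharing), key=min)
            ):
                g = nx.DiGraph(
                    category=category,
                    strain=strain,
                    component=comp_idx,
                    networks=",".join(sorted(comp)),
                )
                for name in sorted(comp):
                    segs = frozenset(active_segments[(name, strain)])
                    for u, v in sorted(by_name[name].edges):
                        if g.has_edge(u, v):
                            g[u][v]["segments"] = frozenset(
                                g[u][v]["segments"] | segs
                            )
                        else:
                            g.add_edge(u, v, segments=segs)
                for node in g.nodes:
                    out_deg = g.out_degree(node)
                    in_deg = g.in_degree(node)
                    role = (
                        "both"
                        if out_deg and in_deg
                        else "TF" if out_deg else "target"
                    )
                    node_segs: set[str] = set()
                    for _, _, d in g.in_edges(node, data=True):
                        node_segs |= d["segments"]
                    for _, _, d in g.out_edges(node, data=True):
                        node_segs |= d["segments"]
                    g.nodes[node]["role"] = role
                    g.nodes[node]["segments"] = frozenset(node_segs)
                    g.nodes[node]["regulation"] = "none"
                graphs.append(g)
    return graphs


#: Segment-subset -> display color, for a three-segment design, keyed by the
#: positions of the segments (0 = earliest) present at a node or edge.
_COLOR_BY_POSITIONS: dict[frozenset[int], str] = {
    frozenset({0}): "gray",
    frozenset({0, 1}): "yellow",
    frozenset({0, 2}): "purple",
    frozenset({0, 1, 2}): "red",
    frozenset({1}): "right-blue",
    frozenset({1, 2}): "blue",
    frozenset({2}): "green",
}


def segment_color(
    present: frozenset[str], segments: tuple[TimeSegment, ...] = DEFAULT_SEGMENTS
) -> str:
    """Display color encoding which of the (three) segments are present."""
    pos = {seg.label: i for i, seg in enumerate(segments)}
    key = frozenset(pos[label] for label in present if label in pos)
    return _COLOR_BY_POSITIONS.get(key, "")


def annotate_dynamics(
    graph: nx.DiGraph,
    expr: ExpressionMatrix,
    signatures: dict[str, SignatureResult],
    segments: tuple[TimeSegment, ...] = DEFAULT_SEGMENTS,
) -> nx.DiGraph:
    """Annotate nodes with regulation direction and a display color.

    A node is *up*-regulated when it belongs to the signature of at least
    one segment it appears in and its case mean exceeds its control mean
    over those segments' samples (*down* symmetric); otherwise *none*.
    Colors encode the segment subset per the combined-figure convention.
    """
    seg_by_label = {seg.label: seg for seg in segments}
    for node, data in graph.nodes(data=True):
        present = data.get("segments", frozenset())
        data["color"] = segment_color(frozenset(present), segments)
        if node not in expr:
            data["regulation"] = "none"
            continue
        in_sig = any(
            node in signatures[label].signature
            for label in present
            if label in signatures
        )
        if not in_sig or not present:
            data["regulation"] = "none"
            continue
        weeks = frozenset(
            w for label in present for w in seg_by_label[label].weeks
        )
        pooled = TimeSegment("pooled", weeks)
        case_mean = select_samples(expr, CASE, pooled).gene_row(node).mean()
        control_mean = select_samples(expr, CONTROL, pooled).gene_row(node).mean()
        data["regulation"] = "up" if case_mean > control_mean else "down"
    for _, _, data in graph.edges(data=True):
        data["color"] = segment_color(frozenset(data.get("segments", ())), segments)
    return graph


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """End-to-end screening run driven by a config mapping or YAML path.

    Config keys: ``relations``, ``gene_sets``, ``expression``, ``metadata``
    (input paths); ``out_dir``; optional ``segments`` (list of {label,
    weeks}), ``thresholds`` ({gcp, enrich}), ``n_r``, ``seed``,
    ``null_strategy``, ``min_nodes``, ``categories`` (network -> list of
    category labels).  Writes the screening records TSV, per-segment
    signature TSVs, combined GraphML/SIF files and a JSON manifest; rerunning
    with the same config reproduces every output byte for byte.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config.get("out_dir", "netscreen_out"))
    out.mkdir(parents=True, exist_ok=True)

    input_paths = {
        key: Path(config[key])
        for key in ("relations", "gene_sets", "expression", "metadata")
    }
    for key, path in input_paths.items():
        if not path.exists():
            raise FileNotFoundError(f"input {key!r} not found: {path}")

    relations = read_relations(input_paths["relations"])
    gene_sets = read_gmt(input_paths["gene_sets"])
    expr = read_expression(input_paths["expression"], input_paths["metadata"])

    if "segments" in config:
        segments = tuple(
            TimeSegment(s["label"], s["weeks"]) for s in config["segments"]
        )
    else:
        segments = DEFAULT_SEGMENTS
    validate_segments(segments)

    thresholds = config.get("thresholds", {})
    gcp_thr = float(thresholds.get("gcp", DEFAULT_GCP_THRESHOLD))
    enrich_thr = float(thresholds.get("enrich", DEFAULT_ENRICH_THRESHOLD))
    n_r = int(config.get("n_r", DEFAULT_N_R))
    seed = int(config.get("seed", 0))
    strategy = config.get("null_strategy", RANDOM_DAG)
    min_nodes = int(config.get("min_nodes", 3))

    networks = [
        resolve_cycles(n, mode=config.get("cycle_mode", "break"))
        for n in build_reference(relations, gene_sets)
    ]
    if not networks:
        raise ValueError("no candidate networks could be built from the inputs")

    signatures = {seg.label: expression_signature(expr, seg) for seg in segments}
    records = screen_all(
        networks,
        expr,
        segments=segments,
        n_r=n_r,
        seed=seed,
        strategy=strategy,
        min_nodes=min_nodes,
        gcp_threshold=gcp_thr,
        enrich_threshold=enrich_thr,
        signatures=signatures,
    )

    frame = records_to_frame(records)
    frame.to_csv(out / "screening_records.tsv", sep="\t", index=False,
                 float_format="%.10g")
    for label, sig in signatures.items():
        safe = label.replace("/", "_")
        sig.table.to_csv(
            out / f"signature_{safe}.tsv", sep="\t", index=False,
            float_format="%.10g",
        )

    graph_files: list[str] = []
    graphs: list[nx.DiGraph] = []
    if config.get("categories"):
        graphs = combine_by_category(records, networks, config["categories"])
        for g in graphs:
            annotate_dynamics(g, expr, signatures, segments)
            stem = (
                f"combined_{g.graph['category']}_{g.graph['strain']}"
                f"_{g.graph['component']}"
            ).replace(" ", "_")
            write_graph(g, out / f"{stem}.graphml", "graphml")
            write_graph(g, out / f"{stem}.sif", "sif")
            graph_files.extend([f"{stem}.graphml", f"{stem}.sif"])

    manifest = {
        "netscreen_version": __version__,
        "parameters": {
            "n_r": n_r,
            "seed": seed,
            "null_strategy": strategy,
            "min_nodes": min_nodes,
            "thresholds": {"gcp": gcp_thr, "enrich": enrich_thr},
            "segments": [
                {"label": s.label, "weeks": sorted(s.weeks)} for s in segments
            ],
        },
        "inputs": {k: _sha256(p) for k, p in input_paths.items()},
        "n_networks": len(networks),
        "n_records": len(records),
        "n_active": int(frame["active"].sum()),
        "skips": sorted(
            {(r.network_name, r.skip_reason) for r in records if r.skip_reason}
        ),
        "graphs": sorted(graph_files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "records": records,
        "signatures": signatures,
        "networks": networks,
        "graphs": graphs,
        "out_dir": out,
    }
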