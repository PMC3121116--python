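"""Synthetic two-strain time-course datasets with planted regulatory signal.

The generator emulates the study design the screening pipeline expects:
two strains (case = diabetic, control = normoglycemic), five sampling ages
(4, 8, 12, 16, 20 weeks) grouped into three segments, five replicates per
strain and age.  It plants two kinds of signal with machine-readable ground
truth:

* **active networks** — for chosen (strain, segment) cells, the member genes
  of chosen reference networks are generated from the network's own
  linear-Gaussian structural equations (child = coef * sum(parents) + noise)
  instead of independent baseline noise, so the network's structure is
  genuinely consistent with the data there;
* **differentially expressed genes** — chosen genes receive a mean shift in
  the case strain within a segment, creating a detectable case-vs-control
  signature.

The reference relations are bipartite with unique targets: each TF regulates
its own block of 3-10 target genes, and each gene set selects a subset of
one TF's targets, so every candidate network is a connected star and any
union of planted networks is automatically acyclic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import (
    CASE,
    CONTROL,
    DEFAULT_SEGMENTS,
    BinaryRelation,
    ExpressionMatrix,
    GeneSet,
    SampleMeta,
    TimeSegment,
    write_expression,
    write_gmt,
    write_relations,
)
from .reference_builder import RegulatoryNetwork, build_reference


@dataclass
class SimulationDesign:
    """All knobs of one synthetic dataset; every random draw flows from seed."""

    n_genes: int = 300
    n_tfs: int = 25
    n_sets: int = 30
    set_size_range: tuple[int, int] = (3, 10)  # targets per gene set
    targets_per_tf: tuple[int, int] = (3, 10)
    n_active: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    edge_coefficient: float = 0.9
    noise_sd: float = 0.3
    baseline_sd: float = 1.0
    de_genes: dict[tuple[str, str], float] = field(default_factory=dict)
    #: default case-strain mean shift for DE genes added via helpers
    de_shift: float = 2.0
    replicates: int = 5
    weeks: tuple[int, ...] = (4, 8, 12, 16, 20)
    segments: tuple[TimeSegment, ...] = DEFAULT_SEGMENTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs >= self.n_genes:
            raise ValueError("n_tfs must be smaller than n_genes")
        if self.noise_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("noise_sd and baseline_sd must be positive")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid set_size_range")

    def segment_by_label(self, label: str) -> TimeSegment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(f"unknown segment label {label!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted signal: which networks are active where, and which genes shift."""

    active: frozenset[tuple[str, str, str]]  # (network_name, strain, segment)
    de: frozenset[tuple[str, str, str]]  # (gene, segment, direction)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "active": sorted(list(t) for t in self.active),
            "de": sorted(list(t) for t in self.de),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            frozenset(tuple(t) for t in payload["active"]),
            frozenset(tuple(t) for t in payload["de"]),
        )


def _gene_names(design: SimulationDesign) -> tuple[list[str], list[str]]:
    tfs = [f"TF{i:03d}" for i in range(1, design.n_tfs + 1)]
    others = [f"G{i:04d}" for i in range(1, design.n_genes - design.n_tfs + 1)]
    return tfs, others


def simulate_reference(
    design: SimulationDesign,
) -> tuple[list[BinaryRelation], list[GeneSet]]:
    """Random TF->target relations and gene sets over them.

    Each TF regulates a disjoint block of targets (uniform count within
    ``targets_per_tf``); each gene set picks one TF and a random subset of
    its targets, so the induced network is a connected TF-centred star of
    4-12 nodes at the defaults.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    tfs, others = _gene_names(design)
    lo_t, hi_t = design.targets_per_tf
    counts = rng.integers(lo_t, hi_t + 1, size=design.n_tfs)
    if counts.sum() > len(others):
        raise ValueError(
            f"infeasible design: {counts.sum()} targets needed, "
            f"{len(others)} non-TF genes available"
        )
    pool = list(rng.permutation(others))
    relations: list[BinaryRelation] = []
    targets_of: dict[str, list[str]] = {}
    cursor = 0
    for tf, c in zip(tfs, counts):
        block = pool[cursor:cursor + int(c)]
        cursor += int(c)
        targets_of[tf] = block
        relations.extend(BinaryRelation(tf, t) for t in block)

    lo_s, hi_s = design.set_size_range
    tf_cycle = list(rng.permutation(tfs))
    while len(tf_cycle) < design.n_sets:
        tf_cycle.extend(rng.permutation(tfs))
    gene_sets: list[GeneSet] = []
    for i in range(design.n_sets):
        tf = tf_cycle[i]
        avail = targets_of[tf]
        s = min(int(rng.integers(lo_s, hi_s + 1)), len(avail))
        members = [avail[j] for j in rng.choice(len(avail), s, replace=False)]
        gene_sets.append(GeneSet(f"SET{i + 1:03d}", frozenset(members)))
    return relations, gene_sets


def _sample_grid(design: SimulationDesign) -> list[SampleMeta]:
    samples = []
    for strain in (CASE, CONTROL):
        for week in design.weeks:
            for rep in range(1, design.replicates + 1):
                samples.append(
                    SampleMeta(f"{strain}_w{week:02d}_r{rep}", strain, week, rep)
                )
    return samples


def simulate_expression(
    design: SimulationDesign,
    relations: list[BinaryRelation],
    gene_sets: list[GeneSet],
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the expression matrix with the planted signal of *design*.

    Background genes are i.i.d. Normal(gene baseline, baseline_sd^2) per
    sample.  Within each (strain, segment) cell, member genes of that cell's
    planted-active networks are regenerated in topological order from the
    union of those networks: child = coef * sum(parents) + Normal(0,
    noise_sd^2).  DE genes then receive their mean shift in the case strain.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2]))
    networks = {n.name: n for n in build_reference(relations, gene_sets)}
    for (strain, seg), names in design.n_active.items():
        missing = set(names) - set(networks)
        if missing:
            raise ValueError(f"planted networks absent from reference: {missing}")
        design.segment_by_label(seg)

    tfs, others = _gene_names(design)
    genes = tfs + others
    gidx = {g: i for i, g in enumerate(genes)}
    samples = _sample_grid(design)
    cols = {s.sample_id: j for j, s in enumerate(samples)}

    baseline = rng.normal(0.0, 1.0, size=len(genes))
    values = baseline[:, None] + rng.normal(
        0.0, design.baseline_sd, size=(len(genes), len(samples))
    )

    for strain in (CASE, CONTROL):
        for seg in design.segments:
            names = design.n_active.get((strain, seg.label), frozenset())
            if not names:
                continue
            union = nx.DiGraph()
            for name in sorted(names):
                union.add_edges_from(networks[name].edges)
            if not nx.is_directed_acyclic_graph(union):
                raise ValueError(
                    f"planted networks for ({strain}, {seg.label}) form a cycle"
                )
            col_idx = [
                cols[s.sample_id]
                for s in samples
                if s.strain == strain and s.week in seg.weeks
            ]
            for node in nx.lexicographical_topological_sort(union):
                parents = sorted(union.predecessors(node))
                if not parents:
                    continue
                parent_sum = values[[gidx[p] for p in parents]][:, col_idx].sum(axis=0)
                values[gidx[node], col_idx] = (
                    design.edge_coefficient * parent_sum
                    + rng.normal(0.0, design.noise_sd, size=len(col_idx))
                )

    de_records = set()
    for (gene, seg_label), shift in sorted(design.de_genes.items()):
        seg = design.segment_by_label(seg_label)
        col_idx = [
            cols[s.sample_id]
            for s in samples
            if s.strain == CASE and s.week in seg.weeks
        ]
        values[gidx[gene], col_idx] += shift
        de_records.add((gene, seg_label, "up" if shift > 0 else "down"))

    df = pd.DataFrame(values, index=genes, columns=[s.sample_id for s in samples])
    expr = ExpressionMatrix(df, samples)
    truth = GroundTruth(
        frozenset(
            (name, strain, seg)
            for (strain, seg), names in design.n_active.items()
            for name in names
        ),
        frozenset(de_records),
    )
    return expr, truth


@dataclass(frozen=True)
class BenchmarkBundle:
    """Everything the screening pipeline needs, plus ground truth."""

    design: SimulationDesign
    relations: list[BinaryRelation]
    gene_sets: list[GeneSet]
    networks: list[RegulatoryNetwork]
    expression: ExpressionMatrix
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "relations": out / "relations.tsv",
            "gene_sets": out / "gene_sets.gmt",
            "expression": out / "expression.tsv",
            "metadata": out / "metadata.tsv",
            "truth": out / "truth.json",
        }
        write_relations(self.relations, paths["relations"])
        write_gmt(self.gene_sets, paths["gene_sets"])
        write_expression(self.expression, paths["expression"], paths["metadata"])
        self.truth.to_json(paths["truth"])
        return paths


#: Case-strain mean shift used for the benchmark's planted DE genes, in
#: within-strain standard deviations.  Chosen by a power analysis of the
#: weakest cell of the design (the single-week segment has only 5 replicates
#: per strain): a 3-sd shift survives BH selection over 300 genes there,
#: while the generator's 2-sd default does not.
BENCHMARK_DE_SHIFT = 3.0
BENCHMARK_DE_PER_SEGMENT = 25


def standard_benchmark(seed: int = 0) -> BenchmarkBundle:
    """The canonical planted-truth benchmark.

    300 genes (25 TFs), 30 candidate networks; per segment, 3 networks are
    active in the case strain only, and one additional network is active in
    *both* strains at the middle segment (a control for the differential
    flag: truly active, but not differentially so).  25 genes per segment
    are differentially expressed (case-strain shift), drawn first from the
    member genes of that segment's planted case-active networks so the
    enrichment filter has signal, then padded with background genes of
    alternating sign.
    """
    design = SimulationDesign(seed=seed)
    relations, gene_sets = simulate_reference(design)
    networks = build_reference(relations, gene_sets)
    by_name = {n.name: n for n in networks}

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    names = [n.name for n in networks]
    picks = [names[i] for i in rng.choice(len(names), 10, replace=False)]
    shared = picks[9]
    labels = [seg.label for seg in design.segments]
    n_active: dict[tuple[str, str], frozenset[str]] = {
        (CASE, labels[0]): frozenset(picks[0:3]),
        (CASE, labels[1]): frozenset(picks[3:6]) | {shared},
        (CASE, labels[2]): frozenset(picks[6:9]),
        (CONTROL, labels[1]): frozenset({shared}),
    }

    tf_names = set(_gene_names(design)[0])
    network_genes = sorted({g for n in networks for g in n.nodes})
    background = sorted(set(_gene_names(design)[1]) - set(network_genes))
    de_genes: dict[tuple[str, str], float] = {}
    for label in labels:
        members: list[str] = sorted(
            {
                g
                for name in n_active.get((CASE, label), frozenset())
                for g in by_name[name].targets
            }
        )
        chosen = members[:BENCHMARK_DE_PER_SEGMENT]
        pad_needed = BENCHMARK_DE_PER_SEGMENT - len(chosen)
        if pad_needed > 0:
            pad = [
                background[i]
                for i in rng.choice(len(background), pad_needed, replace=False)
            ]
        else:
            pad = []
        for g in chosen:
            de_genes[(g, label)] = BENCHMARK_DE_SHIFT
        for j, g in enumerate(pad):
            de_genes[(g, label)] = BENCHMARK_DE_SHIFT * (1 if j % 2 == 0 else -1)
    design.n_active = n_active
    design.de_genes = de_genes

    expr, truth = simulate_expression(design, relations, gene_sets)
    return BenchmarkBundle(design, relations, gene_sets, networks, expr, truth)
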