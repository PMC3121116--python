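"""Input/output for relation tables, gene sets, expression matrices and graphs.

All tabular formats are plain TSV; gene sets use the GMT dialect (one set per
line: name, description, members...); networks are serialized as GraphML (all
node/edge attributes preserved) or SIF (``tf regulates target`` triples).

Readers reject malformed input rather than repairing it silently.  The only
permitted repairs — collapsing duplicate relations and dropping expression
rows with missing values — are counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
STRAINS = (CASE, CONTROL)


class DataFormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class BinaryRelation:
    """One directed regulatory relation: a transcription factor and its target."""

    tf: str
    target: str

    def __post_init__(self) -> None:
        if not self.tf or not self.target:
            raise ValueError("tf and target must be non-empty gene symbols")


@dataclass(frozen=True)
class GeneSet:
    """A named functional gene set (one GMT line)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one array: strain (case/control), week of age, replicate."""

    sample_id: str
    strain: str
    week: int
    replicate: int

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"strain must be one of {STRAINS}, got {self.strain!r}")
        if self.week <= 0 or self.replicate <= 0:
            raise ValueError("week and replicate must be positive")


@dataclass(frozen=True)
class TimeSegment:
    """A pooled-week analysis window, e.g. '8-12w' = weeks {8, 12}."""

    label: str
    weeks: frozenset[int]

    def __init__(self, label: str, weeks: Iterable[int]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "weeks", frozenset(int(w) for w in weeks))
        if not self.weeks or any(w <= 0 for w in self.weeks):
            raise ValueError("segment weeks must be positive integers")


#: Default segmentation of the five sampling ages into early / unstable /
#: stable hyperglycemia windows.
DEFAULT_SEGMENTS: tuple[TimeSegment, ...] = (
    TimeSegment("4w", {4}),
    TimeSegment("8-12w", {8, 12}),
    TimeSegment("16-20w", {16, 20}),
)


def validate_segments(segments: Sequence[TimeSegment]) -> None:
    """Check that segments are pairwise disjoint."""
    seen: dict[int, str] = {}
    for seg in segments:
        for w in seg.weeks:
            if w in seen:
                raise ValueError(
                    f"week {w} appears in segments {seen[w]!r} and {seg.label!r}"
                )
            seen[w] = seg.label


class ExpressionMatrix:
    """Gene x sample expression values with per-sample metadata.

    Values are assumed already normalized and on the log scale.  Rows with
    any missing value are dropped at load time (the count is logged); the
    retained matrix is dense and fully numeric.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta]):
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise DataFormatError("duplicate sample_id in metadata")
        keys = [(s.strain, s.week, s.replicate) for s in samples]
        if len(set(keys)) != len(keys):
            raise DataFormatError("duplicate (strain, week, replicate) in metadata")
        if list(values.columns) != sample_ids:
            missing = set(sample_ids) - set(values.columns)
            extra = set(values.columns) - set(sample_ids)
            if missing or extra:
                raise DataFormatError(
                    f"matrix/metadata sample mismatch: missing={sorted(missing)}, "
                    f"unmatched={sorted(extra)}"
                )
            values = values[sample_ids]
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate gene symbols: {dups[:5]}")
        n_na = int(values.isna().any(axis=1).sum())
        if n_na:
            logger.info("dropping %d gene rows with missing values", n_na)
            values = values.dropna(axis=0)
        self._df = values.astype(float)
        self.samples: tuple[SampleMeta, ...] = tuple(samples)
        self._gene_index = {g: i for i, g in enumerate(self._df.index)}

    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def gene_row(self, gene: str) -> np.ndarray:
        return self._df.to_numpy()[self._gene_index[gene]]

    def gene_indices(self, genes: Iterable[str]) -> list[int]:
        return [self._gene_index[g] for g in genes]


def read_relations(path: str | Path) -> list[BinaryRelation]:
    """Read a two-column TF/target TSV; duplicates collapsed, order kept."""
    path = Path(path)
    seen: dict[tuple[str, str], None] = {}
    n_lines = 0
    n_dup = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            n_lines += 1
            key = (fields[0].strip(), fields[1].strip())
            if not key[0] or not key[1]:
                raise DataFormatError(f"{path}:{lineno}: empty gene symbol")
            if key in seen:
                n_dup += 1
            else:
                seen[key] = None
    if not seen:
        raise DataFormatError(f"{path}: no relations found")
    if n_dup:
        logger.info("%s: collapsed %d duplicate relations", path, n_dup)
    return [BinaryRelation(tf, target) for tf, target in seen]


def write_relations(relations: Iterable[BinaryRelation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#tf\ttarget\n")
        for r in relations:
            fh.write(f"{r.tf}\t{r.target}\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set collection; the description column is discarded."""
    path = Path(path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member"
                )
            name = fields[0].strip()
            if name in names:
                raise DataFormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(t.strip() for t in fields[2:] if t.strip())
            if not members:
                raise DataFormatError(f"{path}:{lineno}: set {name!r} has no members")
            names.add(name)
            sets.append(GeneSet(name, members))
    if not sets:
        raise DataFormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\tna\t{members}\n")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "strain": str})
    required = {"sample_id", "strain", "week", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise DataFormatError(f"{path}: metadata missing columns {sorted(missing)}")
    return [
        SampleMeta(row.sample_id, row.strain, int(row.week), int(row.replicate))
        for row in meta.itertuples()
    ]


def read_expression(matrix_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column = gene) and its sample metadata."""
    samples = read_metadata(meta_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        for col in non_numeric:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise DataFormatError(
                    f"{matrix_path}: non-numeric value {bad[col].iloc[0]!r} "
                    f"at gene {bad.index[0]!r}, sample {col!r}"
                )
        df = df.apply(pd.to_numeric)
    return ExpressionMatrix(df, samples)


def write_expression(
    expr: ExpressionMatrix, matrix_path: str | Path, meta_path: str | Path
) -> None:
    expr.frame.to_csv(matrix_path, sep="\t", index_label="gene", float_format="%.12g")
    rows = [
        (s.sample_id, s.strain, s.week, s.replicate) for s in expr.samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "strain", "week", "replicate"]).to_csv(
        meta_path, sep="\t", index=False
    )


def select_samples(
    expr: ExpressionMatrix, strain: str, segment: TimeSegment
) -> ExpressionMatrix:
    """Sub-matrix of samples with the given strain and week in the segment."""
    if strain not in STRAINS:
        raise ValueError(f"unknown strain {strain!r}")
    keep = [s for s in expr.samples if s.strain == strain and s.week in segment.weeks]
    if not keep:
        raise ValueError(
            f"no samples for strain={strain!r}, segment={segment.label!r}"
        )
    return ExpressionMatrix(expr.frame[[s.sample_id for s in keep]], keep)


_SETLIKE_ATTRS = ("segments",)


def _encode_attrs(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (set, frozenset)):
            out[k] = ",".join(sorted(v))
        else:
            out[k] = v
    return out


def write_graph(graph: nx.DiGraph, path: str | Path, format: str = "graphml") -> None:
    """Serialize an annotated graph as GraphML or SIF.

    Set-valued attributes (e.g. the segments a node is active in) are encoded
    as sorted comma-joined strings so they survive the GraphML round trip.
    """
    path = Path(path)
    if format == "graphml":
        out = nx.DiGraph(**_encode_attrs(dict(graph.graph)))
        for n, d in graph.nodes(data=True):
            out.add_node(n, **_encode_attrs(d))
        for u, v, d in graph.edges(data=True):
            out.add_edge(u, v, **_encode_attrs(d))
        nx.write_graphml(out, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v in graph.edges():
                fh.write(f"{u}\tregulates\t{v}\n")
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graphml(path: str | Path) -> nx.DiGraph:
    """Read a GraphML file written by :func:`write_graph` (set attrs decoded)."""
    g = nx.read_graphml(path)
    out = nx.DiGraph(**dict(g.graph))
    for n, d in g.nodes(data=True):
        out.add_node(n, **_decode_attrs(d))
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, **_decode_attrs(d))
    return out


def _decode_attrs(d: dict) -> dict:
    out = dict(d)
    for k in _SETLIKE_ATTRS:
        if k in out and isinstance(out[k], str):
            out[k] = frozenset(t for t in out[k].split(",") if t)
    return out


def apply_ortholog_map(
    relations: list[BinaryRelation], mapping: dict[str, str]
) -> list[BinaryRelation]:
    """Rename genes through a 2-column ortholog table (pure pre-pass rename)."""
    seen: dict[tuple[str, str], None] = {}
    for r in relations:
        key = (mapping.get(r.tf, r.tf), mapping.get(r.target, r.target))
        seen.setdefault(key, None)
    return [BinaryRelation(tf, t) for tf, t in seen]
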