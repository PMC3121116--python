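"""Expression signature (Student's t + BH FDR) and hypergeometric enrichment.

The expression signature of a time segment is the set of genes whose mean
expression differs between the case and control strains at a false discovery
rate below 5% (pooled-variance two-sample Student's t-test, two-sided,
Benjamini-Hochberg step-up).  A candidate network of k genes containing l
signature genes is then scored by the upper-tail hypergeometric probability
of drawing >= l signature members in k draws without replacement from the
N-gene reference universe containing M signature genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import CASE, CONTROL, ExpressionMatrix, TimeSegment, select_samples
from .reference_builder import RegulatoryNetwork

logger = logging.getLogger(__name__)

#: FDR level defining the signature, and the enrichment significance cut.
SIGNATURE_Q = 0.05
ENRICHMENT_THRESHOLD = 0.05


@dataclass(frozen=True)
class SignatureResult:
    """Per-gene differential-expression statistics for one segment."""

    segment: str
    table: pd.DataFrame  # columns: gene, t, p, q, significant
    signature: frozenset[str]

    @property
    def m_sig(self) -> int:
        return len(self.signature)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of the signature in one network."""

    network_name: str
    k: int
    l: int
    m_sig: int
    n_univ: int
    p_enrich: float

    @property
    def significant(self) -> bool:
        return self.p_enrich <= ENRICHMENT_THRESHOLD


def student_t(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Classical pooled-variance two-sample t with a two-sided p-value.

    Zero pooled variance (both groups constant) is reported as (t=0, p=1)
    by convention: such a gene carries no evidence either way.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    with warnings.catch_warnings():
        # constant genes trigger a precision warning; handled by convention
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):
        logger.debug("zero pooled variance; reporting t=0, p=1")
        return 0.0, 1.0
    return float(t), float(p)


def bh_fdr(p_values: np.ndarray, q: float = SIGNATURE_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, monotone q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals


def expression_signature(
    expr: ExpressionMatrix, segment: TimeSegment, q: float = SIGNATURE_Q
) -> SignatureResult:
    """Case-vs-control signature for one segment (weeks pooled)."""
    case = select_samples(expr, CASE, segment)
    control = select_samples(expr, CONTROL, segment)
    if case.n_samples < 2 or control.n_samples < 2:
        raise ValueError(
            f"segment {segment.label!r}: need >=2 replicates per strain"
        )
    if case.genes != control.genes:
        raise ValueError("case/control gene lists diverged")  # cannot happen
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(
            case.values, control.values, axis=1, equal_var=True
        )
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.info(
            "segment %s: %d constant genes reported as t=0, p=1",
            segment.label, int(degenerate.sum()),
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    reject, qvals = bh_fdr(p, q)
    table = pd.DataFrame(
        {
            "gene": case.genes,
            "t": t,
            "p": p,
            "q": qvals,
            "significant": reject,
        }
    )
    signature = frozenset(table.loc[table.significant, "gene"])
    return SignatureResult(segment.label, table, signature)


def enrichment_probability(k: int, l: int, m_sig: int, n_univ: int) -> float:
    """Upper-tail hypergeometric P(X >= l) for l signature genes in k draws.

    X ~ Hypergeometric(population n_univ, successes m_sig, draws k).
    """
    if not (0 <= l <= k <= n_univ):
        raise ValueError(f"need 0 <= l <= k <= N (got l={l}, k={k}, N={n_univ})")
    if not (l <= m_sig <= n_univ):
        raise ValueError(f"need l <= M <= N (got l={l}, M={m_sig}, N={n_univ})")
    if l == 0:
        return 1.0
    return float(stats.hypergeom.sf(l - 1, n_univ, m_sig, k))


def network_enrichment(
    network: RegulatoryNetwork,
    signature: SignatureResult,
    universe: frozenset[str] | set[str],
) -> EnrichmentResult:
    """Enrichment of *signature* in *network* against the reference universe.

    The universe N is the union of genes over all reference networks that
    are measured on the array; both the network's gene count k and the
    signature size M are intersected with it so the hypergeometric model is
    coherent.
    """
    if not universe:
        raise ValueError("empty reference universe")
    universe = frozenset(universe)
    nodes = network.nodes & universe
    sig = frozenset(signature.signature) & universe
    k = len(nodes)
    l = len(nodes & sig)
    p = enrichment_probability(k, l, len(sig), len(universe))
    return EnrichmentResult(network.name, k, l, len(sig), len(universe), p)
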