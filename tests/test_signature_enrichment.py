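import itertools
import math

import numpy as np
import pytest
from scipy import stats

from netscreen.data_io import CASE, CONTROL, TimeSegment
from netscreen.reference_builder import RegulatoryNetwork
from netscreen.signature_enrichment import (
    bh_fdr,
    enrichment_probability,
    expression_signature,
    network_enrichment,
    student_t,
)

from conftest import make_expression


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t, independent of the implementation."""
    na, nb = len(a), len(b)
    sp2 = (
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
        / (na + nb - 2)
    )
    t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def enumeration_oracle(k, l, M, N):
    """P(X >= l) by counting all size-k subsets of an N-gene universe."""
    universe = list(range(N))
    hits = sum(
        1
        for subset in itertools.combinations(universe, k)
        if sum(1 for g in subset if g < M) >= l
    )
    return hits / math.comb(N, k)


class TestStudentT:
    def test_identical_groups(self):
        t, p = student_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == 0.0 and p == 1.0

    def test_constant_groups_convention(self):
        t, p = student_t(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert (t, p) == (0.0, 1.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=5)
        t1, p1 = student_t(a, b)
        t2, p2 = student_t(b, a)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_worked_example_matches_formula_oracle(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([3.0, 4, 5, 6, 7])
        t, p = student_t(a, b)
        t_o, p_o = pooled_t_oracle(a, b)
        assert t == pytest.approx(t_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            student_t(np.array([1.0]), np.array([1.0, 2.0]))


class TestBhFdr:
    def test_all_ones_nothing_significant(self):
        reject, q = bh_fdr(np.ones(10))
        assert not reject.any()
        assert (q == 1.0).all()

    def test_step_up_worked_example(self):
        """Hand-executed BH step-up on (0.01, 0.02, 0.04, 0.9) at q=0.05:
        thresholds 0.0125, 0.025, 0.0375, 0.05 -> largest passing rank is 2."""
        reject, _ = bh_fdr(np.array([0.01, 0.02, 0.04, 0.9]), q=0.05)
        assert reject.tolist() == [True, True, False, False]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))

    def test_superset_of_bonferroni(self, rng):
        for _ in range(50):
            p = rng.uniform(size=30) ** 3  # push some small values
            bh, _ = bh_fdr(p, q=0.05)
            bonf = p <= 0.05 / len(p)
            assert (bh | ~bonf).all()  # bonferroni rejections subset of BH

    def test_qvalues_monotone_in_p(self, rng):
        p = rng.uniform(size=40)
        _, q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestExpressionSignature:
    def test_pure_noise_rarely_yields_signature(self):
        empties = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            vals = r.normal(size=(300, 10))
            expr = make_expression(vals, [f"g{i}" for i in range(300)],
                                   weeks=(4,), replicates=5)
            sig = expression_signature(expr, TimeSegment("4w", {4}))
            empties += sig.m_sig == 0
        assert empties >= 27  # BH controls FDR: >=1 rejection in <~5% of runs

    def test_planted_shifts_recovered(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            vals = r.normal(size=(500, 20))
            vals[:20, :10] += 3.0  # case columns come first in the grid
            expr = make_expression(vals, [f"g{i}" for i in range(500)],
                                   weeks=(4, 8), replicates=5)
            seg = TimeSegment("4-8w", {4, 8})
            sig = expression_signature(expr, seg)
            found = sum(f"g{i}" in sig.signature for i in range(20))
            hits += found >= 16
        assert hits >= 18

    def test_constant_gene_convention(self, rng):
        vals = rng.normal(size=(3, 10))
        vals[1] = 5.0
        expr = make_expression(vals, ["a", "const", "c"], weeks=(4,), replicates=5)
        sig = expression_signature(expr, TimeSegment("4w", {4}))
        row = sig.table.set_index("gene").loc["const"]
        assert row.t == 0.0 and row.p == 1.0 and not row.significant

    def test_missing_strain_is_error(self, rng):
        vals = rng.normal(size=(2, 4))
        expr = make_expression(vals, ["a", "b"], weeks=(4,), replicates=4,
                               strains=(CASE,))
        with pytest.raises(ValueError):
            expression_signature(expr, TimeSegment("4w", {4}))


class TestEnrichmentProbability:
    def test_l_zero_is_one(self):
        assert enrichment_probability(5, 0, 3, 20) == 1.0

    def test_small_case_against_enumeration(self):
        # k=2, l=1, M=2, N=4: 1 - C(2,2)/C(4,2) = 5/6
        assert enrichment_probability(2, 1, 2, 4) == pytest.approx(5 / 6, abs=1e-12)

    def test_matches_enumeration_oracle_small(self):
        for N in range(1, 9):
            for M in range(N + 1):
                for k in range(1, N + 1):
                    for l in range(min(k, M) + 1):
                        assert enrichment_probability(k, l, M, N) == pytest.approx(
                            enumeration_oracle(k, l, M, N), abs=1e-12
                        )

    def test_monotone_nonincreasing_in_l(self):
        vals = [enrichment_probability(6, l, 10, 40) for l in range(7)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_probability(3, 4, 5, 10)  # l > k
        with pytest.raises(ValueError):
            enrichment_probability(3, 1, 12, 10)  # M > N


class TestNetworkEnrichment:
    def _signature(self, genes):
        import pandas as pd

        from netscreen.signature_enrichment import SignatureResult

        table = pd.DataFrame({"gene": sorted(genes)})
        return SignatureResult("4w", table, frozenset(genes))

    def test_counts_on_hand_fixture(self):
        universe = {f"u{i}" for i in range(26)} | {"TF1", "n1", "n2", "n3"}
        net = RegulatoryNetwork(
            "S",
            frozenset({"TF1", "n1", "n2", "n3"}),
            frozenset({("TF1", "n1"), ("TF1", "n2"), ("TF1", "n3")}),
        )
        sig = self._signature({"n1", "n2", "u0", "u1", "u2"})
        res = network_enrichment(net, sig, universe)
        assert (res.k, res.l, res.m_sig, res.n_univ) == (4, 2, 5, 30)
        assert res.p_enrich == pytest.approx(
            enumeration_oracle(4, 2, 5, 30), abs=1e-12
        )

    def test_empty_signature_never_significant(self):
        net = RegulatoryNetwork(
            "S", frozenset({"a", "b"}), frozenset({("a", "b")})
        )
        res = network_enrichment(net, self._signature(set()), {"a", "b", "c"})
        assert res.p_enrich == 1.0 and not res.significant

    def test_empty_universe_is_error(self):
        net = RegulatoryNetwork(
            "S", frozenset({"a", "b"}), frozenset({("a", "b")})
        )
        with pytest.raises(ValueError):
            network_enrichment(net, self._signature({"a"}), set())
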