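import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reticulotype import (
    ReticulotypeBuilder,
    build_reticulotype,
    count_pairs,
    run_cohort,
    z_statistic,
)
from reticulotype.builder import PerturbationRecord
from reticulotype.synthetic import ModuleSpec, SyntheticCohortSpec, generate

from conftest import make_interactome, make_matrix


class TestCountPairs:
    @pytest.mark.parametrize("m,expected", [(2, 1), (3, 3), (10, 45)])
    def test_small(self, m, expected):
        assert count_pairs(m) == expected

    def test_error_below_two(self):
        with pytest.raises(ValueError):
            count_pairs(1)


class TestZStatistic:
    def test_worked_example(self):
        # r = 0, n = 5, r' = 0.9: z = 0.9 * 4 = 3.6, p = 2(1 - Phi(3.6))
        z, p = z_statistic(0.0, 0.9, 5)
        assert z == pytest.approx(3.6)
        assert p == pytest.approx(2 * stats.norm.sf(3.6))
        assert p == pytest.approx(3.18e-4, rel=2e-2)

    def test_null_change_is_null(self):
        z, p = z_statistic(0.3, 0.3, 5)
        assert z == 0.0 and p == 1.0

    def test_degenerate_reference(self):
        z, p = z_statistic(1.0, 0.5, 5)
        assert z == -math.inf and p == 0.0
        z, p = z_statistic(1.0, 1.0, 5)
        assert z == 0.0 and p == 1.0


class TestFit:
    def test_perfectly_linear_pair(self):
        X = np.array([[1, 2], [2, 4], [3, 6], [4, 8], [5, 10]], dtype=float)
        b = ReticulotypeBuilder().fit(X, gene_ids=["a", "b"])
        assert b.r_[0, 1] == pytest.approx(1.0)
        assert b.n_reference_ == 5

    def test_constant_gene_invalid(self):
        X = np.array([[1, 7], [2, 7], [3, 7]], dtype=float)
        b = ReticulotypeBuilder().fit(X)
        assert not b.valid_pair_[0, 1]
        assert math.isnan(b.r_[0, 1])

    def test_pair_count(self):
        X = np.random.default_rng(0).random((5, 4))
        b = ReticulotypeBuilder().fit(X)
        assert int(np.triu(b.valid_pair_, 1).sum()) == count_pairs(4) == 6

    def test_too_few_controls(self):
        with pytest.raises(ValueError, match=">= 3 control"):
            ReticulotypeBuilder().fit(np.ones((2, 4)))


class TestPerturb:
    def _builder(self):
        rng = np.random.default_rng(3)
        X = rng.random((5, 6))
        inter = make_interactome([("g0", "g1"), ("g2", "g3")])
        b = ReticulotypeBuilder(interactome=inter)
        return b.fit(X), rng

    def test_records_match_formula(self):
        b, rng = self._builder()
        recs = b.perturb(rng.random(6))
        assert len(recs) == count_pairs(6)
        for rec in recs:
            assert rec.delta == pytest.approx(rec.r_prime - rec.r)
            z, p = z_statistic(rec.r, rec.r_prime, b.n_reference_)
            assert rec.z == pytest.approx(z) and rec.p == pytest.approx(p)
            assert rec.p_adjusted == pytest.approx(min(1.0, rec.p * len(recs)))
            assert rec.significant == (rec.p_adjusted < b.alpha)

    def test_bonferroni_family_override(self):
        b, rng = self._builder()
        recs = b.perturb(rng.random(6), family_size=10)
        for rec in recs:
            assert rec.p_adjusted == pytest.approx(min(1.0, rec.p * 10))

    def test_incremental_equals_scratch(self):
        rng = np.random.default_rng(11)
        X = rng.random((5, 6))
        y = rng.random(6)
        b = ReticulotypeBuilder().fit(X)
        rp, _ = b._r_prime(y)
        scratch = np.corrcoef(np.vstack([X, y]), rowvar=False)
        assert np.allclose(rp, scratch, atol=1e-12)

    def test_misaligned_gene_ids(self):
        b, _ = self._builder()
        bad = pd.Series(np.zeros(6), index=[f"x{i}" for i in range(6)])
        with pytest.raises(ValueError, match="gene ids"):
            b.perturb(bad)

    def test_interactome_family_restricts_tests(self):
        b, rng = self._builder()
        b.set_params(family="interactome_pairs")
        b._tested_mask = b._make_tested_mask()
        recs = b.perturb(rng.random(6))
        assert {(r.gene_a, r.gene_b) for r in recs} == {("g0", "g1"), ("g2", "g3")}


class TestBuildReticulotype:
    def _rec(self, a, b, sig):
        return PerturbationRecord(a, b, 0.0, 0.9, 0.9, 3.6, 1e-4, 1e-3, sig)

    def test_intersection_with_interactome(self):
        inter = make_interactome([("A", "B"), ("B", "D")])
        recs = [self._rec("A", "B", True), self._rec("A", "C", True)]
        net = build_reticulotype(recs, inter, "p1")
        assert net.edges == {("A", "B")} and net.nodes == {"A", "B"}

    def test_empty_network(self):
        inter = make_interactome([("A", "B")])
        net = build_reticulotype([self._rec("A", "B", False)], inter, "p1")
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_saturation(self):
        inter = make_interactome([("A", "B"), ("C", "D")])
        recs = [self._rec("A", "B", True), self._rec("C", "D", True),
                self._rec("A", "C", True)]
        net = build_reticulotype(recs, inter, "p1")
        assert net.edges == inter.edges


class TestAlphaMonotonicity:
    def test_decreasing_alpha_never_adds_edges(self):
        rng = np.random.default_rng(5)
        X = rng.random((5, 8))
        y = rng.random(8)
        genes = [f"g{i}" for i in range(8)]
        inter = make_interactome(
            [(genes[i], genes[j]) for i in range(8) for j in range(i + 1, 8)]
        )
        edges = {}
        for alpha in (0.001, 0.05, 0.5):
            b = ReticulotypeBuilder(alpha=alpha, interactome=inter).fit(
                X, gene_ids=genes
            )
            edges[alpha] = b.transform([y])[0].edges
        assert edges[0.001] <= edges[0.05] <= edges[0.5]


class TestPermutationSymmetry:
    def test_relabeling_permutes_network(self):
        rng = np.random.default_rng(9)
        X = rng.random((5, 5))
        y = rng.random(5)
        genes = [f"g{i}" for i in range(5)]
        perm = [3, 1, 4, 0, 2]
        pg = [genes[i] for i in perm]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
        inter = make_interactome(pairs)
        net = ReticulotypeBuilder(interactome=inter).fit(X, gene_ids=genes).transform([y])[0]
        net_p = (
            ReticulotypeBuilder(interactome=inter)
            .fit(X[:, perm], gene_ids=pg)
            .transform([y[perm]])[0]
        )
        assert net.edges == net_p.edges


class TestRunCohort:
    def test_one_network_per_patient_shared_reference(self, tiny_matrix):
        inter = make_interactome([("GA", "GB"), ("GB", "GC")])
        res = run_cohort(tiny_matrix, inter)
        assert len(res.networks) == 2
        assert [n.patient_id for n in res.networks] == ["P1", "P2"]
        assert all(
            n.params["n_reference"] == 5 and n.params["family_size"] == res.log["family_size"]
            for n in res.networks
        )

    def test_no_patients_empty_list(self):
        m = make_matrix({"G1": [1, 5, 3, 2, 8], "G2": [4, 2, 7, 1, 9]})
        inter = make_interactome([("G1", "G2")])
        assert run_cohort(m, inter).networks == []

    def test_planted_perturbation_is_patient_specific(self):
        # patient 1 decouples the module; patients 2-3 are null draws
        spec = SyntheticCohortSpec(
            n_genes=40,
            n_patients=3,
            modules=[ModuleSpec("mod", 10, 0.9)],
            perturbations=[[("mod", "decouple")], [], []],
            seed=42,
        )
        cohort = generate(spec)
        res = run_cohort(
            cohort.expression, cohort.interactome, family="interactome_pairs"
        )
        planted = cohort.truth.covered_pairs["P01"]
        hits = {
            n.patient_id: len(n.edges & planted) for n in res.networks
        }
        assert hits["P01"] >= 1
        assert hits["P01"] > max(hits["P02"], hits["P03"])
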