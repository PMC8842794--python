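import networkx as nx
import numpy as np
import pytest

from pertnet import diffexpr, errors, simulate
from pertnet.nettest import lcc_size


class TestPerturbation:
    def test_zero_de_fraction_has_no_de_genes(self):
        _, truth = simulate.simulate_perturbation(n_genes=50, de_fraction=0.0, seed=1)
        assert truth.genes["is_de"].sum() == 0
        assert (truth.genes["true_lfc"] == 0).all()

    def test_same_seed_identical(self):
        a, _ = simulate.simulate_perturbation(n_genes=100, seed=42)
        b, _ = simulate.simulate_perturbation(n_genes=100, seed=42)
        assert a.values.equals(b.values)

    def test_different_seed_differs(self):
        a, _ = simulate.simulate_perturbation(n_genes=100, seed=1)
        b, _ = simulate.simulate_perturbation(n_genes=100, seed=2)
        assert not a.values.equals(b.values)

    def test_group_sizes_and_flavor(self):
        em, _ = simulate.simulate_perturbation(n_genes=10, n_per_group=4, seed=0)
        assert len(em.samples_in_group("treated")) == 4
        assert len(em.samples_in_group("control")) == 4
        assert em.flavor == "intensity"

    def test_small_group_rejected(self):
        with pytest.raises(errors.ParameterError):
            simulate.simulate_perturbation(n_per_group=1, seed=0)

    def test_down_fraction_controls_sign_split(self):
        _, truth = simulate.simulate_perturbation(
            n_genes=1000, de_fraction=0.5, down_fraction=0.76, seed=3
        )
        lfc = truth.genes.loc[truth.genes["is_de"], "true_lfc"]
        assert (lfc < 0).mean() == pytest.approx(0.76, abs=0.01)

    def test_planted_effects_recoverable_by_deg_filter(self):
        em, truth = simulate.simulate_perturbation(
            n_genes=1000, n_per_group=3, de_fraction=0.05,
            lfc_location=2.0, sigma=0.5, seed=11,
        )
        table = diffexpr.call_degs(
            diffexpr.ttest_fold_change(em, "control", "treated")
        )
        sens = table.loc[truth.de_genes, "is_deg"].mean()
        assert sens >= 0.9


class TestCohort:
    def test_same_seed_identical_counts(self):
        a, _ = simulate.simulate_cohort(n_genes=50, seed=9)
        b, _ = simulate.simulate_cohort(n_genes=50, seed=9)
        assert a.values.equals(b.values)

    def test_counts_are_nonnegative_integers(self):
        em, _ = simulate.simulate_cohort(n_genes=50, seed=2)
        arr = em.values.to_numpy()
        assert (arr >= 0).all() and np.issubdtype(arr.dtype, np.integer)

    def test_low_dispersion_null_yields_no_degs(self):
        # with no planted effects and near-Poisson noise the count screen
        # should call nothing at FDR <= 0.05 in nearly every replicate
        hits = 0
        for seed in range(10):
            em, _ = simulate.simulate_cohort(
                n_tumor=20, n_normal=20, n_genes=300, de_fraction=0.0,
                dispersion=1e-4, seed=seed,
            )
            hits += int(diffexpr.count_degs(em)["is_deg"].sum() > 0)
        assert hits <= 1

    def test_planted_multiplier_matches_empirical_ratio(self):
        em, truth = simulate.simulate_cohort(
            n_tumor=500, n_normal=500, n_genes=20, de_fraction=0.0,
            dispersion=0.1, seed=4, lfc_of={"GENE0003": 2.0},
        )
        tum = em.values.loc["GENE0003", em.samples_in_group("tumor")].mean()
        nor = em.values.loc["GENE0003", em.samples_in_group("normal")].mean()
        # dispersion 0.1 at n=500 puts the ratio's spread well inside 10%
        assert tum / nor == pytest.approx(4.0, rel=0.1)
        assert truth.genes.loc["GENE0003", "is_de"]

    def test_bad_dispersion_rejected(self):
        with pytest.raises(errors.ParameterError):
            simulate.simulate_cohort(dispersion=0.0, seed=0)


class TestSurvival:
    def _expr(self, seed=0, n=40):
        em, _ = simulate.simulate_perturbation(
            n_genes=5, n_per_group=n // 2, de_fraction=0.0, seed=seed
        )
        return em

    def test_same_seed_identical(self):
        em = self._expr()
        a = simulate.simulate_survival(em, {"GENE0001": 1.0}, seed=5)
        b = simulate.simulate_survival(em, {"GENE0001": 1.0}, seed=5)
        assert a.time.equals(b.time) and a.event.equals(b.event)

    def test_censoring_boundary(self):
        em = self._expr()
        cohort = simulate.simulate_survival(em, {}, censor_time=3.0, seed=1)
        assert (cohort.time <= 3.0).all()
        assert ((cohort.event == 0) == (cohort.time == 3.0)).all()

    def test_zero_censor_time_leaves_no_events_for_cox(self):
        from pertnet.survival import cox_univariate
        em = self._expr()
        cohort = simulate.simulate_survival(em, {}, censor_time=0.0, seed=1)
        assert cohort.n_events == 0
        with pytest.raises(errors.DataError, match="no events"):
            cox_univariate(cohort, "GENE0001")

    def test_unknown_risk_gene_rejected(self):
        with pytest.raises(errors.ParameterError):
            simulate.simulate_survival(self._expr(), {"NOPE": 1.0}, seed=0)

    def test_bad_base_hazard_rejected(self):
        with pytest.raises(errors.ParameterError):
            simulate.simulate_survival(self._expr(), {}, base_hazard=0.0, seed=0)


class TestNetwork:
    def test_no_module_is_plain_graph(self):
        g, truth = simulate.simulate_network(n_nodes=100, planted_module_size=0, seed=1)
        assert truth.planted_module == []
        assert g.number_of_nodes() == 100

    def test_full_density_module_is_clique(self):
        g, truth = simulate.simulate_network(
            n_nodes=100, planted_module_size=10, planted_density=1.0, seed=2
        )
        mod = truth.planted_module
        assert len(mod) == 10
        assert lcc_size(g, mod) == 10
        sub = g.subgraph(mod)
        assert sub.number_of_edges() == 45

    def test_same_seed_identical_edges(self):
        a, _ = simulate.simulate_network(n_nodes=80, planted_module_size=5,
                                         planted_density=0.5, seed=3)
        b, _ = simulate.simulate_network(n_nodes=80, planted_module_size=5,
                                         planted_density=0.5, seed=3)
        assert set(map(frozenset, a.edges())) == set(map(frozenset, b.edges()))

    def test_simple_graph_invariants(self):
        g, _ = simulate.simulate_network(n_nodes=60, planted_module_size=20,
                                         planted_density=0.8, seed=4)
        assert nx.number_of_selfloops(g) == 0

    def test_oversized_module_rejected(self):
        with pytest.raises(errors.ParameterError):
            simulate.simulate_network(n_nodes=10, planted_module_size=11, seed=0)


class TestGeneSets:
    GENES = [f"GENE{i:04d}" for i in range(200)]

    def test_full_fraction_set_is_subset_of_de(self):
        de = self.GENES[:80]
        coll, _ = simulate.simulate_gene_sets(
            self.GENES, de, n_sets=3, set_size_range=(10, 20),
            enriched_sets={"S": 1.0}, seed=1,
        )
        assert coll.members("S") <= set(de)

    def test_same_seed_identical(self):
        a, _ = simulate.simulate_gene_sets(self.GENES, self.GENES[:20], seed=7)
        b, _ = simulate.simulate_gene_sets(self.GENES, self.GENES[:20], seed=7)
        assert a.sets == b.sets

    def test_oversized_set_rejected(self):
        with pytest.raises(errors.ParameterError):
            simulate.simulate_gene_sets(self.GENES[:10], [], set_size_range=(5, 50),
                                        seed=0)

    def test_type_invariants_over_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n_sets = int(rng.integers(1, 8))
            lo = int(rng.integers(5, 15))
            hi = int(rng.integers(lo, 40))
            coll, _ = simulate.simulate_gene_sets(
                self.GENES, self.GENES[:50], n_sets=n_sets,
                set_size_range=(lo, hi), seed=int(rng.integers(2**31)),
            )
            assert len(coll) == n_sets
            for name in coll:
                members = coll.sets[name]
                assert members and len(members) == len(set(members))
                assert len(members) <= hi


class TestStudy:
    def test_study_is_coherent_and_reproducible(self):
        a = simulate.simulate_study(5, n_genes=300, n_tumor=20, n_normal=10)
        b = simulate.simulate_study(5, n_genes=300, n_tumor=20, n_normal=10)
        assert a.perturbation.values.equals(b.perturbation.values)
        assert a.true_regulator == b.true_regulator
        assert set(map(frozenset, a.network.edges())) == set(
            map(frozenset, b.network.edges()))
        # the regulator is a drug-down DE gene with a planted hazard
        assert a.perturbation_truth.genes.loc[a.true_regulator, "true_lfc"] < 0
        assert a.cohort_truth.genes.loc[a.true_regulator, "true_beta"] > 0
        # planted module nodes are network nodes and DE genes
        assert set(a.network_truth.planted_module) <= set(a.network.nodes())
        assert set(a.network_truth.planted_module) <= set(a.perturbation_truth.de_genes)
        # survival cohort covers tumor samples only
        assert all(s.startswith("tumor") for s in a.survival.samples)
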