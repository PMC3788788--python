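import numpy as np
import pandas as pd
import pytest

from miractive import (
    ConsensusCall,
    ConsensusCallSet,
    EdgeList,
    GeneGeneNetwork,
    RunConfig,
    SimulationConfig,
    SimulationTruth,
    ValidationError,
    add_expression_noise,
    apply_diffusion,
    evaluate_recovery,
    perturb_network,
    robustness_sweep,
    simulate_cohort,
    synthetic_gene_network,
    synthetic_target_network,
)
import scipy.sparse as sp

from conftest import de_matrix


class TestSimulateCohort:
    def test_degenerate_sd_reproduces_means(self, small_network):
        cfg = SimulationConfig(n_active=4, n_patients=6, patient_sd=0.0, seed=1)
        mirna_de, _, truth = simulate_cohort(small_network, cfg)
        for m, mean in truth.planted_means.items():
            np.testing.assert_allclose(mirna_de.data.loc[m], mean)
        inactive = set(small_network.mirna_ids) - set(truth.active_mirna_ids)
        for m in inactive:
            np.testing.assert_allclose(mirna_de.data.loc[m], 0.0)

    def test_gene_de_is_network_times_mirna_de(self, small_network):
        cfg = SimulationConfig(n_active=4, n_patients=5, seed=2)
        mirna_de, gene_de, _ = simulate_cohort(small_network, cfg)
        expected = small_network.matrix @ mirna_de.values
        np.testing.assert_allclose(gene_de.values, expected)

    def test_untargeted_by_active_gene_has_zero_mean(self, small_network):
        """Genes hit only by inactive miRNAs have expectation 0 across
        patients (inactive miRNA DE is zero-mean noise)."""
        cfg = SimulationConfig(n_active=3, n_patients=100, seed=3)
        mirna_de, gene_de, truth = simulate_cohort(small_network, cfg)
        active_idx = [
            small_network.mirna_ids.index(m) for m in truth.active_mirna_ids
        ]
        dense = small_network.matrix.toarray()
        untouched = np.flatnonzero(dense[:, active_idx].sum(axis=1) == 0)
        assert len(untouched) > 0
        degrees = (dense[untouched] != 0).sum(axis=1)
        means = gene_de.values[untouched].mean(axis=1)
        se = cfg.patient_sd * np.sqrt(np.maximum(degrees, 1) / cfg.n_patients)
        assert np.all(np.abs(means) <= 3.5 * se + 1e-12)

    def test_single_active_target_sign_flip(self):
        """A gene targeted by exactly one active miRNA with planted mean +mu
        has expected DE -mu (the -1 design entry flips the sign)."""
        edges = EdgeList.from_pairs([("mir0", "g0"), ("mir1", "g1")])
        from miractive import build_influence_matrix

        N = build_influence_matrix(edges, ["g0", "g1"], ["mir0", "mir1"])
        cfg = SimulationConfig(
            n_active=1, n_patients=400, patient_sd=0.5, seed=4
        )
        _, gene_de, truth = simulate_cohort(N, cfg)
        (active,) = truth.active_mirna_ids
        mu = truth.planted_means[active]
        gene = "g0" if active == "mir0" else "g1"
        observed = gene_de.data.loc[gene].mean()
        se = cfg.patient_sd / np.sqrt(cfg.n_patients)
        assert abs(observed - (-mu)) <= 3 * se

    def test_too_many_active_rejected(self, small_network):
        with pytest.raises(ValidationError):
            simulate_cohort(
                small_network,
                SimulationConfig(n_active=100, n_patients=3, seed=0),
            )

    def test_reproducible_with_seed(self, small_network):
        cfg = SimulationConfig(n_active=3, n_patients=4, seed=11)
        a = simulate_cohort(small_network, cfg)
        b = simulate_cohort(small_network, cfg)
        pd.testing.assert_frame_equal(a[0].data, b[0].data)
        pd.testing.assert_frame_equal(a[1].data, b[1].data)
        assert a[2].planted_means == b[2].planted_means


class TestPerturbNetwork:
    def test_identity_when_zero(self, toy_edges):
        assert perturb_network(toy_edges, 0.0, 0.0, seed=0) is toy_edges

    def test_removal_count_is_floor(self):
        edges = EdgeList.from_pairs(
            (f"m{j}", f"g{i}") for j in range(10) for i in range(100)
        )
        out = perturb_network(edges, 0.0, 0.5, seed=1)
        assert len(out) == 1000 - 500
        out2 = perturb_network(edges, 0.0, 0.333, seed=1)
        assert len(out2) == 1000 - 333

    def test_added_edges_are_new_and_counted(self, rng):
        edges = EdgeList.from_pairs(
            (f"m{j}", f"g{i}") for j in range(5) for i in rng.choice(60, 20, replace=False)
        )
        out = perturb_network(edges, 0.3, 0.0, seed=2)
        added = out.edges - edges.edges
        assert len(added) == int(0.3 * len(edges))
        assert edges.edges <= out.edges

    def test_full_removal_rejected(self, toy_edges):
        with pytest.raises(ValidationError):
            perturb_network(toy_edges, 0.0, 1.0, seed=0)


class TestApplyDiffusion:
    def _path_graph(self):
        adj = sp.csr_matrix(np.array([[0, 1], [1, 0]], dtype=float))
        return GeneGeneNetwork(gene_ids=("g0", "g1"), adjacency=adj)

    def test_gamma_zero_identity(self):
        de = de_matrix([[1.0], [0.0]], feature_prefix="g")
        out = apply_diffusion(de, self._path_graph(), 0.0)
        np.testing.assert_array_equal(out.values, de.values)

    def test_two_gene_path_hand_computed(self):
        de = de_matrix([[1.0], [0.0]], feature_prefix="g")
        out = apply_diffusion(de, self._path_graph(), 0.1)
        np.testing.assert_allclose(out.values[:, 0], [1.01, 0.1])

    def test_isolated_gene_unchanged(self):
        adj = sp.csr_matrix(
            np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float)
        )
        G = GeneGeneNetwork(gene_ids=("g0", "g1", "g2"), adjacency=adj)
        de = de_matrix([[1.0], [2.0], [5.0]], feature_prefix="g")
        out = apply_diffusion(de, G, 0.4)
        assert out.values[2, 0] == 5.0

    def test_gamma_out_of_range_rejected(self):
        de = de_matrix([[1.0], [0.0]], feature_prefix="g")
        with pytest.raises(ValidationError):
            apply_diffusion(de, self._path_graph(), 1.0)


class TestAddExpressionNoise:
    def test_nu_zero_identity(self, rng):
        de = de_matrix(rng.normal(size=(5, 4)))
        out = add_expression_noise(de, 0.0, seed=0)
        np.testing.assert_array_equal(out.values, de.values)

    def test_variance_proportional_to_signal(self):
        const = 2.5
        de = de_matrix(np.full((1000, 1000), const))
        nu = 0.8
        out = add_expression_noise(de, nu, seed=5)
        noise = out.values - const
        assert abs(noise.mean()) < 3 * np.sqrt(nu * const / noise.size)
        assert noise.var() == pytest.approx(nu * const, rel=0.05)

    def test_zero_entries_get_cohort_anchor(self):
        values = np.zeros((200, 50))
        values[:100] = 4.0  # mean |Y| = 2.0
        de = de_matrix(values)
        out = add_expression_noise(de, 1.0, seed=6)
        zero_noise = out.values[100:]
        assert zero_noise.var() == pytest.approx(2.0, rel=0.1)


class TestEvaluateRecovery:
    def _truth(self, signs):
        cfg = SimulationConfig(n_active=len(signs), n_patients=2, seed=0)
        return SimulationTruth(
            active_mirna_ids=tuple(signs),
            planted_means={m: 2.0 * s for m, s in signs.items()},
            config=cfg,
        )

    def _calls(self, signs):
        return ConsensusCallSet(
            tuple(ConsensusCall(m, s, 0.9) for m, s in signs.items())
        )

    def test_perfect_recovery(self):
        truth = self._truth({"a": 1, "b": -1})
        calls = self._calls({"a": 1, "b": -1})
        assert evaluate_recovery(calls, truth) == (1.0, 1.0, 1.0)

    def test_partial_overlap(self):
        truth = self._truth({"a": 1, "b": -1, "c": 1})
        calls = self._calls({"a": 1, "b": -1, "d": 1})
        sens, prec, _ = evaluate_recovery(calls, truth)
        assert sens == pytest.approx(2 / 3)
        assert prec == pytest.approx(2 / 3)

    def test_empty_predictions(self):
        truth = self._truth({"a": 1})
        sens, prec, sign_acc = evaluate_recovery(ConsensusCallSet(()), truth)
        assert (sens, prec) == (0.0, 0.0)

    def test_matches_brute_force_set_arithmetic(self, rng):
        universe = [f"m{i}" for i in range(12)]
        for _ in range(30):
            t_ids = rng.choice(universe, size=4, replace=False)
            p_ids = rng.choice(universe, size=int(rng.integers(0, 6)), replace=False)
            truth = self._truth({m: int(rng.choice([-1, 1])) for m in t_ids})
            calls = self._calls({m: int(rng.choice([-1, 1])) for m in p_ids})
            sens, prec, sign_acc = evaluate_recovery(calls, truth)
            ts, ps = truth.signs(), calls.signs()
            inter = set(ts) & set(ps)
            assert sens == len(inter) / len(ts)
            if ps:
                assert prec == len(inter) / len(ps)
            if inter:
                assert sign_acc == sum(ts[m] == ps[m] for m in inter) / len(inter)


class TestSyntheticNetworks:
    def test_target_network_median_fraction(self):
        edges = synthetic_target_network(40, 1000, seed=0, median_target_fraction=0.04)
        counts = {}
        for m, _ in edges.edges:
            counts[m] = counts.get(m, 0) + 1
        med = np.median(list(counts.values()))
        assert 0.02 * 1000 <= med <= 0.08 * 1000

    def test_gene_network_is_valid_and_sized(self):
        ids = [f"g{i}" for i in range(300)]
        G = synthetic_gene_network(ids, seed=1, mean_degree=8.0)
        assert G.adjacency.diagonal().sum() == 0
        assert (G.adjacency != G.adjacency.T).nnz == 0
        mean_deg = G.adjacency.sum() / len(ids)
        assert 5.0 <= mean_deg <= 8.5


@pytest.fixture(scope="module")
def mini_network():
    from miractive import build_influence_matrix

    edges = synthetic_target_network(10, 150, seed=21)
    return build_influence_matrix(edges, edges.genes, edges.mirnas)


class TestRobustnessSweep:
    def _configs(self):
        sim = SimulationConfig(n_active=2, n_patients=8, seed=0)
        run = RunConfig(cv_folds=4, seed=0)
        return sim, run

    def test_single_cell_shape(self, mini_network):
        sim, run = self._configs()
        table = robustness_sweep(
            mini_network, [{}], n_replicates=3, seed=5, sim_config=sim, run_config=run
        )
        assert len(table) == 3
        metrics = table[["sensitivity", "precision", "sign_accuracy"]]
        assert (metrics >= 0).all().all() and (metrics <= 1).all().all()

    def test_identical_seed_identical_table(self, mini_network):
        sim, run = self._configs()
        t1 = robustness_sweep(
            mini_network, [{"edge_remove_fraction": 0.2}], 2, seed=9,
            sim_config=sim, run_config=run,
        )
        t2 = robustness_sweep(
            mini_network, [{"edge_remove_fraction": 0.2}], 2, seed=9,
            sim_config=sim, run_config=run,
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_grid_rows(self, mini_network):
        sim, run = self._configs()
        grid = [{"edge_add_fraction": a, "edge_remove_fraction": r}
                for a in (0.0, 0.2) for r in (0.0, 0.2)]
        table = robustness_sweep(
            mini_network, grid, n_replicates=1, seed=2, sim_config=sim, run_config=run
        )
        assert len(table) == 4

    def test_empty_grid_rejected(self, mini_network):
        with pytest.raises(ValidationError):
            robustness_sweep(mini_network, [], 1, seed=0)
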