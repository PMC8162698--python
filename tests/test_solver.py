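"""Matrix-exponential solver: exactness, conservation, factorized path."""

import numpy as np
import pytest

import cryptdyn as cd
from cryptdyn.errors import NumericalError, ParameterError
from cryptdyn.genes import build_gene_graph


class TestSolve:
    def test_age_zero_returns_initial_state(self, lynch_system, lynch_config):
        x0 = cd.initial_state(lynch_config, lynch_system.index)
        traj = cd.solve(lynch_system, x0, np.array([0.0, 1.0]))
        assert traj.states[0] == pytest.approx(x0)

    def test_two_state_closed_form(self):
        """dx1/dt = -r x1, x2 absorbing: x2(t) = N (1 - exp(-r t))."""
        r, N = 0.3, 1000.0
        M = np.array([[-r, r], [0.0, 0.0]])
        ages = np.linspace(0, 10, 11)
        traj = cd.solve(M, np.array([N, 0.0]), ages)
        assert traj.states[:, 1] == pytest.approx(N * (1 - np.exp(-r * ages)), rel=1e-12)
        assert traj.states[:, 0] == pytest.approx(N * np.exp(-r * ages), rel=1e-12)

    def test_conservation_without_fitness(self, lynch_b0_trajectory):
        totals = lynch_b0_trajectory.total()
        assert np.allclose(totals, 9.95e6, rtol=1e-9)

    def test_semigroup_property(self, lynch_system, lynch_config):
        x0 = cd.initial_state(lynch_config, lynch_system.index)
        direct = cd.solve(lynch_system, x0, np.array([40.0]))
        first = cd.solve(lynch_system, x0, np.array([25.0]))
        restart = cd.solve(lynch_system, first.states[0], np.array([15.0]))
        assert restart.states[0] == pytest.approx(direct.states[0], rel=1e-8, abs=1e-12)

    def test_absorbing_counts_nondecreasing(self, lynch_b0_trajectory):
        """Without fitness terms, fully mutated (absorbing) genotypes only
        accumulate mass."""
        traj = lynch_b0_trajectory
        idx = traj.index
        terminal = idx.to_flat(("ll", "ml", "ml", "m", "ml"))
        diffs = np.diff(traj.states[:, terminal])
        assert np.all(diffs >= -1e-9)

    def test_sparse_action_path_matches_dense(self, lynch_system, lynch_config):
        x0 = cd.initial_state(lynch_config, lynch_system.index)
        ages = np.array([0.0, 10.0, 30.0])
        dense = cd.solve(lynch_system, x0, ages)
        sparse = cd.solve(lynch_system, x0, ages, dense_limit=10)
        assert sparse.states == pytest.approx(dense.states, rel=1e-8, abs=1e-9)

    def test_invalid_grid_rejected(self, lynch_system, lynch_config):
        x0 = cd.initial_state(lynch_config, lynch_system.index)
        with pytest.raises(ParameterError):
            cd.solve(lynch_system, x0, np.array([5.0, 1.0]))
        with pytest.raises(ParameterError):
            cd.solve(lynch_system, x0[:-1], np.array([0.0, 1.0]))

    def test_significant_negativity_raises(self):
        # a matrix violating the generator sign convention drives the
        # solution negative far beyond the clamping tolerance
        M = np.array([[0.0, -5.0], [0.0, 0.0]])
        with pytest.raises(NumericalError):
            cd.solve(M, np.array([1.0, 1.0]), np.array([1.0]))


class TestFactorized:
    def test_matches_full_solution_on_A_only(self, lynch_config, globals_calibrated):
        cfg = lynch_config
        graphs = [build_gene_graph(gene, cfg.global_params) for gene in cfg.genes]
        factors = [np.eye(g.gene.n_states)[g.gene.state_index(s)]
                   for g, s in zip(graphs, ("m", "0", "0", "0", "0"))]
        ages = cd.default_age_grid()
        fact = cd.solve_factorized(graphs, factors, cfg.global_params.n_crypts, ages)

        system = cd.assemble(list(cfg.genes), cfg.global_params, active=frozenset())
        x0 = cd.initial_state(cfg, system.index)
        full = cd.solve(system, x0, ages)
        np.testing.assert_allclose(fact.states, full.states, rtol=1e-8, atol=1e-12)

    def test_age_zero_is_scaled_unit_kronecker(self, lynch_config):
        cfg = lynch_config
        graphs = [build_gene_graph(gene, cfg.global_params) for gene in cfg.genes]
        factors = [np.eye(g.gene.n_states)[g.gene.state_index(s)]
                   for g, s in zip(graphs, ("m", "0", "0", "0", "0"))]
        traj = cd.solve_factorized(graphs, factors, 9.95e6, np.array([0.0]))
        assert traj.states[0].sum() == pytest.approx(9.95e6)
        nz = np.flatnonzero(traj.states[0])
        assert nz.size == 1
        assert traj.index.to_tuple(int(nz[0])) == ("m", "0", "0", "0", "0")

    def test_single_gene_model_matches_direct_solve(self, globals_calibrated):
        spec = cd.default_gene_specs()["APC"]
        graph = build_gene_graph(spec, globals_calibrated)
        ages = np.linspace(0, 50, 6)
        fact = cd.solve_factorized([graph], [np.eye(5)[0]], 100.0, ages)
        direct = cd.solve(graph.rate_matrix, 100.0 * np.eye(5)[0], ages)
        assert fact.states == pytest.approx(direct.states, rel=1e-10)

    def test_factor_shape_mismatch_rejected(self, globals_calibrated):
        spec = cd.default_gene_specs()["APC"]
        graph = build_gene_graph(spec, globals_calibrated)
        with pytest.raises(ParameterError):
            cd.solve_factorized([graph], [np.zeros(3)], 1.0, np.array([0.0]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_solver_matches_dense_reference_on_toys(self, seed):
        model = cd.make_toy(seed, n_genes=2, states_per_gene=3, rate_range=(1e-3, 1e-1))
        M = cd.kronecker_sum(list(model.factors))
        rng = np.random.default_rng(seed + 1000)
        x0 = rng.uniform(0, 100, size=model.total_dim)
        t = 25.0
        got = cd.solve(M, x0, np.array([t])).states[0]
        want = cd.dense_reference_solve(model, x0, t)
        np.testing.assert_allclose(got, np.clip(want, 0, None), rtol=1e-9, atol=1e-10)

    @pytest.mark.parametrize("seed", [2, 9, 17])
    def test_factorized_matches_reference_on_toys(self, seed):
        model = cd.make_toy(seed, n_genes=3, states_per_gene=2, rate_range=(1e-3, 1e-1))
        genes = [
            cd.GeneSpec(f"G{i}", "oncogene", n_hs=1.0)
            for i in range(3)
        ]
        graphs = [
            cd.MutationGraph(gene=g, rate_matrix=f)
            for g, f in zip(genes, model.factors)
        ]
        factors = [np.eye(2)[0]] * 3
        traj = cd.solve_factorized(graphs, factors, 50.0, np.array([0.0, 12.5]))
        want = cd.dense_reference_solve(model, 50.0 * np.kron(np.kron(factors[0], factors[1]), factors[2]), 12.5)
        np.testing.assert_allclose(traj.states[1], want, rtol=1e-9, atol=1e-10)


class TestTrajectory:
    def test_to_frame_tidy_and_wide(self, lynch_b0_trajectory):
        tidy = lynch_b0_trajectory.to_frame()
        assert set(tidy.columns) == {"age", "genotype", "count"}
        wide = lynch_b0_trajectory.to_frame(tidy=False)
        assert wide.shape == (71, 1250)
        assert wide.sum(axis=1).to_numpy() == pytest.approx(np.full(71, 9.95e6))

    def test_at_age(self, lynch_b0_trajectory):
        assert lynch_b0_trajectory.at_age(0.0) == pytest.approx(lynch_b0_trajectory.x0)
        with pytest.raises(KeyError):
            lynch_b0_trajectory.at_age(70.5)
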