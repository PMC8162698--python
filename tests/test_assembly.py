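"""Genotype index, Kronecker sum and dependency matrices."""

import numpy as np
import pytest
import scipy.sparse as sp

import cryptdyn as cd
from cryptdyn.errors import ConfigurationError


def rowsums(mat):
    return np.asarray(mat.sum(axis=1)).ravel()


class TestGenotypeIndex:
    def test_bijection_and_ordering(self, lynch_system):
        idx = lynch_system.index
        assert idx.total_dim == 1250
        seen = set()
        prev = -1
        for genotype in idx.genotypes():
            flat = idx.to_flat(genotype)
            assert idx.to_tuple(flat) == genotype
            assert flat == prev + 1  # iteration is flat-index order
            prev = flat
            seen.add(flat)
        assert seen == set(range(1250))

    def test_single_gene_advance_increases_flat_index(self, lynch_system):
        idx = lynch_system.index
        base = ("m", "0", "0", "0", "0")
        for pos, gene in enumerate(idx.genes):
            s0 = base[pos]
            for later in gene.states[gene.state_index(s0) + 1:]:
                advanced = base[:pos] + (later,) + base[pos + 1:]
                assert idx.to_flat(advanced) > idx.to_flat(base)

    def test_label_renders_wild_type_as_zero(self, lynch_system):
        idx = lynch_system.index
        lab = idx.label(idx.to_flat(("mm", "0", "0", "0", "0")))
        assert lab == "MLH1:mm|CTNNB1:0|APC:0|KRAS:0|TP53:0"


class TestKroneckerSum:
    def test_scalar_case(self):
        out = cd.kronecker_sum([np.array([[2.0]]), np.array([[3.0]])])
        assert out.toarray() == pytest.approx(np.array([[5.0]]))

    def test_dimension_is_product(self):
        mats = [np.zeros((n, n)) for n in (5, 5, 5, 2, 5)]
        assert cd.kronecker_sum(mats).shape == (1250, 1250)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            cd.kronecker_sum([np.zeros((2, 3))])

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_cartesian_product_adjacency(self, seed):
        """Kronecker sum vs brute-force Cartesian-product enumeration."""
        model = cd.make_toy(seed, n_genes=2, states_per_gene=3)
        got = cd.kronecker_sum(list(model.factors)).toarray()
        assert got == pytest.approx(cd.brute_force_product(model), rel=1e-14, abs=1e-18)

    @pytest.mark.parametrize("seed", [3, 11])
    def test_three_factor_oracle(self, seed):
        model = cd.make_toy(seed, n_genes=3, states_per_gene=(2, 4, 3))
        got = cd.kronecker_sum(list(model.factors)).toarray()
        assert got == pytest.approx(cd.brute_force_product(model), rel=1e-14, abs=1e-18)

    def test_single_factor_identity(self):
        model = cd.make_toy(7, n_genes=1, states_per_gene=4)
        assert cd.kronecker_sum(list(model.factors)).toarray() == pytest.approx(
            model.factors[0]
        )


class TestIndependentComponent:
    def test_lynch_dimension(self, lynch_system):
        assert lynch_system.A.shape == (1250, 1250)

    def test_generator_when_fitness_zero(self):
        cfg = cd.preset("lynch-mlh1", b_zero=True)
        system = cd.build_system_matrix(cfg)
        assert np.allclose(rowsums(system.A), 0.0, atol=1e-18)
        # summing six components leaves cancellation residue at double
        # precision of the largest entries (~1e-3)
        assert np.allclose(rowsums(system.M), 0.0, atol=1e-15)

    def test_embedded_single_gene_rate(self, lynch_config, lynch_system):
        idx = lynch_system.index
        g = lynch_config.global_params
        mlh1 = lynch_config.gene("MLH1")
        i = idx.to_flat(("m", "0", "0", "0", "0"))
        j = idx.to_flat(("mm", "0", "0", "0", "0"))
        assert lynch_system.A[i, j] == pytest.approx(cd.point_mutation_rate(mlh1, 1, g))

    def test_graph_order_mismatch_rejected(self, lynch_config, globals_calibrated):
        graphs = [
            cd.build_gene_graph(gene, globals_calibrated) for gene in lynch_config.genes
        ]
        idx = cd.GenotypeIndex(genes=tuple(lynch_config.genes))
        with pytest.raises(ConfigurationError):
            cd.build_A(list(reversed(graphs)), idx)


class TestDependencyMatrices:
    def test_all_upper_triangular(self, lynch_system):
        for name in "ABCDEF":
            mat = lynch_system.component(name)
            low = mat - sp.triu(mat)
            assert abs(low).sum() == 0.0

    @pytest.mark.parametrize("name", list("BCDEF"))
    def test_zero_row_sums(self, name, lynch_system):
        assert np.allclose(rowsums(lynch_system.component(name)), 0.0, atol=1e-16)

    def test_B_selector_zeroes_mmr_proficient_rows(self, lynch_system):
        idx = lynch_system.index
        B = lynch_system.B.tocsr()
        for state in ("m", "l"):
            i = idx.to_flat((state, "0", "0", "0", "0"))
            assert B[i].nnz == 0

    def test_B_scaled_apc_entry(self, lynch_config, lynch_system):
        idx = lynch_system.index
        g, dep = lynch_config.global_params, lynch_config.dependency_params
        i = idx.to_flat(("mm", "0", "0", "0", "0"))
        j = idx.to_flat(("mm", "0", "m", "0", "0"))
        assert lynch_system.B[i, j] == pytest.approx(
            dep.beta * cd.point_mutation_rate(lynch_config.gene("APC"), 0, g)
        )

    def test_C_nonzero_count_and_redirection(self, lynch_config, lynch_system):
        assert lynch_system.C.nnz == 400
        idx = lynch_system.index
        g, dep = lynch_config.global_params, lynch_config.dependency_params
        w = dep.r_eff_loh * cd.loh_rate(lynch_config.gene("MLH1"), 1, g)
        i = idx.to_flat(("m", "0", "0", "0", "0"))
        assert lynch_system.C[i, idx.to_flat(("ml", "0", "0", "0", "0"))] == pytest.approx(-w)
        assert lynch_system.C[i, idx.to_flat(("ml", "l", "0", "0", "0"))] == pytest.approx(w)

    def test_C_preserves_row_outflow_of_A(self, lynch_system):
        """C redirects flux: A+C and A have identical row sums."""
        a = rowsums(lynch_system.A)
        ac = rowsums(lynch_system.A + lynch_system.C)
        assert np.allclose(a, ac, atol=1e-16)

    def test_D_selector_and_entry(self, lynch_config, lynch_system):
        idx = lynch_system.index
        D = lynch_system.D.tocsr()
        for apc_state in ("0", "m", "l"):
            i = idx.to_flat(("m", "0", apc_state, "0", "0"))
            assert D[i].nnz == 0
        g, dep = lynch_config.global_params, lynch_config.dependency_params
        i = idx.to_flat(("m", "0", "mm", "0", "0"))
        j = idx.to_flat(("ml", "0", "mm", "0", "0"))
        assert D[i, j] == pytest.approx(
            dep.delta * cd.loh_rate(lynch_config.gene("MLH1"), 1, g)
        )

    def test_E_nonzero_count(self, lynch_system):
        assert lynch_system.E.nnz == 160

    def test_F_scaled_kras_entry(self, lynch_config, lynch_system):
        idx = lynch_system.index
        g, dep = lynch_config.global_params, lynch_config.dependency_params
        i = idx.to_flat(("mm", "0", "0", "0", "0"))
        j = idx.to_flat(("mm", "0", "0", "m", "0"))
        assert lynch_system.F[i, j] == pytest.approx(
            dep.zeta * cd.point_mutation_rate(lynch_config.gene("KRAS"), 0, g)
        )

    def test_zero_parameters_give_zero_matrices(self, lynch_config):
        cfg = lynch_config.with_overrides(
            dependency_params=dict(beta=0.0, delta=0.0, zeta=0.0, r_eff_loh=0.0)
        )
        system = cd.build_system_matrix(cfg)
        for name in "BCDEF":
            assert system.component(name).nnz == 0 or abs(system.component(name)).max() == 0
        assert abs(system.M - system.A).max() == 0.0

    def test_msh2_scenario_has_no_mlh1_ctnnb1_coupling(self):
        system = cd.build_system_matrix(cd.preset("lynch-msh2"))
        assert system.C.nnz == 0
        assert system.E.nnz == 0
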