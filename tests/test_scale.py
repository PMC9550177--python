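import warnings

import numpy as np
import pytest

from kappavelo import fit as fm
from kappavelo import kinetics as kin
from kappavelo import scale as sc


def make_fit(alpha=2.0, gamma=0.5, m=1.0, q_switch=0.9, n=10):
    return fm.GeneKineticsFit(
        alpha=alpha, gamma=gamma, m=m, q_switch=q_switch, k=np.ones(n, int),
        tau=np.zeros(n), residual_variance=1.0, log_likelihood=0.0, converged=True,
        n_iter=1, objective=0.0, sd_u=1.0, sd_s=1.0,
    )


class TestOrdering:
    def test_upregulation_sorted_by_increasing_u(self):
        u = np.array([0.1, 0.3, 0.2])
        order = sc.order_cells_in_phase(u, np.ones(3, int))
        assert list(order[1]) == [0, 2, 1]

    def test_downregulation_sorted_by_decreasing_u(self):
        u = np.array([0.1, 0.3, 0.2])
        order = sc.order_cells_in_phase(u, np.zeros(3, int))
        assert list(order[0]) == [1, 2, 0]

    def test_ties_keep_index_order(self):
        u = np.array([0.5, 0.2, 0.5, 0.2])
        order = sc.order_cells_in_phase(u, np.ones(4, int))
        assert list(order[1]) == [1, 3, 0, 2]

    def test_noiseless_ranking_equals_time_ranking(self, small_sim):
        adata, truth = small_sim
        g = int(np.argmin(truth.scaled_beta))  # slowest gene: all cells active
        u = adata.layers["unspliced"][:, g]
        order = sc.order_cells_in_phase(u, np.ones(len(u), int))
        assert np.array_equal(order[1], np.argsort(truth.t, kind="stable"))


class TestPairF:
    def test_equal_cells_give_zero(self):
        f = make_fit()
        assert sc.pair_f(1.0, 1.0, f) == pytest.approx(0.0)

    def test_downregulation_closed_form(self):
        f = make_fit(alpha=2.0, m=1.0)
        assert sc.pair_f(2.0, 1.0, f, phase=0) == pytest.approx(np.log(2.0))

    def test_upregulation_inverts_forward_solution(self):
        # u goes 0 -> alpha(1 - e^-1) in unit time when beta = 1
        f = make_fit(alpha=2.0, m=1.0)
        u_j = 2.0 * (1 - np.exp(-1.0))
        assert sc.pair_f(0.0, u_j, f, phase=1) == pytest.approx(1.0)

    def test_beyond_asymptote_is_nan(self):
        f = make_fit(alpha=2.0, m=1.0)
        assert np.isnan(sc.pair_f(0.5, 2.5, f, phase=1))


class TestSamplePairs:
    def test_counting_convention(self):
        ranking = np.array([10, 11, 12, 13])
        i, j, d = sc.sample_pairs(ranking, n_pairs=100)
        lookup = {(a, b): dd for a, b, dd in zip(i, j, d)}
        assert lookup[(10, 13)] == 2  # two cells strictly between
        assert lookup[(10, 11)] == 0  # adjacent ranks

    def test_exhaustive_matches_enumeration(self):
        ranking = np.arange(10)
        i, j, d = sc.sample_pairs(ranking, n_pairs=10_000)
        expected = [(a, b, b - a - 1) for a in range(10) for b in range(a + 1, 10)]
        assert sorted(zip(i, j, d)) == sorted(expected)

    def test_sampling_reproducible_and_within_bounds(self):
        ranking = np.arange(100)
        i1, j1, d1 = sc.sample_pairs(ranking, n_pairs=50, rng_seed=4)
        i2, j2, d2 = sc.sample_pairs(ranking, n_pairs=50, rng_seed=4)
        assert np.array_equal(i1, i2) and np.array_equal(d1, d2)
        assert np.all(i1 < j1)

    def test_eligible_subset_keeps_full_ordering_counts(self):
        ranking = np.arange(6)
        i, j, d = sc.sample_pairs(ranking, n_pairs=100, eligible=np.array([1, 4]))
        assert list(i) == [1] and list(j) == [4] and list(d) == [2.0]


class TestParallelogram:
    def test_exact_line_recovers_slope(self):
        d = np.arange(200, dtype=float)
        f = 3.0 * d
        assert sc.fit_parallelogram(d, f) == pytest.approx(3.0, rel=0.01)

    def test_robust_to_steady_state_mimic(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 200, 600).astype(float)
        f = 3.0 * d
        low = rng.random(600) < 0.3
        f[low] *= rng.uniform(0.2, 0.8, low.sum())  # displaced strictly below
        assert sc.fit_parallelogram(d, f) == pytest.approx(3.0, rel=0.05)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            sc.fit_parallelogram(np.zeros(100), np.ones(100))
        with pytest.raises(ValueError):
            sc.fit_parallelogram(np.arange(100.0), np.zeros(100))  # no transient signal

    def test_few_pairs_fall_back_with_warning(self):
        d = np.arange(10, dtype=float)
        f = 2.0 * d
        with pytest.warns(UserWarning):
            est = sc.fit_parallelogram(d, f)
        assert est > 0


class TestKappaEstimation:
    def test_density_and_time_estimates_agree_on_clean_gene(self, small_sim):
        adata, truth = small_sim
        g = int(np.argmin(truth.scaled_beta))
        u = adata.layers["unspliced"][:, g]
        s = adata.layers["spliced"][:, g]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = fm.fit_gene_em(u, s, fm.EMConfig(fit_m=False))
        k_d, stats = sc.estimate_kappa(u, f, rng_seed=0)
        k_t, _ = sc.estimate_kappa(u, f, rng_seed=0, times=truth.t)
        # the density clock ticks in cells, the time clock in simulation
        # time; their ratio is the sampling density T/n up to count noise
        T_over_n = truth.t_max / adata.n_obs
        assert k_d / k_t == pytest.approx(T_over_n, rel=0.2)

    def test_kappa_from_spliced_consistent(self, small_sim):
        adata, truth = small_sim
        g = int(np.argmin(truth.scaled_beta))
        u = adata.layers["unspliced"][:, g]
        s = adata.layers["spliced"][:, g]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = fm.fit_gene_em(u, s, fm.EMConfig(fit_m=False))
        k_u, stats = sc.estimate_kappa(u, f, rng_seed=0)
        k_s = sc.kappa_from_spliced(s, f, stats)
        assert k_s == pytest.approx(k_u, rel=0.05)

    def test_steady_only_gene_errors(self):
        f = make_fit(alpha=2.0, n=50)
        f.k = np.ones(50, int)
        rng = np.random.default_rng(1)
        u = np.full(50, 1.99) + rng.normal(0, 1e-4, 50)  # parked at the asymptote
        with pytest.raises(ValueError):
            sc.estimate_kappa(u, f)


class TestAssemblyAndVelocity:
    def test_unit_kappa_is_identity_scaling(self):
        fits = {"g0": make_fit(alpha=2.0, gamma=0.5, m=1.5)}
        scaled = sc.assemble_scaled(fits, {"g0": 1.0})
        assert scaled.A[0] == pytest.approx(2.0)
        assert scaled.B[0] == pytest.approx(1.0)
        assert scaled.Gamma[0] == pytest.approx(0.5)
        assert scaled.M[0] == pytest.approx(1.5)

    def test_kappa_scales_B_linearly_and_ratios_invariant(self):
        fits = {"g0": make_fit(gamma=0.5)}
        s1 = sc.assemble_scaled(fits, {"g0": 2.0})
        s2 = sc.assemble_scaled(fits, {"g0": 4.0})
        assert s2.B[0] == pytest.approx(2 * s1.B[0])
        assert s1.B[0] / s1.Gamma[0] == pytest.approx(s2.B[0] / s2.Gamma[0])

    def test_missing_kappa_drops_gene_with_warning(self):
        fits = {"g0": make_fit(), "g1": make_fit()}
        with pytest.warns(UserWarning):
            scaled = sc.assemble_scaled(fits, {"g0": 1.0})
        assert scaled.genes == ["g0"]

    def test_velocity_zero_at_steady_state(self):
        fits = {"g0": make_fit(alpha=2.0, gamma=0.5, m=1.0)}
        scaled = sc.assemble_scaled(fits, {"g0": 3.0})
        U = np.array([[2.0]])  # u_ss = alpha/(m beta) with beta = 1
        S = np.array([[4.0]])  # s_ss = alpha/gamma
        assert sc.velocity_field(scaled, U, S)[0, 0] == pytest.approx(0.0)

    def test_velocity_linear_in_kappa(self):
        fits = {"g0": make_fit(alpha=2.0, gamma=0.5)}
        U = np.array([[0.5], [1.2]])
        S = np.array([[0.2], [3.0]])
        v1 = sc.velocity_field(sc.assemble_scaled(fits, {"g0": 1.0}), U, S)
        v2 = sc.velocity_field(sc.assemble_scaled(fits, {"g0": 2.0}), U, S)
        assert np.allclose(v2, 2 * v1)

    def test_shape_mismatch_rejected(self):
        scaled = sc.assemble_scaled({"g0": make_fit()}, {"g0": 1.0})
        with pytest.raises(ValueError):
            sc.velocity_field(scaled, np.ones((3, 2)), np.ones((3, 2)))

    def test_velocity_proportional_to_truth_on_noiseless_sim(self, small_sim):
        """With true kappas supplied, the assembled velocities equal the true
        ones up to one shared constant per gene family (exactly, noiseless)."""
        adata, truth = small_sim
        U, S = adata.layers["unspliced"], adata.layers["spliced"]
        fits, kappas = {}, {}
        genes = list(adata.var_names[:5])
        for g, name in enumerate(genes):
            a = truth.rates["alpha"].iloc[g] / truth.rates["beta"].iloc[g]
            gm = truth.rates["gamma"].iloc[g] / truth.rates["beta"].iloc[g]
            fits[name] = make_fit(alpha=a, gamma=gm, m=1.0, n=adata.n_obs)
            kappas[name] = float(truth.scaled_beta[g])
        scaled = sc.assemble_scaled(fits, kappas)
        V = sc.velocity_field(scaled, U[:, :5], S[:, :5])
        assert np.allclose(V, adata.layers["true_velocity"][:, :5], rtol=1e-8, atol=1e-10)
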