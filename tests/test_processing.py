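import json

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from kappavelo import processing as pr


def make_dataset(U, S, **uns):
    U = np.asarray(U, float)
    S = np.asarray(S, float)
    ad = AnnData(
        X=S.copy(),
        layers={"unspliced": U, "spliced": S},
        obs=pd.DataFrame(index=[f"c{i}" for i in range(U.shape[0])]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(U.shape[1])]),
    )
    ad.uns.update(uns)
    return ad


class TestPearsonResidualSelection:
    def test_null_model_gives_zero_residuals_and_input_order(self):
        # every cell an exact scaled copy of one profile: mu reproduces x
        profile = np.array([1.0, 2.0, 4.0, 8.0])
        S = np.outer([1, 2, 3, 5], profile)
        ad = make_dataset(np.ones_like(S), S)
        assert np.allclose(pr.pearson_residuals(S), 0.0, atol=1e-12)
        idx = pr.select_variable_genes(ad, n_top=4)
        assert list(idx) == [0, 1, 2, 3]

    def test_bimodal_gene_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 60
        S = rng.poisson(5.0, size=(n, 6)).astype(float)
        S[:, 2] = 0.0
        S[: n // 2, 2] = 40.0  # expressed high in half the cells only
        ad = make_dataset(np.ones_like(S), S)
        idx = pr.select_variable_genes(ad, n_top=3)
        assert idx[0] == 2
        # direct-formula oracle: residual variance computed independently
        tot = S.sum()
        mu = np.outer(S.sum(1), S.sum(0)) / tot
        r = np.clip((S - mu) / np.sqrt(mu + mu**2 / 100.0), -np.sqrt(n), np.sqrt(n))
        assert np.argmax(r.var(0)) == 2

    def test_matches_scanpy_reference(self):
        """Cross-check the residual-variance ranking against scanpy's
        analytic Pearson-residual implementation."""
        import scanpy as sc

        rng = np.random.default_rng(1)
        S = rng.negative_binomial(3, 0.3, size=(80, 30)).astype(float)
        ad = make_dataset(np.ones_like(S), S)
        ours = pr.select_variable_genes(ad, n_top=10)
        ref = AnnData(S.copy())
        sc.experimental.pp.highly_variable_genes(ref, theta=100, n_top_genes=10, flavor="pearson_residuals")
        assert set(ours) == set(np.flatnonzero(ref.var["highly_variable"].to_numpy()))

    def test_n_top_exceeding_genes_warns(self):
        ad = make_dataset(np.ones((4, 3)), np.ones((4, 3)))
        with pytest.warns(UserWarning):
            idx = pr.select_variable_genes(ad, n_top=10)
        assert len(idx) == 3


class TestLowCountFilter:
    def test_hand_enumerated_survivors(self):
        # 10 cells, 5 genes with known nonzero fractions in U and S
        U = np.zeros((10, 5))
        S = np.zeros((10, 5))
        U[:5, 0] = 1  # 0.5
        S[:9, 0] = 1  # 0.9
        U[:1, 1] = 1  # 0.1 -> fails min_u_frac=0.2
        S[:, 1] = 1
        U[:, 2] = 1
        S[:1, 2] = 1  # 0.1 -> fails min_s_frac=0.3
        U[:, 3] = 1
        S[:, 3] = 1
        # gene 4 all-zero U -> removed for any positive threshold
        S[:, 4] = 1
        ad = make_dataset(U, S)
        assert list(pr.filter_low_count_genes(ad, 0.2, 0.3)) == [0, 3]

    def test_zero_thresholds_are_identity(self):
        ad = make_dataset(np.zeros((3, 4)), np.zeros((3, 4)))
        assert list(pr.filter_low_count_genes(ad, 0.0, 0.0)) == [0, 1, 2, 3]

    def test_invalid_threshold(self):
        ad = make_dataset(np.ones((3, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError):
            pr.filter_low_count_genes(ad, -0.1, 0.5)


class TestJointNormalisation:
    def test_factors_from_totals(self):
        U = np.array([[30.0, 20.0], [150.0, 50.0]])
        S = np.array([[25.0, 25.0], [50.0, 50.0]])  # totals 100 and 300
        ad = make_dataset(U, S)
        out = pr.joint_size_normalise(ad, target=200.0)
        assert np.allclose(out.layers["unspliced"][0], U[0] * 2)
        assert np.allclose(out.layers["spliced"][1], S[1] * 2 / 3)

    def test_within_cell_us_ratio_preserved_exactly(self):
        rng = np.random.default_rng(3)
        U = rng.poisson(4, (20, 8)).astype(float) + 1
        S = rng.poisson(9, (20, 8)).astype(float) + 1
        out = pr.joint_size_normalise(make_dataset(U, S))
        assert np.allclose(out.layers["unspliced"] / out.layers["spliced"], U / S, rtol=1e-14)

    def test_equal_totals_identity(self):
        U = np.full((4, 2), 2.0)
        S = np.full((4, 2), 3.0)
        out = pr.joint_size_normalise(make_dataset(U, S))
        assert np.allclose(out.layers["unspliced"], U)

    def test_zero_total_cell_removed(self):
        U = np.array([[1.0, 1.0], [0.0, 0.0]])
        S = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.warns(UserWarning):
            out = pr.joint_size_normalise(make_dataset(U, S))
        assert out.n_obs == 1

    def test_pipeline_order_enforced(self):
        ad = make_dataset(np.ones((5, 3)), np.ones((5, 3)))
        out = pr.joint_size_normalise(ad)
        with pytest.raises(ValueError):
            pr.joint_size_normalise(out)  # cannot re-normalise
        with pytest.raises(ValueError):
            pr.knn_impute(ad, k=2)  # cannot impute raw data


class TestKnnImputation:
    def test_identical_cells_are_fixed_point(self):
        U = np.tile([1.0, 2.0, 3.0], (8, 1))
        S = np.tile([2.0, 1.0, 4.0], (8, 1))
        ad = pr.joint_size_normalise(make_dataset(U, S))
        out = pr.knn_impute(ad, k=3, n_pcs=2)
        assert np.allclose(out.layers["unspliced"], ad.layers["unspliced"])

    def test_k_zero_is_identity(self):
        rng = np.random.default_rng(0)
        ad = pr.joint_size_normalise(make_dataset(rng.poisson(5, (6, 4)) + 1.0, rng.poisson(5, (6, 4)) + 1.0))
        out = pr.knn_impute(ad, k=0)
        assert np.allclose(out.layers["spliced"], ad.layers["spliced"])

    def test_matches_brute_force_neighbour_means(self):
        rng = np.random.default_rng(5)
        U = rng.poisson(6, (10, 5)).astype(float) + 1
        S = rng.poisson(12, (10, 5)).astype(float) + 1
        ad = pr.joint_size_normalise(make_dataset(U, S))
        out = pr.knn_impute(ad, k=3, n_pcs=3)
        # exhaustive oracle: PCA on z-scaled spliced, all-pairs distances
        Sn = ad.layers["spliced"]
        Z = (Sn - Sn.mean(0)) / Sn.std(0)
        from sklearn.decomposition import PCA

        pcs = PCA(n_components=3, svd_solver="full").fit_transform(Z)
        d2 = ((pcs[:, None] - pcs[None, :]) ** 2).sum(-1)
        for i in range(10):
            members = np.argsort(d2[i], kind="stable")[:4]
            if i not in members:
                members = np.r_[i, members[:3]]
            assert np.allclose(out.layers["unspliced"][i], ad.layers["unspliced"][members].mean(0))

    def test_imputation_shrinks_gene_variance(self):
        rng = np.random.default_rng(9)
        U = rng.poisson(6, (40, 6)).astype(float) + 1
        S = rng.poisson(12, (40, 6)).astype(float) + 1
        ad = pr.joint_size_normalise(make_dataset(U, S))
        out = pr.knn_impute(ad, k=5, n_pcs=4)
        assert np.all(out.layers["spliced"].var(0) <= ad.layers["spliced"].var(0) + 1e-12)

    def test_k_too_large(self):
        ad = pr.joint_size_normalise(make_dataset(np.ones((4, 2)), np.ones((4, 2))))
        with pytest.raises(ValueError):
            pr.knn_impute(ad, k=4)


class TestEcoNormalisation:
    def test_unit_norm_rows(self):
        rng = np.random.default_rng(2)
        U = rng.poisson(3, (12, 5)).astype(float) + 1
        S = rng.poisson(6, (12, 5)).astype(float) + 1
        Un, Sn = pr.eco_normalise(make_dataset(U, S))
        assert np.allclose(np.linalg.norm(Un, axis=1), 1.0)
        assert np.allclose(np.linalg.norm(Sn, axis=1), 1.0)

    def test_constant_matrix_gives_identical_unit_rows(self):
        Un, Sn = pr.eco_normalise(make_dataset(np.full((5, 4), 3.0), np.full((5, 4), 7.0)))
        assert np.allclose(Un, Un[0])
        assert np.allclose(Un[0], 0.5)  # 4 equal entries -> 1/sqrt(4)

    def test_three_by_three_hand_computation(self):
        U = np.array([[1.0, 3.0, 7.0], [2.0, 2.0, 2.0], [0.0, 4.0, 4.0]])
        X = np.log1p(U)
        totals = X.sum(1)
        X = X * (np.median(totals) / totals)[:, None]
        expected = X / np.linalg.norm(X, axis=1, keepdims=True)
        Un, _ = pr.eco_normalise(make_dataset(U, U.copy()))
        assert np.allclose(Un, expected, atol=1e-12)

    def test_zero_cell_rejected(self):
        U = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            pr.eco_normalise(make_dataset(U, U.copy()))


def test_processing_log_reconstructs_attrition():
    rng = np.random.default_rng(4)
    U = rng.poisson(4, (15, 6)).astype(float)
    S = rng.poisson(8, (15, 6)).astype(float)
    ad = make_dataset(U, S)
    pr.select_variable_genes(ad, n_top=4)
    pr.filter_low_count_genes(ad, 0.1, 0.1)
    log = [json.loads(entry) for entry in ad.uns["processing_log"]]
    assert log[0]["n_before"] == 6 and log[0]["n_after"] == 4
    assert all({"rule", "axis", "n_before", "n_after"} <= set(e) for e in log)
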