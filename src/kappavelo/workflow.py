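"""End-to-end workflows tying processing, inference and visualisation together.

:func:`run_kvelo` executes the detailed pipeline: variable-gene selection,
low-count filtering, joint normalisation, kNN imputation, per-gene EM
fitting, likelihood (and optional cluster-order) filtering, density-based
kappa recovery, velocity assembly and Nystrom projection onto an embedding
of the processed spliced counts.  :func:`run_eco` executes the heuristic
pipeline: filtering, per-modality normalisation, cross-modal mutual nearest
neighbours and embedding arrows.  Every filtering stage appends a record to
the dataset's processing log, so the full gene-attrition path is machine
readable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from anndata import AnnData

from . import processing, fit as fit_mod, scale as scale_mod, eco as eco_mod, projection

__all__ = ["RunConfig", "KveloResult", "EcoResult", "run_kvelo", "run_eco"]


@dataclass
class RunConfig:
    """All tunable knobs of both workflows (every field has a default)."""

    # processing
    n_top_genes: int = 2000
    theta: float = 100.0
    min_u_frac: float = 0.05
    min_s_frac: float = 0.10
    impute_k: int = 30
    n_pcs: int = 30
    # fitting
    em: fit_mod.EMConfig = field(default_factory=fit_mod.EMConfig)
    likelihood_quantile: float = 0.5
    likelihood_threshold: float | None = None
    hierarchy: list[str] | None = None
    # kappa recovery
    n_pairs: int = 2000
    coverage: float = 0.95
    # eco
    mnn_k: int = 5
    arrow_scale: float = 0.5
    # embedding / projection
    embedding: str = "pca"
    n_components: int = 2
    downscale_quantile: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class KveloResult:
    adata: AnnData  # processed dataset restricted to retained genes
    fits: dict[str, fit_mod.GeneKineticsFit]
    kappa: dict[str, float]
    scaled: scale_mod.ScaledKinetics
    velocity: np.ndarray  # cells x retained genes
    table: pd.DataFrame  # per-gene parameter/likelihood/kappa export
    embedding: np.ndarray
    arrows: projection.ProjectedArrows


@dataclass
class EcoResult:
    adata: AnnData
    mnn: eco_mod.MnnResult
    embedding: np.ndarray
    start: np.ndarray
    end: np.ndarray
    has_arrow: np.ndarray


def _embed(S: np.ndarray, method: str, n_components: int, seed: int) -> np.ndarray:
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=n_components, svd_solver="full").fit_transform(S)
    if method == "tsne":
        from sklearn.manifold import TSNE

        return TSNE(n_components=n_components, random_state=seed, init="pca").fit_transform(S)
    if method == "umap":
        import umap

        return umap.UMAP(n_components=n_components, random_state=seed).fit_transform(S)
    raise ValueError(f"unknown embedding method '{method}'")


def _preprocess(adata: AnnData, config: RunConfig, impute: bool) -> AnnData:
    adata = adata.copy()  # the workflow never mutates the caller's dataset
    hv = processing.select_variable_genes(adata, n_top=config.n_top_genes, theta=config.theta)
    sub = adata[:, hv].copy()
    keep = processing.filter_low_count_genes(
        sub, min_u_frac=config.min_u_frac, min_s_frac=config.min_s_frac
    )
    sub = sub[:, keep].copy()
    if impute:
        sub = processing.joint_size_normalise(sub)
        sub = processing.knn_impute(sub, k=config.impute_k, n_pcs=config.n_pcs)
    return sub


def run_kvelo(adata: AnnData, config: RunConfig | None = None) -> KveloResult:
    """Run the full detailed workflow on a raw-count dataset."""
    config = config or RunConfig()
    sub = _preprocess(adata, config, impute=True)
    U, S = processing.get_layers(sub)

    fits: dict[str, fit_mod.GeneKineticsFit] = {}
    for gi, gene in enumerate(sub.var_names):
        try:
            fits[gene] = fit_mod.fit_gene_em(U[:, gi], S[:, gi], config.em)
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"gene {gene}: fit failed ({err}); dropped", stacklevel=2)

    kept = fit_mod.filter_by_likelihood(
        fits, threshold=config.likelihood_threshold, quantile=config.likelihood_quantile
    )
    if config.hierarchy is not None and "cell_type" in sub.obs:
        ordered = fit_mod.filter_by_cluster_order(
            {g: fits[g] for g in kept}, sub.obs["cell_type"].to_numpy(), config.hierarchy
        )
        kept = ordered

    kappa: dict[str, float] = {}
    for gene in kept:
        gi = sub.var_names.get_loc(gene)
        try:
            kappa[gene], _ = scale_mod.estimate_kappa(
                U[:, gi],
                fits[gene],
                n_pairs=config.n_pairs,
                coverage=config.coverage,
                rng_seed=config.seed,
                gene_id=gene,
            )
        except ValueError as err:
            warnings.warn(f"gene {gene}: kappa estimation failed ({err}); dropped", stacklevel=2)

    scaled = scale_mod.assemble_scaled({g: fits[g] for g in kept if g in kappa}, kappa)
    cols = [sub.var_names.get_loc(g) for g in scaled.genes]
    velocity = scale_mod.velocity_field(scaled, U[:, cols], S[:, cols])

    S_ret = S[:, cols]
    Y = _embed(S_ret, config.embedding, config.n_components, config.seed)
    model = projection.EmbeddingModel(X_train=S_ret, Y_train=Y, method=config.embedding)
    arrows = projection.velocity_endpoints(
        model, S_ret, velocity, downscale_quantile=config.downscale_quantile
    )

    out = sub[:, scaled.genes].copy()
    out.layers["velocity"] = velocity
    out.obsm["X_embed"] = Y
    out.obsm["velocity_embed"] = arrows.delta

    table = pd.DataFrame(
        {
            "gene_id": list(fits),
            "alpha": [f.alpha for f in fits.values()],
            "gamma": [f.gamma for f in fits.values()],
            "m": [f.m for f in fits.values()],
            "u_switch": [f.u_switch for f in fits.values()],
            "likelihood": [f.log_likelihood for f in fits.values()],
            "converged": [f.converged for f in fits.values()],
            "passed_likelihood": [g in kept for g in fits],
            "kappa": [kappa.get(g, np.nan) for g in fits],
        }
    ).set_index("gene_id")

    return KveloResult(
        adata=out,
        fits=fits,
        kappa=kappa,
        scaled=scaled,
        velocity=velocity,
        table=table,
        embedding=Y,
        arrows=arrows,
    )


def run_eco(adata: AnnData, config: RunConfig | None = None) -> EcoResult:
    """Run the heuristic workflow on a raw-count dataset."""
    config = config or RunConfig()
    sub = _preprocess(adata, config, impute=False)
    U_norm, S_norm = processing.eco_normalise(sub)
    mnn = eco_mod.mutual_nearest_neighbors(U_norm, S_norm, k=config.mnn_k)
    Y = _embed(S_norm, config.embedding, config.n_components, config.seed)
    start, end, has_arrow = eco_mod.eco_arrows(mnn, Y, scale=config.arrow_scale)
    return EcoResult(adata=sub, mnn=mnn, embedding=Y, start=start, end=end, has_arrow=has_arrow)
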