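"""Count processing for the two velocity workflows.

The detailed (kappa-velo) pipeline runs: variable-gene selection by analytic
Pearson-residual variance, low-count gene filtering, *joint* size
normalisation of u and s with one shared per-cell factor, and kNN imputation
in PCA space of the scaled spliced counts.  Joint normalisation is the load-
bearing choice: a shared factor preserves every within-cell u:s ratio, while
normalising the two matrices separately distorts phase portraits whenever
cell types differ in their total-unspliced to total-spliced ratio.

The heuristic (eco-velo) pipeline treats u and s as separate modalities:
log transform, per-modality size normalisation, then per-cell L2
normalisation -- the standard preparation for cross-modal nearest-neighbour
matching.

Datasets are AnnData objects with layers ``"unspliced"`` and ``"spliced"``.
A processing-state tag in ``.uns`` enforces the pipeline order (raw ->
normalised -> imputed) and every filtering step appends a machine-readable
record to ``.uns["processing_log"]``.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "select_variable_genes",
    "filter_low_count_genes",
    "joint_size_normalise",
    "knn_impute",
    "eco_normalise",
    "pearson_residuals",
]

_STATE_KEY = "kv_state"
_LOG_KEY = "processing_log"
_ORDER = {"raw": 0, "normalised": 1, "imputed": 2}


def get_layers(adata: AnnData) -> tuple[np.ndarray, np.ndarray]:
    """Dense (U, S) layer pair of a dataset."""
    out = []
    for name in ("unspliced", "spliced"):
        if name not in adata.layers:
            raise KeyError(f"dataset is missing the '{name}' layer")
        layer = adata.layers[name]
        out.append(np.asarray(layer.todense()) if sp.issparse(layer) else np.asarray(layer, dtype=float))
    return out[0], out[1]


def _state(adata: AnnData) -> str:
    return adata.uns.get(_STATE_KEY, "raw")


def _require_state(adata: AnnData, allowed: tuple[str, ...], op: str) -> None:
    if _state(adata) not in allowed:
        raise ValueError(
            f"{op} expects a dataset in state {allowed}, got '{_state(adata)}' "
            "(pipeline order is select/filter -> normalise -> impute)"
        )


def _log(adata: AnnData, rule: str, n_before: int, n_after: int, axis: str = "genes") -> None:
    # JSON strings so the log survives an h5ad round trip
    adata.uns.setdefault(_LOG_KEY, []).append(
        json.dumps(
            {"rule": rule, "axis": axis, "n_before": int(n_before), "n_after": int(n_after)}
        )
    )


def pearson_residuals(X: np.ndarray, theta: float = 100.0, clip: float | None = None) -> np.ndarray:
    """Analytic Pearson residuals of a count matrix under the null model
    mu_cg = (rowsum_c * colsum_g) / grand_sum with NB overdispersion theta.

    Residuals are clipped at +-sqrt(n_cells) by default.
    """
    X = np.asarray(X, dtype=float)
    n_cells = X.shape[0]
    total = X.sum()
    if total == 0:
        return np.zeros_like(X)
    mu = np.outer(X.sum(axis=1), X.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (X - mu) / np.sqrt(mu + mu**2 / theta)
    r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    if clip is None:
        clip = np.sqrt(n_cells)
    return np.clip(r, -clip, clip)


def select_variable_genes(adata: AnnData, n_top: int = 2000, theta: float = 100.0) -> np.ndarray:
    """Indices of the ``n_top`` most variable genes by Pearson-residual
    variance of the spliced counts, ordered by decreasing variance.
    """
    _require_state(adata, ("raw",), "select_variable_genes")
    _, S = get_layers(adata)
    var = pearson_residuals(S, theta=theta).var(axis=0)
    n_genes = S.shape[1]
    if n_top > n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds the {n_genes} available genes; returning all",
            stacklevel=2,
        )
        n_top = n_genes
    # stable sort so zero-variance ties fall back to input order
    order = np.argsort(-var, kind="stable")[:n_top]
    _log(adata, f"variable_genes(n_top={n_top}, theta={theta})", n_genes, n_top)
    return order


def filter_low_count_genes(
    adata: AnnData, min_u_frac: float = 0.05, min_s_frac: float = 0.10
) -> np.ndarray:
    """Indices of genes detected (nonzero) in at least ``min_u_frac`` of
    cells in U and ``min_s_frac`` of cells in S."""
    for frac in (min_u_frac, min_s_frac):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("detection-fraction thresholds must lie in [0, 1]")
    U, S = get_layers(adata)
    n_cells = U.shape[0]
    keep = ((U > 0).sum(axis=0) / n_cells >= min_u_frac) & (
        (S > 0).sum(axis=0) / n_cells >= min_s_frac
    )
    idx = np.flatnonzero(keep)
    _log(
        adata,
        f"low_count_filter(min_u_frac={min_u_frac}, min_s_frac={min_s_frac})",
        U.shape[1],
        idx.size,
    )
    return idx


def joint_size_normalise(adata: AnnData, target: float | None = None) -> AnnData:
    """Size-normalise U and S with one shared factor per cell.

    Each cell's U row and S row are multiplied by ``target / (sum_u + sum_s)``
    so the combined per-cell total becomes ``target`` (default: the median
    combined total).  The shared factor preserves every within-cell u:s
    ratio.  Cells with zero combined counts are removed with a warning.
    """
    _require_state(adata, ("raw",), "joint_size_normalise")
    U, S = get_layers(adata)
    totals = U.sum(axis=1) + S.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"removing {int((~keep).sum())} cells with zero total counts", stacklevel=2)
    out = adata[keep].copy()
    U, S, totals = U[keep], S[keep], totals[keep]
    if target is None:
        target = float(np.median(totals))
    factors = target / totals
    out.layers["unspliced"] = U * factors[:, None]
    out.layers["spliced"] = S * factors[:, None]
    out.X = out.layers["spliced"].copy()
    out.uns[_STATE_KEY] = "normalised"
    _log(out, "joint_size_normalise", adata.n_obs, out.n_obs, axis="cells")
    return out


def knn_impute(adata: AnnData, k: int = 30, n_pcs: int = 30) -> AnnData:
    """Replace each cell's u and s by the mean over itself and its k nearest
    neighbours.

    Neighbours are found in PCA space of the z-scaled (per-gene standardised)
    normalised spliced counts.  Distance ties are broken by cell index so the
    result is deterministic.
    """
    from sklearn.decomposition import PCA

    _require_state(adata, ("normalised",), "knn_impute")
    n_cells = adata.n_obs
    if k >= n_cells:
        raise ValueError("k must be smaller than the number of cells")
    U, S = get_layers(adata)
    out = adata.copy()
    if k > 0:
        Z = S - S.mean(axis=0)
        sd = S.std(axis=0)
        sd[sd == 0] = 1.0
        Z = Z / sd
        n_comp = min(n_pcs, n_cells - 1, Z.shape[1])
        pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(Z)
        # argsort on (distance, index) lexicographic order for determinism
        d2 = ((pcs[:, None, :] - pcs[None, :, :]) ** 2).sum(-1) if n_cells <= 2048 else None
        if d2 is None:
            from sklearn.neighbors import NearestNeighbors

            nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
            neigh = nn.kneighbors(pcs, return_distance=False)
        else:
            neigh = np.argsort(d2, axis=1, kind="stable")[:, : k + 1]
        # ensure self is part of every neighbourhood
        U_imp = np.empty_like(U)
        S_imp = np.empty_like(S)
        for i in range(n_cells):
            members = neigh[i]
            if i not in members:
                members = np.concatenate([[i], members[:-1]])
            U_imp[i] = U[members].mean(axis=0)
            S_imp[i] = S[members].mean(axis=0)
        out.layers["unspliced"] = U_imp
        out.layers["spliced"] = S_imp
        out.X = S_imp.copy()
    out.uns[_STATE_KEY] = "imputed"
    _log(out, f"knn_impute(k={k}, n_pcs={n_pcs})", n_cells, n_cells, axis="cells")
    return out


def eco_normalise(adata: AnnData) -> tuple[np.ndarray, np.ndarray]:
    """Eco-velo normalisation chain: log1p -> per-modality size normalisation
    -> per-cell L2 normalisation, applied to U and S independently.

    Returns the two normalised matrices; every returned cell row has unit
    Euclidean norm in each modality.
    """
    U, S = get_layers(adata)
    out = []
    for X in (U, S):
        X = np.log1p(X)
        totals = X.sum(axis=1)
        if np.any(totals == 0):
            raise ValueError("cell with zero counts in one modality; filter cells first")
        X = X * (np.median(totals) / totals)[:, None]
        norms = np.linalg.norm(X, axis=1)
        out.append(X / norms[:, None])
    return out[0], out[1]
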