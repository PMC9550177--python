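"""Per-gene time-scale (kappa) recovery and velocity assembly.

A gene's phase portrait determines its rates only up to a joint rescaling of
(alpha, beta, gamma) and time.  To put genes on a common time axis, the
number of cells observed between two cell states is used as a proxy for the
typical travel time between them: in snapshot data the probability of
capturing a cell in a region is proportional to the time cells spend there.

For a cell pair (i, j) in the same transcriptional phase, inverting the
beta = 1 unspliced solution gives

    f(i, j) = log((m u_i - alpha) / (m u_j - alpha)),

which equals kappa * dt_ij on the true time axis.  Plotting f against the
in-between cell count d(i, j) yields points on a line of slope kappa (in
cells-between units) -- except that dwell at a steady state inflates d
without advancing f, pushing points strictly below that line.  The upper
boundary slope is therefore extracted with a parallelogram fit: among
candidate slopes, choose the one whose residual band of fixed coverage is
narrowest (minimum area at fixed d-range).

The recovered kappas share one unknown global unit (the cells-per-time
density); scaling every gene's velocity by the same constant leaves the
direction of the high-dimensional velocity vector unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fit import GeneKineticsFit, _curve_up, _curve_down

__all__ = [
    "PairStatistics",
    "ScaledKinetics",
    "order_cells_in_phase",
    "pair_f",
    "sample_pairs",
    "fit_parallelogram",
    "estimate_kappa",
    "kappa_from_spliced",
    "assemble_scaled",
    "velocity_field",
]


@dataclass
class PairStatistics:
    """Sampled same-phase cell pairs of one gene with their d and f values."""

    gene_id: str
    i: np.ndarray  # earlier cell (global index)
    j: np.ndarray  # later cell
    d: np.ndarray  # cells strictly between i and j in the phase ordering
    f: np.ndarray  # log-ratio time statistic (kappa * dt on the true axis)
    phase: np.ndarray  # phase each pair belongs to


@dataclass
class ScaledKinetics:
    """Correctly scaled kinetic parameters of the retained genes."""

    genes: list[str]
    kappa: np.ndarray
    A: np.ndarray  # kappa * alpha
    B: np.ndarray  # kappa * beta = kappa (beta = 1)
    Gamma: np.ndarray  # kappa * gamma
    M: np.ndarray  # unspliced upscaling factors
    estimator: str = "density-parallelogram"


def order_cells_in_phase(u: np.ndarray, phases: np.ndarray) -> dict[int, np.ndarray]:
    """Cell indices of each phase, ordered along the direction of time.

    Upregulated cells (k=1) are ordered by increasing u, downregulated ones
    (k=0) by decreasing u; equal u values keep their index order.
    """
    u = np.asarray(u, dtype=float)
    phases = np.asarray(phases)
    out: dict[int, np.ndarray] = {}
    for k in (1, 0):
        idx = np.flatnonzero(phases == k)
        if idx.size == 0:
            continue
        key = u[idx] if k == 1 else -u[idx]
        out[k] = idx[np.argsort(key, kind="stable")]
    return out


def pair_f(u_i, u_j, fit: GeneKineticsFit, phase: int = 1):
    """Elapsed-time statistic f = log((m u_i - a)/(m u_j - a)) with beta = 1.

    ``a`` is the phase's effective transcription rate (``fit.alpha`` during
    upregulation, 0 during downregulation).  Pairs whose ratio is
    nonpositive (a cell beyond the asymptote, possible under noise) get NaN
    and are skipped downstream.
    """
    alpha_eff = fit.alpha if phase == 1 else 0.0
    num = fit.m * np.asarray(u_i, float) - alpha_eff
    den = fit.m * np.asarray(u_j, float) - alpha_eff
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
        f = np.where(ratio > 0, np.log(np.where(ratio > 0, ratio, 1.0)), np.nan)
    return f


def sample_pairs(
    ranking: np.ndarray,
    n_pairs: int = 2000,
    rng_seed: int = 0,
    eligible: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample ordered cell pairs from one phase ranking.

    Returns (i, j, d): global indices of the earlier/later cell and the
    number of cells strictly between them in the *full* phase ordering.
    ``eligible`` optionally restricts the sampled endpoints to a subset of
    ranking positions (in-between counts still include every cell).  All
    pairs are returned when fewer than ``n_pairs`` exist.
    """
    ranking = np.asarray(ranking)
    positions = np.arange(ranking.size) if eligible is None else np.asarray(eligible)
    n = positions.size
    if n < 2:
        raise ValueError("need at least 2 cells in the phase")
    total = n * (n - 1) // 2
    if n_pairs >= total:
        a, b = np.triu_indices(n, k=1)
    else:
        rng = np.random.default_rng(rng_seed)
        flat = rng.choice(total, size=n_pairs, replace=False)
        # decode upper-triangle linear index
        a = (n - 2 - np.floor(np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(int)
        b = (flat + a + 1 - n * (n - 1) // 2 + (n - a) * ((n - a) - 1) // 2).astype(int)
    pa, pb = positions[a], positions[b]
    return ranking[pa], ranking[pb], (pb - pa - 1).astype(float)


def _band_width(r: np.ndarray, coverage: float) -> float:
    """Width of the narrowest interval covering the given fraction of r."""
    r = np.sort(r)
    w = max(int(np.ceil(coverage * r.size)), 2)
    if w >= r.size:
        return float(r[-1] - r[0])
    return float(np.min(r[w - 1 :] - r[: r.size - w + 1]))


def fit_parallelogram(
    d: np.ndarray,
    f: np.ndarray,
    coverage: float = 0.95,
    min_pairs: int = 50,
    n_grid: int = 120,
) -> float:
    """Slope of the upper boundary of the (d, f) point cloud.

    Scans candidate slopes; for each, the parallelogram is the band of
    intercepts of ``f - a d`` whose width covers ``coverage`` of the points,
    and the returned slope minimises the band width (equivalently the
    parallelogram area at fixed d-range).  Falls back to a robust quantile
    slope when too few usable pairs remain.
    """
    d = np.asarray(d, float)
    f = np.asarray(f, float)
    ok = np.isfinite(f) & np.isfinite(d)
    d, f = d[ok], f[ok]
    if d.size == 0 or np.all(d == 0):
        raise ValueError("no usable pairs with positive in-between counts")
    a0 = float(np.quantile(f / (d + 1.0), 0.95))
    if a0 <= 0:
        raise ValueError("no transient signal: nonpositive initial slope")
    if d.size < min_pairs:
        warnings.warn(
            f"only {d.size} usable pairs; falling back to the quantile slope", stacklevel=2
        )
        return a0

    def scan(grid):
        widths = [_band_width(f - a * d, coverage) for a in grid]
        return grid[int(np.argmin(widths))]

    best = scan(np.geomspace(0.1 * a0, 10 * a0, n_grid))
    best = scan(np.linspace(0.7 * best, 1.4 * best, n_grid))
    return float(best)


def estimate_kappa(
    u: np.ndarray,
    fit: GeneKineticsFit,
    n_pairs: int = 2000,
    coverage: float = 0.95,
    rng_seed: int = 0,
    gene_id: str = "",
    transient_range: tuple[float, float] = (0.1, 0.9),
    times: np.ndarray | None = None,
) -> tuple[float, PairStatistics]:
    """Density-based kappa of one gene from its unspliced counts.

    The gene's speed is only observable while its expression is actually
    changing, so pair endpoints are restricted to cells in the transient
    window of their branch (fitted m*u between ``transient_range`` fractions
    of the branch amplitude); cells dwelling at the pre-activation or
    steady plateau still contribute to the in-between counts, where the
    parallelogram's boundary fit absorbs them.

    ``times`` optionally replaces the cells-between count of every sampled
    pair by the absolute time difference |t_j - t_i| (e.g. true simulated
    times), keeping the pairs and f values identical -- the device used to
    check that cell density is a faithful proxy of elapsed time.

    The in-between count uses *all* cells in the expression interval
    (irrespective of their phase assignment), so the density clock is not
    thinned when a noisy single-branch gene gets part of its cells assigned
    to the other branch; the estimate itself comes from the phase holding
    the most transient cells (genes are single-branch at any expression
    level in this model).
    """
    u = np.asarray(u, float)
    x = fit.m * u
    # global expression ranking: the density clock counts every cell
    global_rank = np.empty(len(u), dtype=int)
    global_rank[np.argsort(u, kind="stable")] = np.arange(len(u))
    orderings = order_cells_in_phase(u, fit.k)
    lo_frac, hi_frac = transient_range
    candidates: list[PairStatistics] = []
    for k, ranking in orderings.items():
        if ranking.size < 2:
            continue
        amplitude = fit.alpha if k == 1 else fit.q_switch * fit.alpha
        xr = x[ranking]
        eligible = np.flatnonzero((xr > lo_frac * amplitude) & (xr < hi_frac * amplitude))
        if eligible.size < 2:
            continue
        i, j, _ = sample_pairs(
            ranking, n_pairs=n_pairs, rng_seed=rng_seed + (1 - k), eligible=eligible
        )
        d = np.abs(global_rank[j] - global_rank[i]) - 1.0
        f = pair_f(u[i], u[j], fit, phase=k)
        if times is not None:
            d = np.abs(np.asarray(times, float)[j] - np.asarray(times, float)[i])
        candidates.append(
            PairStatistics(gene_id=gene_id, i=i, j=j, d=d, f=f, phase=np.full(i.size, k))
        )
    if not candidates:
        raise ValueError("no phase with at least 2 transient cells")
    # dominant phase first; fall back to the other if its fit degenerates
    candidates.sort(key=lambda st: -st.i.size)
    err: Exception | None = None
    for stats in candidates:
        try:
            kappa = fit_parallelogram(stats.d, stats.f, coverage=coverage)
            return kappa, stats
        except ValueError as e:  # no usable signal in this phase
            err = e
    raise err


def _invert_spliced(s: np.ndarray, fit: GeneKineticsFit, phase: int, n_grid: int = 2000):
    """Latent time of each cell from its spliced value on the fitted branch."""
    t_sw = fit.t_switch
    scale = 1.0 / min(1.0, fit.gamma)
    q = np.linspace(0.0, 0.99995, n_grid)
    if phase == 1:
        tau = np.minimum(-np.log1p(-q) * scale, t_sw)
        _, s_grid = _curve_up(fit.alpha, fit.gamma, tau)
        if not np.all(np.diff(s_grid) >= -1e-12):
            raise ValueError("spliced curve not monotone on the up branch")
    else:
        tau = -np.log1p(-q) * scale
        _, s_grid = _curve_down(fit.alpha, fit.gamma, t_sw, tau)
        # keep the (eventually) decreasing tail, flip for interpolation
        peak = int(np.argmax(s_grid))
        tau, s_grid = tau[peak:], s_grid[peak:]
        return np.interp(np.asarray(s, float), s_grid[::-1], tau[::-1])
    return np.interp(np.asarray(s, float), s_grid, tau)


def kappa_from_spliced(
    s: np.ndarray,
    fit: GeneKineticsFit,
    stats: PairStatistics,
    coverage: float = 0.95,
) -> float:
    """Cross-check kappa estimated from the spliced counts.

    The spliced solution is inverted numerically on the fitted curve to
    assign each cell a latent time; f becomes the latent-time difference of
    each sampled pair, and the same parallelogram fit recovers kappa.  This
    route depends on gamma as well as alpha, so it is the more error-prone
    of the two estimators and serves as a consistency check.
    """
    s = np.asarray(s, float)
    f = np.full(stats.d.size, np.nan)
    for k in np.unique(stats.phase):
        mask = stats.phase == k
        tau_i = _invert_spliced(s[stats.i[mask]], fit, int(k))
        tau_j = _invert_spliced(s[stats.j[mask]], fit, int(k))
        f[mask] = tau_j - tau_i
    f = np.where(f > 0, f, np.nan)
    return fit_parallelogram(stats.d, f, coverage=coverage)


def assemble_scaled(
    fits: dict[str, GeneKineticsFit], kappas: dict[str, float]
) -> ScaledKinetics:
    """Scaled parameter vectors Theta = (A, B, Gamma) plus M for the genes
    with both a fit and a kappa estimate; genes missing kappa are dropped."""
    genes = [g for g in fits if g in kappas and np.isfinite(kappas[g])]
    missing = set(fits) - set(genes)
    if missing:
        warnings.warn(f"dropping {len(missing)} genes without a kappa estimate", stacklevel=2)
    kap = np.array([kappas[g] for g in genes])
    return ScaledKinetics(
        genes=genes,
        kappa=kap,
        A=kap * np.array([fits[g].alpha for g in genes]),
        B=kap.copy(),
        Gamma=kap * np.array([fits[g].gamma for g in genes]),
        M=np.array([fits[g].m for g in genes]),
    )


def velocity_field(scaled: ScaledKinetics, U: np.ndarray, S: np.ndarray) -> np.ndarray:
    """High-dimensional velocity V_i = B o M o U_i - Gamma o S_i.

    ``U``/``S`` must be the processed matrices restricted to (and ordered
    like) ``scaled.genes``.
    """
    U = np.asarray(U, float)
    S = np.asarray(S, float)
    n_genes = len(scaled.genes)
    if U.shape != S.shape or U.shape[1] != n_genes:
        raise ValueError("U/S shape does not match the retained gene set")
    return scaled.B[None, :] * scaled.M[None, :] * U - scaled.Gamma[None, :] * S
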