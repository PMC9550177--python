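"""Per-gene recovery of phase-portrait parameters by expectation maximisation.

For each gene the u-s phase portrait is fitted with the beta = 1 splicing-
kinetics curve.  The free parameters are the transcription rate ``alpha``,
the degradation rate ``gamma``, the unspliced upscaling factor ``m`` and the
switch point (the position on the upregulation curve where transcription
turns off).  The latent variables are each cell's branch assignment
(up/downregulation, ``k``) and its position ``tau`` along the assigned
branch.

The EM alternates:

E-step
    project every cell onto the nearest point of the current curve (both
    branches, dense tau grid), assigning ``k`` and ``tau``;
M-step
    update the parameters by nonlinear least squares on the standardised
    orthogonal residuals at the fixed projections.

Distances are measured after standardising u and s to unit variance so
neither axis dominates; consequently the likelihood is invariant to
gene-wide rescaling.  Both steps decrease the summed squared distance, so
the objective is monotone non-increasing; a small number of jittered
restarts guards against poor initialisation.

The true splicing rate is unidentifiable from a phase portrait alone
(scaling all rates and time jointly leaves the curve unchanged); the
beta = 1 solution recovered here is later put on a common time axis by the
density-based kappa estimator in :mod:`kappavelo.scale`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import spearmanr

__all__ = [
    "EMConfig",
    "GeneKineticsFit",
    "fit_gene_em",
    "assign_phase",
    "gene_likelihood",
    "filter_by_likelihood",
    "filter_by_cluster_order",
]

_Q_MAX = 0.99995  # curve grids stop this close to the branch asymptote
_VAR_FLOOR = 1e-12


@dataclass
class EMConfig:
    max_iter: int = 10
    tol: float = 1e-6  # relative parameter-change convergence threshold
    obj_tol: float = 1e-9  # relative objective-change convergence threshold
    grid_size: int = 250  # tau grid points per branch in the E-step
    n_restarts: int = 4  # jittered restarts after the deterministic run
    restart_sd: float = 0.3  # log-space jitter of the initial parameters
    seed: int = 0
    fit_m: bool = True
    switch_margin: float = 0.05  # relative improvement a switch must deliver
    polish_maxfev: int = 300  # profiled-objective polish budget (final best start)
    early_stop_obj: float = 1e-7  # per-cell objective treated as a perfect fit


@dataclass
class GeneKineticsFit:
    """Fitted beta = 1 kinetics of one gene."""

    alpha: float
    gamma: float
    m: float
    q_switch: float  # switch position as fraction of the up-branch asymptote
    k: np.ndarray  # per-cell phase (1 up, 0 down)
    tau: np.ndarray  # per-cell position along the assigned branch
    residual_variance: float
    log_likelihood: float
    converged: bool
    n_iter: int
    objective: float  # mean squared standardised distance to the curve
    sd_u: float
    sd_s: float
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    flags: dict = field(default_factory=dict)

    @property
    def t_switch(self) -> float:
        return -np.log1p(-self.q_switch)

    @property
    def u_switch(self) -> float:
        """Switch point in measured-u units (m * u_switch <= alpha)."""
        return self.q_switch * self.alpha / self.m

    @property
    def s_switch(self) -> float:
        return _curve_up(self.alpha, self.gamma, np.array([self.t_switch]))[1][0]

    def progression(self) -> np.ndarray:
        """Monotone curve coordinate: up-branch tau, then t_switch + down tau."""
        return np.where(self.k == 1, self.tau, self.t_switch + self.tau)


def _curve_up(alpha: float, gamma: float, tau: np.ndarray):
    """(x, s) on the upregulation branch (beta=1, x = m*u, zero initials)."""
    e = np.exp(-tau)
    x = alpha * (1.0 - e)
    eg = np.exp(-gamma * tau)
    if abs(gamma - 1.0) < 1e-8:
        s = alpha * (1.0 - eg) / gamma + alpha * (-tau * e)
    else:
        s = alpha / gamma * (1.0 - eg) + alpha / (gamma - 1.0) * (eg - e)
    return x, s


def _curve_down(alpha: float, gamma: float, t_sw: float, tau: np.ndarray):
    """(x, s) on the downregulation branch, initialised at the switch point."""
    x_sw, s_sw = _curve_up(alpha, gamma, np.array([t_sw]))
    x_sw, s_sw = float(x_sw[0]), float(s_sw[0])
    e = np.exp(-tau)
    x = x_sw * e
    eg = np.exp(-gamma * tau)
    if abs(gamma - 1.0) < 1e-8:
        s = s_sw * eg - x_sw * (-tau * e)
    else:
        s = s_sw * eg - x_sw / (gamma - 1.0) * (eg - e)
    return x, s


def _tau_grids(gamma: float, t_sw: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-uniform tau grids covering both branches up to near-equilibration."""
    q = np.linspace(0.0, _Q_MAX, n)
    scale = 1.0 / min(1.0, gamma)  # slow degradation needs a longer horizon
    tau_up = np.minimum(-np.log1p(-q) * scale, t_sw)
    tau_down = -np.log1p(-q) * scale
    return tau_up, tau_down


def _branch_dist2(u_std, s_std, alpha, gamma, m, t_sw, sd_u, sd_s, tau, branch):
    """Squared standardised distances from cells to curve points at tau."""
    if branch == 1:
        x, sv = _curve_up(alpha, gamma, np.minimum(tau, t_sw))
    else:
        x, sv = _curve_down(alpha, gamma, t_sw, tau)
    return (u_std - x / (m * sd_u)) ** 2 + (s_std - sv / sd_s) ** 2


def _refine_tau(u_std, s_std, alpha, gamma, m, t_sw, sd_u, sd_s, tau_lo, tau_hi, branch, iters=10):
    """Vectorised golden-section refinement of per-cell projections."""
    inv_phi = 0.6180339887498949
    a, b = tau_lo.copy(), tau_hi.copy()
    c = b - inv_phi * (b - a)
    d = a + inv_phi * (b - a)
    fc = _branch_dist2(u_std, s_std, alpha, gamma, m, t_sw, sd_u, sd_s, c, branch)
    fd = _branch_dist2(u_std, s_std, alpha, gamma, m, t_sw, sd_u, sd_s, d, branch)
    for _ in range(iters):
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c = b - inv_phi * (b - a)
        d = a + inv_phi * (b - a)
        fc = _branch_dist2(u_std, s_std, alpha, gamma, m, t_sw, sd_u, sd_s, c, branch)
        fd = _branch_dist2(u_std, s_std, alpha, gamma, m, t_sw, sd_u, sd_s, d, branch)
    tau = 0.5 * (a + b)
    return tau, _branch_dist2(u_std, s_std, alpha, gamma, m, t_sw, sd_u, sd_s, tau, branch)


def _project(u, s, alpha, gamma, m, q_sw, sd_u, sd_s, grid_size, refine=True, branches="both"):
    """E-step: nearest curve point per cell -> (k, tau, squared distances)."""
    t_sw = -np.log1p(-q_sw)
    tau_up, tau_down = _tau_grids(gamma, t_sw, grid_size)
    u_std = u / sd_u
    s_std = s / sd_s
    if branches == "up":
        xu, su = _curve_up(alpha, gamma, tau_up)
        cx = xu / (m * sd_u)
        cs = su / sd_s
        d2 = (u_std[:, None] - cx[None, :]) ** 2 + (s_std[:, None] - cs[None, :]) ** 2
        j = np.argmin(d2, axis=1)
        if refine:
            lo = tau_up[np.maximum(j - 1, 0)]
            hi = tau_up[np.minimum(j + 1, grid_size - 1)]
            tau, best = _refine_tau(u_std, s_std, alpha, gamma, m, t_sw, sd_u, sd_s, lo, hi, 1)
            return np.ones(len(u), int), tau, best
        return np.ones(len(u), int), tau_up[j], d2[np.arange(len(u)), j]
    xu, su = _curve_up(alpha, gamma, tau_up)
    xd, sd_ = _curve_down(alpha, gamma, t_sw, tau_down)
    # curves in standardised measured space
    cx = np.concatenate([xu, xd]) / (m * sd_u)
    cs = np.concatenate([su, sd_]) / sd_s
    d2 = (u_std[:, None] - cx[None, :]) ** 2 + (s_std[:, None] - cs[None, :]) ** 2
    if refine:
        # refine each cell's projection on both branches, then pick the branch
        best_tau = np.empty((2, len(u)))
        best_d2 = np.empty((2, len(u)))
        for bi, (branch, taus, off) in enumerate(
            ((1, tau_up, 0), (0, tau_down, grid_size))
        ):
            sub = d2[:, off : off + grid_size]
            j = np.argmin(sub, axis=1)
            lo = taus[np.maximum(j - 1, 0)]
            hi = taus[np.minimum(j + 1, grid_size - 1)]
            best_tau[bi], best_d2[bi] = _refine_tau(
                u_std, s_std, alpha, gamma, m, t_sw, sd_u, sd_s, lo, hi, branch
            )
        # ties resolve to the up branch (listed first)
        k = (best_d2[0] <= best_d2[1]).astype(int)
        tau = np.where(k == 1, best_tau[0], best_tau[1])
        return k, tau, np.where(k == 1, best_d2[0], best_d2[1])
    best = np.argmin(d2, axis=1)
    k = (best < grid_size).astype(int)
    tau = np.where(k == 1, tau_up[np.minimum(best, grid_size - 1)], tau_down[best - grid_size])
    return k, tau, d2[np.arange(len(u)), best]


def _pack(alpha, gamma, m, q_sw, fit_m, fit_switch):
    x = [np.log(alpha), np.log(gamma)]
    if fit_m:
        x.append(np.log(m))
    if fit_switch:
        x.append(np.log(q_sw / (1.0 - q_sw)))
    return np.array(x)


def _unpack(x, m_fixed, q_fixed, fit_m, fit_switch):
    x = np.clip(x, -30.0, 30.0)  # keep exp/logit finite
    alpha, gamma = np.exp(x[0]), np.exp(x[1])
    i = 2
    m = np.exp(x[i]) if fit_m else m_fixed
    i += fit_m
    q_sw = 1.0 / (1.0 + np.exp(-x[i])) if fit_switch else q_fixed
    q_sw = float(np.clip(q_sw, 1e-6, 1.0 - 1e-6))
    return alpha, gamma, m, q_sw


def _residuals(x, u, s, k, tau, sd_u, sd_s, m_fixed, q_fixed, fit_m, fit_switch):
    alpha, gamma, m, q_sw = _unpack(x, m_fixed, q_fixed, fit_m, fit_switch)
    t_sw = -np.log1p(-q_sw)
    up = k == 1
    xm = np.empty_like(u)
    sm = np.empty_like(s)
    if up.any():
        xm[up], sm[up] = _curve_up(alpha, gamma, np.minimum(tau[up], t_sw))
    if (~up).any():
        xm[~up], sm[~up] = _curve_down(alpha, gamma, t_sw, tau[~up])
    return np.concatenate([(u - xm / m) / sd_u, (s - sm) / sd_s])


def _initial_guess(u, s):
    sd_u = u.std()
    sd_s = s.std()
    m0 = sd_s / sd_u if sd_u > 0 else 1.0
    alpha0 = 1.05 * m0 * u.max()
    # slope of s on x over the extreme-abundance cells; at steady state
    # s = x/gamma, so gamma0 is the inverse slope
    x = m0 * u
    q_lo, q_hi = np.quantile(x, [0.05, 0.95])
    extreme = (x <= q_lo) | (x >= q_hi)
    denom = (x[extreme] ** 2).sum()
    slope = (s[extreme] * x[extreme]).sum() / denom if denom > 0 else 1.0
    gamma0 = 1.0 / max(slope, 1e-3)
    q_sw0 = min(u.max() * m0 / alpha0, 0.98)
    return alpha0, gamma0, m0, q_sw0


def _profiled_objective(x, u, s, sd_u, sd_s, m_cur, q_cur, fit_m, fit_switch, grid_size, branches):
    """Mean squared curve distance with cells re-projected at every call."""
    alpha, gamma, m, q_sw = _unpack(x, m_cur, q_cur, fit_m, fit_switch)
    try:
        _, _, d2 = _project(u, s, alpha, gamma, m, q_sw, sd_u, sd_s, grid_size, branches=branches)
    except (ValueError, FloatingPointError):
        return np.inf
    return float(d2.mean())


def _run_em(u, s, alpha, gamma, m, q_sw, sd_u, sd_s, config: EMConfig, polish_maxfev=None, branches="both"):
    if polish_maxfev is None:
        polish_maxfev = config.polish_maxfev
    history = []
    prev_params = np.array([alpha, gamma, m, q_sw])
    prev_obj = np.inf
    converged = False
    it = 0
    for it in range(config.max_iter):
        k, tau, d2 = _project(u, s, alpha, gamma, m, q_sw, sd_u, sd_s, config.grid_size, branches=branches)
        obj = d2.mean()
        history.append(obj)
        fit_switch = bool((k == 0).any()) and branches == "both"
        x0 = _pack(alpha, gamma, m, q_sw, config.fit_m, fit_switch)
        res = least_squares(
            _residuals,
            x0,
            args=(u, s, k, tau, sd_u, sd_s, m, q_sw, config.fit_m, fit_switch),
            method="lm",
            max_nfev=100,
        )
        cand = _unpack(res.x, m, q_sw, config.fit_m, fit_switch)
        # accept the M-step only if it improves the profiled objective,
        # keeping the objective monotone non-increasing
        _, _, d2_cand = _project(u, s, *cand, sd_u, sd_s, config.grid_size, branches=branches)
        if d2_cand.mean() <= obj:
            alpha, gamma, m, q_sw = cand
        params = np.array([alpha, gamma, m, q_sw])
        dparam = np.max(np.abs(params - prev_params) / np.maximum(np.abs(prev_params), 1e-12))
        dobj = (prev_obj - obj) / max(obj, 1e-300)
        prev_params, prev_obj = params, obj
        if obj < config.early_stop_obj or dparam < config.tol or (0 <= dobj < config.obj_tol):
            converged = True
            break

    # polish: direct minimisation of the profiled objective (re-projecting
    # every evaluation), which escapes the slow zigzag of the alternation
    k, tau, d2 = _project(u, s, alpha, gamma, m, q_sw, sd_u, sd_s, config.grid_size, branches=branches)
    fit_switch = bool((k == 0).any()) and branches == "both"
    x0 = _pack(alpha, gamma, m, q_sw, config.fit_m, fit_switch)
    polish_grid = max(100, config.grid_size // 2)
    res = minimize(
        _profiled_objective,
        x0,
        args=(u, s, sd_u, sd_s, m, q_sw, config.fit_m, fit_switch, polish_grid, branches),
        method="Nelder-Mead",
        options={"maxfev": polish_maxfev, "xatol": 1e-8, "fatol": 1e-14},
    )
    if np.isfinite(res.fun) and res.fun <= d2.mean():
        alpha, gamma, m, q_sw = _unpack(res.x, m, q_sw, config.fit_m, fit_switch)
        converged = converged or bool(res.success)

    k, tau, d2 = _project(u, s, alpha, gamma, m, q_sw, sd_u, sd_s, config.grid_size, branches=branches)
    history.append(d2.mean())
    converged = converged or d2.mean() < config.early_stop_obj
    return alpha, gamma, m, q_sw, k, tau, d2, converged, it + 1, np.array(history)


def fit_gene_em(u: np.ndarray, s: np.ndarray, config: EMConfig | None = None) -> GeneKineticsFit:
    """Fit the beta = 1 phase-portrait kinetics of one gene.

    ``u`` and ``s`` are the per-cell (imputed, jointly normalised) unspliced
    and spliced abundances.  Returns the best fit over the deterministic
    initialisation plus ``config.n_restarts`` jittered restarts.
    """
    config = config or EMConfig()
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(u) < 20:
        raise ValueError("need at least 20 cells to fit a gene")
    sd_u, sd_s = u.std(), s.std()
    if sd_u <= 0 or sd_s <= 0:
        raise ValueError("gene has zero variance in u or s; filter first")

    alpha0, gamma0, m0, q_sw0 = _initial_guess(u, s)
    if not config.fit_m:
        m0 = 1.0
    rng = np.random.default_rng(config.seed)
    starts = [(alpha0, gamma0, m0, q_sw0)]
    for _ in range(config.n_restarts):
        jit = np.exp(rng.normal(0.0, config.restart_sd, size=3))
        starts.append(
            (
                alpha0 * jit[0],
                gamma0 * jit[1],
                m0 * jit[2] if config.fit_m else 1.0,
                float(np.clip(q_sw0 * np.exp(rng.normal(0, 0.1)), 0.05, 0.99)),
            )
        )

    best = None
    cheap_budget = max(config.polish_maxfev // 3, 50)
    for a0, g0, mm0, q0 in starts:
        try:
            out = _run_em(u, s, a0, g0, mm0, q0, sd_u, sd_s, config, polish_maxfev=cheap_budget)
        except (ValueError, FloatingPointError):
            continue
        if best is None or out[6].mean() < best[6].mean():
            best = out
        if best[6].mean() < config.early_stop_obj:
            break
    if best is None:
        raise RuntimeError("EM failed from every initialisation")

    # one full-budget polish of the winning start
    if best[6].mean() >= config.early_stop_obj:
        try:
            best = _run_em(u, s, *best[:4], sd_u, sd_s, config)
        except (ValueError, FloatingPointError):
            pass

    # nested model selection: a transcriptional switch stays in the model
    # only if it beats the induction-only fit by a clear margin, otherwise
    # noise around a single branch gets absorbed into a spurious switch
    try:
        up_only = _run_em(
            u, s, best[0], best[1], best[2], 1.0 - 1e-6, sd_u, sd_s, config, branches="up"
        )
        if up_only[6].mean() <= best[6].mean() * (1.0 + config.switch_margin):
            best = up_only
    except (ValueError, FloatingPointError):
        pass

    alpha, gamma, m, q_sw, k, tau, d2, converged, n_iter, history = best
    resid_var = max(d2.mean() / 2.0, _VAR_FLOOR)  # per-coordinate variance
    ll = -np.log(2.0 * np.pi * resid_var) - d2.mean() / (2.0 * resid_var)
    fit = GeneKineticsFit(
        alpha=float(alpha),
        gamma=float(gamma),
        m=float(m),
        q_switch=float(q_sw),
        k=k,
        tau=tau,
        residual_variance=float(resid_var),
        log_likelihood=float(ll),
        converged=bool(converged),
        n_iter=int(n_iter),
        objective=float(d2.mean()),
        sd_u=float(sd_u),
        sd_s=float(sd_s),
        objective_history=history,
    )
    if not converged:
        fit.flags["non_converged"] = True
        warnings.warn("EM did not converge; returning best-so-far parameters", stacklevel=2)
    # a cloud parked at a fixed point constrains no kinetics: flag fits whose
    # data cover only a sliver of the fitted curve in both coordinates
    if np.ptp(m * u) < 0.1 * alpha and np.ptp(s) < 0.1 * alpha / gamma:
        fit.flags["unidentifiable"] = True
    return fit


def assign_phase(u: np.ndarray, s: np.ndarray, fit: GeneKineticsFit, grid_size: int = 400):
    """Per-cell phase labels (1 up, 0 down) under a fitted curve.

    Each cell goes to the branch whose nearest curve point (in standardised
    u-s space) is closer; exact ties resolve to upregulation.
    """
    k, _, _ = _project(
        np.asarray(u, float),
        np.asarray(s, float),
        fit.alpha,
        fit.gamma,
        fit.m,
        fit.q_switch,
        fit.sd_u,
        fit.sd_s,
        grid_size,
    )
    return k


def gene_likelihood(fit: GeneKineticsFit) -> float:
    """Mean per-cell Gaussian log-likelihood of the fit (higher is better)."""
    return fit.log_likelihood


def filter_by_likelihood(
    fits: dict[str, GeneKineticsFit],
    threshold: float | None = None,
    quantile: float = 0.5,
) -> list[str]:
    """Genes whose fit likelihood passes the threshold.

    With no absolute ``threshold`` the top ``1 - quantile`` fraction is
    retained (default: upper half).
    """
    lls = {g: f.log_likelihood for g, f in fits.items()}
    if threshold is None:
        threshold = float(np.quantile(list(lls.values()), quantile))
    return [g for g, ll in lls.items() if ll >= threshold]


def filter_by_cluster_order(
    fits: dict[str, GeneKineticsFit],
    cell_labels: np.ndarray,
    hierarchy: list[str] | None = None,
) -> list[str]:
    """Reject genes whose fitted dynamics run against a known cell-type order.

    For each gene the mean fitted curve position (up-branch time, continuing
    through the switch) is computed per cluster; the gene is dropped when
    the Spearman rank correlation between the cluster's position in
    ``hierarchy`` and its mean fitted position is negative.  Identity when
    no hierarchy is given.
    """
    if hierarchy is None:
        return list(fits)
    labels = np.asarray(cell_labels)
    rank = {lab: i for i, lab in enumerate(hierarchy)}
    unknown = set(labels) - set(rank)
    if unknown:
        warnings.warn(f"labels {sorted(unknown)} absent from hierarchy; ignored", stacklevel=2)
    keep = []
    for g, fit in fits.items():
        pos = fit.progression()
        means, ranks = [], []
        for lab, r in rank.items():
            mask = labels == lab
            if mask.any():
                means.append(pos[mask].mean())
                ranks.append(r)
        if len(means) < 2:
            keep.append(g)
            continue
        rho = spearmanr(ranks, means).statistic
        if not (rho < 0):
            keep.append(g)
    return keep
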