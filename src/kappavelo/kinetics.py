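"""Closed-form splicing kinetics.

The two-stage model of transcription couples nascent (unspliced, ``u``) and
mature (spliced, ``s``) mRNA of one gene through three rate constants:

.. math::

    du/dt = \\alpha - \\beta u, \\qquad ds/dt = \\beta u - \\gamma s

with transcription rate ``alpha`` (molecules/time), splicing rate ``beta``
(1/time) and degradation rate ``gamma`` (1/time).  Transcriptional regulation
is a binary switch: during upregulation (phase ``k=1``) alpha is active;
at the switch time transcription shuts off and the downregulation branch
(``k=0``) evolves with alpha = 0 from the switch-time state.

Because sequencing protocols systematically undercount nascent reads, the
*measured* unspliced abundance is modelled as the true one divided by a
gene-specific upscaling factor ``m``; internally every formula operates on
``m * u``.

All functions are vectorised over time / abundance arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GeneParams",
    "unspliced_at",
    "spliced_at",
    "phase_portrait",
    "steady_state",
    "gene_velocity",
]

#: threshold below which |beta - gamma| (or |gamma - 1|) selects the
#: analytic-limit branch of the spliced solution
_DEGENERACY_TOL = 1e-8


@dataclass(frozen=True)
class GeneParams:
    """Kinetic parameters of one gene.

    ``u0``/``s0`` are the initial abundances at the start of upregulation
    (measured-u units), ``t_switch`` the time at which transcription turns
    off, and ``m`` the unspliced upscaling factor.
    """

    alpha: float
    beta: float = 1.0
    gamma: float = 0.5
    u0: float = 0.0
    s0: float = 0.0
    t_switch: float = np.inf
    m: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.u0 < 0 or self.s0 < 0:
            raise ValueError("initial abundances must be nonnegative")


def _branch_initials(params: GeneParams, phase: int) -> tuple[float, float, float]:
    """Return (alpha_eff, x0, s0) for the requested phase.

    ``x0`` is in true-unspliced units (m * measured u).  For the
    downregulation branch the initial conditions are the upregulation curve
    evaluated at ``t_switch`` and alpha is set to 0.
    """
    if phase == 1:
        return params.alpha, params.m * params.u0, params.s0
    if not np.isfinite(params.t_switch):
        raise ValueError("downregulation requested but t_switch is not finite")
    u_sw = unspliced_at(params, params.t_switch, phase=1)
    s_sw = spliced_at(params, params.t_switch, phase=1)
    return 0.0, params.m * float(u_sw), float(s_sw)


def _x_at(alpha: float, beta: float, x0: float, tau: np.ndarray) -> np.ndarray:
    """True unspliced x(tau) = x0 e^{-beta tau} + (alpha/beta)(1 - e^{-beta tau})."""
    e = np.exp(-beta * tau)
    return x0 * e + (alpha / beta) * (1.0 - e)


def _s_at(
    alpha: float, beta: float, gamma: float, x0: float, s0: float, tau: np.ndarray
) -> np.ndarray:
    eg = np.exp(-gamma * tau)
    s = s0 * eg + (alpha / gamma) * (1.0 - eg)
    if abs(gamma - beta) < _DEGENERACY_TOL:
        # analytic limit of (e^{-gamma tau} - e^{-beta tau})/(gamma - beta)
        s = s + (alpha - beta * x0) * (-tau * np.exp(-beta * tau))
    else:
        eb = np.exp(-beta * tau)
        s = s + (alpha - beta * x0) / (gamma - beta) * (eg - eb)
    return s


def unspliced_at(params: GeneParams, tau, phase: int = 1):
    """Measured unspliced abundance after elapsed time ``tau`` within a phase.

    ``tau`` counts from the start of the phase (activation for ``k=1``, the
    switch for ``k=0``).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be nonnegative")
    alpha_eff, x0, _ = _branch_initials(params, phase)
    return _x_at(alpha_eff, params.beta, x0, tau) / params.m


def spliced_at(params: GeneParams, tau, phase: int = 1):
    """Spliced abundance after elapsed time ``tau`` within a phase."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be nonnegative")
    alpha_eff, x0, s0 = _branch_initials(params, phase)
    return _s_at(alpha_eff, params.beta, params.gamma, x0, s0, tau)


def invert_unspliced(params: GeneParams, u, phase: int = 1):
    """Elapsed time tau at which the phase's u-curve passes through ``u``.

    Inverts u(t) via exp(-beta tau) = (beta m u - alpha)/(beta m u0 - alpha).
    Values of ``u`` beyond the branch asymptote raise.
    """
    u = np.asarray(u, dtype=float)
    alpha_eff, x0, _ = _branch_initials(params, phase)
    beta = params.beta
    num = beta * params.m * u - alpha_eff
    den = beta * x0 - alpha_eff
    if abs(den) < _DEGENERACY_TOL:
        raise ValueError("degenerate ratio base: m*u0 equals the asymptote")
    ratio = num / den
    if np.any(ratio <= 0):
        raise ValueError("u lies beyond the asymptote of this branch")
    return -np.log(ratio) / beta


def phase_portrait(params: GeneParams, u, phase: int = 1):
    """Spliced abundance s(u) on the time-independent phase-portrait curve.

    Computed by inverting the unspliced solution for the elapsed time and
    evaluating the spliced solution there, which is algebraically identical
    to the closed-form s(u) expression (including its gamma -> beta limit).
    """
    tau = invert_unspliced(params, u, phase=phase)
    return spliced_at(params, tau, phase=phase)


def steady_state(params: GeneParams) -> tuple[float, float]:
    """Fixed point of the active kinetics, in measured-u units.

    u_ss = alpha/(m beta), s_ss = alpha/gamma; the gene velocity vanishes
    there.
    """
    return params.alpha / (params.m * params.beta), params.alpha / params.gamma


def gene_velocity(B, M, Gamma, u, s):
    """Velocity component v = B*M*u - Gamma*s.

    ``B``, ``Gamma`` are the correctly scaled splicing/degradation rates
    (kappa*beta, kappa*gamma) and ``M`` the unspliced upscale; broadcasts
    over matching array shapes.
    """
    return np.asarray(B) * np.asarray(M) * np.asarray(u) - np.asarray(Gamma) * np.asarray(s)
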