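"""The idealized sparse-coding dynamical system (locally competitive algorithm).

The network infers coefficients a for a stimulus s under the objective

    E(a) = ½‖s − Φa‖₂² + λ‖a‖₁,

by integrating the internal-state dynamics

    τ u̇(t) = Φᵀs − u(t) − (G − I) a(t),      a(t) = T_λ(u(t)),

with G = ΦᵀΦ and T_λ the soft-threshold function.  Thresholded fixed points
of these dynamics are minimizers of E.  Integration is forward Euler from
u(0) = 0 with step dt = dt_over_tau · τ.

By default the code is constrained to be nonnegative (one-sided threshold),
matching the interpretation of a as firing rates; the two-sided threshold is
retained for generality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import ConnectivityMatrix, Dictionary
from .errors import IntegrationDivergedError, ParameterError
from .stimuli import Stimulus

#: Activities with |a| above this count as "active" for the l0 sparsity
#: measure; thresholding produces exact zeros, so any tiny value works.
ACTIVITY_ZERO_TOL = 1e-12


@dataclass
class LCAParams:
    """Threshold λ, time constant τ, Euler step and step count."""

    lam: float = 0.1
    tau: float = 1.0
    dt_over_tau: float = 0.1
    n_steps: int = 25
    nonneg: bool = True

    def __post_init__(self):
        if self.lam <= 0:
            raise ParameterError("lambda must be positive")
        if not (0 < self.dt_over_tau <= 1):
            raise ParameterError("dt_over_tau must lie in (0, 1]")
        if self.n_steps < 1:
            raise ParameterError("n_steps must be >= 1")


@dataclass
class Trajectory:
    """Stored time course of a simulation plus its final metrics.

    ``u`` and ``a`` have shape (n_steps + 1, M) including the initial
    condition.  ``interneurons`` optionally maps population names to
    (n_steps + 1, count) activity courses for E/I simulations.
    """

    u: np.ndarray
    a: np.ndarray
    energy: np.ndarray
    final_active_fraction: float
    final_rel_l2_error: float
    interneurons: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def final_a(self) -> np.ndarray:
        return self.a[-1]

    @property
    def final_energy(self) -> float:
        return float(self.energy[-1])


def soft_threshold(u: np.ndarray, lam: float,
                   nonneg: bool = False) -> np.ndarray:
    """T_λ(u): two-sided shrinkage, or its one-sided (rectified) variant."""
    if lam < 0:
        raise ParameterError("threshold must be >= 0")
    u = np.asarray(u, dtype=float)
    if nonneg:
        return np.maximum(u - lam, 0.0)
    return np.sign(u) * np.maximum(np.abs(u) - lam, 0.0)


def energy(s: Stimulus | np.ndarray, d: Dictionary, a: np.ndarray,
           lam: float) -> float:
    """Sparse-coding objective ½‖s − Φa‖² + λ‖a‖₁."""
    s_vec = s.s if isinstance(s, Stimulus) else np.asarray(s, dtype=float)
    residual = s_vec - d.phi @ a
    return float(0.5 * residual @ residual + lam * np.sum(np.abs(a)))


def active_fraction(a: np.ndarray, tol: float = ACTIVITY_ZERO_TOL) -> float:
    """Fraction of units with |aᵢ| > tol (i.e. ‖a‖₀ / M)."""
    if tol < 0:
        raise ParameterError("tol must be >= 0")
    a = np.asarray(a)
    return float(np.count_nonzero(np.abs(a) > tol) / a.shape[0])


def _check_finite(u: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(u)):
        raise IntegrationDivergedError(step)


def simulate_lca(d: Dictionary, s: Stimulus, p: LCAParams,
                 g: ConnectivityMatrix | None = None) -> Trajectory:
    """Integrate the idealized recurrent dynamics and record the trajectory.

    ``g`` defaults to the Gram matrix of ``d``; a caller-supplied equivalent
    (e.g. a cached or perturbed connectivity) may be passed instead.
    """
    from .dictionary import gram_matrix

    if g is None:
        g = gram_matrix(d)
    gm = g.g
    m = d.n_elements
    if s.s.shape[0] != d.n_pixels:
        raise ParameterError("stimulus length does not match dictionary")
    b = d.phi.T @ s.s  # feed-forward drive Φᵀs
    dt = p.dt_over_tau

    u = np.zeros(m)
    u_hist = np.empty((p.n_steps + 1, m))
    a_hist = np.empty((p.n_steps + 1, m))
    u_hist[0] = u
    a = soft_threshold(u, p.lam, p.nonneg)
    a_hist[0] = a
    for t in range(1, p.n_steps + 1):
        u = u + dt * (b - u - (gm @ a - a))
        _check_finite(u, t)
        a = soft_threshold(u, p.lam, p.nonneg)
        u_hist[t] = u
        a_hist[t] = a
    energies = np.array([energy(s, d, a_hist[t], p.lam)
                         for t in range(p.n_steps + 1)])
    s_norm = np.linalg.norm(s.s)
    rel_err = float(np.linalg.norm(s.s - d.phi @ a) / s_norm) \
        if s_norm > 0 else 0.0
    return Trajectory(u=u_hist, a=a_hist, energy=energies,
                      final_active_fraction=active_fraction(a),
                      final_rel_l2_error=rel_err)


def lca_fixed_point(d: Dictionary, s: Stimulus, p: LCAParams,
                    g: ConnectivityMatrix | None = None,
                    max_steps: int = 10000, tol: float = 1e-10) -> np.ndarray:
    """Run the dynamics until the state stops changing; returns final a.

    Convenience for optimality checks and steady-state response protocols:
    integrates with the same Euler rule until the relative state change per
    step falls below ``tol`` or ``max_steps`` is reached.
    """
    from .dictionary import gram_matrix

    if g is None:
        g = gram_matrix(d)
    gm = g.g
    b = d.phi.T @ s.s
    dt = p.dt_over_tau
    u = np.zeros(d.n_elements)
    a = soft_threshold(u, p.lam, p.nonneg)
    for t in range(1, max_steps + 1):
        u_new = u + dt * (b - u - (gm @ a - a))
        _check_finite(u_new, t)
        delta = np.linalg.norm(u_new - u) / max(np.linalg.norm(u_new), 1e-12)
        u = u_new
        a = soft_threshold(u, p.lam, p.nonneg)
        if delta < tol:
            break
    return a
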