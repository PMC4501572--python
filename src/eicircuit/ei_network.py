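"""Simulation of the Dale's-law E/I networks and their equivalence metrics.

Two interneuron models are simulated for any factorization:

* instantaneous — interneuron activities are pure (linear) functions of the
  principal activities at every step, so the principal dynamics are

      τ u̇ = Φᵀs − [U₊ΣV₊ᵀ + (−U₋)Σ(−V₋ᵀ) + S₊D] a + (I − G^Excite) a − u;

* dynamic — every interneuron population is a leaky integrator with the
  same time constant τ as the principal cells:

      τ ȧ_I = W_in a − a_I,

  and the inhibitory drive uses the integrated activities.

With an exact factorization (direct, gramian, full-rank svd) the
instantaneous network is algebraically identical to the idealized
recurrent model, since the inhibitory and excitatory terms recombine to
−(G − I)a.  Equivalence on approximate factorizations is quantified by
:func:`equivalence_report` over a stimulus set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompositions import EIFactorization
from .dictionary import Dictionary
from .errors import ParameterError
from .lca import (LCAParams, Trajectory, active_fraction, energy,
                  simulate_lca, soft_threshold, _check_finite)
from .stimuli import Stimulus


@dataclass
class EquivalenceReport:
    """Per-stimulus comparison of the idealized and E/I networks."""

    per_stimulus: pd.DataFrame
    mean_rel_energy_error: float
    sd_rel_energy_error: float
    mode: str
    degenerate_sd: bool = False  # single stimulus: sd reported as 0

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "n_stimuli": int(len(self.per_stimulus)),
            "mean_rel_energy_error": self.mean_rel_energy_error,
            "sd_rel_energy_error": self.sd_rel_energy_error,
            "max_active_fraction_orig":
                float(self.per_stimulus["l0_orig"].max()),
            "max_active_fraction_ei":
                float(self.per_stimulus["l0_ei"].max()),
        }


def _gain_scaled_inputs(f: EIFactorization) -> list[np.ndarray]:
    return [gain[:, np.newaxis] * w_in
            for gain, w_in in zip(f.inhib_gain, f.inhib_in)]


def simulate_ei_instantaneous(d: Dictionary, s: Stimulus,
                              f: EIFactorization,
                              p: LCAParams) -> Trajectory:
    """E/I network with interneurons as instantaneous linear relays."""
    if s.s.shape[0] != d.n_pixels:
        raise ParameterError("stimulus length does not match dictionary")
    w_ins = _gain_scaled_inputs(f)
    w_outs = f.inhib_out
    ge = f.g_excite_direct
    b = d.phi.T @ s.s
    dt = p.dt_over_tau
    m = d.n_elements

    u = np.zeros(m)
    a = soft_threshold(u, p.lam, p.nonneg)
    u_hist = np.empty((p.n_steps + 1, m))
    a_hist = np.empty((p.n_steps + 1, m))
    inter_hist = {name: np.empty((p.n_steps + 1, w.shape[0]))
                  for name, w in zip(f.population_names, w_ins)}
    u_hist[0], a_hist[0] = u, a
    for name, w in zip(f.population_names, w_ins):
        inter_hist[name][0] = w @ a
    for t in range(1, p.n_steps + 1):
        inhib = np.zeros(m)
        for name, w_in, w_out in zip(f.population_names, w_ins, w_outs):
            a_i = w_in @ a
            inter_hist[name][t] = a_i
            inhib += w_out @ a_i
        u = u + dt * (b - inhib + ge @ a - u)
        _check_finite(u, t)
        a = soft_threshold(u, p.lam, p.nonneg)
        u_hist[t], a_hist[t] = u, a
    energies = np.array([energy(s, d, a_hist[t], p.lam)
                         for t in range(p.n_steps + 1)])
    s_norm = np.linalg.norm(s.s)
    rel = float(np.linalg.norm(s.s - d.phi @ a) / s_norm) if s_norm else 0.0
    return Trajectory(u=u_hist, a=a_hist, energy=energies,
                      final_active_fraction=active_fraction(a),
                      final_rel_l2_error=rel, interneurons=inter_hist)


def simulate_ei_dynamic(d: Dictionary, s: Stimulus, f: EIFactorization,
                        p: LCAParams) -> Trajectory:
    """E/I network with leaky-integrator interneurons (shared τ).

    All populations are integrated jointly with the same Euler step as the
    principal cells, starting from zero.
    """
    if s.s.shape[0] != d.n_pixels:
        raise ParameterError("stimulus length does not match dictionary")
    w_ins = _gain_scaled_inputs(f)
    w_outs = f.inhib_out
    ge = f.g_excite_direct
    b = d.phi.T @ s.s
    dt = p.dt_over_tau
    m = d.n_elements

    u = np.zeros(m)
    a = soft_threshold(u, p.lam, p.nonneg)
    a_int = [np.zeros(w.shape[0]) for w in w_ins]
    u_hist = np.empty((p.n_steps + 1, m))
    a_hist = np.empty((p.n_steps + 1, m))
    inter_hist = {name: np.empty((p.n_steps + 1, w.shape[0]))
                  for name, w in zip(f.population_names, w_ins)}
    u_hist[0], a_hist[0] = u, a
    for name, ai in zip(f.population_names, a_int):
        inter_hist[name][0] = ai
    for t in range(1, p.n_steps + 1):
        inhib = np.zeros(m)
        for k, (name, w_in, w_out) in enumerate(
                zip(f.population_names, w_ins, w_outs)):
            inhib += w_out @ a_int[k]
        u_new = u + dt * (b - inhib + ge @ a - u)
        for k, (name, w_in) in enumerate(zip(f.population_names, w_ins)):
            a_int[k] = a_int[k] + dt * (w_in @ a - a_int[k])
            inter_hist[name][t] = a_int[k]
        u = u_new
        _check_finite(u, t)
        a = soft_threshold(u, p.lam, p.nonneg)
        u_hist[t], a_hist[t] = u, a
    energies = np.array([energy(s, d, a_hist[t], p.lam)
                         for t in range(p.n_steps + 1)])
    s_norm = np.linalg.norm(s.s)
    rel = float(np.linalg.norm(s.s - d.phi @ a) / s_norm) if s_norm else 0.0
    return Trajectory(u=u_hist, a=a_hist, energy=energies,
                      final_active_fraction=active_fraction(a),
                      final_rel_l2_error=rel, interneurons=inter_hist)


def equivalence_report(d: Dictionary, stimuli: list[Stimulus],
                       f: EIFactorization, p: LCAParams,
                       mode: str = "instantaneous") -> EquivalenceReport:
    """Run the idealized and E/I networks side by side on each stimulus.

    Records final energy, active fraction (‖a‖₀/M) and relative l2
    reconstruction error for both networks, plus the relative final-energy
    error |E_ei − E_orig| / E_orig per stimulus and its mean ± sd.
    """
    if not stimuli:
        raise ParameterError("need at least one stimulus")
    if mode not in ("instantaneous", "dynamic"):
        raise ParameterError(f"unknown mode {mode!r}")
    simulate_ei = simulate_ei_instantaneous if mode == "instantaneous" \
        else simulate_ei_dynamic
    from .dictionary import gram_matrix
    g = gram_matrix(d)
    rows = []
    for idx, s in enumerate(stimuli):
        orig = simulate_lca(d, s, p, g)
        approx = simulate_ei(d, s, f, p)
        e_orig, e_ei = orig.final_energy, approx.final_energy
        rel = abs(e_ei - e_orig) / e_orig if e_orig > 0 else 0.0
        rows.append({
            "stimulus": idx,
            "energy_orig": e_orig, "energy_ei": e_ei,
            "rel_energy_error": rel,
            "l0_orig": orig.final_active_fraction,
            "l0_ei": approx.final_active_fraction,
            "rel_l2_orig": orig.final_rel_l2_error,
            "rel_l2_ei": approx.final_rel_l2_error,
        })
    table = pd.DataFrame(rows)
    mean = float(table["rel_energy_error"].mean())
    degenerate = len(table) < 2
    sd = 0.0 if degenerate else float(table["rel_energy_error"].std(ddof=1))
    return EquivalenceReport(per_stimulus=table, mean_rel_energy_error=mean,
                             sd_rel_energy_error=sd, mode=mode,
                             degenerate_sd=degenerate)
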