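"""Closed-form two-state unfolding thermodynamics for RNA hairpins.

The model: a hairpin exchanges between a folded (F) and an unfolded (U)
state.  Near the melting temperature ``T_m`` the standard free energy of
unfolding is linearized as

    dG_u(T) = g1 * (T - T_m)

where ``g1`` (kJ/mol/K) is the first-order cooperativity parameter, the
slope of dG_u versus temperature at T_m.  For a hairpin that unfolds on
heating g1 < 0, so dG_u is positive below T_m (folded favored) and zero
at T_m.  The unfolding equilibrium constant and populations follow as

    K_u = [U]/[F] = exp(-dG_u / (R T)),   f_u = K_u / (1 + K_u).

All free energies are carried in kJ/mol; the gas constant is kept in
J/mol/K and the conversion is explicit.  The physiological reference
temperature is 310 K ("37 degC"), used by :func:`delta_g_37`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Gas constant, J mol^-1 K^-1.
R = 8.314

#: Physiological reference temperature, K (310 exactly, not 310.15).
T_REF = 310.0


@dataclass(frozen=True)
class MeltingParameters:
    """Two-state melting parameters of one RNA in one environment.

    Parameters
    ----------
    tm : float
        Melting temperature, K.  Folded and unfolded populations are
        equal at ``tm``.
    g1 : float
        First-order cooperativity, kJ/mol/K: slope of dG_u versus T at
        ``tm``.  Negative for heat-induced unfolding.
    sigma_tm, sigma_g1 : float
        Standard deviations of ``tm`` (K) and ``g1`` (kJ/mol/K).
    cov_tm_g1 : float
        Covariance of (tm, g1), kJ/mol; default 0.
    """

    tm: float
    g1: float
    sigma_tm: float = 0.0
    sigma_g1: float = 0.0
    cov_tm_g1: float = 0.0

    def __post_init__(self) -> None:
        if not self.tm > 0:
            raise ValueError(f"tm must be positive, got {self.tm}")
        if self.sigma_tm < 0 or self.sigma_g1 < 0:
            raise ValueError("parameter uncertainties must be >= 0")


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    return T


def free_energy_at(params: MeltingParameters, T):
    """Standard free energy of unfolding dG_u(T) = g1*(T - T_m), kJ/mol.

    Zero at T = T_m by construction; accepts scalar or array T (K).
    """
    T = _check_temperature(T)
    out = params.g1 * (T - params.tm)
    return float(out) if out.ndim == 0 else out


def delta_g_37(params: MeltingParameters) -> float:
    """dG_u at the 310 K reference: (310 - T_m) * g1, kJ/mol."""
    return float(free_energy_at(params, T_REF))


def equilibrium_constant(dg_u, T):
    """Unfolding equilibrium constant K_u = exp(-dG_u/(R T)).

    ``dg_u`` in kJ/mol, ``T`` in K.  K_u > 1 means the unfolded state is
    favored; strictly decreasing in dg_u at fixed T.
    """
    T = _check_temperature(T)
    arg = -np.asarray(dg_u, dtype=float) * 1e3 / (R * T)
    out = np.exp(np.clip(arg, -745.0, 709.0))   # saturate instead of overflow
    return float(out) if out.ndim == 0 else out


def unfolded_fraction(dg_u, T):
    """Equilibrium unfolded population f_u = K_u/(1+K_u) in [0, 1].

    Evaluated in logistic form, overflow-free for any |dG|.
    """
    from scipy.special import expit

    T = _check_temperature(T)
    out = expit(-np.asarray(dg_u, dtype=float) * 1e3 / (R * T))
    return float(out) if out.ndim == 0 else out


def folded_fraction(dg_u, T):
    """Equilibrium folded population 1 - f_u."""
    out = 1.0 - np.asarray(unfolded_fraction(dg_u, T))
    return float(out) if out.ndim == 0 else out
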