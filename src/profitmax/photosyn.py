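"""Farquhar C3 photosynthesis, CO2 diffusion and leaf water exchange.

Supplies the stomatal optimiser with A(Ci) over a discretised Ci grid,
the leaf transpiration rate for a given stomatal conductance, and an
optional iterative leaf energy balance. Default leaf-temperature mode is
isothermal (T_leaf = T_air); the iterative mode closes the leaf energy
balance against a finite boundary-layer heat conductance.

Net assimilation is the minimum of the Rubisco-limited and
RuBP-regeneration-limited rates less day respiration:

    Ac = Vcmax (Ci - Gamma*) / (Ci + Km),   Km = Kc (1 + O/Ko)
    Aj = (J/4) (Ci - Gamma*) / (Ci + 2 Gamma*)
    A  = min(Ac, Aj) - Rd

with J the root of the non-rectangular hyperbola
theta J^2 - (alpha Q + Jmax) J + alpha Q Jmax = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import constants as k

__all__ = [
    "LeafEnvironment",
    "PhotosynParams",
    "make_params",
    "temperature_adjusted_params",
    "net_assimilation",
    "ci_grid",
    "leaf_transpiration",
    "leaf_energy_balance",
    "saturation_vapour_pressure",
    "vpd_from_vapour_pressure",
]


@dataclass(frozen=True)
class LeafEnvironment:
    """Environmental drivers at the leaf for one timestep.

    T_air degC; PAR_leaf = absorbed PAR per unit leaf area, umol m-2 s-1;
    Cs = leaf-surface CO2, umol mol-1; VPD_leaf kPa; P_atm kPa; wind m s-1.
    """

    T_air: float
    PAR_leaf: float
    Cs: float
    VPD_leaf: float
    P_atm: float = k.P_ATM_DEFAULT
    wind: float = 2.0

    def __post_init__(self) -> None:
        if self.Cs <= 0 or self.VPD_leaf < 0 or self.P_atm <= 0:
            raise ValueError("require Cs > 0, VPD_leaf >= 0, P_atm > 0")


@dataclass(frozen=True)
class PhotosynParams:
    """Farquhar parameter set at a given leaf temperature.

    Units: Vcmax, Jmax, Rd, gamma_star, Kc in umol (mol-1 / m-2 s-1);
    Ko in mmol mol-1.
    """

    Vcmax: float
    Jmax: float
    Rd: float
    gamma_star: float
    Kc: float
    Ko: float

    @property
    def Km(self) -> float:
        """Effective Michaelis-Menten constant, umol mol-1."""
        return self.Kc * (1.0 + k.O2_PARTIAL / self.Ko)


def make_params(Vcmax25: float) -> PhotosynParams:
    """Base (25 degC) parameter set from a species' Vcmax25.

    Jmax25 = 1.67 Vcmax25 and Rd25 = 0.015 Vcmax25 by the frozen defaults.
    """
    return PhotosynParams(
        Vcmax=Vcmax25,
        Jmax=k.JMAX25_OVER_VCMAX25 * Vcmax25,
        Rd=k.RD25_FRAC_VCMAX * Vcmax25,
        gamma_star=k.GAMMA_STAR_25,
        Kc=k.KC25,
        Ko=k.KO25,
    )


def _arrhenius(value25: float, ha: float, tk: float) -> float:
    return value25 * np.exp(ha * (tk - k.T_REF) / (k.T_REF * k.R_GAS * tk))


def _peaked_arrhenius(value25: float, ha: float, hd: float, ds: float, tk: float) -> float:
    num = 1.0 + np.exp((k.T_REF * ds - hd) / (k.T_REF * k.R_GAS))
    den = 1.0 + np.exp((tk * ds - hd) / (tk * k.R_GAS))
    return _arrhenius(value25, ha, tk) * num / den


def temperature_adjusted_params(base: PhotosynParams, T_leaf: float) -> PhotosynParams:
    """Scale a 25 degC parameter set to ``T_leaf`` (degC).

    Kc, Ko, Gamma* and Rd follow Arrhenius responses; Vcmax and Jmax a
    peaked Arrhenius. At 25 degC this is the identity.
    """
    tk = T_leaf + 273.15
    return PhotosynParams(
        Vcmax=_peaked_arrhenius(base.Vcmax, k.HA_VCMAX, k.HD_VCMAX, k.DS_VCMAX, tk),
        Jmax=_peaked_arrhenius(base.Jmax, k.HA_JMAX, k.HD_JMAX, k.DS_JMAX, tk),
        Rd=_arrhenius(base.Rd, k.HA_RD, tk),
        gamma_star=_arrhenius(base.gamma_star, k.HA_GAMMA_STAR, tk),
        Kc=_arrhenius(base.Kc, k.HA_KC, tk),
        Ko=_arrhenius(base.Ko, k.HA_KO, tk),
    )


def electron_transport(par_leaf: float, jmax: float) -> float:
    """Potential electron transport J from absorbed PAR (umol m-2 s-1)."""
    q = k.J_QUANTUM_YIELD * par_leaf
    theta = k.J_CURVATURE
    if q <= 0.0 or jmax <= 0.0:
        return 0.0
    disc = (q + jmax) ** 2 - 4.0 * theta * q * jmax
    return (q + jmax - np.sqrt(disc)) / (2.0 * theta)


def net_assimilation(Ci, env: LeafEnvironment, params: PhotosynParams):
    """Net CO2 assimilation A(Ci), umol m-2 s-1; scalar or vectorised in Ci.

    Raises on Ci below the compensation point Gamma*.
    """
    Ci = np.asarray(Ci, dtype=float)
    if np.any(Ci < params.gamma_star - 1e-9):
        raise ValueError("Ci below the CO2 compensation point Gamma*")
    ac = params.Vcmax * (Ci - params.gamma_star) / (Ci + params.Km)
    j = electron_transport(env.PAR_leaf, params.Jmax)
    aj = (j / 4.0) * (Ci - params.gamma_star) / (Ci + 2.0 * params.gamma_star)
    a = np.minimum(ac, aj) - params.Rd
    return a if a.ndim else float(a)


def ci_grid(gamma_star: float, Cs: float, n: int = 1000) -> np.ndarray:
    """``n`` uniformly spaced Ci candidates spanning [Gamma*, Cs] inclusive."""
    if Cs <= gamma_star:
        raise ValueError(f"Cs ({Cs}) must exceed Gamma* ({gamma_star})")
    if n < 2:
        raise ValueError("need at least 2 grid points")
    return np.linspace(gamma_star, Cs, n)


def leaf_transpiration(g_sw, env: LeafEnvironment):
    """Leaf transpiration E_leaf = 1000 g_sw VPD / P_atm, mmol m-2 s-1."""
    g_sw = np.asarray(g_sw, dtype=float)
    e = 1000.0 * g_sw * env.VPD_leaf / env.P_atm
    return e if e.ndim else float(e)


def saturation_vapour_pressure(T: float):
    """Saturation vapour pressure over water (Magnus), kPa, T in degC."""
    T = np.asarray(T, dtype=float)
    es = 0.6108 * np.exp(17.27 * T / (T + 237.3))
    return es if es.ndim else float(es)


def vpd_from_vapour_pressure(T_air, e_air):
    """Leaf-to-air vapour pressure deficit (kPa), floored at zero."""
    vpd = np.maximum(saturation_vapour_pressure(T_air) - np.asarray(e_air, float), 0.0)
    return vpd if vpd.ndim else float(vpd)


def leaf_energy_balance(
    env: LeafEnvironment,
    g_sw: float,
    net_radiation: float,
    mode: str = "isothermal",
    g_bh: float = 1.0,
    max_iter: int = 5,
    tol: float = 0.01,
) -> float:
    """Leaf temperature (degC) closing Rn = H + LE.

    ``mode='isothermal'`` returns T_air. In ``'iterative'`` mode the
    sensible flux is H = 2 cp g_bh (T_leaf - T_air) (two-sided exchange,
    ``g_bh`` in mol m-2 s-1) and the latent flux uses the leaf-to-air VPD
    evaluated at the current T_leaf iterate. Iteration is capped at
    ``max_iter``; non-convergence warns and returns the last iterate.
    """
    if mode == "isothermal":
        return env.T_air
    if mode != "iterative":
        raise ValueError(f"unknown leaf temperature mode {mode!r}")

    e_air = saturation_vapour_pressure(env.T_air) - env.VPD_leaf
    t_leaf = env.T_air
    for _ in range(max_iter):
        vpd = max(saturation_vapour_pressure(t_leaf) - e_air, 0.0)
        le = k.LAMBDA_VAP_MOLAR * g_sw * vpd / env.P_atm  # mol -> W m-2
        t_new = env.T_air + (net_radiation - le) / (2.0 * k.CP_AIR_MOLAR * g_bh)
        if abs(t_new - t_leaf) < tol:
            return t_new
        t_leaf = t_new
    warnings.warn("leaf energy balance did not converge; returning last iterate")
    return t_leaf
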