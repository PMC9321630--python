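"""Instantaneous profit-maximisation stomatal optimisation.

Each timestep the scheme evaluates every candidate intercellular CO2
concentration Ci on a uniform grid between the compensation point Gamma*
and the leaf-surface CO2 Cs. For each candidate: A via Farquhar,
g_sc = A / (Cs - Ci) by Fick's law, g_sw = 1.57 g_sc, the transpiration
rate E_leaf, and the leaf water potential from the steady-state supply
relation

    E_leaf = k(Psi_leaf) (Psi_soil,w - Psi_leaf),

taking the least-negative root (the ascending, physiologically stable
branch of the supply curve). Candidates whose demand exceeds the critical
supply E_crit, or whose conductance would fall below k_crit, are
infeasible. The chosen operating point maximises

    profit = CG - HC,   CG = A / A_max,
    HC = (k_imax - k(Psi_leaf)) / (k_imax - k_crit),

with k_imax = k(Psi_soil,w) and k_crit = 0.05 k_max by default. When no
candidate yields positive profit (night, or soil beyond the critical
potential) stomata close: g = 0, E = 0, Psi_leaf = Psi_soil,w, A = -Rd.

Cavitation carries no memory: k depends only on the current potential
(full recovery on rewetting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import constants as const
from .photosyn import (
    LeafEnvironment,
    PhotosynParams,
    ci_grid,
    leaf_transpiration,
    make_params,
    net_assimilation,
    temperature_adjusted_params,
)
from .traits import SpeciesTraits, VulnerabilityCurve, conductance, plc

__all__ = [
    "OptimiserSettings",
    "GasExchangeSolution",
    "hydraulic_cost",
    "solve_leaf_potential",
    "critical_transpiration",
    "optimise_gas_exchange",
    "psi_crit",
    "BeyondCritical",
]


class BeyondCritical(Exception):
    """Soil potential already past the critical conductance threshold."""


@dataclass(frozen=True)
class OptimiserSettings:
    """Tunable knobs of the optimiser.

    ``n_ci`` grid size; ``kcrit_fraction`` defines hydraulic failure as a
    fraction of k_max; ``root_tol`` (MPa) for the supply-curve root;
    ``gate_ecrit``/``gate_kcrit`` toggle the two feasibility gates;
    ``leaf_temperature`` is 'isothermal' or 'iterative'.
    """

    n_ci: int = 1000
    kcrit_fraction: float = 0.05
    root_tol: float = 1e-5
    gate_ecrit: bool = True
    gate_kcrit: bool = True
    leaf_temperature: str = "isothermal"

    def __post_init__(self) -> None:
        if not 0.0 < self.kcrit_fraction < 1.0:
            raise ValueError("kcrit_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class GasExchangeSolution:
    """One timestep's optimiser output (leaf-area basis)."""

    Ci: float            # umol mol-1
    A: float             # umol m-2 s-1
    g_sc: float          # mol m-2 s-1
    g_sw: float          # mol m-2 s-1
    E_leaf: float        # mmol m-2 s-1
    psi_leaf: float      # MPa
    CG: float
    HC: float
    profit: float
    PLC: float           # %
    k_at_leaf: float     # mmol m-2 s-1 MPa-1
    closed: bool


def psi_crit(curve: VulnerabilityCurve, kcrit_fraction: float = const.KCRIT_FRACTION) -> float:
    """Potential (MPa) at which conductance falls to kcrit_fraction * k_max."""
    return -curve.b * (-np.log(kcrit_fraction)) ** (1.0 / curve.c)


def hydraulic_cost(
    psi_leaf, psi_soil_w: float, curve: VulnerabilityCurve, kcrit: float
):
    """Normalised hydraulic cost in [0, 1].

    HC = (k_imax - k(Psi_leaf)) / (k_imax - kcrit), k_imax = k(Psi_soil,w).
    Raises :class:`BeyondCritical` when the soil itself is past kcrit.
    """
    k_imax = conductance(psi_soil_w, curve)
    if k_imax <= kcrit:
        raise BeyondCritical(
            f"k(psi_soil) = {k_imax:.4g} <= kcrit = {kcrit:.4g}; stomata must close"
        )
    hc = (k_imax - conductance(psi_leaf, curve)) / (k_imax - kcrit)
    out = np.clip(hc, 0.0, 1.0)
    return out if np.ndim(out) else float(out)


def _psi_at_supply_max(psi_soil_w: float, curve: VulnerabilityCurve) -> float:
    """Potential maximising the supply function k(Psi)(Psi_soil - Psi)."""
    # stationarity: 1 - (c/b)(x/b)^(c-1) (x - x_s) = 0 with x = -Psi
    xs = -psi_soil_w
    b, c = curve.b, curve.c

    def dfd(x: float) -> float:
        return 1.0 - (c / b) * (x / b) ** (c - 1.0) * (x - xs)

    hi = xs + b * (-np.log(1e-12)) ** (1.0 / c) + b  # far past any root
    lo = xs + 1e-12
    if dfd(lo) <= 0:
        return psi_soil_w
    return -optimize.brentq(dfd, lo, hi, xtol=1e-12)


def _supply(psi, psi_soil_w: float, curve: VulnerabilityCurve):
    return conductance(psi, curve) * (psi_soil_w - np.asarray(psi))


def critical_transpiration(
    psi_soil_w: float,
    curve: VulnerabilityCurve,
    kcrit: float,
    gate_kcrit: bool = True,
    psi_supply_max: float | None = None,
) -> float:
    """Maximum steady-state supply E_crit (mmol m-2 s-1).

    The supply function is maximised over the allowed potentials: down to
    Psi_crit (where k = kcrit) when the conductance gate is active,
    otherwise down to the unconstrained supply maximum. Zero when the soil
    is at or beyond critical.
    """
    if conductance(psi_soil_w, curve) <= kcrit:
        return 0.0
    psi_floor = (
        _psi_at_supply_max(psi_soil_w, curve)
        if psi_supply_max is None
        else psi_supply_max
    )
    if gate_kcrit:
        pc = psi_crit(curve, kcrit / curve.k_max)
        psi_floor = max(psi_floor, pc)
    return float(max(_supply(psi_floor, psi_soil_w, curve), 0.0))


def solve_leaf_potential(
    E_leaf,
    psi_soil_w: float,
    curve: VulnerabilityCurve,
    n_bisect: int = 45,
    psi_supply_max: float | None = None,
):
    """Least-negative root of E = k(Psi)(Psi_soil,w - Psi).

    Vectorised bisection on the ascending branch [Psi_supply_max,
    Psi_soil,w], on which supply decreases monotonically towards zero at
    Psi_soil,w. Entries with E above the branch maximum return NaN
    (infeasible). Scalar input returns a scalar (NaN = infeasible).
    ``psi_supply_max`` may be supplied by the caller to avoid recomputing
    the supply-curve maximum.
    """
    E = np.asarray(E_leaf, dtype=float)
    scalar = E.ndim == 0
    E = np.atleast_1d(E)
    if np.any(E < 0):
        raise ValueError("E_leaf must be non-negative")

    psi_lo = (
        _psi_at_supply_max(psi_soil_w, curve)
        if psi_supply_max is None
        else psi_supply_max
    )
    e_max = _supply(psi_lo, psi_soil_w, curve)
    out = np.full(E.shape, np.nan)
    out[E == 0.0] = psi_soil_w
    todo = (E > 0.0) & (E <= e_max)

    if todo.any():
        b, c, kmax = curve.b, curve.c, curve.k_max
        e_t = E[todo]
        lo = np.full(e_t.shape, psi_lo)
        hi = np.full(e_t.shape, psi_soil_w)
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            supply = kmax * np.exp(-((-mid / b) ** c)) * (psi_soil_w - mid)
            high_supply = supply > e_t
            lo = np.where(high_supply, mid, lo)
            hi = np.where(high_supply, hi, mid)
        out[todo] = 0.5 * (lo + hi)
    return float(out[0]) if scalar else out


def _closed_solution(
    psi_soil_w: float, curve: VulnerabilityCurve, rd: float
) -> GasExchangeSolution:
    return GasExchangeSolution(
        Ci=np.nan,
        A=-rd,
        g_sc=0.0,
        g_sw=0.0,
        E_leaf=0.0,
        psi_leaf=psi_soil_w,
        CG=0.0,
        HC=0.0,
        profit=0.0,
        PLC=plc(psi_soil_w, curve),
        k_at_leaf=conductance(psi_soil_w, curve),
        closed=True,
    )


def optimise_gas_exchange(
    env: LeafEnvironment,
    psi_soil_w: float,
    traits: SpeciesTraits,
    settings: OptimiserSettings = OptimiserSettings(),
    params: PhotosynParams | None = None,
) -> GasExchangeSolution:
    """Profit-maximising gas exchange for one timestep.

    ``params`` optionally supplies a pre-built 25 degC Farquhar set
    (otherwise built from traits.Vcmax25); it is temperature-adjusted to
    the leaf temperature internally. Pathological inputs (night, dry soil,
    no feasible candidate) resolve to the closed solution.
    """
    curve = traits.curve
    kcrit = settings.kcrit_fraction * curve.k_max
    base = params if params is not None else make_params(traits.Vcmax25)
    p = temperature_adjusted_params(base, env.T_air)

    if conductance(psi_soil_w, curve) <= kcrit:
        return _closed_solution(psi_soil_w, curve, p.Rd)
    if env.Cs <= p.gamma_star:
        return _closed_solution(psi_soil_w, curve, p.Rd)

    ci = ci_grid(p.gamma_star, env.Cs, settings.n_ci)
    a = net_assimilation(ci, env, p)
    if a.max() <= 0.0:  # night or degenerate light: no candidate can profit
        return _closed_solution(psi_soil_w, curve, p.Rd)

    # Fick's law; the Ci = Cs endpoint would need infinite conductance
    with np.errstate(divide="ignore", invalid="ignore"):
        g_sc = np.where(a > 0.0, a / (env.Cs - ci), 0.0)
    g_sc[~np.isfinite(g_sc)] = np.inf
    g_sw = const.GSW_OVER_GSC * g_sc
    with np.errstate(invalid="ignore"):
        e_leaf = leaf_transpiration(g_sw, env)

    psi_supply_max = _psi_at_supply_max(psi_soil_w, curve)
    e_crit = critical_transpiration(
        psi_soil_w, curve, kcrit, settings.gate_kcrit, psi_supply_max
    )
    feasible = np.isfinite(e_leaf)
    if settings.gate_ecrit:
        feasible &= e_leaf <= e_crit

    psi_leaf = np.full(ci.shape, psi_soil_w)
    if feasible.any():
        psi_leaf[feasible] = solve_leaf_potential(
            e_leaf[feasible], psi_soil_w, curve, psi_supply_max=psi_supply_max
        )
    feasible &= ~np.isnan(psi_leaf)  # demand beyond the supply maximum
    psi_leaf = np.where(np.isnan(psi_leaf), psi_soil_w, psi_leaf)
    k_leaf = conductance(np.minimum(psi_leaf, 0.0), curve)
    if settings.gate_kcrit:
        feasible &= k_leaf >= kcrit
    if not feasible.any():
        return _closed_solution(psi_soil_w, curve, p.Rd)

    a_max = a[feasible].max()
    if a_max <= 0.0:
        return _closed_solution(psi_soil_w, curve, p.Rd)

    cg = np.clip(np.maximum(a, 0.0) / a_max, 0.0, 1.0)
    hc = hydraulic_cost(psi_leaf, psi_soil_w, curve, kcrit)
    profit = np.where(feasible, cg - hc, -np.inf)

    best = profit.max()
    if best <= 0.0:
        return _closed_solution(psi_soil_w, curve, p.Rd)
    # tie-break equal profit on the hydraulically safer (less negative) Psi
    ties = np.flatnonzero(profit >= best)
    i = ties[np.argmax(psi_leaf[ties])]

    return GasExchangeSolution(
        Ci=float(ci[i]),
        A=float(a[i]),
        g_sc=float(g_sc[i]),
        g_sw=float(g_sw[i]),
        E_leaf=float(e_leaf[i]),
        psi_leaf=float(psi_leaf[i]),
        CG=float(cg[i]),
        HC=float(hc[i]),
        profit=float(profit[i]),
        PLC=float(plc(psi_leaf[i], curve)),
        k_at_leaf=float(k_leaf[i]),
        closed=False,
    )
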