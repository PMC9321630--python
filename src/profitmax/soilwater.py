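"""Multilayer soil water store with Campbell retention.

Retention and conductivity follow Campbell's power-law forms,

    Psi_s(theta) = psi_e (theta/theta_sat)^(-b_soil)
    K(theta)     = K_sat (theta/theta_sat)^(2 b_soil + 3),

and the root-zone water potential seen by the plant is the average of the
per-layer potentials weighted by root fraction times soil conductivity, so
uptake weight shifts to deeper, wetter layers as the surface dries.

Vertical water movement is a tipping-bucket cascade: infiltration fills
layers from the top, saturation excess runs off, drainage between layers is
conductivity-limited release of water above field capacity, and the bottom
layer drains freely. Mass balance is exact by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "WaterBalanceFluxes",
    "matric_potential",
    "hydraulic_conductivity",
    "weighted_soil_potential",
    "update_water_balance",
    "default_profile",
]

# default 6-layer discretisation totalling 4.6 m
DEFAULT_THICKNESS = (0.1, 0.25, 0.65, 1.0, 1.3, 1.3)

# e-folding depth of the exponential root distribution, m
ROOT_EFOLD_DEPTH = 0.5

# matric potential defining field capacity, MPa
PSI_FIELD_CAPACITY = -0.033


@dataclass(frozen=True)
class SoilLayer:
    """One soil layer: geometry, Campbell parameters and state.

    thickness m; theta, theta_sat m3 m-3; psi_e MPa (negative, small
    magnitude); b_soil dimensionless; K_sat mm h-1; root_fraction in [0, 1].
    """

    thickness: float
    theta: float
    theta_sat: float = 0.45
    psi_e: float = -0.0015
    b_soil: float = 5.0
    K_sat: float = 20.0
    root_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= self.theta_sat + 1e-12):
            raise ValueError(f"theta {self.theta} outside [0, theta_sat={self.theta_sat}]")
        if self.b_soil <= 0 or self.psi_e >= 0 or self.thickness <= 0:
            raise ValueError("require b_soil > 0, psi_e < 0, thickness > 0")

    @property
    def storage_mm(self) -> float:
        return self.theta * self.thickness * 1000.0

    @property
    def theta_fc(self) -> float:
        """Field capacity water content (Campbell inverse at -0.033 MPa)."""
        return self.theta_sat * (self.psi_e / PSI_FIELD_CAPACITY) ** (1.0 / self.b_soil)


@dataclass(frozen=True)
class SoilProfile:
    """Ordered stack of layers, surface first."""

    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        total_roots = sum(l.root_fraction for l in self.layers)
        if abs(total_roots - 1.0) > 1e-6:
            raise ValueError(f"root fractions must sum to 1, got {total_roots}")

    @property
    def depth(self) -> float:
        return sum(l.thickness for l in self.layers)

    @property
    def total_storage_mm(self) -> float:
        return sum(l.storage_mm for l in self.layers)

    def theta_array(self) -> np.ndarray:
        return np.array([l.theta for l in self.layers])

    def with_theta(self, theta: np.ndarray) -> "SoilProfile":
        return SoilProfile(
            tuple(replace(l, theta=float(t)) for l, t in zip(self.layers, theta))
        )


@dataclass(frozen=True)
class WaterBalanceFluxes:
    """Per-step flux bookkeeping, all in mm."""

    infiltration: float
    runoff: float
    drainage: float
    extraction: np.ndarray  # per layer
    shortfall: float

    @property
    def total_extraction(self) -> float:
        return float(np.sum(self.extraction))


def matric_potential(theta: float, layer: SoilLayer) -> float:
    """Campbell matric potential Psi_s (MPa, negative) at water content theta."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    rel = min(theta / layer.theta_sat, 1.0)
    return layer.psi_e * rel ** (-layer.b_soil)


def hydraulic_conductivity(theta: float, layer: SoilLayer) -> float:
    """Campbell unsaturated conductivity (units of K_sat, mm h-1)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    rel = min(theta / layer.theta_sat, 1.0)
    return layer.K_sat * rel ** (2.0 * layer.b_soil + 3.0)


def weighted_soil_potential(profile: SoilProfile) -> tuple[float, np.ndarray]:
    """Root-zone water potential and the per-layer uptake weights.

    Weights are proportional to root_fraction * K(theta), normalised to
    sum to one (low layer conductance = high soil-to-root resistance =
    low weight). A fully dry profile returns the deepest layer's
    potential with a warning.
    """
    raw = np.array(
        [
            l.root_fraction * (hydraulic_conductivity(l.theta, l) if l.theta > 0 else 0.0)
            for l in profile.layers
        ]
    )
    psi = np.array(
        [matric_potential(max(l.theta, 1e-9), l) for l in profile.layers]
    )
    total = raw.sum()
    if total <= 0.0:
        warnings.warn("all uptake weights zero (dry profile); using deepest layer")
        weights = np.zeros(len(profile.layers))
        weights[-1] = 1.0
        return float(psi[-1]), weights
    weights = raw / total
    return float(np.dot(weights, psi)), weights


def update_water_balance(
    profile: SoilProfile,
    infiltration: float,
    canopy_extraction: float,
    dt: float = 10800.0,
) -> tuple[SoilProfile, WaterBalanceFluxes]:
    """Advance the store one step; returns (new profile, fluxes).

    ``infiltration`` and ``canopy_extraction`` in mm per step; ``dt`` in
    seconds scales the conductivity-limited drainage (K_sat is mm h-1).
    Extraction is distributed by the current uptake weights and clipped to
    the water available in each layer; the unmet remainder is reported as
    ``shortfall``. Saturation excess of infiltration leaves as runoff and
    the bottom layer drains freely.
    """
    if infiltration < 0 or canopy_extraction < 0:
        raise ValueError("fluxes must be non-negative")
    layers = list(profile.layers)
    storage = np.array([l.storage_mm for l in layers])
    capacity = np.array([l.theta_sat * l.thickness * 1000.0 for l in layers])

    # infiltration: fill from the top, remainder is runoff
    remaining = infiltration
    for i in range(len(layers)):
        room = capacity[i] - storage[i]
        added = min(remaining, room)
        storage[i] += added
        remaining -= added
        if remaining <= 0:
            break
    runoff = remaining

    # extraction by uptake weights, clipped to available water per layer
    _, weights = weighted_soil_potential(profile)
    demand = weights * canopy_extraction
    extraction = np.minimum(demand, storage)
    storage -= extraction
    shortfall = canopy_extraction - float(extraction.sum())

    # conductivity-limited cascade of water above field capacity
    hours = dt / 3600.0
    drainage = 0.0
    for i, layer in enumerate(layers):
        theta_i = storage[i] / (layer.thickness * 1000.0)
        excess = max(storage[i] - layer.theta_fc * layer.thickness * 1000.0, 0.0)
        if excess <= 0 or theta_i <= 0:
            continue
        flux = min(hydraulic_conductivity(theta_i, layer) * hours, excess)
        if i + 1 < len(layers):
            accepted = min(flux, capacity[i + 1] - storage[i + 1])
            storage[i] -= accepted
            storage[i + 1] += accepted
        else:
            storage[i] -= flux
            drainage += flux

    theta_new = storage / (np.array([l.thickness for l in layers]) * 1000.0)
    new_profile = profile.with_theta(theta_new)
    return new_profile, WaterBalanceFluxes(
        infiltration=infiltration,
        runoff=runoff,
        drainage=drainage,
        extraction=extraction,
        shortfall=shortfall,
    )


def default_profile(
    theta_frac: float = 0.7,
    thicknesses: tuple[float, ...] = DEFAULT_THICKNESS,
    theta_sat: float = 0.45,
    psi_e: float = -0.0015,
    b_soil: float = 5.0,
    K_sat: float = 20.0,
    root_efold: float = ROOT_EFOLD_DEPTH,
) -> SoilProfile:
    """Vertically uniform 6-layer profile (4.6 m) at a fraction of saturation.

    Root fractions decay exponentially with depth (e-folding ``root_efold``
    m), normalised over the profile.
    """
    tops = np.concatenate([[0.0], np.cumsum(thicknesses)[:-1]])
    bottoms = np.cumsum(thicknesses)
    # integral of exp(-z/L) over each layer
    raw = np.exp(-tops / root_efold) - np.exp(-bottoms / root_efold)
    roots = raw / raw.sum()
    layers = tuple(
        SoilLayer(
            thickness=float(th),
            theta=theta_frac * theta_sat,
            theta_sat=theta_sat,
            psi_e=psi_e,
            b_soil=b_soil,
            K_sat=K_sat,
            root_fraction=float(r),
        )
        for th, r in zip(thicknesses, roots)
    )
    return SoilProfile(layers)
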