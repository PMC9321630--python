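"""Species trait registry and xylem vulnerability-curve mathematics.

The soil-to-canopy hydraulic pathway is described by a cumulative Weibull
vulnerability curve,

    k(Psi) = k_max * exp(-(|Psi| / b)^c),

with sensitivity ``b`` (MPa), shape ``c`` (dimensionless) and maximum
conductance ``k_max`` (mmol m-2 leaf s-1 MPa-1). Percent loss of
conductivity is PLC = 100 * (1 - k / k_max), and the potential inducing a
fractional loss x is Psi_x = -b * (-ln(1 - x))^(1/c).

Water potentials are negative MPa throughout; the Weibull operates on |Psi|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import KMAX_DEFAULT, VCMAX25_DEFAULT

__all__ = [
    "VulnerabilityCurve",
    "SpeciesTraits",
    "conductance",
    "plc",
    "pxx",
    "fit_bc_from_pxx",
    "load_species_registry",
]


@dataclass(frozen=True)
class VulnerabilityCurve:
    """Weibull decline of hydraulic conductance with water potential.

    Parameters
    ----------
    b : float
        Sensitivity (water-potential scale), MPa, positive magnitude.
    c : float
        Dimensionless shape.
    k_max : float
        Maximum soil-to-canopy conductance, mmol m-2 leaf s-1 MPa-1.
    """

    b: float
    c: float
    k_max: float = KMAX_DEFAULT

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.c > 0 and self.k_max > 0):
            raise ValueError(
                f"b, c, k_max must be positive, got {self.b}, {self.c}, {self.k_max}"
            )

    def conductance(self, psi):
        return conductance(psi, self)

    def plc(self, psi):
        return plc(psi, self)

    def pxx(self, x: float) -> float:
        return pxx(self, x)


@dataclass(frozen=True)
class SpeciesTraits:
    """Per-species hydraulic and photosynthetic parameters.

    P12/P50/P88 are the reported potentials (negative MPa) at 12/50/88%
    loss of conductivity; they are metadata — the curve's (b, c) are the
    authoritative parameters. ``Vcmax25`` is the maximum carboxylation
    rate at 25 degC (umol m-2 s-1).
    """

    species_name: str
    curve: VulnerabilityCurve
    P12: float
    P50: float
    P88: float
    Vcmax25: float = VCMAX25_DEFAULT
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (self.P12 >= self.P50 >= self.P88):
            raise ValueError(
                f"{self.species_name}: require P12 >= P50 >= P88 "
                f"(toward more negative), got {self.P12}, {self.P50}, {self.P88}"
            )
        if not all(p < 0 for p in (self.P12, self.P50, self.P88)):
            raise ValueError(f"{self.species_name}: P12/P50/P88 must be negative")
        if not self.Vcmax25 > 0:
            raise ValueError(f"{self.species_name}: Vcmax25 must be positive")


def conductance(psi, curve: VulnerabilityCurve):
    """Hydraulic conductance k(psi) = k_max * exp(-(|psi|/b)^c).

    ``psi`` is a water potential in MPa, <= 0; scalar or array.
    Returns conductance in the units of ``curve.k_max``.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > 0):
        raise ValueError("water potential must be <= 0 MPa")
    out = curve.k_max * np.exp(-((-psi / curve.b) ** curve.c))
    return out if out.ndim else float(out)


def plc(psi, curve: VulnerabilityCurve):
    """Percent loss of conductivity, 100 * (1 - k(psi)/k_max), in [0, 100)."""
    k = conductance(psi, curve)
    out = 100.0 * (1.0 - np.asarray(k) / curve.k_max)
    return out if out.ndim else float(out)


def pxx(curve: VulnerabilityCurve, x: float) -> float:
    """Water potential (negative MPa) inducing a fractional loss ``x`` in (0, 1)."""
    if not 0.0 < x < 1.0:
        raise ValueError(f"fractional loss must lie in (0, 1), got {x}")
    return -curve.b * (-math.log1p(-x)) ** (1.0 / curve.c)


def fit_bc_from_pxx(p12: float, p50: float) -> tuple[float, float]:
    """Invert (P12, P50) to the Weibull (b, c).

    Uses only the 12% and 50% thresholds (two equations, two unknowns):
    c = ln(ln 2 / -ln 0.88) / ln(|P50|/|P12|), b = |P50| / (ln 2)^(1/c).
    """
    if not (p50 < p12 < 0):
        raise ValueError(f"require p50 < p12 < 0, got p12={p12}, p50={p50}")
    y12 = -math.log(0.88)   # -ln(1 - 0.12)
    y50 = math.log(2.0)     # -ln(1 - 0.50)
    c = math.log(y50 / y12) / math.log(abs(p50) / abs(p12))
    b = abs(p50) / y50 ** (1.0 / c)
    return b, c


_REGISTRY_COLUMNS = {"species", "b_MPa", "c", "P12_MPa", "P50_MPa", "P88_MPa"}


def load_species_registry(source: str | Path | None = None) -> dict[str, SpeciesTraits]:
    """Load a species trait table into a registry of :class:`SpeciesTraits`.

    ``source`` is a CSV with columns
    ``species,b_MPa,c,P12_MPa,P50_MPa,P88_MPa,Vcmax25,kmax,reference``;
    blank ``Vcmax25`` falls back to the cross-species default (86.88) and
    blank ``kmax`` to 1.5. With no argument the packaged 15-species
    eucalypt table is loaded.
    """
    if source is None:
        with resources.as_file(
            resources.files("profitmax.data") / "species_traits.csv"
        ) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)

    missing = _REGISTRY_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species rows: {dups}")

    registry: dict[str, SpeciesTraits] = {}
    for _, row in df.iterrows():
        if row[list(_REGISTRY_COLUMNS)].isna().any():
            raise ValueError(f"malformed row for species {row['species']!r}")
        kmax = row.get("kmax", np.nan)
        kmax = KMAX_DEFAULT if pd.isna(kmax) else float(kmax)
        vcmax = row.get("Vcmax25", np.nan)
        vcmax = VCMAX25_DEFAULT if pd.isna(vcmax) else float(vcmax)
        curve = VulnerabilityCurve(b=float(row["b_MPa"]), c=float(row["c"]), k_max=kmax)
        registry[row["species"]] = SpeciesTraits(
            species_name=row["species"],
            curve=curve,
            P12=float(row["P12_MPa"]),
            P50=float(row["P50_MPa"]),
            P88=float(row["P88_MPa"]),
            Vcmax25=vcmax,
            provenance=str(row.get("reference", "")),
        )
    return registry
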