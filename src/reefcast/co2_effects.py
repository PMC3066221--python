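"""Aragonite saturation state and the calcification multiplier.

Surface-ocean pCO2 is assumed to track atmospheric CO2 on an annual time
scale, so the annual atmospheric mixing ratio (ppm) is used directly as
surface pCO2 (µatm).  Aragonite saturation Ω_a is obtained by solving the
seawater carbonate equilibrium for a water parcel of known total
alkalinity and salinity in contact with that pCO2, on a rectangular
(temperature × pCO2) lookup table with bilinear interpolation between
nodes.

The carbonate-system solve uses standard open-ocean constants:

* CO2 solubility K0 — Weiss (1974);
* carbonic-acid dissociations K1, K2 — Lueker, Dickson & Keeling (2000),
  total pH scale;
* boric acid KB — Dickson (1990); water KW — Millero (1995);
* aragonite solubility product — Mucci (1983);
* calcium and total boron proportional to salinity.

Coral calcification is reduced linearly with the decline of Ω_a below a
reference value: factor = clip(1 − s·max(0, Ω_ref − Ω_t), 0, 1), where
``s`` is the per-Ω-unit sensitivity (0 disables the module, 0.3 is the
central literature value, 0.45 the upper end of the range explored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq

from .errors import ExtrapolationError, ParameterError

__all__ = [
    "CO2Pathway",
    "AragoniteTable",
    "omega_from_pco2",
    "build_aragonite_table",
    "omega_a",
    "calcification_factor",
]


@dataclass(frozen=True)
class CO2Pathway:
    """Annual atmospheric CO2 mixing ratios (ppm), one value per year."""

    years: np.ndarray
    ppm: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        ppm = np.asarray(self.ppm, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "ppm", ppm)
        if len(years) != len(ppm):
            raise ParameterError("years and ppm must have equal length")
        if np.any(ppm <= 0):
            raise ParameterError("CO2 mixing ratios must be > 0")
        if np.any(np.diff(years) != 1):
            raise ParameterError("pathway years must be consecutive")

    def at(self, year: int) -> float:
        """CO2 mixing ratio in a given year; the year must be covered."""
        i = int(year) - int(self.years[0])
        if i < 0 or i >= len(self.ppm):
            raise ParameterError(f"year {year} outside pathway span")
        return float(self.ppm[i])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"year": self.years, "co2_ppm": self.ppm})


# ---------------------------------------------------------------------------
# carbonate equilibrium

def _equilibrium_constants(t_c: float, salinity: float) -> dict[str, float]:
    """Thermodynamic constants at temperature (°C) and salinity, 1 atm."""
    tk = t_c + 273.15
    s = salinity
    # Weiss 1974, mol/kg/atm
    ln_k0 = (
        -60.2409
        + 93.4517 * (100.0 / tk)
        + 23.3585 * np.log(tk / 100.0)
        + s * (0.023517 - 0.023656 * (tk / 100.0) + 0.0047036 * (tk / 100.0) ** 2)
    )
    # Lueker et al. 2000, total scale, mol/kg
    pk1 = 3633.86 / tk - 61.2172 + 9.6777 * np.log(tk) - 0.011555 * s + 0.0001152 * s**2
    pk2 = 471.78 / tk + 25.929 - 3.16967 * np.log(tk) - 0.01781 * s + 0.0001122 * s**2
    # Dickson 1990 (boric acid), total scale
    sqs = np.sqrt(s)
    ln_kb = (
        (-8966.90 - 2890.53 * sqs - 77.942 * s + 1.728 * s * sqs - 0.0996 * s**2) / tk
        + 148.0248 + 137.1942 * sqs + 1.62142 * s
        - (24.4344 + 25.085 * sqs + 0.2474 * s) * np.log(tk)
        + 0.053105 * sqs * tk
    )
    # Millero 1995 (water), total scale approximation
    ln_kw = (
        148.9802 - 13847.26 / tk - 23.6521 * np.log(tk)
        + (118.67 / tk - 5.977 + 1.0495 * np.log(tk)) * sqs
        - 0.01615 * s
    )
    # Mucci 1983, aragonite, mol^2/kg^2
    log_ksp = (
        -171.945 - 0.077993 * tk + 2903.293 / tk + 71.595 * np.log10(tk)
        + (-0.068393 + 0.0017276 * tk + 88.135 / tk) * sqs
        - 0.10018 * s + 0.0059415 * s * sqs
    )
    return {
        "k0": float(np.exp(ln_k0)),
        "k1": float(10.0 ** (-pk1)),
        "k2": float(10.0 ** (-pk2)),
        "kb": float(np.exp(ln_kb)),
        "kw": float(np.exp(ln_kw)),
        "ksp_arag": float(10.0 ** log_ksp),
        # Riley & Tongudai 1967; Uppström 1974 — mol/kg
        "ca": 0.02128 / 40.087 * (s / 1.80655),
        "bt": 0.0004157 * s / 35.0,
    }


def omega_from_pco2(
    t_c: float,
    pco2_uatm: float,
    salinity: float = 35.0,
    alkalinity_umol_kg: float = 2400.0,
) -> float:
    """Aragonite saturation from temperature, pCO2 and total alkalinity.

    With pCO2 fixed, dissolved CO2 is K0·pCO2 and total alkalinity
    TA = HCO3 + 2·CO3 + B(OH)4 + OH − H is solved for [H+] by bracketed
    root finding on pH ∈ [4, 10].
    """
    k = _equilibrium_constants(t_c, salinity)
    co2 = k["k0"] * pco2_uatm * 1e-6  # mol/kg
    ta = alkalinity_umol_kg * 1e-6

    def residual(ph: float) -> float:
        h = 10.0**-ph
        hco3 = k["k1"] * co2 / h
        co3 = k["k1"] * k["k2"] * co2 / h**2
        boh4 = k["bt"] * k["kb"] / (k["kb"] + h)
        oh = k["kw"] / h
        return hco3 + 2 * co3 + boh4 + oh - h - ta

    try:
        ph = brentq(residual, 4.0, 10.0, xtol=1e-12)
    except ValueError as exc:  # pragma: no cover - extreme inputs only
        raise ParameterError(
            f"carbonate solve failed at T={t_c}°C, pCO2={pco2_uatm} µatm: {exc}"
        ) from exc
    h = 10.0**-ph
    co3 = k["k1"] * k["k2"] * co2 / h**2
    return float(k["ca"] * co3 / k["ksp_arag"])


@dataclass(frozen=True)
class AragoniteTable:
    """Ω_a on a rectangular (temperature °C × pCO2 µatm) grid."""

    t_grid: np.ndarray
    pco2_grid: np.ndarray
    omega: np.ndarray  # shape (len(t_grid), len(pco2_grid))
    salinity: float = 35.0
    alkalinity_umol_kg: float = 2400.0

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.t_grid, self.pco2_grid),
            self.omega,
            method="linear",
            bounds_error=True,
        )


def build_aragonite_table(
    t_grid: np.ndarray | None = None,
    pco2_grid: np.ndarray | None = None,
    salinity: float = 35.0,
    alkalinity_umol_kg: float = 2400.0,
) -> AragoniteTable:
    """Tabulate Ω_a over sorted temperature and pCO2 grids.

    Defaults cover subtropical surface conditions and the full emissions
    window: 15–35 °C and 200–1100 µatm.
    """
    if t_grid is None:
        t_grid = np.arange(15.0, 35.5, 1.0)
    if pco2_grid is None:
        pco2_grid = np.arange(200.0, 1101.0, 25.0)
    t_grid = np.asarray(t_grid, dtype=float)
    pco2_grid = np.asarray(pco2_grid, dtype=float)
    if len(t_grid) < 2 or len(pco2_grid) < 2:
        raise ParameterError("grids need at least 2 points each")
    if np.any(np.diff(t_grid) <= 0) or np.any(np.diff(pco2_grid) <= 0):
        raise ParameterError("grids must be strictly increasing")
    omega = np.empty((len(t_grid), len(pco2_grid)))
    for i, t in enumerate(t_grid):
        for j, p in enumerate(pco2_grid):
            omega[i, j] = omega_from_pco2(t, p, salinity, alkalinity_umol_kg)
    return AragoniteTable(t_grid, pco2_grid, omega, salinity, alkalinity_umol_kg)


def omega_a(table: AragoniteTable, t_c: float, pco2_uatm: float) -> float:
    """Bilinear Ω_a lookup; exact at grid nodes, no extrapolation."""
    try:
        return float(table.interpolator()([[t_c, pco2_uatm]])[0])
    except ValueError:
        raise ExtrapolationError(
            f"({t_c}°C, {pco2_uatm} µatm) outside table hull "
            f"T∈[{table.t_grid[0]}, {table.t_grid[-1]}], "
            f"pCO2∈[{table.pco2_grid[0]}, {table.pco2_grid[-1]}]"
        ) from None


def calcification_factor(s: float, omega_ref: float, omega_t: float) -> float:
    """Linear calcification multiplier for a drop of Ω_a below its reference.

    ``s`` is the fractional growth decrease per unit decrease of Ω_a;
    rising Ω_a never boosts growth (the deficit is floored at zero), and
    the multiplier is clipped to [0, 1].
    """
    if not 0.0 <= s <= 0.45:
        raise ParameterError("omega sensitivity must lie in [0, 0.45]")
    deficit = max(0.0, omega_ref - omega_t)
    return float(np.clip(1.0 - s * deficit, 0.0, 1.0))
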