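"""Annual integration of relative coral cover.

Cover is tracked relative to its start-of-run value (1.0 at the start
year) and updated once per calendar year:

    cover' = cover · (1 + τ·G(T̄)·A(Ω) − m0) · (1 − M_epi(DHM))

where τ is the baseline gross turnover (yr⁻¹), G the cubic relative
growth at the annual-mean temperature, A the Ω_a calcification
multiplier, m0 a constant background mortality, and M_epi the fractional
episodic mortality of that year's degree heating months.  m0 is
calibrated once so that the system is in equilibrium under start-year
climate (τ·G(T̄₀)·A(Ω₀) = m0): with no warming, no acidification and no
heat stress, cover holds at 1.0 indefinitely.

Growth is applied before the year's episodic cull (order configurable).
Cover is floored at zero and deliberately not capped at 1: under warming
with bleaching disabled, high-latitude sites can legitimately exceed
their start-year cover as temperatures move toward the growth optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .climatology import MonthlySeries
from .co2_effects import (
    AragoniteTable,
    CO2Pathway,
    calcification_factor,
    omega_a,
)
from .errors import ParameterError
from .growth import GrowthCurve, relative_growth
from .mortality import MortalityCurve, ThresholdPolicy, annual_dhm, episodic_mortality

__all__ = [
    "CoverParams",
    "CoverTrajectory",
    "equilibrium_calibrate",
    "step_cover",
    "run_trajectory",
]


@dataclass(frozen=True)
class CoverParams:
    """Everything the annual cover update needs besides the climate inputs."""

    growth_curve: GrowthCurve
    mortality_curve: MortalityCurve
    threshold_policy: ThresholdPolicy
    baseline_turnover: float = 0.05
    omega_sensitivity: float = 0.0
    co2_enabled: bool = True
    episodic_enabled: bool = True
    growth_floor: float = -1.0
    mortality_first: bool = False

    def __post_init__(self):
        if self.baseline_turnover <= 0:
            raise ParameterError("baseline_turnover must be > 0")

    def with_(self, **changes) -> "CoverParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class CoverTrajectory:
    """Relative cover per year plus the heat-stress event log."""

    year: np.ndarray
    cover: np.ndarray
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["year", "dhm", "mortality"]
        )
    )

    def at(self, year: int) -> float:
        i = int(year) - int(self.year[0])
        if i < 0 or i >= len(self.cover):
            raise ParameterError(f"year {year} outside trajectory span")
        return float(self.cover[i])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.year, "cover_rel": self.cover})
        ev = self.events.set_index("year") if len(self.events) else None
        df["dhm"] = 0.0
        df["episodic_mortality"] = 0.0
        if ev is not None:
            df = df.set_index("year")
            df.loc[ev.index, "dhm"] = ev["dhm"]
            df.loc[ev.index, "episodic_mortality"] = ev["mortality"]
            df = df.reset_index()
        return df


def _omega_factor(
    params: CoverParams,
    table: AragoniteTable | None,
    t_mean: float,
    pco2: float,
    omega_ref: float | None,
) -> float:
    if not params.co2_enabled or params.omega_sensitivity == 0.0:
        return 1.0
    if table is None or omega_ref is None:
        raise ParameterError("CO2 module enabled but no aragonite table/reference")
    om = omega_a(table, t_mean, pco2)
    return calcification_factor(params.omega_sensitivity, omega_ref, om)


def equilibrium_calibrate(
    params: CoverParams,
    start_mean_temp: float,
    co2_start_ppm: float | None = None,
    table: AragoniteTable | None = None,
) -> float:
    """Background mortality m0 balancing growth under start-year climate.

    ``start_mean_temp`` is the climatological annual-mean temperature of
    the reference record; the Ω_a multiplier at start is 1 by definition
    (the reference Ω is the start-year Ω), so m0 reduces to
    τ·G(T̄₀).  Kept explicit for flux bookkeeping.
    """
    g0 = relative_growth(params.growth_curve, start_mean_temp, params.growth_floor)
    if g0 <= 0:
        raise ParameterError(
            f"start-year relative growth {g0:.3f} <= 0; equilibrium infeasible"
        )
    if params.co2_enabled and params.omega_sensitivity > 0 and table is not None:
        if co2_start_ppm is None:
            raise ParameterError("CO2 module enabled but no start-year CO2 given")
        omega0 = omega_a(table, start_mean_temp, co2_start_ppm)
        a0 = calcification_factor(params.omega_sensitivity, omega0, omega0)
    else:
        a0 = 1.0
    return float(params.baseline_turnover * g0 * a0)


def step_cover(
    cover: float,
    t_annual_mean: float,
    dhm: float,
    omega_factor: float,
    params: CoverParams,
    m0: float,
) -> tuple[float, float]:
    """One annual update; returns (next cover, episodic mortality applied)."""
    g = relative_growth(params.growth_curve, t_annual_mean, params.growth_floor)
    net = 1.0 + params.baseline_turnover * g * omega_factor - m0
    m_epi = (
        episodic_mortality(params.mortality_curve, dhm)
        if params.episodic_enabled
        else 0.0
    )
    if params.mortality_first:
        nxt = cover * (1.0 - m_epi) * net
    else:
        nxt = cover * net * (1.0 - m_epi)
    return max(0.0, nxt), m_epi


def run_trajectory(
    sst: MonthlySeries,
    co2: CO2Pathway | None,
    params: CoverParams,
    start_mean_temp: float | None = None,
    table: AragoniteTable | None = None,
) -> CoverTrajectory:
    """Integrate cover over every complete calendar year of ``sst``.

    ``start_mean_temp`` defaults to the first year's annual mean; passing
    the reference climatology's annual mean instead makes the equilibrium
    exact under a noise-free stationary climate.  The event log records
    every year with DHM > 0.
    """
    years = sst.years
    counts = pd.Series(sst.month).groupby(pd.Series(sst.year)).count()
    years = np.array([y for y in years if counts[y] == 12])
    if len(years) == 0:
        raise ParameterError("no complete calendar years in SST input")
    if params.co2_enabled and params.omega_sensitivity > 0:
        if co2 is None:
            raise ParameterError("CO2 module enabled but no pathway given")
        if table is None:
            from .co2_effects import build_aragonite_table

            table = build_aragonite_table()

    sst_by_year = {
        y: sst.sst[sst.year == y] for y in years
    }
    if start_mean_temp is None:
        start_mean_temp = float(np.mean(sst_by_year[years[0]]))

    use_co2 = params.co2_enabled and params.omega_sensitivity > 0
    omega_ref = (
        omega_a(table, start_mean_temp, co2.at(years[0])) if use_co2 else None
    )
    m0 = equilibrium_calibrate(
        params,
        start_mean_temp,
        co2.at(years[0]) if use_co2 else None,
        table if use_co2 else None,
    )

    cover = np.empty(len(years))
    cover[0] = 1.0
    current = 1.0
    events = []
    for i, y in enumerate(years):
        months = sst_by_year[y]
        t_mean = float(np.mean(months))
        thr = params.threshold_policy.at(int(y))
        dhm = annual_dhm(months, thr) if params.episodic_enabled else 0.0
        factor = _omega_factor(
            params, table, t_mean, co2.at(int(y)) if use_co2 else 0.0, omega_ref
        )
        current, m_epi = step_cover(current, t_mean, dhm, factor, params, m0)
        if i + 1 < len(years):
            cover[i + 1] = current
        if dhm > 0:
            events.append({"year": int(y), "dhm": dhm, "mortality": m_epi})
    ev = (
        pd.DataFrame(events)
        if events
        else pd.DataFrame(columns=["year", "dhm", "mortality"])
    )
    return CoverTrajectory(year=years, cover=cover, events=ev)
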