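"""Ensemble projection of cover trajectories and decline probabilities.

Two ensemble routes mirror the two ways the SST forcing can be built:

* **individual** — one trajectory per downscaled climate-model run that
  passed the selection screen;
* **monte_carlo** — trajectories driven by synthetic SST realizations
  drawn about the low-pass multi-model trend (default 500 members).

The ensemble mean trajectory is the pointwise arithmetic mean of the
members — a "most likely" net outcome, not an actual trajectory, since
averaging smooths out individual bleaching drops.  Decline probabilities
at an evaluation year come from a normal fit (sample mean and SD) to the
member cover values at that year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .climatology import Climatology, MonthlySeries, bleaching_threshold
from .co2_effects import AragoniteTable, CO2Pathway
from .cover_dynamics import CoverParams, CoverTrajectory, run_trajectory
from .downscaling import MonthlyDistributions, TrendSeries, simulate_sst
from .errors import InfeasibleCurveError, ParameterError
from .growth import GrowthCurve, fit_growth_curve
from .mortality import MortalityCurve, ThresholdPolicy, load_observation_table, fit_mortality_curve

__all__ = [
    "EnsembleResult",
    "run_individual_ensemble",
    "run_mc_ensemble",
    "decline_probability",
    "case_preset",
    "CASE_NAMES",
]

CASE_NAMES = ("less_resilient", "more_resilient", "no_bleaching", "validation_20c")


@dataclass(frozen=True)
class EnsembleResult:
    """A bag of member trajectories with their pointwise mean."""

    members: list[CoverTrajectory]
    method: str
    seed: int | None = None
    excluded: list[dict] = field(default_factory=list)

    @property
    def year(self) -> np.ndarray:
        return self.members[0].year

    @property
    def mean_trajectory(self) -> np.ndarray:
        return np.mean([m.cover for m in self.members], axis=0)

    def covers_at(self, year: int) -> np.ndarray:
        return np.array([m.at(year) for m in self.members])

    def normal_fit(self, year: int) -> tuple[float, float]:
        """Sample mean and SD of member cover values at ``year``."""
        values = self.covers_at(year)
        if len(values) < 2:
            raise ParameterError("need >= 2 members for a normal fit")
        return float(values.mean()), float(values.std(ddof=1))


def _run_members(
    sst_members: list[MonthlySeries],
    co2: CO2Pathway | None,
    params: CoverParams,
    start_mean_temp: float | None,
    table: AragoniteTable | None,
    method: str,
    seed: int | None = None,
) -> EnsembleResult:
    members, excluded = [], []
    for i, sst in enumerate(sst_members):
        try:
            members.append(
                run_trajectory(sst, co2, params, start_mean_temp, table)
            )
        except InfeasibleCurveError as exc:
            excluded.append({"member": i, "reason": str(exc), **exc.anchors})
    if len(members) < 2:
        raise ParameterError(
            f"only {len(members)} usable members after exclusions; need >= 2"
        )
    return EnsembleResult(members=members, method=method, seed=seed, excluded=excluded)


def run_individual_ensemble(
    downscaled_models: list[MonthlySeries],
    co2: CO2Pathway | None,
    params: CoverParams,
    start_mean_temp: float | None = None,
    table: AragoniteTable | None = None,
) -> EnsembleResult:
    """One trajectory per (already screened and downscaled) model run."""
    if len(downscaled_models) < 2:
        raise ParameterError("need >= 2 member series")
    return _run_members(
        downscaled_models, co2, params, start_mean_temp, table, "individual"
    )


def run_mc_ensemble(
    trend: TrendSeries,
    distributions: MonthlyDistributions,
    co2: CO2Pathway | None,
    params: CoverParams,
    n: int = 500,
    seed: int = 0,
    start_mean_temp: float | None = None,
    table: AragoniteTable | None = None,
) -> EnsembleResult:
    """Monte Carlo ensemble about the multi-model trend (default 500 members)."""
    if n < 2:
        raise ParameterError("need n >= 2 members")
    sst_members = simulate_sst(trend, distributions, n_sims=n, seed=seed)
    return _run_members(
        sst_members, co2, params, start_mean_temp, table, "monte_carlo", seed
    )


def decline_probability(result: EnsembleResult, year: int, decline_frac: float) -> float:
    """P(cover < 1 − decline_frac) from a normal fit of member end states.

    A zero-variance ensemble degenerates to 0 or 1 by the position of the
    mean relative to the threshold.
    """
    if not 0.0 <= decline_frac <= 1.0:
        raise ParameterError("decline_frac must lie in [0, 1]")
    mean, sd = result.normal_fit(year)
    threshold = 1.0 - decline_frac
    if sd == 0.0:
        return 1.0 if mean < threshold else 0.0
    return float(stats.norm.cdf(threshold, loc=mean, scale=sd))


def case_preset(
    name: str,
    clim: Climatology,
    start_year: int = 2000,
    mortality_curve: MortalityCurve | None = None,
    growth_curve: GrowthCurve | None = None,
    baseline_turnover: float = 0.05,
) -> CoverParams:
    """Standard run configurations bounding coral resilience.

    * ``less_resilient`` — fixed bleaching threshold (no adaptation) and
      Ω_a sensitivity 0.3;
    * ``more_resilient`` — threshold drifts up 1 °C per century and the
      CO2 module is off;
    * ``no_bleaching`` — both stressor modules off: pure growth-curve
      dynamics (instructive, not realistic);
    * ``validation_20c`` — less-resilient parameters for a 1900–1999
      hindcast window.
    """
    if name not in CASE_NAMES:
        raise ParameterError(f"unknown case {name!r}; choose from {CASE_NAMES}")
    growth_curve = growth_curve or fit_growth_curve(clim)
    mortality_curve = mortality_curve or fit_mortality_curve(
        load_observation_table("all_data")
    )
    base = bleaching_threshold(clim)
    if name == "validation_20c":
        start_year = 1900
    adaptation = 1.0 if name == "more_resilient" else 0.0
    policy = ThresholdPolicy(
        base_threshold=base, adaptation_rate=adaptation, start_year=start_year
    )
    omega_s = 0.3 if name in ("less_resilient", "validation_20c") else 0.0
    return CoverParams(
        growth_curve=growth_curve,
        mortality_curve=mortality_curve,
        threshold_policy=policy,
        baseline_turnover=baseline_turnover,
        omega_sensitivity=omega_s,
        co2_enabled=omega_s > 0,
        episodic_enabled=name != "no_bleaching",
    )
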