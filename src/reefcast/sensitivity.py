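"""Four-parameter sensitivity protocol with normalized-variance summaries.

One parameter is varied across a grid of levels while everything else —
including the random SST realizations (common random numbers) — is held
fixed.  For each level a Monte Carlo ensemble is run; the sensitivity
metric is the normalized variance (population variance divided by the
mean) of the per-level ensemble means, and separately of the per-level
member standard deviations, evaluated at two milestone years (defaults
2050 and 2099).

Parameters and default level grids:

* ``adaptation`` — bleaching-threshold drift ∈ {0, 0.5, 1, 1.5, 2}
  °C/century;
* ``omega_coeff`` — Ω_a sensitivity ∈ {0, 0.15, 0.3, 0.45};
* ``dhm_curve`` — the three packaged DHM/mortality fits
  (``all_data``, ``mhi_nwhi``, ``carib``);
* ``growth_curve`` — random anchor perturbations of the cubic (zeros
  ±0.5 °C, peak 0–2 °C warmward), one independent draw per level.

Members whose cover change exceeds 500% in magnitude are flagged
unstable; variances are reported both with and without them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climatology import Climatology
from .co2_effects import AragoniteTable, CO2Pathway
from .cover_dynamics import CoverParams
from .downscaling import MonthlyDistributions, TrendSeries
from .ensemble import run_mc_ensemble
from .errors import InfeasibleCurveError, ParameterError
from .growth import perturb_growth_curve
from .mortality import ThresholdPolicy, fit_mortality_curve, load_observation_table

__all__ = [
    "SensitivityReport",
    "normalized_variance",
    "run_sensitivity",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS: dict[str, list] = {
    "adaptation": [0.0, 0.5, 1.0, 1.5, 2.0],
    "omega_coeff": [0.0, 0.15, 0.3, 0.45],
    "dhm_curve": ["all_data", "mhi_nwhi", "carib"],
    "growth_curve": list(range(5)),  # perturbation draw indices
}

UNSTABLE_CHANGE = 5.0  # |cover - 1| beyond this flags a member unstable


def normalized_variance(values) -> float:
    """Population variance divided by the mean of ``values``."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean == 0:
        raise ParameterError("normalized variance undefined for zero mean")
    return float(v.var() / mean)


@dataclass(frozen=True)
class SensitivityReport:
    """Per-parameter sensitivity summary at the milestone years."""

    parameter: str
    levels: list
    eval_years: tuple[int, int]
    level_means: dict[int, list[float]]  # year -> mean cover per level
    level_sds: dict[int, list[float]]  # year -> member SD per level
    nv_mean: dict[int, float]  # year -> normalized variance of level means
    nv_sd: dict[int, float]
    nv_mean_stable: dict[int, float]  # same, unstable members excluded
    unstable_rate: float
    runs_per_level: int
    seed: int = 0
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "levels": [str(level) for level in self.levels],
            "eval_years": list(self.eval_years),
            "normalized_variance_of_means": {
                str(y): self.nv_mean[y] for y in self.eval_years
            },
            "normalized_variance_of_sds": {
                str(y): self.nv_sd[y] for y in self.eval_years
            },
            "normalized_variance_of_means_stable_only": {
                str(y): self.nv_mean_stable[y] for y in self.eval_years
            },
            "unstable_member_rate": self.unstable_rate,
            "runs_per_level": self.runs_per_level,
            "seed": self.seed,
        }


def _params_for_level(
    parameter: str,
    level,
    base: CoverParams,
    clim: Climatology,
    seed: int,
) -> CoverParams:
    if parameter == "adaptation":
        policy = ThresholdPolicy(
            base_threshold=base.threshold_policy.base_threshold,
            adaptation_rate=float(level),
            start_year=base.threshold_policy.start_year,
        )
        return base.with_(threshold_policy=policy)
    if parameter == "omega_coeff":
        return base.with_(omega_sensitivity=float(level), co2_enabled=float(level) > 0)
    if parameter == "dhm_curve":
        return base.with_(
            mortality_curve=fit_mortality_curve(load_observation_table(str(level)))
        )
    if parameter == "growth_curve":
        rng = np.random.default_rng([seed, 7919, int(level)])
        return base.with_(growth_curve=perturb_growth_curve(clim, rng))
    raise ParameterError(f"unknown sensitivity parameter {parameter!r}")


def run_sensitivity(
    parameter: str,
    base_params: CoverParams,
    clim: Climatology,
    trend: TrendSeries,
    distributions: MonthlyDistributions,
    co2: CO2Pathway,
    levels: list | None = None,
    n_runs: int = 200,
    seed: int = 0,
    eval_years: tuple[int, int] = (2050, 2099),
    table: AragoniteTable | None = None,
    start_mean_temp: float | None = None,
) -> SensitivityReport:
    """Vary one parameter over its levels with everything else fixed.

    ``n_runs`` is the total trajectory budget for the parameter, split
    evenly across levels (at least 2 members per level).  All levels see
    the same SST realizations (common random numbers), so level-to-level
    differences isolate the parameter.
    """
    if levels is None:
        levels = DEFAULT_LEVELS[parameter]
    if len(levels) < 1:
        raise ParameterError("need at least one level")
    members_per_level = max(2, n_runs // len(levels))

    if table is None and (
        base_params.omega_sensitivity > 0 or parameter == "omega_coeff"
    ):
        from .co2_effects import build_aragonite_table

        table = build_aragonite_table()

    level_means: dict[int, list[float]] = {y: [] for y in eval_years}
    level_sds: dict[int, list[float]] = {y: [] for y in eval_years}
    level_means_stable: dict[int, list[float]] = {y: [] for y in eval_years}
    n_unstable = 0
    n_total = 0
    infeasible = 0

    for level in levels:
        try:
            params = _params_for_level(parameter, level, base_params, clim, seed)
        except InfeasibleCurveError:
            infeasible += 1
            continue
        result = run_mc_ensemble(
            trend,
            distributions,
            co2,
            params,
            n=members_per_level,
            seed=seed,  # common random numbers across levels
            start_mean_temp=start_mean_temp,
            table=table,
        )
        for y in eval_years:
            covers = result.covers_at(y)
            stable = np.abs(covers - 1.0) <= UNSTABLE_CHANGE
            n_unstable += int((~stable).sum())
            level_means[y].append(float(covers.mean()))
            level_sds[y].append(float(covers.std(ddof=1)))
            level_means_stable[y].append(
                float(covers[stable].mean()) if stable.any() else float("nan")
            )
        n_total += len(result.members) * len(eval_years)

    if not level_means[eval_years[0]]:
        raise ParameterError("no feasible levels")

    def nv(values: list[float]) -> float:
        return normalized_variance(values) if len(values) > 1 else 0.0

    return SensitivityReport(
        parameter=parameter,
        levels=list(levels),
        eval_years=eval_years,
        level_means=level_means,
        level_sds=level_sds,
        nv_mean={y: nv(level_means[y]) for y in eval_years},
        nv_sd={y: nv(level_sds[y]) for y in eval_years},
        nv_mean_stable={y: nv(level_means_stable[y]) for y in eval_years},
        unstable_rate=n_unstable / max(1, n_total),
        runs_per_level=members_per_level,
        seed=seed,
        notes={"infeasible_levels": infeasible},
    )
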