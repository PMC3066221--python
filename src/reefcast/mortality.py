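"""Episodic heat-stress mortality: degree heating months and the DHM curve.

Annual degree heating months (DHM) are the sum over a calendar year of
monthly exceedances above the bleaching threshold (maximum climatological
monthly mean + 1 °C): two months averaging 2 °C above the threshold give
4 DHM.  Fractional colony mortality in an event year is a quadratic in
DHM through the origin, fitted by least squares to observed
(DHM, mortality) pairs from documented bleaching events; evaluated
mortality is clipped to [0, 1].

Thermal adaptation is represented as a linear drift of the bleaching
threshold over time (0–2 °C per century); it affects only episodic
mortality, never the growth curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "MortalityCurve",
    "ThresholdPolicy",
    "annual_dhm",
    "fit_mortality_curve",
    "episodic_mortality",
    "adapted_threshold",
    "load_observation_table",
    "OBSERVATION_TABLES",
]

#: Packaged synthetic observation tables (see data/ CSVs): the real event
#: coordinates are not tabulated in any packaged source, so these fixtures
#: reproduce the qualitative curve ordering only and are non-authoritative.
OBSERVATION_TABLES = ("all_data", "mhi_nwhi", "carib")


@dataclass(frozen=True)
class MortalityCurve:
    """Quadratic DHM→mortality curve through the origin.

    mortality(dhm) = clip(a·dhm² + b·dhm, 0, 1).  ``intercept`` is only
    nonzero for the diagnostic free-intercept fit variant.
    """

    a: float
    b: float
    intercept: float = 0.0
    rss: float = float("nan")
    n: int = 0

    def __call__(self, dhm):
        return np.clip(
            self.a * np.square(dhm) + self.b * np.asarray(dhm) + self.intercept,
            0.0,
            1.0,
        )


@dataclass(frozen=True)
class ThresholdPolicy:
    """Bleaching threshold with linear adaptation drift.

    ``adaptation_rate`` is in °C per century; 0 means a fixed threshold
    ("less resilient"), 1 the optimistic bound of 0.1 °C/decade.
    """

    base_threshold: float
    adaptation_rate: float = 0.0
    start_year: int = 2000

    def __post_init__(self):
        if not 0.0 <= self.adaptation_rate <= 2.0:
            raise ParameterError("adaptation_rate must lie in [0, 2] °C/century")

    def at(self, year: int) -> float:
        return adapted_threshold(self, year)


def annual_dhm(monthly_sst: np.ndarray, threshold: float) -> float:
    """Degree heating months for one calendar year of monthly SST.

    Sum of max(0, T_m − threshold) over exactly 12 monthly values,
    in °C·months.
    """
    t = np.asarray(monthly_sst, dtype=float)
    if t.shape != (12,):
        raise ParameterError(f"need exactly 12 monthly values, got {t.shape}")
    return float(np.sum(np.maximum(0.0, t - threshold)))


def fit_mortality_curve(
    observations: pd.DataFrame, free_intercept: bool = False
) -> MortalityCurve:
    """Least-squares quadratic mortality fit through the origin.

    ``observations`` needs columns ``dhm`` and ``mortality_fraction``.
    The zero intercept guarantees no mortality in stress-free years; the
    free-intercept variant exists for fit comparison only.
    """
    dhm = observations["dhm"].to_numpy(dtype=float)
    mort = observations["mortality_fraction"].to_numpy(dtype=float)
    if len(np.unique(dhm)) < 2:
        raise ParameterError("need >= 2 observations with distinct DHM")
    cols = [dhm**2, dhm]
    if free_intercept:
        cols.append(np.ones_like(dhm))
    design = np.column_stack(cols)
    coef, rss, rank, _ = np.linalg.lstsq(design, mort, rcond=None)
    if rank < design.shape[1]:
        raise ParameterError("degenerate design matrix in mortality fit")
    resid = mort - design @ coef
    return MortalityCurve(
        a=float(coef[0]),
        b=float(coef[1]),
        intercept=float(coef[2]) if free_intercept else 0.0,
        rss=float(resid @ resid),
        n=len(dhm),
    )


def episodic_mortality(curve: MortalityCurve, dhm: float) -> float:
    """Fractional colony mortality for an annual DHM value, in [0, 1]."""
    if dhm < 0:
        raise ParameterError("DHM must be >= 0")
    return float(curve(dhm))


def adapted_threshold(policy: ThresholdPolicy, year: int) -> float:
    """Bleaching threshold in ``year`` under linear adaptation drift."""
    if year < policy.start_year:
        raise ParameterError(
            f"year {year} precedes policy start {policy.start_year}"
        )
    return policy.base_threshold + policy.adaptation_rate * (year - policy.start_year) / 100.0


def load_observation_table(name: str) -> pd.DataFrame:
    """Load a packaged (synthetic) DHM/mortality observation table by name."""
    if name not in OBSERVATION_TABLES:
        raise ParameterError(
            f"unknown table {name!r}; choose from {OBSERVATION_TABLES}"
        )
    path = resources.files("reefcast.data") / f"mortality_{name}.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(Path(p), comment="#")
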