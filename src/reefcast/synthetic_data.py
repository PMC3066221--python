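"""Synthetic inputs with known ground truth for every pipeline stage.

The real analysis runs on observed SST (ERSST-style boxes around four
Hawaiian-archipelago sites), climate-model SST for a 20th-century
reconstruction plus a mid-range 21st-century emissions scenario, and an
atmospheric CO2 trajectory from a carbon-cycle model.  None of those are
packaged; this module emulates their statistical structure instead:

* monthly SST = 12-month climatological cycle + slow warming trend +
  independent per-calendar-month Gaussian noise;
* "model-style" SST additionally carries a constant bias and a distorted
  seasonal amplitude, the two defects the downscaler must remove;
* an annual CO2 pathway between prescribed endpoint mixing ratios;
* noisy (DHM, mortality) observation tables for curve-fitting tests.

Site presets named after the four study locations are illustrative
fixtures whose climatologies reproduce the qualitative latitudinal
ordering (MID coldest with the largest seasonal range, JOH warmest with
the smallest); they are not transcriptions of any observational dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .climatology import MonthlySeries
from .co2_effects import CO2Pathway
from .errors import ParameterError

__all__ = [
    "SyntheticSSTParams",
    "CO2PathwayParams",
    "SITE_PRESETS",
    "A1B_LIKE_CO2",
    "site_preset",
    "gen_historic_sst",
    "gen_model_sst",
    "gen_co2_pathway",
    "gen_mortality_observations",
]


@dataclass(frozen=True)
class SyntheticSSTParams:
    """Ground-truth parameters of a synthetic monthly SST record.

    ``trend_per_century`` shifts the whole record linearly in
    ``t = (year - start_year) / 100``; ``accel_per_century2`` adds an
    optional quadratic term for non-linear warming.  ``bias`` and
    ``seasonal_amp_factor`` only take effect through
    :func:`gen_model_sst` and emulate climate-model defects.
    """

    start_year: int = 1945
    n_years: int = 55
    monthly_clim: np.ndarray = field(
        default_factory=lambda: 25.0 + 2.0 * np.cos(2 * np.pi * (np.arange(12) - 7) / 12)
    )
    monthly_sigma: np.ndarray = field(default_factory=lambda: np.full(12, 0.5))
    trend_per_century: float = 0.0
    accel_per_century2: float = 0.0
    bias: float = 0.0
    seasonal_amp_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        clim = np.asarray(self.monthly_clim, dtype=float)
        sigma = np.asarray(self.monthly_sigma, dtype=float)
        object.__setattr__(self, "monthly_clim", clim)
        object.__setattr__(self, "monthly_sigma", sigma)
        if clim.shape != (12,) or sigma.shape != (12,):
            raise ParameterError("monthly_clim and monthly_sigma must have 12 entries")
        if np.any(sigma < 0):
            raise ParameterError("monthly_sigma must be >= 0")
        if self.seasonal_amp_factor <= 0:
            raise ParameterError("seasonal_amp_factor must be > 0")
        if self.n_years < 2:
            raise ParameterError("n_years must be >= 2")


@dataclass(frozen=True)
class CO2PathwayParams:
    """Endpoints and shape of an annual atmospheric CO2 trajectory."""

    start_year: int = 2000
    end_year: int = 2099
    start_ppm: float = 370.0
    end_ppm: float = 700.0
    shape: str = "logistic"

    def __post_init__(self):
        if self.end_year <= self.start_year:
            raise ParameterError("end_year must exceed start_year")
        if self.start_ppm <= 0 or self.end_ppm <= 0:
            raise ParameterError("ppm values must be > 0")
        if self.shape not in {"linear", "exponential", "logistic"}:
            raise ParameterError(f"unknown pathway shape {self.shape!r}")


def _seasonal_sine(mean: float, amp: float, peak_month: int = 8) -> np.ndarray:
    m = np.arange(12)
    return mean + amp * np.cos(2 * np.pi * (m - (peak_month - 1)) / 12)


# Illustrative site fixtures: warm/small-range in the south (JOH), cold
# with the widest seasonal swing in the north (MID).  Northern sites get
# larger interannual monthly noise, mimicking proximity to the transition
# zone between subtropical-gyre and subarctic surface waters.
SITE_PRESETS: dict[str, SyntheticSSTParams] = {
    "JOH": SyntheticSSTParams(
        monthly_clim=_seasonal_sine(26.3, 1.1),
        monthly_sigma=np.full(12, 0.35),
    ),
    "OAH": SyntheticSSTParams(
        monthly_clim=_seasonal_sine(25.4, 1.5),
        monthly_sigma=np.full(12, 0.40),
    ),
    "FFS": SyntheticSSTParams(
        monthly_clim=_seasonal_sine(24.8, 2.0),
        monthly_sigma=np.full(12, 0.50),
    ),
    "MID": SyntheticSSTParams(
        monthly_clim=_seasonal_sine(22.5, 3.4),
        monthly_sigma=np.full(12, 0.70),
    ),
}

#: Mid-range-emissions-like default: logistic 370 -> 700 ppm over 2000-2099.
A1B_LIKE_CO2 = CO2PathwayParams()


def site_preset(name: str, **overrides) -> SyntheticSSTParams:
    """A copy of a named site preset with optional field overrides."""
    try:
        base = SITE_PRESETS[name.upper()]
    except KeyError:
        raise ParameterError(
            f"unknown site {name!r}; choose from {sorted(SITE_PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


def _base_draw(params: SyntheticSSTParams):
    years = np.repeat(np.arange(params.start_year, params.start_year + params.n_years), 12)
    months = np.tile(np.arange(1, 13), params.n_years)
    t = (years - params.start_year) / 100.0
    trend = params.trend_per_century * t + params.accel_per_century2 * t**2
    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal(len(years)) * params.monthly_sigma[months - 1]
    return years, months, trend, noise


def gen_historic_sst(params: SyntheticSSTParams) -> MonthlySeries:
    """Observation-style monthly SST: climatology + trend + monthly noise.

    Deterministic for a fixed ``params.seed``.  ``bias`` and
    ``seasonal_amp_factor`` are ignored here; they are model-style defects.
    """
    years, months, trend, noise = _base_draw(params)
    sst = params.monthly_clim[months - 1] + trend + noise
    return MonthlySeries(years, months, sst)


def gen_model_sst(params: SyntheticSSTParams) -> MonthlySeries:
    """Climate-model-style SST: as historic, plus bias and a scaled seasonal cycle.

    The seasonal anomaly (climatological cycle about its annual mean) is
    multiplied by ``seasonal_amp_factor`` and the constant ``bias`` is
    added, so with ``bias=0, seasonal_amp_factor=1`` the output is
    bit-identical to :func:`gen_historic_sst` under the same seed.
    """
    years, months, trend, noise = _base_draw(params)
    base = params.monthly_clim[months - 1] + trend + noise
    clim_mean = params.monthly_clim.mean()
    seasonal = params.monthly_clim - clim_mean
    # the amp factor inflates all sub-trend variability (cycle plus monthly
    # anomalies) — the quantity the downscaler diagnoses from detrended
    # residuals — while leaving the slow trend untouched.  Written as a
    # correction on the historic draw so the amp=1, bias=0 case is
    # bit-identical to gen_historic_sst.
    extra = (params.seasonal_amp_factor - 1.0) * (seasonal[months - 1] + noise)
    sst = base + extra + params.bias
    return MonthlySeries(years, months, sst)


def gen_co2_pathway(params: CO2PathwayParams) -> CO2Pathway:
    """Annual CO2 pathway with exact endpoints, monotone for all shapes.

    * ``linear``: straight line between endpoints.
    * ``exponential``: constant growth rate, ``c0 * (c1/c0)**u``.
    * ``logistic``: symmetric sigmoid rescaled to hit both endpoints
      exactly; its value at the midpoint year is the endpoint mean.
    """
    years = np.arange(params.start_year, params.end_year + 1)
    u = (years - params.start_year) / (params.end_year - params.start_year)
    c0, c1 = params.start_ppm, params.end_ppm
    if params.shape == "linear":
        ppm = c0 + (c1 - c0) * u
    elif params.shape == "exponential":
        ppm = c0 * (c1 / c0) ** u
    else:  # logistic
        k = 6.0  # shape parameter: gentle sigmoid over the window
        raw = 1.0 / (1.0 + np.exp(-k * (u - 0.5)))
        lo, hi = raw[0], raw[-1]
        ppm = c0 + (c1 - c0) * (raw - lo) / (hi - lo)
    return CO2Pathway(years=years, ppm=ppm)


def gen_mortality_observations(
    a: float,
    b: float,
    noise_sd: float = 0.0,
    n: int = 30,
    dhm_max: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic (DHM, mortality) table scattered about a known quadratic.

    mortality = clip(a*DHM^2 + b*DHM + N(0, noise_sd), 0, 1) with DHM
    uniform on [0, dhm_max].  Used to test quadratic curve recovery.
    """
    if n < 3:
        raise ParameterError("need n >= 3 observations")
    rng = np.random.default_rng(seed)
    dhm = rng.uniform(0.0, dhm_max, size=n)
    mort = a * dhm**2 + b * dhm
    if noise_sd > 0:
        mort = mort + rng.normal(0.0, noise_sd, size=n)
    mort = np.clip(mort, 0.0, 1.0)
    return pd.DataFrame({"dhm": dhm, "mortality_fraction": mort})
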