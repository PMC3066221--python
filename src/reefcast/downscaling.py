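"""Statistical downscaling of climate-model SST to a site's historic record.

Climate-model reconstructions of 20th-century SST can carry a constant
offset (bias) relative to observations at a site and an unrealistic
seasonal amplitude.  The transformation here removes both while keeping
the model's own slow warming signal:

1. a fourth-order polynomial in fractional year is fitted to both the
   model 20th-century series and the historic record and subtracted,
   leaving two sets of seasonal residuals;
2. normal CDF probabilities of the model residuals are computed and
   re-inverted with the historic residual standard deviation, which under
   normality is the affine map ``r -> (r - mean) * sd_hist / sd_model``;
3. the overlap-period mean bias is subtracted.

Model runs whose 20th-century bias or relative seasonal-amplitude
difference is too large are filtered out before use (strict limits,
|bias| < 3 °C and relative residual-SD difference < 1).

For the Monte Carlo ensemble route, bias-corrected model series are
low-pass filtered (25-month centred moving average) and averaged into a
single multi-model temperature trend, and per-calendar-month normal
anomaly distributions are estimated from the historic record; future SST
realizations are drawn as trend + historic seasonal cycle + monthly
normal anomalies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .climatology import MonthlySeries
from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
)

__all__ = [
    "SelectionStats",
    "DownscaleTransform",
    "TrendSeries",
    "MonthlyDistributions",
    "selection_stats",
    "select_models",
    "fit_detrend",
    "fit_transform",
    "seasonal_scale",
    "downscale_scenario",
    "multi_model_trend",
    "monthly_anomaly_distributions",
    "simulate_sst",
]

BIAS_LIMIT = 3.0  # °C, strict
SD_LIMIT = 1.0  # relative residual-SD difference, strict


@dataclass(frozen=True)
class SelectionStats:
    """Per-model-run screening statistics against the historic record."""

    model_id: str
    bias: float
    seasonal_diff: float

    def passes(self, bias_limit: float = BIAS_LIMIT, sd_limit: float = SD_LIMIT) -> bool:
        return abs(self.bias) < bias_limit and self.seasonal_diff < sd_limit

    def reason(self, bias_limit: float = BIAS_LIMIT, sd_limit: float = SD_LIMIT) -> str:
        problems = []
        if not abs(self.bias) < bias_limit:
            problems.append(f"|bias| {abs(self.bias):.2f} >= {bias_limit}")
        if not self.seasonal_diff < sd_limit:
            problems.append(f"seasonal diff {self.seasonal_diff:.2f} >= {sd_limit}")
        return "; ".join(problems) if problems else "ok"


@dataclass(frozen=True)
class DownscaleTransform:
    """Fitted bias and residual-rescaling parameters of one model run."""

    bias: float
    hist_trend_coeffs: np.ndarray
    model_trend_coeffs: np.ndarray
    hist_resid_sd: float
    model_resid_sd: float
    model_resid_mean: float


@dataclass(frozen=True)
class TrendSeries:
    """Low-pass multi-model temperature trend at monthly resolution."""

    year: np.ndarray
    month: np.ndarray
    trend: np.ndarray
    n_models_averaged: int

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.year)


@dataclass(frozen=True)
class MonthlyDistributions:
    """Historic seasonal cycle and per-calendar-month anomaly normals.

    ``seasonal_anom`` is the detrended per-month mean (zero-mean cycle);
    ``mean``/``sd`` parameterize the normal anomaly about that cycle, so
    ``mean`` is ~0 by construction.
    """

    seasonal_anom: np.ndarray
    mean: np.ndarray
    sd: np.ndarray


def _overlap(a: MonthlySeries, b: MonthlySeries) -> tuple[MonthlySeries, MonthlySeries]:
    lo = max(a.year.min(), b.year.min())
    hi = min(a.year.max(), b.year.max())
    if hi < lo:
        raise InsufficientDataError("series do not overlap")
    return a.window(lo, hi), b.window(lo, hi)


def fit_detrend(series: MonthlySeries, order: int = 4):
    """Least-squares polynomial trend in centred fractional year.

    Returns ``(coeffs, residuals)`` with ``residuals = sst − trend``;
    ``coeffs`` are numpy polynomial coefficients (ascending degree) in
    ``x = frac_year − midpoint``.  Centring keeps the 4th-order normal
    equations well conditioned over a century-long record.
    """
    if len(series.years) < order + 1:
        raise InsufficientDataError(
            f"need >= {order + 1} years for an order-{order} fit"
        )
    x = series.frac_year
    x0 = 0.5 * (x.min() + x.max())
    coeffs = np.polynomial.polynomial.polyfit(x - x0, series.sst, order)
    trend = np.polynomial.polynomial.polyval(x - x0, coeffs)
    return coeffs, series.sst - trend


def selection_stats(
    model_20c: MonthlySeries, historic: MonthlySeries, model_id: str = "model"
) -> SelectionStats:
    """Bias and relative seasonal-amplitude difference over the overlap.

    ``bias`` is the model-minus-historic mean; ``seasonal_diff`` is the
    absolute difference of detrended residual SDs, in units of the
    historic residual SD.
    """
    m, h = _overlap(model_20c, historic)
    if len(m.years) < 10:
        raise InsufficientDataError("need >= 10 overlapping years")
    bias = float(m.sst.mean() - h.sst.mean())
    _, m_res = fit_detrend(m)
    _, h_res = fit_detrend(h)
    h_sd = float(np.std(h_res))
    if h_sd == 0:
        raise DegenerateInputError("historic residual SD is zero")
    seasonal_diff = abs(float(np.std(m_res)) - h_sd) / h_sd
    return SelectionStats(model_id=model_id, bias=bias, seasonal_diff=seasonal_diff)


def select_models(
    stats: list[SelectionStats],
    bias_limit: float = BIAS_LIMIT,
    sd_limit: float = SD_LIMIT,
) -> tuple[list[SelectionStats], list[SelectionStats], dict[str, str]]:
    """Stable partition into (passing, failing) with per-model reasons.

    Both limits are strict inequalities: a run with bias exactly at the
    limit is rejected.
    """
    if not stats:
        raise ParameterError("empty selection-stats list")
    passing = [s for s in stats if s.passes(bias_limit, sd_limit)]
    failing = [s for s in stats if not s.passes(bias_limit, sd_limit)]
    reasons = {s.model_id: s.reason(bias_limit, sd_limit) for s in stats}
    return passing, failing, reasons


def fit_transform(model_20c: MonthlySeries, historic: MonthlySeries) -> DownscaleTransform:
    """Fit the bias + residual-rescaling transform from a 20th-century pair."""
    m, h = _overlap(model_20c, historic)
    bias = float(m.sst.mean() - h.sst.mean())
    m_coeffs, m_res = fit_detrend(m)
    h_coeffs, h_res = fit_detrend(h)
    m_sd = float(np.std(m_res))
    h_sd = float(np.std(h_res))
    if m_sd == 0:
        raise DegenerateInputError("model residual SD is zero; cannot rescale")
    if h_sd == 0:
        raise DegenerateInputError("historic residual SD is zero; cannot rescale")
    return DownscaleTransform(
        bias=bias,
        hist_trend_coeffs=h_coeffs,
        model_trend_coeffs=m_coeffs,
        hist_resid_sd=h_sd,
        model_resid_sd=m_sd,
        model_resid_mean=float(np.mean(m_res)),
    )


def seasonal_scale(model_resids: np.ndarray, transform: DownscaleTransform) -> np.ndarray:
    """Map model residuals onto the historic residual distribution.

    Each residual's normal CDF probability (at the model residual mean
    and SD) is inverted with the historic SD and zero mean:
    ``Phi^-1(Phi(r; mu_m, sd_m); 0, sd_h)``.  For normal inputs this is
    exactly the affine rescaling ``(r − mu_m) · sd_h / sd_m``; the CDF
    path is kept because it is the defined operation.
    """
    if transform.model_resid_sd == 0:
        raise DegenerateInputError("model residual SD is zero")
    p = stats.norm.cdf(
        model_resids, loc=transform.model_resid_mean, scale=transform.model_resid_sd
    )
    # clip away exact 0/1 from far tails before inversion
    p = np.clip(p, 1e-16, 1 - 1e-16)
    return stats.norm.ppf(p, loc=0.0, scale=transform.hist_resid_sd)


def downscale_scenario(
    model_20c: MonthlySeries,
    model_scen: MonthlySeries,
    historic: MonthlySeries,
) -> MonthlySeries:
    """Bias-correct and seasonally rescale a scenario series.

    The transform is fitted on the 20th-century model/historic overlap and
    applied to the scenario about the scenario's own 4th-order trend, so
    the model's native slow warming survives while the overlap-period mean
    and seasonal spread match the historic record.
    """
    transform = fit_transform(model_20c, historic)
    coeffs, resids = fit_detrend(model_scen)
    x = model_scen.frac_year
    x0 = 0.5 * (x.min() + x.max())
    trend = np.polynomial.polynomial.polyval(x - x0, coeffs)
    scaled = seasonal_scale(resids, transform)
    return model_scen.with_sst(trend - transform.bias + scaled)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge reflection; window forced odd."""
    if window % 2 == 0:
        window += 1
    half = window // 2
    padded = np.concatenate([values[half:0:-1], values, values[-2 : -half - 2 : -1]])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def multi_model_trend(
    series_list: list[MonthlySeries], cutoff_months: int = 25
) -> TrendSeries:
    """Remove each model's seasonal cycle, low-pass, and average across models.

    Each series' own climatological monthly-mean anomaly is subtracted
    before the centred moving average (this keeps the filter's edges free
    of seasonal phase artefacts), then the smoothed series are averaged.
    Inputs must share an identical (year, month) axis.
    """
    if not series_list:
        raise ParameterError("need at least one series")
    first = series_list[0]
    for s in series_list[1:]:
        if not (
            np.array_equal(s.year, first.year) and np.array_equal(s.month, first.month)
        ):
            raise ParameterError("series spans do not match")

    def deseasonalized(s: MonthlySeries) -> np.ndarray:
        monthly_mean = np.array([s.sst[s.month == m].mean() for m in range(1, 13)])
        cycle = monthly_mean - monthly_mean.mean()
        return s.sst - cycle[s.month - 1]

    smoothed = np.mean(
        [_moving_average(deseasonalized(s), cutoff_months) for s in series_list],
        axis=0,
    )
    return TrendSeries(
        year=first.year.copy(),
        month=first.month.copy(),
        trend=smoothed,
        n_models_averaged=len(series_list),
    )


def monthly_anomaly_distributions(historic: MonthlySeries) -> MonthlyDistributions:
    """Per-calendar-month normal anomaly distributions of a historic record.

    The record is detrended (4th-order polynomial); residuals are split
    into a per-month mean (the seasonal cycle) and anomalies about it,
    whose per-month mean (~0) and SD parameterize the normals.
    """
    if len(historic.years) < 10:
        raise InsufficientDataError("need >= 10 years of historic data")
    _, resids = fit_detrend(historic)
    seasonal = np.empty(12)
    mean = np.empty(12)
    sd = np.empty(12)
    for m in range(1, 13):
        r = resids[historic.month == m]
        seasonal[m - 1] = r.mean()
        anom = r - r.mean()
        mean[m - 1] = anom.mean()  # ~0 by construction
        sd[m - 1] = anom.std(ddof=1)
    seasonal = seasonal - seasonal.mean()
    return MonthlyDistributions(seasonal_anom=seasonal, mean=mean, sd=sd)


def simulate_sst(
    trend: TrendSeries,
    distributions: MonthlyDistributions,
    n_sims: int = 500,
    seed: int = 0,
) -> list[MonthlySeries]:
    """Draw future SST realizations about the multi-model trend.

    Each member is trend + historic seasonal cycle + independent
    per-calendar-month normal draws.  Member ``k`` uses the seeded stream
    ``(seed, k)`` so members are individually reproducible.
    """
    if n_sims < 1:
        raise ParameterError("n_sims must be >= 1")
    base = trend.trend + distributions.seasonal_anom[trend.month - 1]
    out = []
    for k in range(n_sims):
        rng = np.random.default_rng([seed, k])
        draws = distributions.mean[trend.month - 1] + rng.standard_normal(
            len(base)
        ) * distributions.sd[trend.month - 1]
        out.append(MonthlySeries(trend.year, trend.month, base + draws))
    return out
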