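"""Cubic temperature–relative-growth curve for reef corals.

The curve maps monthly-mean temperature to a dimensionless net growth
rate, anchored entirely by the site's SST climatology:

* maximum growth at ``clim_max − 2·clim_sd`` (the warmest climatological
  monthly mean minus two standard deviations of the 12 monthly means),
  normalized to 1;
* zero net growth at ``clim_min − 5 °C`` and ``clim_max + 5 °C``.

A cubic is the lowest-order polynomial that can satisfy two roots, a
stationary interior peak, and a prescribed peak value; it is solved as a
4×4 linear system in the coefficients.  Outside its zeros the cubic goes
negative (net decline), floored at a configurable value so extreme
extrapolation stays bounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
import numpy as np

from .climatology import Climatology
from .errors import DegenerateInputError, InfeasibleCurveError

__all__ = [
    "GrowthCurve",
    "fit_growth_curve",
    "relative_growth",
    "perturb_growth_curve",
]


@dataclass(frozen=True)
class GrowthCurve:
    """Cubic relative-growth polynomial with its defining anchors."""

    coeffs: np.ndarray  # ascending degree, length 4
    t_gmax: float
    t_zero_low: float
    t_zero_high: float

    def __call__(self, t):
        return np.polynomial.polynomial.polyval(t, self.coeffs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "coeffs": list(self.coeffs),
                "t_gmax": self.t_gmax,
                "t_zero_low": self.t_zero_low,
                "t_zero_high": self.t_zero_high,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GrowthCurve":
        d = json.loads(text)
        return cls(
            np.asarray(d["coeffs"], float),
            d["t_gmax"],
            d["t_zero_low"],
            d["t_zero_high"],
        )


def _fit_from_anchors(t_zero_low: float, t_zero_high: float, t_gmax: float) -> GrowthCurve:
    if not t_zero_low < t_gmax < t_zero_high:
        raise InfeasibleCurveError(
            f"peak temperature {t_gmax:.2f}°C outside zero-growth interval "
            f"({t_zero_low:.2f}, {t_zero_high:.2f})",
            anchors={
                "t_gmax": t_gmax,
                "t_zero_low": t_zero_low,
                "t_zero_high": t_zero_high,
            },
        )
    # rows: G(z_lo)=0, G(z_hi)=0, G'(p)=0, G(p)=1
    def row(t):
        return [1.0, t, t**2, t**3]

    a = np.array(
        [
            row(t_zero_low),
            row(t_zero_high),
            [0.0, 1.0, 2.0 * t_gmax, 3.0 * t_gmax**2],
            row(t_gmax),
        ]
    )
    b = np.array([0.0, 0.0, 0.0, 1.0])
    coeffs = np.linalg.solve(a, b)
    return GrowthCurve(coeffs, t_gmax, t_zero_low, t_zero_high)


def fit_growth_curve(
    clim: Climatology,
    delta_low: float = 5.0,
    delta_high: float = 5.0,
    sd_mult: float = 2.0,
) -> GrowthCurve:
    """Fit the site cubic from a climatology.

    Anchors: peak at ``clim_max − sd_mult·clim_sd``; zeros at
    ``clim_min − delta_low`` and ``clim_max + delta_high``.
    """
    if clim.clim_sd == 0:
        raise DegenerateInputError(
            "climatology has zero seasonal spread; peak placement degenerate"
        )
    return _fit_from_anchors(
        t_zero_low=clim.clim_min - delta_low,
        t_zero_high=clim.clim_max + delta_high,
        t_gmax=clim.clim_max - sd_mult * clim.clim_sd,
    )


def relative_growth(curve: GrowthCurve, t, floor: float = -1.0):
    """Evaluate the cubic at temperature ``t`` (°C), floored below.

    Negative values (net decline beyond the zero-growth temperatures) are
    permitted down to ``floor``.
    """
    return np.maximum(curve(t), floor)


def perturb_growth_curve(
    clim: Climatology,
    seed: int | np.random.Generator = 0,
    delta_low: float = 5.0,
    delta_high: float = 5.0,
    sd_mult: float = 2.0,
) -> GrowthCurve:
    """Randomly perturb the curve anchors and refit.

    Both zero-growth temperatures are shifted by independent U(−0.5, 0.5)
    draws and the peak temperature by U(0, 2) warmward, then the cubic is
    refit.  An infeasible draw raises with the drawn anchors attached —
    callers decide whether to log and skip (no silent retry).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    d_lo = rng.uniform(-0.5, 0.5)
    d_hi = rng.uniform(-0.5, 0.5)
    d_peak = rng.uniform(0.0, 2.0)
    if clim.clim_sd == 0:
        raise DegenerateInputError("climatology has zero seasonal spread")
    return _fit_from_anchors(
        t_zero_low=clim.clim_min - delta_low + d_lo,
        t_zero_high=clim.clim_max + delta_high + d_hi,
        t_gmax=clim.clim_max - sd_mult * clim.clim_sd + d_peak,
    )
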