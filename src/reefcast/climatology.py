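"""Monthly SST records, climatological statistics and the bleaching threshold.

The monthly sea-surface temperature series is the common currency between
every stage of the pipeline: generators emit it, the downscaler transforms
it, and the cover model consumes it.  A :class:`Climatology` summarises a
reference period of such a series per calendar month; it anchors both the
temperature–growth curve and the bleaching threshold (the maximum
climatological monthly mean plus a fixed offset, conventionally 1 °C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError

__all__ = [
    "MonthlySeries",
    "Climatology",
    "read_sst",
    "write_sst",
    "monthly_climatology",
    "bleaching_threshold",
]


@dataclass(frozen=True)
class MonthlySeries:
    """A gap-free, calendar-ordered monthly temperature record.

    Parameters
    ----------
    year, month : ndarray of int
        Calendar coordinates; months run 1–12 with no gaps or duplicates.
    sst : ndarray of float
        Sea-surface temperature in °C.
    """

    year: np.ndarray
    month: np.ndarray
    sst: np.ndarray

    def __post_init__(self):
        year = np.asarray(self.year, dtype=int)
        month = np.asarray(self.month, dtype=int)
        sst = np.asarray(self.sst, dtype=float)
        object.__setattr__(self, "year", year)
        object.__setattr__(self, "month", month)
        object.__setattr__(self, "sst", sst)
        if not (len(year) == len(month) == len(sst)):
            raise FormatError("year, month and sst must have equal length")
        if len(year) == 0:
            raise FormatError("empty series")
        if month.min() < 1 or month.max() > 12:
            raise FormatError("month values must lie in 1..12")
        if np.any(~np.isfinite(sst)):
            bad = int(np.flatnonzero(~np.isfinite(sst))[0])
            raise FormatError(
                f"missing value at {year[bad]:04d}-{month[bad]:02d}"
            )
        # enforce contiguous monthly sampling
        idx = year * 12 + (month - 1)
        order = np.argsort(idx, kind="stable")
        idx = idx[order]
        steps = np.diff(idx)
        if np.any(steps == 0):
            bad = int(np.flatnonzero(steps == 0)[0])
            y, m = divmod(int(idx[bad]), 12)
            raise FormatError(f"duplicate month {y:04d}-{m + 1:02d}")
        if np.any(steps > 1):
            bad = int(np.flatnonzero(steps > 1)[0])
            y, m = divmod(int(idx[bad]) + 1, 12)
            raise FormatError(f"gap at {y:04d}-{m + 1:02d}")
        object.__setattr__(self, "year", year[order])
        object.__setattr__(self, "month", month[order])
        object.__setattr__(self, "sst", sst[order])

    def __len__(self) -> int:
        return len(self.sst)

    @property
    def frac_year(self) -> np.ndarray:
        """Fractional-year time axis with months at their midpoints."""
        return self.year + (self.month - 0.5) / 12.0

    @property
    def years(self) -> np.ndarray:
        """Distinct calendar years, ascending."""
        return np.unique(self.year)

    def window(self, start_year: int, end_year: int) -> "MonthlySeries":
        """Sub-series restricted to ``start_year <= year <= end_year``."""
        keep = (self.year >= start_year) & (self.year <= end_year)
        if not keep.any():
            raise InsufficientDataError(
                f"no records in window {start_year}-{end_year}"
            )
        return MonthlySeries(self.year[keep], self.month[keep], self.sst[keep])

    def with_sst(self, sst: np.ndarray) -> "MonthlySeries":
        """Copy of the series with replaced temperature values."""
        return MonthlySeries(self.year.copy(), self.month.copy(), np.asarray(sst, float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.year, "month": self.month, "sst_c": self.sst}
        )

    def annual_means(self) -> pd.Series:
        """Mean SST per calendar year (partial years included as-is)."""
        return self.to_frame().groupby("year")["sst_c"].mean()


@dataclass(frozen=True)
class Climatology:
    """Per-calendar-month reference statistics of a monthly SST record.

    ``clim_sd`` is the standard deviation of the 12 climatological monthly
    means (the spread of the mean seasonal cycle), which is the quantity
    used to position the temperature of maximum coral growth.  The
    alternative reading — interannual SD of the warmest calendar month —
    is available as ``monthly_sd[argmax(monthly_mean)]``.
    """

    monthly_mean: np.ndarray
    monthly_sd: np.ndarray
    ref_period: tuple[int, int]
    n_years: int = field(default=0)

    @property
    def clim_max(self) -> float:
        return float(np.max(self.monthly_mean))

    @property
    def clim_min(self) -> float:
        return float(np.min(self.monthly_mean))

    @property
    def clim_sd(self) -> float:
        return float(np.std(self.monthly_mean))

    @property
    def annual_mean(self) -> float:
        return float(np.mean(self.monthly_mean))

    @property
    def seasonal_anomaly(self) -> np.ndarray:
        """Monthly means with the annual mean removed (zero-mean cycle)."""
        return self.monthly_mean - self.annual_mean


def read_sst(path: str | Path, format: str | None = None) -> MonthlySeries:
    """Read a monthly SST record from CSV (``year,month,sst_c``) or NetCDF.

    NetCDF files are decoded via xarray (scipy backend, classic format);
    the temperature variable may be named ``tos`` or ``sst`` and the time
    axis must be CF-decodable to calendar months.
    """
    path = Path(path)
    if format is None:
        format = "netcdf" if path.suffix in {".nc", ".cdf", ".nc4"} else "csv"
    if format == "csv":
        df = pd.read_csv(path)
        required = {"year", "month", "sst_c"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        return MonthlySeries(
            df["year"].to_numpy(), df["month"].to_numpy(), df["sst_c"].to_numpy()
        )
    if format == "netcdf":
        import xarray as xr

        with xr.open_dataset(path) as ds:
            name = next((v for v in ("tos", "sst", "sst_c") if v in ds), None)
            if name is None:
                raise FormatError(f"{path}: no 'tos' or 'sst' variable found")
            da = ds[name].squeeze()
            times = pd.DatetimeIndex(da["time"].values)
            return MonthlySeries(
                times.year.to_numpy(), times.month.to_numpy(), da.values
            )
    raise FormatError(f"unknown format {format!r}")


def write_sst(series: MonthlySeries, path: str | Path, format: str | None = None) -> None:
    """Write a monthly SST record as CSV or CF-style NetCDF (variable ``tos``)."""
    path = Path(path)
    if format is None:
        format = "netcdf" if path.suffix in {".nc", ".cdf", ".nc4"} else "csv"
    if format == "csv":
        series.to_frame().to_csv(path, index=False)
        return
    if format == "netcdf":
        import xarray as xr

        time = pd.to_datetime(
            {"year": series.year, "month": series.month, "day": 15}
        )
        da = xr.DataArray(
            series.sst,
            dims=("time",),
            coords={"time": time},
            name="tos",
            attrs={"units": "degC", "standard_name": "sea_surface_temperature"},
        )
        da.to_dataset().to_netcdf(path, engine="scipy")
        return
    raise FormatError(f"unknown format {format!r}")


def monthly_climatology(
    series: MonthlySeries, ref_period: tuple[int, int] | None = None
) -> Climatology:
    """Per-calendar-month mean and interannual SD over a reference period.

    The reference period defaults to the full record.  At least two
    complete years inside the window are required so every calendar month
    has an interannual sample.
    """
    if ref_period is None:
        ref_period = (int(series.year.min()), int(series.year.max()))
    sub = series.window(*ref_period)
    df = sub.to_frame()
    counts = df.groupby("year")["month"].count()
    full_years = int((counts == 12).sum())
    if full_years < 2:
        raise InsufficientDataError(
            f"reference period {ref_period} holds {full_years} full years; need >= 2"
        )
    grouped = df.groupby("month")["sst_c"]
    mean = grouped.mean().reindex(range(1, 13)).to_numpy()
    sd = grouped.std(ddof=1).reindex(range(1, 13)).to_numpy()
    return Climatology(
        monthly_mean=mean, monthly_sd=sd, ref_period=ref_period, n_years=full_years
    )


def bleaching_threshold(clim: Climatology, offset: float = 1.0) -> float:
    """Bleaching threshold: maximum climatological monthly mean + ``offset`` °C."""
    return clim.clim_max + offset
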