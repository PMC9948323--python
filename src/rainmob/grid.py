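"""Regular lon/lat daily-precipitation grid.

The container deliberately stays close to what a CHIRPS-style raster stack
looks like after extraction: a rectangular lon/lat lattice with one rainfall
depth (mm) per cell per calendar day, no gaps. Values are dense numpy arrays;
I/O round-trips through a long-format CSV (cell_id, date, mm) and, for
interoperability, an xarray ``DataArray``/NetCDF file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RainGrid:
    """Daily rainfall on a regular lon/lat grid.

    Parameters
    ----------
    lon_axis, lat_axis
        Cell-center coordinates (decimal degrees), strictly increasing,
        constant spacing along each axis.
    dates
        Consecutive calendar days (``datetime64[D]``), no gaps.
    values
        Rainfall depth in mm, shape ``(n_lat, n_lon, n_days)``, all >= 0.
    """

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    dates: np.ndarray
    values: np.ndarray
    _start: np.datetime64 = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.lat_axis.size, self.lon_axis.size, self.dates.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(n_lat={self.lat_axis.size}, n_lon={self.lon_axis.size}, "
                f"n_days={self.dates.size})"
            )
        for name, ax in (("lon_axis", self.lon_axis), ("lat_axis", self.lat_axis)):
            if ax.size > 1:
                steps = np.diff(ax)
                if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                    raise ValueError(f"{name} must be strictly increasing with constant spacing")
        day_gaps = np.diff(self.dates).astype("timedelta64[D]").astype(int)
        if self.dates.size > 1 and not np.all(day_gaps == 1):
            raise ValueError("dates must be consecutive calendar days with no gaps")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("rainfall values must be finite and non-negative")
        self._start = self.dates[0]

    # -- basic geometry -------------------------------------------------

    @property
    def n_days(self) -> int:
        return int(self.dates.size)

    @property
    def start_date(self) -> np.datetime64:
        return self._start

    @property
    def end_date(self) -> np.datetime64:
        """Last covered day (inclusive)."""
        return self.dates[-1]

    @property
    def lon_spacing(self) -> float:
        return float(self.lon_axis[1] - self.lon_axis[0]) if self.lon_axis.size > 1 else 0.0

    @property
    def lat_spacing(self) -> float:
        return float(self.lat_axis[1] - self.lat_axis[0]) if self.lat_axis.size > 1 else 0.0

    def contains(self, lon: float, lat: float) -> bool:
        """Whether a point lies inside the grid's bounding box of cell centers."""
        return bool(
            self.lon_axis[0] <= lon <= self.lon_axis[-1]
            and self.lat_axis[0] <= lat <= self.lat_axis[-1]
        )

    def day_index(self, date) -> int:
        """Index of a calendar day into the time axis (may be out of range)."""
        return int((np.datetime64(pd.Timestamp(date).date(), "D") - self._start).astype(int))

    def cell_id(self, ilat: int, ilon: int) -> str:
        return f"c{ilat:03d}_{ilon:03d}"

    def series(self, ilat: int, ilon: int) -> np.ndarray:
        """Daily series for one cell, shape (n_days,)."""
        return self.values[ilat, ilon, :]

    # -- I/O -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cell_id, lon, lat, date, mm."""
        nlat, nlon, nd = self.values.shape
        ilat, ilon = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
        ids = np.array([self.cell_id(a, o) for a, o in zip(ilat.ravel(), ilon.ravel())])
        return pd.DataFrame(
            {
                "cell_id": np.repeat(ids, nd),
                "lon": np.repeat(self.lon_axis[ilon.ravel()], nd),
                "lat": np.repeat(self.lat_axis[ilat.ravel()], nd),
                "date": np.tile(self.dates, nlat * nlon),
                "mm": self.values.reshape(-1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RainGrid":
        lon_axis = np.unique(df["lon"].to_numpy())
        lat_axis = np.unique(df["lat"].to_numpy())
        dates = np.unique(df["date"].to_numpy().astype("datetime64[D]"))
        pivot = df.sort_values(["lat", "lon", "date"])
        values = pivot["mm"].to_numpy().reshape(lat_axis.size, lon_axis.size, dates.size)
        return cls(lon_axis, lat_axis, dates, values)

    @classmethod
    def from_csv(cls, path) -> "RainGrid":
        return cls.from_frame(pd.read_csv(path, parse_dates=["date"]))

    def to_xarray(self):
        import xarray as xr

        return xr.DataArray(
            self.values,
            coords={"lat": self.lat_axis, "lon": self.lon_axis, "time": self.dates},
            dims=("lat", "lon", "time"),
            name="precip_mm",
        )

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "RainGrid":
        import xarray as xr

        da = xr.open_dataset(path, engine="scipy")["precip_mm"]
        return cls(
            da["lon"].to_numpy(),
            da["lat"].to_numpy(),
            da["time"].to_numpy().astype("datetime64[D]"),
            da.transpose("lat", "lon", "time").to_numpy(),
        )
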