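"""Gridded climate/elevation covariates and their extraction at sites.

Covariate layers are regular lon/lat lattices (cell-center registration),
one layer per variable per palaeoclimate time step.  Each time bin maps to
the simulation time step closest to the bulk of its data; elevation is a
single time-invariant layer.  Extraction is bilinear by default (cells are
coarse relative to site-location precision), nearest-neighbour by flag.

Layers are carried as thin dataclasses convertible to/from
``xarray.DataArray``; on-disk formats are netCDF (scipy backend) and
long-format CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats import pearsonr

__all__ = [
    "CLIMATE_VARIABLES",
    "DEFAULT_TIME_STEP_MAP",
    "ClimateRaster",
    "select_time_step",
    "sample_raster",
    "build_covariate_table",
    "correlate_covariates",
    "BIOCLIM_VARIABLES",
]

#: Controlled vocabulary: five bioclimatic variables plus elevation.
BIOCLIM_VARIABLES = ("MAT", "MAP", "temp.warm", "precip.warm", "precip.cold")
CLIMATE_VARIABLES = BIOCLIM_VARIABLES + ("elevation",)

#: Bin name -> climate-simulation time step (years BP).
DEFAULT_TIME_STEP_MAP: dict[str, int] = {
    "EH": 11_000,
    "YD": 12_000,
    "LGI": 14_000,
    "LGT": 15_000,
    "LGM": 24_000,
    "LOIS3": 36_000,
    "EOIS3": 42_000,
}


@dataclass
class ClimateRaster:
    """One variable at one time step on a regular lon/lat lattice.

    ``lon`` and ``lat`` are strictly increasing cell-center coordinates;
    ``values`` has shape (len(lat), len(lon)); missing data is NaN.
    ``time_step`` is years BP, or "modern" for time-invariant layers.
    """

    variable: str
    time_step: int | str
    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.variable not in CLIMATE_VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}; expected one of {CLIMATE_VARIABLES}")
        if np.any(np.diff(self.lon) <= 0) or np.any(np.diff(self.lat) <= 0):
            raise ValueError("raster coordinates must be strictly increasing")
        if self.values.shape != (len(self.lat), len(self.lon)):
            raise ValueError("values shape must be (n_lat, n_lon)")

    @property
    def resolution(self) -> float:
        return float(np.diff(self.lon).mean())

    def to_xarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            coords={"lat": self.lat, "lon": self.lon},
            dims=("lat", "lon"),
            name=self.variable,
            attrs={"time_step": str(self.time_step)},
        )

    @classmethod
    def from_xarray(cls, da: xr.DataArray, variable: str | None = None,
                    time_step: int | str | None = None) -> "ClimateRaster":
        lat = np.asarray(da["lat"])
        lon = np.asarray(da["lon"])
        vals = np.asarray(da)
        if lat[0] > lat[-1]:
            lat, vals = lat[::-1], vals[::-1]
        if lon[0] > lon[-1]:
            lon, vals = lon[::-1], vals[:, ::-1]
        ts = time_step if time_step is not None else da.attrs.get("time_step", "modern")
        if isinstance(ts, str) and ts.isdigit():
            ts = int(ts)
        return cls(variable or str(da.name), ts, lon, lat, vals)

    def write_netcdf(self, path: str | Path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")

    @classmethod
    def read_netcdf(cls, path: str | Path, variable: str | None = None) -> "ClimateRaster":
        with xr.open_dataset(path, engine="scipy") as ds:
            name = variable or list(ds.data_vars)[0]
            return cls.from_xarray(ds[name].load(), variable=name)


def select_time_step(bin_name: str, tmap: dict[str, int] | None = None) -> int:
    """Climate-simulation time step (years BP) mapped to a time bin."""
    tmap = tmap if tmap is not None else DEFAULT_TIME_STEP_MAP
    if bin_name not in tmap:
        raise KeyError(f"no climate time step mapped for bin {bin_name!r}")
    return tmap[bin_name]


def sample_raster(raster: ClimateRaster, lon: float, lat: float,
                  method: str = "bilinear") -> float:
    """Sample one raster at a point; NaN neighbours propagate under bilinear.

    Bounds are the lattice extent plus half a cell on each side (the true
    footprint of the edge cells).  Out-of-bounds points raise.
    """
    res_x = float(np.diff(raster.lon).mean())
    res_y = float(np.diff(raster.lat).mean())
    if not (raster.lon[0] - res_x / 2 <= lon <= raster.lon[-1] + res_x / 2) or not (
        raster.lat[0] - res_y / 2 <= lat <= raster.lat[-1] + res_y / 2
    ):
        raise ValueError(
            f"point (lon={lon}, lat={lat}) outside raster bounds for {raster.variable}"
        )
    if method == "nearest":
        i = int(np.argmin(np.abs(raster.lat - lat)))
        j = int(np.argmin(np.abs(raster.lon - lon)))
        return float(raster.values[i, j])
    if method != "bilinear":
        raise ValueError(f"unknown sampling method {method!r}")
    # clamp to the hull of cell centers; edge cells extend flat to the bound
    x = np.clip(lon, raster.lon[0], raster.lon[-1])
    y = np.clip(lat, raster.lat[0], raster.lat[-1])
    j1 = int(np.clip(np.searchsorted(raster.lon, x), 1, len(raster.lon) - 1))
    i1 = int(np.clip(np.searchsorted(raster.lat, y), 1, len(raster.lat) - 1))
    j0, i0 = j1 - 1, i1 - 1
    tx = (x - raster.lon[j0]) / (raster.lon[j1] - raster.lon[j0])
    ty = (y - raster.lat[i0]) / (raster.lat[i1] - raster.lat[i0])
    v = raster.values
    val = (
        v[i0, j0] * (1 - tx) * (1 - ty)
        + v[i0, j1] * tx * (1 - ty)
        + v[i1, j0] * (1 - tx) * ty
        + v[i1, j1] * tx * ty
    )
    return float(val)


def build_covariate_table(
    sites: pd.DataFrame,
    bins: list[str],
    rasters: dict[tuple[str, int | str], ClimateRaster],
    tmap: dict[str, int] | None = None,
    method: str = "bilinear",
) -> pd.DataFrame:
    """One row per site x bin with the five bioclim variables + elevation.

    ``sites`` needs columns site_id, lon, lat.  Rasters are keyed by
    (variable, time_step); elevation by (``"elevation"``, ``"modern"``).
    Missing required rasters raise with the full list of gaps; a site on a
    missing-data cell yields a flagged (``complete = False``) row, never a
    silent drop.  Provenance columns record the time step used.
    """
    tmap = tmap if tmap is not None else DEFAULT_TIME_STEP_MAP
    gaps = []
    for b in bins:
        step = select_time_step(b, tmap)
        for v in BIOCLIM_VARIABLES:
            if (v, step) not in rasters:
                gaps.append(f"{v} @ {step}")
    if ("elevation", "modern") not in rasters:
        gaps.append("elevation @ modern")
    if gaps:
        raise ValueError("missing raster(s): " + ", ".join(sorted(set(gaps))))

    rows = []
    for b in bins:
        step = select_time_step(b, tmap)
        for _, s in sites.iterrows():
            row = {
                "site_id": s["site_id"],
                "bin": b,
                "lon": float(s["lon"]),
                "lat": float(s["lat"]),
                "time_step": step,
            }
            for v in BIOCLIM_VARIABLES:
                row[v] = sample_raster(rasters[(v, step)], row["lon"], row["lat"], method)
            row["elevation"] = sample_raster(
                rasters[("elevation", "modern")], row["lon"], row["lat"], method
            )
            row["complete"] = all(
                np.isfinite(row[v]) for v in CLIMATE_VARIABLES
            )
            rows.append(row)
    return pd.DataFrame(rows)


def correlate_covariates(
    site_means: pd.DataFrame,
    covariates: pd.DataFrame,
    variables: tuple[str, ...] = CLIMATE_VARIABLES,
) -> pd.DataFrame:
    """Pearson r of site-mean δ15N against each covariate, per bin.

    ``site_means`` needs site_id, bin, mean_d15N.  Complete cases only;
    entries with fewer than 3 pairs or a zero-variance covariate are marked
    not computable (NaN r/p with a note).
    """
    merged = site_means.merge(covariates, on=["site_id", "bin"], how="inner")
    rows = []
    for b, g in merged.groupby("bin", sort=True):
        for v in variables:
            sub = g[["mean_d15N", v]].dropna()
            note = ""
            r = p = np.nan
            if len(sub) < 3:
                note = "fewer than 3 complete pairs"
            elif sub[v].nunique() == 1 or sub["mean_d15N"].nunique() == 1:
                note = "zero variance"
            else:
                r, p = pearsonr(sub["mean_d15N"], sub[v])
            rows.append({"bin": b, "variable": v, "n": len(sub),
                         "pearson_r": float(r), "p_value": float(p), "note": note})
    return pd.DataFrame(rows)
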