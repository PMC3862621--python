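"""Monthly sowing-suitability mapping.

A fitted germination model is applied cell-wise to gridded monthly mean
daily minimum/maximum temperatures: the monthly mean minimum plays the cool
(16 h) temperature and the monthly mean maximum the warm (8 h) temperature.
The result is a suitability raster of predicted germination percentages in
[0, 100].  A synthetic climate generator (sinusoidal annual cycle with a
latitude-dependent mean) stands in for observational temperature grids.

Grids are cell-centered regular lat/lon meshes; I/O supports the ESRI ASCII
grid dialect (row order north -> south, nodata -9999) and a long CSV format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NODATA",
    "ClimateGrid",
    "SuitabilityMap",
    "synth_climate",
    "map_suitability",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_climate_csv",
    "read_climate_csv",
    "render_map",
    "render_surface_contour",
]

NODATA = -9999.0
MONTHS = tuple(range(1, 13))


def _check_mesh(lats, lons):
    lats, lons = np.asarray(lats, float), np.asarray(lons, float)
    for name, ax in (("lats", lats), ("lons", lons)):
        if ax.ndim != 1 or ax.size < 1 or (ax.size > 1 and np.any(np.diff(ax) <= 0)):
            raise ValueError(f"{name} must be a strictly increasing 1-D axis")
    return lats, lons


@dataclass
class ClimateGrid:
    """Monthly mean daily min/max temperature rasters on a regular mesh.

    ``tmin``/``tmax`` have shape (12, nlat, nlon), months January..December;
    axes are cell-center coordinates, strictly increasing.
    """

    lats: np.ndarray
    lons: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.lats, self.lons = _check_mesh(self.lats, self.lons)
        self.tmin = np.asarray(self.tmin, float)
        self.tmax = np.asarray(self.tmax, float)
        shape = (12, self.lats.size, self.lons.size)
        if self.tmin.shape != shape or self.tmax.shape != shape:
            raise ValueError(f"tmin/tmax must have shape {shape}")
        valid = (self.tmin != self.nodata) & (self.tmax != self.nodata)
        if np.any(self.tmin[valid] > self.tmax[valid]):
            raise ValueError("tmin exceeds tmax at some cell")

    def month_layers(self, month: int) -> tuple[np.ndarray, np.ndarray]:
        if month not in MONTHS:
            raise ValueError(f"month must be in 1..12, got {month}")
        return self.tmin[month - 1], self.tmax[month - 1]

    def subset(self, lat_slice: slice, lon_slice: slice) -> "ClimateGrid":
        return ClimateGrid(
            self.lats[lat_slice], self.lons[lon_slice],
            self.tmin[:, lat_slice, lon_slice], self.tmax[:, lat_slice, lon_slice],
            nodata=self.nodata,
        )


@dataclass
class SuitabilityMap:
    """Predicted germination-percentage raster for one month."""

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray  # (nlat, nlon), % in [0, 100] or nodata
    month: int
    nodata: float = NODATA
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lats, self.lons = _check_mesh(self.lats, self.lons)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.lats.size, self.lons.size):
            raise ValueError("values shape does not match mesh")
        valid = self.values != self.nodata
        if np.any((self.values[valid] < 0) | (self.values[valid] > 100)):
            raise ValueError("suitability values outside [0, 100]")

    def subset(self, lat_slice: slice, lon_slice: slice) -> "SuitabilityMap":
        return SuitabilityMap(
            self.lats[lat_slice], self.lons[lon_slice],
            self.values[lat_slice, lon_slice], self.month,
            nodata=self.nodata, provenance=dict(self.provenance),
        )


def synth_climate(
    bbox: tuple[float, float, float, float] = (100.0, 20.0, 120.0, 50.0),
    resolution: float = 1.0,
    seed: int = 0,
    amplitude: float = 12.0,
    base_temp: float = 32.0,
    base_gradient: float = 0.55,
    diurnal_range: float = 10.0,
    noise_sd: float = 0.5,
) -> ClimateGrid:
    """Synthetic monthly climate grid with a sinusoidal annual cycle.

    ``bbox`` is (lon_min, lat_min, lon_max, lat_max) in decimal degrees;
    the monthly mean maximum at latitude φ is
    base_temp − base_gradient·|φ| + amplitude·cos(2π(m − m_peak)/12) + noise,
    with the warm peak in July north of the equator and January south of it;
    the monthly mean minimum is ``diurnal_range`` below the maximum.  Noise
    never violates tmin ≤ tmax (the range is applied after noise).
    """
    lon_min, lat_min, lon_max, lat_max = bbox
    if not (lon_max > lon_min and lat_max > lat_min and resolution > 0):
        raise ValueError("invalid bbox or resolution")
    if diurnal_range < 0:
        raise ValueError("diurnal_range must be >= 0")
    lats = np.arange(lat_min + resolution / 2, lat_max, resolution)
    lons = np.arange(lon_min + resolution / 2, lon_max, resolution)
    rng = np.random.default_rng(seed)
    months = np.arange(1, 13, dtype=float)
    peak = np.where(lats >= 0, 7.0, 1.0)  # (nlat,)
    annual_mean = base_temp - base_gradient * np.abs(lats)  # (nlat,)
    cycle = amplitude * np.cos(
        2.0 * np.pi * (months[:, None] - peak[None, :]) / 12.0
    )  # (12, nlat)
    tmax = (annual_mean[None, :] + cycle)[:, :, None] * np.ones(lons.size)
    tmax = tmax + rng.normal(0.0, noise_sd, size=tmax.shape) if noise_sd > 0 else tmax
    tmin = tmax - diurnal_range
    return ClimateGrid(lats=lats, lons=lons, tmin=tmin, tmax=tmax)


def map_suitability(model, grid: ClimateGrid, month: int) -> SuitabilityMap:
    """Evaluate a fitted model over one month's (tmin, tmax) layers.

    ``model`` is any object with ``predict(cool, warm)`` returning fractions
    (a polynomial surface or a trained network).  tmin plays the cool (16 h)
    temperature, tmax the warm (8 h) one; predictions are clamped to [0, 1]
    and scaled to %.  Cells outside the 5–40 °C calibration range are counted
    in provenance as extrapolated.
    """
    tmin, tmax = grid.month_layers(month)
    valid = (tmin != grid.nodata) & (tmax != grid.nodata)
    values = np.full(tmin.shape, grid.nodata, float)
    if np.any(valid):
        frac = np.clip(
            np.asarray(model.predict(tmin[valid], tmax[valid]), float), 0.0, 1.0
        )
        values[valid] = 100.0 * frac
    extrapolated = int(np.sum(valid & ((tmax < 5.0) | (tmin > 40.0))))
    provenance = {
        "model": getattr(model, "cultivar", None) or type(model).__name__,
        "backend": getattr(model, "backend", None),
        "month": month,
        "clamped_to": [0.0, 100.0],
        "extrapolated_cells": extrapolated,
    }
    return SuitabilityMap(grid.lats.copy(), grid.lons.copy(), values, month,
                          nodata=grid.nodata, provenance=provenance)


# ---------------------------------------------------------------------------
# grid I/O


def write_ascii_grid(path, lats, lons, values, nodata: float = NODATA) -> None:
    """Write one layer as an ESRI ASCII grid (north -> south row order,
    cell-centered header, 6-decimal values)."""
    lats, lons = _check_mesh(lats, lons)
    values = np.asarray(values, float)
    dlat = lats[1] - lats[0] if lats.size > 1 else 1.0
    dlon = lons[1] - lons[0] if lons.size > 1 else dlat
    if lats.size > 1 and lons.size > 1 and not np.isclose(dlat, dlon):
        raise ValueError("ASCII grid requires square cells")
    cell = dlon
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {lons.size}\n")
        fh.write(f"nrows {lats.size}\n")
        fh.write(f"xllcorner {lons[0] - cell / 2:.6f}\n")
        fh.write(f"yllcorner {lats[0] - cell / 2:.6f}\n")
        fh.write(f"cellsize {cell:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in values[::-1]:  # north first
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (lats, lons, values, nodata) with
    south -> north (increasing) latitude order."""
    with open(path, encoding="utf-8") as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        cell = header["cellsize"]
        rows = []
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            vals = line.split()
            if len(vals) != ncols:
                raise ValueError(
                    f"row {i + 1}: expected {ncols} columns, got {len(vals)}"
                )
            rows.append([float(v) for v in vals])
    if len(rows) != nrows:
        raise ValueError(f"expected {nrows} rows, got {len(rows)}")
    values = np.asarray(rows)[::-1]  # back to south -> north
    lons = header["xllcorner"] + cell / 2 + cell * np.arange(ncols)
    lats = header["yllcorner"] + cell / 2 + cell * np.arange(nrows)
    return lats, lons, values, header["nodata_value"]


def write_climate_csv(grid: ClimateGrid, path) -> None:
    """Write all 12 months as long CSV: lat,lon,month,tmin,tmax (6 decimals)."""
    lat_g, lon_g = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    frames = []
    for m in MONTHS:
        tmin, tmax = grid.month_layers(m)
        frames.append(pd.DataFrame({
            "lat": lat_g.ravel(), "lon": lon_g.ravel(),
            "month": m, "tmin": tmin.ravel(), "tmax": tmax.ravel(),
        }))
    pd.concat(frames).to_csv(path, index=False, float_format="%.6f")


def read_climate_csv(path) -> ClimateGrid:
    """Read a long-format climate CSV back into a :class:`ClimateGrid`."""
    df = pd.read_csv(path)
    required = {"lat", "lon", "month", "tmin", "tmax"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns {sorted(missing)}")
    present = sorted(int(m) for m in df["month"].unique())
    if present != list(MONTHS):
        raise ValueError(f"climate CSV must hold months 1..12, found {present}")
    lats = np.array(sorted(df["lat"].unique()))
    lons = np.array(sorted(df["lon"].unique()))
    shape = (12, lats.size, lons.size)
    tmin = np.full(shape, NODATA)
    tmax = np.full(shape, NODATA)
    lat_idx = {v: i for i, v in enumerate(lats)}
    lon_idx = {v: i for i, v in enumerate(lons)}
    for row in df.itertuples(index=False):
        i, j = lat_idx[row.lat], lon_idx[row.lon]
        tmin[int(row.month) - 1, i, j] = row.tmin
        tmax[int(row.month) - 1, i, j] = row.tmax
    return ClimateGrid(lats=lats, lons=lons, tmin=tmin, tmax=tmax)


# ---------------------------------------------------------------------------
# rendering

_MONTH_NAMES = ("January", "February", "March", "April", "May", "June", "July",
                "August", "September", "October", "November", "December")


def render_map(smap: SuitabilityMap, path) -> None:
    """Render a suitability raster as a PNG with a fixed 0–100 % scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.ma.masked_equal(smap.values, smap.nodata)
    fig, ax = plt.subplots(figsize=(6, 5))
    extent = [smap.lons[0], smap.lons[-1], smap.lats[0], smap.lats[-1]]
    im = ax.imshow(values, origin="lower", extent=extent, vmin=0, vmax=100,
                   cmap="RdYlGn", aspect="auto")
    fig.colorbar(im, ax=ax, label="Germination suitability (%)")
    ax.set_xlabel("Longitude (°E)")
    ax.set_ylabel("Latitude (°N)")
    ax.set_title(f"{_MONTH_NAMES[smap.month - 1]}")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_surface_contour(model, path, lo: float = 5.0, hi: float = 40.0) -> None:
    """Contour plot of a fitted surface over the cool <= warm triangle."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    axis = np.linspace(lo, hi, 71)
    cool, warm = np.meshgrid(axis, axis, indexing="ij")
    z = 100.0 * np.clip(np.asarray(model.predict(cool.ravel(), warm.ravel())),
                        0, 1).reshape(cool.shape)
    z = np.ma.masked_where(cool > warm, z)
    fig, ax = plt.subplots(figsize=(6, 5))
    cs = ax.contourf(cool, warm, z, levels=np.linspace(0, 100, 11), cmap="RdYlGn")
    fig.colorbar(cs, ax=ax, label="Predicted germination (%)")
    ax.set_xlabel("Cool-period temperature (°C, 16 h)")
    ax.set_ylabel("Warm-period temperature (°C, 8 h)")
    fig.savefig(path, dpi=100)
    plt.close(fig)
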