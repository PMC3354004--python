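"""Co-location of tracks with chlorophyll, thermocline and nutricline fields.

The thermocline depth is the depth of the maximum vertical temperature
gradient (assigned to the midpoint of the discrete layer, shallow tie-break);
the nutricline is proxied by the depth where nitrate crosses a threshold
(2 µmol by default), linearly interpolated between standard depth levels.
Chlorophyll is sampled from 8-day composites at the nearest fine-grid cell,
with a bounded ring search around cloud gaps. Dive summaries are binned
against latitude in 1° bins together with the mean thermocline/nutricline
depth of the climatology cells traversed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "thermocline_depth",
    "nutricline_depth",
    "thermocline_depth_grid",
    "nutricline_depth_grid",
    "sample_chl",
    "sample_chl_track",
    "chl_summary",
    "bin_dive_depths",
]


# ---------------------------------------------------------------------------
# profile analyzers
# ---------------------------------------------------------------------------

def thermocline_depth(depths, temperatures) -> float:
    """Depth (m) of the maximum |dT/dz|, at the layer midpoint.

    Ties break toward the shallower layer; an isothermal profile returns NaN
    (undefined).
    """
    z = np.asarray(depths, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    if z.size < 3:
        raise ValueError("profile needs at least 3 depth levels")
    if np.any(np.diff(z) <= 0):
        raise ValueError("depths must be strictly increasing")
    if not np.all(np.isfinite(t)):
        raise ValueError("temperatures must be finite")
    grad = np.abs(np.diff(t) / np.diff(z))
    if np.all(grad == 0.0):
        return float("nan")
    k = int(np.argmax(grad))           # argmax returns the first (shallowest)
    return float(0.5 * (z[k] + z[k + 1]))


def nutricline_depth(depths, nitrate, threshold: float = 2.0) -> float:
    """Shallowest depth (m) where nitrate crosses ``threshold`` µmol.

    Linear interpolation between bracketing levels; 0 if the surface value
    is already at/above the threshold; NaN if never reached.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(depths, dtype=float)
    n = np.asarray(nitrate, dtype=float)
    if not np.all(np.isfinite(n)):
        raise ValueError("nitrate must be finite")
    if n[0] >= threshold:
        return 0.0
    above = np.nonzero(n >= threshold)[0]
    if above.size == 0:
        return float("nan")
    k = int(above[0])
    frac = (threshold - n[k - 1]) / (n[k] - n[k - 1])
    return float(z[k - 1] + frac * (z[k] - z[k - 1]))


def thermocline_depth_grid(climatology: xr.Dataset) -> xr.DataArray:
    """Thermocline depth at every climatology cell (vectorized)."""
    z = climatology["depth"].to_numpy()
    t = climatology["temperature"].to_numpy()      # (depth, lat, lon)
    grad = np.abs(np.diff(t, axis=0) / np.diff(z)[:, None, None])
    k = np.argmax(grad, axis=0)
    mids = 0.5 * (z[:-1] + z[1:])
    out = mids[k].astype(float)
    out[np.all(grad == 0.0, axis=0)] = np.nan
    return xr.DataArray(out, coords={"lat": climatology["lat"],
                                     "lon": climatology["lon"]},
                        dims=("lat", "lon"), name="thermocline_depth")


def nutricline_depth_grid(climatology: xr.Dataset,
                          threshold: float = 2.0) -> xr.DataArray:
    """Nutricline depth at every climatology cell (vectorized)."""
    z = climatology["depth"].to_numpy()
    n = climatology["nitrate"].to_numpy()
    nz, ny, nx = n.shape
    flat = n.reshape(nz, -1)
    out = np.full(flat.shape[1], np.nan)
    surface = flat[0] >= threshold
    out[surface] = 0.0
    reached = (flat >= threshold).any(axis=0) & ~surface
    idx = np.argmax(flat >= threshold, axis=0)
    cols = np.nonzero(reached)[0]
    k = idx[cols]
    n_hi = flat[k, cols]
    n_lo = flat[k - 1, cols]
    frac = (threshold - n_lo) / (n_hi - n_lo)
    out[cols] = z[k - 1] + frac * (z[k] - z[k - 1])
    return xr.DataArray(out.reshape(ny, nx),
                        coords={"lat": climatology["lat"],
                                "lon": climatology["lon"]},
                        dims=("lat", "lon"), name="nutricline_depth")


# ---------------------------------------------------------------------------
# chlorophyll sampling
# ---------------------------------------------------------------------------

def _nearest_index(coord: np.ndarray, value: float) -> int:
    return int(np.argmin(np.abs(coord - value)))


def sample_chl(chl: xr.DataArray, lat: float, lon: float, time,
               max_rings: int = 3) -> float:
    """CHL (mg/m³) for one position/time from the matching 8-day composite.

    Takes the composite window containing the timestamp and the nearest
    grid cell; if that cell is cloud-masked the search expands in square
    rings (up to ``max_rings``), returning the mean of valid cells in the
    first non-empty ring. NaN when outside the grid/stack or all rings are
    cloudy.
    """
    tvals = chl["time"].to_numpy()
    t = np.datetime64(time)
    widx = int(np.searchsorted(tvals, t, side="right")) - 1
    if widx < 0 or widx >= tvals.size:
        return float("nan")
    lats = chl["lat"].to_numpy()
    lons = chl["lon"].to_numpy()
    res = float(np.diff(lats).mean())
    if not (lats.min() - res <= lat <= lats.max() + res
            and lons.min() - res <= lon <= lons.max() + res):
        return float("nan")
    iy = _nearest_index(lats, lat)
    ix = _nearest_index(lons, lon)
    grid = chl.isel(time=widx).to_numpy()
    if np.isfinite(grid[iy, ix]):
        return float(grid[iy, ix])
    ny, nx = grid.shape
    for ring in range(1, max_rings + 1):
        y0, y1 = max(iy - ring, 0), min(iy + ring, ny - 1)
        x0, x1 = max(ix - ring, 0), min(ix + ring, nx - 1)
        block = grid[y0:y1 + 1, x0:x1 + 1].copy()
        # blank the interior so only the ring remains
        by0, by1 = iy - (ring - 1) - y0, iy + (ring - 1) - y0
        bx0, bx1 = ix - (ring - 1) - x0, ix + (ring - 1) - x0
        block[max(by0, 0):by1 + 1, max(bx0, 0):bx1 + 1] = np.nan
        vals = block[np.isfinite(block)]
        if vals.size:
            return float(vals.mean())
    return float("nan")


def sample_chl_track(chl: xr.DataArray, lats, lons, times,
                     max_rings: int = 3) -> np.ndarray:
    """Vectorized loop of :func:`sample_chl` over track positions."""
    return np.array([sample_chl(chl, la, lo, t, max_rings=max_rings)
                     for la, lo, t in zip(np.asarray(lats),
                                          np.asarray(lons),
                                          np.asarray(times))])


def chl_summary(samples) -> dict:
    """Mean/SD/min/max of non-missing CHL samples (SD with n-1; NaN if n=1)."""
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no valid CHL samples")
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
        "min": float(x.min()),
        "max": float(x.max()),
        "n": int(x.size),
    }


# ---------------------------------------------------------------------------
# dive depth vs latitude
# ---------------------------------------------------------------------------

def bin_dive_depths(dives: pd.DataFrame, track_frame: pd.DataFrame,
                    climatology: xr.Dataset, bin_deg: float = 1.0,
                    nutricline_umol: float = 2.0) -> pd.DataFrame:
    """Mean (±SD) dive depth per latitude bin, with climatology context.

    ``dives`` carries 6-h bins (animal_id, bin_start, mean_depth_m);
    ``track_frame`` the regular positions (animal_id, time, lat, lon). Each
    dive record is joined to its position by animal and bin start time;
    unjoinable records are dropped (logged). Bins are 1° wide centered on
    half-integer degrees to align with a 1° climatology; per bin the mean
    thermocline and nutricline depths are averaged over the climatology
    cells actually traversed in that bin.
    """
    pos = track_frame[["animal_id", "time", "lat", "lon"]]
    merged = dives.merge(pos, left_on=["animal_id", "bin_start"],
                         right_on=["animal_id", "time"], how="left")
    lost = merged["lat"].isna().sum()
    if lost:
        logger.info("bin_dive_depths: dropped %d unjoinable dive records", lost)
        merged = merged.dropna(subset=["lat"])
    thermo = thermocline_depth_grid(climatology)
    nutr = nutricline_depth_grid(climatology, threshold=nutricline_umol)
    pts_lat = xr.DataArray(merged["lat"].to_numpy(), dims="p")
    pts_lon = xr.DataArray(merged["lon"].to_numpy(), dims="p")
    merged["thermocline_m"] = thermo.sel(lat=pts_lat, lon=pts_lon,
                                         method="nearest").to_numpy()
    merged["nutricline_m"] = nutr.sel(lat=pts_lat, lon=pts_lon,
                                      method="nearest").to_numpy()
    center = (np.floor(merged["lat"] / bin_deg) + 0.5) * bin_deg
    merged["bin_center_lat"] = center
    rows = []
    for lat_c, grp in merged.groupby("bin_center_lat", sort=True):
        d = grp["mean_depth_m"].to_numpy()
        rows.append({
            "bin_center_lat": float(lat_c),
            "mean_depth": float(d.mean()),
            "sd_depth": float(d.std(ddof=1)) if d.size > 1 else float("nan"),
            "n": int(d.size),
            "mean_thermocline": float(np.nanmean(grp["thermocline_m"])),
            "mean_nutricline": float(np.nanmean(grp["nutricline_m"])),
        })
    return pd.DataFrame(rows)
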