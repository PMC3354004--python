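"""Surface currents from gridded fields, and their removal from tracks.

Geostrophic velocities follow from sea-surface-height (SSH) slopes,
u = -(g/f) dη/dy, v = (g/f) dη/dx, with f = 2 Ω sin(lat). Within an
equatorial band the 1/f singularity is removed with the β-plane form that
uses the meridional derivative of f: u_b = -(g/β) d²η/dy²,
v_b = (g/β) d²η/dxdy, blended into the f-form with Gaussian weights
w = exp(-(lat/L)²) (the standard satellite-altimetry treatment; L defaults
to 2.2°, blending applied inside ±4°).

The wind-driven (Ekman) surface velocity is a two-parameter slab model:
(u + iv) = (τx + iτy) / (ρ h (r + i f)), rotated clockwise of the wind in
the northern hemisphere and counterclockwise in the southern; the friction
parameter r keeps the field finite on the equator.

Subtracting the sampled current from each step's ground velocity yields the
animal's swimming velocity: swim = ground - current, exactly invertible.
Velocities are handled in km/d at the interface (1 m/s = 86.4 km/d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from pelagitrack.track_processing import RegularTrack, _wrap_lon, EARTH_RADIUS_KM

G_MS2 = 9.81
OMEGA_S = 7.2921e-5
RHO_SEAWATER = 1025.0           # kg/m3
MS_TO_KMD = 86.4
_KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0

__all__ = [
    "EkmanParams",
    "geostrophic_from_ssh",
    "ekman_from_wind",
    "total_current",
    "sample_current",
    "correct_track",
]


def _coriolis(lat_deg):
    return 2.0 * OMEGA_S * np.sin(np.deg2rad(lat_deg))


BETA_S = 2.0 * OMEGA_S / (EARTH_RADIUS_KM * 1e3)   # df/dy at the equator, 1/m/s


def geostrophic_from_ssh(ssh: xr.DataArray,
                         equator_band_deg: float = 4.0,
                         blend_efold_deg: float = 2.2,
                         cap_kmd: float | None = 200.0) -> xr.Dataset:
    """Geostrophic surface current (km/d) from SSH (m) on a regular grid.

    Central finite differences; inside ``equator_band_deg`` the β-plane form
    replaces the f-form with a smooth Gaussian blend so the field is
    continuous and finite at the equator. ``cap_kmd`` clips runaway values
    near the band edges of noisy fields (None disables).
    """
    lat = ssh["lat"].to_numpy()
    lon = ssh["lon"].to_numpy()
    if lat.size < 3 or lon.size < 3:
        raise ValueError("SSH grid too coarse for finite differences")
    dres = float(np.diff(lat).mean())
    if dres > 1.0 + 1e-9:
        raise ValueError("SSH grid spacing must be <= 1 degree")
    eta = ssh.to_numpy()
    dy = np.gradient(lat) * _KM_PER_DEG * 1e3                   # m
    dx = (np.gradient(lon) * _KM_PER_DEG * 1e3)[None, :] \
        * np.cos(np.deg2rad(lat))[:, None]
    deta_dy = np.gradient(eta, axis=0) / dy[:, None]
    deta_dx = np.gradient(eta, axis=1) / dx
    d2eta_dy2 = np.gradient(deta_dy, axis=0) / dy[:, None]
    d2eta_dxdy = np.gradient(deta_dx, axis=0) / dy[:, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        f = _coriolis(lat)[:, None]
        u_f = -G_MS2 / f * deta_dy
        v_f = G_MS2 / f * deta_dx
    u_b = -G_MS2 / BETA_S * d2eta_dy2
    v_b = G_MS2 / BETA_S * d2eta_dxdy

    w = np.exp(-(lat[:, None] / blend_efold_deg) ** 2)
    inside = np.abs(lat)[:, None] <= equator_band_deg
    w = np.where(inside, w, 0.0)
    # exactly on the equator the f-form is undefined; weight is ~1 there
    u_f = np.where(np.isfinite(u_f), u_f, 0.0)
    v_f = np.where(np.isfinite(v_f), v_f, 0.0)
    u = (w * u_b + (1.0 - w) * u_f) * MS_TO_KMD
    v = (w * v_b + (1.0 - w) * v_f) * MS_TO_KMD
    if cap_kmd is not None:
        u = np.clip(u, -cap_kmd, cap_kmd)
        v = np.clip(v, -cap_kmd, cap_kmd)
    return xr.Dataset(
        {"u": (("lat", "lon"), u), "v": (("lat", "lon"), v)},
        coords={"lat": lat, "lon": lon},
        attrs={"provenance": "derived_geostrophic", "units": "km d-1"})


@dataclass(frozen=True)
class EkmanParams:
    """Slab-model constants: effective layer depth and linear friction."""

    depth_m: float = 25.0
    friction_s: float = 1.0e-4


def ekman_from_wind(wind: xr.Dataset,
                    params: EkmanParams = EkmanParams()) -> xr.Dataset:
    """Ekman surface velocity (km/d) from wind stress (N/m², taux/tauy)."""
    lat = wind["lat"].to_numpy()
    taux = wind["taux"].to_numpy()
    tauy = wind["tauy"].to_numpy()
    if not (np.all(np.isfinite(taux)) and np.all(np.isfinite(tauy))):
        raise ValueError("wind stress must be finite")
    f = _coriolis(lat)[:, None]
    denom = RHO_SEAWATER * params.depth_m * (params.friction_s + 1j * f)
    vel = (taux + 1j * tauy) / denom * MS_TO_KMD
    return xr.Dataset(
        {"u": (("lat", "lon"), vel.real), "v": (("lat", "lon"), vel.imag)},
        coords={"lat": lat, "lon": wind["lon"].to_numpy()},
        attrs={"provenance": "derived_ekman", "units": "km d-1"})


def total_current(geostrophic: xr.Dataset, ekman: xr.Dataset) -> xr.Dataset:
    """Sum of the geostrophic and Ekman components on the common grid."""
    ek = ekman.interp(lat=geostrophic["lat"], lon=geostrophic["lon"])
    out = geostrophic + ek
    out.attrs["provenance"] = "total"
    out.attrs["units"] = "km d-1"
    return out


def sample_current(field: xr.Dataset, lats, lons,
                   times=None) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation of (u, v) at positions; NaN outside the hull.

    If the field carries a time dimension the nearest time slice is used for
    each query time (composites are piecewise-constant in time).
    """
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    if "time" in field.dims:
        if times is None:
            raise ValueError("field has a time axis; query times required")
        fld = field.sel(time=xr.DataArray(np.asarray(times), dims="p"),
                        method="nearest")
        u = fld["u"].interp(lat=xr.DataArray(lats, dims="p"),
                            lon=xr.DataArray(lons, dims="p"))
        v = fld["v"].interp(lat=xr.DataArray(lats, dims="p"),
                            lon=xr.DataArray(lons, dims="p"))
    else:
        u = field["u"].interp(lat=xr.DataArray(lats, dims="p"),
                              lon=xr.DataArray(lons, dims="p"))
        v = field["v"].interp(lat=xr.DataArray(lats, dims="p"),
                              lon=xr.DataArray(lons, dims="p"))
    return u.to_numpy(), v.to_numpy()


def ground_velocity(track: RegularTrack) -> pd.DataFrame:
    """Per-step ground velocity components (km/d) at step midpoints.

    East/north components from consecutive valid same-segment positions on a
    local tangent plane at the step midpoint; the step is the track's
    regular interval.
    """
    ok = (track.valid[:-1] & track.valid[1:]
          & (track.segment_id[:-1] == track.segment_id[1:]))
    i = np.nonzero(ok)[0]
    step_days = track.interval_hours / 24.0
    dlat = track.lats[i + 1] - track.lats[i]
    dlon = _wrap_lon(track.lons[i + 1] - track.lons[i])
    mid_lat = 0.5 * (track.lats[i] + track.lats[i + 1])
    mid_lon = _wrap_lon(track.lons[i] + 0.5 * dlon)
    u = dlon * np.cos(np.deg2rad(mid_lat)) * _KM_PER_DEG / step_days
    v = dlat * _KM_PER_DEG / step_days
    mid_time = track.times[i] + (track.times[i + 1] - track.times[i]) / 2
    return pd.DataFrame({"mid_time": mid_time, "mid_lat": mid_lat,
                         "mid_lon": mid_lon, "u_ground": u, "v_ground": v,
                         "segment": track.segment_id[i]})


def correct_track(track: RegularTrack, field: xr.Dataset) -> pd.DataFrame:
    """Remove the sampled current from each step's ground velocity.

    Returns a DataFrame with ground, current and swimming velocity
    components plus ``speed_swim`` (km/d). Steps whose midpoint falls
    outside the current field keep NaN swimming velocity (flagged missing,
    never treated as zero current).
    """
    gv = ground_velocity(track)
    uc, vc = sample_current(field, gv["mid_lat"].to_numpy(),
                            gv["mid_lon"].to_numpy(),
                            times=gv["mid_time"].to_numpy()
                            if "time" in field.dims else None)
    gv["u_current"] = uc
    gv["v_current"] = vc
    gv["u_swim"] = gv["u_ground"] - uc
    gv["v_swim"] = gv["v_ground"] - vc
    gv["speed_swim"] = np.hypot(gv["u_swim"], gv["v_swim"])
    gv["current_missing"] = ~np.isfinite(uc) | ~np.isfinite(vc)
    return gv
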