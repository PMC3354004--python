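"""Synthetic inputs with the statistical structure the analysis assumes.

Nothing downstream should be able to tell these apart (structurally) from the
real thing, so every stage of the pipeline can be exercised end to end:

* regime-switching correlated random walks on the sphere, with per-regime
  truncated-gamma ground speeds and wrapped-normal turning — a slow,
  tortuous area-restricted-search (ARS) regime against fast, directed
  transit;
* an Argos observation process: thinning to a fix rate, class-dependent
  isotropic position error, multi-day transmission holes;
* a synthetic ocean: smooth sea-surface height and wind stress, a
  chlorophyll-a stack on a fine grid with 8-day composites and lognormal
  patchiness, and a 1-degree temperature/nitrate climatology whose
  thermocline and nutricline depths follow a prescribed latitude shape;
* 6-h dive summaries linked to the local thermocline depth.

Defaults emulate the North Atlantic (NA) and Eastern Pacific (EP) leatherback
contrast: the NA speed mixture has bands 0-15 and 20-45 km/d holding 29 % and
42 % of the time with modes near 12.5 and 37.5 km/d; the EP distribution is
unimodal with mode 21 km/d. All randomness flows from one seed through
numpy SeedSequence streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from pelagitrack.track_processing import EARTH_RADIUS_KM, _wrap_lon

__all__ = [
    "MovementRegimeParams",
    "SyntheticScenario",
    "OceanParams",
    "SyntheticOcean",
    "na_scenario",
    "ep_scenario",
    "simulate_true_track",
    "degrade_to_argos",
    "synth_ocean",
    "synth_dive_summaries",
    "save_field_text",
    "load_field_text",
]

#: Published order-of-magnitude Argos errors per location class, km (1-sigma).
DEFAULT_CLASS_ERROR_SD_KM = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0,
                             "A": 10.0, "B": 20.0, "Z": 50.0}
#: Quality mix of a good relay-data-logger deployment. Kept deliberately
#: high-quality: with 6-h surface fixes, sub-threshold (<10 km/h) position
#: blunders from A/B classes cannot be speed-filtered and would blur the slow
#: foraging mode, which real studies counter with state-space filtering.
DEFAULT_CLASS_MIX = {"3": 0.42, "2": 0.36, "1": 0.17, "0": 0.02,
                     "A": 0.02, "B": 0.008, "Z": 0.002}

# Standard depth levels of the synthetic climatology. Spacing doubles below
# 50 m so that layer midpoints land on round values (e.g. 75 m between the
# 50 and 100 m levels), which the profile analyzers can recover exactly.
STANDARD_DEPTHS_M = np.array([0, 10, 20, 30, 50, 100, 150,
                              200, 250, 300, 400, 500], dtype=float)

_KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0


def _stream(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one stage, split from the scenario seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# scenario parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovementRegimeParams:
    """One movement regime of the switching random walk.

    ``speed_center`` is the mode (km/d) of the regime's gamma speed
    distribution, truncated to ``speed_band``; ``speed_shape`` is the gamma
    shape (larger = tighter around the mode). ``turning_concentration`` is
    the wrapped-normal concentration of heading changes (0 = headings drawn
    uniformly; large = nearly straight). ``occupancy`` is the stationary
    fraction of time spent in the regime.
    """

    name: str
    speed_center: float
    speed_band: tuple[float, float]
    turning_concentration: float
    occupancy: float
    speed_shape: float = 12.0

    def __post_init__(self):
        lo, hi = self.speed_band
        if not lo < hi:
            raise ValueError(f"regime {self.name}: speed_band low must be < high")
        if not lo <= self.speed_center <= hi:
            raise ValueError(f"regime {self.name}: speed_center outside band")
        if self.turning_concentration < 0:
            raise ValueError(f"regime {self.name}: concentration must be >= 0")

    def sample_speeds(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Truncated-gamma speeds (km/d) via inverse-CDF sampling."""
        a = self.speed_shape
        scale = self.speed_center / (a - 1.0) if a > 1.0 else self.speed_center
        dist = stats.gamma(a, scale=scale)
        lo, hi = self.speed_band
        qlo, qhi = dist.cdf(lo), dist.cdf(hi)
        return dist.ppf(qlo + (qhi - qlo) * rng.random(n))


@dataclass(frozen=True)
class SyntheticScenario:
    """Everything needed to simulate one animal's track and its observation."""

    regimes: tuple[MovementRegimeParams, ...]
    start_position: tuple[float, float] = (12.0, -55.0)   # lat, lon deg
    duration_days: float = 180.0
    fix_rate: float = 4.0                                 # mean fixes per day
    gap_spec: tuple[tuple[float, float], ...] = ()        # (start_day, length)
    argos_class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    class_error_sd: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_ERROR_SD_KM))
    seed: int = 0
    step_hours: float = 6.0
    regime_persistence: float = 0.8    # self-transition stickiness: ~2-day bouts
    start_time: str = "2005-01-01"
    animal_id: str = "synth-01"

    def __post_init__(self):
        occ = sum(r.occupancy for r in self.regimes)
        if abs(occ - 1.0) > 1e-9:
            raise ValueError(f"regime occupancies sum to {occ}, expected 1")
        pc = sum(self.argos_class_mix.values())
        if abs(pc - 1.0) > 1e-9:
            raise ValueError(f"argos class probabilities sum to {pc}")
        sds = [self.class_error_sd[c] for c in ("3", "2", "1", "0", "A", "B", "Z")
               if c in self.class_error_sd]
        if any(b < a for a, b in zip(sds, sds[1:])):
            raise ValueError("class error SDs must be non-decreasing 3 -> Z")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([r.occupancy for r in self.regimes])

    def transition_matrix(self) -> np.ndarray:
        """Markov matrix rho*I + (1-rho)*1 pi^T; stationary dist = occupancy."""
        pi = self.occupancies
        rho = self.regime_persistence
        return rho * np.eye(pi.size) + (1.0 - rho) * np.tile(pi, (pi.size, 1))


def na_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """North-Atlantic-like preset: bimodal ARS/transit plus a fast tail.

    Mixture weights 0.29 / 0.42 / 0.29 with bands 0-15, 20-45 and 45-95 km/d,
    so the 0-15 and 20-45 band occupancies of the published NA distribution
    are recoverable and the bands do not leak into each other.
    """
    regimes = (
        MovementRegimeParams("ars", 12.5, (0.0, 15.0),
                             turning_concentration=1.5, occupancy=0.29,
                             speed_shape=14.0),
        MovementRegimeParams("transit", 37.5, (20.0, 45.0),
                             turning_concentration=40.0, occupancy=0.42,
                             speed_shape=30.0),
        MovementRegimeParams("fast", 50.0, (45.0, 95.0),
                             turning_concentration=20.0, occupancy=0.29,
                             speed_shape=2.0),
    )
    defaults = dict(regimes=regimes, start_position=(12.0, -55.0),
                    gap_spec=((60.0, 4.5),), seed=seed,
                    animal_id="na-synth")
    defaults.update(overrides)
    return SyntheticScenario(**defaults)


def ep_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """Eastern-Pacific-like preset: one broad transit regime, mode 21 km/d."""
    regimes = (
        MovementRegimeParams("transit", 21.0, (0.0, 110.0),
                             turning_concentration=25.0, occupancy=1.0,
                             speed_shape=9.0),
    )
    defaults = dict(regimes=regimes, start_position=(9.5, -85.5),
                    gap_spec=((45.0, 4.0),), seed=seed,
                    animal_id="ep-synth")
    defaults.update(overrides)
    return SyntheticScenario(**defaults)


# ---------------------------------------------------------------------------
# movement simulation
# ---------------------------------------------------------------------------

def sample_speed_mixture(scenario: SyntheticScenario, n: int,
                         seed: int | None = None) -> np.ndarray:
    """Draw n i.i.d. speeds (km/d) from the scenario's stationary mixture.

    This is the marginal speed distribution the regime-switching walk visits
    in the long run: regimes drawn by occupancy, speeds from each regime's
    truncated gamma.
    """
    rng = _stream(scenario.seed if seed is None else seed, 5)
    which = rng.choice(len(scenario.regimes), size=n, p=scenario.occupancies)
    out = np.empty(n)
    for i, reg in enumerate(scenario.regimes):
        mask = which == i
        out[mask] = reg.sample_speeds(int(mask.sum()), rng)
    return out


def _forward_step(lat, lon, heading_rad, dist_km):
    """Destination point along a great circle (vectorized)."""
    delta = dist_km / EARTH_RADIUS_KM
    phi = np.deg2rad(lat)
    lam = np.deg2rad(lon)
    phi2 = np.arcsin(np.sin(phi) * np.cos(delta)
                     + np.cos(phi) * np.sin(delta) * np.cos(heading_rad))
    lam2 = lam + np.arctan2(np.sin(heading_rad) * np.sin(delta) * np.cos(phi),
                            np.cos(delta) - np.sin(phi) * np.sin(phi2))
    return np.rad2deg(phi2), _wrap_lon(np.rad2deg(lam2))


def simulate_true_track(scenario: SyntheticScenario) -> pd.DataFrame:
    """Simulate the regime-switching correlated random walk.

    Returns a DataFrame with columns ``time, lat, lon, regime, speed_kmd``
    (``speed_kmd`` is the drawn ground speed of the step *leaving* each
    position; the last row has NaN). The regime chain starts from its
    stationary distribution; everything is reproducible from the scenario
    seed.
    """
    rng = _stream(scenario.seed, 1)
    n_steps = int(round(scenario.duration_days * 24.0 / scenario.step_hours))
    if n_steps < 1:
        raise ValueError("duration too short for one step")
    k = len(scenario.regimes)
    P = scenario.transition_matrix()
    cum_p = np.cumsum(P, axis=1)
    regimes = np.empty(n_steps + 1, dtype=np.int64)
    regimes[0] = rng.choice(k, p=scenario.occupancies)
    u = rng.random(n_steps)
    for t in range(n_steps):
        regimes[t + 1] = np.searchsorted(cum_p[regimes[t]], u[t], side="right")
    # speeds drawn per regime (in chain order for reproducibility by regime)
    step_days = scenario.step_hours / 24.0
    speeds = np.empty(n_steps)
    for i, reg in enumerate(scenario.regimes):
        mask = regimes[:-1] == i
        speeds[mask] = reg.sample_speeds(int(mask.sum()), rng)
    # headings: wrapped-normal increments with per-regime concentration
    headings = np.empty(n_steps)
    h = rng.uniform(0.0, 2.0 * np.pi)
    turn_u = rng.standard_normal(n_steps)
    fresh = rng.uniform(0.0, 2.0 * np.pi, n_steps)
    for t in range(n_steps):
        kappa = scenario.regimes[regimes[t]].turning_concentration
        if kappa <= 0:
            h = fresh[t]
        else:
            h = h + turn_u[t] / np.sqrt(kappa)
        headings[t] = h
    lats = np.empty(n_steps + 1)
    lons = np.empty(n_steps + 1)
    lats[0], lons[0] = scenario.start_position
    for t in range(n_steps):
        lats[t + 1], lons[t + 1] = _forward_step(
            lats[t], lons[t], headings[t], speeds[t] * step_days)
    t0 = np.datetime64(scenario.start_time, "ns")
    step = np.timedelta64(int(scenario.step_hours * 3600), "s")
    times = t0 + np.arange(n_steps + 1) * step
    return pd.DataFrame({
        "time": times, "lat": lats, "lon": lons,
        "regime": [scenario.regimes[i].name for i in regimes],
        "speed_kmd": np.append(speeds, np.nan),
    })


def degrade_to_argos(true_track: pd.DataFrame,
                     scenario: SyntheticScenario) -> pd.DataFrame:
    """Apply the Argos observation process to a simulated track.

    Thins positions to the scenario fix rate, draws a location class per fix,
    perturbs positions with class-dependent isotropic Gaussian error, and
    removes fixes inside the transmission holes of ``gap_spec``. Output is a
    time-sorted fix table (animal_id, time, lat, lon, lc).
    """
    if len(true_track) == 0:
        raise ValueError("true_track is empty")
    rng = _stream(scenario.seed, 2)
    steps_per_day = 24.0 / scenario.step_hours
    p_keep = min(1.0, scenario.fix_rate / steps_per_day)
    keep = rng.random(len(true_track)) <= p_keep
    t0 = true_track["time"].iloc[0]
    day = (true_track["time"] - t0).dt.total_seconds().to_numpy() / 86400.0
    for start, length in scenario.gap_spec:
        keep &= ~((day >= start) & (day < start + length))
    obs = true_track.loc[keep, ["time", "lat", "lon"]].copy()
    classes = list(scenario.argos_class_mix)
    probs = np.array([scenario.argos_class_mix[c] for c in classes])
    lc = rng.choice(len(classes), size=len(obs), p=probs / probs.sum())
    sd_km = np.array([scenario.class_error_sd[classes[i]] for i in lc])
    dlat = rng.standard_normal(len(obs)) * sd_km / _KM_PER_DEG
    coslat = np.cos(np.deg2rad(obs["lat"].to_numpy()))
    dlon = rng.standard_normal(len(obs)) * sd_km / (_KM_PER_DEG
                                                    * np.maximum(coslat, 0.05))
    obs["lat"] = np.clip(obs["lat"].to_numpy() + dlat, -89.9, 89.9)
    obs["lon"] = _wrap_lon(obs["lon"].to_numpy() + dlon)
    obs["lc"] = [classes[i] for i in lc]
    obs.insert(0, "animal_id", scenario.animal_id)
    return obs.sort_values("time").reset_index(drop=True)


# ---------------------------------------------------------------------------
# synthetic ocean
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermoclineShape:
    """Target thermocline depth by latitude: a gyre-like mid-latitude bowl."""

    base_m: float = 45.0
    amplitude_m: float = 70.0
    peak_lat: float = 28.0
    width_deg: float = 14.0
    nutricline_ratio: float = 0.8   # nutricline sits above the thermocline

    def depth(self, lat) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        return self.base_m + self.amplitude_m * np.exp(
            -((lat - self.peak_lat) / self.width_deg) ** 2)


@dataclass(frozen=True)
class OceanParams:
    lat_range: tuple[float, float] = (-5.0, 55.0)
    lon_range: tuple[float, float] = (-80.0, -20.0)
    time_start: str = "2005-01-01"
    n_windows: int = 23                   # 8-day composite windows
    window_days: float = 8.0
    ssh_res_deg: float = 0.5
    chl_res_deg: float = 0.05
    ssh_amp_m: float = 0.35               # gyre bump height
    ssh_center: tuple[float, float] = (28.0, -50.0)
    ssh_scale_deg: tuple[float, float] = (12.0, 20.0)
    wind_amp_nm2: float = 0.06
    chl_foraging_mean: float = 0.67       # mg/m3 in the productive box
    chl_gyre_mean: float = 0.18
    chl_sigma_log: float = 1.0            # lognormal shape of patchiness
    chl_foraging_box: tuple[float, float, float, float] = (38.0, 48.0, -55.0, -35.0)
    chl_gyre_box: tuple[float, float, float, float] = (18.0, 28.0, -55.0, -35.0)
    chl_cloud_fraction: float = 0.12
    thermocline: ThermoclineShape = field(default_factory=ThermoclineShape)


@dataclass
class SyntheticOcean:
    """Gridded synthetic fields, all with explicit lat/lon coordinates."""

    ssh: xr.DataArray                 # m, (lat, lon)
    wind: xr.Dataset                  # taux/tauy N/m2, (lat, lon)
    chl: xr.DataArray                 # mg/m3, (time, lat, lon); NaN = cloud
    climatology: xr.Dataset           # temperature (degC), nitrate (umol), (depth, lat, lon)
    thermocline_true: xr.DataArray    # m, generator target, (lat, lon)
    nutricline_true: xr.DataArray     # m, generator target, (lat, lon)
    params: OceanParams


def _grid(lo, hi, res):
    n = int(round((hi - lo) / res)) + 1
    return lo + np.arange(n) * res


def synth_ocean(params: OceanParams = OceanParams(), seed: int = 0) -> SyntheticOcean:
    """Build all gridded fields of the synthetic ocean.

    The climatology is constructed so that the analyzers recover the
    generator's targets exactly: the maximum temperature gradient sits across
    the pair of standard depths whose midpoint is closest to the latitude
    target (that snapped midpoint is stored as ``thermocline_true``), and
    nitrate is linear through 2 umol exactly at ``nutricline_true``.
    """
    rng = _stream(seed, 3)
    lat0, lat1 = params.lat_range
    lon0, lon1 = params.lon_range

    # --- SSH: smooth anticyclonic gyre bump (differentiable) ---
    lats = _grid(lat0, lat1, params.ssh_res_deg)
    lons = _grid(lon0, lon1, params.ssh_res_deg)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    cy, cx = params.ssh_center
    sy, sx = params.ssh_scale_deg
    ssh_vals = params.ssh_amp_m * np.exp(-((glat - cy) / sy) ** 2
                                         - ((glon - cx) / sx) ** 2)
    ssh = xr.DataArray(ssh_vals, coords={"lat": lats, "lon": lons},
                       dims=("lat", "lon"), name="ssh",
                       attrs={"units": "m"})

    # --- wind stress: smooth trades/westerlies pattern ---
    taux = params.wind_amp_nm2 * -np.cos(np.pi * (glat - 10.0) / 40.0)
    tauy = 0.2 * params.wind_amp_nm2 * np.sin(np.pi * glat / 60.0)
    wind = xr.Dataset(
        {"taux": (("lat", "lon"), taux), "tauy": (("lat", "lon"), tauy)},
        coords={"lat": lats, "lon": lons}, attrs={"units": "N m-2"})

    # --- chlorophyll stack: lognormal with latitudinal gradient ---
    clats = _grid(lat0, lat1, params.chl_res_deg)
    clons = _grid(lon0, lon1, params.chl_res_deg)
    sig = params.chl_sigma_log
    mu_f = np.log(params.chl_foraging_mean) - 0.5 * sig ** 2
    mu_g = np.log(params.chl_gyre_mean) - 0.5 * sig ** 2
    fy0, fy1, _, _ = params.chl_foraging_box
    gy0, gy1, _, _ = params.chl_gyre_box
    lat_f = 0.5 * (fy0 + fy1)
    lat_g = 0.5 * (gy0 + gy1)
    # linear ramp in latitude between the two boxes, clipped outside; flat
    # inside each designated box so the box means are exactly the parameters
    t = np.clip((clats - lat_g) / (lat_f - lat_g), -0.3, 1.3)
    mu_lat = mu_g + (mu_f - mu_g) * t
    mu_lat[(clats >= fy0) & (clats <= fy1)] = mu_f
    mu_lat[(clats >= gy0) & (clats <= gy1)] = mu_g
    tvals = (np.datetime64(params.time_start, "ns")
             + np.arange(params.n_windows)
             * np.timedelta64(int(params.window_days * 86400), "s"))
    shape = (params.n_windows, clats.size, clons.size)
    chl_vals = np.exp(mu_lat[None, :, None]
                      + sig * rng.standard_normal(shape))
    cloud = rng.random(shape) < params.chl_cloud_fraction
    chl_vals[cloud] = np.nan
    chl = xr.DataArray(chl_vals.astype(np.float32),
                       coords={"time": tvals, "lat": clats, "lon": clons},
                       dims=("time", "lat", "lon"), name="chl",
                       attrs={"units": "mg m-3", "window_days": params.window_days})

    # --- 1-degree climatology with controlled thermocline/nutricline ---
    klats = np.arange(np.floor(lat0) + 0.5, np.ceil(lat1), 1.0)
    klons = np.arange(np.floor(lon0) + 0.5, np.ceil(lon1), 1.0)
    z = STANDARD_DEPTHS_M
    mids = 0.5 * (z[:-1] + z[1:])
    target = params.thermocline.depth(klats)
    pair = np.argmin(np.abs(mids[None, :] - target[:, None]), axis=1)
    thermo_snap = mids[pair]
    sst = 28.0 - 0.2 * np.abs(klats - 5.0)          # warm tropics, cool poles
    temp = np.empty((z.size, klats.size))
    for i in range(klats.size):
        p = pair[i]
        prof = np.empty(z.size)
        prof[:p + 1] = sst[i] - 0.004 * z[:p + 1]    # mixed layer, mild slope
        drop = 8.0                                   # sharp interface
        prof[p + 1] = prof[p] - drop
        below = z[p + 2:] - z[p + 1]
        prof[p + 2:] = prof[p + 1] - 0.004 * below
        temp[:, i] = prof
    nutr_target = params.thermocline.nutricline_ratio * thermo_snap
    nit = 2.0 + 0.05 * (z[:, None] - nutr_target[None, :])
    nit = np.maximum(nit, 0.05)
    temp3 = np.repeat(temp[:, :, None], klons.size, axis=2)
    nit3 = np.repeat(nit[:, :, None], klons.size, axis=2)
    clim = xr.Dataset(
        {"temperature": (("depth", "lat", "lon"), temp3),
         "nitrate": (("depth", "lat", "lon"), nit3)},
        coords={"depth": z, "lat": klats, "lon": klons})
    thermo_true = xr.DataArray(np.tile(thermo_snap[:, None], (1, klons.size)),
                               coords={"lat": klats, "lon": klons},
                               dims=("lat", "lon"), name="thermocline_true")
    nutr_true = xr.DataArray(np.tile(nutr_target[:, None], (1, klons.size)),
                             coords={"lat": klats, "lon": klons},
                             dims=("lat", "lon"), name="nutricline_true")
    return SyntheticOcean(ssh=ssh, wind=wind, chl=chl, climatology=clim,
                          thermocline_true=thermo_true,
                          nutricline_true=nutr_true, params=params)


# ---------------------------------------------------------------------------
# dive summaries
# ---------------------------------------------------------------------------

def synth_dive_summaries(true_track: pd.DataFrame, ocean: SyntheticOcean,
                         noise_sd: float = 5.0,
                         link: tuple[float, float] = (1.0, 0.0),
                         seed: int = 0,
                         animal_id: str = "synth-01") -> pd.DataFrame:
    """6-h dive-summary records linked to the local thermocline depth.

    Mean dive depth per bin = ``link[0] * thermocline_depth + link[1]`` plus
    Gaussian noise, floored at 1 m. Track positions must fall inside the
    climatology grid.
    """
    rng = _stream(seed, 4)
    lat = true_track["lat"].to_numpy()
    lon = true_track["lon"].to_numpy()
    tt = ocean.thermocline_true
    if (lat.min() < float(tt.lat.min()) - 0.5
            or lat.max() > float(tt.lat.max()) + 0.5
            or lon.min() < float(tt.lon.min()) - 0.5
            or lon.max() > float(tt.lon.max()) + 0.5):
        raise ValueError("track leaves the climatology grid")
    local = tt.sel(lat=xr.DataArray(lat, dims="p"),
                   lon=xr.DataArray(lon, dims="p"), method="nearest").to_numpy()
    scale, offset = link
    depth = scale * local + offset
    if noise_sd > 0:
        depth = depth + rng.standard_normal(depth.size) * noise_sd
    depth = np.maximum(depth, 1.0)
    times = true_track["time"]
    binh = np.timedelta64(6, "h")
    return pd.DataFrame({
        "animal_id": animal_id,
        "bin_start": times.to_numpy(),
        "bin_end": times.to_numpy() + binh,
        "mean_depth_m": depth,
    })


# ---------------------------------------------------------------------------
# plain-text gridded-field fallback dialect
# ---------------------------------------------------------------------------

def save_field_text(da: xr.DataArray, path) -> None:
    """Write a DataArray as long-form CSV (dialect: one column per dim, then
    'value'); a plain-text alternative to NetCDF."""
    df = da.to_dataframe(name="value").reset_index()
    with open(path, "w") as fh:
        fh.write(f"# pelagitrack-field v1 name={da.name or 'field'} "
                 f"dims={','.join(da.dims)}\n")
        df.to_csv(fh, index=False)


def load_field_text(path) -> xr.DataArray:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# pelagitrack-field v1"):
            raise ValueError("not a pelagitrack text field file")
        meta = dict(kv.split("=") for kv in header.split()[3:])
        df = pd.read_csv(fh)
    dims = meta["dims"].split(",")
    for d in dims:
        if np.issubdtype(df[d].dtype, np.object_):
            try:
                df[d] = pd.to_datetime(df[d])
            except (ValueError, TypeError):
                pass
    da = df.set_index(dims)["value"].to_xarray()
    da.name = meta["name"]
    return da


def write_scenario_config(scenario: SyntheticScenario, path) -> None:
    """Flat key=value scenario file (schema v1); regimes are flattened."""
    lines = ["schema = pelagitrack-scenario-v1"]
    simple = {
        "start_lat": scenario.start_position[0],
        "start_lon": scenario.start_position[1],
        "duration_days": scenario.duration_days,
        "fix_rate": scenario.fix_rate,
        "seed": scenario.seed,
        "step_hours": scenario.step_hours,
        "regime_persistence": scenario.regime_persistence,
        "start_time": scenario.start_time,
        "animal_id": scenario.animal_id,
    }
    lines += [f"{k} = {v}" for k, v in simple.items()]
    lines += [f"gap.{i} = {s},{l}" for i, (s, l) in enumerate(scenario.gap_spec)]
    lines += [f"class_mix.{c} = {p}" for c, p in scenario.argos_class_mix.items()]
    lines += [f"class_sd.{c} = {p}" for c, p in scenario.class_error_sd.items()]
    for i, r in enumerate(scenario.regimes):
        lines += [
            f"regime.{i}.name = {r.name}",
            f"regime.{i}.speed_center = {r.speed_center}",
            f"regime.{i}.speed_band = {r.speed_band[0]},{r.speed_band[1]}",
            f"regime.{i}.turning_concentration = {r.turning_concentration}",
            f"regime.{i}.occupancy = {r.occupancy}",
            f"regime.{i}.speed_shape = {r.speed_shape}",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_scenario_config(path) -> SyntheticScenario:
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
    if kv.pop("schema", None) != "pelagitrack-scenario-v1":
        raise ValueError("unknown scenario schema")
    nreg = len({k.split(".")[1] for k in kv if k.startswith("regime.")})
    regimes = []
    for i in range(nreg):
        band = tuple(float(v) for v in kv[f"regime.{i}.speed_band"].split(","))
        regimes.append(MovementRegimeParams(
            name=kv[f"regime.{i}.name"],
            speed_center=float(kv[f"regime.{i}.speed_center"]),
            speed_band=band,
            turning_concentration=float(kv[f"regime.{i}.turning_concentration"]),
            occupancy=float(kv[f"regime.{i}.occupancy"]),
            speed_shape=float(kv[f"regime.{i}.speed_shape"]),
        ))
    gaps = tuple(tuple(float(v) for v in kv[k].split(","))
                 for k in sorted(kv) if k.startswith("gap."))
    mix = {k.split(".")[1]: float(v) for k, v in kv.items()
           if k.startswith("class_mix.")}
    sds = {k.split(".")[1]: float(v) for k, v in kv.items()
           if k.startswith("class_sd.")}
    return SyntheticScenario(
        regimes=tuple(regimes),
        start_position=(float(kv["start_lat"]), float(kv["start_lon"])),
        duration_days=float(kv["duration_days"]),
        fix_rate=float(kv["fix_rate"]),
        gap_spec=gaps,
        argos_class_mix=mix or dict(DEFAULT_CLASS_MIX),
        class_error_sd=sds or dict(DEFAULT_CLASS_ERROR_SD_KM),
        seed=int(kv["seed"]),
        step_hours=float(kv["step_hours"]),
        regime_persistence=float(kv["regime_persistence"]),
        start_time=kv["start_time"],
        animal_id=kv["animal_id"],
    )
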