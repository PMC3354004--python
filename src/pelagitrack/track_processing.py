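"""Raw Argos fixes -> regularized 6-h tracks -> travel-speed series.

The processing chain mirrors standard practice for Argos platform-transmitted
locations of marine megafauna:

1. :func:`filter_fixes` — drop unusable location classes and any fix implying a
   biologically implausible travel speed (default > 10 km/h) from the last kept
   fix (forward-pass / "keep last kept" semantics).
2. :func:`regularize` — smooth the retained fixes with a centered running mean
   and interpolate along great circles to exact regular knots (default 6 h).
3. :func:`mask_gaps` — invalidate regular positions that fall inside long raw
   transmission gaps (default > 3 days), splitting the track into segments so
   no speed is ever computed across a data hole.
4. :func:`compute_speeds` — first-difference consecutive valid positions into
   travel speeds in km/d.

Tracks are held as plain pandas DataFrames (columns ``animal_id``, ``time``,
``lat``, ``lon``, ``lc``) on the way in, and as :class:`RegularTrack` /
:class:`SpeedSeries` containers afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
#: Argos location classes, best to worst. "Z" is invalid.
LC_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")

FIX_COLUMNS = ["animal_id", "time", "lat", "lon", "lc"]

__all__ = [
    "EARTH_RADIUS_KM",
    "LC_CLASSES",
    "RegularTrack",
    "SpeedSeries",
    "great_circle_km",
    "filter_fixes",
    "regularize",
    "mask_gaps",
    "compute_speeds",
    "process_track",
    "track_from_regular_positions",
    "read_fixes_csv",
    "write_fixes_csv",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RegularTrack:
    """Positions at exact regular intervals with a validity mask.

    ``segment_id`` is constant between masked gaps and increments across them;
    invalid positions carry the id of the segment that follows them.
    """

    animal_id: str
    times: np.ndarray          # datetime64[ns], exactly interval-spaced
    lats: np.ndarray
    lons: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    segment_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    interval_hours: float = 6.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.times.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.segment_id is None:
            self.segment_id = np.zeros(self.times.size, dtype=int)
        else:
            self.segment_id = np.asarray(self.segment_id, dtype=int)
        if self.times.size >= 2:
            steps = np.diff(self.times).astype("timedelta64[s]").astype(float)
            expected = self.interval_hours * 3600.0
            if not np.allclose(steps, expected):
                raise ValueError("RegularTrack times are not uniformly spaced "
                                 f"at {self.interval_hours} h")

    def __len__(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal_id": self.animal_id,
            "time": self.times,
            "lat": self.lats,
            "lon": self.lons,
            "valid": self.valid,
            "segment_id": self.segment_id,
        })


@dataclass
class SpeedSeries:
    """Per-step travel speeds (km/d) from first-differenced regular positions."""

    animal_id: str
    step_mid_times: np.ndarray
    speeds: np.ndarray          # km/d, >= 0
    step_mid_lats: np.ndarray
    step_mid_lons: np.ndarray
    segment_id: np.ndarray

    def __len__(self) -> int:
        return int(self.speeds.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal_id": self.animal_id,
            "mid_time": self.step_mid_times,
            "speed_kmd": self.speeds,
            "mid_lat": self.step_mid_lats,
            "mid_lon": self.step_mid_lons,
            "segment": self.segment_id,
        })

    @staticmethod
    def concat(series: list["SpeedSeries"]) -> pd.DataFrame:
        """Pool several animals' speed series into one long DataFrame."""
        frames = [s.to_frame() for s in series if len(s)]
        if not frames:
            return pd.DataFrame(columns=["animal_id", "mid_time", "speed_kmd",
                                         "mid_lat", "mid_lon", "segment"])
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Haversine great-circle distance on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays of coordinates in degrees.
    """
    lat1, lon1, lat2, lon2 = (np.deg2rad(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def _to_unit_vectors(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    lat = np.deg2rad(lats)
    lon = np.deg2rad(lons)
    return np.stack([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


def _from_unit_vectors(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lat = np.rad2deg(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(v[..., 1], v[..., 0]))
    return lat, _wrap_lon(lon)


def _wrap_lon(lon):
    """Wrap longitudes to [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _check_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FIX_COLUMNS if c not in fixes.columns]
    if missing:
        raise ValueError(f"fix table is missing columns {missing}")
    out = fixes.copy()
    t = pd.to_datetime(out["time"], utc=True, format="ISO8601")
    out["time"] = t.dt.tz_localize(None)       # tz-naive UTC throughout
    return out


def filter_fixes(fixes: pd.DataFrame,
                 max_speed_kmh: float = 10.0,
                 drop_classes: set[str] = frozenset({"Z"})) -> pd.DataFrame:
    """Drop unwanted location classes, then speed-filter with a forward pass.

    Class-dropped fixes are removed first. The remaining fixes are scanned in
    time order per animal: the first fix is kept, and each subsequent fix is
    kept iff its implied great-circle speed from the *last kept* fix is at most
    ``max_speed_kmh``. The output is a subsequence of the input.

    Duplicate timestamps (after the first) are discarded; otherwise
    non-monotone times raise.
    """
    if max_speed_kmh <= 0:
        raise ValueError("max_speed_kmh must be positive")
    fixes = _check_fixes(fixes)
    if fixes.empty:
        return fixes
    drop_classes = {str(c) for c in (drop_classes or ())}
    kept_parts = []
    for animal, grp in fixes.groupby("animal_id", sort=False):
        t = grp["time"].to_numpy()
        if np.any(np.diff(t) < np.timedelta64(0, "ns")):
            raise ValueError(f"fixes for {animal!r} are not time-sorted")
        grp = grp[~grp["lc"].astype(str).isin(drop_classes)]
        grp = grp.loc[~grp["time"].duplicated(keep="first")]
        if grp.empty:
            continue
        lats = grp["lat"].to_numpy(float)
        lons = grp["lon"].to_numpy(float)
        times = grp["time"].to_numpy()
        keep = np.zeros(len(grp), dtype=bool)
        keep[0] = True
        last = 0
        for i in range(1, len(grp)):
            dt_h = (times[i] - times[last]) / np.timedelta64(1, "h")
            dist = great_circle_km(lats[last], lons[last], lats[i], lons[i])
            if dt_h > 0 and dist / dt_h <= max_speed_kmh:
                keep[i] = True
                last = i
        kept_parts.append(grp.loc[keep])
    if not kept_parts:
        return fixes.iloc[0:0]
    return pd.concat(kept_parts).reset_index(drop=True)


# ---------------------------------------------------------------------------
# smoothing + regularization
# ---------------------------------------------------------------------------

def _smooth_positions(lats: np.ndarray, lons: np.ndarray,
                      window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered running mean on lat and unwrapped lon (dateline-safe)."""
    if window <= 1:
        return lats, lons
    lon_unwrapped = np.rad2deg(np.unwrap(np.deg2rad(lons)))
    s_lat = (pd.Series(lats).rolling(window, center=True, min_periods=1)
             .mean().to_numpy())
    s_lon = (pd.Series(lon_unwrapped).rolling(window, center=True, min_periods=1)
             .mean().to_numpy())
    return s_lat, _wrap_lon(s_lon)


def _slerp(v0: np.ndarray, v1: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Spherical linear interpolation between paired unit vectors."""
    dot = np.clip(np.sum(v0 * v1, axis=-1), -1.0, 1.0)
    omega = np.arccos(dot)
    out = np.empty_like(v0)
    small = omega < 1e-12
    f = frac[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        w0 = np.sin((1.0 - frac) * omega) / np.sin(omega)
        w1 = np.sin(frac * omega) / np.sin(omega)
    out = w0[..., None] * v0 + w1[..., None] * v1
    # nearly identical endpoints: fall back to linear blend
    if np.any(small):
        lin = (1.0 - f) * v0 + f * v1
        out[small] = lin[small]
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def regularize(fixes: pd.DataFrame,
               interval_hours: float = 6.0,
               smooth_window: int = 3) -> RegularTrack:
    """Smooth fixes and interpolate along great circles at regular knots.

    Knots are anchored at the animal's first retained fix and never
    extrapolated beyond the last fix. ``smooth_window <= 1`` disables
    smoothing. Expects the fixes of a single animal.
    """
    fixes = _check_fixes(fixes)
    if len(fixes) < 2:
        raise ValueError("regularize needs at least 2 fixes")
    animals = fixes["animal_id"].unique()
    if len(animals) != 1:
        raise ValueError("regularize expects fixes of a single animal; "
                         "group by animal_id first")
    fixes = fixes.sort_values("time")
    times = fixes["time"].to_numpy()
    lats, lons = _smooth_positions(fixes["lat"].to_numpy(float),
                                   fixes["lon"].to_numpy(float),
                                   smooth_window)
    span_h = (times[-1] - times[0]) / np.timedelta64(1, "h")
    if span_h < interval_hours:
        raise ValueError("fixes span less than one interval")
    n_knots = int(np.floor(span_h / interval_hours)) + 1
    step = np.timedelta64(int(round(interval_hours * 3600)), "s")
    knot_times = times[0] + np.arange(n_knots) * step

    t_sec = (times - times[0]) / np.timedelta64(1, "s")
    k_sec = (knot_times - times[0]) / np.timedelta64(1, "s")
    idx = np.searchsorted(t_sec, k_sec, side="right") - 1
    idx = np.clip(idx, 0, len(t_sec) - 2)
    dt = t_sec[idx + 1] - t_sec[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(dt > 0, (k_sec - t_sec[idx]) / dt, 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    vec = _to_unit_vectors(lats, lons)
    knot_vec = _slerp(vec[idx], vec[idx + 1], frac)
    knot_lat, knot_lon = _from_unit_vectors(knot_vec)
    return RegularTrack(animal_id=str(animals[0]), times=knot_times,
                        lats=knot_lat, lons=knot_lon,
                        interval_hours=interval_hours)


def track_from_regular_positions(df: pd.DataFrame,
                                 interval_hours: float = 6.0) -> RegularTrack:
    """Ingest externally regularized positions (e.g. a state-space model's
    most-probable track) so they can flow through the same downstream stages."""
    df = _check_fixes(df.assign(lc=df.get("lc", "3"))) if "lc" not in df.columns \
        else _check_fixes(df)
    df = df.sort_values("time")
    return RegularTrack(animal_id=str(df["animal_id"].iloc[0]),
                        times=df["time"].to_numpy(),
                        lats=df["lat"].to_numpy(float),
                        lons=df["lon"].to_numpy(float),
                        interval_hours=interval_hours)


# ---------------------------------------------------------------------------
# gap masking
# ---------------------------------------------------------------------------

def mask_gaps(track: RegularTrack, fixes: pd.DataFrame,
              max_gap_days: float = 3.0) -> RegularTrack:
    """Invalidate knots whose bracketing raw fixes are > ``max_gap_days`` apart.

    Speeds computed across such a hole would underestimate travel rate, so the
    knots strictly inside each long gap are masked and ``segment_id``
    increments across every masked run. Knots coincident with a raw fix time
    stay valid.
    """
    fixes = _check_fixes(fixes)
    ft = np.sort(fixes.loc[fixes["animal_id"] == track.animal_id, "time"]
                 .to_numpy())
    if ft.size == 0:
        raise ValueError("no raw fixes for this animal")
    kt = track.times
    prev_idx = np.searchsorted(ft, kt, side="right") - 1
    prev_idx = np.clip(prev_idx, 0, ft.size - 1)
    next_idx = np.clip(prev_idx + 1, 0, ft.size - 1)
    gap_days = (ft[next_idx] - ft[prev_idx]) / np.timedelta64(1, "D")
    at_fix = np.isin(kt, ft)
    invalid = (gap_days > max_gap_days) & ~at_fix
    valid = track.valid & ~invalid
    # segment id: number of completed invalid runs before each knot
    starts_run = invalid & ~np.concatenate([[False], invalid[:-1]])
    segment_id = np.cumsum(starts_run)
    return RegularTrack(animal_id=track.animal_id, times=track.times,
                        lats=track.lats, lons=track.lons, valid=valid,
                        segment_id=segment_id,
                        interval_hours=track.interval_hours)


# ---------------------------------------------------------------------------
# speeds
# ---------------------------------------------------------------------------

def compute_speeds(track: RegularTrack) -> SpeedSeries:
    """First-difference consecutive valid, same-segment positions into km/d."""
    n = len(track)
    if n < 2:
        return SpeedSeries(track.animal_id, *(np.array([]) for _ in range(4)),
                           np.array([], dtype=int))
    ok = (track.valid[:-1] & track.valid[1:]
          & (track.segment_id[:-1] == track.segment_id[1:]))
    i = np.nonzero(ok)[0]
    step_days = track.interval_hours / 24.0
    dist = great_circle_km(track.lats[i], track.lons[i],
                           track.lats[i + 1], track.lons[i + 1])
    speeds = np.atleast_1d(dist) / step_days
    mid_times = track.times[i] + (track.times[i + 1] - track.times[i]) / 2
    mid_lats = 0.5 * (track.lats[i] + track.lats[i + 1])
    dlon = _wrap_lon(track.lons[i + 1] - track.lons[i])
    mid_lons = _wrap_lon(track.lons[i] + 0.5 * dlon)
    return SpeedSeries(animal_id=track.animal_id, step_mid_times=mid_times,
                       speeds=speeds, step_mid_lats=mid_lats,
                       step_mid_lons=mid_lons,
                       segment_id=track.segment_id[i])


def process_track(fixes: pd.DataFrame,
                  max_speed_kmh: float = 10.0,
                  drop_classes: set[str] = frozenset({"Z"}),
                  interval_hours: float = 6.0,
                  smooth_window: int = 3,
                  max_gap_days: float = 3.0) -> tuple[RegularTrack, SpeedSeries]:
    """Full chain for one animal: filter -> regularize -> mask -> speeds."""
    kept = filter_fixes(fixes, max_speed_kmh=max_speed_kmh,
                        drop_classes=drop_classes)
    track = regularize(kept, interval_hours=interval_hours,
                       smooth_window=smooth_window)
    track = mask_gaps(track, kept, max_gap_days=max_gap_days)
    return track, compute_speeds(track)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fixes_csv(path) -> pd.DataFrame:
    """Read the track CSV dialect (id, timestamp ISO-8601 UTC, lat, lon, lc)."""
    df = pd.read_csv(path, dtype={"lc": str})
    df = df.rename(columns={"id": "animal_id", "timestamp": "time"})
    return _check_fixes(df)


def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    out = fixes.rename(columns={"animal_id": "id", "time": "timestamp"})
    out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%SZ")
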