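"""End-to-end orchestration: two-population comparison and reporting.

Composes the stages in analysis order — simulate (or load) fixes, filter,
regularize, mask gaps, first-difference speeds, modality analysis,
current correction, repeat modality on swimming speeds, chlorophyll
co-location, dive-depth/latitude binning — and emits one JSON-serializable
report per population plus a comparison block. Deterministic under the
config seed (reruns are byte-identical).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pelagitrack import track_processing as tp
from pelagitrack import modality_analysis as ma
from pelagitrack import synthetic_data as sd
from pelagitrack import current_correction as cc
from pelagitrack import environment_colocation as ec

logger = logging.getLogger(__name__)

REPORT_SCHEMA = "pelagitrack-report-v1"

__all__ = ["PopulationConfig", "AnalysisConfig", "run_population_analysis",
           "compare_processing_methods"]


@dataclass(frozen=True)
class PopulationConfig:
    """One population's inputs and processing recipe.

    ``preset`` selects the synthetic scenario family ("na": all location
    classes analysed, bimodal two-regime movement; "ep": Z-class dropped,
    single-regime movement). ``fixes`` may instead point to a CSV of real
    fixes (then no synthetic ocean stages run unless an ocean is supplied).
    """

    name: str
    preset: str = "na"                      # "na" | "ep"
    n_animals: int = 3
    duration_days: float = 200.0
    bin_width_kmd: float = 5.0
    drop_classes: tuple[str, ...] = ("Z",)
    max_speed_kmh: float = 10.0
    max_gap_days: float = 3.0
    smooth_window: int = 3
    interval_hours: float = 6.0
    n_boot: int = 2000
    foraging_fraction: float = 0.4
    min_prominence: float = 0.05
    correct_currents: bool = True
    colocate: bool = True
    dive_noise_sd: float = 5.0
    dive_link: tuple[float, float] = (1.0, 0.0)


def _default_populations():
    return (
        PopulationConfig(name="NA", preset="na", drop_classes=(),
                         bin_width_kmd=5.0),
        PopulationConfig(name="EP", preset="ep", drop_classes=("Z",),
                         bin_width_kmd=6.0),
    )


@dataclass(frozen=True)
class AnalysisConfig:
    populations: tuple[PopulationConfig, ...] = field(
        default_factory=_default_populations)
    seed: int = 0


def _ocean_params_for(preset: str, tracks: list[pd.DataFrame],
                      duration_days: float) -> sd.OceanParams:
    """Ocean domain sized to the simulated tracks (plus margin)."""
    lat_min = min(float(t["lat"].min()) for t in tracks) - 3.0
    lat_max = max(float(t["lat"].max()) for t in tracks) + 3.0
    lon_min = min(float(t["lon"].min()) for t in tracks) - 3.0
    lon_max = max(float(t["lon"].max()) for t in tracks) + 3.0
    n_windows = int(np.ceil(duration_days / 8.0)) + 2
    kwargs = dict(lat_range=(lat_min, lat_max), lon_range=(lon_min, lon_max),
                  chl_res_deg=0.1, n_windows=n_windows)
    if preset == "ep":
        kwargs.update(ssh_center=(-25.0, -100.0),
                      thermocline=sd.ThermoclineShape(peak_lat=-25.0),
                      chl_foraging_box=(0.0, 8.0, -110.0, -90.0),
                      chl_gyre_box=(-32.0, -18.0, -110.0, -90.0))
    return sd.OceanParams(**kwargs)


def _scenario_for(pop: PopulationConfig, seed: int, idx: int):
    make = sd.na_scenario if pop.preset == "na" else sd.ep_scenario
    return make(seed=seed + idx, duration_days=pop.duration_days,
                animal_id=f"{pop.name.lower()}-{idx:02d}")


def _analyze_population(pop: PopulationConfig, seed: int) -> dict:
    scens = [_scenario_for(pop, seed, i) for i in range(pop.n_animals)]
    trues = [sd.simulate_true_track(s) for s in scens]
    ocean = sd.synth_ocean(
        _ocean_params_for(pop.preset, trues, pop.duration_days), seed=seed)
    geo = cc.geostrophic_from_ssh(ocean.ssh)
    ek = cc.ekman_from_wind(ocean.wind)
    current = cc.total_current(geo, ek)

    accounting = {"raw_fixes": 0, "class_dropped": 0, "speed_dropped": 0,
                  "gap_masked_knots": 0, "kept_fixes": 0}
    speed_series, swim_speeds, dive_tables, track_frames = [], [], [], []
    for i in range(pop.n_animals):
        scen, true = scens[i], trues[i]
        fixes = sd.degrade_to_argos(true, scen)
        accounting["raw_fixes"] += len(fixes)
        n_class = fixes["lc"].isin(pop.drop_classes).sum()
        kept = tp.filter_fixes(fixes, max_speed_kmh=pop.max_speed_kmh,
                               drop_classes=set(pop.drop_classes))
        accounting["class_dropped"] += int(n_class)
        accounting["speed_dropped"] += len(fixes) - int(n_class) - len(kept)
        accounting["kept_fixes"] += len(kept)
        track = tp.regularize(kept, interval_hours=pop.interval_hours,
                              smooth_window=pop.smooth_window)
        track = tp.mask_gaps(track, kept, max_gap_days=pop.max_gap_days)
        accounting["gap_masked_knots"] += int((~track.valid).sum())
        speeds = tp.compute_speeds(track)
        speed_series.append(speeds)
        track_frames.append(track.to_frame())
        if pop.correct_currents:
            corr = cc.correct_track(track, current)
            swim_speeds.append(
                corr.loc[~corr["current_missing"], "speed_swim"].to_numpy())
        if pop.colocate:
            dive_tables.append(sd.synth_dive_summaries(
                true, ocean, noise_sd=pop.dive_noise_sd, link=pop.dive_link,
                seed=seed + i, animal_id=scen.animal_id))

    pooled = tp.SpeedSeries.concat(speed_series)
    speeds_all = pooled["speed_kmd"].to_numpy()
    modality = ma.analyze_speeds(
        speeds_all, bin_width=pop.bin_width_kmd, n_boot=pop.n_boot,
        seed=seed + 7919, min_prominence=pop.min_prominence,
        fraction=pop.foraging_fraction)
    report = {
        "population": pop.name,
        "n_animals": pop.n_animals,
        "n_steps": int(speeds_all.size),
        "speed_mean_kmd": float(speeds_all.mean()),
        "speed_sd_kmd": float(speeds_all.std(ddof=1)),
        "modality": modality.to_dict(),
        "accounting": accounting,
        "thresholds": {
            "max_speed_kmh": pop.max_speed_kmh,
            "max_gap_days": pop.max_gap_days,
            "drop_classes": list(pop.drop_classes),
            "smooth_window": pop.smooth_window,
            "interval_hours": pop.interval_hours,
            "foraging_fraction": pop.foraging_fraction,
            "bin_width_kmd": pop.bin_width_kmd,
        },
    }
    if pop.correct_currents and swim_speeds:
        swim = np.concatenate(swim_speeds)
        report["corrected_modality"] = ma.analyze_speeds(
            swim, bin_width=pop.bin_width_kmd, n_boot=pop.n_boot,
            seed=seed + 104729, min_prominence=pop.min_prominence,
            fraction=pop.foraging_fraction).to_dict()
    if pop.colocate:
        bimodal = len(modality.modes) > 1 and modality.p_value < 0.05
        mask, _ = ma.classify_foraging(speeds_all,
                                       modality.modal_transiting_speed,
                                       fraction=pop.foraging_fraction)
        lats = pooled["mid_lat"].to_numpy()
        lons = pooled["mid_lon"].to_numpy()
        times = pooled["mid_time"].to_numpy()
        chl_all = ec.sample_chl_track(ocean.chl, lats, lons, times)
        report["chl_all"] = ec.chl_summary(chl_all)
        report["chl_selection"] = "foraging_steps" if bimodal else "all_steps"
        report["chl_foraging"] = ec.chl_summary(chl_all[mask]) \
            if mask.any() else None
        dives = pd.concat(dive_tables, ignore_index=True)
        tracks = pd.concat(track_frames, ignore_index=True)
        table = ec.bin_dive_depths(dives, tracks, ocean.climatology)
        report["depth_lat_table"] = table.to_dict(orient="records")
    return report


def run_population_analysis(config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Run the full comparison; returns the JSON-ready report dict."""
    report = {"schema": REPORT_SCHEMA, "seed": config.seed, "populations": []}
    for pop in config.populations:
        logger.info("analysing population %s", pop.name)
        try:
            report["populations"].append(
                _analyze_population(pop, seed=config.seed))
        except Exception as exc:
            raise RuntimeError(
                f"stage failure in population {pop.name}: {exc}") from exc
    if len(report["populations"]) >= 2:
        a, b = report["populations"][:2]
        cmp_block = {
            "speed_mean_difference_kmd":
                abs(a["speed_mean_kmd"] - b["speed_mean_kmd"]),
            "verdicts": {
                a["population"]:
                    "multimodal" if a["modality"]["p_value"] < 0.05
                    else "unimodal",
                b["population"]:
                    "multimodal" if b["modality"]["p_value"] < 0.05
                    else "unimodal",
            },
        }
        if a.get("chl_foraging") and b.get("chl_all"):
            cmp_block["chl_ratio_foraging_vs_searching"] = (
                a["chl_foraging"]["mean"] / b["chl_all"]["mean"])
        report["comparison"] = cmp_block
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=True)


# ---------------------------------------------------------------------------
# processing-method comparison
# ---------------------------------------------------------------------------

def compare_processing_methods(fixes: pd.DataFrame | None = None,
                               alternative_track: tp.RegularTrack | None = None,
                               means: tuple[float, float] | None = None,
                               alt_smooth_window: int = 7,
                               n_boot: int = 500,
                               seed: int = 0,
                               **process_kwargs) -> dict:
    """Mean-speed difference between two track-processing routes.

    Three modes:

    * ``means=(m_simple, m_alternative)`` — printed/extern means only; the
      report is just their absolute difference.
    * ``fixes`` plus ``alternative_track`` — the in-package filter path
      against an externally regularized track (e.g. a state-space model's
      output, via :func:`~pelagitrack.track_processing.track_from_regular_positions`).
    * ``fixes`` alone — the alternative is the same path with a declared
      heavier smoother (``alt_smooth_window``).

    Dip verdicts for both speed series are included when computable.
    """
    if means is not None:
        m0, m1 = float(means[0]), float(means[1])
        return {"mean_simple_kmd": m0, "mean_alternative_kmd": m1,
                "difference_kmd": abs(m1 - m0), "mode": "printed_means"}
    if fixes is None:
        raise ValueError("need fixes or means")
    _, speeds_simple = tp.process_track(fixes, **process_kwargs)
    if alternative_track is not None:
        alt_speeds = tp.compute_speeds(alternative_track)
        mode = "external_track"
    else:
        kwargs = dict(process_kwargs)
        kwargs["smooth_window"] = alt_smooth_window
        _, alt_speeds = tp.process_track(fixes, **kwargs)
        mode = "heavier_smoother"
    m0 = float(np.mean(speeds_simple.speeds))
    m1 = float(np.mean(alt_speeds.speeds))
    out = {"mean_simple_kmd": m0, "mean_alternative_kmd": m1,
           "difference_kmd": abs(m1 - m0), "mode": mode}
    for label, sp in (("simple", speeds_simple.speeds),
                      ("alternative", alt_speeds.speeds)):
        if sp.size >= 4:
            res = ma.dip_test(sp, n_boot=max(int(n_boot), 100), seed=seed)
            out[f"dip_p_{label}"] = res.p_value
            out[f"verdict_{label}"] = ("multimodal" if res.p_value < 0.05
                                       else "unimodal")
    return out
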