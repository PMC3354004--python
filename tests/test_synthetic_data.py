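"""Generator behaviour: movement model, Argos degradation, ocean fields."""

import numpy as np
import pandas as pd
import pytest

from pelagitrack.synthetic_data import (
    MovementRegimeParams, SyntheticScenario, OceanParams, ThermoclineShape,
    na_scenario, ep_scenario, simulate_true_track, degrade_to_argos,
    sample_speed_mixture, synth_ocean, synth_dive_summaries,
    save_field_text, load_field_text, write_scenario_config,
    read_scenario_config, STANDARD_DEPTHS_M)
from pelagitrack.environment_colocation import (
    thermocline_depth_grid, nutricline_depth_grid)


def constant_speed_scenario(speed=21.0, **kw):
    reg = MovementRegimeParams("steady", speed,
                               (speed - 1e-3, speed + 1e-3),
                               turning_concentration=50.0, occupancy=1.0,
                               speed_shape=500.0)
    return SyntheticScenario(regimes=(reg,), duration_days=kw.pop("duration_days", 1.0),
                             gap_spec=(), seed=kw.pop("seed", 0), **kw)


class TestRegimeParams:
    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            MovementRegimeParams("x", 10, (15, 5), 1.0, 1.0)

    def test_center_outside_band_rejected(self):
        with pytest.raises(ValueError, match="center"):
            MovementRegimeParams("x", 50, (0, 15), 1.0, 1.0)

    def test_occupancies_must_sum_to_one(self):
        reg = MovementRegimeParams("x", 10, (0, 15), 1.0, 0.5)
        with pytest.raises(ValueError, match="occupanc"):
            SyntheticScenario(regimes=(reg,))

    def test_speeds_respect_band(self):
        reg = MovementRegimeParams("x", 12.5, (0, 15), 1.0, 1.0)
        sp = reg.sample_speeds(2000, np.random.default_rng(0))
        assert sp.min() >= 0 and sp.max() <= 15


class TestSimulateTrueTrack:
    def test_constant_speed_steps(self):
        """One day of 6-h steps at 21 km/d covers 5.25 km per step."""
        from pelagitrack.track_processing import great_circle_km
        track = simulate_true_track(constant_speed_scenario())
        assert len(track) == 5
        d = great_circle_km(track["lat"][:-1], track["lon"][:-1],
                            track["lat"][1:].to_numpy(),
                            track["lon"][1:].to_numpy())
        np.testing.assert_allclose(d, 5.25, rtol=1e-3)

    def test_markov_occupancy_converges(self):
        """Empirical occupancy within 2 effective SEs at n = 1e4 steps."""
        scen = na_scenario(seed=12, duration_days=2500.0, gap_spec=())
        track = simulate_true_track(scen)
        counts = track["regime"].value_counts(normalize=True)
        n = len(track)
        rho = scen.regime_persistence
        tau = (1 + rho) / (1 - rho)            # integrated autocorrelation
        for reg in scen.regimes:
            se = np.sqrt(reg.occupancy * (1 - reg.occupancy) * tau / n)
            assert counts[reg.name] == pytest.approx(reg.occupancy,
                                                     abs=2 * se + 1e-3)

    def test_same_seed_identical(self):
        scen = na_scenario(seed=5, duration_days=10.0)
        pd.testing.assert_frame_equal(simulate_true_track(scen),
                                      simulate_true_track(scen))

    def test_speed_mixture_band_weights(self):
        sp = sample_speed_mixture(na_scenario(seed=8), 10_000)
        assert np.mean((sp >= 0) & (sp <= 15)) == pytest.approx(0.29, abs=0.02)
        assert np.mean((sp >= 20) & (sp <= 45)) == pytest.approx(0.42, abs=0.02)


class TestDegradeToArgos:
    def test_zero_error_full_rate_reproduces_truth(self):
        scen = constant_speed_scenario(
            duration_days=5.0,
            argos_class_mix={"3": 1.0},
            class_error_sd={"3": 0.0})
        true = simulate_true_track(scen)
        fixes = degrade_to_argos(true, scen)
        assert len(fixes) == len(true)
        np.testing.assert_allclose(fixes["lat"], true["lat"], atol=1e-12)
        np.testing.assert_allclose(fixes["lon"], true["lon"], atol=1e-12)

    def test_gap_spec_removes_days(self):
        scen = na_scenario(seed=2, duration_days=30.0, gap_spec=((10.0, 4.0),))
        true = simulate_true_track(scen)
        fixes = degrade_to_argos(true, scen)
        day = (fixes["time"] - true["time"].iloc[0]).dt.total_seconds() / 86400
        assert not ((day >= 10.0) & (day < 14.0)).any()

    def test_all_class_z(self):
        scen = na_scenario(seed=3, duration_days=10.0,
                           argos_class_mix={"Z": 1.0})
        fixes = degrade_to_argos(simulate_true_track(scen), scen)
        assert (fixes["lc"] == "Z").all()

    def test_sorted_by_time(self):
        scen = na_scenario(seed=4, duration_days=20.0)
        fixes = degrade_to_argos(simulate_true_track(scen), scen)
        assert fixes["time"].is_monotonic_increasing


class TestSynthOcean:
    def test_flat_ssh_gives_zero_geostrophic(self):
        from pelagitrack.current_correction import geostrophic_from_ssh
        params = OceanParams(lat_range=(5.0, 20.0), lon_range=(-60.0, -50.0),
                            ssh_amp_m=0.0, n_windows=2)
        ocean = synth_ocean(params, seed=0)
        cur = geostrophic_from_ssh(ocean.ssh)
        np.testing.assert_allclose(cur["u"], 0.0, atol=1e-12)
        np.testing.assert_allclose(cur["v"], 0.0, atol=1e-12)

    def test_constant_thermocline_recovered_everywhere(self):
        params = OceanParams(
            lat_range=(5.0, 20.0), lon_range=(-60.0, -50.0), n_windows=2,
            thermocline=ThermoclineShape(base_m=75.0, amplitude_m=0.0))
        ocean = synth_ocean(params, seed=0)
        depth = thermocline_depth_grid(ocean.climatology)
        np.testing.assert_allclose(depth, 75.0)
        np.testing.assert_allclose(ocean.thermocline_true, 75.0)

    def test_generator_analyzer_closure(self, small_ocean):
        """Analyzers recover the generator's snapped targets exactly."""
        thermo = thermocline_depth_grid(small_ocean.climatology)
        nutr = nutricline_depth_grid(small_ocean.climatology, threshold=2.0)
        np.testing.assert_allclose(thermo, small_ocean.thermocline_true,
                                   atol=1e-9)
        np.testing.assert_allclose(nutr, small_ocean.nutricline_true,
                                   atol=1e-9)

    def test_profile_structure(self, small_ocean):
        clim = small_ocean.climatology
        assert np.all(np.diff(clim["depth"]) > 0)
        nit = clim["nitrate"].to_numpy()
        assert np.all(np.diff(nit, axis=0) >= 0)        # nitrate increases
        assert float(small_ocean.chl.min(skipna=True)) >= 0.0

    def test_gyre_box_mean_within_three_se(self, small_ocean):
        """Sampled lognormal CHL box mean close to the requested parameter."""
        p = small_ocean.params
        y0, y1, x0, x1 = p.chl_gyre_box
        box = small_ocean.chl.sel(lat=slice(y0, y1), lon=slice(x0, x1))
        vals = box.to_numpy()
        vals = vals[np.isfinite(vals)]
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert vals.mean() == pytest.approx(p.chl_gyre_mean, abs=3 * se)

    def test_foraging_box_mean_exceeds_gyre(self, small_ocean):
        p = small_ocean.params
        def boxmean(b):
            y0, y1, x0, x1 = b
            v = small_ocean.chl.sel(lat=slice(y0, y1),
                                    lon=slice(x0, x1)).to_numpy()
            return np.nanmean(v)
        assert boxmean(p.chl_foraging_box) > boxmean(p.chl_gyre_box)


class TestDiveSummaries:
    def test_identity_link_zero_noise_equals_thermocline(self, small_ocean):
        scen = constant_speed_scenario(duration_days=4.0)
        true = simulate_true_track(scen)
        dives = synth_dive_summaries(true, small_ocean, noise_sd=0.0,
                                     link=(1.0, 0.0), seed=0)
        import xarray as xr
        local = small_ocean.thermocline_true.sel(
            lat=xr.DataArray(true["lat"].to_numpy(), dims="p"),
            lon=xr.DataArray(true["lon"].to_numpy(), dims="p"),
            method="nearest").to_numpy()
        np.testing.assert_allclose(dives["mean_depth_m"], local, atol=1e-9)

    def test_shallow_lat_shallower_dives(self, small_ocean):
        # gyre-bowl shape: cells near the 28N peak are deeper than near 5N
        shallow = constant_speed_scenario(duration_days=2.0,
                                          start_position=(5.0, -50.0))
        deep = constant_speed_scenario(duration_days=2.0,
                                       start_position=(27.0, -50.0))
        d_shallow = synth_dive_summaries(simulate_true_track(shallow),
                                         small_ocean, noise_sd=0, seed=0)
        d_deep = synth_dive_summaries(simulate_true_track(deep),
                                      small_ocean, noise_sd=0, seed=0)
        assert d_shallow["mean_depth_m"].mean() < d_deep["mean_depth_m"].mean()

    def test_deterministic(self, small_ocean):
        scen = constant_speed_scenario(duration_days=2.0)
        true = simulate_true_track(scen)
        a = synth_dive_summaries(true, small_ocean, seed=3)
        b = synth_dive_summaries(true, small_ocean, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestIO:
    def test_text_field_roundtrip(self, small_ocean, tmp_path):
        path = tmp_path / "ssh.csv"
        save_field_text(small_ocean.ssh, path)
        back = load_field_text(path)
        np.testing.assert_allclose(back.to_numpy(), small_ocean.ssh.to_numpy(),
                                   rtol=1e-12)

    def test_netcdf_roundtrip(self, small_ocean, tmp_path):
        import xarray as xr
        path = str(tmp_path / "ssh.nc")
        small_ocean.ssh.to_netcdf(path, engine="scipy")
        back = xr.open_dataarray(path)
        np.testing.assert_allclose(back.to_numpy(), small_ocean.ssh.to_numpy())

    def test_scenario_config_roundtrip(self, tmp_path):
        scen = na_scenario(seed=77, duration_days=42.0)
        path = tmp_path / "scenario.cfg"
        write_scenario_config(scen, path)
        back = read_scenario_config(path)
        assert back == scen

    def test_fixes_csv_roundtrip(self, tmp_path):
        from pelagitrack.track_processing import read_fixes_csv, write_fixes_csv
        scen = na_scenario(seed=1, duration_days=5.0)
        fixes = degrade_to_argos(simulate_true_track(scen), scen)
        path = tmp_path / "fixes.csv"
        write_fixes_csv(fixes, path)
        back = read_fixes_csv(path)
        assert len(back) == len(fixes)
        np.testing.assert_allclose(back["lat"], fixes["lat"], atol=1e-6)
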