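import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_fixes(times_h, lats, lons, lcs=None, animal="t1"):
    """Fix table from hour offsets and coordinates."""
    t0 = np.datetime64("2005-01-01T00:00:00", "ns")
    times = [t0 + np.timedelta64(int(h * 3600), "s") for h in times_h]
    n = len(times)
    return pd.DataFrame({
        "animal_id": animal,
        "time": times,
        "lat": np.asarray(lats, dtype=float),
        "lon": np.asarray(lons, dtype=float),
        "lc": lcs if lcs is not None else ["3"] * n,
    })


@pytest.fixture(scope="session")
def small_ocean():
    from pelagitrack.synthetic_data import synth_ocean, OceanParams
    params = OceanParams(lat_range=(0.0, 30.0), lon_range=(-60.0, -40.0),
                        n_windows=4, chl_res_deg=0.1,
                        chl_foraging_box=(20.0, 28.0, -55.0, -45.0),
                        chl_gyre_box=(2.0, 10.0, -55.0, -45.0))
    return synth_ocean(params, seed=11)
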