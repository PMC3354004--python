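# pelagitrack

Movement-pattern analysis for satellite-tracked pelagic animals: from raw
Argos fixes to a defensible verdict on whether a population's travel-speed
distribution is unimodal (pure transit) or multimodal (transit plus slow
area-restricted search, the behavioural signature of foraging), with
ocean-current correction and environmental co-location.

The package grew out of the contrast between North Atlantic (NA) and
Eastern Pacific (EP) leatherback turtles: NA travel speeds are bimodal —
a slow foraging mode near 12.5 km/d and a transit mode near 37.5 km/d —
while EP speeds show a single transit mode near 21 km/d, suggesting EP
turtles rarely achieve high foraging success. It is written for movement
ecologists who want that analysis chain as reusable, tested parts, and it
bundles a synthetic-data generator (regime-switching correlated random
walks, an Argos observation model, gridded ocean fields) so the whole
pipeline runs end to end without downloading any data.

## The analysis

1. **Track processing** — drop unusable Argos classes, discard fixes
   implying > 10 km/h, smooth, interpolate along great circles to regular
   6-h positions, mask stretches with > 3 days of missing data, and
   first-difference into travel speeds (km/d).
2. **Modality** — Hartigan's dip statistic on the raw speeds,

   dip(Fₙ) = min over unimodal G of sup ₓ |Fₙ(x) − G(x)|,

   computed from scratch with the greatest-convex-minorant /
   least-concave-majorant iteration and calibrated by a Uniform(0,1)
   bootstrap; histogram modes, the modal transiting speed (the mode holding
   most of the data), and the foraging threshold at 40 % of it
   (15 km/d for a 37.5 km/d mode; 8.4 km/d for 21 km/d).
3. **Current correction** — geostrophic velocity from sea-surface height
   with an equatorial β-plane blend inside ±4°, a slab-model Ekman
   component from wind stress, subtracted from step velocities to reveal
   swimming speed.
4. **Co-location** — chlorophyll-a from 8-day composites with a bounded
   cloud-gap ring search; thermocline depth (maximum temperature gradient)
   and nutricline depth (2 µmol nitrate isocline) from a 1° climatology;
   dive depth against latitude in 1° bins.

See `docs/methods.md` for the model details, parameter defaults and
limitations.

## Worked example

Simulate an EP-like animal, process it, and test its speeds for modality:

```sh
pelagitrack simulate --preset ep --seed 2 --duration-days 120 --out-fixes ep_fixes.csv
pelagitrack process  --fixes ep_fixes.csv --out-speeds ep_speeds.csv
pelagitrack modality --speeds ep_speeds.csv --bin-width 6 --n-boot 2000 --seed 1 --out ep_modality.json
```

which logs

```
simulate: 481 true positions -> 465 fixes
process ep-synth: 465 fixes -> 481 knots -> 463 speeds
modality: n=463 dip=0.0122 p=0.9585 modal=21.0 km/d
```

and writes

```json
{
  "dip": 0.0122,
  "p_value": 0.9585,
  "modes_kmd": [21.0],
  "modal_transiting_speed_kmd": 21.0,
  "foraging_threshold_kmd": 8.4,
  "band_masses": [1.0],
  "n": 463
}
```

Read: the dip test finds no evidence against unimodality (p ≈ 0.96 —
values near 1 are expected for smooth unimodal speed distributions under
the uniform-null calibration), the single mode sits in the bin centered at
21 km/d, and steps at or below 8.4 km/d (40 % of the mode) would be flagged
as putative foraging. The same chain on the NA preset yields two modes
(12.5 and 37.5 km/d), a dip p-value below 0.01, and a 15 km/d foraging
threshold. `pelagitrack run --seed 1 --out report.json` produces the full
two-population comparison — verdicts before and after current correction,
CHL summaries, depth-by-latitude tables and a per-stage fix accounting —
as one JSON report.

The same steps are available as library calls (`process_track`,
`analyze_speeds`, `correct_track`, `bin_dive_depths`, ...), which is the
interface the test suite exercises.

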