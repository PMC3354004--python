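# Methods

`pelagitrack` reimplements, as a tested pipeline, the movement-pattern
analysis used to contrast North Atlantic (NA) and Eastern Pacific (EP)
leatherback turtle populations: Argos track filtering and regularization,
travel-speed modality with a foraging/transit classification, ocean-current
correction, and co-location with chlorophyll-a and thermocline/nutricline
structure. Because the original tracking data are proprietary, the package
ships a synthetic-data generator that reproduces the statistical structure
of those inputs, so every stage runs and is testable offline.

## Track processing

Raw Argos fixes (`animal_id, time, lat, lon, lc`) pass through four stages:

1. **Class and speed filtering.** Location classes in a configurable drop
   set (default `Z`) are removed first; then a single forward pass keeps a
   fix only if its implied great-circle speed from the *last kept* fix is at
   most 10 km/h. Forward-pass ("keep last kept") semantics are the standard
   Argos filtering behaviour; pairwise deletion is ambiguous. The filter is
   idempotent, and every kept consecutive pair respects the bound.
2. **Smoothing.** A centered running mean over 3 fixes on latitude and
   unwrapped longitude (dateline-safe). The window is a declared knob;
   3 is the default. Smoothing trades position noise against a shortening
   of tortuous path segments — see "known limitations".
3. **Regularization.** Great-circle (spherical linear) interpolation of the
   smoothed fixes at exact 6-h knots anchored at each animal's first
   retained fix; no extrapolation beyond the last fix. Knot phase is
   per-animal since cross-animal alignment carries no information here.
4. **Gap masking and first differencing.** Knots whose bracketing raw fixes
   are more than 3 days apart are invalidated (speeds across transmission
   holes underestimate travel rate); `segment_id` increments across each
   masked run and no speed is ever formed across a segment boundary.
   Travel speed is haversine distance (sphere, R = 6371 km) over the 6-h
   step, expressed in km/d.

An ingestion hook (`track_from_regular_positions`) accepts externally
regularized 6-h positions — e.g. the most-probable track of a Bayesian
switching state-space model (SSSM) — so that alternative processing routes
can be compared (`compare_processing_methods`) without reimplementing them.
The SSSM itself is deliberately not reimplemented; its behavioural-mode
output is out of scope.

## Travel-speed modality

**Dip statistic.** Unimodality is tested with Hartigan's dip: the largest
vertical distance between the empirical CDF and the nearest unimodal CDF
(convex then concave). The implementation works on the unique sorted values
with multiplicities: the greatest convex minorant (GCM) is the lower convex
hull of the ECDF left limits, the least concave majorant (LCM) the upper
hull of the right values; the iteration shrinks the candidate modal
interval to the hull vertices bracketing the largest GCM–LCM gap, while
accumulating the one-sided sup deviation of the ECDF from the convex fit
left of the interval and from the concave fit right of it. The jump at the
interval's own endpoints is excluded from those tail scans (an atom at the
mode absorbs it; if the mode lands deeper inside, the next iteration
re-anchors there and re-counts it). The dip is half the largest accumulated
deviation. The core is numba-compiled (about 50 µs at n = 500).

Correctness is established against an independent brute-force oracle
(tests/_dip_oracle.py): for n ≤ 8, the minimal sup-distance to a piecewise
linear unimodal CDF — with kinks at the data points, a jump allowed at the
mode, and the mode scanned over a fine grid — is solved as a linear
program. Exact closed-form anchors are also asserted: equally spaced
samples give 1/(2n); two equal point masses give 0.25; atoms of mass p and
q give min(p, q)/2.

**Calibration.** p-values come from a bootstrap under the Uniform(0,1)
null with an add-one rule, `p = (1 + #{dip* >= dip}) / (n_boot + 1)`,
n_boot = 2000 by default. The uniform is the least-favourable unimodal
null, so the test is *exact* under it (type-I error nominal, verified by
simulation) and *conservative* for peaked unimodal data: normal samples at
n = 500 essentially never reject. This conservatism is a property of the
classical calibration, not a defect; it matches the behaviour implied by
near-unity p-values on clearly unimodal travel-speed data.

**Modes and the foraging threshold.** Frequency distributions use
half-open bins `[k·w, (k+1)·w)` with the first edge at 0. The NA default
width is 5 km/d (mode centers at 12.5/37.5 km/d); the EP default is
6 km/d, whose centers include the published 21 km/d mode (a 5 km/d grid has
no center at 21). Modes are local maxima that exceed their adjacent troughs
by at least 5 % of the maximum count (weakest failing peak merged
iteratively). The histogram is partitioned at the minimum-count bin between
adjacent modes; the **modal transiting speed** is the mode whose partition
holds the most mass (ties break toward the faster mode, since transit is
a priori the dominant behaviour). Steps at or below 40 % of the modal
transiting speed (inclusive) are classified as putative foraging; the dip
test itself always runs on the raw, unbinned speeds. Steps are pooled
across animals by default; per-animal weighting is possible by running the
analysis per animal.

## Current correction

Geostrophic velocity from SSH: u = −(g/f)·∂η/∂y, v = (g/f)·∂η/∂x with
central differences and f = 2Ω sin(lat). Within ±4° of the equator the
β-plane form u = −(g/β)·∂²η/∂y², v = (g/β)·∂²η/∂x∂y replaces the f-form
through a Gaussian blend w = exp(−(lat/2.2°)²) — the standard
satellite-altimetry treatment; the blend weight at the band edge is ~3.7 %,
so the field is continuous there (asserted within a 10 % relative jump for
a linear-slope SSH, which includes the f-form's own ~5 % variation across
the edge) and finite on the equator. The Ekman component is a two-parameter
slab model, (u + iv) = (τx + iτy)/(ρ h (r + if)) with layer depth
h = 25 m and friction r = 1e-4 s⁻¹ — conventions, exposed as configuration,
not values asserted by any data product. Velocities are km/d at the
interface (1 m/s = 86.4 km/d).

Ground velocity is the 6-h displacement resolved into east/north components
on a local tangent plane at the step midpoint, where the current is sampled
(bilinear in space, nearest composite in time). Swimming velocity is ground
minus current — exactly invertible, and steps with no current available are
flagged missing rather than treated as zero-current.

## Environmental co-location

* **Thermocline**: depth of the maximum |ΔT/Δz| between consecutive
  standard levels, reported at the layer midpoint (staggered convention),
  ties toward the shallower layer, NaN for isothermal profiles.
* **Nutricline**: shallowest depth where nitrate crosses 2 µmol, linearly
  interpolated; 0 if the surface already exceeds it; NaN if never reached.
  Monotone in the threshold on monotone profiles.
* **Chlorophyll**: the 8-day composite containing the timestamp, nearest
  0.05° cell; cloud gaps trigger a square ring search of at most 3 rings
  (≤ 0.35° reach — bounded to avoid long-range fill bias), taking the mean
  of the first non-empty ring. Summaries use the n−1 sample SD and flag
  single-sample SDs undefined.
* **Dive depth vs latitude**: 6-h mean dive depths joined to track
  positions by animal and bin start, grouped into 1° latitude bins centered
  on half-integers (aligned with the 1° climatology); per bin the mean ± SD
  dive depth plus the mean thermocline/nutricline depth over the cells the
  animals actually traversed (not zonal means over the whole basin).

## Synthetic data generator

The generator emulates the study's inputs; its defaults *are* the study
conditions of every end-to-end test.

**Movement.** A regime-switching correlated random walk on the sphere at
6-h steps. Per regime: ground speed from a gamma distribution
parameterized by its mode (`speed_center`) and shape, truncated to the
regime's `speed_band`; heading increments wrapped-normal with a per-regime
concentration (low = tortuous ARS, high = directed transit). Regime
switching is Markov with transition matrix ρI + (1−ρ)·1πᵀ, so the
stationary distribution equals the prescribed occupancies π; ρ = 0.8 gives
mean bout lengths near 2 days. The NA preset is a three-component mixture
with weights 0.29 / 0.42 / 0.29: an ARS regime (mode 12.5 km/d, band
0–15), a transit regime (mode 37.5, band 20–45) and a fast tail (band
45–95), making the published 29 %/42 % band occupancies recoverable and
leak-free. The EP preset is a single broad transit regime with mode
21 km/d (gamma shape 9, mean ≈ 24 km/d). Transit-regime shapes are chosen
so the histogram mode is stable at the published bin centers under the
Argos observation noise below; the published per-class error magnitudes
were never stated by the original analysis, so this interplay is a
generator design choice, not an estimate.

**Observation.** Fixes are the 6-h true positions thinned to the fix rate,
with isotropic Gaussian position error by Argos class (defaults 0.25, 0.5,
1.5, 5, 10, 20, 50 km for classes 3, 2, 1, 0, A, B, Z — published orders
of magnitude) and classes drawn from a quality mix weighted toward good
classes (42 % class 3 … 0.2 % Z). The mix is deliberately that of a
high-quality deployment: with 6-h fixes, a 10–20 km blunder implies only
~3 km/h and cannot be caught by the 10 km/h filter, and real studies
counter exactly this with state-space filtering, which is out of scope
here. Multi-day transmission holes (`gap_spec`) remove fixes outright.

**Ocean.** SSH is a smooth gyre-shaped bump (differentiable, so the
geostrophic fields are well behaved); wind stress a smooth trades/westerlies
pattern. Chlorophyll is lognormal with a latitudinal log-mean ramp that is
flat inside two designated boxes — a productive "foraging" box
(mean 0.67 mg/m³) and an oligotrophic "gyre" box (0.18 mg/m³), the
contrast the co-location stage should expose — with 12 % of cells
cloud-masked. The climatology lives on a 1° grid at standard depths
(0–500 m, spacing widening with depth so that layer midpoints land on round
values); temperature profiles place a single sharp interface across the
layer whose midpoint is closest to the latitude-target thermocline depth
(a gyre-like bowl, deepest near the gyre-center latitude), and nitrate is
linear through 2 µmol exactly at the target nutricline (0.8 × thermocline).
The snapped targets are stored on the ocean object, so generator/analyzer
closure is exact at the knots. Dive summaries are a linear link of the
local thermocline depth plus Gaussian noise, floored at 1 m.

All randomness derives from one scenario seed through independent
`numpy.random.SeedSequence` streams per stage, so any stage can be re-run
in isolation with identical results.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: movement is not coupled to the environment (no
preference for productive water, so track-level CHL means do not reproduce
the population contrast; the contrast is asserted at the field/box level),
Argos errors are isotropic Gaussian rather than heavy-tailed ellipses,
fix times are regular rather than orbit-driven, and the ocean fields have
no mesoscale dynamics, fronts or seasonality.

## Problem sizes

End-to-end checks use 2–4 animals of 150–220 days per population (roughly
600–3500 pooled 6-h steps), 10⁴ i.i.d. draws for band-occupancy recovery,
200 replicates of n = 500 with 2000 bootstraps for dip calibration and
power, and 50 seeds for the two-population verdict contrast — sizes at
which every stochastic acceptance check passes with a comfortable margin
while the whole suite runs in a few minutes on one core.

## Known limitations

* The running-mean smoother shortens tortuous path segments: at the ARS
  preset's turning concentration the slow mode shifts from 12.5 to roughly
  9–10 km/d after processing. Band membership (0–15 km/d) and the
  bimodality verdict are unaffected, and the noise-free recovery invariant
  is stated with smoothing disabled.
* The dip test inherits the classical uniform calibration's conservatism
  for peaked unimodal alternatives; reported p-values near 1 are expected
  for smooth unimodal speed distributions.
* Band-edge blending of the geostrophic solution is continuous but not
  derivative-continuous; fields with strong curvature inside ±4° rely on
  the configured velocity cap.
* The EP histogram uses 6 km/d bins so that the published 21 km/d mode is
  a bin center; mode locations are only ever bin-center accurate.
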