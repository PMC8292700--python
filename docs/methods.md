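# Methods

This note documents the models behind `vmatqa`, the parameters that
matter, the numerical choices, and what the synthetic testbed does and
does not establish about real data.

## Delivery model

The simulated treatment control system evolves the machine at 25 Hz and
emits log records at 4 Hz (one per 0.25 s).  Within each arc, MU accrues
linearly in time (dose rate is the leading parameter for this machine
class); all axes track their **MU-interpolated** planned targets — machine
state is interpolated against cumulative meterset, linearly between
control points, never against time.  Deviations are modelled as
truncated-Gaussian noise per internal tick; leaf deviations are
additionally low-pass filtered by a first-order lag (time constant
`leaf_lag_s`) to mimic servo acceleration limits, then truncated at the
configured bound, which plays the role of the machine's dynamic
tolerance.  A deviation beyond the machine tolerance raises a
delivery-fault error, modelling an interlock.

| parameter | default | unit | role |
|---|---|---|---|
| `leaf_sd_mm` / `leaf_bound_mm` | 0.3 / 0.8 | mm | leaf tracking noise, truncation |
| `gantry_sd_deg` / `gantry_bound_deg` | 0.05 / 0.3 | deg | gantry tracking noise |
| `leaf_lag_s` | 0.08 | s | first-order servo lag |
| `mu_sd` / `mu_bound` | 0.02 / 0.1 | MU | MU-counter noise |
| machine tolerance (leaf / gantry) | 1.0 / 1.0 | mm / deg | interlock limits |

Defaults keep deviations sub-millimetre, inside plausible dynamic
tolerances; the vendor publishes no numeric values, so these are chosen
once as representative and exposed as configuration.  Between arcs a 1 s
beam hold is inserted (MU constant, MLC morphing to the next arc's start),
which is how multi-arc logs are later segmented.  4 Hz records are
instantaneous samples, not window averages.  Emitted values are quantized
at 1e-9 (mm/deg/MU) — the plain-text log dialect's precision — which is
far below any machine tolerance, so reconstruction fidelity is limited
only by the 4 Hz sampling, not by encoding.

**Reconstruction** (`log_to_plan`) produces one control point per log
record, verbatim; per arc, cumulative meterset weights are the records'
cumulative MU normalized so the final weight is exactly 1.  Arc
boundaries are detected as runs of ≥ 3 cumulative-MU increments below a
quarter of the median increment (the beam hold); each plateau is cut at
its middle so every record lands in exactly one beam, and the zero-MU
control points this assigns to either neighbour are dosimetrically inert.

## Dose engine

The engine is deliberately **not** Monte Carlo transport.  It is a
divergent-fluence × depth-attenuation × Gaussian-penumbra model that
preserves what the QA statistics are sensitive to — aperture shape, MU
weighting, depth falloff, penumbra, divergence, calibrated statistical
noise — at cohort-capable speed.  Each beam's meterset is integrated on a
fixed grid of `mu_samples` cumulative-meterset fractions; at sample state
*s* a voxel at beam's-eye-view coordinates (x′, y′) (divergently projected
to the isocenter plane) receives

    dose += (MU_beam / mu_samples) · k · F_s(x′, y′) · exp(−μ_eff · d_rad) · (SAD / d_axis)²

where `F_s` is the jaw/MLC aperture rasterized with sub-pixel edge
coverage and blurred by a Gaussian of width σ, `d_rad` the
density-weighted ray path from source to voxel and `k` a flat output
calibration.  Because fluence is looked up at divergently scaled
coordinates, the penumbra width grows geometrically with depth.  Voxels
below the external density threshold receive zero dose.  Uncertainty
modes multiply each voxel by (1 + ε), ε ~ N(0, 1 %) for "fine" and
N(0, 0.5 %) for "extra fine", seeded.

| parameter | default | unit | role |
|---|---|---|---|
| `mu_eff_per_cm` | 0.05 | 1/cm | effective 6 MV-like attenuation |
| `sigma_mm` | 3.0 | mm | penumbra sigma at isocenter |
| `grid_spacing_mm` | 3.0 | mm | dose grid resolution |
| `mu_samples` | 256 | — | meterset integration samples per beam |
| `external_threshold_g_cm3` | 0.1 | g/cm³ | external density threshold |
| `fluence_resolution_mm` | 1.0 | mm | aperture raster pitch |
| `depth_step_mm` / `depth_grid_mm` | 3.0 / 6.0 | mm | ray-march step / auxiliary depth grid |
| `gantry_bucket_deg` | 2.0 | deg | depth-map reuse granularity |

Numerical choices worth knowing:

* **Fixed meterset grid.**  Integrating every plan on the same
  (j + ½)/N meterset fractions makes the engine a pure functional of the
  interpolated machine-state trajectory.  A noise-free 4 Hz log of a plan
  whose control points align with the sampling times reconstructs that
  trajectory exactly, so delivery → reconstruction → recalculation is
  dose-transparent to float precision — the closure property the test
  suite asserts.
* **Absolute raster lattice.**  The aperture raster is snapped to an
  absolute lattice (integer multiples of the raster pitch), so one
  machine state always rasterizes identically regardless of the enclosing
  beam's bounds; otherwise reconstructed beams (whose jaw extrema include
  the inter-arc morph) would see sub-pixel-shifted, slightly different
  blurred fluence.
* **Radiological depth** is ray-marched on a coarser auxiliary grid per
  gantry-angle bucket (2°) and trilinearly refined onto the dose grid;
  maps are cached per phantom content, so a QA cohort or a sensitivity
  sweep pays the tracing cost once.  Bucketing and coarse-grid errors are
  identical on both sides of every comparison and cancel there.
* "Dose-to-medium" is carried as a metadata label only; it has no
  physical meaning in this engine.

Point doses (the analogue of the isocenter chamber check) are trilinear
interpolations of a noise-free grid computation.

## Gamma analysis and DVH metrics

Gamma uses global normalization to the reference grid's maximum (the
conventional reading of "2 %/1 mm/20 %"; a prescription-based
normalization is available), with the 20 % threshold applied to the
reference grid.  The minimum is searched on a 0.1 × DTA lattice inside a
ball of radius 3 × DTA, probes sorted by distance with exact early exit
(a probe's distance term alone bounding the running minimum terminates
the scan); the evaluated grid is sampled by trilinear interpolation **in
its native geometry** at reference-position-plus-offset, which handles
unequal geometries with a single interpolation instead of resampling
first.  Ties break toward smaller distance via the distance-sorted scan
order.  Reference voxels whose entire search ball misses the evaluated
grid get a sentinel gamma of 2 × the search factor (a guaranteed
failure).  Monotonicity in the criteria holds exactly for the dose
criterion and, for DTA, whenever the probe lattices nest (the lattice
scales with DTA; halve `step_factor` when doubling DTA to compare).

Cumulative DVHs use fixed 0.01 Gy bins; V(d) is the percentage of ROI
voxels with dose ≥ d.  D<sub>x</sub> follows the "hottest x %" order
statistic (⌈n·x/100⌉-th largest voxel dose); the curve route linearly
interpolates between bins and agrees with the voxel route within one bin.
Metric differences are 100 × (reference − evaluated)/reference: positive
means under-delivery, the closing-error direction.  A reference metric of
zero yields 0 if the evaluated value is also zero, otherwise the
difference is recorded as not evaluable.

## Synthetic data

The generator emulates the study conditions: dual-arc 6 MV prostate
plans at 2 Gy/fraction, gantry −180°…+180° (arcs in opposite directions),
fixed per-arc collimator within [0°, 45°], 80 × 5 mm leaf pairs, minimum
leaf gap 0.5–1.0 cm, PTV volumes 61–630 ccm on a water-density
elliptical-cylinder pelvis with rectum (posterior), bladder
(anterior-superior), femoral heads (lateral) and the external contour.
Cohorts draw PTV volume log-uniformly over the clinical range,
modulation over [0.15, 0.45], leaf gap over [0.5, 1.0] cm and collimator
angles over [0°, 45°], all from one seed.

Apertures are built per control point from the beam's-eye-view PTV
projection plus a margin (7 mm default), one interval per leaf row.
Modulation is a **sweeping window**: the row aperture is a window
narrower than the conformal interval (width fraction 1 − 1.8 × modulation,
floored at 0.15 and at the minimum gap) whose centre oscillates
sinusoidally across it with seeded per-row frequency and phase.  This
matters: with a sweeping window a voxel's dose is proportional to the
time it spends inside the moving gap, i.e. roughly to the gap width, so
sub-millimetre MLC shifts produce the percent-level PTV D<sub>mean</sub>
changes and steep gamma degradation that make the sensitivity study
meaningful — a perturbed conformal aperture would only move the field
edge.  Modulation 0 reproduces the conformal arc exactly.  Closed rows
park behind the X jaws with the minimum gap.  Total MU is normalized so
the engine's own noise-free PTV D<sub>mean</sub> equals the prescription,
the desk-scale analogue of clinical normalization.

With the default 61 control points per arc and 90 s arcs (or 31 and
45 s at test scale), plan control points fall exactly on 4 Hz sampling
times, which is what makes the noise-free closure exact rather than
merely tight.

The paper's two independent engines (planning system vs secondary check)
are emulated by two configurations of the one engine: "TPS-like"
(μ_eff = 0.050 /cm, σ = 3.0 mm, extra-fine noise) vs "QA-like"
(0.0505 /cm, 3.3 mm, fine noise), seeded independently.  The offsets were
chosen a priori to sit well under the 2 % criterion while giving
plan-size-dependent systematic differences, so cohort correlations have
genuine between-plan variance to work with.

## What passing tests do and do not show

The testbed establishes the *pipeline's* correctness: lossless
interchange, faithful reconstruction, a gamma implementation that matches
an exhaustive oracle, DVH conventions that match closed forms, closure of
the noise-free loop, and the qualitative response surface of the
sensitivity study.  It does **not** establish transport accuracy of the
dose engine (no scatter, no electron transport, no heterogeneity beyond
radiological depth, no leaf-end/tongue-and-groove effects), realism of
patient anatomy or CT texture, or the behaviour of any commercial engine
or real linac servo loop.  Quantities that depend on clinical plan
texture — absolute GPR levels, OAR-difference significance — are
plausible but synthetic; directions and orderings (closing vs opening
signs, monotone degradation, 25-vs-4 Hz negligibility) are the
transferable content.

## Problem sizes

Generator defaults are the study conditions (125 mm phantom radius, 3 mm
grids, 61 control points per arc, 90 s arcs, 30-plan cohorts).  The test
suite and the acceptance script run a reduced scale chosen as the
package's standard desk configuration — 80–100 mm phantom radius, 4 mm
grids, 31 control points per arc, 45 s arcs (365 log records per
delivery), 96–128 meterset samples, cohorts of 5–10 — which preserves
every geometric relation the statistics depend on.  The analysis drivers
state their sizes in `analysis/_common.py`.

## Known limitations

* The delivery simulator has no servo realism (no beam interruptions,
  dose-rate modulation tables, gravity-dependent sag).
* The log dialect is a documented stand-in; the clinical 4 Hz format is
  proprietary and its internal layout unpublished.
* DICOM support covers the RT Plan/Dose subset used here, not full
  conformance; structure sets travel in the HDF5 fixture container
  rather than as DICOM RT Structure Sets (masks, not contours).
* `point_dose` recomputes its grid per call; batch callers should use
  `compute_dose` and sample.
* Statistical tests assume paired, roughly Gaussian metric differences;
  a Wilcoxon alternative is available by configuration.
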