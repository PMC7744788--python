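# Methods

This note records the physical model, the numerical choices, the parameter
defaults (with units and rationale), what the synthetic data do and do not
emulate, and the known limitations.

## Burst waveform and duty cycle

A burst is parameterized by amplitude `V` (V), duration (default 100 µs),
internal frequency (default 100 kHz) and duty `D ∈ (0, 1]`.  The
duration–frequency product must give a whole number of bipolar cycles (ten
at the defaults); fractional cycle counts are rejected because they would
break charge balance.

"50% duty cycle" admits two readings: an on-time fraction, or merely a
description of a symmetric bipolar square wave.  Both are supported and the
**on-time reading is the default**: within each half-cycle the voltage sits
at ±V for `D` of the half-period, centered, and at zero otherwise.  With
`D = 1` the waveform degenerates to the continuous bipolar square wave, so
the alternate reading is one parameter away.  The centered on-phase keeps
the positive and negative lobes mirror images, making every synthesized
burst exactly charge balanced (the sampled waveform sums to zero bit-for-bit
when the sample rate divides evenly into the half-period; phase values are
snapped at 1e−12 so boundary comparisons behave identically in both
half-cycles).  Under this reading the time-averaged Joule heating scales
exactly by `D` (`duty_power_factor`), which is what the thermal module
consumes.

## ECG gating

R peaks are detected as the maxima of over-threshold excursions of the
(lead-III-like) trace — the behavior of a threshold-comparator gating
circuit.  Three robustness conventions:

* a **200 ms refractory lockout** after each detection (no heart at the
  observed rates beats faster; prevents double-firing on one QRS);
* excursions separated by **< 20 ms are merged** (noise blips on the QRS
  shoulder otherwise fire a detection milliseconds early and the lockout
  then masks the true peak);
* the peak is localized on a **5 ms moving-average** copy of the trace so
  single-sample noise does not jitter the detection time.  Thresholding
  itself uses the raw trace.

Bursts are scheduled at `R + delay` with the delay restricted to the
observed safe window **[50, 75] ms**; values outside are hard errors rather
than clamps, since delivery outside the refractory window is a safety
violation, not a modeling choice.

## Scenario grids

Geometries are uniform Cartesian voxel grids (cell-centered coordinates,
lengths in mm) with five labels: blood, myocardium, line/neutral electrodes,
insulator.  Electrodes are Dirichlet voxel groups (perfect conductors); the
catheter shaft is explicit insulator so current cannot short through the
catheter body.  Builders enforce: both polarities present, no line–neutral
face adjacency (grid-level short circuit), electrode tips that fit inside
the blood pool.

Defaults, all config-overridable:

| quantity | default | note |
|---|---|---|
| PV ostium diameter | 13 mm | studied range 12–14 mm; warning outside |
| atrial wall thickness | 5.85 mm | measured mean across the atria |
| septum thickness | 15 mm | measured ventricular barrier |
| loop electrodes | 10 × 1 mm segments | alternating polarity, odd numbers on the line pole |
| tip electrodes | 4 mm (ablation) / 2 mm (diagnostic) | catheter catalogue sizes |
| spacing | 0.25–0.75 mm | per-scenario trade-off, see below |

Material defaults (SI): myocardium σ = 0.381 S/m, k = 0.56 W/m/K,
ρ = 1081 kg/m³, c_p = 3686 J/kg/K; blood σ = 0.70, k = 0.52, ρ = 1050,
c_p = 3617; platinum and nylon for electrodes and shaft.  These are
standard literature-range values for ~100 kHz and body temperature; every
quantitative test in the suite is written to be robust to reasonable
alternatives (closed forms are parameterized by the table, orderings and
conservation do not depend on it).

## Conduction solve

`∇·(σ∇φ) = 0` with Dirichlet electrodes and zero-flux outer boundaries
(insulating bath; domains are padded so the choice is immaterial).
Discretization: 7-point finite volume, **harmonic-mean face conductivities**
(continuous normal current across material interfaces, symmetric positive
definite operator).  Solution: Jacobi-preconditioned conjugate gradients to
relative residual 1e−8.

Electrode currents are integrated over electrode–material faces **with the
same face conductances used in the assembly**, which makes the discrete
line/neutral current balance exact up to the CG residual — the 0.5%
conservation bound in the tests is therefore a check on solver health, not
on discretization luck.

**Embedded boundary.** Voxelized (staircase) Dirichlet electrodes carry an
O(spacing/2) effective-radius bias; on the 0.25 mm concentric-spheres
benchmark this costs ≈ 2.5% peak potential error.  When a grid provides a
signed distance to the conductor surface (`conductor_sdf_mm`), the solver
locates the surface crossing along each electrode–tissue link by linear
interpolation and sets the face conductance to `σ_tissue·s/θ`, `θ` being the
tissue fraction of the link (Shortley–Weller treatment; the plain harmonic
mean is the special case θ = ½).  This reduces the spheres benchmark error
to 0.27% at 0.25 mm with monotone convergence (3.2% → 0.74% → 0.27% at
1.0/0.5/0.25 mm).  Catheter builders currently do not attach SDFs; analytic
fixtures do.

**Field estimation.** `|E|` uses central differences except in the voxel
layer adjacent to an electrode, where the one-sided difference on the
tissue side is used: the potential has a kink at a perfect-conductor face
and the central difference across it biases the near-electrode field low
(the parallel-plate benchmark is exact everywhere with this rule).

The quasi-static DC-equivalent solve deliberately ignores 100 kHz dielectric
dispersion and skin effect; burst-plateau conductivities are static.

## Thermal transient

Bioheat balance `ρc ∂T/∂t = ∇·(k∇T) − ρ_b c_b (u·∇T) + q` with
`q = D·σ|E|²` active during the burst only.  No perfusion sink by default:
on a sub-second single-burst horizon perfusion removes negligible heat (a
config flag can enable it being out of the default path).

**Time stepping is fully explicit**: forward-Euler diffusion on the
harmonic-mean stencil plus first-order upwind advection.  At ≥ 0.25 mm
voxels the explicit diffusion stability bound is ~70 ms — four orders above
the 1 µs burst step and far above the 1 ms relaxation step — so implicit
diffusion would add sparse solves per step for no stability or accuracy
benefit.  Both the stability bound and the advective CFL bound are computed
and violated steps are rejected with the bound in the message.  Verified
against the 1D heat kernel (L2 error 0.02% at default resolution) and exact
adiabatic energy conservation.

Flow is a **static analytic laminar profile**, not a Navier–Stokes solve:
the study design only requires a fixed advective field.  The Poiseuille
variant shapes speed by normalized wall distance, `v = peak·(2s − s²)`,
which is exactly the parabolic profile in a cylindrical lumen and degrades
gracefully for slab pools; one no-slip voxel layer at every tissue wall
carries zero velocity.  Plug flow is uniform with the same no-slip layer.

Probes: `tissue_interface` = hottest myocardial voxel face-adjacent to an
electrode; `blood` = hottest blood voxel; `domain_max` = global maximum.

### What a single burst can and cannot show about flow cooling

Within a 100 µs burst, blood at 0.16 m/s moves 16 µm — two orders below the
voxel size — so the temperature peak is set at burst end and is **flow
invariant** in this model (measured spread across the 0/0.08/0.16 m/s sweep:
3e−9 °C).  The velocity-sweep acceptance therefore asserts the peak is
non-increasing, which holds as equality within a 1e−6 °C numerical-noise
band.  Post-burst, the hottest blood sits in the stagnant no-slip layer that
advection cannot replace; washout redistributes heat downstream (wake
superposition can even raise distant maxima slightly — genuine advective
physics, the scheme is conservative on analytic benchmarks).  The advective
cooling mechanism itself — monotone washout with a shrinking marginal effect
of doubling the velocity — is demonstrated on a channel configuration where
the heated plume lies in moving blood.  A model resolving µm boundary layers
(or an irrigated catheter) would be needed for flow to visibly depress the
near-electrode peak itself.

## Lesion metrics

* **Decay fit**: `T = T₀ + A·e^(−t/τ)` by least squares from the series
  peak onward; initial values from a log-linear regression, refined by
  Levenberg–Marquardt with `A ≥ 0, τ > 0` bounds.  Constant and
  non-decaying series are rejected (τ unidentifiable).
* **Effective radius**: distance transform from the electrode voxels,
  maximized over the super-threshold (default 400 V/cm) myocardium mask.
  `inter_electrode` mode restricts the mask to the mid-surface equidistant
  from the two polarities, where the field sags between adjacent
  electrodes.  The measurement locus (max over the mask) is a documented
  convention; an empty mask returns 0 rather than erroring.
* **Untreated gap**: longest contiguous sub-threshold myocardium run
  sampled at half-voxel steps along the line–neutral centroid axis.
* **Alignment CV**: sample (n−1) standard deviation over mean, in percent.

## Volumetrics and statistics

The specimen volume is myocardium + non-myocardial voxels (background
excluded).  The myocardial percentage is `(Vtot − Vnon)/Vtot·100`; the
non-myocardial percentage is its exact complement and is the quantity group
summaries are reported in — both are returned under unambiguous names.
The ablated percentage is treated minus control non-myocardial percentage
(negative values are flagged, not clipped).  Printed-value comparisons round
half away from zero to two decimals.

Per-slice wall thickness = twice the deepest in-plane distance from
specimen to background — exact for wall-like specimens whose thickness runs
in the slice plane (axial slices cutting across the wall); the extrusion
reference is `π(d/2)² · max slice thickness` for loop diameter `d`.

One-sample and paired t-tests are scipy closed forms; the Welch
unequal-variance variant is selectable.  Dunn's post-hoc z-tests (pooled
rank variance with tie correction) are implemented directly and
**Bonferroni-adjusted** over all pairs — the correction family is a
documented choice.  Degenerate inputs use the conventions: all-identical
groups → omnibus p = 1; zero SD with nonzero effect → p = 0 with a warning.

## Synthetic data

All generators are seed-deterministic (same seed and arguments →
byte-identical output).

* **ECG**: Gaussian R spikes (σ = 12 ms, 1 mV) at the configured rate
  (default 69 bpm, the measured sinus rhythm), first peak half a period in,
  additive white noise; optional T-wave bump for gating-failure
  experiments.  No P wave or baseline wander — gating only needs R peaks,
  so detector performance on real ECG morphology is *not* established by
  these tests.
* **Segmentation**: a flat wall slab (thickness in-plane of the axis-0
  slices), contiguous lesion patches grown by seeded region accretion
  (transmural-scar-like) plus salt-scattered native non-myocardium
  (endo/epicardial connective lining).  Label-exact ground truth; real
  segmentations add partial-volume and inter-rater error that the recovery
  tests do not probe.  Curved atrial anatomy is not modeled.
* **EGM cohort**: paired normal draws at the study's atrial effect sizes
  (amplitude 2.20 ± 0.84 → 0.61 ± 0.18 mV, duration 45.29 ± 8.1 →
  58.38 ± 12.61 ms), truncated above zero.  The impedance *level*
  (120 ± 20 Ω) is a synthetic convention — only the drop (−31.75 ± 13.92 Ω)
  has a published value; post = pre + a draw from the drop.
* **Decay series**: `T₀ + A·e^(−t/τ)(1 + ε)`, `ε ~ N(0, noise)`,
  defaults A = 7.6 °C, τ = 9.22 ms (the tissue-probe parameters of a
  single burst).

## Problem sizes used by the test suite

Benchmarks run at sizes chosen to keep the whole suite under a few minutes
on one core while leaving the asserted tolerances comfortably met: the
concentric-spheres benchmark exploits its octant symmetry (spheres centered
on a domain corner, zero-flux planes as mirrors; ~0.5 M unknowns at
0.25 mm), the velocity sweep runs the atrial-wall scenario at 0.5 mm
(38×38×28), septal comparisons at 0.75 mm.  All scale-dependent checks
(convergence, conservation, closed forms) are formulated so refining the
grid only improves them.

## Known limitations

* No 100 kHz dispersion, electrode–electrolyte interface impedance, or
  temperature-dependent tissue properties.
* Single-burst horizon: multi-burst cumulative heating and lesion growth
  across a 60/120-burst train are out of scope (the transient decays within
  tens of ms, well inside the 800 ms inter-burst interval, which is the
  argument for single-burst sufficiency).
* Electroporation is a sharp field threshold; no pore-kinetics model, no
  fiber-orientation dependence of the threshold.
* Catheter geometries are parametric re-creations (ring segments, cylinder
  tips), not CAD models; reported absolute radii/gaps depend on them, which
  is why the suite asserts orderings, conservation laws and closed forms
  rather than the original study's printed simulation values.
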