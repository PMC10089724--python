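# Methods

This note documents the models behind each stage of the pipeline, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that matter when reading the
outputs.

## Pressure reconstruction

The pressure stage inverts the inviscid incompressible momentum balance
∇p = −ρ Du/Dt, with the material acceleration computed from the velocity
frames by centred differences in time (one-sided at the sequence ends)
and in space (one-sided beside the mask). Viscous terms are omitted by
default: at strike speeds the instantaneous Reynolds number is large and
the viscous contribution to the pressure gradient is negligible; a
kinematic viscosity can be supplied for completeness but is not used by
the solvers.

**Poisson route.** Rather than discretizing ∇²p directly, the solver
poses a weighted least-squares problem: for every face between two fluid
cells, the finite-difference pressure jump is matched to the
face-averaged source −ρ Du/Dt. The normal equations of this problem are
exactly a finite-volume discretization of ∇·(w∇p) = ∇·(w g); faces into
the mask simply carry no equation, which is the natural (Neumann)
boundary treatment at the body. The face weight w realizes the geometry
option: `planar` uses w = 1; `axisymmetric` uses the distance of the face
from the mouth axis (floored at a quarter cell near the axis), making the
operator the cylindrical-coordinate Poisson operator for flows whose
symmetry plane is the imaging plane. One matrix factorization (sparse LU
of the normal equations) serves all frames of a sequence.

On the symmetry plane of an axisymmetric flow the in-plane components of
Du/Dt balance the in-plane pressure gradient exactly, so both weightings
are consistent there and perform equally well on the sink benchmark
(about 1% RMS of peak |p| on a 64×64 grid); `axisymmetric` remains the
default for suction strikes because it is the physically matching
operator away from the symmetry plane. Offering both makes any
planar-inversion bias measurable rather than assumed.

**Multi-path route.** The second solver integrates −ρ Du/Dt along
axis-aligned staircase paths from the zero-pressure reference cells. Each
pass grows a random spanning tree of the fluid region (randomized
priority flood fill) rooted at one reference cell, which realizes one
staircase route to every reachable cell; the per-cell median over passes
(default 8) suppresses path-dependent error. Cells not reachable through
fluid are reported missing (NaN), never silently zero.

**Gauge.** Gauge pressure needs a zero. The reference region is the set
of unmasked domain-boundary cells farthest from the mouth (within 95% of
the maximum boundary distance). The Poisson solver constrains the *mean*
pressure over this region to zero with a single equation; constraining
each reference cell individually would tilt the solution whenever the
true far-field pressure varies along the region — a real effect here,
since the unsteady term of the sink pressure decays only as 1/r. Each
multi-path pass is re-gauged the same way after integration. Any
comparison between a reconstructed and an analytic field must first bring
both to this gauge (subtract the mean over the reference cells);
`reference_offset` does this, and re-gauged differences are invariant to
adding a constant to either field.

**Smoothing.** An optional Savitzky–Golay filter (window in frames,
polynomial order; default window 9, order 2 in the pipeline) is applied
to the velocity in time before differencing, and the same smoother is
shared by the event detector and the tendon stage. With 5%-of-peak
velocity noise and the smoother engaged, the reconstruction error on the
sink benchmark roughly doubles relative to the noise-free case (well
under the 3× regression bound tested).

## Suction power

Q(t) = u_m(t)·πd(t)²/4 assumes a circular aperture with the digitized
lateral gape as its diameter, matching how the flow-rate product is
constructed from video plus PIV. The inflow speed u_m is the average over
the aperture line of the velocity projected on the mouth axis (stored
pointing *into* the mouth; flipping the stored axis flips u_m and the
aperture normal together, leaving the power invariant). Net suction power
P_net = −p_mouth·Q is positive while suction draws water in, and its time
integral is the work done on the external fluid. This is a lower bound on
total suction power: accelerating the skeletal and muscle tissues of the
expanding head is excluded (a few percent of the total in largemouth
bass; possibly more in seahorses).

For the sink model the work integral has a closed form that the tests
exploit: from unsteady Bernoulli at the aperture radius a,
−p(a)Q = d/dt[ρQ²/4πa] + ρQ³/8π²a⁴ — the rate of change of the kinetic
energy stored in the sink field outside the aperture plus the ingested
kinetic-energy flux. Strike onset is the first frame with gape above 20%
of peak (configurable); peak times are global maxima of the (optionally
smoothed) series, ties resolving to the earliest frame, with peaks on the
first/last frame flagged censored.

## Four-bar linkage

Link numbering follows the cranial linkage: link 1 the fixed girdle
frame between the neurocranium pivot N and the cleithrum protrusion C,
link 2 the head (grounded at N), link 3 the hyoid coupler, link 4 the
urohyal + sternohyoideus complex (grounded at C). `solve_fourbar` is the
closed-form Freudenstein position solution driven by the grounded link 4,
with an explicit open/crossed branch; trace-level code selects branches
by continuity from the calibration posture and flags, never silently
switches. Closure residuals are at machine precision (≤ 1e-9 relative,
verified against an independent brute-force circle-intersection oracle on
10³ random linkages).

The rigidity test calibrates link lengths from the digitized joints of
the calibration frame — the last frame before the hyoid's angular speed
exceeds 5% of its peak — then drives the rigid linkage with the observed
hyoid (coupler) orientation and compares the predicted head elevation
with the digitized one. Angles are measured counterclockwise from the
fixed link and elevations relative to the calibration frame, which makes
the discrepancy invariant to rotation, translation and scaling of the
trace. Because the fixed length assumed for the ventral link is itself a
choice, both datums are computed: the pre-strike (calibration) length,
the default, and the mean digitized length; on synthetic traces they
agree to a few degrees. Bar compression is measured directly as
100·(L4_cal − min L4)/L4_cal from the hyoid-tip–cleithrum distance, with
landmark dropouts linearly interpolated across gaps of up to 2 frames.

The discrepancy magnitude at a given compression depends on the linkage
geometry; with the default synthetic geometry it grows monotonically from
0° (rigid) to ≈30° at 50% compression. It is a qualitative diagnostic,
not a universal calibration curve.

## Tendon curves and recoil power

Material-test samples are fit by averaging duplicate extensions, isotonic
regression (non-negative, non-decreasing), and a monotone piecewise-cubic
(PCHIP) interpolant anchored at F(0) = 0. The isotonic constraint is a
physical requirement — stored energy must be non-negative — and makes the
fit invariant to sample order. Data whose smoothed force *decreases* over
more than 20% of the extension range are rejected as invalid loading
curves rather than silently monotonized. Energy is the exact integral of
the interpolant; evaluation beyond the calibrated range is an error
unless extrapolation is explicitly allowed.

Recoil power needs a datum mapping the digitized bar length to bench
extension. The default slack length is the calibration-frame bar length
minus the test's maximum extension, i.e. the pre-strike (loaded) bar sits
at the top of the calibrated range; this is configurable because the
mapping is genuinely unknown for real data. Extension is clipped at zero
(a slack tendon cannot push) and power at zero during lengthening, so the
integral of P_t over a shortening episode equals the stored-energy
difference between its endpoint extensions (verified to well under 1%).
These conventions make the tendon-power estimate conservative by
construction.

## Comparative statistics

All three estimands use linear mixed models (statsmodels `MixedLM`) with
random intercepts for species and individual-within-species; a singular
fit falls back to an individual-only intercept and finally to OLS (the
exact degenerate limit when random-effect variances are zero), with the
fallback flagged in the result. Slopes are reported per group from a
single model with group-specific fixed slopes; an intercept is included
by default, with a no-intercept and a log–log option, because the
original axis treatment is unknown.

Phylogenetically informed Bayesian machinery is deliberately replaced by
species-level random intercepts and likelihood-based tests: the point
estimates, not Bayes factors, are the quantities of interest. For the
group comparison of mass-specific power the asymptotic χ²₁ LRT is
anticonservative when the effect is judged against ~10 species (observed
false-positive rates around 10–15% under the null), so the reported
`pvalue` is a Wald t-test on the group difference with between-species
degrees of freedom (df = #species − 2), which simulates at the nominal 5%
level; the LRT statistic is reported alongside. With few species per
group the asymptotic standard error of a group mean is also somewhat
optimistic (≈85–90% coverage of 2-s.e. intervals in calibration runs);
this is a documented limitation of small-cluster mixed models, not of the
implementation.

## The synthetic generator

The generator's defaults are the study conditions the downstream tests
assume.

* **Sink flow.** Hemispherical point sink at a wall (3-D axisymmetric,
  sampled on the symmetry plane; factor 2π, not 4π, in the potential),
  aperture radius 1.5 mm masked out, 64×64 grid spanning 8 aperture
  radii, 8 kHz frames, seawater density 1025 kg m⁻³ (configurable; the
  working fluid is seawater but no value is prescribed elsewhere).
  Gaussian noise is added to velocity only; pressure frames are exact.
* **Seahorse-like preset.** Peak gape 3 mm; time to peak flow 2.1 ms and
  peak gape 2.5 ms measured from strike onset (the 20% gape crossing,
  which the generator places on a configured onset frame by construction);
  gape-to-flow slope 202 s⁻¹; head rotation 0.5 rad with peak angular
  speed 200 rad s⁻¹, placed at 3.5 ms — only its position *after* peak
  gape is anchored by observation, and 3.5 ms keeps the event ordering
  robust under the default landmark jitter. Ventral-link compression
  defaults to 48%.
* **Waveform shapes** are free choices, documented here because they are
  not observable from published timings. Gape: a slow creep to 22% of
  peak around onset, then an explosive 0.8 ms limb peaking exactly at
  2.5 ms, then a slow raised-cosine reclosure — seahorse mouths open
  explosively late in the strike, and an interior gape peak is required
  for uncensored event timing. Flow speed: a flat-topped
  quartic-exponential rise with a slow Gaussian decay. These shapes are
  what make the published event ordering (flow < power < gape < head
  rotation) hold in the model: at millisecond timescales the unsteady
  term ρ·dQ/dt/(2πr) dominates the mouth pressure, so a sharply curved
  flow peak would flip the sign of that term right at peak flow and pull
  peak power ahead of peak flow; a flat flow peak plus a late gape places
  peak power strictly between peak flow and peak gape. Head elevation
  (and the ventral-link shortening tied to hyoid retroversion) follows a
  compact sin² rise that is exactly zero pre-strike, so the calibration
  frame sees the uncompressed linkage and configured compressions are
  recovered exactly.
* **Generalist preset.** The same construction stretched to
  tens-of-millisecond timing (peak flow 33 ms), 10 mm gape, slope
  24.6 s⁻¹, slow head rotation — a muscle-powered suction feeder.
* **Four-bar geometry.** Head 4 mm, hyoid 6 mm, ventral link 7 mm, ground
  joints 5.1 mm apart, rest head angle 125°: a well-conditioned linkage
  that closes over the whole motion for compressions up to 50% and whose
  rigid-expectation solve never fails on the driven range. Landmark
  jitter is isotropic Gaussian, 0.5% of head length by default, seeded.
* **Tendon tests.** F(x) = k(e^{bx} − 1)/b with k = 150 N m⁻¹,
  b = 400 m⁻¹, 4 mm range — an exponential-toe curve reducing to a linear
  spring as b → 0, with closed-form energy.
* **Strike-summary simulators** for the statistics stage draw species and
  individual intercepts and residual noise around the published effect
  sizes (slopes 202/24.6, group means 3455.1/129.0 W kg⁻¹, tendon-fluid
  slope 0.72 over 67 strikes from 5 individuals of 3 species). Noise
  levels are unpublished; the defaults (e.g. 0.05 m s⁻¹ residual flow
  scatter, species/individual intercepts a factor 2–3 smaller) were
  chosen once as plausible for the measurement chain.

What the generator does **not** emulate: real PIV error structure
(correlated speckle noise, outlier vectors, resolution loss near the
body), body-deformation masks that move between frames, 3-D flow
asymmetries, out-of-plane motion in the digitized landmarks, tendon
viscoelasticity and hysteresis, and phylogenetic covariance between
species. Passing tests therefore establish the correctness of the
computational chain under its stated model, not the field accuracy of any
particular measurement.

## Numerical choices and degenerate inputs

* Problem sizes in tests and the acceptance script: 64×64 grids, 24–72
  frames per sequence, 10³ solver instances, 100 simulation replicates —
  sizes at which every oracle comparison is stable and the whole suite
  runs in minutes on one CPU.
* Masked-aware bilinear interpolation renormalizes over finite corners;
  an aperture wholly inside the mask yields a per-frame missing value
  with a warning, not a failure.
* The sequence-level Poisson factorization requires the mask (and the
  NaN pattern of the source term) to be static; frames with NaN velocity
  in unmasked cells are masked on ingest and counted.
* All angle comparisons wrap through the circle (no 2π jumps); the
  four-bar branch is initialized from the calibration posture and tracked
  by continuity.
* Degenerate statistics inputs (zero residual variance, single species)
  degrade through the documented fallback chain rather than crashing;
  a single-individual group or single-group comparison is an error.
* Seeds: every stochastic component (noise, jitter, path randomization,
  simulators) takes an explicit seed; identical seeds reproduce outputs
  bit-for-bit.
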