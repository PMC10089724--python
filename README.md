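# shpower — suction-feeding power and elastic recoil from PIV and kinematics

Seahorses capture evasive prey with a latch-mediated spring-actuated
(LaMSA) strike: elastic tendons, pre-loaded by slow muscles, recoil in a
few milliseconds to swing the head toward the prey *and* to suck water
into the mouth. Deciding whether the suction flow itself is
spring-powered requires a chain of quantitative steps, each of which this
package implements as a tested, reusable library:

1. **Pressure from PIV.** Given time-resolved 2-D velocity fields u(x, t)
   on a masked grid, reconstruct the gauge pressure field from the
   inviscid momentum balance ∇p = −ρ Du/Dt, where
   Du/Dt = ∂u/∂t + (u·∇)u. Two established routes are provided: a
   finite-volume Poisson solve (least-squares matching of face pressure
   gradients, with optional axisymmetric volume weighting about the mouth
   axis) and median multi-path line integration from far-field
   zero-pressure boundary cells.
2. **Net suction power.** With gape diameter d(t) digitized from video
   and the inflow speed u_m(t) sampled on the aperture, the volumetric
   inflow is Q(t) = u_m·πd²/4 and the power spent accelerating the water
   outside the mouth is P_net(t) = −p_mouth(t)·Q(t). Peak P_net divided
   by the mass of the epaxial + hypaxial muscles gives mass-specific
   power, compared against the vertebrate muscle ceiling of 1121 W kg⁻¹.
3. **Four-bar rigidity.** The cranial linkage (fixed girdle frame, head,
   hyoid, and the urohyal + sternohyoideus ventral link) is solved in
   closed form (Freudenstein relation). Driving the rigid linkage with
   the observed hyoid orientation predicts a head elevation; a systematic
   expected-vs-observed discrepancy, together with direct shortening of
   the digitized ventral bar, diagnoses a flexible (tendon) link.
4. **Tendon recoil power.** Material-test force–extension samples are fit
   with a monotone (isotonic + PCHIP) curve F(x); elastic energy is the
   area under the curve and the recoil power along the observed bar
   shortening is P_t(t) = F(x(t))·(−dx/dt), clipped when slack.
5. **Comparative statistics.** Linear mixed models (random intercepts for
   species and individual-within-species) estimate the gape→flow-speed
   scaling slope per group, group means of mass-specific power with a
   small-sample group test, and the slope of tendon power on fluid power.

A synthetic-data module generates every input with analytically known
truth — a hemispherical point-sink flow with exact unsteady-Bernoulli
pressure p = −ρ(∂φ/∂t + |u|²/2), φ = Q(t)/2πr; strike kinematics driven
through an exactly closed four-bar with a configurable ventral-link
compression; and exponential-toe tendon tests with closed-form stored
energy — so the whole chain is validated end to end without external
data.

## Worked example

Run the full pipeline on the millisecond-scale seahorse preset:

```python
from shpower.pipeline import PipelineConfig, run_strike

row, report = run_strike(PipelineConfig(seed=1, preset_overrides={"jitter_frac": 0.0},
                                        smooth_window=None))
print(f"peak flow at {1e3 * row['t_peak_flow_s']:.2f} ms, "
      f"peak power at {1e3 * row['t_peak_power_s']:.2f} ms, "
      f"peak gape at {1e3 * row['t_peak_gape_s']:.2f} ms, "
      f"peak head rotation at {1e3 * row['t_peak_head_speed_s']:.2f} ms")
print(f"ventral-bar compression {row['bar_compression_pct']:.1f}%, "
      f"rigid-linkage discrepancy {row['fourbar_discrepancy_deg']:.1f} deg")
```

prints

```
peak flow at 1.88 ms, peak power at 2.25 ms, peak gape at 2.50 ms, peak head rotation at 3.50 ms
ventral-bar compression 48.0%, rigid-linkage discrepancy 29.8 deg
```

— the strike events occur in the characteristic LaMSA order (flow, then
power, then gape, then head rotation, all within a few milliseconds), the
flexible ventral bar shortens by the configured 48%, and the observed
head elevation departs from the rigid four-bar expectation by tens of
degrees, the signature of an elastic link inside the linkage loop.

The numbered drivers under `analysis/` tell the same story stage by
stage and write tidy tables to `results/`:

```bash
python analysis/01_synthetic_strikes.py    # end-to-end strike summaries
python analysis/02_pressure_validation.py  # solver error vs analytic pressure
python analysis/03_suction_power.py        # R^2 benchmark + energy budget
python analysis/04_fourbar_rigidity.py     # discrepancy vs known compression
python analysis/05_tendon_power.py         # force-length fit + recoil power
python analysis/06_scaling_stats.py        # mixed-model recoveries
```

For example, `analysis/06_scaling_stats.py` simulates strike summaries at
the published effect sizes and recovers them:

```
scaling_slope_lamsa: true 202.0 -> estimated 198.46 ± 9.52
scaling_slope_generalist: true 24.6 -> estimated 24.15 ± 1.39
mass_specific_power_lamsa: true 3455.1 -> estimated 3475.12 ± 74.14
tendon_fluid_slope: true 0.72 -> estimated 0.70 ± 0.04
```

A `shpower` console script exposes the same stages
(`shpower simulate|pressure|fourbar|tendon-fit|stats|pipeline`).

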