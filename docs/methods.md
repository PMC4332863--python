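# Methods

## Model and assumptions

The organ is an inextensible planar curve of fixed length `L` (elongation
and self-weight bending are deliberately outside scope), clamped at the
base at the initial tilt `A0` and described by its local angle to the
vertical `A(s, t)` and curvature `C(s, t) = ∂A/∂s`. Active bending is
driven entirely by perception-regulation: within the growth zone
(`s > L − L_gz`) the curvature rate is the sum of

- a graviceptive term `−β (A − GSA)` (local; `GSA = 0` for
  ortho-gravitropic organs — the non-zero generalization is exposed but
  untested against data),
- a photoceptive term `−ν (A_sense − A_P)`, where `A_sense` is either the
  local angle (`ARC`) or the apical angle `A(L, t)` (`AaC`, `ARaC`), the
  latter standing for a basipetally transmitted apical signal,
- a proprioceptive term `−γ C`.

Both directional terms are the small-angle linearization of sine laws (the
photoceptive one descends from the Lambert cosine dependence of the flank
irradiance on the angle to the beam). The linearization is first-order
valid only for angles below ~90°; an optional `sine_law=True` mode keeps
the full sine terms so the documented breakdown at steeper tilts can be
reproduced. The gravity and light fields are uniform and coplanar with the
organ; spatially varying or out-of-plane light is out of scope.

Angles are radians everywhere inside the library; degrees appear only in
files that declare them.

## Parameters and defaults

| parameter | units | default | meaning |
|-----------|-------|---------|---------|
| `beta`  | 1/(length·time) | 0 | graviceptive sensitivity |
| `gamma` | 1/time          | 1 | proprioceptive sensitivity |
| `nu`    | 1/(length·time) | 0 | photoceptive sensitivity |
| `L`     | length          | 1 | organ length |
| `L_gz`  | length          | `L` | growth-zone length |
| `A0`, `A_P`, `GSA` | rad | 0 | initial tilt, light direction, set point |

`L_gz` defaults to the whole organ because all closed-form results drop the
growth-zone mask; when `L_gz = L` the mask includes the base node, so the
basal curvature can evolve to its nonzero steady value (the initial
condition `C(0, 0) = 0` is imposed, but the base curvature is not clamped
during the dynamics — only the base angle is). With `L_gz < L` the rate is
strictly zero for `s ≤ L − L_gz`, and the closed forms measure the
exponential decay from the top of the rigid segment.

Derived quantities: `B = βL_gz/γ`, `D = νL_gz/γ`, `M = β/ν` (`inf` in
darkness), `B′ = B + D`, `A_R = A_P/(1+M)`, `T_c = 1/(γ + νL_gz)`,
`L_c = L/B′`. The identity `M·D = B` holds by construction. The Stevens
exponent is stored signed, `M(I) = a·I^b` with `b < 0` for the empirically
decreasing response (magnitude ≈ 0.4); intensity laws use natural log.

## Numerics

- **Method of lines.** The curvature vector on a uniform grid (default 201
  nodes) is the state; the angle field is recomputed from it at every RK4
  stage by trapezoid integration from the clamped base, so the two fields
  cannot drift apart. The default step `dt = 0.05/max(γ+(β+ν)L_gz,
  √((β+ν)L_gz))` resolves both the relaxation and the oscillation scale; a
  blow-up guard raises a solver error advising a smaller step.
- **Exact stepper.** Because every variant is linear time-invariant, an
  independent matrix-exponential stepper (augmented affine system,
  `scipy.linalg.expm`) is provided and used in tests as the oracle for RK4
  accuracy and order checks.
- **Quadrature split.** `curvature_to_angles` (geometry/I-O reconstruction)
  uses cumulative Simpson (4th order) so smooth profiles integrate to
  ~1e−10; the simulator and the exact stepper share a matched trapezoid
  operator, which keeps the discrete angle/curvature coupling strictly
  consistent and makes mirror symmetry exact in floating point.
- **Steady-state detection** uses the earliest stored slice with
  `max_s |dC/dt| < rel_tol · γ · max(|A0 − A_ref|, 1e−6)` (`rel_tol = 1e−3`
  by default), with `A_ref` the variant's set point. Non-convergence is a
  first-class result, because the `γ = 0` dark model genuinely oscillates
  forever. The apical-photoception steady state at `γ = 0` (movement stops
  when the tip faces the light) is served by the analytic module, which
  handles `D → ∞`.
- **Propagation delay.** The apical term at `s` uses
  `A(L, t − T_B (L−s)/L)` — a linear apex-to-base delay profile — and is
  zero before the signal first arrives; the delayed tip angle is linearly
  interpolated from the stored step history. `T_B = 0` delegates to the
  instantaneous integrator, so the zero-delay trajectory is identical by
  construction.
- The limit-profile expressions are the exact `s`-derivatives of the angle
  profiles (for the photo-dominated limit this gives
  `C(s) = −A0′(B/L) e^{−Bs/L}/(1−e^{−B})`, negative for `A0′ > 0`), so
  every closed-form shape plugged back into the model right-hand side
  vanishes to round-off.
- The tabulated apical-photoception "steady state" is time-dependent in the
  source tradition; this package uses its `t → ∞` limit as the steady
  state. The `tip ≈ A_R` report flag operationalizes "negligible
  `e^{−(B+D)}`" as `e^{−(B+D)} < 0.01`; the tip bound
  `|tip − A_R| ≤ 1.5 |A0−A_R| e^{−(B+D)}` is exact for local perception and
  holds for apical perception in the gravi-dominated regime (large `B`,
  modest `D`) where the neglect is derived — in photo-dominated regimes the
  apical steady tip deviates as `|A0−A_R| e^{−B} M/(M+1−e^{−B})` instead.

## Orthogonal regression

The intensity-law fit is total least squares with unit error-variance ratio
in the transformed coordinates (log–log for the power law, semi-log for the
log law): the fitted direction is the principal eigenvector of the 2×2
scatter matrix, which minimizes the summed squared perpendicular distances
(cross-checked in tests against a brute-force grid minimizer over line
angle). `R²` is not canonical for orthogonal fits; it is reported as
`1 − (orthogonal residual SS)/(total scatter about the centroid)`, i.e. the
major-eigenvalue fraction, and this formula is echoed in the output
metadata. Ordinary least squares is available for comparison.

Record exclusion: `M = A_P/tip − 1 ≤ 0`, tip/light sign mismatch, tips of
exactly zero (infinite-`M` marker), non-finite values, and tilts beyond 90°
(outside the linearized model's validity) are masked with reason codes;
`n_used + n_excluded = n_records` always. Infinite `M` or `D` are
serialized as status strings, never as JSON infinities.

The master-curve collapse verdict compares the pooled perpendicular RMS per
point against the mean of the per-tilt-group RMS: collapsed when the ratio
is ≤ 1.2 (configurable), with an absolute floor of `1e−6 ×` the data
scatter so that exactly-collapsing noiseless data (whose residuals are pure
eigenvalue round-off, ~√eps) pass.

## Synthetic data: what it emulates and what it does not

The equilibrium generator reproduces the published experimental design it
stands in for: tilts of 0°, 10°, 30°, 90° and 120° (the 120° rows exist to
exercise the exclusion logic), light perpendicular to the initial tilt
(`A_P = A0 + π/2`), 12 fluence rates spanning 5 decades, 15 replicates, and
i.i.d. Gaussian noise on the measured tip angle with σ = 2° — a
protractor-scale reading error chosen as the calibration default since the
original measurement error is not documented. Noise lives on the tip angle
(not on `M`) because that is where measurement error arises. PROT2 inverts
the truth law for the fluence rate that holds each tilt
(`M* = A_P/A0 − 1`), skipping `A0 = 0` (infinite target).

The kinematics generator adds i.i.d. Gaussian angle noise to a clean
simulation and recomputes curvature from the noisy angles. Real data differ
in ways the generator does not model: elongation during the movement,
photomorphogenetic slowdown and inner-leaf takeover in long coleoptile
runs, spatially correlated digitization error, and intensity-dependent
changes of `β`. Passing recovery tests therefore demonstrates correctness
of the inference machinery under the stated noise model, not robustness to
those real-data effects.

## Problem sizes used by the acceptance script

201 grid nodes; transient comparisons at `dt = T_c/100`; convergence runs
to `t = 40` (relaxation rate 1); the noisy recovery design is
3 tilts × 12 fluence rates × 15 replicates; the Monte-Carlo calibration of
the `B` estimator uses 100 seeds at σ = 0.01 rad. These sizes make every
check deterministic to reproduce in seconds while keeping discretization
error one to two orders below the tolerances asserted.

## Known limitations

- Linear sensing only in the closed forms; the sine-law mode has no
  analytic solutions and is validated only qualitatively.
- No transient closed forms for the local and apical photogravitropic
  variants beyond the apical-photoproprioceptive one; their transients are
  checked against the exact linear-algebra stepper instead.
- The delay integrator interpolates history at first order between steps;
  it is meant for `T_B` up to the movement time scale, not for
  stiff-delay regimes.
- Whether measured "equilibrium" tip angles reflect a true steady state is
  doubtful in the emulated protocol itself; both the strict detector and a
  windowed fallback (last-10% mean with a `transient` flag) are exposed
  rather than choosing one as correct.
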