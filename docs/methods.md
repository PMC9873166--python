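# Methods

## Model

`hbcycle` models anemia treatment as a delayed negative feedback loop
between a patient and a dosing algorithm.  Hemoglobin `h` obeys

    dh/dt = λ + μ φ(e(t − τ)) − η h + ω₁ ξ₁(t),

where `λ` is the residual RBC production expressed as an Hb gain rate, `η`
the eryptosis rate (RBC lifespan `T_RBC = 1/η`), `μ` the maximal Hb gain
evoked by saturating ESA levels, and `φ(e) = eⁿ/(ēⁿ+eⁿ)` a Hill sigmoid
with EC50 `ē` and exponent `n`.  The delay `τ` lumps the proliferation and
maturation lags between an administration and its effect on circulating
Hb.  Systemic ESA decays as `de/dt = −κe` (half-life `T_ESA = ln2/κ`) and
jumps by the administered amount at each administration.  Every `τ_int`
days the loop measures `h + ω₂ξ₂`, updates the integer dose index by the
threshold rule (increase below the target window, maintain inside it,
decrease above it, reset to zero at or above the hold limit, resume only
below the window, clamp to `[0, x_cap]`) and administers `c0·x`.  The
prescription is updated *before* the administration at each epoch.

Assumptions worth making explicit: the dose–response delay is a single
lumped constant; ESA kinetics are linear first-order; the dosing chart is
linear; physiological and measurement noise are smooth interpolated
Gaussian processes rather than white noise; and all parameters are constant
within a simulated course.

### Conventions fixed where the rules are ambiguous

* The target window is closed: measurements exactly at `h₋` or `h₊`
  maintain the dose (the boundary is measure-zero under continuous noise).
* The dose index never exceeds `x_cap`, read as the highest available
  single dose.
* A measurement exactly at the hold limit suspends dosing (`≥ h_hold`).
* Events ("bleed"/"transfusion") are instantaneous Hb offsets, applied
  after the epoch actions when they coincide with an epoch, and snapped to
  the integrator grid.
* If Hb reaches 1 g/dL the run is truncated and flagged rather than
  clipped, so unphysiological parameter sets surface instead of silently
  producing nonsense.

## Reference parameters

| symbol | field | default | unit | meaning |
|---|---|---|---|---|
| λ | `lambda_` | 0.1 | g/dL/d | Hb base gain rate |
| μ | `mu` | 0.3 | g/dL/d | ESA responsiveness |
| ē | `e_half` | 0.75 | a.u. | ESA EC50 |
| n | `n_hill` | 2 | – | Hill exponent |
| τ | `tau` | 10 | d | response delay |
| η | `eta` | 1/60 | 1/d | eryptosis rate (T_RBC = 60 d) |
| x_cap | `x_cap` | 15 | – | maximum dose index |
| κ | `kappa` | 0.36 | 1/d | ESA clearance (T_ESA ≈ 1.9 d) |
| τ_int | `tau_int` | 14 | d | dosing/adjustment interval |
| (h₋,h₊) | `h_lo, h_hi` | (10, 11) | g/dL | Hb target window |
| h_hold | `h_hold` | 12 | g/dL | hold limit |
| c0 | `c0` | 1 | a.u. | minimal non-zero dose |
| ω₁, Δt₁ | `omega1, dt1` | 0.02, 14 | g/dL/d, d | physiological noise |
| ω₂, Δt₂ | `omega2, dt2` | 0.4, 5 | g/dL, d | measurement noise |

At these values the smoothed analysis gives drive `E = 0.25`, steady ESA
level `e* = ē/√3 ≈ 0.433` and steady dose `x* ≈ 2.18`; the feasible band of
RBC lifespans is `26.25 d < T_RBC < 105 d`.

## Numerics

**ESA kinetics are exact.**  `e(t)` is the superposition of exponentially
decayed boluses, evaluated in closed form.  The delayed drive `φ(e(t−τ))`
is therefore available at any stage time without a dense history buffer or
delay-interpolation error.  A brute-force Euler integration of the decay
equation converges to this closed form at first order (checked in the
acceptance suite at a 10⁻³ d step).

**Hb integration.**  Between epochs `dh/dt = A(t) − ηh` with a smooth,
known forcing `A`; one classical RK4 step is then affine in
`(h, A_n, A_mid, A_{n+1})`, so the inner loop reduces to a precomputed
linear recurrence.  The step divides `τ_int` exactly (default 0.1 d).  With
noise off, runs are bit-reproducible and independent of how densely the
trajectory is reported.

**Noise paths.**  `ξᵢ` interpolates i.i.d. N(0,1) draws on a grid of
spacing `Δtᵢ` — cubic spline by default, linear as an option.  The grid
spacing sets the correlation time; the dense-grid variance is slightly
below 1 (≈ 0.87 cubic, ≈ 0.67 linear) because interpolation averages
between knots.  At knots the path equals the stored draws exactly.  All
randomness flows from one master seed through named substreams
(physiological, measurement, burn-in, per-patient, per-cell), so switching
one noise source off does not shift another.

**Smoothed model.**  The continuous counterpart replaces impulsive dosing
by the rate `c0x/τ_int` and the decision tree by `−tanh((h−h̄)/σ)/τ_int`
(window center `h̄`, half-width `σ`), removing cap and hold.  It is
integrated by the method of steps with RK4; the step is snapped so the
delay is an exact multiple of it, and mid-step delayed values use 4-point
cubic interpolation of the stored history.  Its fixed point is analytic;
linear stability reduces to roots of
`χ(α) = βe^{−ατ} + α(α+κ)(α+η)`, `β = μφ′(e*)c0/(στ_int²)`.  The
second-order truncation gives damped-oscillator coefficients
(`γ = κη − βτ`, `m = κ + η + βτ²/2`) and seed roots `α±`; a complex Newton
iteration refines them against the full `χ` (tolerance |χ| < 10⁻¹⁰), with
a multi-start grid over the right part of the root plane guarding against
convergence to a subdominant root (the rightmost converged root is
reported).  `φ` is extended oddly to negative arguments so that implausible
smoothed regimes (negative doses/concentrations, which the smoothed model
admits by construction) remain integrable.

Near the reference point the truncated and refined roots agree to well
under 1% in magnitude, and locate the imaginary-axis crossing on a `κ`
path within a few percent of each other.  Note that at the reference
parameters `γ` is already slightly negative: the *smoothed* loop sits just
beyond its cycling onset, while the discrete loop — stabilized by the
dead zone of the maintain branch and the integer dose steps — shows only
mild quantization-driven variability there.  The smoothed criterion is an
analytic guide, not a quantitative onset prediction for the discrete
algorithm; the two are compared only qualitatively.

## Time-series statistics

Hb is bridged to arbitrary times by a cubic smoothing spline with
residual-sum bound `s = 0.2 × n` points (about a 0.45 g/dL r.m.s.
allowance per point, sized to absorb measurement error).  Because
measurement and dosing times need not overlap — which is the sole reason
interpolation exists — a query that *does* coincide with a measurement
returns the recorded value itself.  Series with fewer than 8 points fall
back to linear interpolation; fewer than 4 is an error.  Zero doses are
made explicit by inserting zeros at 14-day strides into any >14-day gap
between successive administrations (gap ends untouched; leading/trailing
gaps receive none).  The Hb–ESA Pearson correlation pairs interpolated Hb
with the imputed dose series at the imputed dose times restricted to the
Hb span; for phase-shifted sinusoids over whole periods it equals
`cos δ` to machine precision.  Peaks are counted on the same interpolated
series with topographic prominence ≥ 0.75 g/dL.  Eligibility mirrors the
screens used for clinical records: ≥ 5 administrations, no Hb gap over
30 days, finite correlation.  Window metrics (`frac_below`, `frac_above`,
mean distance) use trapezoidal time-averaging; boundaries count as inside
the window.

## Synthetic data

Two generators stand in for clinical records, which are not distributed
with the package:

* `make_fixture_series` builds small clinical-format series of known
  structure (steady, cycling/anti-phase, hold-and-ramp, too-sparse) with
  irregular weekly-ish sampling and non-zero-only dose records.
* Virtual cohorts rescale the five patient-dependent rates
  (λ, η, μ, κ, ω₁) by independent factors ζ drawn from the positive part
  of N(1, 1/3).  The spread is read as a *variance* of 1/3 (σ = 1/√3
  ≈ 0.577), the standard N(mean, variance) convention; with the narrower
  σ = 1/3 reading the cohort is too homogeneous for the
  variability-vs-correlation scatter to show any trend, which settled the
  ambiguity.  A `shared_zeta` switch scales all five rates together for
  sensitivity analysis.  Series lengths are uniform over 399–448 days,
  matching the typical year-long span of clinical records, and each
  virtual series is exported the way clinical series are kept — weekly Hb
  samples of the ground-truth trajectory plus the non-zero dose record —
  then analyzed through the identical clinical path.  Measurement error
  still corrupts every dosing decision; the exported weekly labs are the
  trajectory itself, keeping the cohort statistics about the dynamics
  rather than about the error model.

What the generators do *not* emulate: correlations between physiological
parameters (known to exist in real populations), non-stationary physiology,
intercurrent events (infections, hospitalizations, iron status), missed or
manually overridden doses, and ESA-type switches.  Passing tests therefore
demonstrate internal consistency of the model and statistics, not fidelity
to any clinical population.

## Problem sizes

Defaults were chosen so summary statistics stabilize at desk scale: 2-year
burn-in (728 d, an epoch multiple) before production spans; 5-year runs
with 3 replicate seeds per cell for parameter sweeps; 200 patients per
cohort; 0.1 d integration step (0.05 d for the smoothed oracle runs, which
adaptively extend their span up to ~12 000 d near the bifurcation where
modes decay slowly).

## Known limitations

* The smoothed onset criterion `γ < 0` is an approximation both of the
  full transcendental root condition and — more significantly — of the
  discrete algorithm's behavior; discrete quantization cycles exist even
  where the smoothed loop is stable and vice versa.
* The Hb–ESA correlation estimator inherits the smoothing spline's
  distortion for signals comparable to the smoothing allowance; its value
  is a rank/phase indicator, not an unbiased amplitude estimate.
* The simulator's event model covers instantaneous Hb offsets only.
* `splrep`'s knot placement is not mirror-symmetric, so interpolated
  metrics are only approximately invariant under time reversal.
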