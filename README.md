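# hbcycle

Patients with renal anemia are treated with erythropoiesis-stimulating
agents (ESAs), dosed in a closed loop: hemoglobin (Hb) is measured
regularly, the dose is adjusted by a threshold algorithm, and the patient's
delayed physiological response feeds back into the next measurement.  A
fraction of patients develop *hemoglobin cycling* — weeks-to-months-long
periodic over- and undershoots of the Hb target range, associated with poor
outcomes.  `hbcycle` implements a minimal dynamical model of this treatment
loop for studying when and why such cycles emerge, together with the
time-series statistics that reveal cycling hallmarks in clinical-format
records.

It is intended for modelers and quantitatively minded clinicians who want a
transparent, fully reproducible testbed for ESA dosing schemes, not a
clinical decision tool.

## The model

Three variables: Hb concentration `h` (g/dL), the prescribed dose index `x`
(a dose chart `c(x) = c0·x`) and the systemic ESA level `e` (a.u.):

    dh/dt = λ + μ φ(e(t−τ)) − η h + ω₁ξ₁(t)
    de/dt = −κ e            (+ bolus c0·x at each administration)

with the Hill response `φ(e) = eⁿ/(ēⁿ+eⁿ)`.  Every `τ_int` days the loop
measures `h + ω₂ξ₂(t)`, updates `x` by a decision tree (below the target
window `[h₋, h₊]`: increase by one step; above: decrease; inside: maintain;
above the hold limit `h_hold`: suspend until Hb falls below the window) and
administers `c0·x`.  RBC lifespan is `T_RBC = 1/η`, ESA half-life
`T_ESA = ln2/κ`; the noise terms are cubic interpolations of unit normal
draws on coarse grids.  ESA kinetics are integrated exactly (superposition
of decayed boluses); `h` uses a fixed-step classical Runge-Kutta scheme.

Replacing the impulsive dosing by its continuous-rate counterpart and the
decision tree by `−tanh((h−h̄)/σ)/τ_int` gives a smooth delay system whose
fixed point, feasibility bounds and linear stability are analytic: the
characteristic function `χ(α) = β e^{−ατ} + α(α+κ)(α+η)` with
`β = μφ′(e*)c0/(στ_int²)` truncates to a damped oscillator with damping
`γ = κη − βτ`; `γ < 0` approximates the Hopf bifurcation at which
self-sustained Hb cycling sets in, and the refined dominant root of `χ`
gives growth/decay rates of perturbations (e.g. bleeding episodes).

Statistics for clinical-format records (weekly-ish Hb, non-zero doses
only): smoothing-spline Hb interpolation (`s = 0.2 × n` points), zero-dose
imputation into >14-day dosing gaps, the Hb–ESA Pearson correlation (equal
to `cos δ` for phase-shifted sinusoids, a phase readout under cycling),
prominence-based Hb peak counting (≥ 0.75 g/dL), eligibility screens and
target-window summaries.  Simulated and clinical series flow through the
same code.  Virtual-patient cohorts rescale the physiological rates by
positive-truncated normal factors to emulate population heterogeneity.

## Worked example

```python
from hbcycle import (PatientParams, TreatmentParams, steady_state,
                     stability, equilibrate, simulate, summarize)

patient, treatment = PatientParams(), TreatmentParams()   # reference values

st = steady_state(patient, treatment)
print(f"drive E        = {st.E:.4f}")        # drive E        = 0.2500
print(f"e* (a.u.)      = {st.e_star:.4f}")   # e* (a.u.)      = 0.4330
print(f"x* (dose idx)  = {st.x_star:.4f}")   # x* (dose idx)  = 2.1824

sb = stability(patient, treatment, st)
print(f"gamma          = {sb.gamma:.6f}")    # gamma          = -0.020511
print(f"cycling        = {sb.cycling_predicted}")  # cycling  = True

state = equilibrate(patient, treatment, burn_in=728.0, seed=42)
res = simulate(patient, treatment, span=730.0, init=state, seed=42)
m = summarize(res, treatment)
print(f"Hb sd (g/dL)   = {m.hb_sd:.3f}")     # Hb sd (g/dL)   = 0.619
print(f"mean dose      = {m.mean_dose:.3f}") # mean dose      = 2.736
print(f"Hb-ESA corr    = {m.hb_esa_corr:.3f}")  # Hb-ESA corr = -0.315
```

Reading: at reference physiology a quarter of the maximal ESA response
(`E = 0.25`) holds Hb at the window center, requiring a steady dose of about
2.2 chart steps — so the integer-valued chart must alternate between doses,
and with the smoothed damping `γ` slightly negative the loop sits near its
cycling onset: the two-year course shows mild Hb variability (sd ≈ 0.6
g/dL) around the 10–11 g/dL window and a weakly negative Hb–ESA
correlation.  Tripling ESA responsiveness (`mu=0.9`) tips the loop into
pronounced cycling with a strongly negative correlation.

The same functionality is scriptable from the shell:

```sh
hbcycle simulate --seed 42 --span 730 --out-dir run1     # CSVs + manifest
hbcycle analyze --hb run1/hb.csv --esa run1/esa.csv
hbcycle stability
hbcycle sweep --param "mu:0.15:1.2:6" --out sweep.csv
hbcycle cohort --n 200 --out cohort.csv
```

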