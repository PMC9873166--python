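"""Virtual-patient cohorts, parameter sweeps and synthetic clinical fixtures.

A virtual cohort emulates physiological heterogeneity by rescaling the five
patient-dependent rates (base gain ``lambda``, eryptosis ``eta``,
responsiveness ``mu``, ESA clearance ``kappa`` and physiological noise
``omega1``) from their reference values ``v_i`` to ``zeta_i v_i``, with each
``zeta_i`` drawn from the positive part of a normal distribution with mean 1
and variance 1/3.  Series lengths are drawn uniformly from the 399-448 day
range typical of year-long clinical records, and each virtual series is
exported the way clinical records are kept — weekly Hb values and non-zero
dose administrations — so cohort statistics run through the identical
clinical analysis path.  Parameter correlations between the rates are
deliberately not modelled.

Sweeps evaluate the full pipeline (equilibrate, simulate, summarize) on 1-D
or 2-D parameter grids and attach the smoothed-model diagnostics (steady
state feasibility, onset margin) to every cell, which places the predicted
cycling onset on any swept axis by the sign change of the margin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import ClinicalSeries, summarize
from .model import PatientParams, TreatmentParams
from .simulate import equilibrate, simulate, substream
from .smoothed import onset_margin, steady_state

__all__ = [
    "CohortSpec",
    "SweepResult",
    "sample_patient",
    "run_cohort",
    "sweep",
    "make_fixture_series",
    "SCALED_PARAMETERS",
]

logger = logging.getLogger(__name__)

#: parameters rescaled per virtual patient: (config name, owner, field)
SCALED_PARAMETERS = (
    ("lambda", "patient", "lambda_"),
    ("eta", "patient", "eta"),
    ("mu", "patient", "mu"),
    ("kappa", "treatment", "kappa"),
    ("omega1", "patient", "omega1"),
)


@dataclass
class CohortSpec:
    """Sampling specification for a virtual-patient cohort."""

    patient: PatientParams = field(default_factory=PatientParams)
    treatment: TreatmentParams = field(default_factory=TreatmentParams)
    n_patients: int = 200
    master_seed: int = 0
    zeta_sd: float = 3.0 ** -0.5   # N(1, 1/3): variance 1/3
    shared_zeta: bool = False      # one zeta for all scaled parameters
    length_low: float = 399.0      # days, uniform series-length range
    length_high: float = 448.0
    burn_in: float = 728.0         # days of equilibration before each series
    hb_sampling_days: float = 7.0  # weekly Hb records, as in clinical series


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Rejection draw from the positive part of N(mean, sd)."""
    while True:
        z = mean + sd * rng.standard_normal()
        if z > 0:
            return z


def sample_patient(spec: CohortSpec, index: int):
    """Deterministic virtual patient ``index`` of the cohort.

    Returns ``(patient, treatment, length_days)``.  Each scaled parameter is
    ``zeta * v_i`` with independent (or, with ``shared_zeta``, one common)
    positive-truncated normal draws; unscaled parameters stay at the
    specification's base values.
    """
    if not (0 <= index < spec.n_patients):
        raise ValueError(f"patient index {index} outside [0, {spec.n_patients})")
    rng = np.random.default_rng(substream(spec.master_seed, "cohort", index))
    if spec.shared_zeta:
        z = _positive_normal(rng, 1.0, spec.zeta_sd)
        zetas = {name: z for name, _, _ in SCALED_PARAMETERS}
    else:
        zetas = {name: _positive_normal(rng, 1.0, spec.zeta_sd)
                 for name, _, _ in SCALED_PARAMETERS}
    pkw, tkw = {}, {}
    for name, owner, fld in SCALED_PARAMETERS:
        base = getattr(spec.patient if owner == "patient" else spec.treatment, fld)
        (pkw if owner == "patient" else tkw)[fld] = zetas[name] * base
    patient = replace(spec.patient, **pkw)
    treatment = replace(spec.treatment, **tkw)
    length = float(rng.uniform(spec.length_low, spec.length_high))
    return patient, treatment, length


def run_cohort(spec: CohortSpec, step: float = 0.1) -> pd.DataFrame:
    """Per-patient summary table of a simulated cohort.

    Each row: equilibrate, simulate for the sampled length, export to the
    clinical format (weekly ground-truth Hb samples plus the non-zero dose
    record) and summarize through the clinical analysis path.  Undefined
    correlations are kept as nulls; per-patient failures are logged and
    yield a row flagged ``failed`` rather than aborting the cohort.
    """
    rows = []
    for i in range(spec.n_patients):
        patient, treatment, length = sample_patient(spec, i)
        seed = substream(spec.master_seed, "cohort_run", i)
        row = {"patient": i, "length_days": length, "failed": False}
        try:
            state = equilibrate(patient, treatment, burn_in=spec.burn_in,
                                seed=seed, step=step)
            res = simulate(patient, treatment, span=length, init=state,
                           seed=seed, step=step)
            series = res.to_clinical_series(sampling_days=spec.hb_sampling_days)
            met = summarize(series, treatment)
            row.update(
                hb_sd=met.hb_sd, hb_esa_corr=met.hb_esa_corr,
                n_peaks=met.n_peaks, mean_dose=met.mean_dose,
                esa_sd=met.esa_sd, eligible=met.eligible,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("virtual patient %d failed: %s", i, exc)
            row.update(hb_sd=np.nan, hb_esa_corr=None, n_peaks=np.nan,
                       mean_dose=np.nan, esa_sd=np.nan, eligible=False,
                       failed=True)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

_PATIENT_FIELDS = {f: f for f in ("lambda_", "mu", "e_half", "n_hill", "tau",
                                  "eta", "omega1", "dt1")}
_TREATMENT_FIELDS = {f: f for f in ("tau_int", "h_lo", "h_hi", "h_hold", "c0",
                                    "kappa", "omega2", "dt2")}


def _apply_parameter(patient, treatment, name, value):
    """Set a (possibly derived) parameter by name on the right container."""
    if name == "lambda":
        name = "lambda_"
    if name == "T_RBC":
        return replace(patient, eta=1.0 / value), treatment
    if name == "T_ESA":
        return patient, replace(treatment, kappa=math.log(2.0) / value)
    if name in _PATIENT_FIELDS:
        return replace(patient, **{name: value}), treatment
    if name in _TREATMENT_FIELDS:
        return patient, replace(treatment, **{name: value})
    raise ValueError(f"unknown sweep parameter {name!r}")


@dataclass
class SweepResult:
    """Grid evaluation of simulation metrics plus smoothed-model diagnostics."""

    axes: dict                   # parameter name -> grid array
    table: pd.DataFrame          # one row per cell (averaged over replicates)


_MEAN_METRICS = ("hb_sd", "mean_dose", "esa_sd", "frac_below", "frac_above",
                 "mean_dist_to_window", "n_peaks")


def sweep(param_grids: dict, patient: PatientParams | None = None,
          treatment: TreatmentParams | None = None, replicates: int = 3,
          span: float = 1825.0, burn_in: float = 728.0, master_seed: int = 0,
          step: float = 0.1) -> SweepResult:
    """Run the full pipeline over a 1-D or 2-D parameter grid.

    ``param_grids`` maps one or two parameter names (container fields or the
    derived ``T_RBC``/``T_ESA``) to grids.  Each cell averages ``replicates``
    independent runs (5-year production span after a 2-year burn-in by
    default) and carries the smoothed steady state (with the infeasibility
    reason where the cell lies outside the treatable region) and the
    cycling-onset margin.  Per-cell seeding is derived from the master seed
    and the cell index, so results do not depend on evaluation order.
    """
    if not 1 <= len(param_grids) <= 2:
        raise ValueError("sweep supports one or two parameters")
    patient = patient or PatientParams()
    treatment = treatment or TreatmentParams()
    names = list(param_grids)
    grids = [np.asarray(param_grids[n], dtype=float) for n in names]
    mesh = [g.ravel() for g in np.meshgrid(*grids, indexing="ij")]

    rows = []
    for cell in range(mesh[0].size):
        pat, trt = patient, treatment
        row = {}
        for name, vals in zip(names, mesh):
            row[name] = vals[cell]
            pat, trt = _apply_parameter(pat, trt, name, vals[cell])
        st = steady_state(pat, trt)
        row.update(feasible=st.feasible, infeasibility_reason=st.infeasibility_reason)
        om = onset_margin(pat, trt)
        row.update(onset_margin=om[0] if om else None,
                   cycling_predicted=om[1] if om else None)
        acc = {k: [] for k in _MEAN_METRICS}
        corrs = []
        row["failed"] = False
        try:
            for r in range(replicates):
                seed = substream(master_seed, "sweep", cell, r)
                state = equilibrate(pat, trt, burn_in=burn_in, seed=seed, step=step)
                res = simulate(pat, trt, span=span, init=state, seed=seed, step=step)
                met = summarize(res, trt)
                for k in _MEAN_METRICS:
                    acc[k].append(getattr(met, k))
                if met.hb_esa_corr is not None:
                    corrs.append(met.hb_esa_corr)
            for k in _MEAN_METRICS:
                row[k] = float(np.mean(acc[k]))
            row["hb_esa_corr"] = float(np.mean(corrs)) if corrs else None
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("sweep cell %d (%s) failed: %s", cell, row, exc)
            row["failed"] = True
        rows.append(row)
    return SweepResult(axes={n: g for n, g in zip(names, grids)},
                       table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Synthetic clinical-format fixtures
# ---------------------------------------------------------------------------

def make_fixture_series(kind: str, seed: int = 0) -> ClinicalSeries:
    """Synthetic clinical-format series with known structure (for testing).

    Kinds: ``steady`` (mild fluctuation about the window, no prominent
    peaks), ``cycling`` (sinusoidal Hb with anti-phase dosing, correlation
    near -1), ``holdy`` (dose ramps interrupted by suspension gaps) and
    ``sparse`` (too few administrations to be eligible).  All series use
    irregular weekly-ish Hb sampling and record non-zero doses only.
    """
    rng = np.random.default_rng(substream(seed, "fixture", kind))
    if kind == "steady":
        hb_t = _jittered_grid(rng, 0.0, 420.0, 7.0, 1.5)
        hb_v = 10.5 + 0.12 * rng.standard_normal(hb_t.size)
        esa_t = np.arange(0.0, 420.0, 14.0)
        esa_d = np.where(np.arange(esa_t.size) % 2 == 0, 2.0, 3.0)
    elif kind == "cycling":
        period = 90.0
        hb_t = _jittered_grid(rng, 0.0, 450.0, 7.0, 1.5)
        hb_v = 10.5 + 1.5 * np.sin(2 * np.pi * hb_t / period)
        esa_t = np.arange(0.0, 450.0, 14.0)
        esa_d = 4.0 + 3.0 * np.sin(2 * np.pi * esa_t / period + np.pi)
        esa_d = np.maximum(esa_d, 0.25)
    elif kind == "holdy":
        hb_t = _jittered_grid(rng, 0.0, 420.0, 7.0, 1.5)
        hb_v = 11.0 + 1.2 * np.sin(2 * np.pi * hb_t / 140.0) \
            + 0.1 * rng.standard_normal(hb_t.size)
        esa_t, esa_d = [], []
        t = 0.0
        while t < 420.0:
            for k in range(1, 6):  # ramp, then a 56-day suspension
                if t >= 420.0:
                    break
                esa_t.append(t)
                esa_d.append(float(k))
                t += 14.0
            t += 56.0
        esa_t, esa_d = np.asarray(esa_t), np.asarray(esa_d)
    elif kind == "sparse":
        hb_t = _jittered_grid(rng, 0.0, 100.0, 7.0, 1.5)
        hb_v = 10.5 + 0.2 * rng.standard_normal(hb_t.size)
        esa_t = np.asarray([0.0, 14.0, 28.0, 42.0])
        esa_d = np.asarray([2.0, 3.0, 2.0, 3.0])
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    hb_v = np.maximum(hb_v, 1.0)
    return ClinicalSeries(hb_times=hb_t, hb_values=hb_v,
                          esa_times=esa_t, esa_doses=esa_d,
                          patient_id=f"fixture-{kind}-{seed}")


def _jittered_grid(rng, start, stop, spacing, jitter):
    """Strictly increasing, irregular sampling grid."""
    base = np.arange(start, stop, spacing)
    t = base + rng.uniform(-jitter, jitter, base.size)
    t[0] = max(t[0], start)
    t = np.maximum.accumulate(t + 1e-6 * np.arange(t.size))
    # enforce strict monotonicity
    for i in range(1, t.size):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 0.25
    return t
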