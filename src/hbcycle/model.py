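"""Core model building blocks: parameters, dose-response and the dosing algorithm.

The model couples three quantities of an anemia patient under
erythropoiesis-stimulating-agent (ESA) therapy:

* ``h`` — blood hemoglobin concentration (g/dL), produced at a base rate
  ``lambda_``, boosted by ESA with responsiveness ``mu`` after a delay ``tau``,
  and cleared by eryptosis at rate ``eta`` (red-blood-cell lifespan
  ``T_RBC = 1/eta``);
* ``x`` — the prescribed dose index in a linear dosing chart ``c(x) = c0*x``,
  adjusted every ``tau_int`` days by a threshold rule on the measured Hb;
* ``e`` — the systemic ESA concentration, raised impulsively at each
  administration and cleared at rate ``kappa`` (half-life ``T_ESA = ln2/kappa``).

This module holds the two parameter containers, the sigmoidal (Hill)
dose-response, the dosing chart and the discrete dose-adjustment rule; the
dynamics live in :mod:`hbcycle.simulate` and :mod:`hbcycle.smoothed`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "PatientParams",
    "TreatmentParams",
    "hill_response",
    "hill_derivative",
    "hill_inverse",
    "dose_chart",
    "dose_decision",
    "params_to_dict",
    "params_from_dict",
    "reference_patient",
    "reference_treatment",
    "CONFIG_KEYS",
]


@dataclass(frozen=True)
class PatientParams:
    """Physiological parameters of a simulated patient.

    All rates are per day; Hb-related quantities in g/dL, ESA amounts in
    arbitrary units (a.u.).
    """

    lambda_: float = 0.1   # Hb base gain rate, g/dL/d
    mu: float = 0.3        # ESA responsiveness, g/dL/d at saturating ESA
    e_half: float = 0.75   # ESA EC50, a.u.
    n_hill: float = 2.0    # Hill exponent (dimensionless, >= 1)
    tau: float = 10.0      # delay between administration and Hb response, d
    eta: float = 1.0 / 60.0  # eryptosis rate, 1/d
    omega1: float = 0.02   # physiological noise strength, g/dL/d
    dt1: float = 14.0      # physiological-noise grid spacing, d

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                if f.name in ("omega1",) and v == 0:
                    continue  # noise may be switched off
                raise ValueError(f"PatientParams.{f.name} must be positive, got {v!r}")
        if self.n_hill < 1:
            raise ValueError(f"n_hill must be >= 1, got {self.n_hill}")

    @property
    def T_RBC(self) -> float:
        """Red-blood-cell lifespan in days, the inverse eryptosis rate."""
        return 1.0 / self.eta


@dataclass(frozen=True)
class TreatmentParams:
    """Parameters of the dosing algorithm and of the ESA preparation."""

    tau_int: float = 14.0  # dose adjustment/administration interval, d
    h_lo: float = 10.0     # lower bound of the Hb target window, g/dL
    h_hi: float = 11.0     # upper bound of the Hb target window, g/dL
    h_hold: float = 12.0   # hold limit: suspend dosing above this Hb, g/dL
    c0: float = 1.0        # minimal non-zero dose step, a.u.
    x_cap: int = 15        # maximum dose index (highest available single dose)
    kappa: float = 0.36    # ESA clearance rate, 1/d
    omega2: float = 0.4    # measurement noise strength, g/dL
    dt2: float = 5.0       # measurement-noise grid spacing, d

    def __post_init__(self) -> None:
        if not (self.h_lo < self.h_hi < self.h_hold):
            raise ValueError(
                f"need h_lo < h_hi < h_hold, got ({self.h_lo}, {self.h_hi}, {self.h_hold})"
            )
        if self.tau_int <= 0:
            raise ValueError(f"tau_int must be positive, got {self.tau_int}")
        if not (isinstance(self.x_cap, (int, np.integer)) and self.x_cap >= 1):
            raise ValueError(f"x_cap must be an integer >= 1, got {self.x_cap!r}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.c0 <= 0:
            raise ValueError(f"c0 must be positive, got {self.c0}")
        if self.omega2 < 0 or self.dt2 <= 0:
            raise ValueError("omega2 must be >= 0 and dt2 > 0")

    @property
    def T_ESA(self) -> float:
        """ESA half-life in days, ``ln2 / kappa``."""
        return math.log(2.0) / self.kappa

    @property
    def h_bar(self) -> float:
        """Center of the Hb target window, g/dL."""
        return 0.5 * (self.h_lo + self.h_hi)

    @property
    def sigma(self) -> float:
        """Half-width of the Hb target window, g/dL."""
        return 0.5 * (self.h_hi - self.h_lo)


def reference_patient(**overrides) -> PatientParams:
    """Reference physiology (the defaults of :class:`PatientParams`)."""
    return replace(PatientParams(), **overrides)


def reference_treatment(**overrides) -> TreatmentParams:
    """Reference treatment scheme (the defaults of :class:`TreatmentParams`)."""
    return replace(TreatmentParams(), **overrides)


# ---------------------------------------------------------------------------
# Dose-response nonlinearity
# ---------------------------------------------------------------------------

def hill_response(e, params: PatientParams):
    """Sigmoidal fraction ``e^n / (e_half^n + e^n)`` of the maximal Hb response.

    Accepts scalars or arrays; ``e`` must be non-negative.  The value is in
    ``[0, 1)``, equals ``1/2`` exactly at the EC50 and is strictly increasing.
    """
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < 0):
        raise ValueError("ESA concentration must be non-negative")
    en = e_arr ** params.n_hill
    out = en / (params.e_half ** params.n_hill + en)
    return float(out) if np.isscalar(e) or e_arr.ndim == 0 else out


def hill_derivative(e, params: PatientParams):
    """Exact derivative of :func:`hill_response` with respect to ``e``."""
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < 0):
        raise ValueError("ESA concentration must be non-negative")
    n, eb = params.n_hill, params.e_half
    num = n * eb ** n * e_arr ** (n - 1.0)
    out = num / (eb ** n + e_arr ** n) ** 2
    return float(out) if np.isscalar(e) or e_arr.ndim == 0 else out


def hill_inverse(frac, params: PatientParams):
    """Analytic inverse of the Hill response on the open interval (0, 1)."""
    f = np.asarray(frac, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("hill_inverse is defined on the open interval (0, 1)")
    out = params.e_half * (f / (1.0 - f)) ** (1.0 / params.n_hill)
    return float(out) if np.isscalar(frac) or f.ndim == 0 else out


# ---------------------------------------------------------------------------
# Dosing chart and decision rule
# ---------------------------------------------------------------------------

def dose_chart(x: int, c0: float) -> float:
    """Linear dosing chart: the administered amount for dose index ``x``.

    Every available dose is a multiple of the minimal non-zero dose ``c0``.
    """
    if not isinstance(x, (int, np.integer)):
        raise ValueError(f"dose index must be an integer, got {x!r}")
    if x < 0:
        raise ValueError(f"dose index must be >= 0, got {x}")
    return float(c0) * int(x)


def dose_decision(x: int, h_meas: float, treatment: TreatmentParams) -> int:
    """Dose-adjustment decision based on the most recent Hb measurement.

    Threshold rule of the treatment algorithm:

    * ``h_meas >= h_hold``      -> suspend dosing (index 0);
    * ``h_hi < h_meas < h_hold``-> decrease by one step (not below 0);
    * ``h_lo <= h_meas <= h_hi``-> maintain the current dose;
    * ``h_meas < h_lo``         -> increase by one step (capped at ``x_cap``).

    From a suspended state (``x = 0``) dosing resumes, at index 1, only once
    the measured Hb drops below the target window; the above-window branch
    cannot take the index negative.  The target window is treated as closed
    (boundary values maintain the dose).
    """
    if not isinstance(x, (int, np.integer)):
        raise ValueError(f"dose index must be an integer, got {x!r}")
    x = int(x)
    if not (0 <= x <= treatment.x_cap):
        raise ValueError(f"dose index {x} outside [0, {treatment.x_cap}]")
    if not math.isfinite(h_meas):
        raise ValueError(f"measured Hb must be finite, got {h_meas!r}")
    if h_meas >= treatment.h_hold:
        return 0
    if h_meas > treatment.h_hi:
        return max(x - 1, 0)
    if h_meas >= treatment.h_lo:
        return x
    return min(x + 1, treatment.x_cap)


# ---------------------------------------------------------------------------
# Flat key-value (de)serialization of parameter sets
# ---------------------------------------------------------------------------

# Config keys use the published symbol names; "lambda" is a Python keyword,
# hence the trailing underscore on the dataclass field only.
_PATIENT_KEYS = {
    "lambda": "lambda_", "mu": "mu", "e_half": "e_half", "n_hill": "n_hill",
    "tau": "tau", "eta": "eta", "omega1": "omega1", "dt1": "dt1",
}
_TREATMENT_KEYS = {
    "tau_int": "tau_int", "h_lo": "h_lo", "h_hi": "h_hi", "h_hold": "h_hold",
    "c0": "c0", "x_cap": "x_cap", "kappa": "kappa", "omega2": "omega2",
    "dt2": "dt2",
}
CONFIG_KEYS = tuple(_PATIENT_KEYS) + tuple(_TREATMENT_KEYS)


def params_to_dict(patient: PatientParams, treatment: TreatmentParams) -> dict:
    """Flatten both parameter sets into one key-value mapping."""
    out = {k: getattr(patient, f) for k, f in _PATIENT_KEYS.items()}
    out.update({k: getattr(treatment, f) for k, f in _TREATMENT_KEYS.items()})
    return out


def params_from_dict(cfg: dict) -> tuple[PatientParams, TreatmentParams]:
    """Build parameter sets from a flat mapping; unknown keys are errors.

    Keys omitted from the mapping keep their reference (default) values.
    """
    unknown = set(cfg) - set(CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    pkw = {f: cfg[k] for k, f in _PATIENT_KEYS.items() if k in cfg}
    tkw = {f: cfg[k] for k, f in _TREATMENT_KEYS.items() if k in cfg}
    if "x_cap" in tkw:
        x_cap = tkw["x_cap"]
        if float(x_cap) != int(float(x_cap)):
            raise ValueError(f"x_cap must be an integer, got {x_cap!r}")
        tkw["x_cap"] = int(float(x_cap))
    return PatientParams(**pkw), TreatmentParams(**tkw)
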