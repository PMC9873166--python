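"""Smoothed counterpart of the discrete treatment loop and its analytics.

Replacing the impulsive biweekly administrations by a continuous dosing rate
``c0 x / tau_int`` and the threshold decision rule by the odd sigmoid
``-tanh((h - h_bar)/sigma)`` (and dropping the dose cap and hold limit)
yields the deterministic delay system

    dh/dt = lambda + mu phi(e(t - tau)) - eta h
    dx/dt = -tanh((h - h_bar)/sigma) / tau_int
    de/dt = c0 x / tau_int - kappa e

whose fixed point and linear stability are available analytically:

* steady state: ``h* = h_bar``, ``e* = phi^{-1}(E)`` with the dimensionless
  drive ``E = (eta h_bar - lambda)/mu = (h_bar/T_RBC - lambda)/mu``, and
  ``x* = kappa tau_int e* / c0``; feasible only for ``0 < E < 1`` (otherwise
  either no ESA is needed, or the target is unreachable at any dose);
* perturbation growth exponents are roots of the transcendental
  characteristic function ``chi(alpha) = beta e^{-alpha tau}
  + alpha (alpha + kappa)(alpha + eta)`` with ``beta = mu' c0 / (sigma
  tau_int^2)`` and ``mu' = mu phi'(e*)``;
* truncating ``chi`` at second order maps the loop onto a damped harmonic
  oscillator with stiffness ``beta``, damping ``gamma = kappa eta - beta tau``
  and inertia ``m = kappa + eta + beta tau^2 / 2``; the sign change of
  ``gamma`` approximates the Hopf bifurcation at which self-sustained Hb
  cycling sets in, and ``gamma^2 < 4 beta m`` marks the damped-oscillatory
  (transient-cycling) regime.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .model import (
    PatientParams,
    TreatmentParams,
    hill_derivative,
    hill_inverse,
    hill_response,
)

__all__ = [
    "SteadyState",
    "StabilityResult",
    "steady_state",
    "characteristic_function",
    "stability",
    "onset_margin",
    "simulate_smoothed",
]


@dataclass(frozen=True)
class SteadyState:
    """Fixed point of the smoothed loop (or the reason it does not exist)."""

    h_star: float
    x_star: float
    e_star: float
    E: float
    feasible: bool
    infeasibility_reason: str | None = None


def steady_state(patient: PatientParams, treatment: TreatmentParams) -> SteadyState:
    """Fixed point holding Hb at the window center under steady dosing.

    The drive ``E`` is the fraction of the maximal ESA response needed to
    hold ``h_bar``.  ``E <= 0`` means the patient's residual RBC production
    alone sustains the target (``T_RBC > h_bar / lambda``: no ESA needed);
    ``E >= 1`` means eryptosis outpaces even a saturating response
    (``T_RBC < h_bar / (mu + lambda)``: target unreachable).
    """
    h_bar = treatment.h_bar
    E = (patient.eta * h_bar - patient.lambda_) / patient.mu
    if E <= 0:
        return SteadyState(h_star=h_bar, x_star=0.0, e_star=0.0, E=E,
                           feasible=False, infeasibility_reason="no_ESA_needed")
    if E >= 1:
        return SteadyState(h_star=h_bar, x_star=math.inf, e_star=math.inf, E=E,
                           feasible=False, infeasibility_reason="target_unreachable")
    e_star = hill_inverse(E, patient)
    x_star = treatment.kappa * treatment.tau_int * e_star / treatment.c0
    return SteadyState(h_star=h_bar, x_star=x_star, e_star=e_star, E=E,
                       feasible=True, infeasibility_reason=None)


# ---------------------------------------------------------------------------
# Linear stability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityResult:
    """Characteristic-root diagnostics of the smoothed fixed point."""

    mu_prime: float              # linearized ESA gain mu * phi'(e*)
    beta: float                  # restoring-force coefficient
    gamma: float                 # damping coefficient (negative -> cycling)
    m: float                     # inertial coefficient
    alpha_plus: complex          # truncated (damped-oscillator) roots
    alpha_minus: complex
    alpha_exact: complex         # refined dominant root of the full chi
    residual: float              # |chi(alpha_exact)|
    converged: bool
    cycling_predicted: bool      # gamma < 0
    damped_oscillatory: bool     # gamma > 0 and gamma^2 < 4 beta m


def characteristic_function(alpha, beta: float, tau: float, kappa: float,
                            eta: float):
    """``chi(alpha) = beta e^{-alpha tau} + alpha (alpha+kappa) (alpha+eta)``."""
    a = np.asarray(alpha, dtype=complex)
    out = beta * np.exp(-a * tau) + a * (a + kappa) * (a + eta)
    return complex(out) if np.isscalar(alpha) or a.ndim == 0 else out


def _chi_prime(a: complex, beta: float, tau: float, kappa: float, eta: float) -> complex:
    return (-tau * beta * cmath.exp(-a * tau)
            + 3 * a * a + 2 * (kappa + eta) * a + kappa * eta)


def _newton_root(a0: complex, beta, tau, kappa, eta, tol=1e-12, maxiter=80):
    a = complex(a0)
    for _ in range(maxiter):
        if a.real * tau < -500 or abs(a) > 1e8:  # runaway iterate
            return a, math.inf
        f = characteristic_function(a, beta, tau, kappa, eta)
        if abs(f) < tol:
            return a, abs(f)
        df = _chi_prime(a, beta, tau, kappa, eta)
        if df == 0:
            break
        step = f / df
        a = a - step
        if abs(step) > 1e6:
            break
    if a.real * tau < -500 or abs(a) > 1e8:
        return a, math.inf
    f = characteristic_function(a, beta, tau, kappa, eta)
    return a, abs(f)


def stability(patient: PatientParams, treatment: TreatmentParams,
              steady: SteadyState | None = None, tol: float = 1e-10) -> StabilityResult:
    """Damped-oscillator coefficients and the dominant characteristic root.

    The truncated roots ``alpha_±`` seed a complex Newton iteration on the
    full transcendental ``chi``; a grid of additional starting points over
    the right part of the root plane guards against the seed converging to a
    subdominant root, and the rightmost converged root is reported.
    """
    if steady is None:
        steady = steady_state(patient, treatment)
    if not steady.feasible:
        raise ValueError(
            f"no feasible steady state ({steady.infeasibility_reason}); "
            "stability analysis undefined"
        )
    kappa, eta, tau = treatment.kappa, patient.eta, patient.tau
    mu_prime = patient.mu * hill_derivative(steady.e_star, patient)
    beta = mu_prime * treatment.c0 / (treatment.sigma * treatment.tau_int ** 2)
    gamma = kappa * eta - beta * tau
    m = kappa + eta + beta * tau ** 2 / 2.0

    disc = cmath.sqrt(complex(gamma * gamma - 4.0 * beta * m))
    alpha_plus = (-gamma + disc) / (2.0 * m)
    alpha_minus = (-gamma - disc) / (2.0 * m)

    # Multi-start Newton refinement; keep the rightmost converged root.
    scale = max(kappa, eta, abs(alpha_plus), 1.0 / tau)
    seeds = [alpha_plus, alpha_minus]
    re_grid = np.linspace(-2.0 * scale, 0.75 * scale, 7)
    im_max = 3.0 * math.pi / tau + 2.0 * abs(alpha_plus.imag)
    im_grid = np.linspace(0.0, im_max, 7)
    seeds += [complex(r, i) for r in re_grid for i in im_grid]

    roots = []
    for s in seeds:
        root, res = _newton_root(s, beta, tau, kappa, eta, tol=min(tol, 1e-12))
        if res < tol:
            root = complex(root.real, abs(root.imag))  # conjugate pair: report im >= 0
            if not any(abs(root - r) < 1e-8 * max(1.0, abs(root)) for r, _ in roots):
                roots.append((root, res))
    if roots:
        alpha_exact, residual = max(roots, key=lambda p: p[0].real)
        converged = True
    else:  # refinement failed: report the truncated root
        alpha_exact, residual = alpha_plus, abs(
            characteristic_function(alpha_plus, beta, tau, kappa, eta))
        converged = False

    return StabilityResult(
        mu_prime=mu_prime, beta=beta, gamma=gamma, m=m,
        alpha_plus=alpha_plus, alpha_minus=alpha_minus,
        alpha_exact=alpha_exact, residual=residual, converged=converged,
        cycling_predicted=gamma < 0,
        damped_oscillatory=(gamma > 0 and gamma * gamma < 4.0 * beta * m),
    )


def onset_margin(patient: PatientParams, treatment: TreatmentParams):
    """Signed distance to the cycling-onset criterion, or ``None`` if infeasible.

    Returns ``(margin, cycling_predicted)`` where ``margin = mu' c0 / (sigma
    tau_int^2) - ln2 / (tau T_ESA T_RBC)`` (equal to ``-gamma/tau``); the
    onset of self-sustained cycling is predicted where the margin changes
    sign from negative to positive along a parameter sweep.
    """
    steady = steady_state(patient, treatment)
    if not steady.feasible:
        return None
    st = stability(patient, treatment, steady)
    margin = st.beta - treatment.kappa * patient.eta / patient.tau
    return margin, st.cycling_predicted


# ---------------------------------------------------------------------------
# Deterministic integration of the smoothed loop (method of steps)
# ---------------------------------------------------------------------------

def simulate_smoothed(patient: PatientParams, treatment: TreatmentParams,
                      span: float, init=None, step: float = 0.05):
    """Integrate the smoothed three-variable delay system.

    ``init`` is ``(h0, x0, e0)`` with a constant ESA history ``e(t) = e0``
    on ``[-tau, 0]``; by default the run starts at the feasible fixed point.
    A fixed-step classical Runge-Kutta scheme advances the state; the step
    is snapped so the delay is an exact multiple of it, and mid-step delayed
    values come from 4-point (cubic) interpolation of the stored history.

    Returns ``(t, h, x, e)`` as arrays on the integrator grid.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if init is None:
        st = steady_state(patient, treatment)
        if not st.feasible:
            raise ValueError("no feasible steady state; provide an explicit init")
        init = (st.h_star, st.x_star, st.e_star)
    h0, x0, e0 = (float(v) for v in init)

    tau = patient.tau
    d = max(2, round(tau / step))
    step = tau / d
    n = max(1, round(span / step))

    lam, mu, eta = patient.lambda_, patient.mu, patient.eta
    kappa, c0, tau_int = treatment.kappa, treatment.c0, treatment.tau_int
    h_bar, sigma = treatment.h_bar, treatment.sigma
    eb_n = patient.e_half ** patient.n_hill
    n_hill = patient.n_hill

    def phi(e):
        if e <= 0.0:
            # the smoothed model admits transient negative e in implausible
            # regimes; extend phi oddly to keep the flow well defined
            return -((-e) ** n_hill / (eb_n + (-e) ** n_hill)) if e < 0 else 0.0
        en = e ** n_hill
        return en / (eb_n + en)

    hs = np.empty(n + 1)
    xs = np.empty(n + 1)
    es = np.empty(n + 1)
    hs[0], xs[0], es[0] = h0, x0, e0
    # e-history ring: e at nodes i-d .. i (constant e0 before t=0)
    e_hist = np.full(n + d + 1, e0)

    tanh = math.tanh
    for i in range(n):
        # delayed ESA level at the three stage times
        ed0 = e_hist[i]
        ed1 = e_hist[i + 1]
        # cubic 4-point midpoint interpolation of the stored history; the
        # clamped stencil at i = 0 is exact because the history is constant
        jm1 = i - 1 if i >= 1 else 0
        edh = (-e_hist[jm1] + 9.0 * e_hist[i] + 9.0 * e_hist[i + 1]
               - e_hist[i + 2]) / 16.0

        p0 = mu * phi(ed0)
        ph = mu * phi(edh)
        p1 = mu * phi(ed1)

        h, x, e = hs[i], xs[i], es[i]

        k1h = lam + p0 - eta * h
        k1x = -tanh((h - h_bar) / sigma) / tau_int
        k1e = c0 * x / tau_int - kappa * e

        h2 = h + 0.5 * step * k1h
        x2 = x + 0.5 * step * k1x
        e2 = e + 0.5 * step * k1e
        k2h = lam + ph - eta * h2
        k2x = -tanh((h2 - h_bar) / sigma) / tau_int
        k2e = c0 * x2 / tau_int - kappa * e2

        h3 = h + 0.5 * step * k2h
        x3 = x + 0.5 * step * k2x
        e3 = e + 0.5 * step * k2e
        k3h = lam + ph - eta * h3
        k3x = -tanh((h3 - h_bar) / sigma) / tau_int
        k3e = c0 * x3 / tau_int - kappa * e3

        h4 = h + step * k3h
        x4 = x + step * k3x
        e4 = e + step * k3e
        k4h = lam + p1 - eta * h4
        k4x = -tanh((h4 - h_bar) / sigma) / tau_int
        k4e = c0 * x4 / tau_int - kappa * e4

        s6 = step / 6.0
        hs[i + 1] = h + s6 * (k1h + 2 * k2h + 2 * k3h + k4h)
        xs[i + 1] = x + s6 * (k1x + 2 * k2x + 2 * k3x + k4x)
        es[i + 1] = e + s6 * (k1e + 2 * k2e + 2 * k3e + k4e)
        e_hist[i + d + 1] = es[i + 1]

    t = step * np.arange(n + 1)
    return t, hs, xs, es
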