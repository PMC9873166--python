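"""Hybrid stochastic delay simulator of the Hb/ESA treatment loop.

Between administration epochs the hemoglobin concentration follows

    dh/dt = lambda + mu * phi(e(t - tau)) - eta * h + omega1 * xi1(t),

where ``phi`` is the Hill dose-response and ``e`` the systemic ESA
concentration.  ESA kinetics are linear first-order decay punctuated by
instantaneous administrations, so ``e`` is evaluated in closed form as a
superposition of exponentially decayed boluses — the delayed term needs no
dense history buffer and carries no interpolation error.  Every ``tau_int``
days the engine measures ``h`` (plus measurement noise ``omega2 * xi2``),
updates the dose index through the decision rule and administers the charted
amount.  Both noise channels are smooth interpolations of unit-variance
Gaussian draws on coarse grids, so the right-hand side is smooth between
epochs and a fixed-step classical Runge-Kutta scheme integrates ``h``.

Instantaneous events ("bleed" subtracts, "transfusion" adds a Hb offset) can
be injected at arbitrary times, mimicking e.g. acute blood loss.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .model import (
    PatientParams,
    TreatmentParams,
    dose_chart,
    dose_decision,
    hill_response,
)

__all__ = [
    "NoisePath",
    "ModelState",
    "SimulationResult",
    "substream",
    "make_noise_path",
    "esa_level",
    "simulate",
    "equilibrate",
]

H_FLOOR = 1.0  # g/dL; below this the run is aborted and flagged


def substream(seed, *names) -> np.random.SeedSequence:
    """Named, reproducible child stream of a master seed.

    All randomness in the package flows from one master seed through named
    substreams, so that e.g. switching measurement noise off does not shift
    the physiological-noise draws.
    """
    if isinstance(seed, np.random.SeedSequence):
        base = seed
    else:
        base = np.random.SeedSequence(int(seed))
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    entropy = base.entropy if base.entropy is not None else 0
    return np.random.SeedSequence(entropy=entropy, spawn_key=tuple(base.spawn_key) + key)


# ---------------------------------------------------------------------------
# Interpolated Gaussian noise
# ---------------------------------------------------------------------------

@dataclass
class NoisePath:
    """Smooth random function: interpolated i.i.d. N(0,1) draws on a grid.

    The grid spacing sets the correlation time of the process.  At the grid
    points the path equals the stored draws exactly; in between it is a cubic
    spline (default) or a linear interpolation.
    """

    t0: float
    dt: float
    values: np.ndarray
    kind: str = "cubic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("noise grid spacing must be positive")
        if self.kind not in ("cubic", "linear"):
            raise ValueError(f"unknown interpolation kind {self.kind!r}")
        self._grid = self.t0 + self.dt * np.arange(self.values.size)
        if self.kind == "cubic":
            self._spline = CubicSpline(self._grid, self.values)
        else:
            self._spline = None

    @property
    def grid(self) -> np.ndarray:
        return self._grid

    @property
    def t_end(self) -> float:
        return float(self._grid[-1])

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.t0 - 1e-9) or np.any(t_arr > self.t_end + 1e-9):
            raise ValueError("noise path evaluated outside its span")
        t1 = np.atleast_1d(t_arr)
        if self._spline is not None:
            out = np.asarray(self._spline(t1))
        else:
            out = np.asarray(np.interp(t1, self._grid, self.values))
        # at grid points the path equals the stored draw exactly
        k = np.rint((t1 - self.t0) / self.dt).astype(int)
        on_grid = np.abs(self.t0 + k * self.dt - t1) < 1e-9 * self.dt
        on_grid &= (k >= 0) & (k < self.values.size)
        out[on_grid] = self.values[k[on_grid]]
        return float(out[0]) if np.isscalar(t) or t_arr.ndim == 0 else out


def make_noise_path(dt: float, span: float, seed, kind: str = "cubic",
                    t0: float = 0.0) -> NoisePath:
    """Gaussian noise path covering ``[t0, t0 + span]`` with grid spacing ``dt``."""
    if dt <= 0 or span <= 0:
        raise ValueError("dt and span must be positive")
    n = max(4, int(math.ceil(span / dt)) + 2)  # cover the span with margin
    rng = np.random.default_rng(seed)
    return NoisePath(t0=t0, dt=dt, values=rng.standard_normal(n), kind=kind)


# ---------------------------------------------------------------------------
# ESA kinetics (closed form)
# ---------------------------------------------------------------------------

def esa_level(admin_log, kappa: float, t, *, initial: float = 0.0,
              t_init: float = 0.0):
    """Systemic ESA concentration from the administration history.

    Exact superposition ``e(t) = sum_{t_j <= t} a_j exp(-kappa (t - t_j))``
    plus the exponentially decayed initial value; no integration error.
    """
    times = np.asarray([rec[0] for rec in admin_log], dtype=float)
    amounts = np.asarray([rec[1] for rec in admin_log], dtype=float)
    if np.any(amounts < 0):
        raise ValueError("administered amounts must be non-negative")
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("administration times must be non-decreasing")
    t_arr = np.asarray(t, dtype=float)
    out = np.zeros(t_arr.shape)
    if initial:
        lag = t_arr - t_init
        np.add(out, np.where(lag >= 0, initial * np.exp(-kappa * np.maximum(lag, 0.0)), 0.0), out=out)
    for tj, aj in zip(times, amounts):
        lag = t_arr - tj
        np.add(out, np.where(lag >= 0, aj * np.exp(-kappa * np.maximum(lag, 0.0)), 0.0), out=out)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# State and result containers
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """Instantaneous state plus the injection history determining ``e``.

    ``admin_log`` must hold enough past administrations (times <= ``t``) to
    evaluate the ESA level on ``[t - tau, t]``; before the first logged
    administration the ESA level is zero.
    """

    t: float = 0.0
    h: float = 10.5
    x: int = 0
    admin_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.h > 0):
            raise ValueError(f"h must be positive, got {self.h}")
        if not (isinstance(self.x, (int, np.integer)) and self.x >= 0):
            raise ValueError(f"dose index must be a non-negative integer, got {self.x!r}")
        times = [rec[0] for rec in self.admin_log]
        if any(tj > self.t + 1e-9 for tj in times):
            raise ValueError("admin_log times must not exceed the state time")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("admin_log times must be non-decreasing")
        if any(rec[1] < 0 for rec in self.admin_log):
            raise ValueError("admin_log amounts must be non-negative")


@dataclass
class SimulationResult:
    """Trajectories and records of one simulated treatment course."""

    times: np.ndarray            # dense ground-truth time grid, d
    h: np.ndarray                # ground-truth Hb, g/dL
    meas_times: np.ndarray       # decision epochs, d
    meas_values: np.ndarray      # measured Hb incl. measurement error, g/dL
    admin_times: np.ndarray      # administration times (epochs), d
    admin_amounts: np.ndarray    # administered amounts incl. zeros, a.u.
    dose_indices: np.ndarray     # post-update dose index per epoch
    events: list                 # applied (time, type, magnitude) events
    seed: object                 # master seed of the run
    patient: PatientParams
    treatment: TreatmentParams
    step: float
    flags: dict = field(default_factory=dict)

    @property
    def cumulative_dose(self) -> float:
        return float(np.sum(self.admin_amounts))

    _init_log: list = field(default_factory=list, repr=False)

    def esa(self, t):
        """Closed-form systemic ESA level of this run at arbitrary times."""
        log = sorted(self._init_log) + list(zip(self.admin_times, self.admin_amounts))
        return esa_level(log, self.treatment.kappa, t)

    def to_clinical_series(self, use_measured: bool = True, patient_id=None,
                           sampling_days: float | None = None):
        """Export to the clinical two-channel record format.

        Hb channel: by default the measured values at decision epochs; with
        ``use_measured=False`` the ground-truth trajectory at those epochs,
        or — when ``sampling_days`` is given — the ground truth sampled on a
        regular grid of that spacing (e.g. 7 to emulate weekly Hb records).
        ESA channel: non-zero administrations only, matching the convention
        that zero doses are implicit in clinical records.
        """
        from .metrics import ClinicalSeries

        if sampling_days is not None:
            hb_t = np.arange(0.0, self.times[-1] + 1e-9, float(sampling_days))
            idx = np.clip(np.searchsorted(self.times, hb_t), 0, self.times.size - 1)
            hb_v = self.h[idx]
        elif use_measured:
            hb_t, hb_v = self.meas_times, self.meas_values
        else:
            idx = np.searchsorted(self.times, self.meas_times)
            idx = np.clip(idx, 0, self.times.size - 1)
            hb_t, hb_v = self.meas_times, self.h[idx]
        keep = hb_v > 0
        if not np.all(keep):
            import warnings

            warnings.warn("dropping non-positive measured Hb values on export")
        pos = self.admin_amounts > 0
        return ClinicalSeries(
            hb_times=hb_t[keep], hb_values=hb_v[keep],
            esa_times=self.admin_times[pos], esa_doses=self.admin_amounts[pos],
            patient_id=patient_id,
        )


# ---------------------------------------------------------------------------
# Integration engine
# ---------------------------------------------------------------------------

def _rk4_affine_coeffs(eta: float, dt: float):
    """Coefficients of one classical RK4 step for dh/dt = A(t) - eta*h.

    The update is affine in (h, A_n, A_mid, A_{n+1}); returns those four
    coefficients so the inner loop reduces to a linear recurrence.
    """

    def advance(h, a0, ah, a1):
        k1 = a0 - eta * h
        k2 = ah - eta * (h + 0.5 * dt * k1)
        k3 = ah - eta * (h + 0.5 * dt * k2)
        k4 = a1 - eta * (h + dt * k3)
        return h + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    return (advance(1.0, 0, 0, 0), advance(0.0, 1, 0, 0),
            advance(0.0, 0, 1, 0), advance(0.0, 0, 0, 1))


class _EsaHistory:
    """Post-administration ESA values with O(log n) lookback evaluation."""

    def __init__(self, kappa: float, admin_log) -> None:
        self.kappa = kappa
        self.t: list[float] = []
        self.e_post: list[float] = []
        for tj, aj in admin_log:
            self.add(tj, aj)

    def add(self, tj: float, amount: float) -> None:
        if self.t and tj < self.t[-1] - 1e-12:
            raise ValueError("administrations must be added in time order")
        if amount < 0:
            raise ValueError("administered amounts must be non-negative")
        prev = self.e_post[-1] * math.exp(-self.kappa * (tj - self.t[-1])) if self.t else 0.0
        self.t.append(tj)
        self.e_post.append(prev + amount)

    def eval(self, s: np.ndarray) -> np.ndarray:
        """ESA level at (past) times ``s``; right-continuous at admin times."""
        out = np.zeros(s.shape)
        if not self.t:
            return out
        t_arr = np.asarray(self.t)
        idx = np.searchsorted(t_arr, s, side="right") - 1
        mask = idx >= 0
        if np.any(mask):
            i = idx[mask]
            out[mask] = np.asarray(self.e_post)[i] * np.exp(-self.kappa * (s[mask] - t_arr[i]))
        return out


def simulate(patient: PatientParams, treatment: TreatmentParams, span: float,
             init: ModelState | None = None, seed=0, events=(),
             step: float = 0.1, noise_kind: str = "cubic",
             dosing: bool = True) -> SimulationResult:
    """Integrate the closed treatment loop over ``span`` days.

    Parameters
    ----------
    init:
        Starting state including the administration history (times <= 0)
        that determines the ESA level on ``[-tau, 0]``.  ``None`` means a
        cold start at the window center with no ESA on board; see
        :func:`equilibrate` for a warmed-up state.
    seed:
        Master seed (int or ``SeedSequence``); physiological and measurement
        noise use independent named substreams of it.
    events:
        Iterable of ``(time, type, magnitude)`` with type ``"bleed"``
        (instantaneous Hb drop by ``magnitude`` g/dL) or ``"transfusion"``
        (instantaneous rise).  Event times must lie inside ``[0, span)``.
    dosing:
        If False the decision rule is bypassed (dose index pinned at 0),
        which exposes the ESA-free physiology.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if init is None:
        init = ModelState(t=0.0, h=treatment.h_bar, x=0, admin_log=[])
    if not (0 <= init.x <= treatment.x_cap):
        raise ValueError(f"initial dose index {init.x} outside [0, {treatment.x_cap}]")

    # Fixed step dividing the epoch interval exactly.
    n_per = max(1, round(treatment.tau_int / step))
    step = treatment.tau_int / n_per
    n_nodes = max(1, round(span / step))
    span = n_nodes * step
    n_epochs = int(math.ceil(span / treatment.tau_int - 1e-9))

    event_offsets: dict[int, float] = {}
    applied_events = []
    for ev in events:
        t_ev, kind, mag = ev
        if not (0.0 <= t_ev < span):
            raise ValueError(f"event at t={t_ev} outside the simulated span [0, {span})")
        if kind not in ("bleed", "transfusion"):
            raise ValueError(f"unknown event type {kind!r}")
        if mag < 0:
            raise ValueError("event magnitude must be non-negative")
        node = round(t_ev / step)
        delta = -mag if kind == "bleed" else mag
        event_offsets[node] = event_offsets.get(node, 0.0) + delta
        applied_events.append((node * step, kind, mag))

    # Noise channels on independent substreams of the master seed.
    if patient.omega1 > 0:
        xi1 = make_noise_path(patient.dt1, span + step,
                              substream(seed, "physiological"), kind=noise_kind)
    else:
        xi1 = None
    if treatment.omega2 > 0 and dosing:
        xi2 = make_noise_path(treatment.dt2, span + step,
                              substream(seed, "measurement"), kind=noise_kind)
    else:
        xi2 = None

    hist = _EsaHistory(treatment.kappa, init.admin_log)
    a_h, c_0, c_mid, c_1 = _rk4_affine_coeffs(patient.eta, step)

    hs = np.empty(n_nodes + 1)
    hs[0] = init.h
    h = float(init.h)
    x = int(init.x)
    meas_t, meas_v, adm_t, adm_a, idx_rec = [], [], [], [], []
    flags: dict = {"h_floor": False}
    stop_node = None

    for k in range(n_epochs):
        node_a = k * n_per
        node_b = min((k + 1) * n_per, n_nodes)
        t_k = node_a * step
        # (i) measure, (ii) update the prescription, (iii) administer
        m = h + (treatment.omega2 * xi2(t_k) if xi2 is not None else 0.0)
        meas_t.append(t_k)
        meas_v.append(m)
        if dosing:
            x = dose_decision(x, m, treatment)
        amount = dose_chart(x, treatment.c0) if dosing else 0.0
        adm_t.append(t_k)
        adm_a.append(amount)
        idx_rec.append(x)
        hist.add(t_k, amount)

        # vectorized forcing over the chunk
        nodes_t = t_k + step * np.arange(node_b - node_a + 1)
        half_t = nodes_t[:-1] + 0.5 * step
        e_del_nodes = hist.eval(nodes_t - patient.tau)
        e_del_half = hist.eval(half_t - patient.tau)
        A_nodes = patient.lambda_ + patient.mu * hill_response(e_del_nodes, patient)
        A_half = patient.lambda_ + patient.mu * hill_response(e_del_half, patient)
        if xi1 is not None:
            A_nodes = A_nodes + patient.omega1 * xi1(nodes_t)
            A_half = A_half + patient.omega1 * xi1(half_t)

        for i in range(node_b - node_a):
            node = node_a + i
            if node in event_offsets:
                h += event_offsets[node]
                hs[node] = h
                if h <= H_FLOOR:
                    stop_node = node
                    break
            h = a_h * h + c_0 * A_nodes[i] + c_mid * A_half[i] + c_1 * A_nodes[i + 1]
            hs[node + 1] = h
            if h <= H_FLOOR:
                stop_node = node + 1
                break
        if stop_node is not None:
            break
        if node_b in event_offsets and node_b == n_nodes:
            h += event_offsets[node_b]
            hs[node_b] = h

    if stop_node is not None:
        flags["h_floor"] = True
        flags["h_floor_time"] = stop_node * step
        n_keep = stop_node + 1
    else:
        n_keep = n_nodes + 1

    return SimulationResult(
        times=step * np.arange(n_keep),
        h=hs[:n_keep].copy(),
        meas_times=np.asarray(meas_t),
        meas_values=np.asarray(meas_v),
        admin_times=np.asarray(adm_t),
        admin_amounts=np.asarray(adm_a),
        dose_indices=np.asarray(idx_rec, dtype=int),
        events=applied_events,
        seed=seed,
        patient=patient,
        treatment=treatment,
        step=step,
        flags=flags,
        _init_log=list(init.admin_log),
    )


def equilibrate(patient: PatientParams, treatment: TreatmentParams,
                burn_in: float = 728.0, seed=0, step: float = 0.1,
                noise_kind: str = "cubic") -> ModelState:
    """Terminal state of a burn-in run, for drawing equilibrated initial states.

    Starts from a neutral state (Hb at the window center, no dose, empty
    history) and runs the full stochastic loop for ``burn_in`` days on the
    dedicated ``"burn_in"`` substream of ``seed``, so production runs with
    the same master seed see independent noise.  The returned state is
    re-timed to ``t = 0`` with the administration history shifted to
    negative times.  ``burn_in`` should be large compared to ``tau``,
    ``T_RBC`` and ``T_ESA``; with ``burn_in = 0`` the neutral state itself
    is returned.
    """
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    if burn_in == 0:
        return ModelState(t=0.0, h=treatment.h_bar, x=0, admin_log=[])
    res = simulate(patient, treatment, span=burn_in,
                   init=None, seed=substream(seed, "burn_in"),
                   step=step, noise_kind=noise_kind)
    if res.flags.get("h_floor"):
        raise RuntimeError(
            "Hb fell to the physiological floor during burn-in; "
            "parameter set is unphysiological"
        )
    span_eff = float(res.times[-1])
    log = [(t - span_eff, a) for t, a in zip(res.admin_times, res.admin_amounts) if a > 0]
    x_final = int(res.dose_indices[-1]) if res.dose_indices.size else 0
    return ModelState(t=0.0, h=float(res.h[-1]), x=x_final, admin_log=log)
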