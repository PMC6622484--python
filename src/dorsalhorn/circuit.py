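"""Three-population firing-rate circuit of the dorsal horn.

The circuit follows the gate-control architecture: projection neurons
(P) receive direct input from all three afferent fiber classes, an
excitatory interneuron population (E) driven by C fibers, and an
inhibitory interneuron population (I) driven by Aβ fibers.  I inhibits
both P and E.  Average firing rates relax toward a sigmoid function of
the summed synaptic drive with population-specific time constants:

    tau_P df_P/dt = P_inf(g_AbP f_Ab + g_AdP f_Ad + (g_CP + g_NMDA) f_C
                          + g_EP f_E - g_IP f_I) - f_P
    tau_E df_E/dt = E_inf(g_CE f_C - g_IE f_I) - f_E
    tau_I df_I/dt = I_inf(g_AbI f_Ab) - f_I

The C→P synaptic weight has a slow activity-dependent component
``g_NMDA`` that relaxes toward a sigmoid of the P rate itself,

    tau_NMDA dg_NMDA/dt = M_inf(f_P) - g_NMDA,

representing voltage-dependent relief of the Mg2+ block on NMDA
receptors; its slow time scale (1 s vs 1–20 ms) makes the circuit's
response grow across repeated stimuli (wind-up).

Each sigmoid is ``max/2 * (1 + tanh((x - beta)/alpha))``: ``beta`` is
the half-activation input and ``1/alpha`` the transition slope.

The default parameter set shipped here was obtained by the documented
calibration procedure (``scripts/calibrate.py``): the response-function
and weight values are constrained to reproduce the qualitative and
quantitative behaviors of the circuit (resting activity, wind-up
anchors, daily-rhythm amplitudes) rather than transcribed from any
published table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import numpy as np
from scipy import optimize

from .afferents import BIN_WIDTH, RateTrace

__all__ = [
    "ResponseFunctionParams",
    "CircuitParams",
    "CircuitState",
    "SimulationResult",
    "default_circuit_params",
    "sigmoid_response",
    "circuit_rhs",
    "simulate",
    "simulate_batch",
    "baseline_steady_state",
    "validate_params",
    "ValidationReport",
]


@dataclass(frozen=True)
class ResponseFunctionParams:
    """One sigmoid response function ``max/2*(1+tanh((x-beta)/alpha))``."""

    max_rate: float  # Hz (or max synaptic weight for the NMDA sigmoid)
    alpha: float  # Hz, inverse-slope scale
    beta: float  # Hz, half-maximum input

    def __post_init__(self) -> None:
        if self.max_rate <= 0:
            raise ValueError("max_rate must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class CircuitParams:
    """Synaptic weights, time constants, and response functions."""

    g_abeta_p: float
    g_adelta_p: float
    g_c_p: float
    g_e_p: float
    g_i_p: float
    g_c_e: float
    g_i_e: float
    g_abeta_i: float
    response_p: ResponseFunctionParams
    response_e: ResponseFunctionParams
    response_i: ResponseFunctionParams
    response_m: ResponseFunctionParams
    tau_p: float = 0.001  # s
    tau_e: float = 0.01  # s
    tau_i: float = 0.02  # s
    tau_nmda: float = 1.0  # s

    def __post_init__(self) -> None:
        for name in ("tau_p", "tau_e", "tau_i", "tau_nmda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "g_abeta_p", "g_adelta_p", "g_c_p", "g_e_p",
            "g_i_p", "g_c_e", "g_i_e", "g_abeta_i",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative (signs are structural)")


def default_circuit_params() -> CircuitParams:
    """Calibrated default parameter set (see ``scripts/calibrate.py``)."""
    return CircuitParams(
        g_abeta_p=0.5,
        g_adelta_p=0.5,
        g_c_p=1.0,
        g_e_p=0.5,
        g_i_p=0.5,
        g_c_e=1.0,
        g_i_e=0.5,
        g_abeta_i=1.0,
        response_p=ResponseFunctionParams(max_rate=60.0, alpha=12.0, beta=22.4),
        response_e=ResponseFunctionParams(max_rate=60.0, alpha=10.0, beta=15.0),
        response_i=ResponseFunctionParams(max_rate=100.0, alpha=15.0, beta=15.0),
        response_m=ResponseFunctionParams(max_rate=5.0, alpha=4.0, beta=42.0),
    )


@dataclass(frozen=True)
class CircuitState:
    """Instantaneous state: three population rates and the NMDA weight."""

    f_p: float
    f_e: float
    f_i: float
    g_nmda: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_p, self.f_e, self.f_i, self.g_nmda])


@dataclass
class SimulationResult:
    """Trajectories of the circuit state on the integration grid."""

    time: np.ndarray  # s
    f_p: np.ndarray
    f_e: np.ndarray
    f_i: np.ndarray
    g_nmda: np.ndarray
    dt: float
    inputs: Optional[RateTrace] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "f_p_hz": self.f_p,
                "f_e_hz": self.f_e,
                "f_i_hz": self.f_i,
                "g_nmda": self.g_nmda,
            }
        )


def sigmoid_response(x, params: ResponseFunctionParams):
    """Sigmoid response ``max/2 * (1 + tanh((x - beta)/alpha))``."""
    return 0.5 * params.max_rate * (1.0 + np.tanh((x - params.beta) / params.alpha))


def circuit_rhs(
    state: CircuitState | np.ndarray,
    inputs: tuple[float, float, float],
    params: CircuitParams,
) -> np.ndarray:
    """Time derivatives (df_P, df_E, df_I, dg_NMDA)/dt.

    ``inputs`` is the instantaneous afferent drive (f_Abeta, f_Adelta,
    f_C) in average per-fiber Hz.  Inhibitory synapses enter the drive
    with negative sign, excitatory with positive sign.
    """
    if isinstance(state, CircuitState):
        state = state.as_array()
    f_p, f_e, f_i, g_nmda = state
    f_ab, f_ad, f_c = inputs
    u_p = (
        params.g_abeta_p * f_ab
        + params.g_adelta_p * f_ad
        + (params.g_c_p + g_nmda) * f_c
        + params.g_e_p * f_e
        - params.g_i_p * f_i
    )
    u_e = params.g_c_e * f_c - params.g_i_e * f_i
    u_i = params.g_abeta_i * f_ab
    return np.array(
        [
            (sigmoid_response(u_p, params.response_p) - f_p) / params.tau_p,
            (sigmoid_response(u_e, params.response_e) - f_e) / params.tau_e,
            (sigmoid_response(u_i, params.response_i) - f_i) / params.tau_i,
            (sigmoid_response(f_p, params.response_m) - g_nmda) / params.tau_nmda,
        ]
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _rhs_batch(y: np.ndarray, f_ab, f_ad, f_c, p: CircuitParams) -> np.ndarray:
    """Vectorized right-hand side; ``y`` has shape (B, 4)."""
    f_p = y[:, 0]
    f_e = y[:, 1]
    f_i = y[:, 2]
    g_n = y[:, 3]
    u_p = (
        p.g_abeta_p * f_ab
        + p.g_adelta_p * f_ad
        + (p.g_c_p + g_n) * f_c
        + p.g_e_p * f_e
        - p.g_i_p * f_i
    )
    u_e = p.g_c_e * f_c - p.g_i_e * f_i
    u_i = p.g_abeta_i * f_ab
    out = np.empty_like(y)
    out[:, 0] = (sigmoid_response(u_p, p.response_p) - f_p) / p.tau_p
    out[:, 1] = (sigmoid_response(u_e, p.response_e) - f_e) / p.tau_e
    out[:, 2] = (sigmoid_response(u_i, p.response_i) - f_i) / p.tau_i
    out[:, 3] = (sigmoid_response(f_p, p.response_m) - g_n) / p.tau_nmda
    return out


def simulate_batch(
    inputs: np.ndarray,
    params: CircuitParams,
    dt: float = 1e-4,
    init: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Integrate the circuit for a batch of input realizations.

    Parameters
    ----------
    inputs
        Afferent drive, shape ``(B, T, 3)`` (or ``(T, 3)`` for a single
        realization) on the 1-ms input grid, zero-order held during
        integration.
    params
        Circuit parameters.
    dt
        Fixed RK4 step; must divide the 1-ms input bin and satisfy
        ``dt <= tau_p / 5``.
    init
        Initial state, shape ``(B, 4)`` or ``(4,)``; defaults to the
        baseline steady state under constant 1-Hz drive.

    Returns
    -------
    Trajectories of shape ``(B, n_steps + 1, 4)`` sampled every ``dt``.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim == 2:
        inputs = inputs[None]
    batch, n_bins, _ = inputs.shape
    if dt > params.tau_p / 5 + 1e-15:
        raise ValueError(f"dt={dt} too large: must be <= tau_p/5 = {params.tau_p / 5}")
    n_sub = int(round(BIN_WIDTH / dt))
    if not math.isclose(n_sub * dt, BIN_WIDTH, rel_tol=1e-9):
        raise ValueError("dt must divide the 1-ms input bin exactly")
    if init is None:
        init = baseline_steady_state(params).as_array()
    init = np.asarray(init, dtype=float)
    if init.ndim == 1:
        init = np.broadcast_to(init, (batch, 4))
    y = np.array(init, dtype=float)
    n_steps = n_bins * n_sub
    out = np.empty((batch, n_steps + 1, 4))
    out[:, 0] = y
    half = 0.5 * dt
    sixth = dt / 6.0
    k = 0
    for b in range(n_bins):
        f_ab = inputs[:, b, 0]
        f_ad = inputs[:, b, 1]
        f_c = inputs[:, b, 2]
        for _ in range(n_sub):
            k1 = _rhs_batch(y, f_ab, f_ad, f_c, params)
            k2 = _rhs_batch(y + half * k1, f_ab, f_ad, f_c, params)
            k3 = _rhs_batch(y + half * k2, f_ab, f_ad, f_c, params)
            k4 = _rhs_batch(y + dt * k3, f_ab, f_ad, f_c, params)
            y = y + sixth * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            k += 1
            out[:, k] = y
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"integration diverged at step {k} (t={k * dt:.4f} s)"
            )
    return out


def simulate(
    inputs: RateTrace,
    params: CircuitParams,
    dt: float = 1e-4,
    init: Optional[CircuitState] = None,
) -> SimulationResult:
    """Integrate the circuit ODEs driven by one set of rate traces.

    Fixed-step RK4 with zero-order hold of the 1-ms input traces;
    deterministic given inputs, parameters, and step size.
    """
    arr = inputs.as_array()
    init_arr = init.as_array() if init is not None else None
    traj = simulate_batch(arr, params, dt=dt, init=init_arr)[0]
    n_steps = traj.shape[0] - 1
    time = np.arange(n_steps + 1) * dt
    return SimulationResult(
        time=time,
        f_p=traj[:, 0],
        f_e=traj[:, 1],
        f_i=traj[:, 2],
        g_nmda=traj[:, 3],
        dt=dt,
        inputs=inputs,
    )


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------

def baseline_steady_state(
    params: CircuitParams,
    baseline_inputs: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CircuitState:
    """Self-consistent fixed point under constant afferent drive.

    Under constant inputs the I and E equations decouple and can be
    solved by forward substitution; the remaining (f_P, g_NMDA) pair is
    solved with a damped fixed-point iteration polished by a root solve.
    Falls back to a 2-s burn-in integration if the root solve does not
    converge.
    """
    f_ab, f_ad, f_c = baseline_inputs
    f_i = sigmoid_response(params.g_abeta_i * f_ab, params.response_i)
    f_e = sigmoid_response(
        params.g_c_e * f_c - params.g_i_e * f_i, params.response_e
    )

    def p_residual(z):
        f_p, g_n = z
        u_p = (
            params.g_abeta_p * f_ab
            + params.g_adelta_p * f_ad
            + (params.g_c_p + g_n) * f_c
            + params.g_e_p * f_e
            - params.g_i_p * f_i
        )
        return [
            sigmoid_response(u_p, params.response_p) - f_p,
            sigmoid_response(f_p, params.response_m) - g_n,
        ]

    z = np.array([0.0, 0.0])
    for _ in range(200):
        res = np.asarray(p_residual(z))
        z_new = z + 0.5 * res
        if np.max(np.abs(z_new - z)) < 1e-12:
            z = z_new
            break
        z = z_new
    sol = optimize.root(p_residual, z, tol=1e-13)
    if not sol.success or np.max(np.abs(p_residual(sol.x))) > 1e-8:
        # burn-in fallback: integrate to equilibrium under constant drive
        const = np.tile(np.array(baseline_inputs), (2000, 1))
        traj = simulate_batch(const, params, init=np.zeros(4))
        y = traj[0, -1]
        state = CircuitState(*y)
    else:
        state = CircuitState(sol.x[0], f_e, f_i, sol.x[1])
    resid = circuit_rhs(state, baseline_inputs, params)
    scaled = resid * np.array(
        [params.tau_p, params.tau_e, params.tau_i, params.tau_nmda]
    )
    if np.max(np.abs(scaled)) > 1e-6:
        raise RuntimeError(
            "baseline steady state did not converge; consider a longer burn-in"
        )
    return state


# ---------------------------------------------------------------------------
# Parameter validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Named qualitative constraints with pass/fail status."""

    checks: dict[str, bool]
    details: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(self.checks.values())

    def failures(self) -> list[str]:
        return [name for name, passed in self.checks.items() if not passed]


def validate_params(
    params: CircuitParams,
    diurnal=None,
    fiber_configs=None,
    pain_threshold: float = 25.0,
) -> ValidationReport:
    """Check the qualitative constraints the circuit must satisfy.

    * the inhibitory population has a higher maximum rate than P and E;
    * the inhibitory population fires at rest, the P population stays
      below the pain threshold at rest;
    * a single nociceptive stimulus drives the C-response mean of f_P
      above the pain threshold at every sampled time of day;
    * f_P approaches its maximum at the most pain-sensitive time of day.

    The stimulus-response checks use the noise-free expected afferent
    drive, so the report is deterministic.
    """
    from .afferents import (
        Condition,
        DiurnalParams,
        StimulusProtocol,
        default_fiber_configs,
        expected_rate_traces,
    )
    from .metrics import CResponseWindow, c_response_mean

    diurnal = diurnal if diurnal is not None else DiurnalParams()
    fiber_configs = fiber_configs if fiber_configs is not None else default_fiber_configs()

    checks: dict[str, bool] = {}
    details: dict[str, str] = {}

    checks["max_i_exceeds_max_p"] = params.response_i.max_rate > params.response_p.max_rate
    checks["max_i_exceeds_max_e"] = params.response_i.max_rate > params.response_e.max_rate

    rest = baseline_steady_state(params)
    checks["resting_inhibitory_rate_positive"] = rest.f_i > 0.5
    checks["resting_p_below_threshold"] = rest.f_p < pain_threshold
    details["rest"] = f"f_p={rest.f_p:.3f} Hz, f_i={rest.f_i:.3f} Hz"

    window = CResponseWindow()
    time_points = [0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0]
    init = rest.as_array()
    responses = []
    peaks = []
    for t_hat in time_points:
        protocol = StimulusProtocol(
            total_duration=1.0,
            stimulus_onsets=(0.5,),
            time_of_day=t_hat,
            condition=Condition.NORMAL,
        )
        trace = expected_rate_traces(protocol, fiber_configs, diurnal)
        traj = simulate_batch(trace.as_array(), params, init=init)[0]
        dt = 1e-4
        time = np.arange(traj.shape[0]) * dt
        sim = SimulationResult(
            time=time, f_p=traj[:, 0], f_e=traj[:, 1], f_i=traj[:, 2],
            g_nmda=traj[:, 3], dt=dt,
        )
        responses.append(c_response_mean(sim, 0.5, window))
        peaks.append(traj[:, 0].max())
    responses_arr = np.array(responses)
    checks["c_response_painful_all_day"] = bool(np.all(responses_arr > pain_threshold))
    details["c_response_range"] = (
        f"{responses_arr.min():.2f}-{responses_arr.max():.2f} Hz over the day"
    )
    best = int(np.argmax(responses_arr))
    checks["p_near_max_at_peak_sensitivity"] = peaks[best] > 0.75 * params.response_p.max_rate
    details["peak_f_p"] = f"{peaks[best]:.2f} Hz of max {params.response_p.max_rate:.1f} Hz"

    return ValidationReport(checks=checks, details=details)
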