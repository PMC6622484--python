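"""Calibration of the default circuit parameters.

The response-function and synaptic-weight values shipped in
``dorsalhorn.circuit.default_circuit_params`` are not transcribed from a
published table; they are reconstructed by this script so that the
circuit reproduces the documented behavioral anchors:

* qualitative constraints — the inhibitory population has a nonzero
  resting rate and the highest maximum rate; the projection population
  is silent at rest and crosses the 25-Hz pain threshold only upon
  stimulation;
* wind-up anchors — for a 2-Hz train of five stimuli, the C-response
  mean of the P population is ~25 Hz at the first stimulus and ~50 Hz at
  the fifth, and is flat across indices at 0.5 Hz;
* daily-rhythm amplitudes — the maximum absolute percent-of-mean
  deviation of the 7-point daily profile is ~15% under normal and ~5%
  under neuropathic conditions, with the daily minimum above the pain
  threshold.

The procedure is fully deterministic: all responses are computed with
the noise-free expected afferent drive (``expected_rate_traces``), a
coarse grid over the P response function and NMDA activation is scanned,
and the best candidate is refined by Nelder–Mead on a weighted
least-squares objective over the anchors.  Because the wind-up anchor is
defined at the trough of the daily rhythm (t_hat = 8 h), the
first-stimulus target is placed at 26.5 Hz: the daily minimum then
clears the 25-Hz threshold while remaining within the tolerance of the
~25-Hz anchor.

The procedure has three stages:

1. coarse grid over the P response function and NMDA activation,
   deterministic expected-input objective;
2. Nelder–Mead refinement of the same objective;
3. stochastic polish: a short Nelder–Mead on the same anchors evaluated
   through the full Poisson pipeline with fixed seeds.  This stage is
   required because input noise systematically increases NMDA
   recruitment (fluctuations of f_P spend more time on the upper part
   of the activation sigmoid than the noise-free trace does), so a
   purely deterministic calibration overshoots wind-up.

Stage 3 is followed by a full-scale candidate comparison: a handful of
points around the stage-3 optimum (beta_m, alpha_m, max_m, beta_p varied
by a few Hz) are evaluated at the study's realization counts (20 for
wind-up, 30 per time point for the daily profiles) and the candidate
whose anchors sit most centrally within their bands is shipped.  The
shipped defaults are

    response_p: max=60, alpha=12.0, beta=22.4
    response_m: max=5.0, alpha=4.0, beta=42.0

(with the fixed structural values in ``build_params`` below).

Run from the repository root::

    python scripts/calibrate.py                 # full pipeline
    python scripts/calibrate.py --start 23.5,10,40,8,5   # stage 3 only

and copy the printed parameter block into ``default_circuit_params``.
"""

from __future__ import annotations

import sys
import time
from dataclasses import replace

import numpy as np
from scipy import optimize

from dorsalhorn.afferents import (
    Condition,
    DiurnalParams,
    StimulusProtocol,
    default_fiber_configs,
    expected_rate_traces,
)
from dorsalhorn.circuit import (
    CircuitParams,
    ResponseFunctionParams,
    SimulationResult,
    baseline_steady_state,
    simulate_batch,
)
from dorsalhorn.metrics import CResponseWindow, c_response_mean, percent_of_mean
from dorsalhorn.experiments import DAILY_TIME_POINTS, WINDUP_TIME_OF_DAY

DT = 2e-4  # coarse but within the step-refinement tolerance; final
           # verification and all shipped experiments use 1e-4
WINDOW = CResponseWindow()
FIBERS = default_fiber_configs()
DIURNAL = DiurnalParams()

# anchor targets (value, weight on squared relative error)
TARGETS = {
    "windup_first": (26.5, 8.0),
    "windup_fifth": (50.0, 4.0),
    "daily_amp_normal": (15.0, 2.0),
    "daily_amp_neuro": (5.0, 1.0),
}

# lower bound on the NMDA sigmoid inverse-slope: the Mg2+ unblock is
# graded over tens of Hz of postsynaptic rate, not a hard step
MIN_ALPHA_M = 2.0


def build_params(x: np.ndarray) -> CircuitParams:
    # g_e_p is held fixed: freeing it lets the optimizer disconnect the
    # excitatory-interneuron relay entirely, which is structurally wrong
    beta_p, alpha_p, beta_m, alpha_m, max_m = x
    return CircuitParams(
        g_abeta_p=0.5,
        g_adelta_p=0.5,
        g_c_p=1.0,
        g_e_p=0.5,
        g_i_p=0.5,
        g_c_e=1.0,
        g_i_e=0.5,
        g_abeta_i=1.0,
        response_p=ResponseFunctionParams(60.0, alpha_p, beta_p),
        response_e=ResponseFunctionParams(60.0, 10.0, 15.0),
        response_i=ResponseFunctionParams(100.0, 15.0, 15.0),
        response_m=ResponseFunctionParams(max_m, alpha_m, beta_m),
    )


def _sim_to_result(f_p: np.ndarray) -> SimulationResult:
    time_grid = np.arange(f_p.shape[0]) * DT
    nan = np.full_like(f_p, np.nan)
    return SimulationResult(time=time_grid, f_p=f_p, f_e=nan, f_i=nan, g_nmda=nan, dt=DT)


def daily_responses(params: CircuitParams, condition: Condition, init) -> np.ndarray:
    inputs = []
    for t_hat in DAILY_TIME_POINTS:
        protocol = StimulusProtocol(time_of_day=t_hat, condition=condition)
        inputs.append(expected_rate_traces(protocol, FIBERS, DIURNAL).as_array())
    traj = simulate_batch(np.stack(inputs), params, dt=DT, init=init)
    return np.array(
        [c_response_mean(_sim_to_result(traj[i, :, 0]), 0.5, WINDOW)
         for i in range(len(DAILY_TIME_POINTS))]
    )


def windup_responses(params: CircuitParams, frequency: float, init,
                     n_stimuli: int = 5) -> tuple[np.ndarray, float]:
    """Per-index C-response means and the peak early (A-volley) transient.

    The early transient — f_P within 60 ms of an onset, before the C
    volley arrives — must stay well below the 25-Hz pain threshold so
    that pain latency reflects the C response.
    """
    onsets = tuple(0.5 + k / frequency for k in range(n_stimuli))
    protocol = StimulusProtocol(
        total_duration=onsets[-1] + 0.5,
        stimulus_onsets=onsets,
        time_of_day=WINDUP_TIME_OF_DAY,
    )
    arr = expected_rate_traces(protocol, FIBERS, DIURNAL).as_array()
    traj = simulate_batch(arr, params, dt=DT, init=init)[0]
    sim = _sim_to_result(traj[:, 0])
    early = 0.0
    for on in onsets:
        i0 = int(round(on / DT))
        i1 = int(round((on + 0.060) / DT))
        early = max(early, float(sim.f_p[i0:i1].max()))
    return np.array([c_response_mean(sim, on, WINDOW) for on in onsets]), early


def evaluate(params: CircuitParams) -> dict:
    rest = baseline_steady_state(params)
    init = rest.as_array()
    normal = daily_responses(params, Condition.NORMAL, init)
    neuro = daily_responses(params, Condition.NEUROPATHIC, init)
    windup, early_peak = windup_responses(params, 2.0, init)
    return {
        "rest_f_p": rest.f_p,
        "rest_f_i": rest.f_i,
        "daily_normal": normal,
        "daily_neuro": neuro,
        "windup_first": windup[0],
        "windup_fifth": windup[-1],
        "windup_series": windup,
        "early_peak": early_peak,
        "daily_amp_normal": np.max(np.abs(percent_of_mean(normal))),
        "daily_amp_neuro": np.max(np.abs(percent_of_mean(neuro))),
        "daily_min_normal": normal.min(),
    }


def objective(x: np.ndarray) -> float:
    try:
        params = build_params(x)
        ev = evaluate(params)
    except (ValueError, RuntimeError, FloatingPointError):
        return 1e6
    cost = 0.0
    for key, (target, weight) in TARGETS.items():
        cost += weight * ((ev[key] - target) / target) ** 2
    # soft constraints
    cost += 10.0 * max(0.0, 26.0 - ev["daily_min_normal"]) ** 2
    cost += 10.0 * max(0.0, ev["rest_f_p"] - 5.0) ** 2
    diffs = np.diff(ev["windup_series"])
    cost += 10.0 * np.sum(np.maximum(0.0, 0.5 - diffs) ** 2)  # monotone wind-up
    cost += 10.0 * np.sum(np.maximum(0.0, ev["daily_normal"] - ev["daily_neuro"]) ** 2)
    # keep the A-volley transient of f_P well below the 25-Hz threshold
    cost += 1.0 * max(0.0, ev["early_peak"] - 18.0) ** 2
    # graded NMDA activation, no hard step
    cost += 10.0 * max(0.0, MIN_ALPHA_M - x[3]) ** 2
    # 0.5-Hz flatness proxy: little NMDA recruitment at the first-stimulus
    # response level, so the slow weight cannot build up at long intervals
    m_at_first = 0.5 * x[4] * (1.0 + np.tanh((ev["windup_first"] - x[2]) / max(x[3], 0.5)))
    cost += 2.0 * max(0.0, m_at_first - 0.25 * x[4]) ** 2
    return float(cost)


# ---------------------------------------------------------------------------
# Stage 3: stochastic polish
# ---------------------------------------------------------------------------

STOCH_TARGETS = {
    "windup_first": (26.0, 8.0),
    "windup_fifth": (50.0, 4.0),
    "daily_amp_normal": (14.0, 2.0),
    "daily_amp_neuro": (6.0, 2.0),
}


def stochastic_evaluate(params: CircuitParams) -> dict:
    """Anchor quantities through the full Poisson pipeline, fixed seeds."""
    from dorsalhorn.experiments import run_daily_rhythm, run_windup

    w2 = run_windup(2.0, n_realizations=8, params=params, seed=606)
    w05 = run_windup(0.5, n_realizations=6, params=params, seed=606)
    dn = run_daily_rhythm(params, n_realizations=8, seed=707)
    du = run_daily_rhythm(params, condition="neuropathic", n_realizations=8, seed=707)
    return {
        "windup_first": w2.mean_rate[0],
        "windup_fifth": w2.mean_rate[-1],
        "windup_series": w2.mean_rate,
        "spread_05": w05.mean_rate.max() - w05.mean_rate.min(),
        "daily_amp_normal": np.max(np.abs(dn.percent_of_mean)),
        "daily_amp_neuro": np.max(np.abs(du.percent_of_mean)),
        "daily_min_normal": dn.mean_rate.min(),
        "daily_normal": dn.mean_rate,
        "daily_neuro": du.mean_rate,
    }


def stochastic_objective(x: np.ndarray) -> float:
    try:
        params = build_params(x)
        ev = stochastic_evaluate(params)
    except (ValueError, RuntimeError, FloatingPointError):
        return 1e6
    cost = 0.0
    for key, (target, weight) in STOCH_TARGETS.items():
        cost += weight * ((ev[key] - target) / target) ** 2
    cost += 5.0 * max(0.0, ev["spread_05"] - 2.2) ** 2
    cost += 10.0 * max(0.0, 26.0 - ev["daily_min_normal"]) ** 2
    diffs = np.diff(ev["windup_series"])
    cost += 10.0 * np.sum(np.maximum(0.0, 0.5 - diffs) ** 2)
    cost += 10.0 * max(0.0, MIN_ALPHA_M - x[3]) ** 2
    cost += np.sum(np.maximum(0.0, ev["daily_normal"] - ev["daily_neuro"]) ** 2)
    return float(cost)


def polish(start: np.ndarray, maxfev: int = 60) -> np.ndarray:
    print(f"stage 3 start cost={stochastic_objective(start):.4f}", flush=True)
    res = optimize.minimize(
        stochastic_objective, start, method="Nelder-Mead",
        options={"xatol": 0.02, "fatol": 1e-3, "maxfev": maxfev},
    )
    print(f"stage 3 cost={res.fun:.4f} after {res.nfev} evaluations", flush=True)
    return res.x


def report(x: np.ndarray) -> None:
    params = build_params(x)
    ev = stochastic_evaluate(params)
    print("final parameters:")
    print(f"  response_p: max=60.0 alpha={x[1]:.4f} beta={x[0]:.4f}")
    print(f"  response_m: max={x[4]:.4f} alpha={x[3]:.4f} beta={x[2]:.4f}")
    print("stochastic diagnostics (fixed calibration seeds):")
    for key in ("windup_first", "windup_fifth", "spread_05",
                "daily_amp_normal", "daily_amp_neuro", "daily_min_normal"):
        print(f"  {key}: {ev[key]:.3f}")
    print(f"  windup series (2 Hz): {np.round(ev['windup_series'], 2)}")
    print(f"  daily normal: {np.round(ev['daily_normal'], 2)}")
    print(f"  daily neuro:  {np.round(ev['daily_neuro'], 2)}")


def main() -> None:
    import argparse

    parser = argparse.ArgumentParser()
    parser.add_argument(
        "--start", type=str, default=None,
        help="comma-separated beta_p,alpha_p,beta_m,alpha_m,max_m; "
             "skip stages 1-2 and polish from this point",
    )
    args = parser.parse_args()
    if args.start is not None:
        start = np.array([float(v) for v in args.start.split(",")])
        report(polish(start))
        return
    _grid_and_refine_then_polish()


def _grid_and_refine_then_polish() -> None:
    # Stage 1: coarse grid around physiologically sensible magnitudes.
    grid_beta_p = [16.0, 20.0, 24.0, 28.0]
    grid_alpha_p = [5.0, 8.0, 11.0]
    grid_beta_m = [32.0, 36.0, 40.0]
    grid_alpha_m = [4.0, 8.0]
    grid_max_m = [2.5, 5.0]
    best, best_cost = None, np.inf
    t0 = time.time()
    for bp in grid_beta_p:
        for ap in grid_alpha_p:
            for bm in grid_beta_m:
                for am in grid_alpha_m:
                    for mm in grid_max_m:
                        x = np.array([bp, ap, bm, am, mm])
                        c = objective(x)
                        if c < best_cost:
                            best, best_cost = x, c
                            print(f"grid improve cost={c:.4f} x={np.round(x, 3)}",
                                  flush=True)
    print(f"grid stage done in {time.time() - t0:.0f} s; cost={best_cost:.4f}")

    # Stage 2: local refinement.
    res = optimize.minimize(
        objective, best, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-5, "maxfev": 400},
    )
    x = res.x
    ev = evaluate(build_params(x))
    print(f"refined cost={res.fun:.5f} after {res.nfev} evaluations")
    print(f"stage 2 result: x={np.round(x, 4)}")
    print(f"  deterministic windup (2 Hz): {np.round(ev['windup_series'], 2)}")

    # Stage 3: stochastic polish from the deterministic optimum.
    report(polish(x))


if __name__ == "__main__":
    sys.exit(main())
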