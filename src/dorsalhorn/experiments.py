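"""Experiment drivers: wind-up, daily rhythm, pain inhibition, neuropathy.

Each driver composes Poisson input generation, circuit integration, and
the pain readouts, averaging over seeded realizations of the afferent
spike trains.  All randomness derives from a single master seed through
``numpy.random.SeedSequence`` spawning, so every result is exactly
reproducible and, in the neuropathy comparison, the two conditions see
identical spike-generation streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .afferents import (
    Condition,
    DiurnalParams,
    FiberClass,
    FiberClassConfig,
    SecondaryPulse,
    StimulusProtocol,
    default_fiber_configs,
    generate_spike_trains,
    rate_traces_from_raster,
)
from .circuit import (
    CircuitParams,
    SimulationResult,
    baseline_steady_state,
    default_circuit_params,
    simulate_batch,
)
from .metrics import (
    CResponseWindow,
    PainThreshold,
    c_response_mean,
    pain_latency,
    percent_of_baseline,
    percent_of_mean,
)

__all__ = [
    "DailyProfile",
    "WindupResult",
    "InhibitionGrid",
    "DAILY_TIME_POINTS",
    "WINDUP_TIME_OF_DAY",
    "run_single_trials",
    "run_daily_rhythm",
    "run_windup",
    "run_windup_frequency_sweep",
    "max_nonoverlap_frequency",
    "run_pain_inhibition",
    "run_neuropathy_comparison",
    "sweep_g_neuro",
]

logger = logging.getLogger(__name__)

#: The seven sampled times of day (hours since wake), spanning the full day.
DAILY_TIME_POINTS: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)

#: Default time of day for wind-up protocols: early afternoon, near the
#: trough of pain sensitivity, where the first-stimulus response sits at
#: the pain threshold.
WINDUP_TIME_OF_DAY: float = 8.0

_STIM_START = 0.5  # s; first stimulus onset
_TAIL = 0.5  # s; trailing interval after the last onset


@dataclass
class DailyProfile:
    """Pain-sensitivity profile over the day for one condition."""

    time_points: np.ndarray  # hours since wake
    mean_rate: np.ndarray  # Hz, realization-mean C-response per time point
    sd_rate: np.ndarray  # Hz, across realizations
    percent_of_mean: np.ndarray  # %
    condition: Condition
    n_realizations: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_hat_h": self.time_points,
                "mean_rate_hz": self.mean_rate,
                "sd_rate_hz": self.sd_rate,
                "percent_of_mean": self.percent_of_mean,
            }
        )

    @property
    def peak_time(self) -> float:
        return float(self.time_points[int(np.argmax(self.mean_rate))])


@dataclass
class WindupResult:
    """Per-stimulus-index response to a repeated stimulus train."""

    frequency: float  # Hz
    mean_rate: np.ndarray  # Hz, C-response mean per stimulus index (mean trace)
    sd_rate: np.ndarray  # Hz, across realizations
    latency: list  # s or None per index, on the realization-mean trace
    n_realizations: int
    time_of_day: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "stimulus_index": np.arange(1, len(self.mean_rate) + 1),
                "frequency_hz": self.frequency,
                "mean_rate_hz": self.mean_rate,
                "sd_rate_hz": self.sd_rate,
                "latency_s": [np.nan if v is None else v for v in self.latency],
            }
        )


@dataclass
class InhibitionGrid:
    """Percent-of-baseline pain response by Aβ-pulse delay and time of day."""

    delays: np.ndarray  # s
    time_points: np.ndarray  # hours since wake
    percent_of_baseline: np.ndarray  # (n_delays, n_time_points)
    n_realizations: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, d in enumerate(self.delays):
            for j, t in enumerate(self.time_points):
                rows.append(
                    {
                        "delay_s": d,
                        "t_hat_h": t,
                        "percent_of_baseline": self.percent_of_baseline[i, j],
                    }
                )
        return pd.DataFrame(
            rows, columns=["delay_s", "t_hat_h", "percent_of_baseline"]
        )


# ---------------------------------------------------------------------------
# Trial machinery
# ---------------------------------------------------------------------------

def _simulate_realizations(
    protocol: StimulusProtocol,
    fiber_configs: dict[FiberClass, FiberClassConfig],
    diurnal: Optional[DiurnalParams],
    params: CircuitParams,
    n_realizations: int,
    seed_seq: np.random.SeedSequence,
    dt: float = 1e-4,
    init: Optional[np.ndarray] = None,
) -> np.ndarray:
    """f_P trajectories for ``n_realizations`` seeded Poisson inputs.

    Returns an array of shape ``(n_realizations, n_steps + 1)``.
    """
    children = seed_seq.spawn(n_realizations)
    traces = []
    for child in children:
        rng = np.random.default_rng(child)
        raster = generate_spike_trains(protocol, fiber_configs, diurnal, rng)
        traces.append(rate_traces_from_raster(raster, fiber_configs).as_array())
    inputs = np.stack(traces)
    if init is None:
        init = baseline_steady_state(params).as_array()
    traj = simulate_batch(inputs, params, dt=dt, init=init)
    return traj[:, :, 0]


def _as_result(f_p: np.ndarray, dt: float) -> SimulationResult:
    time = np.arange(f_p.shape[0]) * dt
    empty = np.full_like(f_p, np.nan)
    return SimulationResult(
        time=time, f_p=f_p, f_e=empty, f_i=empty, g_nmda=empty, dt=dt
    )


def run_single_trials(
    t_hat: float,
    condition: Condition,
    params: CircuitParams,
    diurnal: DiurnalParams,
    fiber_configs: dict[FiberClass, FiberClassConfig],
    n_realizations: int,
    seed_seq: np.random.SeedSequence,
    window: CResponseWindow = CResponseWindow(),
    secondary_pulse: Optional[SecondaryPulse] = None,
    dt: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-stimulus trials at one time of day.

    Returns ``(per-realization C-response means, realization-mean f_P
    trace)``.
    """
    protocol = StimulusProtocol(
        total_duration=_STIM_START + _TAIL,
        stimulus_onsets=(_STIM_START,),
        time_of_day=t_hat,
        condition=condition,
        secondary_abeta_pulse=secondary_pulse,
    )
    f_p = _simulate_realizations(
        protocol, fiber_configs, diurnal, params, n_realizations, seed_seq, dt=dt
    )
    means = np.array(
        [c_response_mean(_as_result(tr, dt), _STIM_START, window) for tr in f_p]
    )
    return means, f_p.mean(axis=0)


# ---------------------------------------------------------------------------
# Daily rhythm
# ---------------------------------------------------------------------------

def run_daily_rhythm(
    params: Optional[CircuitParams] = None,
    diurnal: Optional[DiurnalParams] = None,
    condition: Condition | str = Condition.NORMAL,
    n_realizations: int = 30,
    seed: int | np.random.SeedSequence = 0,
    time_points: Sequence[float] = DAILY_TIME_POINTS,
    fiber_configs: Optional[dict[FiberClass, FiberClassConfig]] = None,
    window: CResponseWindow = CResponseWindow(),
) -> DailyProfile:
    """Daily pain-sensitivity profile from single-stimulus trials.

    At each sampled time of day, ``n_realizations`` independent trials
    are run, the C-response mean of the P population is averaged across
    realizations, and the per-time-point means are expressed as percent
    of their daily mean.
    """
    params = params if params is not None else default_circuit_params()
    diurnal = diurnal if diurnal is not None else DiurnalParams()
    condition = Condition(condition)
    fiber_configs = fiber_configs if fiber_configs is not None else default_fiber_configs()
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    point_seqs = seed_seq.spawn(len(time_points))
    mean_rate = np.empty(len(time_points))
    sd_rate = np.empty(len(time_points))
    for i, (t_hat, sub_seq) in enumerate(zip(time_points, point_seqs)):
        means, _ = run_single_trials(
            t_hat, condition, params, diurnal, fiber_configs,
            n_realizations, sub_seq, window,
        )
        valid = np.isfinite(means)
        if not np.all(valid):
            logger.warning(
                "excluded %d unresponsive trials at t_hat=%.1f h",
                int(np.sum(~valid)), t_hat,
            )
        mean_rate[i] = means[valid].mean()
        sd_rate[i] = means[valid].std(ddof=1)
    return DailyProfile(
        time_points=np.asarray(time_points, dtype=float),
        mean_rate=mean_rate,
        sd_rate=sd_rate,
        percent_of_mean=percent_of_mean(mean_rate),
        condition=condition,
        n_realizations=n_realizations,
    )


# ---------------------------------------------------------------------------
# Wind-up
# ---------------------------------------------------------------------------

def max_nonoverlap_frequency(
    window: CResponseWindow = CResponseWindow(),
    smoothing_window: float = 0.010,
) -> float:
    """Highest repetition frequency without overlap of P responses.

    The response to one stimulus, including rate smoothing, extends to
    ``end_offset + smoothing_window`` after onset, so the inter-stimulus
    interval must be at least that long: ``1 / (0.300 + 0.010) ≈ 3.22``
    Hz with defaults.
    """
    return 1.0 / (window.end_offset + smoothing_window)


def run_windup(
    frequency: float,
    n_stimuli: int = 5,
    n_realizations: int = 20,
    params: Optional[CircuitParams] = None,
    diurnal: Optional[DiurnalParams] = None,
    seed: int | np.random.SeedSequence = 0,
    time_of_day: float = WINDUP_TIME_OF_DAY,
    condition: Condition | str = Condition.NORMAL,
    fiber_configs: Optional[dict[FiberClass, FiberClassConfig]] = None,
    window: CResponseWindow = CResponseWindow(),
    threshold: PainThreshold = PainThreshold(),
    dt: float = 1e-4,
) -> WindupResult:
    """Response to a train of identical stimuli at a fixed frequency.

    Per-stimulus-index C-response means and pain latencies are computed
    on the realization-mean f_P trace.
    """
    params = params if params is not None else default_circuit_params()
    diurnal = diurnal if diurnal is not None else DiurnalParams()
    condition = Condition(condition)
    fiber_configs = fiber_configs if fiber_configs is not None else default_fiber_configs()
    limit = max_nonoverlap_frequency(window)
    if frequency > limit + 1e-9:
        raise ValueError(
            f"frequency {frequency} Hz exceeds the non-overlap limit {limit:.2f} Hz"
        )
    onsets = tuple(_STIM_START + k / frequency for k in range(n_stimuli))
    protocol = StimulusProtocol(
        total_duration=onsets[-1] + _TAIL,
        stimulus_onsets=onsets,
        time_of_day=time_of_day,
        condition=condition,
    )
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    f_p = _simulate_realizations(
        protocol, fiber_configs, diurnal, params, n_realizations, seed_seq, dt=dt
    )
    mean_trace = _as_result(f_p.mean(axis=0), dt)
    per_real = np.array(
        [
            [c_response_mean(_as_result(tr, dt), on, window) for on in onsets]
            for tr in f_p
        ]
    )
    mean_rate = np.array([c_response_mean(mean_trace, on, window) for on in onsets])
    latency = [pain_latency(mean_trace, on, threshold) for on in onsets]
    return WindupResult(
        frequency=frequency,
        mean_rate=mean_rate,
        sd_rate=per_real.std(axis=0, ddof=1),
        latency=latency,
        n_realizations=n_realizations,
        time_of_day=time_of_day,
    )


DEFAULT_SWEEP_FREQUENCIES: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 3.22)


def run_windup_frequency_sweep(
    frequencies: Sequence[float] = DEFAULT_SWEEP_FREQUENCIES,
    seed: int | np.random.SeedSequence = 0,
    **kwargs,
) -> dict[float, WindupResult]:
    """Wind-up results over a set of stimulation frequencies."""
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    children = seed_seq.spawn(len(frequencies))
    return {
        f: run_windup(f, seed=child, **kwargs)
        for f, child in zip(frequencies, children)
    }


# ---------------------------------------------------------------------------
# Pain inhibition
# ---------------------------------------------------------------------------

DEFAULT_INHIBITION_DELAYS: tuple[float, ...] = tuple(
    round(0.05 * k, 2) for k in range(9)
)  # 0 to 0.4 s in 50-ms steps


def run_pain_inhibition(
    delays: Sequence[float] = DEFAULT_INHIBITION_DELAYS,
    time_points: Sequence[float] = DAILY_TIME_POINTS,
    params: Optional[CircuitParams] = None,
    diurnal: Optional[DiurnalParams] = None,
    n_realizations: int = 10,
    seed: int | np.random.SeedSequence = 0,
    fiber_configs: Optional[dict[FiberClass, FiberClassConfig]] = None,
    window: CResponseWindow = CResponseWindow(),
) -> InhibitionGrid:
    """Suppression of the pain response by a delayed second Aβ pulse.

    For each time of day and each delay, the C-response mean is
    expressed as a percentage of the same-time-of-day response at the
    longest delay, where the second pulse arrives after the C-response
    window and has no effect (the self-baseline).
    """
    params = params if params is not None else default_circuit_params()
    diurnal = diurnal if diurnal is not None else DiurnalParams()
    fiber_configs = fiber_configs if fiber_configs is not None else default_fiber_configs()
    delays = sorted(delays)
    baseline_delay = delays[-1]
    if baseline_delay < window.end_offset:
        logger.warning(
            "longest delay %.2f s lies inside the C-response window; the "
            "baseline trial may itself be affected", baseline_delay,
        )
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    point_seqs = seed_seq.spawn(len(time_points))
    grid = np.empty((len(delays), len(time_points)))
    for j, (t_hat, point_seq) in enumerate(zip(time_points, point_seqs)):
        responses = np.empty(len(delays))
        for i, delay in enumerate(delays):
            # identical spike seeds across delays at one time of day, so
            # the delay effect is not confounded with input noise
            pulse = SecondaryPulse(onset=_STIM_START + delay)
            means, _ = run_single_trials(
                t_hat, Condition.NORMAL, params, diurnal, fiber_configs,
                n_realizations, _clone(point_seq), window,
                secondary_pulse=pulse,
            )
            responses[i] = means.mean()
        baseline = responses[-1]
        grid[:, j] = [percent_of_baseline(r, baseline) for r in responses]
    return InhibitionGrid(
        delays=np.asarray(delays, dtype=float),
        time_points=np.asarray(time_points, dtype=float),
        percent_of_baseline=grid,
        n_realizations=n_realizations,
    )


def _clone(seq: np.random.SeedSequence) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        entropy=seq.entropy, spawn_key=seq.spawn_key, pool_size=seq.pool_size
    )


# ---------------------------------------------------------------------------
# Neuropathy
# ---------------------------------------------------------------------------

def run_neuropathy_comparison(
    params: Optional[CircuitParams] = None,
    diurnal: Optional[DiurnalParams] = None,
    seed: int | np.random.SeedSequence = 0,
    n_realizations: int = 30,
    **kwargs,
) -> tuple[DailyProfile, DailyProfile]:
    """Daily profiles under normal and neuropathic conditions.

    The two runs reuse identical spike-generation seeds, so any
    difference is attributable to presynaptic inhibition (normal) versus
    presynaptic excitation (neuropathic) alone.
    """
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    normal = run_daily_rhythm(
        params, diurnal, Condition.NORMAL, n_realizations, _clone(seed_seq), **kwargs
    )
    neuro = run_daily_rhythm(
        params, diurnal, Condition.NEUROPATHIC, n_realizations, _clone(seed_seq), **kwargs
    )
    return normal, neuro


def sweep_g_neuro(
    values: Sequence[float],
    params: Optional[CircuitParams] = None,
    diurnal: Optional[DiurnalParams] = None,
    seed: int | np.random.SeedSequence = 0,
    n_realizations: int = 30,
    **kwargs,
) -> dict[float, DailyProfile]:
    """Neuropathic daily profiles for a range of presynaptic-excitation
    strengths, with shared spike seeds across values."""
    diurnal = diurnal if diurnal is not None else DiurnalParams()
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    out = {}
    for g in values:
        out[g] = run_daily_rhythm(
            params,
            diurnal.with_neuro_coupling(g),
            Condition.NEUROPATHIC,
            n_realizations,
            _clone(seed_seq),
            **kwargs,
        )
    return out
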