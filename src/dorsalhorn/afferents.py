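"""Stimulus-evoked afferent fiber activity.

Primary afferent input to the dorsal horn is carried by three fiber
classes that differ in conduction velocity and response duration:

* **Aβ** — fast, myelinated, innocuous touch (30–70 m/s, brief volley),
* **Aδ** — thinly myelinated, fast localized pain (5–30 m/s),
* **C**  — unmyelinated, slow diffuse pain (0.5–2 m/s, long response).

Each fiber is modeled as a Poisson process firing at a low spontaneous
baseline rate, transiently elevated to a stimulus-response rate during a
class-specific window that begins when the volley, delayed by a per-fiber
conduction latency, arrives at the dorsal horn.  Population activity is
summarised as a smoothed average per-fiber firing rate on a 1-ms grid;
these traces are the inputs f_Aβ(t), f_Aδ(t), f_C(t) to the circuit model.

The stimulus-response rates of the Aβ and C classes are modulated over
the 24-h day by sinusoids in antiphase, and the effective C rate further
incorporates Aβ-dependent presynaptic modulation (inhibitory under
normal conditions, excitatory under neuropathic conditions) mediated by
an inhibitory interneuron population that is represented only through
this algebraic rate modification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FiberClass",
    "Condition",
    "FiberClassConfig",
    "DiurnalParams",
    "SecondaryPulse",
    "StimulusProtocol",
    "SpikeRaster",
    "RateTrace",
    "default_fiber_configs",
    "diurnal_rate_abeta",
    "diurnal_rate_c",
    "effective_c_rate",
    "stimulus_rate",
    "sample_conduction_latencies",
    "generate_spike_trains",
    "smooth_population_rate",
    "rate_traces_from_raster",
    "expected_rate_traces",
    "BIN_WIDTH",
    "SMOOTH_WINDOW",
    "PATH_LENGTH",
]

logger = logging.getLogger(__name__)

#: Width of the spike-count bin used for instantaneous rates (s).
BIN_WIDTH = 0.001
#: Length of the moving-average smoothing window (s).
SMOOTH_WINDOW = 0.010
#: Nominal conduction path length from periphery to dorsal horn (m).
PATH_LENGTH = 0.11


class FiberClass(str, Enum):
    ABETA = "abeta"
    ADELTA = "adelta"
    C = "c"


class Condition(str, Enum):
    NORMAL = "normal"
    NEUROPATHIC = "neuropathic"


@dataclass(frozen=True)
class FiberClassConfig:
    """Static description of one afferent fiber class."""

    class_name: FiberClass
    n_fibers: int
    baseline_rate: float  # Hz per fiber, spontaneous
    stim_rate: float  # Hz per fiber during the response window (pre-modulation)
    stim_duration: float  # s
    velocity_range: tuple[float, float]  # m/s

    def __post_init__(self) -> None:
        if self.n_fibers <= 0:
            raise ValueError("n_fibers must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be nonnegative")
        if self.stim_rate < self.baseline_rate:
            raise ValueError("stim_rate must be >= baseline_rate")
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be positive")
        vmin, vmax = self.velocity_range
        if not (0 < vmin <= vmax):
            raise ValueError("velocity_range must satisfy 0 < v_min <= v_max")


def default_fiber_configs() -> dict[FiberClass, FiberClassConfig]:
    """The standard 1000-fiber afferent population.

    82% C fibers, 9% Aδ, 9% Aβ; 1 Hz spontaneous activity everywhere;
    stimulus-response rates 40/20/20 Hz with 10-ms windows for the A
    classes and a 210-ms window for C fibers.
    """
    return {
        FiberClass.ABETA: FiberClassConfig(
            FiberClass.ABETA, 90, 1.0, 40.0, 0.010, (30.0, 70.0)
        ),
        FiberClass.ADELTA: FiberClassConfig(
            FiberClass.ADELTA, 90, 1.0, 20.0, 0.010, (5.0, 30.0)
        ),
        FiberClass.C: FiberClassConfig(
            FiberClass.C, 820, 1.0, 20.0, 0.210, (0.5, 2.0)
        ),
    }


@dataclass(frozen=True)
class DiurnalParams:
    """Parameters of the daily modulation of stimulus-response rates.

    The Aβ rate follows ``mean_abeta + amp_abeta*sin(pi*t_hat/12)`` and
    the C rate ``mean_c + amp_c*sin(pi*t_hat/12 + phase_c)`` where
    ``t_hat`` is hours since habitual morning wake time.  ``g_abeta_c``
    scales presynaptic inhibition of the C response under normal
    conditions, ``g_abeta_c_neuro`` presynaptic excitation under
    neuropathic conditions; both act on the Aβ rate in excess of
    ``i2_offset``, the (lower) firing level of the mediating
    interneuron population.
    """

    mean_abeta: float = 40.0  # Hz
    amp_abeta: float = 6.0  # Hz
    mean_c: float = 21.0  # Hz
    amp_c: float = 0.5  # Hz
    phase_c: float = 2.8  # rad
    period: float = 24.0  # h
    g_abeta_c: float = 0.05
    g_abeta_c_neuro: float = 0.25
    i2_offset: float = 30.0  # Hz

    def __post_init__(self) -> None:
        if self.period != 24.0:
            raise ValueError("period must be 24 hours")
        if self.amp_abeta < 0 or self.amp_c < 0:
            raise ValueError("modulation amplitudes must be nonnegative")
        if self.g_abeta_c < 0 or self.g_abeta_c_neuro < 0:
            raise ValueError("presynaptic weights must be nonnegative")

    def with_neuro_coupling(self, g: float) -> "DiurnalParams":
        return replace(self, g_abeta_c_neuro=g)


@dataclass(frozen=True)
class SecondaryPulse:
    """A second brief Aβ-only stimulation (the 'rub the toe' pulse)."""

    onset: float  # s, absolute time
    duration: float = 0.010  # s
    rate: Optional[float] = None  # Hz; None -> diurnally modulated Aβ rate


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing and condition of a stimulation trial."""

    total_duration: float = 1.0  # s
    stimulus_onsets: tuple[float, ...] = (0.5,)  # s
    time_of_day: float = 8.0  # t_hat, hours since wake
    condition: Condition = Condition.NORMAL
    secondary_abeta_pulse: Optional[SecondaryPulse] = None

    def __post_init__(self) -> None:
        onsets = tuple(self.stimulus_onsets)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] > self.total_duration):
            raise ValueError("stimulus onsets must lie within [0, total_duration]")
        if not 0.0 <= self.time_of_day <= 24.0:
            raise ValueError("time_of_day must be within [0, 24] hours")

    @property
    def n_bins(self) -> int:
        return int(round(self.total_duration / BIN_WIDTH))


@dataclass
class SpikeRaster:
    """Per-fiber spike times with fiber class labels."""

    events: pd.DataFrame  # columns: class_name, fiber_id, spike_time
    total_duration: float

    COLUMNS = ("class_name", "fiber_id", "spike_time")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.events.columns)
        if missing:
            raise ValueError(f"raster frame missing columns {sorted(missing)}")

    def for_class(self, class_name: FiberClass | str) -> pd.DataFrame:
        key = class_name.value if isinstance(class_name, FiberClass) else str(class_name)
        return self.events[self.events["class_name"] == key]

    def counts(self, class_name: FiberClass | str, n_bins: int) -> np.ndarray:
        """Spike counts per 1-ms bin, summed over fibers of one class."""
        t = self.for_class(class_name)["spike_time"].to_numpy()
        edges = np.arange(n_bins + 1) * BIN_WIDTH
        counts, _ = np.histogram(t, bins=edges)
        return counts

    def to_csv(self, path, seed: Optional[int] = None) -> None:
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            self.events.to_csv(fh, index=False)


@dataclass
class RateTrace:
    """Smoothed average per-fiber firing rates on a uniform 1-ms grid."""

    time_grid: np.ndarray  # s
    rates: dict[FiberClass, np.ndarray]  # Hz, average per fiber

    def __post_init__(self) -> None:
        dt = np.diff(self.time_grid)
        if dt.size and not np.allclose(dt, BIN_WIDTH):
            raise ValueError("time grid must have exact 1-ms spacing")
        for cls, r in self.rates.items():
            if len(r) != len(self.time_grid):
                raise ValueError(f"rate trace for {cls} has wrong length")
            if np.any(r < 0):
                raise ValueError(f"negative rate in trace for {cls}")

    def as_array(self) -> np.ndarray:
        """Inputs stacked as (n_bins, 3) in the order (Aβ, Aδ, C)."""
        return np.column_stack(
            [
                self.rates[FiberClass.ABETA],
                self.rates[FiberClass.ADELTA],
                self.rates[FiberClass.C],
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_grid,
                "f_abeta_hz": self.rates[FiberClass.ABETA],
                "f_adelta_hz": self.rates[FiberClass.ADELTA],
                "f_c_hz": self.rates[FiberClass.C],
            }
        )


# ---------------------------------------------------------------------------
# Diurnal stimulus-response rates
# ---------------------------------------------------------------------------

def _check_t_hat(t_hat: float) -> None:
    if not 0.0 <= t_hat <= 24.0:
        raise ValueError(f"time of day t_hat={t_hat} outside [0, 24] hours")


def diurnal_rate_abeta(t_hat: float, params: DiurnalParams) -> float:
    """Aβ stimulus-response rate (Hz) at ``t_hat`` hours after wake."""
    _check_t_hat(t_hat)
    return params.mean_abeta + params.amp_abeta * math.sin(math.pi * t_hat / 12.0)


def diurnal_rate_c(t_hat: float, params: DiurnalParams) -> float:
    """Raw C stimulus-response rate (Hz), in near-antiphase to Aβ."""
    _check_t_hat(t_hat)
    return params.mean_c + params.amp_c * math.sin(
        math.pi * t_hat / 12.0 + params.phase_c
    )


def effective_c_rate(
    t_hat: float, params: DiurnalParams, condition: Condition | str = Condition.NORMAL
) -> float:
    """Effective C stimulus-response rate including presynaptic modulation.

    Normal conditions subtract ``g_abeta_c * (R_abeta - i2_offset)``
    (presynaptic inhibition); neuropathic conditions add the analogous
    term scaled by ``g_abeta_c_neuro`` (inhibition turned excitation).
    """
    condition = Condition(condition)
    r_c = diurnal_rate_c(t_hat, params)
    drive = diurnal_rate_abeta(t_hat, params) - params.i2_offset
    if condition is Condition.NORMAL:
        r = r_c - params.g_abeta_c * drive
    else:
        r = r_c + params.g_abeta_c_neuro * drive
    if r <= 0:
        raise ValueError(
            f"effective C rate {r:.3f} Hz <= 0 at t_hat={t_hat}: invalid parameters"
        )
    return r


def stimulus_rate(
    class_name: FiberClass,
    t_hat: float,
    config: FiberClassConfig,
    diurnal: Optional[DiurnalParams],
    condition: Condition = Condition.NORMAL,
) -> float:
    """Stimulus-response rate of one class at one time of day.

    Only the Aβ and C classes are diurnally modulated; Aδ fibers respond
    at their fixed configured rate.  With ``diurnal=None`` all classes
    use their configured (unmodulated) rates.
    """
    if diurnal is None:
        return config.stim_rate
    if class_name is FiberClass.ABETA:
        return diurnal_rate_abeta(t_hat, diurnal)
    if class_name is FiberClass.C:
        return effective_c_rate(t_hat, diurnal, condition)
    return config.stim_rate


# ---------------------------------------------------------------------------
# Spike-train generation
# ---------------------------------------------------------------------------

def sample_conduction_latencies(
    config: FiberClassConfig,
    path_length: float = PATH_LENGTH,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Per-fiber conduction latencies (s) for one realization.

    Velocities are drawn uniformly within the class range; latency is
    ``path_length / v``.  The spread of latencies across a class
    disperses volley arrival times at the dorsal horn.
    """
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    rng = np.random.default_rng() if rng is None else rng
    vmin, vmax = config.velocity_range
    v = rng.uniform(vmin, vmax, size=config.n_fibers)
    return path_length / v


def _fiber_rate_matrix(
    config: FiberClassConfig,
    latencies: np.ndarray,
    onsets: Sequence[float],
    stim_rate: float,
    n_bins: int,
    extra_windows: Sequence[tuple[float, float, float]] = (),
) -> np.ndarray:
    """Per-fiber, per-bin firing rate (Hz), shape (n_fibers, n_bins).

    ``extra_windows`` are (onset, duration, rate) triples sharing the
    per-fiber latencies.  Overlapping elevated windows resolve to the
    maximum of the competing rates.
    """
    rates = np.full((config.n_fibers, n_bins), config.baseline_rate)
    bin_idx = np.arange(n_bins)
    windows = [(on, config.stim_duration, stim_rate) for on in onsets]
    windows += list(extra_windows)
    covered = np.zeros((config.n_fibers, n_bins), dtype=bool)
    overlap_logged = False
    for onset, duration, rate in windows:
        start = (onset + latencies) / BIN_WIDTH
        stop = (onset + latencies + duration) / BIN_WIDTH
        mask = (bin_idx[None, :] >= start[:, None]) & (bin_idx[None, :] < stop[:, None])
        if not overlap_logged and np.any(mask & covered):
            logger.info("overlapping elevated windows merged (max of rates)")
            overlap_logged = True
        np.maximum(rates, np.where(mask, rate, 0.0), out=rates)
        covered |= mask
    return rates


def generate_spike_trains(
    protocol: StimulusProtocol,
    fiber_configs: dict[FiberClass, FiberClassConfig],
    diurnal: Optional[DiurnalParams],
    rng: np.random.Generator,
    path_length: float = PATH_LENGTH,
) -> SpikeRaster:
    """Simulate Poisson spike trains on all afferent fibers.

    Each fiber fires as a Poisson process at its baseline rate, elevated
    to the (diurnally modulated, condition-dependent) stimulus-response
    rate during ``[onset + latency, onset + latency + stim_duration]``
    for each stimulus.  Spikes are generated by per-bin Bernoulli
    thinning on the 1-ms grid (rate * dt is well below 1 for all
    configured rates, so at most one spike per bin is adequate).
    """
    n_bins = protocol.n_bins
    frames = []
    for cls, config in fiber_configs.items():
        lat = sample_conduction_latencies(config, path_length, rng)
        rate = stimulus_rate(cls, protocol.time_of_day, config, diurnal, protocol.condition)
        extra: list[tuple[float, float, float]] = []
        if cls is FiberClass.ABETA and protocol.secondary_abeta_pulse is not None:
            pulse = protocol.secondary_abeta_pulse
            pulse_rate = pulse.rate if pulse.rate is not None else rate
            extra.append((pulse.onset, pulse.duration, pulse_rate))
        rate_matrix = _fiber_rate_matrix(
            config, lat, protocol.stimulus_onsets, rate, n_bins, extra
        )
        spikes = rng.random((config.n_fibers, n_bins)) < rate_matrix * BIN_WIDTH
        fiber_idx, bin_idx = np.nonzero(spikes)
        frames.append(
            pd.DataFrame(
                {
                    "class_name": cls.value,
                    "fiber_id": fiber_idx,
                    "spike_time": (bin_idx + 0.5) * BIN_WIDTH,
                }
            )
        )
    events = pd.concat(frames, ignore_index=True)
    return SpikeRaster(events=events, total_duration=protocol.total_duration)


# ---------------------------------------------------------------------------
# Population-rate smoothing
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, window_bins: int) -> np.ndarray:
    """Centered moving average with truncated, renormalized edges."""
    kernel = np.ones(window_bins)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def smooth_population_rate(
    raster: SpikeRaster,
    class_name: FiberClass | str,
    n_fibers: int,
    n_bins: Optional[int] = None,
) -> np.ndarray:
    """Smoothed average per-fiber firing rate (Hz) for one class.

    Counts spikes in 1-ms bins, converts to average per-fiber rate, and
    applies a 10-ms moving average.
    """
    if n_bins is None:
        n_bins = int(round(raster.total_duration / BIN_WIDTH))
    counts = raster.counts(class_name, n_bins)
    inst = counts / (n_fibers * BIN_WIDTH)
    window_bins = int(round(SMOOTH_WINDOW / BIN_WIDTH))
    return _moving_average(inst, window_bins)


def rate_traces_from_raster(
    raster: SpikeRaster, fiber_configs: dict[FiberClass, FiberClassConfig]
) -> RateTrace:
    """Smoothed rate traces for all three classes from one raster."""
    n_bins = int(round(raster.total_duration / BIN_WIDTH))
    time_grid = (np.arange(n_bins) + 0.5) * BIN_WIDTH
    rates = {
        cls: smooth_population_rate(raster, cls, cfg.n_fibers, n_bins)
        for cls, cfg in fiber_configs.items()
    }
    return RateTrace(time_grid=time_grid, rates=rates)


# ---------------------------------------------------------------------------
# Noise-free expected drive
# ---------------------------------------------------------------------------

def _latency_cdf(tau: np.ndarray, config: FiberClassConfig, path_length: float) -> np.ndarray:
    """P(latency <= tau) for latency = path_length / v, v ~ U(v_min, v_max)."""
    vmin, vmax = config.velocity_range
    with np.errstate(divide="ignore"):
        v_needed = np.where(tau > 0, path_length / np.maximum(tau, 1e-12), np.inf)
    return np.clip((vmax - v_needed) / (vmax - vmin), 0.0, 1.0)


def expected_rate_traces(
    protocol: StimulusProtocol,
    fiber_configs: dict[FiberClass, FiberClassConfig],
    diurnal: Optional[DiurnalParams],
    path_length: float = PATH_LENGTH,
) -> RateTrace:
    """Expectation of the smoothed rate traces over Poisson realizations.

    The expected per-fiber rate at time t is the baseline plus, for each
    stimulus, ``(stim_rate - baseline)`` times the probability that the
    fiber's response window covers t; that probability follows from the
    uniform-velocity latency distribution.  The same 10-ms moving
    average as the stochastic pipeline is applied.  Used for fast,
    deterministic calibration and parameter validation.
    """
    n_bins = protocol.n_bins
    time_grid = (np.arange(n_bins) + 0.5) * BIN_WIDTH
    rates = {}
    for cls, config in fiber_configs.items():
        rate = stimulus_rate(cls, protocol.time_of_day, config, diurnal, protocol.condition)
        trace = np.full(n_bins, config.baseline_rate)
        windows = [(on, config.stim_duration, rate) for on in protocol.stimulus_onsets]
        if cls is FiberClass.ABETA and protocol.secondary_abeta_pulse is not None:
            pulse = protocol.secondary_abeta_pulse
            pulse_rate = pulse.rate if pulse.rate is not None else rate
            windows.append((pulse.onset, pulse.duration, pulse_rate))
        # Group windows by rate: per fiber, windows of equal rate union
        # (coverage probability clipped at 1), mirroring the max-merge of
        # overlapping elevated windows in the stochastic generator.
        by_rate: dict[float, np.ndarray] = {}
        for onset, duration, r in windows:
            frac = _latency_cdf(time_grid - onset, config, path_length) - _latency_cdf(
                time_grid - onset - duration, config, path_length
            )
            by_rate[r] = by_rate.get(r, 0.0) + frac
        for r, frac in by_rate.items():
            trace = trace + (r - config.baseline_rate) * np.clip(frac, 0.0, 1.0)
        window_bins = int(round(SMOOTH_WINDOW / BIN_WIDTH))
        rates[cls] = _moving_average(trace, window_bins)
    return RateTrace(time_grid=time_grid, rates=rates)
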