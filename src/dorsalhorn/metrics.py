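"""Pain readouts computed from simulated projection-neuron activity.

The model's pain measure is the mean projection-neuron rate over the
*C-response window*, 90–300 ms after stimulus onset — the interval in
which the slowly conducting C volley drives the circuit.  A trace is
"painful" when the P rate exceeds 25 Hz; *pain latency* is the time from
stimulus onset to the first threshold crossing.  Daily profiles are
expressed as percent deviation from their daily mean, and inhibition
experiments as percent of an unperturbed baseline response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .afferents import BIN_WIDTH, FiberClass, SpikeRaster
from .circuit import SimulationResult

__all__ = [
    "CResponseWindow",
    "PainThreshold",
    "c_response_mean",
    "pain_latency",
    "percent_of_mean",
    "percent_of_baseline",
    "rate_to_raster",
]


@dataclass(frozen=True)
class CResponseWindow:
    """C-response averaging window, relative to stimulus onset (s)."""

    start_offset: float = 0.090
    end_offset: float = 0.300

    def __post_init__(self) -> None:
        if not 0 < self.start_offset < self.end_offset:
            raise ValueError("window must satisfy 0 < start_offset < end_offset")


@dataclass(frozen=True)
class PainThreshold:
    """P-population rate above which output is interpreted as painful."""

    threshold: float = 25.0  # Hz

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def _window_slice(sim: SimulationResult, start: float, end: float) -> slice:
    if start < sim.time[0] - 1e-12 or end > sim.time[-1] + 1e-12:
        raise ValueError(
            f"window [{start:.3f}, {end:.3f}] s exceeds simulation span "
            f"[{sim.time[0]:.3f}, {sim.time[-1]:.3f}] s"
        )
    i0 = int(np.ceil((start - sim.time[0]) / sim.dt - 1e-9))
    i1 = int(np.floor((end - sim.time[0]) / sim.dt + 1e-9))
    return slice(i0, i1 + 1)


def c_response_mean(
    sim: SimulationResult,
    stimulus_onset: float,
    window: CResponseWindow = CResponseWindow(),
) -> float:
    """Mean P rate (Hz) over the C-response window of one stimulus."""
    sl = _window_slice(
        sim, stimulus_onset + window.start_offset, stimulus_onset + window.end_offset
    )
    return float(np.mean(sim.f_p[sl]))


def pain_latency(
    sim: SimulationResult,
    stimulus_onset: float,
    threshold: PainThreshold = PainThreshold(),
) -> Optional[float]:
    """Time (s) from stimulus onset to the first P rate strictly above
    threshold, on the integration grid; ``None`` if never exceeded."""
    if stimulus_onset < sim.time[0] or stimulus_onset > sim.time[-1]:
        raise ValueError("stimulus onset outside simulation span")
    i0 = int(np.ceil((stimulus_onset - sim.time[0]) / sim.dt - 1e-9))
    above = sim.f_p[i0:] > threshold.threshold
    idx = np.argmax(above)
    if not above[idx]:
        return None
    return float(sim.time[i0 + idx] - stimulus_onset)


def percent_of_mean(values: Sequence[float]) -> np.ndarray:
    """Per-entry deviation from the sequence mean, in percent.

    The output always averages to zero; it is invariant under scalar
    rescaling of the inputs.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean <= 0:
        raise ValueError("mean of values must be positive")
    return 100.0 * (values - mean) / mean


def percent_of_baseline(value: float, baseline: float) -> float:
    """``100 * value / baseline``; the baseline must be positive."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * value / baseline


def rate_to_raster(
    sim: SimulationResult,
    n_neurons: int,
    rng: np.random.Generator,
    bin_width: float = BIN_WIDTH,
) -> SpikeRaster:
    """Spike raster of P neurons drawn from the simulated rate.

    Each neuron is an independent inhomogeneous Poisson process with
    intensity ``f_P(t)``: the trace is resampled onto ``bin_width`` bins
    and each (neuron, bin) emits a spike with probability
    ``f_P * bin_width``.
    """
    if n_neurons <= 0:
        raise ValueError("n_neurons must be positive")
    n_bins = int(np.floor((sim.time[-1] - sim.time[0]) / bin_width + 1e-9))
    per_bin = max(int(round(bin_width / sim.dt)), 1)
    rate = sim.f_p[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    p = rate * bin_width
    if np.any(p > 1.0):
        raise ValueError(
            "f_P * bin_width exceeds 1 somewhere; use a finer bin_width"
        )
    spikes = rng.random((n_neurons, n_bins)) < p[None, :]
    neuron_idx, bin_idx = np.nonzero(spikes)
    events = pd.DataFrame(
        {
            "class_name": "p",
            "fiber_id": neuron_idx,
            "spike_time": sim.time[0] + (bin_idx + 0.5) * bin_width,
        }
    )
    return SpikeRaster(events=events, total_duration=float(sim.time[-1]))
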