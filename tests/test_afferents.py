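"""Afferent input: diurnal rates, latencies, Poisson trains, smoothing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dorsalhorn import (
    Condition,
    DiurnalParams,
    FiberClass,
    FiberClassConfig,
    SecondaryPulse,
    StimulusProtocol,
    default_fiber_configs,
    diurnal_rate_abeta,
    diurnal_rate_c,
    effective_c_rate,
    expected_rate_traces,
    generate_spike_trains,
    rate_traces_from_raster,
    sample_conduction_latencies,
    smooth_population_rate,
)
from dorsalhorn.afferents import BIN_WIDTH, PATH_LENGTH


class TestDiurnalRates:
    @pytest.mark.parametrize(
        "t_hat, expected",
        [(0.0, 40.0), (6.0, 46.0), (18.0, 34.0), (12.0, 40.0), (24.0, 40.0)],
    )
    def test_abeta_sinusoid(self, diurnal, t_hat, expected):
        assert diurnal_rate_abeta(t_hat, diurnal) == pytest.approx(expected)

    def test_c_rate_at_wake(self, diurnal):
        # 21 + 0.5*sin(2.8)
        assert diurnal_rate_c(0.0, diurnal) == pytest.approx(
            21.0 + 0.5 * math.sin(2.8)
        )

    def test_c_rate_peak_near_19_3_h(self, diurnal):
        t_peak = (math.pi / 2 - 2.8 + 2 * math.pi) * 12 / math.pi
        assert t_peak == pytest.approx(19.30, abs=0.01)
        assert diurnal_rate_c(t_peak, diurnal) == pytest.approx(21.5)

    def test_zero_amplitude_is_constant(self):
        flat = DiurnalParams(amp_c=0.0)
        values = [diurnal_rate_c(t, flat) for t in np.linspace(0, 24, 49)]
        assert np.allclose(values, 21.0)

    def test_peak_to_trough_spans(self, diurnal):
        grid = np.linspace(0, 24, 2401)
        ab = np.array([diurnal_rate_abeta(t, diurnal) for t in grid])
        c = np.array([diurnal_rate_c(t, diurnal) for t in grid])
        assert ab.max() - ab.min() == pytest.approx(12.0, abs=1e-3)
        assert c.max() - c.min() == pytest.approx(1.0, abs=1e-4)

    def test_outside_day_rejected(self, diurnal):
        with pytest.raises(ValueError):
            diurnal_rate_abeta(25.0, diurnal)
        with pytest.raises(ValueError):
            diurnal_rate_c(-0.1, diurnal)


class TestEffectiveCRate:
    def test_values_at_t6(self, diurnal):
        assert effective_c_rate(6.0, diurnal, Condition.NORMAL) == pytest.approx(
            19.73, abs=0.01
        )
        assert effective_c_rate(6.0, diurnal, Condition.NEUROPATHIC) == pytest.approx(
            24.53, abs=0.01
        )

    def test_zero_coupling_recovers_raw_rate(self):
        d = DiurnalParams(g_abeta_c=0.0, g_abeta_c_neuro=0.0)
        for t in (0.0, 5.5, 13.0, 23.0):
            raw = diurnal_rate_c(t, d)
            assert effective_c_rate(t, d, Condition.NORMAL) == pytest.approx(raw)
            assert effective_c_rate(t, d, Condition.NEUROPATHIC) == pytest.approx(raw)

    @given(st.floats(0.0, 24.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inhibition_vs_excitation_ordering(self, t_hat):
        d = DiurnalParams()
        raw = diurnal_rate_c(t_hat, d)
        eff = effective_c_rate(t_hat, d, Condition.NORMAL)
        neuro = effective_c_rate(t_hat, d, Condition.NEUROPATHIC)
        if diurnal_rate_abeta(t_hat, d) > d.i2_offset:
            assert eff <= raw <= neuro
        else:
            assert neuro <= raw <= eff

    def test_negative_result_rejected(self):
        d = DiurnalParams(g_abeta_c=10.0)
        with pytest.raises(ValueError):
            effective_c_rate(6.0, d, Condition.NORMAL)


class TestLatencies:
    def test_degenerate_velocity_gives_constant_latency(self, rng):
        cfg = FiberClassConfig(FiberClass.C, 50, 1.0, 20.0, 0.21, (1.0, 1.0))
        lat = sample_conduction_latencies(cfg, 0.11, rng)
        assert np.allclose(lat, 0.11)

    def test_c_latency_bounds(self, fibers, rng):
        lat = sample_conduction_latencies(fibers[FiberClass.C], 0.11, rng)
        assert np.all(lat >= 0.055) and np.all(lat <= 0.22)

    def test_mean_c_latency_matches_uniform_velocity_integral(self, fibers):
        # E[L/v] with v ~ U(0.5, 2) = L * ln(4) / 1.5
        rng = np.random.default_rng(7)
        lats = np.concatenate(
            [sample_conduction_latencies(fibers[FiberClass.C], 0.11, rng)
             for _ in range(200)]
        )
        expected = 0.11 * math.log(4.0) / 1.5
        assert lats.mean() == pytest.approx(expected, rel=0.02)

    def test_class_latency_ordering(self, fibers, rng):
        means = {
            cls: sample_conduction_latencies(cfg, PATH_LENGTH, rng).mean()
            for cls, cfg in fibers.items()
        }
        assert means[FiberClass.C] > means[FiberClass.ADELTA] > means[FiberClass.ABETA]


class TestSpikeTrains:
    def test_baseline_only_count_is_poisson_mean(self, fibers, diurnal):
        protocol = StimulusProtocol(
            total_duration=1.0, stimulus_onsets=(), time_of_day=0.0
        )
        c_only = {FiberClass.C: fibers[FiberClass.C]}
        counts = []
        for s in range(30):
            rng = np.random.default_rng(s)
            raster = generate_spike_trains(protocol, c_only, diurnal, rng)
            counts.append(len(raster.events))
        # 820 fibers * 1 Hz * 1 s; mean of 30 realizations within 4 sigma
        assert abs(np.mean(counts) - 820) < 4 * math.sqrt(820 / 30)

    def test_stimulus_window_spike_budget(self, diurnal):
        # 90 fibers, one 10-ms window at 40 Hz -> ~36 extra spikes/trial
        cfg = {FiberClass.ABETA: FiberClassConfig(
            FiberClass.ABETA, 90, 0.0, 40.0, 0.010, (30.0, 70.0))}
        protocol = StimulusProtocol(
            total_duration=1.0, stimulus_onsets=(0.5,), time_of_day=0.0
        )
        totals = [
            len(generate_spike_trains(protocol, cfg, None, np.random.default_rng(s)).events)
            for s in range(60)
        ]
        assert np.mean(totals) == pytest.approx(36.0, abs=4 * math.sqrt(36 / 60))

    def test_per_fiber_counts_poisson_gof(self, diurnal):
        # chi-square goodness of fit of per-window counts at 20 Hz
        cfg = {FiberClass.C: FiberClassConfig(
            FiberClass.C, 1000, 20.0, 20.0, 0.21, (0.5, 2.0))}
        protocol = StimulusProtocol(
            total_duration=1.0, stimulus_onsets=(), time_of_day=0.0
        )
        raster = generate_spike_trains(protocol, cfg, diurnal, np.random.default_rng(3))
        counts = raster.events.groupby("fiber_id").size().reindex(
            range(1000), fill_value=0
        )
        # Bernoulli thinning at p = 0.02 per 1-ms bin: Binomial(1000, 0.02)
        kmax = 35
        observed = np.bincount(counts, minlength=kmax + 1)[: kmax + 1].astype(float)
        observed[kmax] += np.sum(counts > kmax)
        probs = stats.binom.pmf(np.arange(kmax + 1), 1000, 20.0 * BIN_WIDTH)
        probs[kmax] = 1 - probs[:kmax].sum()
        keep = probs * 1000 >= 5
        chisq = np.sum((observed[keep] - 1000 * probs[keep]) ** 2 / (1000 * probs[keep]))
        pval = stats.chi2.sf(chisq, keep.sum() - 1)
        assert pval > 0.01

    def test_class_arrival_ordering(self, fibers, diurnal):
        # zero baseline so the first spike after onset is stimulus-driven
        quiet = {
            cls: FiberClassConfig(cls, cfg.n_fibers, 0.0, cfg.stim_rate,
                                  cfg.stim_duration, cfg.velocity_range)
            for cls, cfg in fibers.items()
        }
        protocol = StimulusProtocol(total_duration=1.0, time_of_day=0.0)
        first = {cls: [] for cls in FiberClass}
        for s in range(10):
            raster = generate_spike_trains(
                protocol, quiet, diurnal, np.random.default_rng(100 + s)
            )
            for cls in FiberClass:
                t = raster.for_class(cls)["spike_time"]
                t = t[t >= 0.5]
                first[cls].append(t.min())
        assert (np.mean(first[FiberClass.C])
                > np.mean(first[FiberClass.ADELTA])
                > np.mean(first[FiberClass.ABETA]))

    def test_secondary_pulse_only_on_abeta(self, fibers, diurnal, rng):
        pulse = SecondaryPulse(onset=0.7)
        protocol = StimulusProtocol(
            total_duration=1.0, time_of_day=0.0, secondary_abeta_pulse=pulse
        )
        raster = generate_spike_trains(protocol, fibers, diurnal, rng)
        window = (0.7, 0.72)
        ab = raster.for_class(FiberClass.ABETA)["spike_time"].between(*window).sum()
        ad = raster.for_class(FiberClass.ADELTA)["spike_time"].between(*window).sum()
        # ~90*40Hz*10ms = 36 Abeta spikes vs ~2 baseline Adelta spikes
        assert ab > 15
        assert ad < 10

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            StimulusProtocol(stimulus_onsets=(0.5, 0.4))
        with pytest.raises(ValueError):
            StimulusProtocol(time_of_day=30.0)


class TestSmoothing:
    def test_empty_raster_gives_zero_trace(self, fibers):
        protocol = StimulusProtocol(total_duration=0.2, stimulus_onsets=())
        cfg = {FiberClass.C: FiberClassConfig(
            FiberClass.C, 820, 0.0, 1.0, 0.21, (0.5, 2.0))}
        raster = generate_spike_trains(protocol, cfg, None, np.random.default_rng(0))
        trace = smooth_population_rate(raster, FiberClass.C, 820, 200)
        assert np.all(trace == 0.0)

    def test_homogeneous_rate_recovered(self):
        cfg = {FiberClass.ABETA: FiberClassConfig(
            FiberClass.ABETA, 90, 20.0, 20.0, 0.01, (30.0, 70.0))}
        protocol = StimulusProtocol(total_duration=1.0, stimulus_onsets=())
        means = [
            smooth_population_rate(
                generate_spike_trains(protocol, cfg, None, np.random.default_rng(s)),
                FiberClass.ABETA, 90, 1000,
            ).mean()
            for s in range(20)
        ]
        assert np.mean(means) == pytest.approx(20.0, abs=1.0)

    def test_smoothing_conserves_total_count(self, fibers, diurnal, rng):
        protocol = StimulusProtocol(total_duration=1.0, time_of_day=0.0)
        raster = generate_spike_trains(protocol, fibers, diurnal, rng)
        n_c = fibers[FiberClass.C].n_fibers
        trace = smooth_population_rate(raster, FiberClass.C, n_c, 1000)
        total_from_trace = trace.sum() * BIN_WIDTH * n_c
        n_spikes = len(raster.for_class(FiberClass.C))
        # renormalized edges preserve the sum exactly for interior mass;
        # allow a small edge effect
        assert total_from_trace == pytest.approx(n_spikes, rel=0.02)

    def test_expected_traces_match_monte_carlo(self, fibers, diurnal):
        protocol = StimulusProtocol(total_duration=1.0, time_of_day=8.0)
        expected = expected_rate_traces(protocol, fibers, diurnal)
        acc = None
        n = 40
        for s in range(n):
            raster = generate_spike_trains(
                protocol, fibers, diurnal, np.random.default_rng(s)
            )
            arr = rate_traces_from_raster(raster, fibers).as_array()
            acc = arr if acc is None else acc + arr
        mc = acc / n
        exp = expected.as_array()
        # C-fiber trace: Monte-Carlo mean tracks the analytic expectation
        assert np.max(np.abs(mc[:, 2] - exp[:, 2])) < 1.5
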