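# Methods

## Model

`dorsalhorn` simulates first-stage nociceptive processing in the spinal
dorsal horn as a firing-rate network of three neuronal populations —
projection neurons (P), excitatory interneurons (E), and inhibitory
interneurons (I) — wired according to the gate-control architecture:

```
dfP/dt = [ P∞( g_AβP·fAβ + g_AδP·fAδ + (g_CP + g_NMDA)·fC
             + g_EP·fE − g_IP·fI ) − fP ] / τP
dfE/dt = [ E∞( g_CE·fC − g_IE·fI ) − fE ] / τE
dfI/dt = [ I∞( g_AβI·fAβ ) − fI ] / τI
dg_NMDA/dt = [ M∞( fP ) − g_NMDA ] / τNMDA
```

Each response function is a sigmoid `X∞(x) = max_X/2·[1 + tanh((x −
β_X)/α_X)]`: `max_X` is the population's maximum rate (or maximum
synaptic weight for M), `β_X` the half-activation input, `1/α_X` the
transition slope.  Rates relax toward the sigmoid of the instantaneous
synaptic drive with intrinsic time constants τP = 1 ms, τE = 10 ms,
τI = 20 ms.  The C→P synapse carries, on top of the static weight
`g_CP`, a slow activity-dependent NMDA component `g_NMDA` relaxing at
τNMDA = 1 s toward a sigmoid of the P rate itself — a rate-level
abstraction of voltage-dependent Mg²⁺-block relief.  Because this
component outlives a single response by an order of magnitude, repeated
C-volleys at ~1–3 Hz accumulate synaptic gain and the P response grows
across the train (wind-up); at 0.5 Hz the weight decays back between
stimuli and the response stays flat.

The output quantity is the P-population rate; sustained P activity above
25 Hz is read as painful.  The *C-response mean* — the average P rate
over 90–300 ms after stimulus onset, when the slow C volley drives the
circuit — is the scalar pain measure, and *pain latency* is the time
from onset to the first crossing of the 25-Hz threshold.

## Afferent input

Input arrives on 1000 model fibers: 90 Aβ (conduction velocity uniform
in 30–70 m/s, 10-ms response), 90 Aδ (5–30 m/s, 10 ms), 820 C (0.5–2
m/s, 210 ms).  Each fiber is a Poisson process: 1 Hz spontaneous
baseline, elevated to the class stimulus-response rate (40/20/20 Hz
before modulation) during its response window, which starts one
conduction latency `L/v` after stimulus onset with a nominal path
length L = 0.11 m.  This yields mean class latencies of ~2 ms (Aβ),
~8 ms (Aδ), and ~100 ms (C), so the C volley occupies the 90–300 ms
readout window.  Spikes are drawn by per-bin Bernoulli thinning on a
1-ms grid (rate·Δt ≤ 0.05 everywhere, so the single-spike-per-bin
approximation is accurate to a few percent at most).  Population input
traces are spike counts per 1-ms bin, normalized to average per-fiber
Hz, smoothed by a centered 10-bin moving average with truncated,
renormalized edges.

`expected_rate_traces` provides the noise-free expectation of these
traces in closed form (latency-distribution coverage probabilities
convolved with the same smoothing kernel); it backs the deterministic
parameter validation and the calibration procedure, and is verified
against the Monte-Carlo mean in the test suite.

## Diurnal modulation

Stimulus-response rates (not the 1-Hz baseline, which represents
stimulus-independent spontaneous activity) vary with time of day
`t̂ ∈ [0, 24]` hours since habitual wake:

```
R_Aβ(t̂) = 40 + 6·sin(π t̂/12)          Hz
R_C(t̂)  = 21 + 0.5·sin(π t̂/12 + 2.8)  Hz
```

Aβ sensitivity peaks mid-afternoon, C sensitivity near t̂ ≈ 19.3 h, in
near-antiphase.  An implicit inhibitory interneuron population mediates
Aβ-dependent presynaptic modulation of C signaling; it is never a state
variable, only the algebraic correction

```
R_C^eff(t̂)       = R_C(t̂) − 0.05·(R_Aβ(t̂) − 30)      (normal)
R_C^eff,neuro(t̂) = R_C(t̂) + 0.25·(R_Aβ(t̂) − 30)      (neuropathic)
```

where 30 Hz is the lower firing level of the mediating population.
Under neuropathic conditions chloride dysregulation converts the
presynaptic inhibition into excitation with a larger coupling; the
effective C rhythm then tracks the Aβ rhythm, inverting the daily
pain-sensitivity profile by ~12 h and raising its mean.  Because the
diurnal time scale (hours) is six orders of magnitude slower than the
circuit (ms), `t̂` is held constant within a trial.

Aδ fibers are not modulated.  The Aδ rate stays at 20 Hz at all t̂.

## Experiments

All drivers average over seeded Poisson realizations, with every stream
derived from one master seed via `numpy.random.SeedSequence` spawning.

* **Daily rhythm** — single-stimulus trials (onset 0.5 s, 1-s span) at 7
  time points t̂ ∈ {0, 4, 8, 12, 16, 20, 24} h, 30 realizations each;
  per-time-point C-response means are expressed as percent of their
  daily mean.  The endpoints 0 and 24 h are both kept (they coincide for
  the sinusoids) to mirror a full-day axis.
* **Wind-up** — trains of 5 identical stimuli at 0.5–3.22 Hz, 20
  realizations; per-index C-response means and latencies are computed on
  the realization-mean trace.  3.22 Hz = 1/(0.300 + 0.010) s is the
  highest frequency at which consecutive P responses, including the
  10-ms smoothing tail, do not overlap.  Wind-up trials default to
  t̂ = 8 h — the sampled trough of the daily rhythm — so the
  first-stimulus response sits at the pain threshold; the daily trough
  and the first-stimulus anchor are then the same operating point, which
  ties the two calibration constraints together (see below).
* **Pain inhibition** — a single nociceptive stimulus plus a second,
  Aβ-only 10-ms pulse delayed by 0–0.40 s in 50-ms steps, at each of the
  7 time points.  Each response is reported as percent of the
  longest-delay (0.40 s) trial at the same time of day, in which the
  pulse arrives after the C-response window and is therefore a
  self-baseline.  Spike seeds are shared across delays at one time of
  day so the delay effect is not confounded by input noise.
* **Neuropathy** — the daily-rhythm experiment under both conditions
  with identical spike seeds, so profile differences are attributable to
  the presynaptic sign switch alone; plus a sweep over the neuropathic
  coupling strength.

## Calibration of the default circuit parameters

The response-function parameters and synaptic weights are not taken from
a published table; they are reconstructed by `scripts/calibrate.py`: a
coarse grid plus Nelder–Mead on noise-free expected-input responses,
followed by a short seeded Nelder–Mead *stochastic polish* through the
full Poisson pipeline and a final full-scale comparison of nearby
candidates.  The stochastic stage is essential: input noise rectifies
through the convex lower branch of the NMDA activation sigmoid, so a
noise-free calibration systematically understates NMDA recruitment and
overshoots wind-up when the Poisson input is switched on.  The anchors
targeted are:

* first/fifth C-response means of the 2-Hz train ≈ 26.5/50 Hz (the
  first-stimulus target sits slightly above the nominal ~25 Hz anchor so
  that the daily minimum — the same trial — clears the 25-Hz pain
  threshold with margin);
* daily percent-of-mean amplitude ≈ 15% (normal) and ≈ 5%
  (neuropathic);
* soft constraints: monotone wind-up, neuropathic rates above normal
  ones, resting P rate below 5 Hz.

Structural choices fixed before optimization: max_I = 100 Hz exceeds
max_P = max_E = 60 Hz (interneurons of this class fire faster than
projection neurons); the I sigmoid (β_I = 15, α_I = 15, g_AβI = 1)
gives a nonzero resting rate (~13 Hz) under 1-Hz drive and a strong
phasic response to Aβ volleys — the gate; the E sigmoid (β_E = 15,
α_E = 10, g_CE = 1, g_IE = 0.5) makes E a C-driven amplifier that
inhibition can shut down; the direct A-fiber weights onto P (0.5 each)
are small enough that the brief Aβ/Aδ volley alone stays well below the
pain threshold, so pain latency always reflects the C response; the
E→P weight is fixed at 0.5 (left free, the optimizer disconnects the
relay entirely).  The optimizer tunes the P sigmoid (β_P, α_P) and the
NMDA activation (β_M, α_M, max_M).  `validate_params` re-checks all
qualitative constraints on any parameter set and is run on the shipped
defaults in the test suite.

## Numerics

* Fixed-step classical RK4 with dt = 0.1 ms (dt = τP/10), zero-order
  hold of the 1-ms input traces; step-halving changes the P trace by
  < 0.1 Hz, and trajectories are bit-identical across repeated runs.
  The calibration script uses dt = 0.2 ms for speed, which is inside
  the same refinement tolerance.
* Baseline steady state: I and E fixed points are closed-form under
  constant drive; the coupled (fP, g_NMDA) pair is solved by damped
  fixed-point iteration polished with `scipy.optimize.root`
  (residual < 1e-6 on the τ-scaled derivatives), with a burn-in
  integration fallback.  Simulations start from this state with
  g_NMDA = M∞(fP at rest).
* Pain latency uses strict inequality on the integration grid, no
  sub-step interpolation.
* The C-response window is anchored to stimulus onset, not to C-fiber
  arrival.
* Percent-of-mean requires a positive mean and raises otherwise;
  degenerate (empty or non-increasing) protocols are rejected at
  construction.

## What the generator does and does not emulate

The synthetic afferent input reproduces Poisson spiking statistics,
class-specific conduction-latency dispersion (uniform velocities, not an
empirical arrival-time distribution), response-window durations, and the
diurnal rate modulation.  It does not model stimulus-intensity coding,
fiber-to-fiber rate heterogeneity within a class, axonal propagation
beyond a scalar latency, refractoriness, or correlated (non-Poisson)
discharge.  Passing tests therefore show that the circuit processes
idealized afferent drive as designed, not that it reproduces any
particular empirical recording.

## Known limitations

* With uniform-velocity conduction latencies, the population C drive
  f_C(t) increases monotonically until ~220 ms after onset (every
  fiber's 210-ms response window is still active while later fibers keep
  arriving), so the P response is late-peaked within the 90–300 ms
  readout window for any circuit parameters.  The most effective delay
  for the secondary Aβ (pain-inhibiting) pulse is therefore ~0.15–0.20 s
  — at the late edge of the 0.05–0.15 s range reported for front-loaded
  empirical arrival-time distributions, which this generator does not
  reproduce.

* The daily rhythm enters only through afferent stimulus-response rates;
  top-down (brainstem/cortical) modulation and sleep-homeostatic effects
  are outside the model, and the neuropathic rhythm amplitude (~5%) is
  accordingly small.
* The calibrated defaults are one parameter set satisfying the
  documented constraints, not a unique fit; other sets can reproduce the
  same behaviors.
* Mechanical (non-noxious) stimulation and itch circuitry are not
  modeled; the 25-Hz pain threshold is a convention, not a measured
  psychophysical constant.
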