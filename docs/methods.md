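# Methods

`gammadbs` implements a model-based framework for predicting and detecting
1:2 (sub-harmonic) entrainment of cortical finely-tuned gamma (FTG)
rhythms by periodic deep brain stimulation (DBS). This note documents the
models, the numerical choices, and what the synthetic data do and do not
establish.

## The neural-mass model

Cortex is represented by a two-population Wilson-Cowan system: excitatory
activity `E` (the proxy for the recorded ECoG signal) and inhibitory
activity `I`, coupled through a logistic activation
`f(x) = 1/(1 + exp(-b (x - 1)))`:

    dE = (1/tau_E) [ -E + f(eta_E + w_EE E + w_IE I) ] dt + zeta dW_E
    dI = (1/tau_I) [ -I + f(eta_I + w_EI E) + A_stim(t) ] dt + zeta dW_I

Nine constants define one model: three couplings (`w_EE`, `w_IE` —
expected negative, `w_EI`), two constant inputs (`eta_E`, `eta_I`), two
time constants, the sigmoid steepness `b` and a shared noise standard
deviation `zeta` driving two independent Wiener processes. The noise is
essential: off-stimulation FTG appears as bursts, not a clean sinusoid,
and several good fits operate as noise-sustained quasi-cycles around a
focus rather than deterministic limit cycles.

Stimulation `A_stim(t)` is a periodic pulse train injected directly into
the bracket of the target population (the inhibitory one by default;
subcortical DBS is modelled as net-inhibitory on cortex, with the
excitatory target available as an option). Injecting outside the sigmoid
avoids saturating the pulse. The default pulse is a single-sample
positive step with no recharge; charge-balanced active-recharge and
passive (exponential) recharge waveforms are provided, with the recharge
tail rescaled so each pulse sums to zero exactly in discrete time.

### Integration

Fixed step `dt = 1e-4` s, Heun (predictor-corrector) drift with Maruyama
noise increments scaled by `sqrt(dt)`. A plain Euler drift was measured
to bias the natural frequency of ~75 Hz cycles by several Hz at this step
(the estimate moved by 3-5 Hz when the step was halved); with the Heun
drift the frequency estimate is unchanged under step halving for the
reference set. The step is part of the amplitude-unit definition — a
single-step pulse of amplitude `A` delivers the impulse `A dt / tau` to
its target — so `dt` is frozen rather than adaptive. Initial state is
(0.5, 0.5); analyses discard a 2 s burn-in (1 s for rotation numbers,
which follow a shorter per-cell simulation). Because `f` maps into
(0, 1), the noise-free flow leaves the unit square invariant; the
integrator inherits this to numerical precision and aborts with the step
index if the state ever becomes non-finite.

## Off-stimulation features and fitting

An epoch is fitting-eligible if gap-free and at least 30 s long. The
gamma peak is located in 60-90 Hz as the maximum of the Welch PSD (1 s
Hann windows, 50% overlap) divided by a robust (Huber-weighted) log-log
linear trend fitted over 30-110 Hz excluding ±5 Hz around the candidate;
a peak requires this prominence ratio to exceed 2. The signal is then
band-passed ±3 Hz around the peak (4th-order Butterworth, applied
forward-backward for zero phase) and normalised to unit variance — the
recorded gain makes all downstream features invariant to the recording's
overall scale, which is necessary because the model's activity units are
arbitrary relative to ECoG volts.

Three features summarise the rhythm:

1. PSD of the band-passed signal, restricted to peak ±10 Hz, z-scored;
2. PSD of its Hilbert envelope (2 s windows, 0-25 Hz), z-scored;
3. probability density of the envelope (50 bins up to the 99.9th
   percentile, normalised to integrate to 1 exactly).

Model traces are integrated at `dt`, down-sampled to 250 Hz by polyphase
anti-aliased decimation and passed through the same pipeline, then
interpolated onto the data grids before comparison.

Fitting uses three loops: (i) uniform random draws inside the bounds
(couplings ≤ 10 in magnitude with physiological signs, |eta| ≤ 5, time
constants 1-50 ms, b in 1-10, zeta in 0-0.2) are screened by a 4 s
simulation for a spectral peak in 70-80 Hz; (ii) each accepted draw seeds
a generalized pattern search (poll ± each coordinate, expand ×2 on
success, contract ×0.5 on failure, initial mesh 10% of each bound range,
stop below 1e-3 of range or on budget) minimising the equally weighted
mean-squared distance of the three features, with the simulation seed
frozen per run so the cost is deterministic; (iii) the best local minima
by single-run R² are re-simulated with fresh noise and ranked by the mean
R² across re-simulations, ties broken by cost. R² is computed as
`1 - SS_res/SS_tot` over the concatenation of the three features about
the concatenated data mean.

Desk-scale defaults are 100 screening draws, a 200-evaluation budget per
local search, a top-5 shortlist and 10 re-simulations of 30 s; the
full-scale workflow (thousands of local minima, top 20, 50 × 100 s) is
the same code with larger arguments. A fitted model's oscillation
frequency is reported as the spectral peak of its unstimulated output at
the fitted noise level, because quasi-cycle fits have no noise-free
oscillation to measure.

## Entrainment in the model: rotation numbers and Arnold tongues

Entrainment to a pulse train at frequency `fs` is quantified by the
rotation number `rho = (theta_N - theta_0) / (2 pi N)` — mean gamma
cycles per pulse — where `theta` is the unwrapped Hilbert phase of `E`
sampled at pulse onsets, `N = 50` pulses after a 1 s burn-in. A cell of
the (frequency, amplitude) grid is labelled 1:1, 1:2 or 1:3 when the mean
rho over repeats is within 0.01 of 1, 1/2 or 1/3 *and* the across-repeat
standard deviation is within the same tolerance (a grazing average must
not pass as stable locking). Charting uses 5 repeats (3 at desk scale)
of 50 cycles per cell; the per-cell peak power is the repeat-averaged
maximum Welch power of `E` in 0-200 Hz. The sine circle map
`theta_{n+1} = theta_n + 2 pi Omega - K sin(theta_n)` provides an
independent oracle for the rotation machinery in the tests.

Tongue metrics: the stem is the centroid frequency of labelled cells in
the lowest-amplitude row containing any (at zero amplitude rho crosses
`f0/fs = 1/2` exactly at `fs = 2 f0`, so the stem marks twice the natural
frequency); the top boundary is the greatest labelled amplitude; the
left-lean fraction is the share of labelled cells strictly below the stem
frequency.

## Entrainment in recordings: the ×3 slope baseline

Rotation numbers are not reliable in noisy recordings, so the data-side
detector is spectral: a trial at `fs` shows 1:2 entrainment when the
Welch PSD height at the half harmonic (maximum within ±1 Hz of `fs/2`)
strictly exceeds three times the local baseline. The baseline is the
mean log10 power over `[fs/2-10, fs/2-5]` and `[fs/2+5, fs/2+10]`,
interpolated linearly in log power between the band centres — the ±5 Hz
guard keeps both the entrained peak and any stimulation artefact out of
the estimate, and the log-domain interpolation is the natural choice for
1/f-like spectra. Raising the threshold can only remove detections
(monotone), and the verdict is invariant to overall PSD gain. Repeats at
one parameter pair aggregate as: entrained if any repeat is, flagged
intermittent when verdicts are mixed (a tongue-boundary signature).

## Model-data correspondence

Model amplitude is in arbitrary units; the data's is in mA. A single
linear scale (a.u. per mA) maps each data point onto the charted field by
nearest cell; the scale is chosen from 50 log-spaced candidates spanning
two decades around (field amplitude max / data amplitude max) to maximise
the Spearman correlation between the data's half-harmonic PSD heights and
the model's entrained peak powers at the mapped cells (points mapping
outside the model tongue carry the model's near-zero entrained power).
The data-side quantity is the half-harmonic height rather than the
40-120 Hz maximum because the latter is contaminated by the stimulation
artefact line whenever `fs ≤ 120` Hz.

Because the scale is optimised, significance uses a permutation scheme:
data powers are reshuffled across the tested stimulation parameters, the
scale re-optimised per shuffle, and shuffles whose optimal mapping covers
fewer than five model-entrained points are redrawn rather than counted.
The p-value is the one-sided upper tail of a normal fit to the permuted
maximised correlations (the scientific claim is a positive correlation).
On null data this procedure's type-I rate calibrates to the nominal 5%
within ±2% (checked over 200 synthetic repetitions).

The amplitude-scale statistics run against a finer-amplitude chart of the
tongue region (41 amplitude levels rather than 11): the nearest-cell
lookup makes the correlation piecewise constant in the scale, and coarse
amplitude cells create plateaus wider than one scale-grid step, which
would make the optimum's location meaningless at the grid's resolution.

## The reference model and synthetic data

Patient recordings are not publicly available, so the package carries a
frozen reference parameter set standing in for a fitted patient model:
`w_EE=1.8687, w_IE=-6.9828, w_EI=4.8714, eta_E=4.1264, eta_I=-2.5065,
tau_E=2.6351 ms, tau_I=15.974 ms, b=4.1452, zeta=0.08`. It was found
once by random screening inside the fitting bounds for a noise-free limit
cycle whose frequency (75.75 Hz) lies in the FTG band and is stable under
halving the integration step, then selected among candidates for the
tongue structure the framework is meant to exhibit: a 1:2 tongue stemming
at ~153 Hz (twice the natural frequency), left-leaning (~0.9 of labelled
cells below the stem), with a finite top boundary near 36 a.u. on the
default 0-120 a.u. grid, 1:1 locking above, and entrained power
decreasing along the tongue towards higher stimulation frequencies. At
`zeta = 0.08` the off-stimulation output is a narrowband 76 Hz rhythm
with a fluctuating envelope while 1:2 locking at 130 Hz remains stable
across repeats.

Synthetic off-stimulation epochs superpose a narrowband component on
`1/f^alpha` background noise (default `alpha = 2`, synthesised by
spectral shaping, flat below 1 Hz) at a prescribed spectral
signal-to-noise ratio (peak over background at the peak frequency,
default 10). The narrowband component is either the reference model's
down-sampled E-trace or a phenomenological surrogate: band-limited
Gaussian noise (default 75 ± 1.5 Hz) modulated by a positive envelope
driven by an Ornstein-Uhlenbeck process with a 0.3 s burst timescale.
On-stimulation trials (30 s at 250 Hz, the recording conditions of the
emulated device) plant a tone at `fs/2` whose height is 5-20× the local
baseline in proportion to the field's entrained power for in-tongue
points, plus a stimulation-artefact line at `fs` 20 dB above background
(included deliberately so the detector's guard bands are exercised);
ground-truth labels are returned alongside. Phantom PSDs are analytic
`1/f^alpha` curves with half-harmonic peaks planted at exactly 0.5, 2,
3.5 and 10 times the detector's own baseline, giving the detector suite
exact expected labels including the strict >3 boundary.

What the synthetic data do not emulate: true patient burst statistics
(the OU envelope is a stand-in), non-stationary medication effects,
device packet-loss patterns beyond simple gap markers, or plasticity
under chronic stimulation. Passing tests therefore demonstrate that the
pipeline's inferences are correct when its modelling assumptions hold,
not that the Wilson-Cowan model is the right description of any given
patient.

## Problem sizes and reproducibility

Every stochastic component takes a seed, and identical seeds give
bitwise-identical results (the simulator's noise stream depends only on
the seed and trace length, so a zero-amplitude pulse train reproduces the
unstimulated trace exactly). Desk-scale defaults used throughout the
tests and the reproduction script: tongue charts over 40-200 Hz (2 Hz
step) × 11 amplitudes with 3 repeats of 50 cycles; the fine chart
100-160 Hz × 41 amplitudes; fitting with 100 screens / top 5 / 10
re-simulations; permutation calibration with 200 repetitions of 500
permutations. The full-scale settings reported in the module docstrings
(5 repeats, ~2500 local minima, top 20, 50 × 100 s re-simulations,
10,000 permutations) are reachable through the same interfaces.

## Known limitations

* Tongue boundaries are grid-resolved only; no continuation or
  bifurcation analysis, and locking ratios beyond {1:1, 1:2, 1:3} are
  not labelled.
* The amplitude mapping is a single linear scale with nearest-cell
  lookup; scale precision is bounded by the field's amplitude step.
* The ±3 Hz fitting band and the feature z-scoring conventions are
  reasonable defaults; other conventions would change cost values
  (though not the structure of the pipeline).
* The slope baseline inherits a small upward bias on steep spectra
  (~2-3% at `alpha = 2.5`) from averaging log power over
  linear-frequency side bands.
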