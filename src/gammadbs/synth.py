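"""Synthetic inputs for every stage of the pipeline.

Patient ECoG is not publicly available, so this module generates the
inputs the pipeline consumes:

* off-stimulation epochs — a narrowband, bursty 60-90 Hz gamma rhythm
  riding on a 1/f^alpha broadband background, either phenomenological
  (narrowband Gaussian process with an Ornstein-Uhlenbeck burst envelope)
  or produced by the packaged reference Wilson-Cowan model;
* on-stimulation trial grids with ground-truth 1:2 labels derived from a
  charted entrainment field (or a simple geometric tongue);
* analytic "phantom" PSDs with half-harmonic peaks planted at known
  multiples of the detector's baseline, for exact detector verification.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from gammadbs.detect import baseline_at_half
from gammadbs.features import RecordingEpoch, welch_psd
from gammadbs.model import DEFAULT_DT, WCParameters, simulate
from gammadbs.tongue import EntrainmentField

__all__ = [
    "SyntheticSpec",
    "reference_parameter_set",
    "REFERENCE_F0",
    "generate_off_stim",
    "generate_on_stim_grid",
    "generate_power_dataset",
    "generate_tongue_phantom",
]

# ---------------------------------------------------------------------------
# Reference model
# ---------------------------------------------------------------------------

#: Frozen reference Wilson-Cowan parameter set.  Found once by screening
#: random parameter sets for a noise-free limit cycle near 75 Hz and then
#: verifying by simulation that (i) the fitted noise level produces bursty
#: narrowband dynamics, and (ii) the charted 1:2 Arnold tongue stems from
#: twice the natural frequency, is left leaning and has a finite top
#: boundary.  Values are version-controlled constants; do not tune.
_REFERENCE = WCParameters(
    w_EE=1.8687, w_IE=-6.9828, w_EI=4.8714,
    eta_E=4.1264, eta_I=-2.5065,
    tau_E=0.0026351, tau_I=0.015974,
    b=4.1452, zeta=0.08,
)

#: Natural (noise-free) oscillation frequency of the reference set, Hz,
#: measured once from a 60 s noise-free simulation (stable under halving
#: the integration step).
REFERENCE_F0 = 75.75

#: Top of the default stimulation-amplitude grid (model a.u.) for charting
#: the reference model; the 1:2 tongue's top boundary sits well inside it.
REFERENCE_AMP_MAX = 120.0


def reference_parameter_set() -> tuple[WCParameters, float]:
    """The packaged reference model and its natural frequency (Hz)."""
    return _REFERENCE, REFERENCE_F0


# ---------------------------------------------------------------------------
# Off-stimulation epochs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic off-stimulation epoch."""

    ftg_frequency: float = 75.0    # Hz, must lie in the 60-90 Hz FTG band
    ftg_bandwidth: float = 3.0     # Hz (full width of the narrowband comp)
    burst_timescale: float = 0.3   # s, envelope autocorrelation time
    background_exponent: float = 2.0
    snr: float = 10.0              # FTG peak over background at the peak
    rate: float = 250.0            # Hz
    duration: float = 100.0        # s
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (60.0 <= self.ftg_frequency <= 90.0):
            raise ValueError("ftg_frequency must lie in 60-90 Hz")
        if self.rate / 2 <= self.ftg_frequency + 10:
            raise ValueError("rate too low for the requested FTG peak")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def _background(n: int, rate: float, alpha: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^alpha noise by spectral shaping (flat below 1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(f)
    nz = f >= 1.0
    shape[nz] = f[nz] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    return x / np.std(x)


def _ou(n: int, rate: float, timescale: float,
        rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance Ornstein-Uhlenbeck path (exact update)."""
    a = math.exp(-1.0 / (rate * timescale))
    b = math.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0]
    for k in range(1, n):
        x[k] = a * x[k - 1] + b * eps[k]
    return x


def _narrowband(spec: SyntheticSpec, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Bursty narrowband component: band-limited Gaussian carrier
    modulated by a positive OU-driven envelope."""
    lo = spec.ftg_frequency - spec.ftg_bandwidth / 2.0
    hi = spec.ftg_frequency + spec.ftg_bandwidth / 2.0
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=spec.rate,
                     output="sos")
    carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
    env = np.exp(0.5 * _ou(n, spec.rate, spec.burst_timescale, rng))
    x = carrier * env
    return x / np.std(x)


def _wilson_cowan_component(spec: SyntheticSpec, n: int,
                            seed: int) -> np.ndarray:
    from gammadbs.fitting import model_trace_to_epoch
    params, _ = reference_parameter_set()
    tr = simulate(params, None, dt=DEFAULT_DT,
                  duration=spec.duration + 2.0, seed=seed)
    ep = model_trace_to_epoch(tr.E, DEFAULT_DT, burn_in=2.0)
    x = ep.samples[:n]
    return x / np.std(x)


def generate_off_stim(spec: SyntheticSpec,
                      source: str = "phenomenological") -> RecordingEpoch:
    """One off-stimulation epoch with a planted FTG rhythm.

    ``source="phenomenological"`` uses the OU-burst narrowband process
    centred on ``spec.ftg_frequency``; ``source="wilson_cowan"`` uses the
    reference model's down-sampled E-trace.  Either component is scaled so
    its PSD peak sits ``spec.snr`` times above the 1/f^alpha background at
    the peak frequency.
    """
    if source not in ("phenomenological", "wilson_cowan"):
        raise ValueError("source must be phenomenological or wilson_cowan")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    bg = _background(n, spec.rate, spec.background_exponent, rng)
    if source == "phenomenological":
        nb = _narrowband(spec, n, rng)
    else:
        nb = _wilson_cowan_component(spec, n, int(rng.integers(2 ** 31)))
    f_bg, p_bg = welch_psd(bg, spec.rate)
    f_nb, p_nb = welch_psd(nb, spec.rate)
    kpk = int(np.argmax(np.where(
        (f_nb >= 60) & (f_nb <= 90), p_nb, 0.0)))
    c = math.sqrt(spec.snr * p_bg[kpk] / p_nb[kpk])
    x = bg + c * nb
    return RecordingEpoch(rate=spec.rate, samples=x, label=f"synthetic:{source}")


# ---------------------------------------------------------------------------
# On-stimulation trial grids
# ---------------------------------------------------------------------------

#: Hann-window equivalent noise bandwidth in bins (tone power <-> density).
_HANN_ENBW = 1.5
#: Scalloping compensation for tones between Welch bins.
_SCALLOP = 0.85


def _tone(n: int, rate: float, freq: float, amp: float,
          rng: np.random.Generator) -> np.ndarray:
    phase = rng.uniform(0, 2 * math.pi)
    t = np.arange(n) / rate
    return amp * np.sin(2 * math.pi * freq * t + phase)


def _tone_amp_for_density(target_density: float, rate: float,
                          window_length: float = 1.0) -> float:
    """Amplitude of a sine whose Welch-PSD peak is ``target_density``."""
    enbw_hz = _HANN_ENBW / window_length
    return math.sqrt(2.0 * target_density * enbw_hz) / _SCALLOP


def generate_on_stim_grid(spec: SyntheticSpec,
                          fs_list: Sequence[float],
                          amp_list: Sequence[float],
                          field_: EntrainmentField,
                          scale: float,
                          artefact: bool = True,
                          duration: float = 30.0,
                          seed: Optional[int] = None
                          ) -> tuple[list[RecordingEpoch], list[dict]]:
    """30 s on-stimulation trials over a (frequency, amplitude in mA) grid.

    A trial at ``(fs, A)`` maps into ``field_`` at the nearest cell
    ``(fs, scale * A)``.  Cells inside the 1:2 tongue receive a tone at
    ``fs/2`` whose planted PSD height is 5-20x the local baseline,
    proportional to the field's entrained peak power; every trial gets a
    stimulation-artefact line at ``fs`` (20 dB above background) when that
    frequency is resolvable.  Ground-truth labels are returned alongside.
    """
    if len(fs_list) == 0 or len(amp_list) == 0:
        raise ValueError("fs_list and amp_list must be nonempty")
    rng = np.random.default_rng(seed)
    n = int(round(duration * spec.rate))
    is12 = field_.locking == "1:2"
    pk = np.where(np.isfinite(field_.peak_psd), field_.peak_psd, 0.0)
    pmax = pk[is12].max() if np.any(is12) else 1.0

    epochs, labels = [], []
    for fs in fs_list:
        for amp in amp_list:
            bg = _background(n, spec.rate, spec.background_exponent, rng)
            fi = int(np.argmin(np.abs(field_.freq_grid - fs)))
            ai = int(np.argmin(np.abs(field_.amp_grid - scale * amp)))
            inside = bool(is12[ai, fi])
            rel = float(pk[ai, fi] / pmax) if inside else 0.0
            f_bg, p_bg = welch_psd(bg, spec.rate)
            x = bg.copy()
            if inside:
                base = baseline_at_half(f_bg, p_bg, fs)
                factor = 5.0 + 15.0 * rel
                a = _tone_amp_for_density(factor * base, spec.rate)
                x = x + _tone(n, spec.rate, fs / 2.0, a, rng)
            if artefact and fs < spec.rate / 2 - 1:
                s_art = float(np.interp(fs, f_bg, p_bg))
                x = x + _tone(n, spec.rate, fs,
                              _tone_amp_for_density(100.0 * s_art,
                                                    spec.rate), rng)
            epochs.append(RecordingEpoch(
                rate=spec.rate, samples=x, label="synthetic:onstim",
                stim_frequency=float(fs), stim_amplitude=float(amp)))
            labels.append({"fs_hz": float(fs), "amp_mA": float(amp),
                           "entrained_true": inside, "rel_power": rel})
    return epochs, labels


def generate_power_dataset(field_: EntrainmentField,
                           points: Sequence[tuple],
                           scale: float,
                           cv: float = 0.2,
                           seed: Optional[int] = None) -> list:
    """Entrainment calls whose powers come straight from the field.

    Each ``(fs, amp_mA)`` point is looked up at the nearest cell
    ``(fs, scale * amp_mA)``; points inside the 1:2 tongue become
    entrained calls with power equal to the cell's peak power times
    multiplicative lognormal noise of coefficient of variation ``cv``.
    Points outside become non-entrained calls.  This is the
    self-consistency construction for the amplitude-scale statistics.
    """
    from gammadbs.detect import EntrainmentCall
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    is12 = field_.locking == "1:2"
    pk = np.where(np.isfinite(field_.peak_psd), field_.peak_psd, 0.0)
    calls = []
    for fs, amp in points:
        fi = int(np.argmin(np.abs(field_.freq_grid - fs)))
        ai = int(np.argmin(np.abs(field_.amp_grid - scale * amp)))
        inside = bool(is12[ai, fi])
        base = pk[ai, fi] if inside else 1e-6 * pk.max()
        power = float(base * rng.lognormal(-0.5 * sigma * sigma, sigma))
        calls.append(EntrainmentCall(
            stim_frequency=float(fs), stim_amplitude=float(amp),
            entrained=inside, half_harmonic_power=power,
            baseline_power=power / 10.0, peak_power_40_120=power))
    return calls


# ---------------------------------------------------------------------------
# Phantom PSDs
# ---------------------------------------------------------------------------

#: Planted peak heights as multiples of the interpolated baseline.  The
#: strict "over three times" rule labels 3.5 and 10 entrained.
PHANTOM_FACTORS = (0.5, 2.0, 3.5, 10.0, None)


def generate_tongue_phantom(n_cases: int, seed: Optional[int] = None
                            ) -> list[dict]:
    """Analytic 1/f^alpha PSDs with exactly-known half-harmonic peaks.

    Each case carries ``freqs``, ``power``, the stimulation frequency
    ``fs``, the planted ``factor`` (None for no-peak controls) and the
    ground-truth ``entrained`` label (factor strictly over 3).  The peak
    occupies the single bin nearest ``fs/2``, so the +/-5 Hz guard bands
    are untouched and the detector's baseline equals the analytic one.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = np.arange(0.5, 125.5, 0.5)
    cases = []
    for i in range(n_cases):
        factor = PHANTOM_FACTORS[i % len(PHANTOM_FACTORS)]
        alpha = rng.uniform(1.0, 3.0)
        fs = rng.uniform(100.0, 180.0)
        power = freqs ** (-alpha)
        base = baseline_at_half(freqs, power, fs)
        if factor is not None:
            k = int(np.argmin(np.abs(freqs - fs / 2.0)))
            power = power.copy()
            power[k] = factor * base
        cases.append({"freqs": freqs, "power": power, "fs": fs,
                      "factor": factor,
                      "entrained": factor is not None and factor > 3.0})
    return cases
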