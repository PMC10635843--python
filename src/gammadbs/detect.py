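"""Detect 1:2 entrainment in on-stimulation recordings.

The rotation number cannot be computed reliably from noisy recordings, so
entrainment is called spectrally: a trial stimulated at ``fs`` Hz shows 1:2
entrainment when the PSD at the half harmonic ``fs/2`` is *over three
times* the local 1/f baseline.  The baseline is approximated from the
measured spectral slope by averaging log-power in the guard-banded ranges
``[fs/2-10, fs/2-5]`` and ``[fs/2+5, fs/2+10]`` and interpolating linearly
(in log power) between the two band centres.  The +/-5 Hz guard keeps the
entrained peak itself, and the stimulation artefact at ``fs``, out of the
baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

from gammadbs.features import RecordingEpoch, welch_psd

__all__ = [
    "EntrainmentCall",
    "baseline_at_half",
    "classify_psd",
    "detect_half_harmonic",
    "aggregate_calls",
    "power_trend",
    "calls_to_frame",
]

#: Entrainment threshold: half-harmonic power must be OVER this multiple of
#: the interpolated baseline (strict inequality).
THRESHOLD = 3.0
#: Peak-power search window in the data (Hz).
PEAK_WINDOW = (40.0, 120.0)
#: Half-width (Hz) around fs/2 in which the half-harmonic power is read.
HALF_TOL = 1.0


@dataclass
class EntrainmentCall:
    """Per-trial (or per-parameter-pair) 1:2 entrainment verdict."""

    stim_frequency: float
    stim_amplitude: float
    entrained: bool
    half_harmonic_power: float
    baseline_power: float
    peak_power_40_120: float
    repeats: int = 1
    intermittent: bool = False


def baseline_at_half(freqs: np.ndarray, power: np.ndarray,
                     fs: float) -> float:
    """Slope-approximated baseline power at ``fs/2``.

    Mean log10-power over ``[fs/2-10, fs/2-5]`` and ``[fs/2+5, fs/2+10]``,
    linearly interpolated between the band centres and returned on the
    power scale.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    half = fs / 2.0
    means = []
    for lo, hi in ((half - 10, half - 5), (half + 5, half + 10)):
        sel = (freqs >= lo) & (freqs <= hi)
        if not np.any(sel) or freqs[0] > lo or freqs[-1] < hi:
            raise ValueError(
                f"side band ({lo:.1f}, {hi:.1f}) Hz outside the PSD grid "
                f"({freqs[0]:.1f}, {freqs[-1]:.1f}) Hz")
        p = power[sel]
        if np.any(p <= 0):
            raise ValueError("PSD must be positive in the side bands")
        means.append(np.mean(np.log10(p)))
    # band centres are equidistant from fs/2, so the linear interpolation
    # evaluated at fs/2 is the midpoint of the two band means
    return float(10.0 ** (0.5 * (means[0] + means[1])))


def classify_psd(freqs: np.ndarray, power: np.ndarray, fs: float,
                 threshold: float = THRESHOLD) -> dict:
    """Apply the x3 rule to a ready-made PSD.

    Returns the half-harmonic power (max within +/-1 Hz of fs/2), the
    interpolated baseline, the 40-120 Hz peak power, and the verdict
    ``half > threshold * baseline`` (strict).
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    half = fs / 2.0
    base = baseline_at_half(freqs, power, fs)
    sel = np.abs(freqs - half) <= HALF_TOL
    if not np.any(sel):
        raise ValueError(f"no PSD bins within +/-{HALF_TOL} Hz of {half} Hz")
    half_power = float(np.max(power[sel]))
    win = (freqs >= PEAK_WINDOW[0]) & (freqs <= PEAK_WINDOW[1])
    return {
        "half_harmonic_power": half_power,
        "baseline_power": base,
        "peak_power_40_120": float(np.max(power[win])),
        "entrained": bool(half_power > threshold * base),
    }


def detect_half_harmonic(epoch: RecordingEpoch,
                         threshold: float = THRESHOLD) -> EntrainmentCall:
    """1:2 entrainment verdict for one on-stimulation trial.

    The epoch must carry its stimulation frequency and amplitude and hold
    at least 10 s of data (trials are nominally 30 s).
    """
    if epoch.stim_frequency is None or epoch.stim_amplitude is None:
        raise ValueError("epoch lacks stimulation frequency/amplitude")
    if epoch.duration < 10.0:
        raise ValueError(
            f"trial of {epoch.duration:.1f} s is too short (need >= 10 s)")
    freqs, power = welch_psd(epoch.samples - np.mean(epoch.samples),
                             epoch.rate)
    res = classify_psd(freqs, power, epoch.stim_frequency, threshold)
    return EntrainmentCall(stim_frequency=epoch.stim_frequency,
                           stim_amplitude=epoch.stim_amplitude,
                           entrained=res["entrained"],
                           half_harmonic_power=res["half_harmonic_power"],
                           baseline_power=res["baseline_power"],
                           peak_power_40_120=res["peak_power_40_120"])


def aggregate_calls(trials: Sequence[EntrainmentCall]
                    ) -> list[EntrainmentCall]:
    """Collapse repeated trials of the same (fs, amplitude) pair.

    A pair is entrained if any repeat is; mixed verdicts are flagged
    intermittent (a tongue-boundary signature).  Powers are averaged over
    the entrained repeats when any exist, else over all repeats.
    """
    groups: dict[tuple, list[EntrainmentCall]] = {}
    for t in trials:
        groups.setdefault((t.stim_frequency, t.stim_amplitude),
                          []).append(t)
    out = []
    for (fs, amp), g in sorted(groups.items()):
        verdicts = [t.entrained for t in g]
        ent = any(verdicts)
        pool = [t for t in g if t.entrained] if ent else list(g)
        out.append(EntrainmentCall(
            stim_frequency=fs, stim_amplitude=amp, entrained=ent,
            half_harmonic_power=float(np.mean(
                [t.half_harmonic_power for t in pool])),
            baseline_power=float(np.mean([t.baseline_power for t in pool])),
            peak_power_40_120=float(np.mean(
                [t.peak_power_40_120 for t in pool])),
            repeats=len(g),
            intermittent=ent and not all(verdicts)))
    return out


def power_trend(calls: Sequence[EntrainmentCall],
                predictor: str = "frequency") -> dict:
    """Spearman correlation and single-predictor regression of entrained
    peak power against stimulation frequency or amplitude.

    Only entrained calls are used; fewer than 5 is an error.  Tied powers
    use average ranks (rho = 0 for constant powers).
    """
    if predictor not in ("frequency", "amplitude"):
        raise ValueError("predictor must be 'frequency' or 'amplitude'")
    ent = [c for c in calls if c.entrained]
    if len(ent) < 5:
        raise ValueError(
            f"need >= 5 entrained calls for a trend, got {len(ent)}")
    x = np.array([c.stim_frequency if predictor == "frequency"
                  else c.stim_amplitude for c in ent])
    y = np.array([c.peak_power_40_120 for c in ent])
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        rho, pval = 0.0, 1.0
    else:
        rho, pval = sstats.spearmanr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {"spearman_rho": float(rho), "p_value": float(pval),
            "slope": float(slope), "intercept": float(intercept),
            "n": len(ent)}


def calls_to_frame(calls: Sequence[EntrainmentCall]):
    """Calls as a pandas DataFrame (the CSV output dialect)."""
    import pandas as pd
    return pd.DataFrame([{
        "fs_hz": c.stim_frequency, "amp_mA": c.stim_amplitude,
        "entrained": c.entrained, "intermittent": c.intermittent,
        "half_power": c.half_harmonic_power,
        "baseline": c.baseline_power,
        "peak_power": c.peak_power_40_120,
        "repeats": c.repeats} for c in calls])
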