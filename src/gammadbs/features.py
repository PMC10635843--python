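"""Spectral and envelope features of an off-stimulation recording epoch.

A narrowband finely-tuned gamma (FTG) rhythm is summarised by three
features, computed after band-passing +/-3 Hz around the gamma peak:

* the Welch PSD of the band-passed signal,
* the Welch PSD of its Hilbert envelope (burst dynamics in frequency),
* the probability density of the envelope values (burst statistics in time).

The band-passed signal is normalised to unit variance before the envelope
is computed and the two PSDs are z-scored across their frequency grids, so
the whole feature set is invariant to the overall gain of the recording;
the gain and z-score parameters are retained so model output can be placed
on the identical scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "RecordingEpoch",
    "FeatureSet",
    "PeakResult",
    "NoPeakError",
    "segment_epochs",
    "find_gamma_peak",
    "select_epoch",
    "bandpass",
    "hilbert_envelope",
    "welch_psd",
    "envelope_pdf",
    "extract_features",
]

#: FTG search band (Hz): narrowband gamma peaks live between 60 and 90 Hz.
GAMMA_BAND = (60.0, 90.0)
#: Half-width of the fitting band around the gamma peak (Hz).
BAND_HALFWIDTH = 3.0
#: Minimum epoch length eligible for fitting (s).
MIN_EPOCH_S = 30.0
#: Peak acceptance threshold: PSD must exceed the 1/f trend by this factor.
PROMINENCE_THRESHOLD = 2.0


class NoPeakError(ValueError):
    """No qualifying gamma peak in the searched band."""


@dataclass
class RecordingEpoch:
    """A gap-free stretch of an ECoG-like recording.

    ``stim_frequency``/``stim_amplitude`` are None for off-stimulation
    epochs; on-stimulation trials carry the delivered frequency (Hz) and
    amplitude (mA).
    """

    rate: float
    samples: np.ndarray
    label: str = ""
    stim_frequency: Optional[float] = None
    stim_amplitude: Optional[float] = None
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def to_csv(self, path) -> None:
        """CSV of (time_s, value) with a JSON sidecar for the metadata."""
        import pandas as pd
        path = Path(path)
        t = self.t_start + np.arange(len(self.samples)) / self.rate
        pd.DataFrame({"time_s": t, "value": self.samples}).to_csv(
            path, index=False)
        meta = {"rate": self.rate, "label": self.label,
                "stim_frequency": self.stim_frequency,
                "stim_amplitude": self.stim_amplitude,
                "t_start": self.t_start}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "RecordingEpoch":
        import pandas as pd
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(rate=meta["rate"], samples=df["value"].to_numpy(),
                   label=meta.get("label", ""),
                   stim_frequency=meta.get("stim_frequency"),
                   stim_amplitude=meta.get("stim_amplitude"),
                   t_start=meta.get("t_start", 0.0))


@dataclass
class PeakResult:
    frequency: Optional[float]
    prominence: float

    @property
    def found(self) -> bool:
        return self.frequency is not None


@dataclass
class FeatureSet:
    """The three z-scored fitting features plus their grids."""

    psd_freqs: np.ndarray          # Hz
    psd: np.ndarray                # z-scored power of band-passed signal
    env_psd_freqs: np.ndarray      # Hz
    env_psd: np.ndarray            # z-scored power of envelope
    env_pdf_bins: np.ndarray       # amplitude bin centres (unit-variance sig)
    env_pdf: np.ndarray            # density, integrates to 1
    peak_frequency: float          # Hz
    band: tuple                    # (low, high) Hz
    zscore_params: dict = field(default_factory=dict)

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.psd, self.env_psd, self.env_pdf])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "psd_freqs": self.psd_freqs.tolist(),
            "psd": self.psd.tolist(),
            "env_psd_freqs": self.env_psd_freqs.tolist(),
            "env_psd": self.env_psd.tolist(),
            "env_pdf_bins": self.env_pdf_bins.tolist(),
            "env_pdf": self.env_pdf.tolist(),
            "peak_frequency": self.peak_frequency,
            "band": list(self.band),
            "zscore_params": self.zscore_params}, indent=2))

    @classmethod
    def from_json(cls, path) -> "FeatureSet":
        d = json.loads(Path(path).read_text())
        return cls(psd_freqs=np.array(d["psd_freqs"]),
                   psd=np.array(d["psd"]),
                   env_psd_freqs=np.array(d["env_psd_freqs"]),
                   env_psd=np.array(d["env_psd"]),
                   env_pdf_bins=np.array(d["env_pdf_bins"]),
                   env_pdf=np.array(d["env_pdf"]),
                   peak_frequency=d["peak_frequency"],
                   band=tuple(d["band"]),
                   zscore_params=d.get("zscore_params", {}))


def segment_epochs(samples: Sequence[float], rate: float,
                   min_length: float = MIN_EPOCH_S,
                   t_start: float = 0.0,
                   label: str = "") -> list[RecordingEpoch]:
    """Split a streamed recording into maximal gap-free epochs.

    Gaps (streaming packet losses) are marked by NaNs in ``samples``.
    Only maximal runs of at least ``min_length`` seconds are returned.
    """
    x = np.asarray(samples, dtype=float)
    good = np.isfinite(x)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], good, [False]))
                                   .astype(int)))
    out = []
    for lo, hi in zip(edges[::2], edges[1::2]):
        if (hi - lo) / rate >= min_length:
            out.append(RecordingEpoch(rate=rate, samples=x[lo:hi],
                                      label=label,
                                      t_start=t_start + lo / rate))
    return out


def welch_psd(x: np.ndarray, rate: float, window_length: float = 1.0,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD, Hann windows, default 1 s / 50% overlap."""
    x = np.asarray(x, dtype=float)
    nper = int(round(window_length * rate))
    if nper > len(x):
        raise ValueError(
            f"signal ({len(x)/rate:.2f} s) shorter than window "
            f"({window_length} s)")
    return sps.welch(x, fs=rate, window="hann", nperseg=nper,
                     noverlap=int(round(nper * overlap)))


def _spectral_trend(freqs: np.ndarray, power: np.ndarray,
                    fit_band: tuple = (30.0, 110.0),
                    exclude: Optional[tuple] = None) -> np.ndarray:
    """Robust 1/f trend: linear fit of log power vs log frequency.

    Uses a least-absolute-deviation-flavoured iteratively reweighted fit so
    a strong narrowband peak does not drag the baseline up; ``exclude``
    masks a (lo, hi) Hz region out of the fit entirely.
    """
    m = (freqs >= fit_band[0]) & (freqs <= fit_band[1]) & (power > 0)
    if exclude is not None:
        m &= ~((freqs >= exclude[0]) & (freqs <= exclude[1]))
    lf = np.log10(freqs[m])
    lp = np.log10(power[m])
    w = np.ones_like(lf)
    coef = np.polyfit(lf, lp, 1)
    for _ in range(3):  # IRLS with Huber-like weights
        resid = lp - np.polyval(coef, lf)
        s = np.median(np.abs(resid)) * 1.4826 + 1e-30
        w = 1.0 / np.maximum(1.0, np.abs(resid) / (1.345 * s))
        coef = np.polyfit(lf, lp, 1, w=np.sqrt(w))
    with np.errstate(divide="ignore"):
        return 10.0 ** np.polyval(coef, np.log10(np.maximum(freqs, 1e-12)))


def find_gamma_peak(epoch: RecordingEpoch,
                    search_band: tuple = GAMMA_BAND,
                    threshold: float = PROMINENCE_THRESHOLD) -> PeakResult:
    """Locate the most prominent narrowband peak in ``search_band``.

    Prominence is the ratio of the Welch PSD to a robust log-log linear
    trend fitted over 30-110 Hz excluding +/-5 Hz around the candidate.
    A peak is reported only if that ratio exceeds ``threshold`` and the
    candidate is a local maximum; otherwise ``PeakResult(None, ratio)``.
    """
    lo, hi = search_band
    if not (0 < lo < hi < epoch.rate / 2):
        raise ValueError("search band must lie within (0, Nyquist)")
    freqs, power = welch_psd(epoch.samples - np.mean(epoch.samples),
                             epoch.rate)
    band = (freqs >= lo) & (freqs <= hi)
    # first pass: candidate from trend fitted without exclusion
    trend = _spectral_trend(freqs, power)
    ratio = np.where(band, power / np.maximum(trend, 1e-300), 0.0)
    cand = freqs[np.argmax(ratio)]
    # second pass: refit excluding the candidate's neighbourhood
    trend = _spectral_trend(freqs, power, exclude=(cand - 5, cand + 5))
    ratio = np.where(band, power / np.maximum(trend, 1e-300), 0.0)
    k = int(np.argmax(ratio))
    prom = float(ratio[k])
    # require a genuine local maximum of the raw PSD within the band
    kb = np.flatnonzero(band)
    is_local_max = (k == kb[0] or power[k] >= power[k - 1]) and \
                   (k == kb[-1] or power[k] >= power[k + 1])
    if prom <= threshold or not is_local_max:
        return PeakResult(None, prom)
    return PeakResult(float(freqs[k]), prom)


def select_epoch(epochs: Sequence[RecordingEpoch],
                 dataset_mean_peak: float,
                 search_band: tuple = GAMMA_BAND) -> RecordingEpoch:
    """The most prominent-peaked epoch within +/-3 Hz of the dataset mean.

    Ties in prominence break to the earlier ``t_start``.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    scored = []
    for ep in epochs:
        pk = find_gamma_peak(ep, search_band)
        if pk.found and abs(pk.frequency - dataset_mean_peak) <= BAND_HALFWIDTH:
            scored.append((ep, pk))
    if not scored:
        peaks = [find_gamma_peak(ep, search_band).frequency for ep in epochs]
        raise NoPeakError(
            f"no epoch peaks within +/-{BAND_HALFWIDTH} Hz of "
            f"{dataset_mean_peak} Hz; epoch peaks were {peaks}")
    scored.sort(key=lambda t: (-t[1].prominence, t[0].t_start))
    return scored[0][0]


def bandpass(x: np.ndarray, rate: float, centre: float,
             halfwidth: float = BAND_HALFWIDTH) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, centre +/- halfwidth."""
    lo, hi = centre - halfwidth, centre + halfwidth
    if lo <= 0 or hi >= rate / 2:
        raise ValueError(f"band ({lo}, {hi}) Hz outside (0, Nyquist)")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Modulus of the analytic signal (instantaneous amplitude)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    return np.abs(sps.hilbert(x))


def envelope_pdf(envelope: np.ndarray, n_bins: int = 50
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram density of envelope values, 50 bins up to the 99.9th
    percentile; normalised so bin_width * density sums to exactly 1."""
    env = np.asarray(envelope, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelope must be nonnegative")
    top = float(np.percentile(env, 99.9))
    if top <= 0:
        top = max(float(env.max()), 1e-12)
    edges = np.linspace(0.0, top, n_bins + 1)
    counts, _ = np.histogram(np.clip(env, 0, top), bins=edges)
    width = edges[1] - edges[0]
    dens = counts / (counts.sum() * width)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, dens


#: Width (Hz) of the signal-PSD feature grid around the gamma peak.
PSD_FEATURE_HALFWIDTH = 10.0
#: Upper edge (Hz) of the envelope-PSD feature grid.
ENV_PSD_FMAX = 25.0


def _zscore(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(np.mean(v))
    sd = float(np.std(v))
    if sd == 0:
        raise ValueError("cannot z-score a constant feature")
    return (v - mu) / sd, mu, sd


def extract_features(epoch: RecordingEpoch,
                     search_band: tuple = GAMMA_BAND,
                     centre: Optional[float] = None) -> FeatureSet:
    """Full feature pipeline for one epoch.

    find peak (60-90 Hz) -> band-pass +/-3 Hz -> normalise to unit
    variance -> {Welch PSD of the signal restricted to peak +/-10 Hz;
    Hilbert envelope -> Welch PSD (0-25 Hz) and PDF of the envelope}.
    Both PSDs are z-scored over their grids.  Pass ``centre`` to skip the
    peak search (used when placing model output on a data epoch's band).
    """
    if epoch.duration < MIN_EPOCH_S - 1e-9:
        raise ValueError(
            f"epoch of {epoch.duration:.1f} s is shorter than the "
            f"{MIN_EPOCH_S:.0f} s minimum")
    if centre is None:
        pk = find_gamma_peak(epoch, search_band)
        if not pk.found:
            raise NoPeakError(
                f"no gamma peak in {search_band} Hz "
                f"(best prominence {pk.prominence:.2f})")
        centre = pk.frequency
    x = bandpass(epoch.samples - np.mean(epoch.samples), epoch.rate, centre)
    gain = float(np.std(x))
    if gain == 0:
        raise ValueError("band-passed signal is identically zero")
    x = x / gain

    freqs, power = welch_psd(x, epoch.rate)
    sel = (freqs >= centre - PSD_FEATURE_HALFWIDTH) & \
          (freqs <= centre + PSD_FEATURE_HALFWIDTH)
    psd_z, p_mu, p_sd = _zscore(power[sel])

    env = hilbert_envelope(x)
    efreqs, epower = welch_psd(env - env.mean(), epoch.rate,
                               window_length=2.0)
    esel = efreqs <= ENV_PSD_FMAX
    env_z, e_mu, e_sd = _zscore(epower[esel])

    bins, dens = envelope_pdf(env)
    return FeatureSet(
        psd_freqs=freqs[sel], psd=psd_z,
        env_psd_freqs=efreqs[esel], env_psd=env_z,
        env_pdf_bins=bins, env_pdf=dens,
        peak_frequency=float(centre),
        band=(centre - BAND_HALFWIDTH, centre + BAND_HALFWIDTH),
        zscore_params={"gain": gain, "psd_mean": p_mu, "psd_sd": p_sd,
                       "env_psd_mean": e_mu, "env_psd_sd": e_sd})
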