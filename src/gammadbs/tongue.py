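"""Arnold-tongue charting of a Wilson-Cowan model under periodic pulses.

Frequency locking of the gamma rhythm to a pulse train at frequency ``fs``
is quantified by the rotation number

    rho = (theta_N - theta_0) / (2 pi N),

the average number of oscillation cycles per stimulation pulse, where
``theta`` is the unwrapped Hilbert phase of the excitatory activity sampled
at pulse onsets.  rho = 1 marks 1:1 locking (one cycle per pulse), rho = 0.5
marks 1:2 locking (the rhythm runs at the half harmonic ``fs/2``).  Charted
over a (frequency, amplitude) grid, the locked cells form Arnold tongues;
the 1:2 tongue stems from twice the model's natural frequency.

The sine circle map ``theta_{n+1} = theta_n + 2 pi Omega - K sin(theta_n)``
is included as the classical single-oscillator reduction; it serves as an
independent oracle for the rotation-number machinery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal as sps

from gammadbs.model import (
    DEFAULT_DT,
    SimulatedTrace,
    SimulationError,
    StimulationProtocol,
    WCParameters,
    simulate,
)

__all__ = [
    "EntrainmentField",
    "rotation_from_phase",
    "rotation_number",
    "circle_map_rotation",
    "classify_locking",
    "chart_arnold_tongue",
    "tongue_metrics",
    "natural_frequency",
]

#: Tolerance on the rotation number for a locking label.
LOCKING_TOL = 0.01
#: Burn-in (s) discarded before counting pulses.
BURN_IN_S = 1.0
#: Rational rotation numbers that are labelled, as (label, value).
LOCKING_RATIOS = (("1:1", 1.0), ("1:2", 0.5), ("1:3", 1.0 / 3.0))


@dataclass
class EntrainmentField:
    """Rotation-number and peak-power matrices over a stimulation grid.

    Matrices are indexed ``[amplitude, frequency]``; ``locking`` holds the
    labels ``"1:1"``, ``"1:2"``, ``"1:3"`` or ``"none"`` (``"failed"`` for
    cells whose simulation diverged).
    """

    freq_grid: np.ndarray
    amp_grid: np.ndarray
    rotation: np.ndarray
    rotation_sd: np.ndarray
    peak_psd: np.ndarray
    locking: np.ndarray
    n_repeats: int
    n_cycles: int

    def __post_init__(self) -> None:
        shape = (len(self.amp_grid), len(self.freq_grid))
        for name in ("rotation", "rotation_sd", "peak_psd", "locking"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")

    def cells(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(amplitude indices, frequency indices) of cells with ``label``."""
        return np.nonzero(self.locking == label)

    def save(self, outdir) -> None:
        """CSV matrices plus a JSON header with the grids and settings."""
        import pandas as pd
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("rotation", "rotation_sd", "peak_psd", "locking"):
            pd.DataFrame(getattr(self, name),
                         index=self.amp_grid, columns=self.freq_grid
                         ).to_csv(outdir / f"{name}.csv")
        (outdir / "field.json").write_text(json.dumps({
            "freq_grid": self.freq_grid.tolist(),
            "amp_grid": self.amp_grid.tolist(),
            "n_repeats": self.n_repeats,
            "n_cycles": self.n_cycles}, indent=2))

    @classmethod
    def load(cls, outdir) -> "EntrainmentField":
        import pandas as pd
        outdir = Path(outdir)
        head = json.loads((outdir / "field.json").read_text())
        mats = {}
        for name in ("rotation", "rotation_sd", "peak_psd", "locking"):
            df = pd.read_csv(outdir / f"{name}.csv", index_col=0)
            mats[name] = df.to_numpy() if name != "locking" \
                else df.to_numpy(dtype=str)
        return cls(freq_grid=np.array(head["freq_grid"]),
                   amp_grid=np.array(head["amp_grid"]),
                   n_repeats=head["n_repeats"], n_cycles=head["n_cycles"],
                   **mats)


def unwrapped_phase(x: np.ndarray) -> np.ndarray:
    """Unwrapped Hilbert phase of a (demeaned) oscillatory series."""
    x = np.asarray(x, dtype=float)
    return np.unwrap(np.angle(sps.hilbert(x - x.mean())))


def rotation_from_phase(theta: np.ndarray, n_pulses: Optional[int] = None
                        ) -> float:
    """Rotation number of an unwrapped phase series sampled at pulses.

    ``theta[k]`` is the (unwrapped, radians) phase at the k-th pulse;
    returns ``(theta[N] - theta[0]) / (2 pi N)``.
    """
    theta = np.asarray(theta, dtype=float)
    n = len(theta) - 1 if n_pulses is None else n_pulses
    if n < 1 or n >= len(theta):
        raise ValueError("phase series too short for n_pulses")
    return float((theta[n] - theta[0]) / (2 * math.pi * n))


def rotation_number(trace: SimulatedTrace, n_pulses: int = 50,
                    burn_in: float = BURN_IN_S) -> float:
    """Mean cycles of E per stimulation pulse over ``n_pulses`` pulses.

    The Hilbert phase is computed on the post-burn-in segment; theta_0 is
    the phase at the first pulse onset after burn-in and theta_N the phase
    N pulses later.
    """
    k0 = int(round(burn_in / trace.dt))
    idx = trace.pulse_indices[trace.pulse_indices >= k0] - k0
    if len(idx) < n_pulses + 1:
        raise ValueError(
            f"trace holds {len(idx)} pulses after burn-in; "
            f"need {n_pulses + 1}")
    theta = unwrapped_phase(trace.E[k0:])
    return rotation_from_phase(theta[idx[: n_pulses + 1]])


def circle_map_rotation(omega: float, coupling: float,
                        n_iter: int = 2000) -> float:
    """Rotation number of the sine circle map (independent test oracle).

    Iterates ``theta_{n+1} = theta_n + 2 pi Omega - K sin(theta_n)`` and
    returns ``(theta_n - theta_0) / (2 pi n)``.
    """
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000 for a stable estimate")
    theta = 0.0
    two_pi_omega = 2 * math.pi * omega
    for _ in range(n_iter):
        theta = theta + two_pi_omega - coupling * math.sin(theta)
    return theta / (2 * math.pi * n_iter)


def classify_locking(rho_mean: float, rho_sd: float,
                     tol: float = LOCKING_TOL) -> str:
    """Label a mean rotation number: ``1:1``, ``1:2``, ``1:3`` or ``none``.

    A label additionally requires the across-repeat standard deviation to
    stay within ``tol`` (stable locking, not a grazing average).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if rho_sd > tol:
        return "none"
    for label, value in LOCKING_RATIOS:
        if abs(rho_mean - value) <= tol:
            return label
    return "none"


def peak_power(x: np.ndarray, rate: float, fmax: float = 200.0,
               fmin: float = 0.0, window_length: Optional[float] = None
               ) -> float:
    """Maximum Welch power of ``x`` within [fmin, fmax] Hz."""
    n = len(x)
    nper = n if window_length is None else min(n, int(round(
        window_length * rate)))
    f, p = sps.welch(x - np.mean(x), fs=rate, window="hann", nperseg=nper,
                     noverlap=nper // 2)
    sel = (f >= fmin) & (f <= fmax) & (f > 0)
    return float(np.max(p[sel]))


def chart_arnold_tongue(params: WCParameters,
                        freq_grid: np.ndarray,
                        amp_grid: np.ndarray,
                        waveform: str = "single_step",
                        waveform_param: Optional[float] = None,
                        target: str = "inhibitory",
                        n_repeats: int = 5,
                        n_cycles: int = 50,
                        seed: Optional[int] = None,
                        dt: float = DEFAULT_DT,
                        tol: float = LOCKING_TOL,
                        burn_in: float = BURN_IN_S) -> EntrainmentField:
    """Chart rotation number, locking label and peak power over a grid.

    Each (frequency, amplitude) cell is simulated ``n_repeats`` times with
    independent noise; the rotation number is computed over ``n_cycles``
    stimulation pulses after ``burn_in`` and the peak power is the mean
    over repeats of the maximum Welch power of E in 0-200 Hz.  Cells whose
    simulation diverges are labelled ``"failed"`` rather than aborting the
    chart.  Deterministic under ``seed``.
    """
    freq_grid = np.asarray(freq_grid, dtype=float)
    amp_grid = np.asarray(amp_grid, dtype=float)
    if freq_grid.size == 0 or amp_grid.size == 0:
        raise ValueError("grids must be nonempty")
    na, nf = len(amp_grid), len(freq_grid)
    rotation = np.full((na, nf), np.nan)
    rotation_sd = np.full((na, nf), np.nan)
    pk = np.full((na, nf), np.nan)
    locking = np.full((na, nf), "none", dtype=object)
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(na * nf * n_repeats).reshape(
        na, nf, n_repeats)
    for j, fs in enumerate(freq_grid):
        duration = burn_in + (n_cycles + 2) / fs
        for i, amp in enumerate(amp_grid):
            proto = StimulationProtocol(
                frequency=float(fs), amplitude=float(amp),
                waveform=waveform, waveform_param=waveform_param,
                target=target)
            rhos, powers = [], []
            failed = False
            for r in range(n_repeats):
                try:
                    tr = simulate(params, proto, dt=dt, duration=duration,
                                  seed=int(cell_seeds[i, j, r]))
                    rhos.append(rotation_number(tr, n_cycles, burn_in))
                    k0 = int(round(burn_in / dt))
                    powers.append(peak_power(tr.E[k0:], 1.0 / dt))
                except SimulationError:
                    failed = True
                    break
            if failed:
                locking[i, j] = "failed"
                continue
            rotation[i, j] = np.mean(rhos)
            rotation_sd[i, j] = np.std(rhos)
            pk[i, j] = np.mean(powers)
            locking[i, j] = classify_locking(rotation[i, j],
                                             rotation_sd[i, j], tol)
    return EntrainmentField(freq_grid=freq_grid, amp_grid=amp_grid,
                            rotation=rotation, rotation_sd=rotation_sd,
                            peak_psd=pk, locking=locking.astype(str),
                            n_repeats=n_repeats, n_cycles=n_cycles)


def tongue_metrics(field: EntrainmentField, label: str = "1:2") -> dict:
    """Stem frequency, top boundary, span and left lean of one tongue.

    * stem: centroid frequency of labelled cells in the lowest-amplitude
      row that contains any;
    * top boundary: greatest amplitude with a labelled cell;
    * span: frequency extent of labelled cells (Hz);
    * left-lean fraction: labelled cells strictly below the stem frequency
      over all labelled cells.
    """
    ai, fi = field.cells(label)
    if len(ai) == 0:
        raise ValueError(f"field contains no cells labelled {label}")
    lowest = ai.min()
    stem = float(np.mean(field.freq_grid[fi[ai == lowest]]))
    top = float(field.amp_grid[ai.max()])
    fvals = field.freq_grid[fi]
    span = float(fvals.max() - fvals.min())
    lean = float(np.mean(fvals < stem))
    return {"stem_frequency": stem, "top_amplitude": top,
            "frequency_span": span, "left_lean_fraction": lean,
            "n_cells": int(len(ai))}


def natural_frequency(params: WCParameters, duration: float = 10.0,
                      dt: float = DEFAULT_DT, burn_in: float = 2.0,
                      seed: int = 0) -> float:
    """Dominant frequency (Hz) of a noise-free simulation of the model."""
    tr = simulate(params.replace(zeta=0.0), None, dt=dt,
                  duration=duration, seed=seed)
    k0 = int(round(burn_in / dt))
    x = tr.E[k0:] - tr.E[k0:].mean()
    nper = min(len(x), int(round(2.0 / dt)))  # 0.5 Hz resolution
    f, p = sps.welch(x, fs=1.0 / dt, window="hann", nperseg=nper,
                     noverlap=nper // 2)
    return float(f[np.argmax(p)])
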