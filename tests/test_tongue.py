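"""Rotation numbers, the circle-map oracle and tongue charting."""

import math

import numpy as np
import pytest

from gammadbs.model import SimulatedTrace, StimulationProtocol, simulate
from gammadbs.tongue import (
    EntrainmentField,
    chart_arnold_tongue,
    circle_map_rotation,
    classify_locking,
    rotation_from_phase,
    rotation_number,
    tongue_metrics,
)


class TestCircleMap:
    def test_zero_coupling_gives_bare_rotation(self):
        for omega in (0.1, 0.5, 0.73):
            assert circle_map_rotation(omega, 0.0) == pytest.approx(
                omega, abs=1e-12)

    def test_half_harmonic_tongue_centre(self):
        assert circle_map_rotation(0.5, 0.5, 5000) == pytest.approx(
            0.5, abs=1e-6)

    def test_locking_persists_under_detuning(self):
        # transient before the locked orbit contributes O(1/n)
        assert circle_map_rotation(0.501, 0.5, 20000) == pytest.approx(
            0.5, abs=1e-5)

    def test_oracle_equivalence_with_phase_formula(self):
        # independently iterate the map here, then apply the package's
        # rotation formula to the phase series
        omega, k, n = 0.43, 0.3, 3000
        theta = np.empty(n + 1)
        theta[0] = 0.0
        for i in range(n):
            theta[i + 1] = theta[i] + 2 * math.pi * omega \
                - k * math.sin(theta[i])
        assert abs(rotation_from_phase(theta) -
                   circle_map_rotation(omega, k, n)) < 1e-9


class TestRotationNumber:
    def test_unforced_oscillator_gives_frequency_ratio(self):
        # fictitious pulse markers on a pure 75 Hz cosine: the phase
        # advances 2*pi*f0/fs per marker
        dt, f0, fs = 1e-4, 75.0, 130.0
        n = int(3.0 / dt)
        t = np.arange(n) * dt
        idx = np.round(np.arange(math.floor(3.0 * fs)) / (fs * dt)
                       ).astype(np.int64)
        tr = SimulatedTrace(dt=dt, duration=3.0,
                            E=np.cos(2 * np.pi * f0 * t),
                            I=np.zeros(n), stim=np.zeros(n),
                            pulse_indices=idx, seed=None)
        assert rotation_number(tr, 50) == pytest.approx(f0 / fs, abs=1e-3)

    def test_locked_cells_give_rational_rho(self, reference, column_130):
        params, _ = reference
        rows = np.nonzero(column_130.locking[:, 0] == "1:2")[0]
        assert len(rows) > 0, "no 1:2 cell in the 130 Hz column"
        amp = float(column_130.amp_grid[rows[0]])
        proto = StimulationProtocol(frequency=130.0, amplitude=amp)
        tr = simulate(params.replace(zeta=0.0), proto,
                      duration=1.0 + 52 / 130.0, seed=0)
        assert rotation_number(tr, 50) == pytest.approx(0.5, abs=0.01)

    def test_too_few_pulses_raises(self, reference):
        params, _ = reference
        proto = StimulationProtocol(frequency=130.0, amplitude=5.0)
        tr = simulate(params, proto, duration=1.1, seed=0)
        with pytest.raises(ValueError, match="pulses"):
            rotation_number(tr, 50)


class TestClassifyLocking:
    @pytest.mark.parametrize("rho,sd,expected", [
        (0.500, 0.002, "1:2"),
        (1.003, 0.002, "1:1"),
        (1.0 / 3.0, 0.001, "1:3"),
        (0.47, 0.002, "none"),
        (0.5, 0.05, "none"),  # unstable across repeats
    ])
    def test_labels(self, rho, sd, expected):
        assert classify_locking(rho, sd, tol=0.01) == expected


def synthetic_field():
    """Hand-built field: a left-leaning parallelogram tongue."""
    freq = np.arange(100.0, 161.0, 2.0)
    amp = np.arange(0.0, 41.0, 4.0)
    locking = np.full((len(amp), len(freq)), "none", dtype=object)
    rotation = np.outer(np.ones(len(amp)), 75.0 / freq)
    peak = np.zeros((len(amp), len(freq)))
    for i, a in enumerate(amp):
        if i == 0 or a > 32:
            continue
        centre = 152.0 - 1.5 * a
        for j, f in enumerate(freq):
            if abs(f - centre) <= 4 + 0.25 * a:
                locking[i, j] = "1:2"
                rotation[i, j] = 0.5
                # strong power gradient along the tongue (~50x range)
                peak[i, j] = np.exp(-(f - 100.0) / 15.0) * (1 + a / 40.0)
    return EntrainmentField(
        freq_grid=freq, amp_grid=amp, rotation=rotation,
        rotation_sd=np.zeros_like(rotation), peak_psd=peak,
        locking=locking.astype(str), n_repeats=1, n_cycles=50)


class TestTongueMetrics:
    def test_constructed_left_leaning_field(self):
        # lowest amplitude row with cells is a=4: centre 152-6=146
        m = tongue_metrics(synthetic_field())
        assert m["stem_frequency"] == pytest.approx(146.0, abs=2.0)
        assert m["top_amplitude"] == 32.0
        assert m["left_lean_fraction"] > 0.5

    def test_single_cell_field(self):
        f = synthetic_field()
        f.locking[:] = "none"
        f.locking[2, 10] = "1:2"
        m = tongue_metrics(f)
        assert m["frequency_span"] == 0.0
        assert m["left_lean_fraction"] == 0.0
        assert m["n_cells"] == 1

    def test_empty_field_raises(self):
        f = synthetic_field()
        f.locking[:] = "none"
        with pytest.raises(ValueError):
            tongue_metrics(f)


class TestChart:
    def test_zero_amplitude_row_tracks_frequency_ratio(self, reference,
                                                       reference_field):
        _, f0 = reference
        rho = reference_field.rotation[0]
        expect = f0 / reference_field.freq_grid
        assert np.nanmax(np.abs(rho - expect)) < 0.03

    def test_half_harmonic_peak_inside_tongue(self, reference,
                                              reference_field):
        # inside any 1:2 cell the PSD maximum over 40-120 Hz sits at fs/2
        from gammadbs.tongue import BURN_IN_S
        from scipy.signal import welch
        params, _ = reference
        ai, fi = reference_field.cells("1:2")
        inner = [(a, f) for a, f in zip(ai, fi)
                 if reference_field.amp_grid[a] > 0]
        assert inner, "no positive-amplitude 1:2 cells"
        a, f = inner[len(inner) // 2]
        fs = float(reference_field.freq_grid[f])
        proto = StimulationProtocol(
            frequency=fs, amplitude=float(reference_field.amp_grid[a]))
        tr = simulate(params, proto, duration=3.0, seed=2)
        k0 = int(BURN_IN_S / tr.dt)
        x = tr.E[k0:] - tr.E[k0:].mean()
        fr, p = welch(x, fs=1 / tr.dt, nperseg=int(1 / tr.dt))
        sel = (fr >= 40) & (fr <= 120)
        assert abs(fr[sel][np.argmax(p[sel])] - fs / 2) <= 1.0

    def test_field_save_load_roundtrip(self, tmp_path, reference_field):
        reference_field.save(tmp_path / "field")
        back = EntrainmentField.load(tmp_path / "field")
        assert np.allclose(back.rotation, reference_field.rotation,
                           equal_nan=True)
        assert np.array_equal(back.locking, reference_field.locking)
        assert np.array_equal(back.freq_grid, reference_field.freq_grid)

    def test_deterministic_under_seed(self, reference):
        params, _ = reference
        kw = dict(freq_grid=np.array([130.0, 150.0]),
                  amp_grid=np.array([0.0, 10.0]),
                  n_repeats=2, n_cycles=50, seed=5)
        a = chart_arnold_tongue(params, **kw)
        b = chart_arnold_tongue(params, **kw)
        assert np.array_equal(a.rotation, b.rotation)
        assert np.array_equal(a.locking, b.locking)
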