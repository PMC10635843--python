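"""Wilson-Cowan simulator: sigmoid, pulse trains, integration contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import welch

from gammadbs.model import (
    StimulationProtocol,
    WCParameters,
    build_pulse_train,
    sigmoid,
    simulate,
)
from gammadbs.synth import reference_parameter_set


def stable_params(zeta=0.0):
    """Weak coupling, strongly damped: a stable fixed point, no cycle."""
    return WCParameters(w_EE=0.5, w_IE=-0.5, w_EI=0.5, eta_E=0.2,
                       eta_I=0.1, tau_E=0.01, tau_I=0.01, b=2.0, zeta=zeta)


class TestSigmoid:
    def test_centre_is_half_for_any_steepness(self):
        for b in (0.5, 1.0, 4.0, 10.0):
            assert sigmoid(1.0, b) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert sigmoid(1e3, 4.0) == pytest.approx(1.0)
        assert sigmoid(-1e3, 4.0) == pytest.approx(0.0)

    def test_closed_form_value(self):
        assert sigmoid(0.0, 4.0) == pytest.approx(1 / (1 + math.e ** 4),
                                                  rel=1e-6)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, x1, x2):
        if abs(x1 - x2) < 1e-6:
            return
        lo, hi = sorted((x1, x2))
        assert sigmoid(lo, 3.0) < sigmoid(hi, 3.0)

    def test_rejects_nonfinite_and_bad_steepness(self):
        with pytest.raises(ValueError):
            sigmoid(float("nan"), 4.0)
        with pytest.raises(ValueError):
            sigmoid(0.0, -1.0)


class TestPulseTrain:
    def test_pulse_count_and_spacing(self):
        proto = StimulationProtocol(frequency=130.0, amplitude=1.0)
        stim, idx = build_pulse_train(proto, 1e-4, 1.0)
        assert len(idx) == 130
        gaps = np.diff(idx)
        assert np.all(np.abs(gaps - round(1 / (130 * 1e-4))) <= 1)

    def test_single_step_height_and_charge(self):
        proto = StimulationProtocol(frequency=10.0, amplitude=2.0)
        stim, idx = build_pulse_train(proto, 1e-4, 0.1)
        nz = stim[stim != 0]
        assert np.all(nz == 2.0) and len(nz) == 1
        assert stim.sum() == pytest.approx(2.0)

    @pytest.mark.parametrize("waveform,param", [
        ("active_recharge", 5e-4),
        ("active_recharge", 2e-3),
        ("passive_recharge", 1e-3),
    ])
    def test_recharge_is_charge_balanced(self, waveform, param):
        proto = StimulationProtocol(frequency=130.0, amplitude=3.0,
                                    waveform=waveform, waveform_param=param)
        stim, idx = build_pulse_train(proto, 1e-4, 1.0)
        assert abs(stim.sum()) < 1e-12 * 3.0 * len(idx)

    def test_too_short_duration_errors(self):
        proto = StimulationProtocol(frequency=2.0, amplitude=1.0)
        with pytest.raises(ValueError, match="inter-pulse"):
            build_pulse_train(proto, 1e-4, 0.2)

    def test_zero_amplitude_still_marks_onsets(self):
        proto = StimulationProtocol(frequency=130.0, amplitude=0.0)
        stim, idx = build_pulse_train(proto, 1e-4, 1.0)
        assert len(idx) == 130 and np.all(stim == 0)


class TestSimulate:
    def test_same_seed_is_bitwise_identical(self, reference):
        params, _ = reference
        a = simulate(params, None, duration=1.0, seed=42)
        b = simulate(params, None, duration=1.0, seed=42)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.I, b.I)

    def test_zero_amplitude_matches_unstimulated(self, reference):
        params, _ = reference
        proto = StimulationProtocol(frequency=130.0, amplitude=0.0)
        a = simulate(params, None, duration=1.0, seed=3)
        b = simulate(params, proto, duration=1.0, seed=3)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.I, b.I)

    def test_deterministic_relaxation_to_fixed_point(self):
        tr = simulate(stable_params(), None, duration=2.0, seed=0)
        tail = tr.E[-len(tr.E) // 10:]
        assert tail.max() - tail.min() < 1e-6

    def test_reference_natural_frequency(self, reference):
        params, f0 = reference
        tr = simulate(params.replace(zeta=0.0), None, duration=10.0, seed=0)
        x = tr.E[20000:] - tr.E[20000:].mean()
        f, p = welch(x, fs=1e4, nperseg=40000)
        assert abs(f[np.argmax(p)] - f0) <= f[1] - f[0]

    def test_halving_dt_keeps_natural_frequency(self, reference):
        params, _ = reference
        peaks = []
        for dt in (1e-4, 5e-5):
            tr = simulate(params.replace(zeta=0.0), None, dt=dt,
                          duration=10.0, seed=0)
            k = int(2 / dt)
            x = tr.E[k:] - tr.E[k:].mean()
            f, p = welch(x, fs=1 / dt, nperseg=int(4 / dt))
            peaks.append(f[np.argmax(p)])
        assert abs(peaks[0] - peaks[1]) < 0.5

    def test_trajectory_stays_in_unit_square(self):
        # f in (0,1) makes the square forward-invariant without noise
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = WCParameters(
                w_EE=rng.uniform(0, 10), w_IE=rng.uniform(-10, 0),
                w_EI=rng.uniform(0, 10), eta_E=rng.uniform(-5, 5),
                eta_I=rng.uniform(-5, 5), tau_E=rng.uniform(0.002, 0.05),
                tau_I=rng.uniform(0.002, 0.05),
                b=rng.uniform(1, 10), zeta=0.0)
            tr = simulate(p, None, duration=0.3, seed=0)
            assert tr.E.min() >= 0.0 and tr.E.max() <= 1.0
            assert tr.I.min() >= 0.0 and tr.I.max() <= 1.0

    def test_excitatory_target_differs_from_inhibitory(self, reference):
        params, _ = reference
        pi = StimulationProtocol(frequency=130.0, amplitude=20.0)
        pe = StimulationProtocol(frequency=130.0, amplitude=20.0,
                                 target="excitatory")
        a = simulate(params, pi, duration=1.0, seed=5)
        b = simulate(params, pe, duration=1.0, seed=5)
        assert not np.allclose(a.E, b.E)

    def test_coarse_dt_rejected_when_stimulating(self, reference):
        params, _ = reference
        proto = StimulationProtocol(frequency=130.0, amplitude=1.0)
        with pytest.raises(ValueError, match="dt"):
            simulate(params, proto, dt=1e-3, duration=1.0, seed=0)

    def test_trace_length_and_pulse_gaps(self, reference):
        params, _ = reference
        proto = StimulationProtocol(frequency=150.0, amplitude=5.0)
        tr = simulate(params, proto, duration=2.0, seed=0)
        assert len(tr.E) == round(2.0 / tr.dt)
        assert np.all(np.diff(tr.pulse_indices) > 0)


def test_reference_roundtrips_through_json(tmp_path, reference):
    params, _ = reference
    params.to_json(tmp_path / "p.json")
    assert WCParameters.from_json(tmp_path / "p.json") == params
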