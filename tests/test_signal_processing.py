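"""Envelope, mode windows, amplitude measurement, synthetic fixture."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from boneguide import (
    SignalError,
    envelope,
    envelope_diagram,
    measure_modes,
    plan_windows,
    ratio_rmse_over_distance,
    synthetic_trace,
)
from boneguide.signal_processing import ModeAmplitudes


class TestEnvelope:
    def test_sinusoid_amplitude_recovered(self):
        t = np.arange(0, 200, 0.1)
        env = envelope(2.5 * np.sin(2 * math.pi * 0.1 * t))
        core = env[200:-200]
        assert np.allclose(core, 2.5, rtol=0.01)

    def test_toneburst_envelope_peak_at_center(self):
        time, trace = synthetic_trace(z=120, amp_s0=1.0, amp_a0=0.0 + 1e-12,
                                      v_S0=3.95, v_A0=1.51)
        env = envelope(trace)
        assert time[np.argmax(env)] == pytest.approx(120 / 3.95, abs=2 * 0.1)

    def test_zero_trace_zero_envelope(self):
        assert np.all(envelope(np.zeros(100)) == 0)

    def test_sign_flip_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=512)
        assert np.allclose(envelope(x), envelope(-x))

    def test_short_trace_rejected(self):
        with pytest.raises(SignalError):
            envelope(np.ones(4))


class TestWindows:
    def test_reference_boundary_and_separation(self):
        # z = 120 mm with the printed velocities: boundary 54.9 µs and the
        # 49.1 µs arrival gap falls just short of the 50 µs pulse
        plan = plan_windows(120, 3.95, 1.51, 50.0)
        assert plan.s0_window[1] == pytest.approx(54.93, abs=0.01)
        assert plan.a0_window[0] == pytest.approx(54.93, abs=0.01)
        assert not plan.separation_ok

    def test_separation_recovers_at_longer_distance(self):
        plan = plan_windows(150, 3.95, 1.51, 50.0)
        assert plan.separation_ok

    def test_windows_disjoint_and_ordered(self):
        plan = plan_windows(100, 3.4, 1.9, 50.0, t0=25.0)
        assert plan.s0_window[0] < plan.s0_window[1] <= plan.a0_window[0] < plan.a0_window[1]

    def test_equal_velocities_rejected(self):
        with pytest.raises(SignalError):
            plan_windows(120, 1.51, 1.51, 50.0)


class TestMeasure:
    def test_known_amplitude_ratio_recovered(self):
        time, trace = synthetic_trace(z=150, amp_s0=0.5, amp_a0=1.0, v_S0=3.95, v_A0=1.51)
        plan = plan_windows(150, 3.95, 1.51, 50.0)
        m = measure_modes(trace, time, plan, z=150)
        assert m.ratio_db == pytest.approx(-6.02, abs=0.2)

    def test_equal_amplitudes_give_zero_db(self):
        time, trace = synthetic_trace(z=150, amp_s0=0.7, amp_a0=0.7, v_S0=3.95, v_A0=1.51)
        plan = plan_windows(150, 3.95, 1.51, 50.0)
        assert measure_modes(trace, time, plan).ratio_db == pytest.approx(0.0, abs=0.1)

    def test_ratio_recovery_over_random_amplitude_pairs(self):
        """50 random (amp_s0, amp_a0) pairs recovered within 0.2 dB."""
        rng = np.random.default_rng(11)
        plan = plan_windows(160, 3.95, 1.51, 50.0)
        for _ in range(50):
            a_s, a_a = rng.uniform(0.1, 2.0, size=2)
            time, trace = synthetic_trace(z=160, amp_s0=a_s, amp_a0=a_a,
                                          v_S0=3.95, v_A0=1.51)
            m = measure_modes(trace, time, plan)
            expected = 20 * math.log10(a_s / a_a)
            assert m.ratio_db == pytest.approx(expected, abs=0.2)

    def test_global_scaling_invariance_of_ratio(self):
        time, trace = synthetic_trace(z=150, amp_s0=0.4, amp_a0=1.3, v_S0=3.95, v_A0=1.51)
        plan = plan_windows(150, 3.95, 1.51, 50.0)
        r1 = measure_modes(trace, time, plan).ratio_db
        r2 = measure_modes(17.3 * trace, time, plan).ratio_db
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_vanishing_a0_guarded(self):
        time, trace = synthetic_trace(z=150, amp_s0=1.0, amp_a0=0.0, v_S0=3.95, v_A0=1.51)
        plan = plan_windows(150, 3.95, 1.51, 50.0)
        m = measure_modes(trace, time, plan)
        # the A0 window sees at most the S0 Gaussian tail (or nothing: inf)
        assert m.ratio_db > 40

    def test_empty_window_rejected(self):
        time, trace = synthetic_trace(z=150, amp_s0=1.0, amp_a0=1.0, v_S0=3.95, v_A0=1.51)
        plan = plan_windows(150, 3.95, 1.51, 50.0, t0=1e4)
        with pytest.raises(SignalError):
            measure_modes(trace, time, plan)


class TestSyntheticTrace:
    def test_deterministic_per_seed(self):
        kw = dict(z=150, amp_s0=1.0, amp_a0=0.5, v_S0=3.95, v_A0=1.51, noise_rms=0.05)
        _, a = synthetic_trace(seed=42, **kw)
        _, b = synthetic_trace(seed=42, **kw)
        _, c = synthetic_trace(seed=43, **kw)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_converted_packet_midway_when_legs_equal(self):
        time, trace = synthetic_trace(z=120, amp_s0=0.0, amp_a0=0.0 + 0,
                                      amp_conv=1.0, z1=60, z2=60, v_S0=3.95, v_A0=1.51)
        env = envelope(trace)
        t_conv = 60 / 3.95 + 60 / 1.51
        assert time[np.argmax(env)] == pytest.approx(t_conv, abs=0.2)

    def test_path_split_must_sum_to_z(self):
        with pytest.raises(SignalError):
            synthetic_trace(z=120, amp_s0=1, amp_a0=1, amp_conv=0.5, z1=60, z2=70,
                            v_S0=3.95, v_A0=1.51)

    def test_undersampling_rejected(self):
        with pytest.raises(SignalError):
            synthetic_trace(z=120, amp_s0=1, amp_a0=1, v_S0=3.95, v_A0=1.51,
                            sample_dt=1.0)


class TestRatioRmse:
    def test_identical_ratios_zero_rmse(self):
        amps = [ModeAmplitudes(1, 1, 0.0, z) for z in (90, 120, 150)]
        mean, rmse = ratio_rmse_over_distance(amps)
        assert mean == 0.0 and rmse == 0.0

    def test_hand_computed_pair(self):
        amps = [ModeAmplitudes(1, 1, 0.0, 90), ModeAmplitudes(1, 1, 2.0, 120)]
        mean, rmse = ratio_rmse_over_distance(amps)
        assert mean == pytest.approx(1.0)
        assert rmse == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(offset=st.floats(-30, 30), n=st.integers(2, 8))
    def test_translation_invariance(self, offset, n):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 3, size=n)
        a = [ModeAmplitudes(1, 1, r, 100 + i) for i, r in enumerate(base)]
        b = [ModeAmplitudes(1, 1, r + offset, 100 + i) for i, r in enumerate(base)]
        assert ratio_rmse_over_distance(a)[1] == pytest.approx(
            ratio_rmse_over_distance(b)[1], abs=1e-9
        )

    def test_insufficient_data(self):
        with pytest.raises(SignalError):
            ratio_rmse_over_distance([ModeAmplitudes(1, 1, 0.0, 90)])


class TestEnvelopeDiagram:
    def test_single_trace_column(self):
        t = np.arange(0, 100, 0.1)
        x = np.sin(2 * math.pi * 0.1 * t) * np.exp(-((t - 50) ** 2) / 50)
        diag = envelope_diagram(x, t)
        assert diag.shape == (1, len(t))
        assert np.allclose(diag[0], envelope(x))

    def test_zero_traces_zero_diagram(self):
        t = np.arange(0, 10, 0.1)
        assert np.all(envelope_diagram(np.zeros((3, len(t))), t) == 0)

    def test_ridge_slopes_recover_packet_velocities(self):
        """Peak-time regression over a receiver scan gives 1/v_S0 and 1/v_A0."""
        zs = np.arange(90, 151, 5.0)
        t = np.arange(0, 160, 0.1)
        traces = []
        for z in zs:
            _, tr = synthetic_trace(z=float(z), amp_s0=1.0, amp_a0=1.0,
                                    v_S0=3.95, v_A0=1.51)
            padded = np.zeros_like(t)
            padded[: len(tr)] = tr[: len(t)]
            traces.append(padded)
        diag = envelope_diagram(np.array(traces), t)
        for v, window in ((3.95, (15, 45)), (1.51, (55, 110))):
            times = []
            for row, z in zip(diag, zs):
                sel = (t >= window[0]) & (t <= window[1])
                times.append(t[sel][np.argmax(row[sel])])
            slope = np.polyfit(zs, times, 1)[0]
            assert 1.0 / slope == pytest.approx(v, rel=0.02)

    def test_inconsistent_time_base_rejected(self):
        with pytest.raises(SignalError):
            envelope_diagram(np.zeros((2, 50)), np.arange(40))

    def test_plot_written_to_file(self, tmp_path):
        from boneguide.signal_processing import plot_envelope_diagram

        t = np.arange(0, 100, 0.5)
        zs = np.array([90.0, 100.0, 110.0])
        diag = np.random.default_rng(0).random((3, len(t)))
        out = tmp_path / "diag.png"
        plot_envelope_diagram(diag, t, zs, path=out, arrivals={"S0": 3.95, "A0": 1.51})
        assert out.stat().st_size > 0
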