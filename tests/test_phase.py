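import numpy as np
import pytest
from hypothesis import given, strategies as st

import optoclock as oc
from optoclock.phase import PhaseResponseCurve, _phase_shifts, wrap_phase


class TestWrapPhase:
    @given(st.floats(min_value=-50, max_value=50))
    def test_wraps_into_half_open_interval(self, x):
        w = float(wrap_phase(x))
        assert -0.5 <= w < 0.5
        assert abs((x - w) - round(x - w)) < 1e-9


class TestDetectPeaks:
    def test_cosine_peaks_at_multiples_of_period(self):
        t = np.arange(0, 70.0001, 0.005)
        peaks = oc.detect_peaks(t, np.cos(2 * np.pi * t / 17.5))
        # interior maxima only; boundary extrema are not peaks
        assert np.allclose(peaks, [17.5, 35, 52.5], atol=0.01)

    def test_flat_signal_has_no_peaks(self):
        t = np.arange(0, 10, 0.1)
        assert len(oc.detect_peaks(t, np.ones_like(t))) == 0

    def test_limit_cycle_peak_spacings_are_uniform(self, params):
        traj = oc.simulate(params, oc.LightProtocol.constant("off"), t_end=160.0)
        spacings = np.diff(oc.detect_peaks(traj.times, traj.y)[1:])
        assert np.max(np.abs(spacings - spacings.mean())) < 0.01 * spacings.mean()


class TestNaturalPeriod:
    def test_time_rescaling_doubles_period(self):
        from optoclock.model import OptoParams, RepressilatorParams

        slow = OptoParams(base=RepressilatorParams(alpha=0.375, beta=150.0))
        T_slow = oc.natural_period(slow, t_end=320.0)
        assert T_slow == pytest.approx(2 * 17.507, rel=0.01)

    def test_steep_repression_approaches_digital_period(self):
        from optoclock.model import OptoParams, RepressilatorParams

        p = OptoParams(base=RepressilatorParams(n=20))
        T = oc.natural_period(p)
        assert abs(T - oc.digital_period(p.base)) / oc.digital_period(p.base) < 0.15

    def test_too_short_run_rejected(self, params):
        with pytest.raises(ValueError):
            oc.natural_period(params, t_end=40.0)


class TestPhaseResponse:
    def test_no_pulse_means_no_shift(self, params, T0):
        shifts, _ = _phase_shifts(params, np.array([-0.3, 0.0, 0.3]), tau=2.0,
                                  beta_prime_pulse=0.0, T0=T0)
        assert np.allclose(shifts, 0.0, atol=1e-6)

    def test_advance_before_peak_delay_after(self, params, T0):
        shifts, _ = _phase_shifts(params, np.array([-0.1, 0.25]), tau=2.0,
                                  beta_prime_pulse=80.0, T0=T0)
        assert shifts[0] > 0.05   # pulse on the rising edge advances
        assert shifts[1] < 0.0    # pulse after the peak delays

    def test_shift_independent_of_measurement_peak_index(self, params, T0):
        """The asymptotic shift must not depend on which downstream peak is
        used to read it off (no transient contamination)."""
        phis = np.array([-0.3, -0.1, 0.2])
        s3, _ = _phase_shifts(params, phis, 2.0, 80.0, k=3, T0=T0)
        s5, _ = _phase_shifts(params, phis, 2.0, 80.0, k=5, T0=T0)
        assert np.max(np.abs(s3 - s5)) < 0.02

    def test_shift_shrinks_with_pulse_duration(self, params, T0):
        """At fixed intensity the phase shift vanishes with pulse duration
        (monotonically on the sensitive rising edge)."""
        mags = []
        for tau in (2.0, 0.2, 0.1, 0.05, 0.02):
            s, _ = _phase_shifts(params, np.array([-0.1]), tau=tau,
                                 beta_prime_pulse=80.0, T0=T0)
            mags.append(abs(float(s[0])))
        # saturated for long pulses, then shrinking once beta' * tau ~ K
        assert mags[1] > mags[2] > mags[3] > mags[4]
        assert mags[4] < 0.25 * mags[0]


class TestPrcShape:
    def test_grid_is_uniform_in_half_open_interval(self, prc64):
        assert len(prc64.phis) == 64
        assert prc64.phis[0] == -0.5
        assert np.allclose(np.diff(prc64.phis), 1 / 64)

    def test_negative_slope_through_crossover(self, prc64):
        """The curve crosses zero near phi = 0 with negative slope, the
        signature of a stable entrained state at resonant forcing."""
        near = np.abs(prc64.phis) <= 0.1
        dp = prc64.delta_phis[near]
        assert dp[0] > 0 > dp[-1]

    def test_longer_pulses_shift_more(self, params, T0):
        short, _ = _phase_shifts(params, np.array([0.25]), tau=1.0,
                                 beta_prime_pulse=80.0, T0=T0)
        long, _ = _phase_shifts(params, np.array([0.25]), tau=4.0,
                                beta_prime_pulse=80.0, T0=T0)
        assert long[0] < short[0] < 0

    def test_minimum_grid_size_enforced(self, params):
        with pytest.raises(ValueError):
            oc.compute_prc(params, n_points=4)

    def test_csv_export(self, prc64, tmp_path):
        import json

        import pandas as pd

        path = tmp_path / "prc.csv"
        prc64.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["phi", "delta_phi"]
        meta = json.loads((tmp_path / "prc.csv.json").read_text())
        assert meta["tau"] == 2.0 and meta["beta_prime"] == 80.0


class TestCircleMap:
    def test_resonant_forcing_at_prc_zero_is_fixed(self):
        phis = np.linspace(-0.5, 0.5, 65)[:-1]
        prc = PhaseResponseCurve(phis=phis, delta_phis=-0.5 * phis,
                                 pulse_tau=2.0, pulse_beta_prime=80.0, T0=17.5)
        assert oc.circle_map_step(0.0, prc, TL=17.5) == pytest.approx(0.0, abs=1e-9)

    def test_zero_prc_gives_pure_rotation(self):
        phis = np.linspace(-0.5, 0.5, 65)[:-1]
        prc = PhaseResponseCurve(phis=phis, delta_phis=np.zeros_like(phis),
                                 pulse_tau=2.0, pulse_beta_prime=0.0, T0=16.0)
        seq = oc.iterate_circle_map(0.1, prc, TL=20.0, n_steps=4)
        assert np.allclose(seq, wrap_phase(0.1 + 0.25 * np.arange(5)))

    def test_iteration_converges_to_stable_zero(self, prc64, T0):
        seq = oc.iterate_circle_map(0.3, prc64, TL=T0, n_steps=400)
        target = oc.entrained_phase(prc64, T0).phi_star
        assert abs(float(wrap_phase(seq[-1] - target))) < 0.01


class TestEntrainedPhase:
    def test_resonant_fixed_point_is_prc_zero_with_negative_slope(self, prc64, T0):
        st_ = oc.entrained_phase(prc64, T0)
        assert abs(float(prc64(st_.phi_star))) < 1e-3
        assert -2.0 < st_.slope < 0.0
        assert st_.stable

    @pytest.mark.parametrize("ratio", [0.9, 1.1, 1.2])
    def test_detuned_fixed_point_lies_on_the_prc(self, prc64, T0, ratio):
        """(phi*, 1 - TL/T0) sits on the phase response curve, modulo whole
        cycles (the circle map only sees the detuning mod 1)."""
        st_ = oc.entrained_phase(prc64, ratio * T0)
        mismatch = float(wrap_phase(float(prc64(st_.phi_star)) - (1 - ratio)))
        assert abs(mismatch) < 2e-3

    def test_steep_fixed_points_are_map_unstable(self, prc64, T0):
        """At TL/T0 = 0.8 the required advance falls on the steep part of the
        curve where the slope is below -2: the first-order map classifies no
        fixed point as stable."""
        with pytest.raises(oc.OutsideLockingRangeError):
            oc.entrained_phase(prc64, 0.8 * T0)

    def test_shallow_curve_has_no_root_for_large_detuning(self):
        phis = np.linspace(-0.5, 0.5, 65)[:-1]
        prc = PhaseResponseCurve(phis=phis, delta_phis=-0.05 * np.sin(2 * np.pi * phis),
                                 pulse_tau=2.0, pulse_beta_prime=10.0, T0=17.5)
        with pytest.raises(oc.OutsideLockingRangeError):
            oc.entrained_phase(prc, 1.2 * 17.5)


class TestMeasuredEntrainedPhase:
    def test_resonant_train_matches_map_prediction(self, params, prc64, T0):
        proto = oc.LightProtocol.pulse_train(3.0, T0, 2.0, 40)
        traj = oc.simulate(params, proto, t_end=3.0 + 40 * T0)
        measured, sd = oc.measured_entrained_phase(traj, T0, discard_periods=27)
        predicted = oc.entrained_phase(prc64, T0).phi_star
        assert abs(float(wrap_phase(measured - predicted))) < 0.03
        assert sd < 0.05

    def test_mother_machine_detuning_is_entrained(self, params, T0):
        TL = 0.97 * T0
        proto = oc.LightProtocol.pulse_train(3.0, TL, 2.0, 30)
        traj = oc.simulate(params, proto, t_end=3.0 + 30 * TL)
        measured, sd = oc.measured_entrained_phase(traj, T0, discard_periods=20)
        assert sd < 0.05
        assert -0.1 < measured < 0.1

    def test_far_detuned_train_raises_drift_flag(self, params, T0):
        proto = oc.LightProtocol.pulse_train(3.0, 0.5 * T0, 2.0, 30)
        traj = oc.simulate(params, proto, t_end=3.0 + 15 * T0)
        with pytest.raises(oc.NotEntrainedError):
            oc.measured_entrained_phase(traj, T0, discard_periods=8)

    def test_slow_cells_lead_fast_cells_lag(self, T0):
        """In an entrained population, cells growing slower than average meet
        the pulse before their y peak (advance side) and faster cells after
        it: per-cell growth rate and entrained phase correlate positively."""
        spec = oc.EnsembleSpec(n_cells=30, seed=4)
        proto = oc.LightProtocol.pulse_train(0.0, T0, 2.0, 30)
        res = oc.simulate_ensemble(spec, proto, t_end=30 * T0, record_full=True)
        phis = []
        for i in range(30):
            phi, _ = oc.measured_entrained_phase(res.cell_trajectory(i), T0,
                                                 discard_periods=15)
            phis.append(phi)
        r = np.corrcoef(res.alphas, phis)[0, 1]
        assert r > 0.5
        slow = np.asarray(phis)[res.alphas < res.alphas.mean()]
        assert np.mean(slow) < 0.05
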