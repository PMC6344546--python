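"""Movement generator and movement regulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synergait import _engine
from synergait.motor_control import (
    MUSCLES,
    DelayLine,
    PhaseState,
    RegulatorParameters,
    advance_phase,
    delayed_regulator,
    rectangular_pulse,
    regulator_contribution,
    speed_regulator,
    synergy_command,
    total_command,
    trunk_regulator,
)

TWO_PI = 2 * np.pi
IL, GM, VA, BFS, TA, SO, RF, BFL, GC = range(9)


class TestPhase:
    @pytest.mark.parametrize(
        "phi, T, dt, expected",
        [
            (0.0, 1.0, 0.5, np.pi),  # half cycle
            (6.0, 1.0, 0.1, (6.0 + 0.2 * np.pi) % TWO_PI),  # wraps past 2*pi
            (0.0, 0.8, 0.8, 0.0),  # one full running cycle
        ],
    )
    def test_advance(self, phi, T, dt, expected):
        ps = advance_phase(PhaseState(phi=phi, T=T), dt)
        assert ps.phi == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_T(self):
        with pytest.raises(ValueError):
            PhaseState(phi=0.0, T=0.0)
        with pytest.raises(ValueError):
            advance_phase(PhaseState(phi=0.0, T=1.0), dt=-0.1)


class TestRectangularPulse:
    def test_inside(self):
        assert rectangular_pulse(0.5, 0.0, 0.75) == 1.0

    def test_strict_onset(self):
        assert rectangular_pulse(1.3, 1.3, 0.5) == 0.0

    def test_wraparound_fifth_pulse(self):
        # pulse 5 of the presets ends at 5.36 + 0.94 = 6.30 > 2*pi: phases just
        # past zero still fall inside the wrapped window
        assert (0.01 - 5.36) % TWO_PI == pytest.approx(0.9332, abs=1e-4)
        assert rectangular_pulse(0.01, 5.36, 0.94) == 1.0
        assert rectangular_pulse(0.02, 5.36, 0.94) == 0.0


class TestSynergyCommand:
    def test_walking_pulse1(self, walking_preset):
        # phi=0.5: only pulse 1 active -> VA gets Lambda_1*w_VA1, SO silent
        u = synergy_command(PhaseState(0.5, 1.0), walking_preset.pulses, "right")
        assert u[VA] == pytest.approx(1.02)
        assert u[SO] == 0.0

    def test_running_pulses_1_and_2(self, running_preset):
        # running: Phi_2 = 0.16 so pulses 1 and 2 overlap at phi=0.5
        u = synergy_command(PhaseState(0.5, 0.8), running_preset.pulses, "right")
        assert u[SO] == pytest.approx(1.29 * 1.09)
        assert u[VA] == pytest.approx(1.34 * 1.02)

    def test_zero_amplitude(self, walking_preset):
        pp = walking_preset.pulses
        pp = type(pp)(T=pp.T, onset=pp.onset, duration=pp.duration,
                      weights=pp.weights, amplitude=np.zeros(5))
        u = synergy_command(PhaseState(1.0, 1.0), pp, "left")
        assert np.all(u == 0.0)

    @settings(deadline=None, max_examples=50)
    @given(phi=st.floats(0, 100, allow_nan=False))
    def test_periodicity_and_symmetry(self, phi, walking_preset):
        from hypothesis import assume

        pp = walking_preset.pulses
        # strict pulse edges flip under float rounding; stay clear of them
        for onset, dur in zip(pp.onset, pp.duration):
            for probe in (phi, phi + np.pi):
                d = (probe - onset) % TWO_PI
                assume(min(abs(d), abs(d - dur), abs(d - TWO_PI)) > 1e-6)
        a = synergy_command(PhaseState(phi % TWO_PI, 1.0), pp, "right")
        b = synergy_command(PhaseState((phi + TWO_PI) % TWO_PI, 1.0), pp, "right")
        np.testing.assert_allclose(a, b)
        # left leg at phi equals right leg at phi + pi
        left = synergy_command(PhaseState(phi % TWO_PI, 1.0), pp, "left")
        right_shift = synergy_command(PhaseState((phi + np.pi) % TWO_PI, 1.0), pp, "right")
        np.testing.assert_allclose(left, right_shift)
        assert np.all(a >= 0.0)

    def test_pulse_duty_fraction(self, walking_preset):
        # the fraction of the cycle each pulse is active equals Delta_i / 2*pi
        pp = walking_preset.pulses
        phis = (np.arange(200_000) + 0.5) / 200_000 * TWO_PI
        for i in range(5):
            frac = np.mean(
                [(rectangular_pulse(p, pp.onset[i], pp.duration[i])) for p in phis[::2]]
            )
            assert frac == pytest.approx(pp.duration[i] / TWO_PI, abs=2e-4)

    def test_engine_kernel_matches_reference(self, walking_preset, running_preset):
        from synergait.skeleton_dynamics import pack_control

        for preset in (walking_preset, running_preset):
            ctrl = pack_control(preset.pulses, preset.regulator)
            rng = np.random.default_rng(3)
            for phi in rng.uniform(0, TWO_PI, 40):
                u = np.zeros(18)
                _engine.synergy_commands(phi, ctrl, u)
                ref_r = synergy_command(PhaseState(phi, preset.pulses.T), preset.pulses, "right")
                ref_l = synergy_command(PhaseState(phi, preset.pulses.T), preset.pulses, "left")
                np.testing.assert_allclose(u[:9], ref_r, atol=1e-12)
                np.testing.assert_allclose(u[9:], ref_l, atol=1e-12)


class TestRegulators:
    def test_trunk_equilibrium(self, walking_preset):
        p = trunk_regulator(0.01, 0.0, True, walking_preset.regulator)
        np.testing.assert_allclose(p, 0.0)

    def test_trunk_printed_gains(self, walking_preset):
        p = trunk_regulator(0.11, 0.0, True, walking_preset.regulator)
        assert p[GM] == pytest.approx(-0.20)
        assert p[IL] == pytest.approx(+0.10)
        assert np.all(p[[VA, BFS, TA, SO, RF, BFL, GC]] == 0.0)

    def test_trunk_swing_leg_silent(self, walking_preset):
        p = trunk_regulator(0.5, 1.0, False, walking_preset.regulator)
        np.testing.assert_allclose(p, 0.0)

    def test_speed_printed_gains(self, walking_preset):
        p = speed_regulator(1.5, True, walking_preset.regulator)
        assert p[SO] == pytest.approx(0.004)
        assert p[TA] == pytest.approx(-0.02)
        assert speed_regulator(1.6, True, walking_preset.regulator).sum() == 0.0
        assert np.all(speed_regulator(1.0, False, walking_preset.regulator) == 0.0)


class TestDelayLine:
    def test_startup_zero(self):
        dl = DelayLine(tau=0.08, dt=0.01, width=9)
        for k in range(5):  # t < tau
            dl.push(np.full(9, 7.0))
            assert np.all(delayed_regulator(k * 0.01, dl) == 0.0)

    def test_step_delayed_by_tau(self):
        dl = DelayLine(tau=0.08, dt=0.01, width=1)
        seen = []
        for k in range(30):
            t = k * 0.01
            dl.push(np.array([0.0 if t < 0.1 else 0.004]))
            seen.append(delayed_regulator(t, dl)[0])
        t_arr = np.arange(30) * 0.01
        # output steps exactly at t = 0.1 + 0.08
        assert all(v == 0.0 for v, t in zip(seen, t_arr) if t < 0.18 - 1e-12)
        assert all(v == pytest.approx(0.004) for v, t in zip(seen, t_arr) if t >= 0.18)

    def test_constant_history_passthrough(self):
        dl = DelayLine(tau=0.05, dt=0.01, width=2)
        for _ in range(20):
            dl.push(np.array([1.5, -0.5]))
        np.testing.assert_allclose(delayed_regulator(0.2, dl), [1.5, -0.5])

    def test_zero_delay_is_instantaneous(self):
        dl = DelayLine(tau=0.0, dt=0.01, width=1)
        dl.push(np.array([0.25]))
        assert delayed_regulator(0.0, dl)[0] == 0.25


class TestTotalCommand:
    def test_sum_and_clamp(self):
        assert total_command(np.array([1.02]), np.array([0.0]))[0] == pytest.approx(1.02)
        assert total_command(np.array([0.0]), np.array([-0.02]))[0] == 0.0
        assert total_command(np.array([1.09]), np.array([0.004]))[0] == pytest.approx(1.094)
        assert total_command(np.array([2.0]), np.array([0.0]), u_max=1.5)[0] == 1.5


class TestRegulatorContribution:
    def test_zero_and_symmetric(self):
        u_syn = np.abs(np.random.default_rng(0).normal(size=(50, 9))) + 0.1
        assert regulator_contribution(u_syn, np.zeros_like(u_syn)) == 0.0
        # u_reg equal to u_syn everywhere: regulator is half the total command
        assert regulator_contribution(2 * u_syn, u_syn) == pytest.approx(50.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            regulator_contribution(np.zeros((5, 9)), np.zeros((5, 9)))

    def test_modes(self):
        u = np.ones((4, 9))
        ureg = np.zeros((4, 9))
        ureg[:, [TA, SO]] = 0.5
        assert regulator_contribution(u, ureg, "all") == pytest.approx(100 * 4 / 36)
        assert regulator_contribution(u, ureg, "speed") == pytest.approx(100 * 4 / 36)
        assert regulator_contribution(u, ureg, "taso") == pytest.approx(50.0)
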