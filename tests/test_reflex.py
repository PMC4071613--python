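"""Reflex-network tests: state machine, clamps, gating, delays,
pathway table and the direct-map equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurogait.reflex import (DEFAULT_BASAL, DelayLine, LimbState,
                              ReflexController, SensorSample, StateMachine,
                              build_default_pathways, delay_steps,
                              interneuron_update, motoneuron_update,
                              stimulation_clamp, trunk_balance_signal,
                              update_limb_state)


class TestLimbStateMachine:
    def test_unloaded_limb_swings(self):
        assert update_limb_state(0.05, LimbState.ST, LimbState.ST,
                                 LimbState.ST) == LimbState.SW

    def test_contralateral_touchdown_triggers_stance_end(self):
        s = update_limb_state(0.5, LimbState.ST, LimbState.ST, LimbState.SW)
        assert s == LimbState.STEND

    def test_loaded_with_steady_contra_swing_is_stance(self):
        s = update_limb_state(0.5, LimbState.SW, LimbState.ST, LimbState.SW)
        assert s == LimbState.ST

    def test_stance_end_persists_until_takeoff(self):
        s = update_limb_state(0.5, LimbState.ST, LimbState.STEND, LimbState.ST)
        assert s == LimbState.STEND
        s = update_limb_state(0.05, LimbState.ST, LimbState.STEND, LimbState.ST)
        assert s == LimbState.SW

    def test_state_machine_logs_events(self):
        sm = StateMachine()
        grf = np.array([0.5, 0.5])
        sm.update(grf, 0.0)
        sm.update(np.array([0.05, 0.5]), 0.1)  # left takeoff
        sm.update(np.array([0.5, 0.5]), 0.4)  # left touchdown
        assert sm.takeoffs[0] == [0.1]
        assert sm.touchdowns[0] == [0.4]
        # the loaded right limb saw the left touchdown -> finishing stance
        assert sm.states[1] == LimbState.STEND

    def test_flight_phase_both_swing(self):
        sm = StateMachine()
        sm.update(np.array([0.0, 0.0]), 0.0)
        assert sm.states == [LimbState.SW, LimbState.SW]


class TestLayers:
    def test_interneuron_affine_and_clamp(self):
        v = interneuron_update(np.array([[2.0, -1.0]]), np.array([0.3, 0.4]))
        assert v[0] == pytest.approx(0.2)
        assert interneuron_update(np.zeros((1, 3)), np.ones(3))[0] == 0.0
        assert interneuron_update(np.array([[10.0]]), np.array([0.37]))[0] == 1.0

    def test_interneuron_dimension_mismatch(self):
        with pytest.raises(ValueError):
            interneuron_update(np.ones((1, 2)), np.ones(3))

    def test_motoneuron_passthrough_without_gates(self):
        x0 = np.array([0.1, 0.7])
        out = motoneuron_update(np.zeros((2, 3)), np.ones(3), x0)
        assert np.allclose(out, x0)

    def test_motoneuron_gate_selects_contributions(self):
        G = np.zeros((2, 2))
        G[0, 1] = 1.0
        out = motoneuron_update(G, np.array([0.9, 0.4]), np.zeros(2))
        assert out[0] == pytest.approx(0.4)
        assert out[1] == 0.0

    @given(st.floats(-2, 2))
    @settings(deadline=None, max_examples=50)
    def test_stimulation_clamp_range(self, x):
        y = stimulation_clamp(x)
        assert 0.01 <= y <= 1.0
        if 0.01 <= x <= 1.0:
            assert y == x

    def test_trunk_balance_pd(self):
        ref = 0.1
        # at the reference with zero rate: no correction
        v = trunk_balance_signal(ref, 0.0, ref, 2.0, 0.5, grf=1.0)
        assert all(x == 0.0 for x in v.values())
        # unloaded limb: no correction regardless of lean
        v = trunk_balance_signal(ref + 0.3, 1.0, ref, 2.0, 0.5, grf=0.0)
        assert all(x == 0.0 for x in v.values())
        # forward lean excites extensors, inhibits the flexor;
        # adding a forward rate strengthens the correction
        lean = trunk_balance_signal(ref + 0.2, 0.0, ref, 2.0, 0.5, grf=1.0)
        lean_rate = trunk_balance_signal(ref + 0.2, 0.5, ref, 2.0, 0.5, grf=1.0)
        assert lean["GLU"] > 0 and lean["HAM"] > 0 and lean["HF"] < 0
        assert lean_rate["GLU"] > lean["GLU"]


class TestDelayLine:
    @given(st.integers(1, 9))
    @settings(deadline=None, max_examples=20)
    def test_exact_shift_for_integer_delays(self, lag):
        rng = np.random.default_rng(0)
        x = rng.random(40)
        dl = DelayLine(1, 10)
        outs = []
        for v in x:
            dl.push([v])
            outs.append(dl.read(lag)[0])
        # after the prefill transient the output is the input shifted
        assert np.allclose(outs[lag:], x[:-lag])

    def test_prefill_with_first_sample(self):
        dl = DelayLine(1, 5)
        dl.push([0.7])
        assert dl.read(5)[0] == 0.7

    def test_per_component_lags(self):
        dl = DelayLine(2, 5)
        for i in range(10):
            dl.push([i, 10 * i])
        out = dl.read(np.array([2, 4]))
        assert out[0] == 7 and out[1] == 50

    def test_half_step_delay_rounds_up(self):
        assert delay_steps(2.5e-3, 1e-3) == 3
        assert delay_steps(5e-3, 1e-3) == 5
        assert delay_steps(10e-3, 1e-3) == 10


class TestPathwayTable:
    def test_fifteen_pathways_per_limb(self, pathways):
        assert len(pathways) == 15

    def test_nine_muscle_sensor_pathways(self, pathways):
        assert sum(p.is_muscle_sensor for p in pathways) == 9

    def test_negative_pathways_match_table(self, pathways):
        neg = {p.name for p in pathways if p.sign < 0}
        assert neg == {"TA<-SOL MFF ST", "HF<-HAM MLF SW", "HF<-HF MLF SW",
                       "HF<-GSIF ST", "VAS<-GCF STend", "VAS<-KNEE OPF"}

    def test_gcf_pathway_is_stance_end_inhibition(self, pathways):
        p = next(p for p in pathways if p.name == "VAS<-GCF STend")
        assert p.sign == -1
        assert p.phase == "stance_end"
        assert p.source == "cFoot"


class TestControllerStep:
    @staticmethod
    def _quiet_sensors():
        return SensorSample(m_force=np.zeros((2, 7)),
                            m_length=np.full((2, 7), 1.0),
                            knee_over=np.zeros(2), grf=np.array([0.5, 0.5]),
                            pitch=0.0, pitch_rate=0.0)

    def test_quiet_input_yields_basal_stimulation(self):
        ctl = ReflexController()
        stim = None
        for _ in range(15):  # flush delay lines
            stim, _ = ctl.step(self._quiet_sensors(),
                               [LimbState.ST, LimbState.ST])
        basal = np.array([DEFAULT_BASAL[m] for m in
                          ("GLU", "HF", "VAS", "SOL", "TA", "HAM", "GAS")])
        expected = np.clip(basal, 0.01, 1.0)
        # TA<-TA length pathway fires at l_ce = l_opt (above its offset)
        expected_ta = np.clip(basal[4] + ctl.pathways[6].gain *
                              (1.0 - ctl.pathways[6].l_off), 0.01, 1.0)
        assert np.allclose(stim[0, [0, 1, 2, 3, 5, 6]],
                           expected[[0, 1, 2, 3, 5, 6]])
        assert stim[0, 4] == pytest.approx(expected_ta)

    def test_phase_ineligible_pathway_changes_nothing(self):
        """Toggling a swing pathway's input while the limb stands must
        leave every motoneuron untouched."""
        ctl_a = ReflexController()
        ctl_b = ReflexController()
        s_a = self._quiet_sensors()
        s_b = self._quiet_sensors()
        s_b.m_force[:, 0] = 0.9  # GLU force feedback: swing-gated
        out = []
        for ctl, s in ((ctl_a, s_a), (ctl_b, s_b)):
            for _ in range(15):
                stim, _ = ctl.step(SensorSample(s.m_force.copy(),
                                                s.m_length.copy(),
                                                s.knee_over.copy(),
                                                s.grf.copy(), s.pitch,
                                                s.pitch_rate),
                                   [LimbState.ST, LimbState.ST])
            out.append(stim)
        assert np.array_equal(out[0], out[1])

    def test_outputs_always_in_declared_ranges(self):
        rng = np.random.default_rng(3)
        ctl = ReflexController()
        states = [LimbState.ST, LimbState.SW]
        for _ in range(50):
            s = SensorSample(m_force=rng.random((2, 7)) * 2,
                             m_length=rng.random((2, 7)) * 2,
                             knee_over=rng.random(2),
                             grf=rng.random(2) * 1.5,
                             pitch=rng.normal() * 0.3,
                             pitch_rate=rng.normal())
            stim, in_sen = ctl.step(s, states)
            assert np.all((in_sen >= 0) & (in_sen <= 1))
            assert np.all((stim >= 0.01) & (stim <= 1))

    def test_equivalent_to_direct_sensor_muscle_map(self):
        """With the interneuron stage being a gain and the motoneuron a
        gated sum, the layered network equals a direct delayed affine
        sensor->stimulation map when the total loop delay matches."""
        ctl = ReflexController()
        rng = np.random.default_rng(5)
        forces = rng.random((80, 2, 7))
        stims = []
        for i in range(80):
            s = SensorSample(m_force=forces[i],
                             m_length=np.full((2, 7), 0.5),
                             knee_over=np.zeros(2),
                             grf=np.array([0.5, 0.5]),
                             pitch=0.0, pitch_rate=0.0)
            stim, _ = ctl.step(s, [LimbState.ST, LimbState.ST])
            stims.append(stim.copy())
        # SOL stimulation: basal + gain * F_SOL delayed by 2*10 ms
        gain = ctl.pathways[3].gain
        basal = DEFAULT_BASAL["SOL"]
        for i in range(25, 80):
            direct = np.clip(
                np.clip(basal + gain * np.clip(forces[i - 20, 0, 3], 0, 1),
                        0, 1), 0.01, 1)
            assert stims[i][0, 3] == pytest.approx(direct)
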