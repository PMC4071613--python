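"""CPG tests: shaping extraction, morphed-oscillator dynamics, phase
synchronization, blend algebra and network construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurogait.cpg import (PRESETS, CombinationConfig, CpgNetwork,
                           OscillatorState, ShapingFunction,
                           apply_supraspinal, build_cpg_network,
                           combine_motoneurons, constant_predictor,
                           extract_shaping_function, oscillator_step,
                           phase_advance, phase_at, slowdown_rate)
from neurogait.reflex import build_default_pathways


def _flat_shape(level=0.5):
    return ShapingFunction.from_samples(np.full(64, level), 1)


def _cosine_shape():
    theta = np.arange(128) / 128
    return ShapingFunction.from_samples(0.5 + 0.4 * np.cos(2 * np.pi * theta), 1)


class TestShapingFunction:
    def test_periodic_closure(self):
        g = _cosine_shape()
        assert float(g(0.0)) == pytest.approx(float(g(1.0)))

    def test_identical_cycles_recovered(self):
        t = np.arange(0, 10.0, 1e-3)
        sig = 0.4 + 0.3 * np.sin(2 * np.pi * t)
        events = np.arange(0.0, 10.0 + 1e-9, 1.0)
        g = extract_shaping_function(sig, t, events)
        theta = np.linspace(0, 1, 200, endpoint=False)
        expected = 0.4 + 0.3 * np.sin(2 * np.pi * theta)
        assert np.max(np.abs(g(theta) - expected)) < 1e-4

    def test_noise_averages_out_with_cycles(self):
        """Zero-mean noise shrinks roughly like 1/sqrt(N) in the mean."""
        rng = np.random.default_rng(11)
        t = np.arange(0, 50.0, 1e-3)
        clean = 0.5 + 0.25 * np.sin(2 * np.pi * t)
        noisy = clean + 0.1 * rng.standard_normal(len(t))
        theta = np.linspace(0, 1, 200, endpoint=False)
        truth = 0.5 + 0.25 * np.sin(2 * np.pi * theta)
        errs = {}
        for n_cyc in (4, 49):
            events = np.arange(0.0, n_cyc + 1.0 + 1e-9, 1.0)
            g = extract_shaping_function(noisy[t <= n_cyc + 1], t[t <= n_cyc + 1],
                                         events)
            errs[n_cyc] = np.sqrt(np.mean((g(theta) - truth) ** 2))
        assert errs[49] < 0.6 * errs[4]

    def test_requires_two_cycles(self):
        t = np.arange(0, 1.5, 1e-3)
        with pytest.raises(ValueError):
            extract_shaping_function(np.sin(t), t, np.array([0.0, 1.0]))

    def test_rejects_unordered_events(self):
        t = np.arange(0, 5.0, 1e-3)
        with pytest.raises(ValueError):
            extract_shaping_function(np.sin(t), t,
                                     np.array([0.0, 2.0, 1.0, 3.0]))

    def test_samples_clamped_to_unit_interval(self):
        g = ShapingFunction.from_samples(np.linspace(-0.5, 1.5, 64), 1)
        knots = np.arange(64) / 64
        # the fitted samples themselves are clamped into [0, 1]; between
        # knots only bounded spline ringing remains
        assert np.all((g(knots) >= 0.0) & (g(knots) <= 1.0))
        theta = np.linspace(0, 1, 300)
        assert g(theta).min() >= -0.2 and g(theta).max() <= 1.2


class TestConstantPredictor:
    def test_constant_signal(self):
        assert constant_predictor(np.full(100, 0.37),
                                  np.ones(100, dtype=bool)) == pytest.approx(0.37)

    def test_full_cycle_mean_of_sinusoid(self):
        t = np.linspace(0, 1, 10000, endpoint=False)
        sig = 0.5 + 0.3 * np.sin(2 * np.pi * t)
        assert constant_predictor(sig, np.ones_like(t, dtype=bool)) == \
            pytest.approx(0.5, abs=1e-6)

    def test_masked_samples_only(self):
        sig = np.concatenate([np.full(50, 0.8), np.full(50, 0.2)])
        mask = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        assert constant_predictor(sig, mask) == pytest.approx(0.8)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            constant_predictor(np.ones(10), np.zeros(10, dtype=bool))


class TestOscillator:
    def test_constant_shape_fixed_point(self):
        g = _flat_shape(0.5)
        st_ = OscillatorState(theta=0.0, x=0.5, omega=1.0)
        for _ in range(100):
            oscillator_step(st_, g, 1e-3)
        assert st_.x == pytest.approx(0.5, abs=1e-9)

    def test_offset_decays_at_rate_gamma(self):
        """x started one unit off the limit cycle decays like exp(-gamma t)
        because the feedforward dg term keeps the tracking error linear."""
        g = _cosine_shape()
        st_ = OscillatorState(theta=0.0, x=float(g(0.0)) + 1.0, omega=1.0,
                              gamma=100.0)
        for _ in range(50):  # 0.05 s
            oscillator_step(st_, g, 1e-3)
        offset = st_.x - float(g(st_.theta))
        assert offset == pytest.approx(math.exp(-5.0), rel=1e-2)

    def test_limit_cycle_tracking_over_ten_cycles(self):
        g = _cosine_shape()
        st_ = OscillatorState(theta=0.0, x=float(g(0.0)), omega=1.0)
        worst = 0.0
        for i in range(10000):  # 10 cycles at 1 Hz
            oscillator_step(st_, g, 1e-3)
            worst = max(worst, abs(st_.x - float(g(st_.theta))))
        assert worst < 1e-4

    def test_frequency_sets_cycle_duration(self):
        st1 = OscillatorState(omega=1.0)
        st2 = OscillatorState(omega=2.0)
        g = _flat_shape()
        for _ in range(500):
            oscillator_step(st1, g, 1e-3)
            oscillator_step(st2, g, 1e-3)
        # at t = 0.5 s: omega=2 has hit its slowdown (theta ~ 0.93),
        # omega=1 sits at exactly 0.5
        assert st1.theta == pytest.approx(0.5, abs=1e-9)
        assert st2.theta > 0.9


class TestPhaseSync:
    def test_linear_phase_before_onset(self):
        assert phase_at(0.5 / 1.3, 1.3) == pytest.approx(0.5)

    def test_slowdown_rate_continuous_at_onset(self):
        for omega in (0.3, 1.0, 2.5):
            assert slowdown_rate(0.9 / omega, omega) == pytest.approx(omega)

    def test_printed_slowdown_closed_form(self):
        # c(t) = 10 w exp(-10 w t - ln 10 + 9) for p = 0.9
        for omega, t in ((0.8, 1.4), (1.7, 0.7)):
            printed = 10 * omega * math.exp(-10 * omega * t - math.log(10) + 9)
            assert slowdown_rate(t, omega) == pytest.approx(printed, rel=1e-12)

    def test_late_event_resets_phase(self):
        st_ = OscillatorState(omega=1.0)
        st_.t_since = 1.5  # t > 1/omega: the oscillator lags
        st_.theta = phase_at(1.5, 1.0)
        phase_advance(st_, sync_event=True, dt=1e-3)
        assert st_.theta == 0.0 and st_.t_since == 0.0

    def test_phase_rate_before_onset_is_omega(self):
        st_ = OscillatorState(omega=1.0)
        phase_advance(st_, False, 1e-3)
        assert st_.theta == pytest.approx(1e-3)

    @given(st.floats(0.2, 2.5), st.integers(0, 10 ** 6))
    @settings(deadline=None, max_examples=200)
    def test_phase_never_exceeds_one(self, omega, seed):
        """Randomized event jitter never drives theta past 1."""
        rng = np.random.default_rng(seed)
        st_ = OscillatorState(omega=omega)
        for _ in range(50):
            dt = rng.uniform(5e-4, 0.3)
            sync = rng.random() < 0.2
            phase_advance(st_, sync, dt)
            assert 0.0 <= st_.theta <= 1.0


class TestCombination:
    @given(st.integers(0, 10 ** 6))
    @settings(deadline=None, max_examples=50)
    def test_blend_and_corrective_forms_identical(self, seed):
        rng = np.random.default_rng(seed)
        n = 9
        sen = rng.random(n)
        cpg = rng.random(n)
        alpha = np.full(n, 0.37)
        G = rng.integers(0, 2, size=(7, n)).astype(float)
        x0 = rng.random(7) * 0.1
        a = combine_motoneurons(sen, cpg, alpha, G, x0, form="blend")
        b = combine_motoneurons(sen, cpg, alpha, G, x0, form="corrective")
        assert np.array_equal(a, b) or np.allclose(a, b, rtol=0, atol=5e-16)

    def test_alpha_one_reduces_to_pure_feedback(self):
        rng = np.random.default_rng(1)
        sen = rng.random(5)
        cpg = rng.random(5)
        G = np.eye(5)
        x0 = np.zeros(5)
        out = combine_motoneurons(sen, cpg, np.ones(5), G, x0)
        pure = np.clip(G @ sen + x0, 0, 1)
        assert np.array_equal(out, pure)

    def test_alpha_zero_ignores_feedback(self):
        sen = np.array([0.9, 0.1])
        cpg = np.array([0.2, 0.8])
        out = combine_motoneurons(sen, cpg, np.zeros(2), np.eye(2), np.zeros(2))
        assert np.allclose(out, cpg)

    def test_convex_between_endpoints(self):
        rng = np.random.default_rng(2)
        sen = rng.random(6)
        cpg = rng.random(6)
        alpha = np.full(6, 0.4)
        mix = alpha * sen + (1 - alpha) * cpg
        assert np.all(mix >= np.minimum(sen, cpg) - 1e-15)
        assert np.all(mix <= np.maximum(sen, cpg) + 1e-15)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_motoneurons(np.ones(3), np.ones(2), np.ones(3),
                                np.eye(3), np.zeros(3))


class TestNetwork:
    def _network(self, synthetic_gait, preset="3FBL_ankle"):
        return build_cpg_network(synthetic_gait.pathways, PRESETS[preset],
                                 synthetic_gait)

    def test_four_clocks(self, synthetic_gait):
        net = self._network(synthetic_gait)
        assert len(net.clocks) == 4

    def test_default_eligibility_is_muscle_sensors(self, synthetic_gait):
        cfg = CombinationConfig(modes={"HF<-GSIF ST": "osc"},
                                alpha={"HF<-GSIF ST": 0.5})
        with pytest.raises(ValueError):
            build_cpg_network(synthetic_gait.pathways, cfg, synthetic_gait)

    def test_nine_predictors_per_limb_when_all_bound(self, synthetic_gait):
        names = [p.name for p in synthetic_gait.pathways if p.is_muscle_sensor]
        cfg = CombinationConfig(modes={n: "osc" for n in names},
                                alpha={n: 0.5 for n in names})
        net = build_cpg_network(synthetic_gait.pathways, cfg, synthetic_gait)
        assert net.n_oscillators(0) == 9
        assert net.n_oscillators() == 18

    def test_swing_pathway_binds_takeoff_clock(self, synthetic_gait):
        cfg = CombinationConfig(modes={"HF<-HF MLF SW": "osc"},
                                alpha={"HF<-HF MLF SW": 0.5})
        net = build_cpg_network(synthetic_gait.pathways, cfg, synthetic_gait)
        k = [p.name for p in synthetic_gait.pathways].index("HF<-HF MLF SW")
        pred = net.predictors[0][k]
        assert net.CLOCKS[pred.clock] == ("L", "takeoff")

    def test_omega_estimated_from_recording(self, synthetic_gait):
        net = self._network(synthetic_gait)
        mean_cycle = np.mean(np.diff(synthetic_gait.touchdowns[0]))
        assert net.omega == pytest.approx(1.0 / mean_cycle)

    def test_supraspinal_scaling_and_validation(self, synthetic_gait):
        net = self._network(synthetic_gait)
        base = None
        for _ in range(400):
            net.step(1e-3, {})
        base = net.outputs().copy()
        apply_supraspinal(net, mu_osc=2.0)
        assert np.allclose(net.outputs(), 2.0 * base)
        apply_supraspinal(net, omega=1.7)
        assert all(c.omega == 1.7 for c in net.clocks)
        with pytest.raises(ValueError):
            apply_supraspinal(net, mu_osc=0.0)
        with pytest.raises(ValueError):
            apply_supraspinal(net, omega=-1.0)

    def test_alpha_map_with_unbound_pathways_is_one(self, synthetic_gait):
        net = self._network(synthetic_gait, "3FBL_biArt")
        a = net.alpha
        names = [p.name for p in synthetic_gait.pathways]
        k = names.index("HF<-HAM MLF SW")
        assert a[0, k] == pytest.approx(0.1)
        mask = np.ones(len(names), dtype=bool)
        mask[k] = False
        assert np.all(a[:, mask] == 1.0)
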