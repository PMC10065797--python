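import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lgkinetics import synthetic
from lgkinetics.differentiation import (LN81, classify_trajectory,
                                        fast_phase_bounds,
                                        fast_phase_bounds_from_params,
                                        fit_differentiation_rate, logistic4,
                                        normalize_dual_channel)
from lgkinetics.errors import (DegenerateTrackError, InsufficientDataError,
                               ValidationError)
from lgkinetics.trackio import IntensityTrack, RunConfig

from conftest import random_track


def make_track(green, red, dt_min=0.25, cell_id="t"):
    n = len(green)
    return IntensityTrack(cell_id, np.arange(n), np.arange(n) * dt_min,
                          np.asarray(green, float), np.asarray(red, float))


class TestNormalization:
    def test_worked_example(self):
        norm = normalize_dual_channel(make_track([0, 10], [5, 10]))
        assert np.allclose(norm.norm_green, [0.0, 1.0])
        assert np.allclose(norm.norm_red, [0.5, 1.0])

    def test_joint_min_zero_max_one(self, rng):
        for _ in range(50):
            norm = normalize_dual_channel(random_track(rng))
            both = np.concatenate([norm.norm_green, norm.norm_red])
            assert both.min() == pytest.approx(0.0)
            assert both.max() == pytest.approx(1.0)

    def test_equals_bruteforce_formula_on_1000_random_tracks(self, rng):
        """Element-wise re-evaluation of the printed min-max equations."""
        for i in range(1000):
            tr = random_track(rng, cell_id=f"r{i}")
            norm = normalize_dual_channel(tr)
            lo = min(tr.green.min(), tr.red.min())
            hi = max(tr.green.max(), tr.red.max())
            for k in range(tr.n_frames):
                assert norm.norm_green[k] == pytest.approx(
                    (tr.green[k] - lo) / (hi - lo), abs=1e-12)
                assert norm.norm_red[k] == pytest.approx(
                    (tr.red[k] - lo) / (hi - lo), abs=1e-12)

    def test_degenerate_track_rejected(self):
        with pytest.raises(DegenerateTrackError):
            normalize_dual_channel(make_track([3, 3, 3], [3, 3, 3]))

    def test_idempotent_on_normalized_values(self, rng):
        tr = random_track(rng, n=20)
        norm = normalize_dual_channel(tr)
        again = normalize_dual_channel(
            make_track(norm.norm_green, norm.norm_red))
        assert np.allclose(again.norm_green, norm.norm_green)
        assert np.allclose(again.norm_red, norm.norm_red)
        assert again.norm_min == pytest.approx(0.0)
        assert again.norm_max == pytest.approx(1.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(99)
        tr = random_track(rng, n=30)
        scaled = make_track(tr.green * c, tr.red * c)
        a, b = normalize_dual_channel(tr), normalize_dual_channel(scaled)
        assert np.allclose(a.norm_green, b.norm_green)
        assert np.allclose(a.norm_red, b.norm_red)
        assert np.allclose(a.ratio, b.ratio)


class TestClassification:
    def test_noiseless_sigmoid_recovered(self):
        m = synthetic.DifferentiationModel.for_kind("sigmoid_wt", noise_cv=0.0)
        tr = synthetic.simulate_differentiation_track(m, 1280, seed=1)
        fit = classify_trajectory(normalize_dual_channel(tr))
        assert fit.trajectory_class == "sigmoid"
        _, _, t0, tau = fit.logistic_params
        assert abs(t0 - (m.t_mid + m.delay)) <= m.tau

    def test_exact_line_is_linear_with_exact_rate(self):
        t = np.arange(120) * 0.25
        ratio = 0.2 + 0.004 * t
        # constant red, green constructed so red/green equals the target line
        red = np.full_like(t, 80.0)
        green = red / ratio
        fit = classify_trajectory(normalize_dual_channel(
            make_track(green, red)))
        assert fit.trajectory_class == "linear"
        assert fit.rate == pytest.approx(0.004, rel=1e-9)

    def test_too_few_frames(self):
        tr = make_track(np.linspace(10, 5, 8), np.linspace(1, 9, 8))
        with pytest.raises(InsufficientDataError):
            classify_trajectory(normalize_dual_channel(tr))

    def test_scale_invariant_class_and_rate(self):
        m = synthetic.DifferentiationModel.for_kind("sigmoid_wt", noise_cv=0.0)
        tr = synthetic.simulate_differentiation_track(m, 1280, seed=2)
        scaled = make_track(tr.green * 7.3, tr.red * 7.3)
        a = classify_trajectory(normalize_dual_channel(tr))
        b = classify_trajectory(normalize_dual_channel(scaled))
        assert a.trajectory_class == b.trajectory_class == "sigmoid"
        assert a.rate == pytest.approx(b.rate, rel=1e-6)

    def test_flat_noise_never_sigmoid(self):
        """Specificity: pure-noise flat-ratio tracks are classified ambiguous
        or linear with near-zero rate, essentially never sigmoid."""
        rng = np.random.default_rng(7)
        n_sigmoid = 0
        n_runs = 400
        for i in range(n_runs):
            g = np.clip(100 * (1 + rng.normal(0, 0.2, 240)), 0, None)
            r = np.clip(50 * (1 + rng.normal(0, 0.2, 240)), 0, None)
            fit = classify_trajectory(normalize_dual_channel(
                make_track(g, r, cell_id=f"f{i}")))
            if fit.trajectory_class == "sigmoid":
                n_sigmoid += 1
            elif fit.trajectory_class == "linear":
                assert abs(fit.rate) < 0.01
        assert n_sigmoid / n_runs <= 0.01

    def test_labeled_cohort_agreement(self):
        """>= 95% label agreement at noise_cv = 0.1 (smoke-scale cohort;
        the full-scale suite runs in the acceptance tests)."""
        for kind in synthetic.DIFFERENTIATION_KINDS:
            tracks = synthetic.simulate_differentiation_cohort(
                kind, 40, seed=21, noise_cv=0.1)
            calls = [classify_trajectory(normalize_dual_channel(t)).trajectory_class
                     for t in tracks]
            agree = np.mean([c == kind.split("_")[0] for c in calls])
            assert agree >= 0.95, kind


class TestRates:
    def test_linear_rate_arithmetic(self):
        t = np.arange(401) * 0.25  # 0..100 min
        ratio = t / 100.0 + 0.05
        red = np.full_like(t, 60.0)
        fit = classify_trajectory(normalize_dual_channel(
            make_track(red / ratio, red)))
        assert fit.trajectory_class == "linear"
        assert fit.rate == pytest.approx(0.01, rel=1e-6)

    def test_logistic_closed_form_rate(self):
        """Noiseless logistic with A = 1, tau = 10: the 10-90% fast-phase
        rate is 0.8 / (ln(81) * 10) ~= 0.0182 per min."""
        t = np.arange(1200) * 0.25  # 300 min
        ratio = logistic4(t, 0.05, 1.0, 150.0, 10.0)
        red = np.full_like(t, 90.0)
        green = red / ratio
        fit = classify_trajectory(normalize_dual_channel(make_track(green, red)))
        assert fit.trajectory_class == "sigmoid"
        expected = 0.8 / (LN81 * 10.0)
        assert fit.rate == pytest.approx(expected, rel=0.01)

    def test_rate_recovery_noiseless_all_kinds(self):
        """Estimated rate within 2% of the generative rate, noiseless."""
        for kind in synthetic.DIFFERENTIATION_KINDS:
            m = synthetic.DifferentiationModel.for_kind(kind, noise_cv=0.0)
            tr = synthetic.simulate_differentiation_track(
                m, synthetic.DEFAULT_N_FRAMES[kind], seed=1)
            fit = classify_trajectory(normalize_dual_channel(tr))
            gen = m.generative_rate(tr.times_min)
            assert abs(fit.rate - gen) / gen < 0.02, kind

    def test_sigmoid_faster_than_linear_on_default_cohorts(self):
        rates = {}
        for kind in ("sigmoid_wt", "linear_wt"):
            tracks = synthetic.simulate_differentiation_cohort(
                kind, 15, seed=8, noise_cv=0.1)
            rates[kind] = np.mean([
                classify_trajectory(normalize_dual_channel(t)).rate
                for t in tracks])
        assert rates["sigmoid_wt"] > rates["linear_wt"]

    def test_rate_undefined_for_ambiguous(self, rng):
        tr = random_track(rng, n=30)
        norm = normalize_dual_channel(tr)
        fit = classify_trajectory(norm)
        fit.trajectory_class = "ambiguous"
        with pytest.raises(ValidationError):
            fit_differentiation_rate(norm, fit)


class TestFastPhase:
    def test_duration_is_ln81_tau(self):
        lo, hi = fast_phase_bounds_from_params(t0=100.0, tau=10.0)
        assert hi - lo == pytest.approx(LN81 * 10.0, rel=1e-12)

    def test_step_limit(self):
        lo, hi = fast_phase_bounds_from_params(t0=100.0, tau=1e-9)
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_clipped_to_window(self):
        lo, hi = fast_phase_bounds_from_params(
            t0=10.0, tau=20.0, window=(0.0, 50.0))
        assert lo >= 0.0 and hi <= 50.0

    def test_only_defined_for_sigmoid(self):
        t = np.arange(60) * 0.25
        red = np.full_like(t, 60.0)
        fit = classify_trajectory(normalize_dual_channel(
            make_track(red / (0.2 + 0.01 * t), red)))
        assert fit.trajectory_class == "linear"
        with pytest.raises(ValidationError):
            fast_phase_bounds(fit)

    def test_infected_fast_phase_starts_later_than_wt(self):
        """The prolonged low/low intermediary phase after infection delays
        the switch."""
        starts = {}
        for kind in ("sigmoid_wt", "sigmoid_infected"):
            tracks = synthetic.simulate_differentiation_cohort(
                kind, 10, seed=31, noise_cv=0.1)
            fits = [classify_trajectory(normalize_dual_channel(t))
                    for t in tracks]
            starts[kind] = np.mean([f.fast_phase[0] for f in fits
                                    if f.trajectory_class == "sigmoid"])
        assert starts["sigmoid_infected"] > starts["sigmoid_wt"]
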