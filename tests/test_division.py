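import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lgkinetics import synthetic
from lgkinetics.division import (DivisionEvent, classify_division_axis,
                                 critical_size_metrics, division_duration,
                                 event_distances, mitotic_index,
                                 orientation_to_heart_tube,
                                 qq_orientation_bias, summarize_divisions)
from lgkinetics.errors import (DataError, InsufficientDataError,
                               ValidationError)
from lgkinetics.trackio import LGGeometry, RunConfig


class TestDuration:
    def test_default_offset_adds_ten_minutes(self, config):
        assert division_duration(0.0, 47.74, config) == pytest.approx(57.74)
        assert division_duration(0.0, 0.25, config) == pytest.approx(10.25)

    def test_zero_offset_passthrough(self):
        cfg = RunConfig(onset_offset_frames=0)
        assert division_duration(5.0, 17.0, cfg) == pytest.approx(12.0)

    def test_nonpositive_interval_rejected(self, config):
        with pytest.raises(DataError):
            division_duration(10.0, 10.0, config)


class TestAxisClassification:
    def test_examples(self, geometry, config):
        assert classify_division_axis([0, 0, 1], geometry, config) == "z"
        assert classify_division_axis([1, 0, 0], geometry, config) == "rho"

    def test_boundary_assigned_to_z(self, geometry, config):
        v = np.array([1.0, 0.0, 1.0]) / math.sqrt(2)  # exactly 45 deg to z
        assert classify_division_axis(v, geometry, config) == "z"

    def test_zero_vector_rejected(self, geometry, config):
        with pytest.raises(DataError):
            classify_division_axis([0, 0, 0], geometry, config)


class TestOrientation:
    def test_parallel_and_perpendicular(self, geometry):
        assert orientation_to_heart_tube([0, 1, 0], geometry) == pytest.approx(0.0)
        assert orientation_to_heart_tube([1, 0, 0], geometry) == pytest.approx(90.0)

    def test_antiparallel_folds_to_zero(self, geometry):
        assert orientation_to_heart_tube([0, -1, 0], geometry) == pytest.approx(0.0)

    def test_fold_bijective_on_rotation_sweep(self, geometry):
        """Brute-force sweep: an in-plane axis at angle theta to the tube
        recovers theta for all theta in [0, 180)."""
        e1 = np.array([0.0, 1.0, 0.0])   # tube direction
        e2 = np.cross(geometry.z_dir, e1)
        for theta in np.linspace(0.0, 179.9, 73):
            v = math.cos(math.radians(theta)) * e1 \
                + math.sin(math.radians(theta)) * e2
            got = orientation_to_heart_tube(v, geometry)
            assert got == pytest.approx(theta, abs=1e-9)

    def test_relabeling_maps_theta_to_180_minus(self, geometry):
        v = np.array([0.6, 0.8, 0.0])
        th = orientation_to_heart_tube(v, geometry)
        th_flip = orientation_to_heart_tube(-v, geometry)
        assert (th + th_flip) % 180.0 == pytest.approx(0.0, abs=1e-9)

    def test_vertical_axis_rejected(self, geometry):
        with pytest.raises(DataError):
            orientation_to_heart_tube([0, 0, 1], geometry)

    def test_rotation_equivariance(self, geometry):
        """Rotating geometry and axes together leaves class and theta
        unchanged."""
        rot = Rotation.from_euler("zyx", [33.0, 12.0, -41.0], degrees=True)
        g2 = LGGeometry(
            tube_point=rot.apply(geometry.tube_point),
            tube_dir=rot.apply(geometry.tube_dir),
            posterior_end=rot.apply(geometry.posterior_end),
            z_dir=rot.apply(geometry.z_dir),
            lobe_boundary=geometry.lobe_boundary)
        cfg = RunConfig()
        rng = np.random.default_rng(3)
        for _ in range(25):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            assert classify_division_axis(v, geometry, cfg) == \
                classify_division_axis(rot.apply(v), g2, cfg)
            if classify_division_axis(v, geometry, cfg) == "rho":
                a = orientation_to_heart_tube(v, geometry)
                b = orientation_to_heart_tube(rot.apply(v), g2)
                assert a == pytest.approx(b, abs=1e-6)


class TestQQ:
    def test_normal_sample_near_line(self):
        rng = np.random.default_rng(0)
        rep = qq_orientation_bias(rng.normal(90, 30, 1000))
        assert rep.r_squared > 0.99

    def test_bimodal_sample_below_normal(self):
        rng = np.random.default_rng(0)
        normal = qq_orientation_bias(rng.normal(90, 30, 500)).r_squared
        bimodal = qq_orientation_bias(
            np.concatenate([np.full(250, 10.0) + rng.normal(0, 0.5, 250),
                            np.full(250, 170.0) + rng.normal(0, 0.5, 250)]))
        assert bimodal.r_squared < normal - 0.05

    def test_five_angles_shape_contract(self):
        rep = qq_orientation_bias([10, 45, 90, 135, 170])
        assert len(rep.sample_quantiles) == 5
        assert len(rep.theoretical_quantiles) == 5
        assert np.isfinite([rep.line_intercept, rep.line_slope]).all()

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DataError):
            qq_orientation_bias([90.0] * 10)

    def test_type_one_rate_at_n50(self):
        """Under a true normal, r^2 < 0.95 is rare (< 5% of runs)."""
        rng = np.random.default_rng(123)
        low = sum(qq_orientation_bias(rng.normal(90, 30, 50)).r_squared < 0.95
                  for _ in range(200))
        assert low / 200 < 0.05


class TestCriticalSize:
    @staticmethod
    def _event(d1, d2, times):
        return DivisionEvent(
            event_id="e", t_breakdown_min=0.0, t_complete_min=40.0,
            position_um=[0, 0, 0], axis_vec=[1, 0, 0],
            mother_area_pre_um2=72.0,
            daughter_areas_um2=(np.asarray(d1, float), np.asarray(d2, float)),
            daughter_area_times_min=np.asarray(times, float))

    def test_constant_daughters(self):
        times = np.arange(0, 241, 15)
        ev = self._event(np.full(len(times), 36.0), np.full(len(times), 36.0),
                         times)
        mother, combined, growth = critical_size_metrics(ev)
        assert mother == 72.0
        assert combined == pytest.approx(72.0)
        assert growth == (0.0, 0.0)

    def test_growth_fraction(self):
        times = np.arange(0, 241, 15)
        d = np.linspace(30.0, 39.0, len(times))
        ev = self._event(d, d, times)
        _, _, growth = critical_size_metrics(ev)
        assert growth[0] == pytest.approx(0.30)

    def test_missing_series_partial_result(self):
        ev = DivisionEvent(event_id="e", t_breakdown_min=0.0,
                           t_complete_min=40.0, position_um=[0, 0, 0],
                           axis_vec=[1, 0, 0], mother_area_pre_um2=70.0)
        mother, combined, growth = critical_size_metrics(ev)
        assert mother == 70.0 and combined is None and growth is None

    def test_combined_daughters_exceed_mother_on_cohort(self, geometry):
        """Daughters regrow: summed area at +3 h exceeds the pre-mitotic
        mother area on average."""
        m = synthetic.DivisionCohortModel(n_events=200)
        events = synthetic.simulate_division_cohort(m, geometry, 6)
        diffs = []
        for ev in events:
            mother, combined, _ = critical_size_metrics(ev)
            diffs.append(combined - mother)
        assert np.mean(diffs) > 0


class TestIndexAndDistances:
    def test_mitotic_index(self):
        assert mitotic_index(0, 500) == 0.0
        assert mitotic_index(5, 500) == pytest.approx(0.01)
        with pytest.raises(ValidationError):
            mitotic_index(6, 5)
        with pytest.raises(ValidationError):
            mitotic_index(0, 0)

    def test_point_on_axis_and_at_posterior(self, geometry):
        on_axis = geometry.tube_point + 42.0 * geometry.tube_dir
        d_tube, _ = event_distances(on_axis, geometry)
        assert d_tube == pytest.approx(0.0, abs=1e-9)
        _, d_post = event_distances(geometry.posterior_end, geometry)
        assert d_post == pytest.approx(0.0, abs=1e-9)

    def test_against_bruteforce_line_distance(self, geometry, rng):
        """Dense sampling of points along the tube axis as an independent
        minimum-distance oracle."""
        s = np.linspace(-2000, 2000, 400001)
        axis_pts = geometry.tube_point + s[:, None] * geometry.tube_dir
        for _ in range(20):
            p = rng.uniform(-300, 300, 3)
            d_tube, d_post = event_distances(p, geometry)
            brute = np.sqrt(((axis_pts - p) ** 2).sum(axis=1)).min()
            assert d_tube == pytest.approx(brute, abs=1e-3)
            assert d_post == pytest.approx(np.linalg.norm(p - geometry.posterior_end))


class TestSummary:
    def test_rho_percent_from_printed_counts(self, geometry, config):
        """54 rho + 6 z events summarize to exactly 90% rho."""
        events = []
        for i in range(54):
            events.append(DivisionEvent(
                event_id=f"r{i}", t_breakdown_min=0.0, t_complete_min=43.9,
                position_um=[100, 0, 0], axis_vec=[1, 0, 0]))
        for i in range(6):
            events.append(DivisionEvent(
                event_id=f"z{i}", t_breakdown_min=0.0, t_complete_min=65.0,
                position_um=[100, 0, 0], axis_vec=[0, 0, 1]))
        from lgkinetics.division import annotate_events
        annotate_events(events, geometry, config)
        s = summarize_divisions(events)
        assert s["rho_percent"] == pytest.approx(90.0)
        assert s["n_rho"] == 54 and s["n_z"] == 6

    def test_empty_cohort_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_divisions([])
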