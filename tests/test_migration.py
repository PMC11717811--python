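import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliamig import migration, synthetic
from gliamig.errors import ParameterError

from oracles import brute_count_migrated

finite_coord = st.floats(-1e5, 1e5, allow_nan=False)


class TestNetDistance:
    def test_three_four_five(self):
        assert migration.net_distance((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_identical_points(self):
        assert migration.net_distance((2.5, -1), (2.5, -1)) == 0.0

    @given(x1=finite_coord, y1=finite_coord, x2=finite_coord, y2=finite_coord)
    @settings(max_examples=50, deadline=None)
    def test_matches_independent_recomputation(self, x1, y1, x2, y2):
        expected = ((x2 - x1) ** 2 + (y2 - y1) ** 2) ** 0.5
        assert migration.net_distance((x1, y1), (x2, y2)) == pytest.approx(expected)


class TestAxisDistance:
    def test_lateral_and_radial(self):
        assert migration.axis_distance((0, 0), (3, 4), "lateral_x") == 3.0
        assert migration.axis_distance((0, 0), (3, 4), "radial_y") == 4.0

    def test_symmetry(self):
        p1, p2 = (1.0, 2.0), (-4.0, 7.0)
        for axis in ("lateral_x", "radial_y"):
            assert migration.axis_distance(p1, p2, axis) == migration.axis_distance(p2, p1, axis)

    @given(x1=finite_coord, y1=finite_coord, x2=finite_coord, y2=finite_coord)
    @settings(max_examples=50, deadline=None)
    def test_pythagorean_identity(self, x1, y1, x2, y2):
        lat = migration.axis_distance((x1, y1), (x2, y2), "lateral_x")
        rad = migration.axis_distance((x1, y1), (x2, y2), "radial_y")
        net = migration.net_distance((x1, y1), (x2, y2))
        assert net**2 == pytest.approx(lat**2 + rad**2, rel=1e-12)

    def test_unknown_axis(self):
        with pytest.raises(ParameterError):
            migration.axis_distance((0, 0), (1, 1), "diagonal")


class TestMigrationSpeed:
    def test_simple_division(self):
        assert migration.migration_speed(100.0, 2.0) == 50.0

    def test_zero_distance(self):
        assert migration.migration_speed(0.0, 1.5) == 0.0

    def test_nonpositive_time(self):
        with pytest.raises(ParameterError):
            migration.migration_speed(10.0, 0.0)

    def test_speed_recovery_from_synthetic_tracks(self):
        tracks = synthetic.make_timelapse(500, 39.0, 10.0, 30.0, 5, seed=21)
        speeds = migration.speeds_from_tracks(tracks)
        assert abs(speeds["v_um_h"].mean() - 39.0) < 3 * 10.0 / np.sqrt(500)


class TestDeriveRecords:
    def test_invariant_exact(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "cell_id": range(n),
                "litter": "L1",
                "slice": "S1",
                "treatment": "control",
                "x1": rng.normal(size=n),
                "y1": rng.normal(size=n),
                "x2": rng.normal(size=n) * 100,
                "y2": rng.normal(size=n) * 100,
                "t_h": 2.0,
            }
        )
        out = migration.derive_records(df)
        np.testing.assert_allclose(out["net"] ** 2, out["lateral"] ** 2 + out["radial"] ** 2)
        np.testing.assert_allclose(out["v_um_h"], out["net"] / 2.0)

    def test_missing_columns(self):
        with pytest.raises(ParameterError):
            migration.derive_records(pd.DataFrame({"x1": [0]}))


class TestWhiteMatterCurve:
    def test_two_points_horizontal_segment(self):
        curve = migration.smooth_white_matter_curve([(0, 0), (100, 0)])
        assert curve.y_at(37.5) == pytest.approx(0.0)
        np.testing.assert_allclose(curve.samples[:, 1], 0.0, atol=1e-12)

    def test_interpolates_collinear_points_exactly(self):
        pts = [(0, 1), (10, 2), (20, 3), (30, 4)]
        curve = migration.smooth_white_matter_curve(pts, smoothing=0.0)
        for x, y in pts:
            assert curve.y_at(x) == pytest.approx(y, abs=1e-8)

    def test_noisy_sine_within_bound(self, rng):
        x = np.linspace(0, 200, 60)
        y_true = 20 * np.sin(x / 40)
        noisy = np.column_stack([x, y_true + rng.normal(0, 1.0, len(x))])
        curve = migration.smooth_white_matter_curve(noisy, smoothing=len(x) * 1.0)
        fitted = np.interp(x, curve.samples[:, 0], curve.samples[:, 1])
        assert np.max(np.abs(fitted - y_true)) < 5.0

    def test_duplicate_x_deduplicated(self, caplog):
        with caplog.at_level("WARNING"):
            curve = migration.smooth_white_matter_curve([(0, 0), (0, 2), (10, 1)])
        assert any("duplicate" in r.message for r in caplog.records)
        assert curve.control_points.shape[0] == 2

    def test_single_point_rejected(self):
        with pytest.raises(ParameterError):
            migration.smooth_white_matter_curve([(0, 0)])


class TestDistanceToCurve:
    def test_horizontal_curve_signed(self):
        curve = migration.smooth_white_matter_curve([(0, 0), (100, 0)])
        assert migration.distance_to_curve((10, 25), curve) == pytest.approx(25.0)
        assert migration.distance_to_curve((10, -25), curve) == pytest.approx(-25.0)

    def test_point_on_curve(self):
        curve = migration.smooth_white_matter_curve([(0, 0), (100, 0)])
        assert abs(migration.distance_to_curve((50, 0), curve)) < 0.5

    def test_45_degree_line_closed_form(self):
        curve = migration.smooth_white_matter_curve([(-50, -50), (50, 50)])
        d = migration.distance_to_curve((0, 10), curve)
        assert d == pytest.approx(10 / np.sqrt(2), abs=0.01)

    def test_horizontal_equals_abs_dy(self, rng):
        curve = migration.smooth_white_matter_curve([(0, 5), (500, 5)])
        for _ in range(50):
            x = rng.uniform(0, 500)
            y = rng.uniform(-100, 100)
            assert abs(migration.distance_to_curve((x, y), curve)) == pytest.approx(
                abs(y - 5), abs=0.5
            )

    def test_cortex_orientation_flip(self):
        curve = migration.smooth_white_matter_curve(
            [(0, 0), (100, 0)], cortex_positive_y=False
        )
        assert migration.distance_to_curve((10, 25), curve) == pytest.approx(-25.0)


def _scene(blobs, shape=(200, 200)):
    """Paint square blobs (y, x, size) onto a float image."""
    image = np.zeros(shape)
    for y, x, s in blobs:
        image[y : y + s, x : x + s] = 1.0
    return image


class TestCountMigrated:
    def test_planted_blobs_inside_and_outside(self):
        outside = [(10, 10, 6), (10, 180, 6), (180, 10, 6), (180, 180, 6), (10, 90, 6), (180, 90, 6), (90, 180, 6)]
        inside = [(95, 95, 6), (105, 105, 6)]
        image = _scene(outside + inside)
        counts = migration.count_migrated(
            image, (100.0, 100.0), 30.0, min_area_px=5,
            threshold_method="fixed", fixed_threshold=0.5,
        )
        assert counts["n_outside"] == 7
        assert counts["n_in_implant"] == 2

    def test_empty_image(self):
        counts = migration.count_migrated(
            np.zeros((50, 50)), (25.0, 25.0), 10.0,
            threshold_method="fixed", fixed_threshold=0.5,
        )
        assert counts["n_outside"] == 0

    def test_min_area_filter(self):
        image = _scene([(5, 5, 2), (40, 40, 10)], shape=(60, 60))
        counts = migration.count_migrated(
            image, (0.0, 0.0), 1.0, min_area_px=20,
            threshold_method="fixed", fixed_threshold=0.5,
        )
        assert counts["n_outside"] == 1
        assert counts["n_below_min_area"] == 1

    def test_translation_invariance(self):
        blobs = [(20, 20, 5), (60, 30, 5), (30, 70, 5)]
        image_a = _scene(blobs, (120, 120))
        image_b = _scene([(y + 10, x + 10, s) for y, x, s in blobs], (120, 120))
        a = migration.count_migrated(
            image_a, (25.0, 25.0), 12.0, threshold_method="fixed", fixed_threshold=0.5
        )
        b = migration.count_migrated(
            image_b, (35.0, 35.0), 12.0, threshold_method="fixed", fixed_threshold=0.5
        )
        assert a["n_outside"] == b["n_outside"]

    def test_zero_radius_excludes_nothing(self, caplog):
        image = _scene([(20, 20, 5)], (60, 60))
        with caplog.at_level("WARNING"):
            counts = migration.count_migrated(
                image, (22.0, 22.0), 0.0, threshold_method="fixed", fixed_threshold=0.5
            )
        assert counts["n_outside"] == 1

    def test_cortex_mask_count(self):
        image = _scene([(10, 10, 5), (80, 80, 5)], (100, 100))
        cortex = np.zeros((100, 100), bool)
        cortex[:50] = True
        counts = migration.count_migrated(
            image, (50.0, 50.0), 5.0, cortex_mask=cortex,
            threshold_method="fixed", fixed_threshold=0.5,
        )
        assert counts["n_outside"] == 2
        assert counts["n_cortex"] == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        image = (rng.random((28, 28)) > 0.75).astype(float)
        center = (float(rng.uniform(0, 28)), float(rng.uniform(0, 28)))
        radius = float(rng.uniform(0, 10))
        min_area = int(rng.integers(1, 4))
        cortex = rng.random((28, 28)) > 0.5
        counts = migration.count_migrated(
            image, center, radius, cortex, min_area,
            threshold_method="fixed", fixed_threshold=0.5,
        )
        exp_out, exp_ctx = brute_count_migrated(
            image >= 0.5, center, radius, cortex, min_area, 1.0
        )
        assert counts["n_outside"] == exp_out
        assert counts["n_cortex"] == exp_ctx
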