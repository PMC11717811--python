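import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliamig import coloc, synthetic
from gliamig.coloc import LabelMask
from gliamig.errors import EmptyResultError, ParameterError

from conftest import random_label_grid
from oracles import brute_donut, brute_overlap_fractions


class TestBinarizeChannel:
    def test_zeros_fixed_threshold(self):
        out = coloc.binarize_channel(np.zeros((5, 5)), "fixed", 0.5)
        assert not out.any()

    def test_two_valued_otsu_separates(self):
        image = np.zeros((10, 10))
        image[::2] = 10.0
        out = coloc.binarize_channel(image, "otsu")
        np.testing.assert_array_equal(out, image == 10.0)

    def test_fixed_matches_elementwise_oracle(self, rng):
        image = rng.random((16, 16))
        out = coloc.binarize_channel(image, "fixed", 0.37)
        expected = np.array(
            [[image[y, x] >= 0.37 for x in range(16)] for y in range(16)]
        )
        np.testing.assert_array_equal(out, expected)

    def test_constant_otsu_warns_not_raises(self, caplog):
        with caplog.at_level("WARNING"):
            out = coloc.binarize_channel(np.full((4, 4), 3.0), "otsu")
        assert not out.any()
        assert any("constant" in r.message for r in caplog.records)

    def test_nonfinite_rejected(self):
        with pytest.raises(ParameterError):
            coloc.binarize_channel(np.array([[np.nan, 0.0]]))


class TestDonutOutline:
    def test_empty_mask(self):
        out = coloc.donut_outline(LabelMask(np.zeros((8, 8), dtype=int)), 1, 1)
        assert out.labels.size == 0

    def test_square_cell_square_footprint_ring_area(self, square_cell_mask):
        # 3x3 cell, radius-1 square element: 5x5 dilation minus 1-px erosion
        out = coloc.donut_outline(square_cell_mask, 1, 1, footprint="square")
        assert (out.grid == 1).sum() == 24

    def test_ring_disjoint_from_eroded_interior(self, rng):
        grid = random_label_grid(rng, (28, 28), 5)
        mask = LabelMask(grid)
        out = coloc.donut_outline(mask, 2, 2)
        from skimage.morphology import disk, erosion

        for lab in mask.labels:
            ero = erosion(grid == lab, disk(2))
            assert not (out.grid[ero] == lab).any()

    def test_both_radii_zero_rejected(self, square_cell_mask):
        with pytest.raises(ParameterError):
            coloc.donut_outline(square_cell_mask, 0, 0)

    def test_labels_subset_of_input(self, rng):
        grid = random_label_grid(rng, (24, 24), 6)
        out = coloc.donut_outline(LabelMask(grid), 1, 2)
        assert set(out.labels) <= set(np.unique(grid)) - {0}

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("footprint", ["disk", "square"])
    def test_matches_brute_force_oracle(self, seed, footprint):
        rng = np.random.default_rng(seed)
        grid = random_label_grid(rng, (20, 20), 5)
        r_in = int(rng.integers(0, 3))
        r_out = int(rng.integers(0, 3))
        if r_in == 0 and r_out == 0:
            r_out = 1
        out = coloc.donut_outline(LabelMask(grid), r_in, r_out, footprint)
        expected = brute_donut(grid, r_in, r_out, footprint)
        np.testing.assert_array_equal(out.grid, expected)


class TestOverlapFraction:
    def test_partial_overlap(self, square_cell_mask):
        marker = np.zeros((9, 9), dtype=bool)
        marker[3:5, 3:6] = True  # 6 of the 9 cell pixels
        table = coloc.overlap_fraction(square_cell_mask, marker)
        assert table.loc[0, "fraction"] == pytest.approx(6 / 9)

    def test_marker_everywhere(self, rng):
        grid = random_label_grid(rng, (20, 20), 4)
        table = coloc.overlap_fraction(LabelMask(grid), np.ones((20, 20), bool))
        assert (table["fraction"] == 1.0).all()

    def test_marker_nowhere(self, rng):
        grid = random_label_grid(rng, (20, 20), 4)
        table = coloc.overlap_fraction(LabelMask(grid), np.zeros((20, 20), bool))
        assert (table["fraction"] == 0.0).all()

    def test_shape_mismatch(self, square_cell_mask):
        with pytest.raises(ParameterError):
            coloc.overlap_fraction(square_cell_mask, np.zeros((4, 4), bool))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_fractions_in_unit_interval_and_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = random_label_grid(rng, (16, 16), 4)
        marker = rng.random((16, 16)) > 0.5
        table = coloc.overlap_fraction(LabelMask(grid), marker)
        assert ((table["fraction"] >= 0) & (table["fraction"] <= 1)).all()
        expected = brute_overlap_fractions(grid, marker)
        for _, row in table.iterrows():
            assert row["fraction"] == pytest.approx(expected[row["label"]])


class TestClassifyPositive:
    def table(self, *fractions):
        return pd.DataFrame({"label": range(1, len(fractions) + 1), "fraction": fractions})

    def test_two_thirds_is_positive(self):
        out = coloc.classify_positive(self.table(6 / 9))
        assert bool(out["positive"].iloc[0])

    def test_exact_threshold_is_negative(self):
        out = coloc.classify_positive(self.table(0.6))
        assert not bool(out["positive"].iloc[0])

    def test_zero_threshold(self):
        out = coloc.classify_positive(self.table(1e-9, 0.0), threshold=0.0)
        assert out["positive"].tolist() == [True, False]

    def test_threshold_out_of_range(self):
        with pytest.raises(ParameterError):
            coloc.classify_positive(self.table(0.5), threshold=1.5)


class TestPercentPositive:
    def test_three_of_twenty(self):
        table = pd.DataFrame({"positive": [True] * 3 + [False] * 17})
        assert coloc.percent_positive(table) == pytest.approx(15.0)

    def test_all_positive(self):
        assert coloc.percent_positive(pd.DataFrame({"positive": [True] * 7})) == 100.0

    def test_empty_is_error(self):
        with pytest.raises(EmptyResultError):
            coloc.percent_positive(pd.DataFrame({"positive": []}))


class TestRegisterTranslation:
    def test_identical_images(self, rng):
        image = rng.random((32, 32))
        assert coloc.register_translation(image, image) == (0, 0)

    def test_constructed_shift_recovered(self, rng):
        fixed = np.zeros((64, 64))
        fixed[20:30, 25:40] = rng.random((10, 15)) + 1.0
        moving = np.roll(fixed, (-3, 2), axis=(0, 1))
        assert coloc.register_translation(moving, fixed) == (3, -2)

    def test_shift_under_noise(self, rng):
        fixed = np.zeros((64, 64))
        fixed[10:50, 10:50] = rng.random((40, 40)) * 5.0
        moving = np.roll(fixed, (-4, 6), axis=(0, 1))
        moving = moving + rng.normal(0, 1.0, moving.shape)  # SNR ~ 5
        dy, dx = coloc.register_translation(moving, fixed)
        assert abs(dy - 4) <= 1 and abs(dx + 6) <= 1

    def test_constant_images_warn(self, caplog):
        with caplog.at_level("WARNING"):
            offset = coloc.register_translation(np.ones((8, 8)), np.ones((8, 8)))
        assert offset == (0, 0)
        assert any("constant" in r.message for r in caplog.records)


class TestScoreNuclearMarker:
    def _nuclei(self):
        grid = np.zeros((20, 20), dtype=int)
        grid[2:6, 2:6] = 1
        grid[10:14, 10:14] = 2
        grid[2:6, 12:16] = 3
        return LabelMask(grid)

    def test_marker_everywhere(self):
        mask = self._nuclei()
        everywhere = np.ones((20, 20), bool)
        _, summary = coloc.score_nuclear_marker(mask, everywhere, everywhere)
        assert summary["percent_positive"] == 100.0

    def test_marker_nowhere(self):
        mask = self._nuclei()
        _, summary = coloc.score_nuclear_marker(
            mask, np.ones((20, 20), bool), np.zeros((20, 20), bool)
        )
        assert summary["percent_positive"] == 0.0

    def test_planted_flags_recovered_exactly(self):
        mask = self._nuclei()
        reporter = np.ones((20, 20), bool)
        marker = np.zeros((20, 20), bool)
        marker[2:6, 2:6] = True  # only nucleus 1
        table, summary = coloc.score_nuclear_marker(mask, reporter, marker)
        assert table.set_index("label")["positive"].to_dict() == {1: True, 2: False, 3: False}
        assert summary["percent_positive"] == pytest.approx(100 / 3)

    def test_no_reporter_positive_nuclei(self):
        mask = self._nuclei()
        with pytest.raises(EmptyResultError):
            coloc.score_nuclear_marker(
                mask, np.zeros((20, 20), bool), np.ones((20, 20), bool)
            )


@pytest.mark.parametrize("pattern", ["membrane", "cytoplasmic", "nuclear"])
def test_full_pipeline_recovers_truth_fraction(pattern):
    truth = synthetic.ColocTruth(
        n_cells=120,
        true_positive_fraction=0.3,
        marker_pattern=pattern,
        image_shape=(560, 560),
    )
    sim = synthetic.make_coloc_image(truth, seed=7)
    result = coloc.score_pattern(sim.mask, sim.marker, pattern, reporter_image=sim.reporter)
    empirical = 100.0 * sim.truth["true_positive"].mean()
    # binomial 99% band around the design fraction
    band = 2.576 * np.sqrt(0.3 * 0.7 / truth.n_cells) * 100
    assert abs(result.summary["percent_positive"] - 30.0) < band
    # and near-exact agreement with the per-image empirical truth
    assert abs(result.summary["percent_positive"] - empirical) < 3.0
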