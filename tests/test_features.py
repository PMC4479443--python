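"""The 67-feature cell description: morphology, statistics, GLCM, eigen, ratios."""

import numpy as np
import pandas as pd
import pytest

from conftest import disc_mask
from leukosmear.features import (
    FEATURE_NAMES,
    eigen_features,
    extract_feature_vector,
    flat_feature_names,
    glcm_features,
    morphological_features,
    region_crop,
    size_ratio_features,
    statistical_features,
)


class TestSchema:
    def test_canonical_names_count(self):
        assert len(FEATURE_NAMES) == 67
        assert len(set(FEATURE_NAMES)) == 67

    def test_flat_schema_stable(self):
        names = flat_feature_names()
        assert names == flat_feature_names()
        assert len(names) == len(set(names))
        # blocks: 2x14 morphology + cytoplasm area + 2x60 stats/glcm + 80 eigen + 3 ratios
        assert len(names) == 28 + 1 + 60 + 60 + 80 + 3


class TestMorphology:
    def test_filled_square(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        f = morphological_features(mask)
        assert f["area"] == 100
        assert f["width"] == 10 and f["length"] == 10
        assert f["elongation"] == 1.0
        assert f["extent"] == 1.0
        assert f["solidity"] == pytest.approx(1.0)
        assert f["euler_number"] == 1
        assert f["convex_area"] == 100

    def test_annulus_euler_number(self):
        outer = disc_mask((40, 40), (20, 20), 15)
        inner = disc_mask((40, 40), (20, 20), 6)
        f = morphological_features(outer & ~inner)
        assert f["euler_number"] == 0

    def test_rectangle_closed_forms(self):
        mask = np.zeros((30, 20), dtype=bool)
        mask[5:25, 5:15] = True
        f = morphological_features(mask)
        assert f["elongation"] == pytest.approx(2.0)
        assert f["equivalent_diameter"] == pytest.approx(np.sqrt(4 * 200 / np.pi), rel=1e-6)
        assert f["area"] == 200

    def test_scale_doubling(self):
        small = disc_mask((60, 60), (30, 30), 12)
        big = disc_mask((120, 120), (60, 60), 24)
        fs, fb = morphological_features(small), morphological_features(big)
        assert fb["area"] / fs["area"] == pytest.approx(4.0, rel=0.05)
        assert fb["perimeter"] / fs["perimeter"] == pytest.approx(2.0, rel=0.05)
        for name in ("elongation", "extent", "solidity"):
            assert fb[name] == pytest.approx(fs[name], rel=0.02)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            morphological_features(np.zeros((5, 5), dtype=bool))


class TestStatistics:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(st.integers(min_value=0, max_value=255), min_size=1, max_size=200).map(np.array)
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_consistency_properties(self, values):
        f = statistical_features(values)
        assert f["variance"] == pytest.approx(f["std"] ** 2)
        assert f["sum"] == pytest.approx(f["mean"] * len(values))
        assert values.min() <= f["mode"] <= values.max()

    def test_constant_region(self):
        f = statistical_features(np.full(50, 7.0))
        assert f == {"mode": 7.0, "mean": 7.0, "std": 0.0, "variance": 0.0, "sum": 350.0}

    def test_hand_arithmetic(self):
        f = statistical_features(np.array([1.0, 2.0, 2.0, 3.0]))
        assert f["mode"] == 2.0
        assert f["mean"] == 2.0
        assert f["variance"] == pytest.approx(0.5)  # population convention
        assert f["sum"] == 8.0
        assert f["std"] == pytest.approx(np.sqrt(0.5))

    def test_multimodal_tie_breaks_low(self):
        assert statistical_features(np.array([1, 1, 2, 2]))["mode"] == 1.0


class TestGlcm:
    def test_constant_region(self):
        plane = np.full((6, 6), 100.0)
        mask = np.ones((6, 6), dtype=bool)
        f = glcm_features(plane, mask)
        assert f["contrast"] == 0.0
        assert f["homogeneity"] == 1.0
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0

    def test_stripe_anticorrelation(self):
        # strict two-value column stripes: every horizontal pair is (a,b) or (b,a)
        plane = np.tile([40.0, 200.0], (4, 2))
        mask = np.ones((4, 4), dtype=bool)
        f = glcm_features(plane, mask)
        assert f["correlation"] == pytest.approx(-1.0)

    def test_uniform_four_cell_entropy(self):
        # pairs split evenly over 4 distinct (i, j) cells -> entropy = 2 bits
        plane = np.array([[10.0, 100.0], [200.0, 60.0]])
        mask = np.ones((2, 2), dtype=bool)
        f = glcm_features(plane, mask)
        assert f["entropy"] == pytest.approx(2.0)

    def test_out_of_region_pairs_excluded(self):
        plane = np.zeros((3, 4))
        plane[:, 2:] = 250.0
        mask = np.zeros((3, 4), dtype=bool)
        mask[:, :2] = True  # only the constant left half is in-region
        f = glcm_features(plane, mask)
        assert f["contrast"] == 0.0 and f["energy"] == 1.0

    def test_no_pairs_rejected(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[:, 1] = True  # single column: no horizontal pairs
        with pytest.raises(ValueError):
            glcm_features(np.ones((3, 3)), mask)


class TestEigen:
    def test_rank_one_image(self):
        row = np.linspace(0, 50, 12)
        crop = np.outer(np.ones(10), row) + np.outer(np.arange(10), np.zeros(12))
        vals = eigen_features(crop)
        assert vals[0] > 0
        assert vals[1:] == pytest.approx(np.zeros(9), abs=1e-8)

    def test_sorted_non_negative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            crop = rng.normal(100, 20, (int(rng.integers(5, 30)), int(rng.integers(5, 30))))
            vals = eigen_features(crop)
            assert (vals >= 0).all()
            assert (np.diff(vals) <= 1e-9).all()

    def test_matches_full_decomposition(self):
        rng = np.random.default_rng(1)
        crop = rng.normal(0, 1, (20, 15))
        vals = eigen_features(crop)
        full = np.sort(np.linalg.eigvalsh(np.cov(crop, rowvar=False)))[::-1]
        assert vals == pytest.approx(np.clip(full[:10], 0, None))

    def test_degenerate_single_row(self):
        with pytest.warns(UserWarning):
            vals = eigen_features(np.ones((1, 8)))
        assert vals == pytest.approx(np.zeros(10))


class TestSizeRatios:
    def test_arithmetic(self):
        nucleus = np.zeros((20, 20), dtype=bool)
        nucleus[5:11, 5:15] = True  # 60 px
        cell = np.zeros((20, 20), dtype=bool)
        cell[5:15, 5:15] = True  # 100 px
        ratios, flags = size_ratio_features(nucleus, cell)
        assert ratios["n_cell_area"] == pytest.approx(0.6)
        assert ratios["n_cyto_area"] == pytest.approx(1.5)
        assert not flags

    def test_no_cytoplasm_flagged(self):
        mask = disc_mask((30, 30), (15, 15), 10)
        ratios, flags = size_ratio_features(mask, mask)
        assert ratios["n_cell_area"] == pytest.approx(1.0)
        assert np.isnan(ratios["n_cyto_area"])
        assert "zero-cytoplasm-area" in flags

    def test_concentric_disc_perimeter_ratio(self):
        nucleus = disc_mask((60, 60), (30, 30), 10)
        cell = disc_mask((60, 60), (30, 30), 20)
        ratios, _ = size_ratio_features(nucleus, cell)
        assert ratios["n_cell_perimeter"] == pytest.approx(0.5, abs=0.05)


class TestFullVector:
    def _scene(self, offset=(0, 0)):
        shape = (64, 64)
        cell = disc_mask(shape, (32 + offset[0], 32 + offset[1]), 20)
        nucleus = disc_mask(shape, (32 + offset[0], 32 + offset[1]), 11)
        rng = np.random.default_rng(0)
        rgb = np.full(shape + (3,), 230, dtype=float)
        rgb[cell] = (170, 175, 215)
        rgb[nucleus] = (95, 70, 150)
        rgb += rng.normal(0, 3, rgb.shape)
        return nucleus, cell, np.clip(rgb, 0, 255).astype(np.uint8)

    def test_all_finite_and_schema_ordered(self):
        nucleus, cell, rgb = self._scene()
        vec = extract_feature_vector(nucleus, cell, rgb)
        assert list(vec.index) == flat_feature_names()
        assert np.isfinite(vec.to_numpy()).all()

    def test_translation_invariance(self):
        n1, c1, rgb1 = self._scene()
        vec1 = extract_feature_vector(n1, c1, rgb1)
        shape = (64, 64)
        shift = (4, -6)
        n2 = np.roll(np.roll(n1, shift[0], axis=0), shift[1], axis=1)
        c2 = np.roll(np.roll(c1, shift[0], axis=0), shift[1], axis=1)
        rgb2 = np.roll(np.roll(rgb1, shift[0], axis=0), shift[1], axis=1)
        vec2 = extract_feature_vector(n2, c2, rgb2)
        pd.testing.assert_series_equal(vec1, vec2, atol=1e-9, rtol=1e-9)

    def test_variance_std_consistency_across_blocks(self):
        nucleus, cell, rgb = self._scene()
        vec = extract_feature_vector(nucleus, cell, rgb)
        for region in ("nucleus", "cytoplasm", "cell"):
            for ch in ("R", "G", "B", "gray"):
                assert vec[f"{region}_{ch}_variance"] == pytest.approx(
                    vec[f"{region}_{ch}_std"] ** 2
                )

    def test_region_mean_fill_keeps_background_out(self):
        nucleus, cell, rgb = self._scene()
        crop = region_crop(rgb[..., 0].astype(float), nucleus)
        rows, cols = np.nonzero(nucleus)
        sub = nucleus[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
        in_mean = crop[sub].mean()
        assert crop[~sub] == pytest.approx(in_mean)
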