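"""MRF segmentation: observation assembly, ICM estimation, scoring."""

import numpy as np
import pytest

from leukosmear.color import cluster_channel, rgb_to_lab, select_foreground_group
from leukosmear.mrf import (
    ObservationStack,
    build_observations,
    global_energy,
    icm_map_estimate,
    score_segmentation,
    segment_image,
)
from leukosmear.synthetic import SmearSpec, generate_smear
from leukosmear.texture import decompose


def _stack(intensity, fg_mu, fg_var, bg_mu, bg_var):
    """Observation stack with flat texture planes (no texture influence)."""
    zeros = np.zeros_like(intensity)
    return ObservationStack(
        intensity=intensity,
        structural=zeros,
        stochastic=zeros,
        fg_means=np.array([fg_mu, 0.0, 0.0]),
        fg_vars=np.array([fg_var, 1.0, 1.0]),
        bg_means=np.array([[bg_mu, 0.0, 0.0]]),
        bg_vars=np.array([[bg_var, 1.0, 1.0]]),
    )


def _two_region_image(rng=None, noise=0.0, size=32):
    truth = np.zeros((size, size), dtype=np.int8)
    truth[:, size // 2 :] = 1
    intensity = np.where(truth == 1, 80.0, 20.0)
    if rng is not None and noise > 0:
        intensity = intensity + rng.normal(0, noise, intensity.shape)
    return intensity, truth


class TestIcm:
    def test_beta_zero_equals_pixelwise_ml(self):
        rng = np.random.default_rng(0)
        intensity, _ = _two_region_image(rng, noise=40.0)
        obs = _stack(intensity, 80.0, 400.0, 20.0, 400.0)
        res = icm_map_estimate(obs, beta=0.0)
        ml = (np.abs(intensity - 80.0) < np.abs(intensity - 20.0)).astype(np.int8)
        assert np.array_equal(res.labels, ml)

    def test_noise_free_recovered_exactly(self):
        intensity, truth = _two_region_image()
        obs = _stack(intensity, 80.0, 1.0, 20.0, 1.0)
        for beta in (0.0, 1.5, 5.0):
            res = icm_map_estimate(obs, beta=beta)
            assert np.array_equal(res.labels, truth)

    def test_energy_trace_non_increasing(self):
        rng = np.random.default_rng(1)
        intensity, _ = _two_region_image(rng, noise=35.0)
        obs = _stack(intensity, 80.0, 900.0, 20.0, 900.0)
        res = icm_map_estimate(obs, beta=1.5)
        trace = np.array(res.energy_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_icm_beats_ml_on_noisy_image(self):
        rng = np.random.default_rng(7)
        intensity, truth = _two_region_image(rng, noise=35.0)
        obs = _stack(intensity, 80.0, 1225.0, 20.0, 1225.0)
        ml = (np.abs(intensity - 80.0) < np.abs(intensity - 20.0)).astype(np.int8)
        res = icm_map_estimate(obs, beta=1.5)
        acc_ml = (ml == truth).mean()
        acc_icm = (res.labels == truth).mean()
        assert acc_icm >= acc_ml
        # oracle: evaluate the global energy functional on both labelings
        assert global_energy(res.labels, obs, 1.5) <= global_energy(ml, obs, 1.5)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(3)
        intensity, _ = _two_region_image(rng, noise=30.0)
        obs = _stack(intensity, 80.0, 900.0, 20.0, 900.0)
        flipped = _stack(intensity, 20.0, 900.0, 80.0, 900.0)
        a = icm_map_estimate(obs, beta=1.5).labels
        b = icm_map_estimate(flipped, beta=1.5).labels
        assert np.array_equal(a, 1 - b)

    def test_invalid_sweeps_rejected(self):
        obs = _stack(np.zeros((8, 8)), 1.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            icm_map_estimate(obs, max_sweeps=0)


class TestBuildObservations:
    def test_intensity_plane_follows_mode(self, small_smear):
        img, _ = small_smear
        lab = rgb_to_lab(img)
        fields = decompose(lab.L)
        gl = cluster_channel(lab.L, k=3, seed=0)
        select_foreground_group(gl, "nucleus")
        obs_n = build_observations(lab, fields, gl, "nucleus")
        gb = cluster_channel(lab.b, k=3, seed=0)
        select_foreground_group(gb, "cell")
        obs_c = build_observations(lab, decompose(lab.b), gb, "cell")
        assert np.array_equal(obs_n.intensity, lab.L)
        assert np.array_equal(obs_c.intensity, lab.b)
        assert not np.array_equal(obs_n.intensity, obs_c.intensity)

    def test_textured_foreground_raises_structural_energy(self):
        rng = np.random.default_rng(0)
        plane = np.full((64, 64), 50.0)
        x = np.arange(64)
        plane[:, 32:] += 25 * np.cos(2 * np.pi * 8 * x[32:] / 64) + 20.0
        rgb = np.clip(np.dstack([plane * 2.0] * 3), 0, 255).astype(np.uint8)
        lab = rgb_to_lab(rgb)
        fields = decompose(lab.L)
        groups = cluster_channel(lab.L, k=2, seed=0)
        select_foreground_group(groups, "nucleus")
        obs = build_observations(lab, fields, groups, "nucleus")
        fg_region = np.zeros((64, 64), dtype=bool)
        fg_region[:, 36:] = True
        bg_region = np.zeros((64, 64), dtype=bool)
        bg_region[:, :28] = True
        assert obs.structural[fg_region].mean() > obs.structural[bg_region].mean()

    def test_variance_floored(self):
        rgb = np.zeros((32, 32, 3), dtype=np.uint8)
        rgb[:, 16:] = 200
        lab = rgb_to_lab(rgb)
        groups = cluster_channel(lab.L, k=2, seed=0)
        select_foreground_group(groups, "nucleus")
        obs = build_observations(lab, decompose(lab.L), groups, "nucleus")
        assert (obs.fg_vars > 0).all() and (obs.bg_vars > 0).all()


class TestSegmentImage:
    def test_noiseless_single_cell_perfect_nucleus(self):
        spec = SmearSpec(
            n_leukocytes=1, n_erythrocytes=4, noise_sd=0.0, stain_shift=(0, 0, 0), seed=2
        )
        img, truth = generate_smear(spec)
        mask = segment_image(img, "nucleus")
        s = score_segmentation(mask, truth.nucleus_mask > 0)
        assert s.precision == pytest.approx(100.0, abs=0.5)

    def test_all_background_empty_mask(self):
        spec = SmearSpec(n_leukocytes=0, n_erythrocytes=0, seed=4)
        img, _ = generate_smear(spec)
        mask = segment_image(img, "nucleus")
        assert not mask.any()

    def test_precision_non_increasing_in_noise(self):
        means = []
        for noise in (2.0, 8.0, 16.0):
            precisions = []
            for seed in range(10):
                img, truth = generate_smear(SmearSpec(seed=seed, noise_sd=noise))
                s = score_segmentation(segment_image(img, "nucleus"), truth.nucleus_mask > 0)
                precisions.append(s.precision)
            means.append(np.mean(precisions))
        assert means[1] <= means[0] + 0.25
        assert means[2] <= means[1] + 0.25


class TestScoreSegmentation:
    def test_perfect_prediction(self):
        truth = np.zeros((10, 10), dtype=bool)
        truth[2:5, 2:5] = True
        s = score_segmentation(truth, truth)
        assert (s.precision, s.fp_rate, s.fn_rate) == (100.0, 0.0, 0.0)

    def test_hand_counted_toy(self):
        truth = np.zeros((4, 4), dtype=bool)
        truth[:, :2] = True  # left 8 pixels
        pred = np.zeros((4, 4), dtype=bool)
        pred[:2, :] = True  # top 8 pixels
        s = score_segmentation(pred, truth)
        assert s.precision == pytest.approx(50.0)
        assert s.fp_rate == pytest.approx(50.0)
        assert s.fn_rate == pytest.approx(50.0)

    def test_precision_fp_sum_to_100(self):
        rng = np.random.default_rng(0)
        pred = rng.random((16, 16)) > 0.4
        truth = rng.random((16, 16)) > 0.6
        s = score_segmentation(pred, truth)
        assert s.precision + s.fp_rate == pytest.approx(100.0)

    def test_empty_prediction_undefined(self):
        truth = np.ones((4, 4), dtype=bool)
        s = score_segmentation(np.zeros((4, 4), dtype=bool), truth)
        assert np.isnan(s.precision) and np.isnan(s.fp_rate)
        assert "P = 0" in s.note
        assert s.fn_rate == pytest.approx(100.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_segmentation(np.zeros((3, 3), bool), np.zeros((4, 4), bool))
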