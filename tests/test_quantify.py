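"""Translocation-ratio and Haralick-contrast quantification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr
from skimage.feature import graycomatrix

from conftest import brute_force_contrast, brute_force_glcm
from organotrace.quantify import (
    GLCMatrix, compute_glcm, contrast_timecourse, haralick_contrast,
    measure_cells, translocation_ratio,
)
from organotrace.segment import (
    derive_cytoplasm_rings, estimate_background, segment_nuclei,
)
from organotrace.simulate import (
    ImagingConfig, random_cell_layout, render_monolayer_frame,
    render_tubulin_timelapse,
)


def _measure_frame(img, background=None, pixel_size_um=0.325):
    nuclei = segment_nuclei(img[0], pixel_size_um=pixel_size_um)
    rings = derive_cytoplasm_rings(nuclei, 5)
    if background is None:
        fg = (nuclei.labels > 0) | (rings.labels > 0)
        background = estimate_background(img[1], fg)
    return measure_cells(img[1], nuclei, rings, background)


class TestTranslocationRatio:
    @pytest.mark.parametrize("nuc,cyt,bg,expected", [
        (500.0, 100.0, 100.0, 1.0),     # complete nuclear
        (100.0, 500.0, 100.0, 0.0),     # complete cytoplasmic
        (60.0, 40.0, 10.0, 0.625),      # 50 / (50 + 30)
    ])
    def test_formula(self, nuc, cyt, bg, expected):
        assert translocation_ratio(nuc, cyt, bg) == pytest.approx(expected)

    def test_no_signal_flags_invalid(self):
        assert math.isnan(translocation_ratio(50.0, 80.0, 100.0))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            translocation_ratio(math.inf, 1.0, 0.0)
        with pytest.raises(ValueError):
            translocation_ratio(1.0, 1.0, -1.0)

    def test_scale_invariance_on_rendered_frame(self, imaging_noise_free):
        """Multiplying image and background by gamma leaves ratios
        unchanged."""
        cells = random_cell_layout(6, imaging_noise_free, seed=1)
        img, _ = render_monolayer_frame(cells, imaging_noise_free, 2)
        nuclei = segment_nuclei(img[0])
        rings = derive_cytoplasm_rings(nuclei, 5)
        base = measure_cells(img[1].astype(float), nuclei, rings, 100.0)
        for gamma in (0.5, 3.0):
            scaled = measure_cells(img[1].astype(float) * gamma, nuclei,
                                   rings, 100.0 * gamma)
            assert np.allclose(base["ratio"], scaled["ratio"], atol=1e-6)

    def test_ratio_monotone_in_true_fraction(self, imaging_noise_free):
        fracs = np.linspace(0.0, 1.0, 8)
        cells = random_cell_layout(8, imaging_noise_free, seed=3,
                                   nuclear_fraction=fracs)
        img, gt = render_monolayer_frame(cells, imaging_noise_free, 1)
        out = _measure_frame(img)
        from organotrace.pipeline import match_to_ground_truth
        merged = match_to_ground_truth(out, gt.cells)
        assert len(merged) == 8
        rho = spearmanr(merged["ratio"],
                        merged["nuclear_fraction_true"]).statistic
        assert rho == pytest.approx(1.0)


class TestMeasureCells:
    def test_cardinality_matches_nuclei(self, imaging_noise_free):
        cells = random_cell_layout(10, imaging_noise_free, seed=5)
        img, _ = render_monolayer_frame(cells, imaging_noise_free, 1)
        out = _measure_frame(img)
        assert len(out) == 10
        assert sorted(out["cell_id"]) == list(range(1, 11))

    def test_uniform_fraction_recovered(self, imaging_noise_free):
        cells = random_cell_layout(8, imaging_noise_free, seed=7,
                                   nuclear_fraction=0.8)
        img, _ = render_monolayer_frame(cells, imaging_noise_free, 1)
        out = _measure_frame(img)
        assert np.all(np.abs(out["ratio"] - 0.8) < 0.05)

    def test_empty_frame_gives_empty_table(self, imaging_default):
        img, _ = render_monolayer_frame([], imaging_default, 1)
        assert _measure_frame(img, background=100.0).empty


class TestGLCM:
    def test_constant_image_is_diagonal_with_zero_contrast(self):
        g = compute_glcm(np.full((8, 8), 3.0), np.ones((8, 8), bool),
                         levels=8, value_range=(0, 7))
        assert haralick_contrast(g) == 0.0
        assert g.matrix.diagonal().sum() == pytest.approx(1.0)

    def test_checkerboard_contrast_is_one(self):
        board = (np.indices((4, 4)).sum(axis=0) % 2).astype(float)
        g = compute_glcm(board, np.ones((4, 4), bool), levels=2,
                         offsets=[(0, 1)], value_range=(0, 1))
        assert g.matrix[0, 1] + g.matrix[1, 0] == pytest.approx(1.0)
        assert haralick_contrast(g) == pytest.approx(1.0)

    def test_single_offdiagonal_pair(self):
        p = np.zeros((3, 3))
        p[0, 2] = p[2, 0] = 0.5
        assert haralick_contrast(GLCMatrix(3, ((0, 1),), p)) == 4.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_oracle(self, data):
        """Vectorized co-occurrence counting equals exhaustive pair
        enumeration on random masked images up to 16x16."""
        h = data.draw(st.integers(3, 16))
        w = data.draw(st.integers(3, 16))
        levels = data.draw(st.integers(2, 8))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        img = rng.integers(0, levels, (h, w)).astype(float)
        mask = rng.random((h, w)) < 0.85
        offsets = data.draw(st.lists(
            st.sampled_from([(0, 1), (1, 0), (1, 1), (1, -1)]),
            min_size=1, max_size=4, unique=True))
        try:
            g = compute_glcm(img, mask, levels, offsets,
                             value_range=(0, levels - 1))
        except ValueError:
            return  # mask admits no pair: oracle would fail identically
        oracle = brute_force_glcm(img, mask, levels, offsets,
                                  (0, levels - 1))
        assert np.array_equal(g.matrix, oracle)

    def test_matches_skimage_graycomatrix(self):
        """Independent library cross-check on a full-frame integer image."""
        rng = np.random.default_rng(1)
        img = rng.integers(0, 16, (32, 32))
        g = compute_glcm(img.astype(float), np.ones((32, 32), bool),
                         levels=16, offsets=[(0, 1)], value_range=(0, 15))
        ref = graycomatrix(img.astype(np.uint8), [1], [0], levels=16,
                           symmetric=True, normed=True)[:, :, 0, 0]
        assert np.allclose(g.matrix, ref)

    def test_contrast_invariant_to_intensity_offset(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(10, 50, (20, 20))
        mask = np.ones((20, 20), bool)
        c0 = haralick_contrast(compute_glcm(img, mask, 16,
                                            value_range=(10, 50)))
        c1 = haralick_contrast(compute_glcm(img + 7.0, mask, 16,
                                            value_range=(17, 57)))
        assert c0 == pytest.approx(c1, abs=1e-12)

    def test_parameter_validation(self):
        img, mask = np.zeros((4, 4)), np.ones((4, 4), bool)
        with pytest.raises(ValueError, match="levels"):
            compute_glcm(img, mask, levels=1)
        with pytest.raises(ValueError, match="offsets"):
            compute_glcm(img, mask, levels=4, offsets=[])
        with pytest.raises(ValueError, match="pair"):
            lone = np.zeros((4, 4), bool)
            lone[0, 0] = True
            compute_glcm(img, lone, levels=4)


class TestContrastTimecourse:
    def test_constant_frames_constant_contrast(self):
        stack = np.full((4, 16, 16), 200.0)
        out = contrast_timecourse(stack, np.ones((16, 16), bool))
        assert np.allclose(out["contrast"], out["contrast"].iloc[0],
                           atol=1e-9)

    def test_stabilization_ramp_strictly_increases(self):
        cfg = ImagingConfig(width_px=256, height_px=256, noise_sd=0.0)
        times = np.arange(10, dtype=float)
        ramp = times / 9.0
        stack, mask, _ = render_tubulin_timelapse(ramp, times, cfg, seed=3)
        out = contrast_timecourse(stack, mask, times)
        assert np.all(np.diff(out["contrast"]) > 0)

    def test_bleaching_detrend_restores_ramp(self):
        """Photobleaching drags raw contrast down over an 18 h series;
        subtracting the linear control trend restores the underlying
        stabilization ramp (Spearman rho vs truth > 0.95)."""
        cfg = ImagingConfig(width_px=256, height_px=256)
        times = np.arange(0.0, 18.01, 1.0)
        ramp = times / 18.0
        treated, t_mask, _ = render_tubulin_timelapse(
            ramp, times, cfg, seed=3, bleach_rate_per_h=0.025)
        control, c_mask, _ = render_tubulin_timelapse(
            np.zeros_like(ramp), times, cfg, seed=4,
            bleach_rate_per_h=0.025)
        ctrl = contrast_timecourse(control, c_mask, times)
        raw = contrast_timecourse(treated, t_mask, times)
        detrended = contrast_timecourse(treated, t_mask, times,
                                        detrend_control=ctrl["contrast"])
        rho_raw = spearmanr(raw["contrast"], ramp).statistic
        rho_det = spearmanr(detrended["contrast"], ramp).statistic
        assert rho_det > rho_raw
        assert rho_det > 0.95

    def test_frame_mask_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            contrast_timecourse(np.zeros((3, 8, 8)),
                                [np.ones((8, 8), bool)] * 2)
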