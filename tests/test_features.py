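"""Texture descriptors: dimensionalities, oracle equivalence, invariances."""

import numpy as np
import pytest

from subloc2l.features import (
    SET_DIMENSIONS,
    CLBPConfig,
    HaralickConfig,
    extract_all,
    extract_clbp,
    extract_dna_distribution,
    extract_haralick,
    extract_lbp,
    extract_letrist,
    extract_riclbp,
    lbp_codes,
)
from subloc2l.features.lbp import clbp_components, riclbp_pair_labels, _ric_table, _riu2
from subloc2l.features.slfs import _glcm_stats, HARALICK_STATS
from subloc2l.imaging import ChannelPair
from oracles import lbp_codes_loop, clbp_sm_loop, riclbp_hist_loop, glcm_loop


@pytest.fixture(scope="module")
def channel_pair(small_image, rng):
    dna = np.clip(small_image * 0.4 + rng.normal(0, 2, small_image.shape), 0, None)
    return ChannelPair(dna=dna, protein=np.clip(small_image, 0, None), source_id="t")


class TestDimensionalities:
    def test_all_sets_have_declared_lengths(self, channel_pair):
        vecs = extract_all(channel_pair)
        assert {k: v.values.size for k, v in vecs.items()} == SET_DIMENSIONS

    def test_slfs_is_dna_block_plus_haralick(self, channel_pair):
        vecs = extract_all(channel_pair)
        dna4 = extract_dna_distribution(channel_pair.dna, channel_pair.protein)
        har = extract_haralick(channel_pair.protein)
        assert np.array_equal(vecs["SLFs"].values, np.concatenate([dna4, har]))

    def test_extraction_is_deterministic(self, channel_pair):
        a = extract_all(channel_pair)
        b = extract_all(channel_pair)
        for name in a:
            assert np.array_equal(a[name].values, b[name].values)


class TestHistogramProperties:
    def test_constituent_histograms_sum_to_one(self, small_image):
        assert extract_lbp(small_image).sum() == pytest.approx(1.0)
        clbp = extract_clbp(small_image)
        pos = 0
        for _ in CLBPConfig().radii:
            for size in (200, 100, 2):
                block = clbp[pos : pos + size]
                assert block.min() >= 0 and block.sum() == pytest.approx(1.0)
                pos += size
        ric = extract_riclbp(small_image)
        for k in range(3):
            assert ric[k * 136 : (k + 1) * 136].sum() == pytest.approx(1.0)
        let = extract_letrist(small_image)
        assert let[:343].sum() == pytest.approx(1.0)
        assert let[343:407].sum() == pytest.approx(1.0)
        for k in range(3):
            assert let[407 + 2 * k : 409 + 2 * k].sum() == pytest.approx(1.0)


class TestLBP:
    def test_constant_image_all_mass_in_all_ones_code(self):
        hist = extract_lbp(np.full((8, 8), 40.0))
        assert hist[255] == pytest.approx(1.0)

    def test_codes_match_brute_force_oracle(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, (7, 9)).astype(float)
            assert np.array_equal(lbp_codes(img), lbp_codes_loop(img))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            extract_lbp(np.zeros((2, 2)))


class TestCLBP:
    def test_codes_match_brute_force_oracle(self, rng):
        img = rng.integers(0, 256, (7, 7)).astype(float)
        s, m, _ = clbp_components(img, radius=1)
        s_raw, m_raw = clbp_sm_loop(img, radius=1)
        assert np.array_equal(s, _riu2(s_raw))
        assert np.array_equal(m, _riu2(m_raw))

    def test_constant_image_gives_all_ones_sign_pattern(self):
        s, m, c = clbp_components(np.full((9, 9), 7.0), radius=1)
        assert np.all(s == 8)  # riu2 bin of the all-ones code

    def test_output_length_906(self, small_image):
        assert extract_clbp(small_image).size == 906


class TestRICLBP:
    def test_table_has_136_classes(self):
        assert _ric_table().max() == 135

    def test_pair_labels_match_enumeration_oracle(self, rng):
        img = rng.integers(0, 256, (12, 12)).astype(float)
        labels = riclbp_pair_labels(img, radius=1, disp=2)
        hist = np.bincount(labels, minlength=136).astype(float)
        assert np.allclose(hist / hist.sum(), riclbp_hist_loop(img, 1, 2))

    def test_constant_image_single_bin_per_scale(self):
        hist = extract_riclbp(np.full((32, 32), 5.0))
        for k in range(3):
            assert hist[k * 136 : (k + 1) * 136].max() == pytest.approx(1.0)

    def test_invariant_under_90_degree_rotation(self, rng):
        img = np.kron(rng.random((16, 16)) > 0.5, np.ones((4, 4))) * 200.0
        img += rng.normal(0, 3, img.shape)
        h0 = extract_riclbp(img)
        h1 = extract_riclbp(np.rot90(img))
        assert np.abs(h0 - h1).max() < 0.02


class TestHaralick:
    def test_constant_image_degenerate_glcm(self):
        vec = extract_haralick(np.full((40, 40), 9.0))
        vec = vec.reshape(-1, len(HARALICK_STATS))
        assert np.allclose(vec[:, HARALICK_STATS.index("asm")], 1.0)
        assert np.allclose(vec[:, HARALICK_STATS.index("contrast")], 0.0)
        assert np.all(np.isfinite(vec))

    def test_checkerboard_contrast_matches_hand_glcm(self):
        img = np.indices((24, 24)).sum(axis=0) % 2 * 255.0
        cfg = HaralickConfig(levels=64, distances=(1,), angles=(0.0,))
        vec = extract_haralick(img, cfg)
        # Hand-built 2x2 GLCM: horizontal neighbors always differ (levels 0, 63).
        contrast = vec[HARALICK_STATS.index("contrast")]
        assert contrast == pytest.approx(63.0**2)
        assert vec[HARALICK_STATS.index("asm")] == pytest.approx(0.5)

    def test_glcm_stats_match_loop_oracle(self, rng, small_image):
        from skimage.feature import graycomatrix
        from subloc2l.features.base import rescale_u8

        q = (rescale_u8(small_image).astype(int) * 8 // 256).astype(np.uint8)
        for d, angle, dy, dx in ((1, 0.0, 0, 1), (2, np.pi / 2, 2, 0)):
            P_impl = graycomatrix(
                q, [d], [angle], levels=8, symmetric=True, normed=True
            )[:, :, 0, 0]
            P_oracle = glcm_loop(q, dy, dx, 8)
            assert np.allclose(P_impl, P_oracle)
            stats = _glcm_stats(P_oracle, 8)
            assert np.all(np.isfinite(stats))
            # contrast from definition
            ii, jj = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
            assert stats[1] == pytest.approx(np.sum(P_oracle * (ii - jj) ** 2))

    def test_default_length_836(self, small_image):
        assert extract_haralick(small_image).size == 836


class TestDNADistribution:
    def test_identical_channels_full_overlap(self, small_image):
        stats = extract_dna_distribution(small_image, small_image)
        assert stats[0] == pytest.approx(1.0)
        assert stats[2] == pytest.approx(0.0, abs=1e-12)
        assert stats[3] == pytest.approx(1.0)

    def test_zero_protein_gives_all_zeros(self, small_image):
        stats = extract_dna_distribution(small_image, np.zeros_like(small_image))
        assert np.array_equal(stats, np.zeros(4))

    def test_matches_counting_oracle(self):
        dna = np.zeros((16, 16))
        dna[2:10, 2:10] = 10.0
        prot = np.zeros((16, 16))
        prot[6:14, 6:14] = 4.0
        stats = extract_dna_distribution(dna, prot)
        # Otsu on a two-valued image thresholds between the two values.
        prot_pix = 8 * 8
        overlap_pix = 4 * 4
        assert stats[0] == pytest.approx(overlap_pix / prot_pix)
        assert stats[1] == pytest.approx(overlap_pix * 4.0 / (prot_pix * 4.0))
        com_d = (5.5, 5.5)
        com_p = (9.5, 9.5)
        diag = np.hypot(15, 15)
        assert stats[2] == pytest.approx(np.hypot(4, 4) / diag)
        assert stats[3] == pytest.approx(prot_pix * 4.0 / (8 * 8 * 10.0))


class TestLETRIST:
    def test_constant_image_lowest_magnitude_bin(self):
        vec = extract_letrist(np.full((40, 40), 3.0))
        assert vec[0] == pytest.approx(1.0)  # joint magnitude code (0,0,0)

    def test_ramp_concentrates_histogram(self):
        xx = np.tile(np.arange(64, dtype=float), (64, 1))
        vec = extract_letrist(3.0 * xx)
        # constant gradient magnitude at every scale -> one joint bin
        assert vec[:343].max() == pytest.approx(1.0)

    def test_ramp_derivative_matches_closed_form(self):
        from scipy import ndimage

        # Convolving a linear ramp with any normalized Gaussian-derivative
        # kernel returns the slope exactly (closed-form oracle); the
        # interior response must be constant and equal to it.
        xx = np.tile(np.arange(64, dtype=float), (64, 1))
        resp = ndimage.gaussian_filter(3.0 * xx, 2.0, order=(0, 1), mode="reflect")
        interior = resp[16:-16, 16:-16]
        assert interior.std() < 1e-9
        assert interior[0, 0] == pytest.approx(3.0, rel=1e-2)

    def test_length_413(self, small_image):
        assert extract_letrist(small_image).size == 413
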