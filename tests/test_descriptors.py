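import numpy as np
import pytest

from texens.descriptors import (circle_offsets, colors_features,
                                lbp_histogram, lbp_label_image, lcp_features,
                                lpq_histogram, lpq_label_images,
                                ltp_histograms, multiscale_lpq_histogram,
                                riclbp_histogram, riclbp_orbit_table,
                                sample_neighbors, wld_histogram)
from texens.mapping import mapping_table, transitions, uniform_table

from oracles import (lbp_histogram_oracle, lpq_labels_oracle,
                     ltp_histogram_oracle, riclbp_orbit_count_oracle,
                     u2_bins, wld_histogram_oracle)


@pytest.fixture
def small_image(rng):
    return rng.uniform(0, 255, size=(8, 8))


class TestMappings:
    @pytest.mark.parametrize("p,expected", [(8, 59), (16, 243)])
    def test_u2_bin_counts(self, p, expected):
        _, n = uniform_table(p)
        assert n == expected

    def test_riu2_bins_and_rotation_invariance(self):
        table, n = mapping_table(8, "riu2")
        assert n == 10
        for code in range(256):
            rotated = ((code << 1) | (code >> 7)) & 255
            assert table[code] == table[rotated]

    def test_transition_count_examples(self):
        assert transitions(0b00000000, 8) == 0
        assert transitions(0b00001111, 8) == 2
        assert transitions(0b01010101, 8) == 8


class TestSampling:
    def test_constant_image_all_copies(self):
        img = np.full((5, 5), 42.0)
        v = sample_neighbors(img, circle_offsets(1, 8), (2, 2))
        assert np.allclose(v, 42.0)

    def test_integer_position_exact(self):
        img = np.arange(25, dtype=float).reshape(5, 5)
        v = sample_neighbors(img, circle_offsets(1, 8), (2, 2))
        assert v[0] == img[2, 3]       # angle 0 -> (dy, dx) = (0, 1)
        assert v[2] == img[1, 2]       # angle 90 deg -> (-1, 0)

    def test_bilinear_matches_hand_computation(self):
        img = np.add.outer(np.arange(3.0), 10 * np.arange(3.0))
        offs = circle_offsets(1, 8)
        v = sample_neighbors(img, offs, (1, 1))
        from oracles import bilinear
        for k, (dy, dx) in enumerate(offs):
            assert v[k] == pytest.approx(bilinear(img, 1 + dy, 1 + dx),
                                         abs=1e-12)

    def test_outside_valid_region_raises(self):
        img = np.zeros((5, 5))
        with pytest.raises(ValueError):
            sample_neighbors(img, circle_offsets(1, 8), (0, 0))


class TestLbp:
    def test_constant_image_mass_on_all_ones_code(self):
        img = np.full((10, 10), 50.0)
        h = lbp_histogram(img, ((1, 8),))
        table, _ = uniform_table(8)
        assert h[table[255]] == 1.0
        assert h.sum() == pytest.approx(1.0)

    def test_multiscale_length(self, small_image):
        assert lbp_histogram(small_image).shape == (59 + 243,)

    def test_matches_bruteforce_oracle(self, small_image):
        h = lbp_histogram(small_image, ((1, 8),))
        expect = lbp_histogram_oracle(small_image, 1, 8)
        assert np.allclose(h, expect, atol=1e-9)

    def test_bright_center_pixel_oracle(self):
        img = np.full((5, 5), 10.0)
        img[2, 2] = 250.0
        assert np.allclose(lbp_histogram(img, ((1, 8),)),
                           lbp_histogram_oracle(img, 1, 8), atol=1e-12)

    def test_riu2_invariant_under_90deg_rotation(self, rng):
        img = rng.uniform(0, 255, size=(12, 12))
        h1 = lbp_histogram(img, ((1, 8),), mapping="riu2")
        h2 = lbp_histogram(np.rot90(img), ((1, 8),), mapping="riu2")
        assert np.allclose(h1, h2, atol=1e-12)


class TestLtp:
    def test_tau_zero_positive_half_equals_lbp(self, small_image):
        h_ltp = ltp_histograms(small_image, ((1, 8),), tau=0.0)
        h_lbp = lbp_histogram(small_image, ((1, 8),))
        assert np.allclose(h_ltp[:59], h_lbp, atol=1e-12)

    def test_constant_image_concentrates_on_zero_pattern(self):
        img = np.full((10, 10), 99.0)
        h = ltp_histograms(img, ((1, 8),), tau=5.0)
        table, _ = uniform_table(8)
        zero_bin = table[0]
        assert h[zero_bin] == 1.0 and h[59 + zero_bin] == 1.0

    def test_matches_bruteforce_ternary_oracle(self, small_image):
        h = ltp_histograms(small_image, ((1, 8),), tau=3.0)
        pos, neg = ltp_histogram_oracle(small_image, 1, 8, 3.0)
        assert np.allclose(h[:59], pos, atol=1e-9)
        assert np.allclose(h[59:], neg, atol=1e-9)


class TestLpq:
    def test_constant_image_all_labels_zero(self):
        h = lpq_histogram(np.full((12, 12), 77.0), r=3)
        assert h[0] == 1.0

    @pytest.mark.parametrize("tau,length", [(None, 256), (0.5, 512)])
    def test_output_lengths(self, small_image, tau, length):
        assert lpq_histogram(small_image, r=3, ternary_tau=tau).shape \
            == (length,)

    def test_multiscale_length(self, small_image):
        assert multiscale_lpq_histogram(small_image).shape == (512,)

    @pytest.mark.parametrize("a,rho", [(1.0, 0.9), (1.6, 1.55)])
    def test_labels_match_windowed_dft_oracle(self, rng, a, rho):
        img = rng.uniform(0, 255, size=(9, 9))
        (lab,) = lpq_label_images(img, r=3, a=a, rho=rho)
        expect = lpq_labels_oracle(img, 3, a, rho)
        assert np.array_equal(lab.codes, expect)

    def test_even_window_rejected(self, small_image):
        with pytest.raises(ValueError):
            lpq_histogram(small_image, r=4)


class TestLcp:
    def test_constant_image_finite(self):
        feats = lcp_features(np.full((12, 12), 5.0), ((1, 8),))
        assert np.all(np.isfinite(feats))

    def test_feature_length_bookkeeping(self, small_image):
        # per config: (P+2)*P weight-DFT magnitudes + (P+2) occurrences
        feats = lcp_features(small_image, ((1, 8),))
        assert feats.shape == (10 * 8 + 10,)
        both = lcp_features(small_image)
        assert both.shape == (90 + 18 * 16 + 18,)

    def test_weights_match_normal_equations(self, rng):
        img = rng.uniform(0, 255, size=(7, 7))
        from texens.descriptors import neighbor_stack
        from texens.mapping import mapping_table as mt
        stack, center, _ = neighbor_stack(img, circle_offsets(1, 8))
        bits = stack >= center[:, :, None]
        codes = (bits << np.arange(8)).sum(axis=2)
        table, _ = mt(8, "riu2")
        classes = table[codes]
        feats = lcp_features(img, ((1, 8),))
        k = classes.ravel()[0]
        sel = classes.ravel() == k
        a_mat = stack.reshape(-1, 8)[sel]
        b = center.ravel()[sel]
        w = np.linalg.solve(a_mat.T @ a_mat + 1e-6 * np.eye(8), a_mat.T @ b)
        assert np.allclose(feats[k * 8:(k + 1) * 8], np.abs(np.fft.fft(w)),
                           atol=1e-9)


class TestRiclbp:
    def test_constant_image_occupies_only_uniform_pair_classes(self):
        # the all-ones code pairs with itself; axis and diagonal
        # displacements live in separate quarter-turn orbits
        h = riclbp_histogram(np.full((20, 20), 3.0), radii=(1,))
        assert np.count_nonzero(h) == 2

    def test_rotation_90deg_invariance(self, rng):
        img = rng.uniform(0, 255, size=(16, 16))
        h1 = riclbp_histogram(img, radii=(1, 2))
        h2 = riclbp_histogram(np.rot90(img), radii=(1, 2))
        assert np.allclose(h1, h2, atol=1e-12)

    def test_orbit_count_matches_bruteforce_enumeration(self):
        _, n_classes = riclbp_orbit_table(4)
        assert n_classes == riclbp_orbit_count_oracle(4)

    def test_histogram_blocks_normalized(self, rng):
        img = rng.uniform(0, 255, size=(24, 24))
        h = riclbp_histogram(img)
        _, n = riclbp_orbit_table(4)
        for i in range(3):
            assert h[i * n:(i + 1) * n].sum() == pytest.approx(1.0)


class TestWld:
    def test_constant_image_central_excitation_bin(self):
        h = wld_histogram(np.full((10, 10), 128.0), 6, 8)
        # xi = 0 -> excitation bin 3 of 6; orientation of zero gradient -> bin 0
        assert h[3 * 8 + 0] == 1.0

    def test_output_length(self, small_image):
        assert wld_histogram(small_image, 5, 7).shape == (35,)

    def test_matches_arctan_oracle(self, rng):
        img = rng.uniform(0, 255, size=(6, 6))
        assert np.allclose(wld_histogram(img, 6, 8),
                           wld_histogram_oracle(img, 6, 8), atol=1e-9)


class TestColors:
    def test_output_length_42(self, rng):
        rgb = rng.uniform(0, 255, size=(16, 16, 3))
        assert colors_features(rgb).shape == (42,)

    def test_constant_color_statistics(self):
        rgb = np.full((16, 16, 3), 100.0)
        f = colors_features(rgb)
        per = f.reshape(3, 14)
        assert np.allclose(per[:, 2:6], 0.0)        # sd + central moments
        assert np.allclose(per[:, 6:].max(axis=1), 1.0)  # one full hist bin

    def test_checkerboard_homogeneity_hand_value(self):
        chan = np.zeros((8, 8))
        chan[::2, 1::2] = 255.0
        chan[1::2, ::2] = 255.0
        rgb = np.stack([chan] * 3, axis=-1)
        f = colors_features(rgb)
        # horizontal co-occurrence always pairs levels 0 and 7:
        # homogeneity = sum p/(1+|i-j|) = 1/(1+7)
        assert f[1] == pytest.approx(1.0 / 8.0)

    def test_grayscale_input_rejected(self, random_image):
        with pytest.raises(ValueError, match="COLORS"):
            colors_features(random_image)


class TestHistogramInvariants:
    @pytest.mark.parametrize("func", [
        lambda im: lbp_histogram(im, ((1, 8),)),
        lambda im: ltp_histograms(im, ((1, 8),), tau=4.0),
        lambda im: lpq_histogram(im, r=3),
        lambda im: riclbp_histogram(im, radii=(1,)),
        lambda im: wld_histogram(im),
    ], ids=["lbp", "ltp", "lpq", "riclbp", "wld"])
    def test_nonnegative_with_unit_blocks(self, rng, func):
        img = rng.uniform(0, 255, size=(14, 14))
        h = func(img)
        assert np.all(h >= 0)
        # total mass equals the number of normalized blocks
        assert h.sum() == pytest.approx(round(h.sum()))
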