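import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from texens.descriptors import circle_offsets
from texens.mapping import mapping_table
from texens.quinary import (CIRCLE_ONLY, MLQP_THRESHOLDS, GeometricLocus,
                            QuinaryThresholds, default_loci, locus_points,
                            mlcp_channels, mlpq_channels, mlqp_channels,
                            quinary_encode, split_quinary)
from texens.selection import sffs_select, subset_objective, \
    oof_score_matrices


class TestQuinaryEncode:
    TH = QuinaryThresholds(2.0, 4.0)

    @pytest.mark.parametrize("x,digit", [
        (5, 2), (3, 1), (0, 0), (-3, -1), (-5, -2),
        (4, 2),        # x = tau2 -> 2 (boundary inclusive)
        (-2, 0),       # x = -tau1 -> lower edge of the middle band
        (2, 1),        # x = tau1 -> 1
        (-4, -1),      # x = -tau2 -> -1
    ])
    def test_piecewise_values(self, x, digit):
        assert quinary_encode(x, self.TH) == digit

    @given(st.floats(min_value=-50, max_value=50,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_exactly_one_branch_fires(self, x):
        th = QuinaryThresholds(1.5, 6.0)
        d = quinary_encode(x, th)
        branches = [x >= th.tau2,
                    th.tau1 <= x < th.tau2,
                    -th.tau1 <= x < th.tau1,
                    -th.tau2 <= x < -th.tau1,
                    x < -th.tau2]
        assert sum(branches) == 1
        assert d == [2, 1, 0, -1, -2][branches.index(True)]

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            QuinaryThresholds(4.0, 2.0)
        with pytest.raises(ValueError):
            QuinaryThresholds(0.0, 2.0)


class TestSplitQuinary:
    def test_worked_example(self):
        pats = split_quinary(np.array([2, 0, -1, 1]))
        assert np.array_equal(pats[0], [1, 0, 0, 0])   # c = 2
        assert np.array_equal(pats[1], [0, 0, 0, 1])   # c = 1
        assert np.array_equal(pats[2], [0, 0, 1, 0])   # c = -1
        assert np.array_equal(pats[3], [0, 0, 0, 0])   # c = -2

    def test_partition_of_nonzero_digits(self, rng):
        digits = rng.integers(-2, 3, size=40)
        pats = split_quinary(digits)
        assert np.array_equal(sum(pats), (digits != 0).astype(int))

    def test_all_zero_digits(self):
        for pat in split_quinary(np.zeros(8, dtype=int)):
            assert not pat.any()


class TestLoci:
    def test_circle_reproduces_lbp_sampling(self):
        pts = locus_points(GeometricLocus("circle", (1.0,), 0.0, 8))
        assert np.allclose(pts, circle_offsets(1, 8), atol=1e-12)

    def test_ellipse_90deg_rotation_swaps_axes(self):
        base = locus_points(GeometricLocus("ellipse", (2.0, 1.0), 0.0, 8))
        rot = locus_points(GeometricLocus("ellipse", (2.0, 1.0), 90.0, 8))
        # rotating (dy, dx) by 90 deg CCW in math coords: (dy,dx)->(-dx,dy)
        expect = np.column_stack([base[:, 1], -base[:, 0]])
        assert np.allclose(np.sort(rot, axis=0), np.sort(expect, axis=0),
                           atol=1e-9)

    def test_spiral_b0_lies_on_circle(self):
        pts = locus_points(GeometricLocus("spiral", (1.0, 0.0), 0.0, 8))
        assert np.allclose(np.hypot(pts[:, 0], pts[:, 1]), 1.0, atol=1e-12)

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            locus_points(GeometricLocus("ellipse", (0.0, 1.0), 0.0, 8))

    def test_circle_rotation_forbidden(self):
        with pytest.raises(ValueError):
            GeometricLocus("circle", (1.0,), 45.0, 8)

    def test_default_family_has_17_loci(self):
        loci = default_loci()
        assert len(loci) == 17
        assert len({l.tag for l in loci}) == 17


class TestChannelGrids:
    def test_threshold_grid_is_25_pairs(self):
        assert len(MLQP_THRESHOLDS) == 25
        assert {t.tau1 for t in MLQP_THRESHOLDS} == {1, 3, 5, 7, 9}
        for t in MLQP_THRESHOLDS:
            assert t.tau2 - t.tau1 in (2, 4, 6, 8, 10)

    def test_mlqp_circle_only_25_channels(self, rng):
        img = rng.uniform(0, 255, size=(12, 12))
        chans = mlqp_channels(img)
        assert len(chans) == 25
        assert all(h.shape == (4 * 59,) for _, h in chans)

    def test_mlqp_constant_image_zero_patterns(self):
        img = np.full((10, 10), 30.0)
        table, _ = mapping_table(8, "u2")
        zero_bin = table[0]
        for _, h in mlqp_channels(img, MLQP_THRESHOLDS[:2]):
            for block in range(4):
                assert h[block * 59 + zero_bin] == 1.0

    def test_mlcp_grid_and_degenerate_input(self):
        img = np.full((10, 10), 4.0)
        chans = mlcp_channels(img, MLQP_THRESHOLDS[:3])
        assert len(chans) == 3
        for _, h in chans:
            assert np.all(np.isfinite(h))

    def test_mlcp_huge_tau_only_zero_pattern_block(self, rng):
        img = rng.uniform(0, 255, size=(10, 10))
        th = QuinaryThresholds(500.0, 600.0)
        [(_, h)] = mlcp_channels(img, [th])
        per = h.reshape(4, 90)
        for blk in per:
            weights = blk[:80].reshape(10, 8)
            assert np.allclose(weights[1:], 0.0)   # only class 0 occupied
            assert blk[80] == 1.0                  # all mass on zero pattern

    @pytest.mark.parametrize("mode,count", [("mlpq", 5), ("mlpqens", 96)])
    def test_mlpq_channel_counts(self, rng, mode, count):
        img = rng.uniform(0, 255, size=(12, 12))
        chans = mlpq_channels(img, mode)
        assert len(chans) == count

    def test_mlpq_constant_image_zero_pattern(self):
        img = np.full((12, 12), 60.0)
        for _, h in mlpq_channels(img, "mlpq"):
            per = h.reshape(-1, 256)
            assert np.all(per[:, 0] == 1.0)


def _toy_channels(rng, n_noise=4, n=60):
    """One informative channel + pure-noise channels, two classes."""
    labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    informative = np.where(labels == "a", 1.0, -1.0)[:, None] \
        + rng.normal(0, 0.3, (n, 3))
    chans = [informative]
    for _ in range(n_noise):
        chans.append(rng.normal(size=(n, 3)))
    return chans, labels


class TestSffs:
    def test_selects_informative_channel(self, rng):
        chans, labels = _toy_channels(rng)
        state = sffs_select(chans, labels, folds=5, max_size=3, seed=0)
        assert 0 in state.selected
        assert state.objective > 95.0

    def test_matches_exhaustive_subset_search(self, rng):
        from itertools import combinations
        chans, labels = _toy_channels(rng, n_noise=4)
        oof = oof_score_matrices(chans, labels, folds=5, seed=0)
        best_obj, best_sub = -1.0, None
        for k in range(1, len(chans) + 1):
            for sub in combinations(range(len(chans)), k):
                obj = subset_objective(oof, labels, sub)
                if obj > best_obj:
                    best_obj, best_sub = obj, sub
        state = sffs_select(chans, labels, folds=5,
                            max_size=len(chans), seed=0)
        assert state.objective == pytest.approx(best_obj, abs=1e-9)

    def test_objective_at_least_best_singleton(self, rng):
        chans, labels = _toy_channels(rng, n_noise=3)
        oof = oof_score_matrices(chans, labels, folds=5, seed=0)
        singles = max(subset_objective(oof, labels, [j])
                      for j in range(len(chans)))
        state = sffs_select(chans, labels, folds=5, max_size=4, seed=0)
        assert state.objective >= singles - 1e-12

    def test_history_objectives_non_decreasing(self, rng):
        chans, labels = _toy_channels(rng, n_noise=5)
        state = sffs_select(chans, labels, folds=5, max_size=5, seed=0)
        objs = [o for _, _, o in state.history]
        assert all(b >= a for a, b in zip(objs, objs[1:]))

    def test_single_class_rejected(self, rng):
        chans = [rng.normal(size=(10, 2)), rng.normal(size=(10, 2))]
        with pytest.raises(ValueError):
            sffs_select(chans, np.array(["a"] * 10), folds=3)

    def test_group_aware_folding(self, rng):
        chans, labels = _toy_channels(rng, n_noise=1, n=40)
        groups = np.repeat(np.arange(10), 4)
        state = sffs_select(chans, labels, groups=groups, folds=5, seed=0)
        assert state.selected
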