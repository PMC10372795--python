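import numpy as np
import pytest

from etem.config import LowFusionConfig
from etem.lowfreq import (consistency_filter, fuse_low, guided_filter,
                          initial_maps, random_walk_combine)

from oracles import absorbing_chain_probability, naive_consistency, \
    naive_guided_filter


def _partition(pair):
    m1, m2 = pair
    np.testing.assert_array_equal(m1 + m2, 1.0)
    assert set(np.unique(m1)) <= {0.0, 1.0}


class TestInitialMaps:
    def test_strict_dominance(self, rng):
        l1 = rng.random((8, 8)) + 2.0
        l2 = rng.random((8, 8))
        maps = initial_maps((l1, l2), (l1, l2), (l1, l2))
        np.testing.assert_array_equal(maps.lmp[0], 1.0)
        np.testing.assert_array_equal(maps.lmp[1], 0.0)

    def test_ties_go_to_first_source(self, rng):
        x = rng.random((8, 8))
        maps = initial_maps((x, x.copy()), (x, x.copy()), (x, x.copy()))
        for pair in maps:
            np.testing.assert_array_equal(pair[0], 1.0)

    def test_all_maps_partition(self, rng):
        args = [(rng.random((10, 10)), rng.random((10, 10)))
                for _ in range(3)]
        for mode in ("literal", "union"):
            maps = initial_maps(*args, LowFusionConfig(tlmp_mode=mode))
            for pair in maps:
                _partition(pair)

    def test_literal_mode_reduces_to_source_map(self, rng):
        args = [(rng.random((10, 10)), rng.random((10, 10)))
                for _ in range(3)]
        maps = initial_maps(*args, LowFusionConfig(tlmp_mode="literal"))
        np.testing.assert_array_equal(maps.tlmp[0], maps.slmp[0])


class TestGuidedFilter:
    def test_constant_input_is_fixed_point(self, rng):
        guide = rng.random((12, 12))
        out = guided_filter(guide, np.full((12, 12), 0.6), r=3, eps=0.3)
        np.testing.assert_allclose(out, 0.6, atol=1e-10)

    def test_huge_eps_gives_box_mean(self, rng):
        guide = rng.random((12, 12))
        src = rng.random((12, 12))
        out = guided_filter(guide, src, r=2, eps=1e12)
        from etem.lowfreq import _box_mean
        np.testing.assert_allclose(out, np.clip(_box_mean(_box_mean(src, 2), 2), 0, 1),
                                   atol=1e-6)

    def test_matches_windowed_regression_oracle(self, rng):
        guide = rng.random((16, 16))
        src = rng.random((16, 16))
        out = guided_filter(guide, src, r=2, eps=0.3)
        expected = naive_guided_filter(guide, src, 2, 0.3)
        assert np.max(np.abs(out - expected)) < 1e-6


class TestRandomWalker:
    def test_one_sided_seeding_selects_first_map(self):
        gmp_a = np.ones((6, 6))
        gmp_b = np.zeros((6, 6))
        guide = np.linspace(0, 1, 36).reshape(6, 6)
        m, u = random_walk_combine(gmp_a, gmp_b, guide)
        np.testing.assert_allclose(u, 0.5, atol=1e-10)
        np.testing.assert_array_equal(m, gmp_a)

    def test_unique_absorbing_class_wins_everywhere(self):
        cfg = LowFusionConfig()
        gmp_a = np.full((6, 6), 0.5)
        gmp_a[2, 3] = 0.95  # the single A-seed
        gmp_b = np.full((6, 6), 0.5)  # no B-seeds
        guide = np.full((6, 6), 0.3)  # uniform -> all edge weights equal
        m, u = random_walk_combine(gmp_a, gmp_b, guide, cfg)
        np.testing.assert_allclose(u, 1.0, atol=1e-8)
        np.testing.assert_array_equal(m, gmp_a)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_absorbing_chain_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cfg = LowFusionConfig()
        # moderate guide contrast keeps the lattice well connected
        guide = 0.35 * rng.random((6, 6))
        gmp_a = rng.random((6, 6))
        gmp_b = rng.random((6, 6))
        m, u = random_walk_combine(gmp_a, gmp_b, guide, cfg)
        from etem.lowfreq import _seed_weights
        y_a = _seed_weights(gmp_a, cfg)
        y_b = _seed_weights(gmp_b, cfg)
        if not np.any(y_a + y_b):
            pytest.skip("no seeds drawn")
        expected = absorbing_chain_probability(guide, y_a, y_b, cfg.rw_sigma)
        assert np.max(np.abs(u - expected)) < 1e-8
        assert u.min() >= 0.0 and u.max() <= 1.0

    def test_no_seeds_falls_back_with_warning(self):
        flat = np.full((6, 6), 0.5)  # inside the (0.2, 0.8) dead zone
        with pytest.warns(UserWarning, match="no random-walker seeds"):
            m, u = random_walk_combine(flat, flat, flat)
        np.testing.assert_array_equal(m, flat)


class TestConsistencyFilter:
    def test_extremes(self):
        np.testing.assert_array_equal(
            consistency_filter(np.ones((12, 12)), 9), 1.0)
        np.testing.assert_array_equal(
            consistency_filter(np.full((12, 12), 0.4), 9), 0.0)

    def test_matches_bruteforce(self, rng):
        m = rng.random((12, 12))
        out = consistency_filter(m, 9)
        np.testing.assert_array_equal(out, naive_consistency(m, 9))


class TestFuseLow:
    def test_pure_selection(self, rng):
        l1, l2 = rng.random((2, 8, 8))
        np.testing.assert_array_equal(fuse_low((l1, l2), np.ones((8, 8))), l1)
        np.testing.assert_array_equal(fuse_low((l1, l2), np.zeros((8, 8))), l2)

    def test_checkerboard_interleaves(self, rng):
        l1, l2 = rng.random((2, 8, 8))
        board = np.indices((8, 8)).sum(axis=0) % 2
        out = fuse_low((l1, l2), board.astype(float))
        np.testing.assert_array_equal(out[board == 1], l1[board == 1])
        np.testing.assert_array_equal(out[board == 0], l2[board == 0])
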