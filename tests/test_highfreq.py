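import numpy as np
import pytest

from etem.config import HighFusionConfig
from etem.highfreq import (fuse_high, ge_operator, local_entropy,
                           local_window_stats, saliency_operator)
from etem.phantoms import PhantomSpec, make_pair

from oracles import naive_ge, naive_local_entropy, naive_window_stats


class TestWindowStats:
    def test_constant(self):
        arr = np.full((8, 8), 2.5)
        mx, mn = local_window_stats(arr, 3)
        np.testing.assert_array_equal(mx, arr)
        np.testing.assert_array_equal(mn, arr)

    def test_single_spike(self):
        arr = np.zeros((5, 5))
        arr[2, 2] = 1.0
        mx, _ = local_window_stats(arr, 3)
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 1.0
        np.testing.assert_array_equal(mx, expected)

    def test_matches_bruteforce(self, rng):
        arr = rng.random((16, 16))
        mx, mn = local_window_stats(arr, 3)
        omx, omn = naive_window_stats(arr, 3)
        np.testing.assert_array_equal(mx, omx)
        np.testing.assert_array_equal(mn, omn)


class TestLocalEntropy:
    def test_constant_window_zero(self):
        assert np.all(local_entropy(np.full((6, 6), 0.3), 3, 8) == 0.0)

    def test_uniform_histogram(self):
        # 9 values in 9 distinct bins of a 9-bin histogram -> log2(9) bits
        tile = np.arange(9, dtype=float).reshape(3, 3) / 8.0
        arr = np.tile(tile, (3, 3))
        ent = local_entropy(arr, 3, 9)
        assert ent[4, 4] == pytest.approx(np.log2(9))

    def test_matches_bruteforce(self, rng):
        arr = rng.random((16, 16))
        ent = local_entropy(arr, 3, 8)
        np.testing.assert_allclose(ent, naive_local_entropy(arr, 3, 8),
                                   atol=1e-12)


class TestGEOperator:
    def test_zero_band_is_zero(self):
        out = ge_operator(np.zeros((10, 10)), np.random.default_rng(0).random((10, 10)))
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_literal_transcription(self, rng):
        high = np.zeros((7, 7))
        high[:, 4:] = 0.5  # one step edge
        high += 0.01 * rng.random((7, 7))
        source = rng.random((7, 7))
        cfg = HighFusionConfig(psi=3, entropy_bins=8)
        out = ge_operator(high, source, cfg)
        np.testing.assert_allclose(out, naive_ge(high, source, 3, 8),
                                   atol=1e-12)

    def test_sharp_half_outranks_blurred_half(self):
        a, b, masks = make_pair(PhantomSpec(kind="step-texture", size=96,
                                            seed=2, texture_amplitude=0.1))
        from scipy import ndimage
        sharp_left = b.copy()
        sharp_left[:, 48:] = ndimage.gaussian_filter(b, 4.0,
                                                     mode="nearest")[:, 48:]
        from etem.decompose import decompose
        bands = decompose(sharp_left)
        ge = ge_operator(bands.high, sharp_left)
        assert ge[:, :48].mean() > ge[:, 48:].mean()

    def test_scaling_band_never_decreases_saliency(self, rng):
        high = rng.standard_normal((12, 12)) * 0.1
        source = rng.random((12, 12))
        base = ge_operator(high, source)
        scaled = ge_operator(3.0 * high, source)
        assert np.all(scaled >= base - 1e-12)


class TestFuseHigh:
    def test_identical_bands(self, rng):
        h = rng.standard_normal((10, 10))
        s = rng.random((10, 10))
        fh, (m1, m2) = fuse_high((h, h.copy()), (s, s.copy()))
        np.testing.assert_array_equal(fh, h)
        np.testing.assert_array_equal(m1 + m2, 1.0)
        np.testing.assert_array_equal(m1, 1.0)  # ties go to source 1

    def test_dominant_saliency_selects_band(self, rng):
        h1, h2 = rng.standard_normal((2, 10, 10))
        fh, _ = fuse_high((h1, h2), (np.ones((10, 10)), np.zeros((10, 10))))
        np.testing.assert_array_equal(fh, h1)

    def test_selection_closure(self, rng):
        h1, h2 = rng.standard_normal((2, 12, 12))
        s1, s2 = rng.random((2, 12, 12))
        fh, (m1, m2) = fuse_high((h1, h2), (s1, s2))
        chosen = np.where(m1 == 1.0, h1, h2)
        np.testing.assert_array_equal(fh, chosen)
        assert np.all((m1 == 0) | (m1 == 1))


@pytest.mark.parametrize("operator", ["GE", "EOL", "SML", "STO"])
def test_operator_interface_preserves_fusion_contract(operator, rng):
    """Every ablation operator yields finite nonnegative saliency maps
    and a valid winner-take-all fusion."""
    h1, h2 = 0.1 * rng.standard_normal((2, 16, 16))
    s1, s2 = rng.random((2, 16, 16))
    cfg = HighFusionConfig(operator=operator)
    sal1 = saliency_operator(h1, s1, cfg)
    sal2 = saliency_operator(h2, s2, cfg)
    assert sal1.shape == h1.shape
    assert np.all(np.isfinite(sal1)) and np.all(sal1 >= 0)
    fh, (m1, m2) = fuse_high((h1, h2), (sal1, sal2))
    np.testing.assert_array_equal(m1 + m2, 1.0)
    assert np.all((fh == h1) | (fh == h2))
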