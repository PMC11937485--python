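"""Wavelet layer: perfect reconstruction, Parseval energy conservation,
agreement with an independent 2x2 block filter-bank oracle, and the
frequency-domain ablation filter."""

import numpy as np
import pytest

from mvmdm import wavelet
from mvmdm.wavelet import (
    SubbandSet,
    decompose_volume,
    frequency_filter,
    haar_dwt2,
    haar_idwt2,
    nyquist_radius,
)


def haar_block_oracle(img):
    """Brute-force single-level Haar as a 2x2 block transform (orthonormal)."""
    a, b = img[0::2, 0::2], img[0::2, 1::2]
    c, d = img[1::2, 0::2], img[1::2, 1::2]
    return (
        (a + b + c + d) / 2,
        (a + b - c - d) / 2,  # variation across rows: horizontal-edge content
        (a - b + c - d) / 2,
        (a - b - c + d) / 2,
    )


class TestHaarAnalysis:
    def test_constant_2x2(self):
        s = haar_dwt2(np.ones((2, 2)))
        assert s.CA[0, 0] == pytest.approx(2.0)
        for name in ("CH", "CV", "CD"):
            assert s.get(name)[0, 0] == pytest.approx(0.0)

    def test_2x2_worked_values(self):
        s = haar_dwt2(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert s.CA[0, 0] == pytest.approx(5.0)
        assert abs(s.CH[0, 0]) == pytest.approx(2.0)
        assert abs(s.CV[0, 0]) == pytest.approx(1.0)
        assert s.CD[0, 0] == pytest.approx(0.0)

    def test_orientation_convention(self):
        """CH responds to a horizontal edge (variation across rows), CV to a
        vertical edge."""
        hedge = np.zeros((4, 4))
        hedge[1:3, :] = 1.0  # edge crosses block interiors
        s = haar_dwt2(hedge)
        assert np.abs(s.CH).sum() > 0 and np.abs(s.CV).sum() == 0
        s = haar_dwt2(hedge.T)
        assert np.abs(s.CV).sum() > 0 and np.abs(s.CH).sum() == 0

    def test_matches_block_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=(8, 8))
            s = haar_dwt2(x)
            for got, want in zip((s.CA, s.CH, s.CV, s.CD), haar_block_oracle(x)):
                np.testing.assert_allclose(got, want, atol=1e-10)

    def test_shape_halving_256(self, rng):
        s = haar_dwt2(rng.normal(size=(256, 256)))
        assert all(s.get(n).shape == (128, 128) for n in ("CA", "CH", "CV", "CD"))

    def test_one_pixel_dimension_rejected(self):
        with pytest.raises(ValueError):
            haar_dwt2(np.ones((1, 8)))

    def test_linearity(self, rng):
        x, y = rng.normal(size=(2, 8, 8))
        sx, sy, sxy = haar_dwt2(x), haar_dwt2(y), haar_dwt2(2.0 * x - 3.0 * y)
        for name in ("CA", "CH", "CV", "CD"):
            np.testing.assert_allclose(
                sxy.get(name), 2.0 * sx.get(name) - 3.0 * sy.get(name), atol=1e-10
            )


class TestReconstruction:
    def test_round_trip_and_parseval_random_even_sizes(self, rng):
        for _ in range(100):
            h, w = rng.integers(1, 17, size=2) * 2
            x = rng.normal(size=(int(h), int(w)))
            s = haar_dwt2(x)
            np.testing.assert_allclose(haar_idwt2(s), x, atol=1e-10)
            coeff_energy = sum(np.sum(s.get(n) ** 2) for n in ("CA", "CH", "CV", "CD"))
            assert coeff_energy == pytest.approx(np.sum(x**2), rel=1e-8)

    def test_inverse_of_constant(self):
        s = SubbandSet(CA=np.array([[2.0]]), CH=np.zeros((1, 1)), CV=np.zeros((1, 1)), CD=np.zeros((1, 1)))
        np.testing.assert_allclose(haar_idwt2(s), np.ones((2, 2)), atol=1e-12)

    def test_mismatched_subband_shapes_rejected(self):
        s = SubbandSet(CA=np.zeros((2, 2)), CH=np.zeros((2, 2)), CV=np.zeros((2, 2)), CD=np.zeros((3, 2)))
        with pytest.raises(ValueError, match="shapes"):
            haar_idwt2(s)


class TestDecomposeVolume:
    def test_volume_shapes_and_no_cross_slice_mixing(self, rng):
        vol = rng.normal(size=(6, 16, 16))
        sub = decompose_volume(vol)
        assert sub.CA.shape == (6, 8, 8)
        # each slice's subbands depend on that slice alone
        one = haar_dwt2(vol[3])
        np.testing.assert_allclose(sub.CD[3], one.CD, atol=1e-12)

    def test_constant_slices_give_zero_details(self):
        sub = decompose_volume(np.full((3, 8, 8), 2.5))
        for name in ("CH", "CV", "CD"):
            np.testing.assert_allclose(sub.get(name), 0.0, atol=1e-12)

    def test_per_slice_round_trip(self, rng):
        vol = rng.normal(size=(4, 8, 8))
        sub = decompose_volume(vol)
        rec = np.stack(
            [
                haar_idwt2(SubbandSet(sub.CA[i], sub.CH[i], sub.CV[i], sub.CD[i]))
                for i in range(4)
            ]
        )
        np.testing.assert_allclose(rec, vol, atol=1e-10)

    def test_unknown_wavelet_rejected(self, rng):
        with pytest.raises(ValueError, match="wavelet"):
            wavelet.dwt2_subbands(rng.normal(size=(8, 8)), wavelet="db42")


class TestFrequencyFilter:
    def test_lowpass_at_nyquist_is_all_pass(self, rng):
        x = rng.normal(size=(16, 16))
        np.testing.assert_allclose(
            frequency_filter(x, nyquist_radius(x.shape), "lowpass"), x, atol=1e-8
        )

    def test_highpass_kills_constant(self):
        out = frequency_filter(np.full((8, 8), 3.0), 2.0, "highpass")
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_sinusoid_pass_and_stop(self):
        n, f = 64, 8
        x = np.cos(2 * np.pi * f * np.arange(n) / n)[None, :] * np.ones((n, 1))
        stopped = frequency_filter(x, f - 2, "lowpass")
        passed = frequency_filter(x, f, "lowpass")
        assert np.sum(stopped**2) < 1e-10 * np.sum(x**2)
        np.testing.assert_allclose(passed, x, atol=1e-8)

    @pytest.mark.parametrize("cutoff", [0.0, -1.0, 1e6])
    def test_cutoff_out_of_range(self, cutoff):
        with pytest.raises(ValueError):
            frequency_filter(np.ones((8, 8)), cutoff, "lowpass")

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            frequency_filter(np.ones((8, 8)), 2.0, "bandpass")
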