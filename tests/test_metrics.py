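"""Metric identities, hand-computed values and oracle cross-checks."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.signal import convolve2d
from skimage.metrics import structural_similarity as sk_ssim

from fdacnn import ValidationError, evaluate_batch, nrmse, psnr, ssim, vifp
from fdacnn.metrics import PSNR_CAP_DB


def reference_vifp(ref, dist, sigma_nsq=2.0):
    """Independent transcription of the standard pixel-domain VIF.

    Follows the published four-scale algorithm directly with
    convolve2d and explicit per-scale loops; serves as the oracle for
    the package's vectorised implementation.
    """
    ref = np.asarray(ref, dtype=np.float64)
    dist = np.asarray(dist, dtype=np.float64)
    if ref.max() <= 1.0:
        ref, dist = ref * 255.0, dist * 255.0
    eps = 1e-10
    num = den = 0.0
    for scale in range(1, 5):
        n = 2 ** (4 - scale + 1) + 1
        sd = n / 5.0
        ax = np.arange(n) - (n - 1) / 2.0
        g = np.exp(-(ax**2) / (2 * sd**2))
        win = np.outer(g, g)
        win /= win.sum()
        if scale > 1:
            ref = convolve2d(ref, win, mode="valid")[::2, ::2]
            dist = convolve2d(dist, win, mode="valid")[::2, ::2]
        mu1 = convolve2d(ref, win, mode="valid")
        mu2 = convolve2d(dist, win, mode="valid")
        s1 = np.maximum(convolve2d(ref * ref, win, mode="valid") - mu1**2, 0)
        s2 = np.maximum(convolve2d(dist * dist, win, mode="valid") - mu2**2, 0)
        s12 = convolve2d(ref * dist, win, mode="valid") - mu1 * mu2
        gq = s12 / (s1 + eps)
        sv = s2 - gq * s12
        gq[s1 < eps] = 0
        sv[s1 < eps] = s2[s1 < eps]
        s1[s1 < eps] = 0
        gq[s2 < eps] = 0
        sv[s2 < eps] = 0
        sv[gq < 0] = s2[gq < 0]
        gq[gq < 0] = 0
        sv[sv <= eps] = eps
        num += np.sum(np.log10(1 + gq**2 * s1 / (sv + sigma_nsq)))
        den += np.sum(np.log10(1 + s1 / sigma_nsq))
    return num / den


class TestPSNR:
    def test_identical_images_return_infinity(self, rng):
        t = rng.random((32, 32))
        assert math.isinf(psnr(t, t.copy()))

    def test_unit_mse_on_8bit_scale(self):
        t = np.full((32, 32), 255.0)
        r = np.full((32, 32), 254.0)
        assert psnr(t, r) == pytest.approx(20 * math.log10(255), abs=1e-9)

    def test_halving_mse_adds_3dB(self, rng):
        t = rng.random((32, 32))
        noise = rng.normal(size=(32, 32)) * 0.05
        a = psnr(t, t + noise)
        b = psnr(t, t + noise / math.sqrt(2))
        assert b - a == pytest.approx(10 * math.log10(2), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            psnr(np.zeros((8, 8)), np.zeros((9, 9)))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        t = rng.random((48, 48))
        assert ssim(t, t.copy()) == pytest.approx(1.0, abs=1e-12)

    def test_structural_inversion_degrades(self, rng):
        t = (rng.random((48, 48)) > 0.5).astype(float)
        assert ssim(t, 1.0 - t) < 1.0

    def test_matches_reference_implementation_on_random_pairs(self, rng):
        for _ in range(50):
            t = rng.random((64, 64))
            r = np.clip(t + rng.normal(size=(64, 64)) * rng.uniform(0.01, 0.3), 0, 1)
            expected = sk_ssim(t, r, data_range=float(t.max() - t.min()))
            assert ssim(t, r) == pytest.approx(expected, abs=1e-3)

    def test_constant_pair_conventions(self):
        c = np.full((16, 16), 0.5)
        assert ssim(c, c.copy()) == 1.0
        with pytest.raises(ValidationError):
            ssim(c, c + 0.1)


class TestNRMSE:
    def test_identity_is_zero(self, rng):
        t = rng.random((32, 32))
        assert nrmse(t, t.copy()) == 0.0

    def test_hand_computed_binary_swap(self):
        t = np.array([[0.0, 1.0]] * 8)
        r = np.array([[1.0, 0.0]] * 8)
        assert nrmse(t, r) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        t = rng.random((32, 32))
        r = rng.random((32, 32))
        assert nrmse(3.7 * t, 3.7 * r) == pytest.approx(nrmse(t, r), rel=1e-12)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValidationError):
            nrmse(np.ones((8, 8)), np.zeros((8, 8)))


class TestVIFP:
    def test_identity_scores_one(self, rng):
        t = rng.random((64, 64))
        assert vifp(t, t.copy()) == pytest.approx(1.0, abs=1e-6)

    def test_heavier_blur_scores_lower(self, rng):
        t = rng.random((64, 64))
        mild = gaussian_filter(t, 0.8)
        heavy = gaussian_filter(t, 3.0)
        assert vifp(t, heavy) < vifp(t, mild)

    def test_matches_reference_implementation_on_random_pairs(self, rng):
        for _ in range(50):
            t = gaussian_filter(rng.random((64, 64)), 1.0)
            r = np.clip(t + rng.normal(size=(64, 64)) * rng.uniform(0.005, 0.1), 0, 1)
            assert vifp(t, r) == pytest.approx(reference_vifp(t, r), abs=1e-3)

    def test_small_image_rejected(self):
        with pytest.raises(ValidationError):
            vifp(np.zeros((16, 16)), np.zeros((16, 16)))


class TestBatchEvaluation:
    def test_identical_pair_report(self, rng):
        t = rng.random((64, 64))
        report = evaluate_batch([t], [t.copy()])
        assert report.ssim[0] == pytest.approx(1.0)
        assert report.nrmse[0] == 0.0
        assert report.vifp[0] == pytest.approx(1.0, abs=1e-6)
        assert math.isinf(report.psnr[0])
        assert report.means["psnr"] == PSNR_CAP_DB

    def test_mean_is_arithmetic_average(self, rng):
        ts = [rng.random((64, 64)) for _ in range(2)]
        rs = [np.clip(t + rng.normal(size=t.shape) * 0.05, 0, 1) for t in ts]
        report = evaluate_batch(ts, rs)
        assert report.means["ssim"] == pytest.approx(np.mean(report.ssim))
        assert report.means["nrmse"] == pytest.approx(np.mean(report.nrmse))

    def test_permutation_stability(self, rng):
        ts = [rng.random((64, 64)) for _ in range(3)]
        rs = [np.clip(t + rng.normal(size=t.shape) * 0.1, 0, 1) for t in ts]
        fwd = evaluate_batch(ts, rs)
        rev = evaluate_batch(ts[::-1], rs[::-1])
        assert fwd.ssim == rev.ssim[::-1]
        assert fwd.psnr == rev.psnr[::-1]

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            evaluate_batch([rng.random((64, 64))], [])

    def test_psnr_nrmse_consistency(self, rng):
        # at fixed dynamic range, NRMSE is proportional to 10^(-PSNR/20)
        t = rng.random((64, 64))
        t[0, 0], t[0, 1] = 0.0, 1.0  # pin the range
        for sd in (0.02, 0.1):
            r = t + rng.normal(size=t.shape) * sd
            ratio = nrmse(t, r) / 10 ** (-psnr(t, r) / 20)
            assert ratio == pytest.approx(1.0, rel=1e-9)

    def test_csv_export(self, rng, tmp_path):
        ts = [rng.random((64, 64)) for _ in range(2)]
        report = evaluate_batch(ts, ts)
        out = tmp_path / "report.csv"
        report.to_csv(out)
        import pandas as pd

        frame = pd.read_csv(out)
        assert list(frame.columns) == ["slice", "label", "ssim", "psnr", "nrmse", "vifp"]
        assert len(frame) == 2
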