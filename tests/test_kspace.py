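"""Fourier model and under-sampling mask construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdacnn import (
    ConfigurationError,
    MaskSpec,
    ValidationError,
    apply_mask,
    forward_fft,
    inverse_fft,
    make_mask,
    zero_filled_recon,
)
from fdacnn.kspace import mcp_line_counts
from fdacnn.metrics import psnr


class TestFourier:
    def test_constant_image_concentrates_at_dc(self):
        n, c = 64, 0.7
        k = forward_fft(np.full((n, n), c)).values
        dc = n // 2
        assert k[dc, dc] == pytest.approx(c * n, rel=1e-10)
        off = k.copy()
        off[dc, dc] = 0
        assert np.abs(off).max() < 1e-10

    def test_parseval_energy_preservation(self, small_dataset):
        img = small_dataset.images[0].values
        k = forward_fft(img).values
        assert np.sum(img**2) == pytest.approx(np.sum(np.abs(k) ** 2), rel=1e-6)

    def test_round_trip_identity(self, rng):
        img = rng.random((64, 64))
        back = inverse_fft(forward_fft(img)).values
        np.testing.assert_allclose(back, img, atol=1e-10)

    def test_dc_impulse_gives_constant_magnitude(self):
        n = 32
        k = np.zeros((n, n), dtype=complex)
        k[n // 2, n // 2] = 5.0
        img = inverse_fft(k).values
        np.testing.assert_allclose(img, img[0, 0], rtol=1e-10)

    def test_zero_kspace_gives_zero_image(self):
        assert inverse_fft(np.zeros((32, 32), dtype=complex)).values.max() == 0.0

    def test_nonfinite_input_rejected(self):
        bad = np.full((32, 32), np.nan)
        with pytest.raises(ValidationError):
            forward_fft(bad)


class TestMaskConstruction:
    def test_mcp_composition_at_rate_020_on_100_lines(self):
        # 20% of 100 lines: half from the center, a quarter from the
        # periphery, a quarter at random
        s, sc, sp, sr = mcp_line_counts(100, 0.20)
        assert (s, sc, sp, sr) == (20, 10, 5, 5)
        assert sc / s == 0.5 and sp / s == 0.25 and sr / s == 0.25

    def test_mcp_rounding_at_256_lines(self):
        assert mcp_line_counts(256, 0.20) == (51, 26, 13, 12)

    @pytest.mark.parametrize("kind", ["mcp", "1dg", "2dg"])
    def test_full_rate_gives_all_ones(self, kind):
        m = make_mask(MaskSpec(kind=kind, sampling_rate=1.0, image_size=64, seed=0))
        assert m.matrix.all()

    @pytest.mark.parametrize("kind", ["mcp", "1dg", "2dg"])
    def test_ones_fraction_matches_rate_within_one_line(self, kind):
        n = 128
        m = make_mask(MaskSpec(kind=kind, sampling_rate=0.2, image_size=n, seed=1))
        assert abs(m.fraction - 0.2) <= 1.0 / n

    def test_mcp_structure_center_block_and_edges(self):
        n = 128
        m = make_mask(MaskSpec(kind="mcp", sampling_rate=0.2, image_size=n, seed=5))
        cols = m.matrix[0]  # line mask: every row identical
        assert (m.matrix == cols[None, :]).all()
        assert m.S == m.s_c + m.s_p + m.s_r
        dc = n // 2
        # contiguous center block including DC, extra line on the low side
        start = dc - m.s_c // 2
        assert cols[start : start + m.s_c].all()
        # outermost edge lines present on both sides
        n_low = (m.s_p + 1) // 2
        assert cols[:n_low].all() and cols[n - m.s_p // 2 :].all()

    def test_mask_determinism_and_seed_sensitivity(self):
        spec = MaskSpec(kind="mcp", sampling_rate=0.2, image_size=64, seed=9)
        a, b = make_mask(spec), make_mask(spec)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        c = make_mask(MaskSpec(kind="1dg", sampling_rate=0.2, image_size=64, seed=9))
        d = make_mask(MaskSpec(kind="1dg", sampling_rate=0.2, image_size=64, seed=10))
        assert (c.matrix != d.matrix).any()

    def test_gaussian_masks_always_include_dc(self):
        for kind in ("1dg", "2dg"):
            m = make_mask(MaskSpec(kind=kind, sampling_rate=0.1, image_size=64, seed=2))
            assert m.matrix[32, 32] == 1

    def test_too_small_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            make_mask(MaskSpec(kind="mcp", sampling_rate=0.005, image_size=64, seed=0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.sampled_from([64, 100, 128, 256]),
        rate=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_mcp_counts_property(self, n, rate):
        try:
            s, sc, sp, sr = mcp_line_counts(n, rate)
        except ConfigurationError:
            return
        assert s == sc + sp + sr
        assert s == int(np.floor(rate * n + 0.5))
        assert sc >= 1 and sp >= 0 and sr >= 0


class TestMaskApplication:
    def test_identity_and_annihilation(self, small_dataset, mcp_mask_64):
        k = small_dataset.kspaces[0].values
        ones = make_mask(MaskSpec(kind="mcp", sampling_rate=1.0, image_size=64, seed=0))
        np.testing.assert_array_equal(apply_mask(k, ones).values, k)
        masked = apply_mask(k, mcp_mask_64).values
        assert (masked[:, mcp_mask_64.matrix[0] == 0] == 0).all()

    def test_shape_mismatch_rejected(self, mcp_mask_64):
        with pytest.raises(ValidationError):
            apply_mask(np.zeros((32, 32), dtype=complex), mcp_mask_64)

    def test_nonzero_line_count(self, mcp_mask_64):
        assert int(mcp_mask_64.matrix.sum()) == mcp_mask_64.S * 64


class TestZeroFilled:
    def test_full_sampling_recovers_image(self, small_dataset):
        img = small_dataset.images[1].values
        ones = make_mask(MaskSpec(kind="mcp", sampling_rate=1.0, image_size=64, seed=0))
        rec = zero_filled_recon(small_dataset.kspaces[1].values, ones)
        np.testing.assert_allclose(rec.values, img, atol=1e-6)
        assert rec.role == "aliased"

    def test_zero_image_reconstructs_to_zero(self, mcp_mask_64):
        k = forward_fft(np.zeros((64, 64)))
        assert zero_filled_recon(k.values, mcp_mask_64).values.max() == 0.0

    def test_more_sampling_improves_psnr(self, small_dataset):
        img = small_dataset.images[2].values
        k = small_dataset.kspaces[2].values
        low = make_mask(MaskSpec(kind="1dg", sampling_rate=0.2, image_size=64, seed=4))
        high = make_mask(MaskSpec(kind="1dg", sampling_rate=0.5, image_size=64, seed=4))
        p_low = psnr(img, zero_filled_recon(k, low).values)
        p_high = psnr(img, zero_filled_recon(k, high).values)
        assert p_low < p_high

    def test_constant_image_aliases_to_constant(self):
        n = 64
        img = np.full((n, n), 0.6)
        mask = make_mask(MaskSpec(kind="mcp", sampling_rate=0.2, image_size=n, seed=0))
        rec = zero_filled_recon(forward_fft(img).values, mask).values
        np.testing.assert_allclose(rec, rec[0, 0], atol=1e-10)
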