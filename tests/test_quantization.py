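"""Embedding / blind extraction: the QIM contract at block and slice level."""

import numpy as np
import pytest

from niistego.block_transform import forward_block
from niistego.quantization import (
    QuantizationParams, denormalize, embed_block, embed_slice, extract_block,
    extract_slice, interval_index, median_filter_3x3, normalize,
)


class TestNormalize:
    def test_linear_map_and_clip(self):
        ns = normalize(np.array([0.0, 25.0, 50.0, 100.0, 150.0]), 0, 100)
        assert np.allclose(ns.values, [0.0, 0.25, 0.5, 1.0, 1.0])
        assert not ns.constant

    def test_constant_slice_flagged(self):
        ns = normalize(np.full((4, 4), 9.0), 9.0, 9.0)
        assert ns.constant and not ns.values.any()

    def test_denormalize_examples(self):
        assert denormalize(np.array([0.5]), 0, 100, np.uint16)[0] == 50
        assert denormalize(np.array([1.2]), 0, 100, np.uint16)[0] == 100  # clamp

    def test_roundtrip_exact_on_integers(self):
        """normalize/denormalize is the identity on every integer in [lo, hi]."""
        for lo, hi in [(0, 255), (3, 1000), (0, 4095)]:
            x = np.arange(lo, hi + 1, dtype=np.uint16)
            back = denormalize(normalize(x, lo, hi).values, lo, hi, np.uint16)
            assert np.array_equal(back, x)


class TestIntervalIndex:
    @pytest.mark.parametrize(
        "c_abs,beta,expect", [(0.5, 500, 125), (0.0, 500, 0), (2.0, 500, 499),
                              (0.004, 500, 1), (1.9999, 100, 99)]
    )
    def test_examples(self, c_abs, beta, expect):
        assert interval_index(c_abs, beta) == expect


class TestBlockCodec:
    def test_embed_moves_coefficient_within_its_interval(self):
        p = QuantizationParams(beta=500)
        cb = np.zeros((4, 4)); cb[0, 1] = 0.5
        mb = np.zeros((4, 4)); mb[0, 1] = 0.25
        stego = embed_block(cb, mb, p)
        assert stego[0, 1] == pytest.approx((2 / 500) * (0.25 + 125), abs=1e-12)  # 0.5010

    def test_sign_rule(self):
        p = QuantizationParams(beta=500)
        cb = np.zeros((4, 4)); cb[0, 1] = -0.5
        mb = np.zeros((4, 4)); mb[0, 1] = 0.25
        assert embed_block(cb, mb, p)[0, 1] == pytest.approx(-0.5010, abs=1e-12)

    def test_zero_message_lands_on_interval_boundary(self):
        p = QuantizationParams(beta=500)
        cb = np.zeros((4, 4)); cb[1, 1] = 0.5
        assert embed_block(cb, np.zeros((4, 4)), p)[1, 1] == pytest.approx(0.5, abs=1e-12)

    def test_extract_example_and_sign_invariance(self):
        p = QuantizationParams(beta=500)
        for s in (1.0, -1.0):
            cb = np.zeros((4, 4)); cb[0, 1] = s * 0.5010
            assert extract_block(cb, p)[0, 1] == pytest.approx(0.25, abs=1e-9)

    def test_dc_preserved_and_neighbour_filled(self, rng):
        p = QuantizationParams(beta=200)
        cover = forward_block(rng.random((20, 4, 4)))
        msg = rng.random((20, 4, 4))
        stego = embed_block(cover, msg, p)
        assert np.array_equal(stego[:, 0, 0], cover[:, 0, 0])
        rec = extract_block(stego, p)
        assert np.allclose(rec[:, 0, 0], 0.5 * (rec[:, 0, 1] + rec[:, 1, 0]), atol=0)

    @pytest.mark.parametrize("beta", [100, 500, 1000])
    def test_float_roundtrip_recovers_details(self, rng, beta):
        """embed then extract returns every detail message value to 1e-9."""
        p = QuantizationParams(beta=beta)
        cover = np.clip(rng.normal(0, 0.5, size=(10_000, 4, 4)), -1.999, 1.999)
        msg = rng.uniform(0, 1 - p.msg_clamp_eps, size=(10_000, 4, 4))
        rec = extract_block(embed_block(cover, msg, p), p)
        detail = np.ones((4, 4), dtype=bool); detail[0, 0] = False
        assert np.abs((rec - msg)[:, detail]).max() < 1e-9

    def test_interval_index_preserved_by_embedding(self):
        """The stego coefficient stays in the cover's interval for any message."""
        beta = 100
        p = QuantizationParams(beta=beta)
        c = np.linspace(0, 1.98, 67)
        m = np.linspace(0, 1 - p.msg_clamp_eps, 41)
        cc, mm = np.meshgrid(c, m)
        i = interval_index(cc, beta)
        stego = (2 / beta) * (np.minimum(mm, 1 - p.msg_clamp_eps) + i)
        assert np.array_equal(interval_index(np.abs(stego), beta), i)


class TestSliceCodec:
    def _pair(self, rng, shape=(32, 32)):
        cover = rng.integers(0, 4000, size=shape).astype(np.uint16)
        msg = np.clip(
            cover.astype(np.int64) + rng.integers(-200, 200, size=shape), 0, 4000
        ).astype(np.uint16)
        return cover, msg

    def test_stego_matches_cover_shape_and_dtype(self, rng):
        cover, msg = self._pair(rng)
        stego = embed_slice(cover, msg, QuantizationParams(beta=500), lo=0, hi=4000)
        assert stego.shape == cover.shape and stego.dtype == cover.dtype

    def test_constant_cover_passes_through(self):
        cover = np.full((16, 16), 55, np.uint16)
        msg = np.full((16, 16), 99, np.uint16)
        stego = embed_slice(cover, msg, QuantizationParams(beta=100), lo=55, hi=55)
        assert np.array_equal(stego, cover)

    def test_float_domain_pipeline_recovers_message_pixels(self, rng):
        """Without integer casting the reconstruction is exact off-DC/margins."""
        p = QuantizationParams(beta=500)
        cover, msg = self._pair(rng, shape=(34, 30))  # ragged: margins exist
        stego_norm = embed_slice(cover, msg, p, lo=0, hi=4000, cast=False)
        rec_norm = extract_slice(stego_norm, p, lo=0, hi=1, cast=False)
        msg_norm = normalize(msg, 0, 4000).values
        mask = np.zeros((34, 30), dtype=bool)
        mask[:32, :28] = True          # inside the block grid
        mask[0::4, 0::4] = False       # DC positions are neighbour-filled
        assert np.abs((rec_norm - msg_norm)[mask]).max() < 1.0 / p.beta

    def test_extraction_is_blind(self, rng):
        """extract_slice needs only the stego plane, beta and a range."""
        import inspect
        sig = inspect.signature(extract_slice)
        assert "cover" not in sig.parameters and "msg" not in sig.parameters

    def test_sign_symmetry_of_embedding(self, rng):
        """Embedding into -c then extracting equals embedding into +c."""
        p = QuantizationParams(beta=300)
        cover = forward_block(rng.random((50, 4, 4)))
        msg = rng.uniform(0, 0.99, size=(50, 4, 4))
        rec_pos = extract_block(embed_block(cover, msg, p), p)
        rec_neg = extract_block(embed_block(-cover, msg, p), p)
        detail = np.ones((4, 4), dtype=bool); detail[0, 0] = False
        assert np.allclose(rec_pos[:, detail], rec_neg[:, detail], atol=1e-12)


class TestMedianFilter:
    def test_impulse_removed(self):
        x = np.full((9, 9), 10, np.uint16)
        x[4, 4] = 1000
        assert median_filter_3x3(x)[4, 4] == 10

    def test_border_padding_modes(self):
        x = np.full((5, 5), 7, np.uint16)
        zero = median_filter_3x3(x, padding="zero")
        repl = median_filter_3x3(x, padding="replicate")
        assert np.array_equal(zero[1:-1, 1:-1], x[1:-1, 1:-1])
        assert np.array_equal(repl, x)           # replicate keeps constants
        assert zero[0, 0] == 0                   # 5 of 9 padded zeros win

    def test_center_of_1_to_9(self):
        x = np.arange(1, 10).reshape(3, 3)
        assert median_filter_3x3(x)[1, 1] == 5
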