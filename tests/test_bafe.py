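"""Haar decomposition algebra and cascaded windowed attention."""

import numpy as np
import pytest

from beamyolo.bafe import (BAFEBlock, BAFEConfig, HaarFilterBank,
                           SubbandSet, WindowedAttention, haar_decompose,
                           haar_reconstruct, subband_fuse)
from beamyolo.nn import functional as F


class TestHaarAlgebra:
    def test_filter_bank_is_orthonormal(self):
        bank = HaarFilterBank()
        np.testing.assert_allclose(bank.gram(), np.eye(4), atol=1e-15)
        assert bank.trainable is False

    def test_single_block_decomposition(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        s = haar_decompose(x)
        assert s.approx.item() == pytest.approx(5.0)
        assert s.horiz.item() == pytest.approx(2.0)
        assert s.vert.item() == pytest.approx(1.0)
        assert s.diag.item() == pytest.approx(0.0)

    def test_energy_conservation_on_single_block(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        s = haar_decompose(x)
        subband_energy = sum(float(np.sum(np.square(b))) for b in s)
        assert subband_energy == pytest.approx(30.0)

    def test_energy_conservation_random_even_dims(self, rng):
        x = rng.normal(size=(2, 3, 8, 10))
        s = haar_decompose(x)
        e_in = np.sum(x ** 2)
        e_out = sum(np.sum(np.square(b)) for b in s)
        assert e_out == pytest.approx(e_in, rel=1e-5)

    def test_constant_input_annihilated_by_high_pass(self):
        x = np.full((1, 2, 6, 6), 4.2)
        s = haar_decompose(x)
        np.testing.assert_allclose(s.approx, 2 * 4.2)
        for band in (s.horiz, s.vert, s.diag):
            np.testing.assert_allclose(band, 0.0, atol=1e-12)

    def test_reconstruction_inverts_single_block(self):
        s = SubbandSet(*(np.full((1, 1, 1, 1), v) for v in (5.0, 2.0, 1.0, 0.0)))
        x = haar_reconstruct(s)
        np.testing.assert_allclose(x.reshape(2, 2), [[1, 2], [3, 4]], atol=1e-12)

    def test_round_trip_random_even_dims(self, rng):
        x = rng.normal(size=(1, 3, 8, 8))
        back = haar_reconstruct(haar_decompose(x))
        assert np.abs(back - x).max() < 1e-6

    def test_zero_subbands_reconstruct_to_zero(self):
        s = SubbandSet(*(np.zeros((1, 1, 3, 3)) for _ in range(4)))
        np.testing.assert_allclose(haar_reconstruct(s), 0.0)

    def test_odd_dims_drop_trailing_row_col(self, rng):
        x = rng.normal(size=(1, 1, 5, 7))
        s = haar_decompose(x)
        assert s.approx.shape == (1, 1, 2, 3)
        s_even = haar_decompose(x[:, :, :4, :6])
        np.testing.assert_allclose(s.approx, s_even.approx)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="H, W >= 2"):
            haar_decompose(np.ones((1, 1, 1, 4)))

    def test_mismatched_subband_shapes_rejected(self):
        s = SubbandSet(np.zeros((1, 1, 2, 2)), np.zeros((1, 1, 2, 2)),
                       np.zeros((1, 1, 2, 2)), np.zeros((1, 1, 3, 3)))
        with pytest.raises(ValueError, match="differ"):
            haar_reconstruct(s)


class TestSubbandFuse:
    def test_elementwise_sum_and_passthrough(self):
        s = SubbandSet(*(np.full((1, 1, 1, 1), v) for v in (5.0, 2.0, 1.0, 0.0)))
        f_high, f_low = subband_fuse(s)
        assert f_high.item() == pytest.approx(3.0)
        assert f_low.item() == pytest.approx(5.0)

    def test_linearity(self, rng):
        bands = [rng.normal(size=(1, 2, 4, 4)) for _ in range(4)]
        h1, l1 = subband_fuse(SubbandSet(*bands))
        h2, l2 = subband_fuse(SubbandSet(*(3.0 * b for b in bands)))
        np.testing.assert_allclose(h2, 3.0 * h1)
        np.testing.assert_allclose(l2, 3.0 * l1)


class TestWindowedAttention:
    def test_rows_are_probability_vectors(self, rng):
        att = WindowedAttention(8, 8, heads=2, k=3)
        guide = rng.normal(size=(1, 8, 6, 6))
        a = att.attention_weights(guide, att.state())
        assert a.shape == (1, 2, 36, 9, 9)
        np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-5)
        assert np.all(a >= 0)

    def test_zero_queries_give_uniform_window_mean(self, rng):
        att = WindowedAttention(4, 4, heads=1, k=3)
        state = att.state()
        state["q"]["weight"] = np.zeros_like(state["q"]["weight"])
        state["key"]["weight"] = np.zeros_like(state["key"]["weight"])
        a = att.attention_weights(rng.normal(size=(1, 4, 5, 5)), state)
        np.testing.assert_allclose(a, 1.0 / 9.0, atol=1e-12)

    def test_k1_degenerates_to_projection_of_values(self, rng):
        att = WindowedAttention(4, 4, heads=2, k=1)
        guide = rng.normal(size=(1, 4, 5, 5))
        v = rng.normal(size=(1, 4, 5, 5))
        got = att((guide, v), att.state())
        vals = F.conv2d(v, att.state()["v"]["weight"])
        want = att.proj(vals)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_attention_invariant_to_slot_permutation_of_keys_and_values(self, rng):
        # softmax(q k^T) v is unchanged when key/value slots permute together
        kk, dh = 4, 3
        q = rng.normal(size=(1, 1, 2, kk, dh))
        k = rng.normal(size=(1, 1, 2, kk, dh))
        v = rng.normal(size=(1, 1, 2, kk, dh))

        def attend(k_, v_):
            a = F.softmax(np.einsum("bnlid,bnljd->bnlij", q, k_) / np.sqrt(dh))
            return np.einsum("bnlij,bnljd->bnlid", a, v_)

        perm = rng.permutation(kk)
        np.testing.assert_allclose(attend(k, v), attend(k[..., perm, :], v[..., perm, :]),
                                   atol=1e-12)

    def test_window_larger_than_map_rejected(self, rng):
        att = WindowedAttention(4, 4, heads=1, k=3)
        with pytest.raises(ValueError, match="exceeds spatial extent"):
            att((rng.normal(size=(1, 4, 2, 2)), rng.normal(size=(1, 4, 2, 2))),
                att.state())

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="not divisible"):
            WindowedAttention(8, 6, heads=4)


class TestBAFEBlock:
    def test_shape_contract_at_terminal_placement(self, rng):
        blk = BAFEBlock(BAFEConfig(32, mid_channels=48))
        x = rng.normal(size=(1, 32, 20, 20))
        assert blk(x).shape == (1, 32, 20, 20)

    def test_frozen_filters_survive_training_steps(self, rng):
        import autograd
        from autograd.misc import flatten

        blk = BAFEBlock(BAFEConfig(8, mid_channels=16, heads=2))
        blk.set_training(True)
        x = rng.normal(size=(2, 8, 8, 8))
        flat, unflatten = flatten(blk.state())
        grad_fn = autograd.grad(lambda f: np.sum(blk(x, unflatten(f)) ** 2) * 1e-3)
        before = blk.filter_bank.filters.copy()
        for _ in range(5):
            flat = flat - 0.01 * grad_fn(flat)
        blk.load_state(unflatten(flat))
        np.testing.assert_array_equal(blk.filter_bank.filters, before)
        assert blk.frozen_param_count() == 16

    def test_output_finite_for_large_amplitude_input(self, rng):
        blk = BAFEBlock(BAFEConfig(8, mid_channels=16, heads=2))
        x = rng.choice([-1e3, 1e3], size=(1, 8, 8, 8))
        assert np.all(np.isfinite(blk(x)))
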