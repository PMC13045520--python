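"""Progressive refinement decoder: up-sampling blocks, DF heads, the exact
warp laws of feature rectification, aggregation and the full forward pass."""

import numpy as np
import pytest

from prored.decoder import (DecoderConfig, RefinementModule, UpsampleBlock,
                            aggregate, frf_rectify)
from prored.model import ProredModel, tiny_config
from prored.nn import Conv2d, Tensor


def _ramp(h, w):
    """F0(x) = column index, constant over rows/channels."""
    return np.broadcast_to(np.arange(w, dtype=np.float32), (1, 1, h, w)).copy()


def _const_df(h, w, dx, dy):
    df = np.zeros((1, 2, h, w), dtype=np.float32)
    df[:, 0] = dx
    df[:, 1] = dy
    return df


class TestUpsampleBlock:
    def test_doubles_resolution_with_skip(self):
        rng = np.random.default_rng(0)
        block = UpsampleBlock(4, 3, 8, rng)
        x = Tensor(np.random.default_rng(1).random((1, 4, 16, 16), np.float32))
        skip = Tensor(np.random.default_rng(2).random((1, 3, 32, 32), np.float32))
        out = block(x, skip)
        assert out.data.shape == (1, 8, 32, 32)  # configured stage width

    def test_spatial_mismatch_raises(self):
        block = UpsampleBlock(4, 3, 8, np.random.default_rng(0))
        x = Tensor(np.zeros((1, 4, 16, 16), np.float32))
        with pytest.raises(ValueError, match="twice"):
            block(x, Tensor(np.zeros((1, 3, 48, 48), np.float32)))

    def test_zero_input_deterministic(self):
        block = UpsampleBlock(2, 0, 4, np.random.default_rng(3))
        x = Tensor(np.zeros((1, 2, 8, 8), np.float32))
        a, b = block(x).data, block(x).data
        assert np.array_equal(a, b) and (a >= 0).all()


class TestDFHead:
    def test_two_channel_output(self):
        head = Conv2d(16, 2, 1, rng=np.random.default_rng(0))
        out = head(Tensor(np.random.default_rng(1).random((2, 16, 9, 9), np.float32)))
        assert out.data.shape == (2, 2, 9, 9)

    def test_zero_weights_give_identity_rectification(self):
        head = Conv2d(8, 2, 1, rng=np.random.default_rng(0))
        head.weight.data[:] = 0
        head.bias.data[:] = 0
        f = Tensor(np.random.default_rng(2).random((1, 8, 6, 6), np.float32))
        df = head(f)
        warped = frf_rectify(f, df, steps=6)
        np.testing.assert_array_equal(warped.data, f.data)

    def test_gradient_reaches_head_from_df_supervision(self):
        from prored.losses import df_loss

        head = Conv2d(4, 2, 1, rng=np.random.default_rng(0))
        f = Tensor(np.random.default_rng(1).random((1, 4, 5, 5), np.float32))
        pred = head(f)
        gt = np.zeros((1, 2, 5, 5), np.float32)
        fg = np.ones((1, 5, 5), bool)
        df_loss(pred, gt, fg).backward()
        assert head.weight.grad is not None and np.abs(head.weight.grad).sum() > 0


class TestFrfRectify:
    @pytest.mark.parametrize("steps", [0, 1, 3, 6])
    def test_zero_field_is_exact_identity(self, steps):
        f = Tensor(np.random.default_rng(0).random((2, 3, 7, 7), np.float32))
        out = frf_rectify(f, np.zeros((2, 2, 7, 7), np.float32), steps)
        np.testing.assert_array_equal(out.data, f.data)

    def test_unit_shift_one_step_clamps_last_column(self):
        h, w = 4, 6
        out = frf_rectify(Tensor(_ramp(h, w)), _const_df(h, w, 1.0, 0.0), 1)
        expected = np.minimum(np.arange(w) + 1, w - 1).astype(np.float32)
        np.testing.assert_array_equal(out.data[0, 0], np.broadcast_to(expected, (h, w)))

    def test_unit_shift_three_steps_is_composed_shift(self):
        h, w = 3, 8
        out = frf_rectify(Tensor(_ramp(h, w)), _const_df(h, w, 1.0, 0.0), 3)
        expected = np.minimum(np.arange(w) + 3, w - 1).astype(np.float32)
        np.testing.assert_array_equal(out.data[0, 0], np.broadcast_to(expected, (h, w)))

    def test_fractional_displacement_bilinear(self):
        h, w = 2, 5
        out = frf_rectify(Tensor(_ramp(h, w)), _const_df(h, w, 0.5, 0.0), 1)
        expected = np.minimum(np.arange(w) + 0.5, w - 1).astype(np.float32)
        np.testing.assert_allclose(out.data[0, 0], np.broadcast_to(expected, (h, w)),
                                   atol=1e-6)

    def test_row_displacement_uses_dy_channel(self):
        rows = np.broadcast_to(np.arange(4, dtype=np.float32)[:, None], (4, 3)).copy()
        f = Tensor(rows[None, None])
        out = frf_rectify(f, _const_df(4, 3, 0.0, 1.0), 1)
        expected = np.minimum(np.arange(4) + 1, 3).astype(np.float32)
        np.testing.assert_array_equal(out.data[0, 0], np.broadcast_to(expected[:, None], (4, 3)))

    def test_negative_steps_rejected_and_shape_checked(self):
        f = Tensor(np.zeros((1, 1, 4, 4), np.float32))
        with pytest.raises(ValueError):
            frf_rectify(f, np.zeros((1, 2, 4, 4), np.float32), -1)
        with pytest.raises(ValueError, match="spatial"):
            frf_rectify(f, np.zeros((1, 2, 5, 5), np.float32), 1)


class TestRefinementAndAggregation:
    def test_refinement_module_returns_both_outputs(self):
        rng = np.random.default_rng(0)
        mod = RefinementModule(8, rect_steps=6, rng=rng)
        f = Tensor(np.random.default_rng(1).random((1, 8, 10, 10), np.float32))
        refined, df = mod(f)
        assert refined.data.shape == f.data.shape
        assert df.data.shape == (1, 2, 10, 10)

    def test_zero_df_head_reduces_to_fusion_of_duplicates(self):
        rng = np.random.default_rng(0)
        mod = RefinementModule(4, rect_steps=6, rng=rng)
        mod.df_head.weight.data[:] = 0
        mod.df_head.bias.data[:] = 0
        f = Tensor(np.random.default_rng(1).random((1, 4, 6, 6), np.float32))
        refined, _ = mod(f)
        from prored.nn import concat
        expected = mod.fuse(concat([f, f], axis=1))
        np.testing.assert_allclose(refined.data, expected.data, atol=1e-6)

    def test_aggregate_empty_list_is_decoder_head_alone(self):
        head_out = Tensor(np.random.default_rng(0).random((1, 7, 16, 16), np.float32))
        out = aggregate([], head_out, [])
        assert out is head_out

    def test_aggregate_zero_map_is_additive_identity(self):
        rng = np.random.default_rng(1)
        head_out = Tensor(np.random.default_rng(0).random((1, 7, 16, 16), np.float32))
        proj = Conv2d(4, 7, 1, rng=rng, bias=False)
        zero_map = Tensor(np.zeros((1, 4, 8, 8), np.float32))
        out = aggregate([zero_map], head_out, [proj])
        np.testing.assert_array_equal(out.data, head_out.data)


class TestModelForward:
    def test_tiny_config_shapes_and_df_count(self, tiny_model):
        x = np.random.default_rng(0).random((1, 64, 64), np.float32)
        logits, dfs = tiny_model.forward(x)
        assert logits.data.shape == (1, 7, 64, 64)
        assert len(dfs) == 3  # n_refine
        for df in dfs:
            assert df.data.shape[1] == 2

    def test_softmax_normalization(self, tiny_model):
        x = np.random.default_rng(1).random((1, 64, 64), np.float32)
        logits, _ = tiny_model.forward(x)
        sums = logits.softmax(axis=1).data.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-5)

    def test_bit_stable_across_runs_and_seeds_differ(self):
        x = np.random.default_rng(2).random((1, 64, 64), np.float32)
        a = ProredModel(tiny_config(seed=0)).forward(x)[0].data
        b = ProredModel(tiny_config(seed=0)).forward(x)[0].data
        c = ProredModel(tiny_config(seed=1)).forward(x)[0].data
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("n_refine", [0, 4])
    def test_refine_count_ablation_arms_run(self, n_refine):
        model = ProredModel(tiny_config(n_refine=n_refine, seed=0))
        x = np.random.default_rng(3).random((1, 64, 64), np.float32)
        logits, dfs = model.forward(x)
        assert logits.data.shape == (1, 7, 64, 64)
        assert len(dfs) == n_refine

    def test_speech_config_rect_steps_default_six(self):
        cfg = tiny_config()
        assert cfg.decoder.rect_steps == 6

    def test_gradients_reach_df_heads_and_decoder_from_losses(self, phantom8):
        from prored.losses import dice_loss, df_loss, downsample_field, downsample_mask
        from prored.fields import compute_df
        from prored.pipeline import normalize_frames

        model = ProredModel(tiny_config(seed=0))
        images = normalize_frames(phantom8["images"][:2])
        labels = np.stack([m.grid for m in phantom8["masks"][:2]])
        gt_df = np.stack([compute_df(m).vectors.transpose(2, 0, 1)
                          for m in phantom8["masks"][:2]]).astype(np.float32)
        logits, dfs = model.forward(images)
        loss = dice_loss(logits.softmax(axis=1), labels)
        for pdf in dfs:
            hw = pdf.data.shape[2:]
            loss = loss + df_loss(pdf, downsample_field(gt_df, hw),
                                  downsample_mask(labels, hw) > 0)
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, f"no gradient reached {name}"
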