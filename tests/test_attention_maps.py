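import numpy as np
import pytest

from glaupie.attention_maps import (
    AttentionStack,
    aggregate_layers,
    collect_attention_and_gradients,
    explain,
    fuse_heads,
    render_overlay,
)
from glaupie.images import FundusImage
from glaupie.nn import PRESETS, VisionTransformer
from glaupie.polar_transform import to_polar


@pytest.fixture(scope="module")
def tiny_model():
    return VisionTransformer(PRESETS["tiny"], seed=1)


@pytest.fixture(scope="module")
def tiny_image():
    return np.random.default_rng(0).random((32, 32, 3))


class TestCollect:
    def test_attention_matrices_are_row_stochastic(self, tiny_model, tiny_image):
        stack = collect_attention_and_gradients(tiny_model, tiny_image)
        assert np.allclose(stack.raw_attention.sum(axis=-1), 1.0, atol=1e-5)

    def test_shapes_follow_architecture(self, tiny_model, tiny_image):
        stack = collect_attention_and_gradients(tiny_model, tiny_image)
        t = PRESETS["tiny"].num_tokens  # 4x4 patches + class + distillation
        assert stack.raw_attention.shape == (2, 2, t, t)
        assert stack.class_gradients.shape == (2, 2, t, t)
        assert stack.grid_size == 4

    def test_deit_small_stack_is_12_layers_by_6_heads(self):
        model = VisionTransformer(PRESETS["deit_small_patch16_224"], seed=0)
        img = np.random.default_rng(0).random((224, 224, 3))
        stack = collect_attention_and_gradients(model, img)
        assert stack.raw_attention.shape[:2] == (12, 6)
        assert stack.grid_size == 14

    def test_constant_score_yields_zero_gradients(self, tiny_image):
        model = VisionTransformer(PRESETS["tiny"], seed=2)
        model.params["head.weight"].data[:] = 0.0  # logit = bias, constant
        stack = collect_attention_and_gradients(model, tiny_image)
        assert np.allclose(stack.class_gradients, 0.0)

    def test_negative_target_flips_gradient_sign(self, tiny_model, tiny_image):
        pos = collect_attention_and_gradients(tiny_model, tiny_image, "positive")
        neg = collect_attention_and_gradients(tiny_model, tiny_image, "negative")
        assert np.allclose(pos.class_gradients, -neg.class_gradients)

    def test_invalid_target_rejected(self, tiny_model, tiny_image):
        with pytest.raises(ValueError):
            collect_attention_and_gradients(tiny_model, tiny_image, "G")


class TestFuseHeads:
    def _stack(self, attn, grads):
        return AttentionStack(raw_attention=attn, class_gradients=grads)

    def test_identical_heads_fuse_to_any_single_head(self):
        rng = np.random.default_rng(0)
        one = rng.random((1, 1, 6, 6))
        attn = np.repeat(one, 6, axis=1)
        grads = np.ones_like(attn)
        fused = fuse_heads(self._stack(attn, grads))
        assert np.allclose(fused[0], one[0, 0])

    def test_one_zero_head_scales_fusion_by_five_sixths(self):
        attn = np.ones((1, 6, 4, 4))
        grads = np.ones_like(attn)
        grads[0, 3] = 0.0
        fused = fuse_heads(self._stack(attn, grads))
        assert np.allclose(fused, 5.0 / 6.0)

    def test_fusion_commutes_with_head_permutation(self):
        rng = np.random.default_rng(1)
        attn = rng.random((2, 6, 5, 5))
        grads = rng.normal(size=(2, 6, 5, 5))
        perm = rng.permutation(6)
        a = fuse_heads(self._stack(attn, grads))
        b = fuse_heads(self._stack(attn[:, perm], grads[:, perm]))
        assert np.allclose(a, b)

    def test_negative_contributions_clamped(self):
        attn = np.ones((1, 2, 3, 3))
        grads = -np.ones_like(attn)
        assert np.all(fuse_heads(self._stack(attn, grads)) == 0.0)


class TestAggregateLayers:
    def test_uniform_single_layer_gives_flat_map(self):
        t = 2 + 9
        maps = np.full((1, t, t), 1.0 / t)
        grid = aggregate_layers(maps)
        assert grid.shape == (3, 3)
        assert np.allclose(grid, grid.flat[0])

    def test_identity_layers_are_idempotent(self):
        t = 2 + 4
        one = np.eye(t)[None]
        three = np.repeat(one, 3, axis=0)
        assert np.allclose(aggregate_layers(one), aggregate_layers(three))

    def test_rollout_matches_bruteforce_matrix_product(self):
        """Hand-multiplied identity-augmented row-normalized product on a
        toy stack."""
        rng = np.random.default_rng(2)
        t = 2 + 4
        maps = rng.random((3, t, t))
        expected = np.eye(t)
        for layer in maps:
            a = layer / layer.sum(axis=-1, keepdims=True) + np.eye(t)
            a = a / a.sum(axis=-1, keepdims=True)
            expected = a @ expected
        row = expected[0, 2:].reshape(2, 2)
        row = (row - row.min()) / (row.max() - row.min())
        assert np.allclose(aggregate_layers(maps), row)

    def test_degenerate_zero_maps_give_uniform_with_warning(self, caplog):
        import logging

        # all-zero off-diagonals: rollout stays identity, patch row is flat
        with caplog.at_level(logging.WARNING):
            grid = aggregate_layers(np.zeros((2, 6, 6)))
        assert np.allclose(grid, 0.5)
        assert "degenerate" in caplog.text

    def test_gradient_scaling_invariance_of_normalized_map(self, tiny_model, tiny_image):
        stack = collect_attention_and_gradients(tiny_model, tiny_image)
        base = aggregate_layers(fuse_heads(stack))
        stack.class_gradients = stack.class_gradients * 7.3
        scaled = aggregate_layers(fuse_heads(stack))
        assert np.allclose(base, scaled, atol=1e-9)


class TestRenderOverlay:
    @pytest.fixture()
    def polar(self):
        img = np.full((65, 65, 3), 0.6)
        return to_polar(FundusImage(img, "OD"), R_h=32, R_w=32)

    def test_overlay_matches_reverse_polar_dimensions(self, polar):
        out = render_overlay(np.random.default_rng(0).random((4, 4)), polar)
        assert out.shape == (65, 65, 3)
        assert out.dtype == np.uint8

    def test_flat_map_tints_disc_uniformly_and_leaves_outside_black(self, polar):
        out = render_overlay(np.full((4, 4), 0.5), polar)
        c = 32
        ys, xs = np.meshgrid(np.arange(65), np.arange(65), indexing="ij")
        r = np.hypot(xs - c, ys - c)
        inside = out[(r < polar.r_max * 0.8) & (r > 1)]
        assert inside.std(axis=0).max() < 3  # uniform tint
        assert np.all(out[r > polar.r_max + 1] == 0)

    def test_hot_column_band_maps_to_hot_sector(self, polar):
        from glaupie.pie_augment import DEFAULT_REGIONS
        from glaupie.polar_transform import region_angle_mask

        fused = np.zeros((polar.R_h, polar.R_w))
        fused[:, 4:12] = 1.0  # superior band at R_w=32: columns 4..11
        out = render_overlay(fused, polar, alpha=1.0)
        sector = region_angle_mask(polar, DEFAULT_REGIONS["superior"].angular_interval,
                                   65, 65, polar.source_center)
        ys, xs = np.meshgrid(np.arange(65), np.arange(65), indexing="ij")
        r = np.hypot(xs - 32, ys - 32)
        core = sector & (r < polar.r_max * 0.8) & (r > 4)
        rest = ~sector & (r < polar.r_max * 0.8) & (r > 4)
        # "jet" maps high values toward red, low toward blue: compare
        # red-minus-blue between the hot sector and the rest of the disc
        redness = out[..., 0].astype(int) - out[..., 2].astype(int)
        assert redness[core].mean() > redness[rest].mean() + 50

    def test_size_mismatch_rejected(self, polar):
        with pytest.raises(ValueError):
            render_overlay(np.zeros((4, 4, 3)), polar)


def test_explain_populates_normalized_fused_map(tiny_model, tiny_image):
    stack = explain(tiny_model, tiny_image)
    assert stack.fused_map is not None
    assert stack.fused_map.shape == (4, 4)
    assert 0.0 <= stack.fused_map.min() <= stack.fused_map.max() <= 1.0
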