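"""Gradient-weighted attention-map explanations for the transformer.

For a chosen class score the per-layer, per-head post-softmax attention
matrices are multiplied elementwise by the gradients of that score with
respect to the attention weights; negative contributions are clamped to
zero and the heads of each layer are fused by their mean.  Layers are
combined by attention rollout (identity-augmented, row-normalized matrix
products), the class-token row is restricted to the patch tokens,
reshaped onto the token grid and min-max normalized.  Warping the map
through the inverse polar transform puts the explanation back onto the
fundus crop for overlay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .images import FundusImage, PolarImage
from .nn import VisionTransformer
from .polar_transform import from_polar

logger = logging.getLogger(__name__)


@dataclass
class AttentionStack:
    """Per-layer/head attention and class-score gradients for one image."""

    raw_attention: np.ndarray   # (layers, heads, tokens, tokens)
    class_gradients: np.ndarray  # same shape
    num_special_tokens: int = 2
    target_class: str = ""
    fused_map: Optional[np.ndarray] = None  # (grid, grid) in [0, 1]

    @property
    def num_layers(self) -> int:
        return self.raw_attention.shape[0]

    @property
    def num_heads(self) -> int:
        return self.raw_attention.shape[1]

    @property
    def grid_size(self) -> int:
        n_patch = self.raw_attention.shape[-1] - self.num_special_tokens
        g = int(round(np.sqrt(n_patch)))
        if g * g != n_patch:
            raise ValueError("patch tokens do not form a square grid")
        return g


def collect_attention_and_gradients(
    model: VisionTransformer,
    image: Union[np.ndarray, PolarImage],
    target: str = "positive",
) -> AttentionStack:
    """Forward + backward pass capturing attention weights and gradients.

    ``target`` selects the class score to differentiate: ``"positive"``
    uses the sigmoid-head logit, ``"negative"`` its negation (the score
    of the complementary class of the binary task).
    """
    if target not in ("positive", "negative"):
        raise ValueError("target must be 'positive' or 'negative'")
    arr = image.pixels if isinstance(image, PolarImage) else np.asarray(image)
    out = model.forward(np.asarray(arr, dtype=np.float64)[None])
    score = out["logit"] if target == "positive" else -out["logit"]
    model.zero_grad()
    score.backward()
    if not model.attentions:
        raise RuntimeError("model exposed no attention matrices")
    attn = np.stack([a.data[0] for a in model.attentions])          # (L, H, T, T)
    grads = np.stack([
        (a.grad[0] if a.grad is not None else np.zeros_like(a.data[0]))
        for a in model.attentions
    ])
    return AttentionStack(
        raw_attention=attn,
        class_gradients=grads,
        num_special_tokens=model.NUM_SPECIAL_TOKENS,
        target_class=target,
    )


def fuse_heads(stack: AttentionStack) -> np.ndarray:
    """Per-layer maps: mean over heads of relu(attention * gradient)."""
    weighted = np.maximum(stack.raw_attention * stack.class_gradients, 0.0)
    return weighted.mean(axis=1)  # (L, T, T)


def aggregate_layers(per_layer_maps: np.ndarray) -> np.ndarray:
    """Attention rollout across layers -> class-token patch map.

    Each layer map is identity-augmented and row-normalized, the layers
    are multiplied in network order, and the class-token row restricted
    to the patch tokens is reshaped to the token grid and min-max
    normalized to [0, 1].
    """
    maps = np.asarray(per_layer_maps, dtype=float)
    if maps.ndim != 3 or maps.shape[0] < 1:
        raise ValueError("need at least one (T, T) layer map")
    t = maps.shape[-1]
    rollout = np.eye(t)
    for layer in maps:
        # row-normalize the weighted map first (zero rows stay zero), so
        # the result is invariant to a global rescaling of the gradients
        row_sums = layer.sum(axis=-1, keepdims=True)
        safe = np.where(row_sums == 0, 1.0, row_sums)
        a = layer / safe + np.eye(t)
        a = a / a.sum(axis=-1, keepdims=True)
        rollout = a @ rollout
    n_special = 2
    cls_row = rollout[0, n_special:]
    n_patch = t - n_special
    g = int(round(np.sqrt(n_patch)))
    grid = cls_row.reshape(g, g)
    span = grid.max() - grid.min()
    if span == 0:
        logger.warning("degenerate attention map; returning uniform saliency")
        return np.full((g, g), 0.5)
    return (grid - grid.min()) / span


def explain(
    model: VisionTransformer,
    image: Union[np.ndarray, PolarImage],
    target: str = "positive",
) -> AttentionStack:
    """Full pipeline: collect, fuse heads, rollout; returns the stack
    with ``fused_map`` populated."""
    stack = collect_attention_and_gradients(model, image, target)
    stack.fused_map = aggregate_layers(fuse_heads(stack))
    return stack


def render_overlay(
    fused_map: np.ndarray,
    polar: PolarImage,
    alpha: float = 0.5,
    cmap: str = "jet",
) -> np.ndarray:
    """Warp the token-grid map to Cartesian space and blend it onto the
    reverse-polar fundus image.  Returns a uint8 RGB array whose size
    matches the reverse-polar image."""
    fused_map = np.asarray(fused_map, dtype=float)
    if fused_map.ndim != 2:
        raise ValueError("fused_map must be 2-D")
    heat_polar = resize(fused_map, (polar.R_h, polar.R_w), order=1, anti_aliasing=False)
    heat_img = PolarImage(
        np.repeat(heat_polar[..., None], 3, axis=2),
        r_max=polar.r_max,
        source_center=polar.source_center,
        source_shape=polar.source_shape,
        source_eye_side=polar.source_eye_side,
        nasal_side=polar.nasal_side,
    )
    heat_cart = from_polar(heat_img).pixels[..., 0]
    base = from_polar(polar).pixels
    colored = colormaps[cmap](np.clip(heat_cart, 0.0, 1.0))[..., :3]
    inside = heat_cart > 0
    out = base.copy()
    out[inside] = (1 - alpha) * base[inside] + alpha * colored[inside]
    return np.clip(np.round(out * 255), 0, 255).astype(np.uint8)
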