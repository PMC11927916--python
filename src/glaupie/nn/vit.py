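"""Data-efficient vision transformer (DeiT-style) on the numpy autodiff engine.

The topology follows the published small variant: patch embedding of
16x16 patches of a 224x224 RGB input (a 14x14 token grid), a class token
plus a distillation token, learned position embeddings, pre-norm
transformer blocks with multi-head self-attention and a 4x MLP, and
single-logit sigmoid heads on both the class and the distillation token
(the screening tasks are binary).  Per-layer post-softmax attention
matrices are retained on every forward pass so gradient-weighted
attention maps can be read off after a backward sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .autodiff import Tensor, gelu, layer_norm


@dataclass(frozen=True)
class ViTConfig:
    img_size: int = 224
    patch_size: int = 16
    in_chans: int = 3
    embed_dim: int = 384
    depth: int = 12
    num_heads: int = 6
    mlp_ratio: float = 4.0

    def __post_init__(self) -> None:
        if self.img_size % self.patch_size != 0:
            raise ValueError("img_size must be divisible by patch_size")
        if self.embed_dim % self.num_heads != 0:
            raise ValueError("embed_dim must be divisible by num_heads")

    @property
    def grid_size(self) -> int:
        return self.img_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid_size ** 2

    @property
    def num_tokens(self) -> int:
        # class token + distillation token + patch tokens
        return self.num_patches + 2


# Published DeiT-S geometry; the tiny preset is a desk-scale override for
# CPU training experiments, not part of the study recipe.
PRESETS: Dict[str, ViTConfig] = {
    "deit_small_patch16_224": ViTConfig(
        img_size=224, patch_size=16, embed_dim=384, depth=12, num_heads=6
    ),
    "tiny": ViTConfig(img_size=32, patch_size=8, embed_dim=64, depth=2, num_heads=2),
}


class VisionTransformer:
    """ViT with class + distillation tokens and sigmoid binary heads."""

    NUM_SPECIAL_TOKENS = 2  # class token, distillation token

    def __init__(self, config: ViTConfig, seed: int = 0) -> None:
        self.config = config
        self.params: Dict[str, Tensor] = {}
        self.attentions: List[Tensor] = []
        self._init_params(np.random.default_rng(seed))

    # -- parameters --------------------------------------------------------

    def _param(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array, requires_grad=True, name=name)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        d = cfg.embed_dim
        patch_dim = cfg.patch_size ** 2 * cfg.in_chans
        std = 0.02

        def tn(*shape):
            # truncated-normal-ish init, standard for ViT
            return np.clip(rng.normal(0.0, std, size=shape), -2 * std, 2 * std)

        self._param("patch_embed.weight", tn(patch_dim, d))
        self._param("patch_embed.bias", np.zeros(d))
        self._param("cls_token", tn(1, 1, d))
        self._param("dist_token", tn(1, 1, d))
        self._param("pos_embed", tn(1, cfg.num_tokens, d))
        hidden = int(d * cfg.mlp_ratio)
        for i in range(cfg.depth):
            p = f"blocks.{i}."
            self._param(p + "norm1.weight", np.ones(d))
            self._param(p + "norm1.bias", np.zeros(d))
            self._param(p + "attn.qkv.weight", tn(d, 3 * d))
            self._param(p + "attn.qkv.bias", np.zeros(3 * d))
            self._param(p + "attn.proj.weight", tn(d, d))
            self._param(p + "attn.proj.bias", np.zeros(d))
            self._param(p + "norm2.weight", np.ones(d))
            self._param(p + "norm2.bias", np.zeros(d))
            self._param(p + "mlp.fc1.weight", tn(d, hidden))
            self._param(p + "mlp.fc1.bias", np.zeros(hidden))
            self._param(p + "mlp.fc2.weight", tn(hidden, d))
            self._param(p + "mlp.fc2.bias", np.zeros(d))
        self._param("norm.weight", np.ones(d))
        self._param("norm.bias", np.zeros(d))
        self._param("head.weight", tn(d, 1))
        self._param("head.bias", np.zeros(1))
        self._param("head_dist.weight", tn(d, 1))
        self._param("head_dist.bias", np.zeros(1))

    def num_parameters(self) -> int:
        """Total trainable parameter count."""
        return int(sum(p.data.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unknown parameter {k!r}")
            if self.params[k].data.shape != np.asarray(v).shape:
                raise ValueError(f"shape mismatch for {k!r}")
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, config: ViTConfig, seed: int = 0) -> "VisionTransformer":
        model = cls(config, seed=seed)
        with np.load(path) as f:
            model.load_state_dict({k: f[k] for k in f.files})
        return model

    # -- forward -----------------------------------------------------------

    def patchify(self, images: np.ndarray) -> np.ndarray:
        """(B, H, W, C) float array -> (B, N, patch*patch*C)."""
        cfg = self.config
        b, h, w, c = images.shape
        if h != cfg.img_size or w != cfg.img_size or c != cfg.in_chans:
            raise ValueError(
                f"expected input ({cfg.img_size}, {cfg.img_size}, {cfg.in_chans}), "
                f"got ({h}, {w}, {c})"
            )
        g, p = cfg.grid_size, cfg.patch_size
        x = images.reshape(b, g, p, g, p, c)
        x = x.transpose(0, 1, 3, 2, 4, 5)  # (B, g, g, p, p, C), row-major grid
        return x.reshape(b, g * g, p * p * c)

    def forward(self, images: np.ndarray) -> Dict[str, Tensor]:
        """Run the network; returns class/distillation logits and probabilities.

        Side effect: ``self.attentions`` holds the per-layer post-softmax
        attention Tensors of shape (B, heads, tokens, tokens).
        """
        cfg = self.config
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        b = images.shape[0]
        d = cfg.embed_dim
        nh, hd = cfg.num_heads, d // cfg.num_heads
        t = cfg.num_tokens

        patches = Tensor(self.patchify(images))
        x = patches @ self.params["patch_embed.weight"] + self.params["patch_embed.bias"]
        cls_tok = self.params["cls_token"] + Tensor(np.zeros((b, 1, d)))
        dist_tok = self.params["dist_token"] + Tensor(np.zeros((b, 1, d)))
        x = Tensor.concat([cls_tok, dist_tok, x], axis=1)
        x = x + self.params["pos_embed"]

        self.attentions = []
        scale = hd ** -0.5
        for i in range(cfg.depth):
            p = f"blocks.{i}."
            xn = layer_norm(x, self.params[p + "norm1.weight"], self.params[p + "norm1.bias"])
            qkv = xn @ self.params[p + "attn.qkv.weight"] + self.params[p + "attn.qkv.bias"]
            qkv = qkv.reshape(b, t, 3, nh, hd).transpose(2, 0, 3, 1, 4)
            q, k, v = qkv[0], qkv[1], qkv[2]  # each (B, nh, T, hd)
            scores = (q @ k.transpose(0, 1, 3, 2)) * scale
            attn = scores.softmax(axis=-1)
            self.attentions.append(attn)
            out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
            out = out @ self.params[p + "attn.proj.weight"] + self.params[p + "attn.proj.bias"]
            x = x + out
            xn = layer_norm(x, self.params[p + "norm2.weight"], self.params[p + "norm2.bias"])
            h = gelu(xn @ self.params[p + "mlp.fc1.weight"] + self.params[p + "mlp.fc1.bias"])
            h = h @ self.params[p + "mlp.fc2.weight"] + self.params[p + "mlp.fc2.bias"]
            x = x + h

        x = layer_norm(x, self.params["norm.weight"], self.params["norm.bias"])
        cls_feat = x[:, 0, :]
        dist_feat = x[:, 1, :]
        logit = (cls_feat @ self.params["head.weight"] + self.params["head.bias"]).reshape(b)
        dist_logit = (
            dist_feat @ self.params["head_dist.weight"] + self.params["head_dist.bias"]
        ).reshape(b)
        return {
            "logit": logit,
            "dist_logit": dist_logit,
            "prob": logit.sigmoid(),
            "dist_prob": dist_logit.sigmoid(),
        }

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Sigmoid probability of the positive side, as a plain array."""
        return self.forward(images)["prob"].data.copy()
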