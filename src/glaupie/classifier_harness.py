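"""Training and inference harness for the two binary screening tasks.

The screening decision is decomposed into two sigmoid-output DeiT-style
models: (1) glaucoma-or-suspect (GS) vs no glaucoma (N) and (2) glaucoma
(G) vs suspect (S).  The study recipe is the default configuration:
DeiT-S backbone at 224x224 with 16x16 patches, focal loss, LAMB
optimizer at learning rate 1e-3, batch size 32, 100 epochs, 5 stratified
folds, and teacher-student distillation (through the distillation token)
when fine-tuning from a unanimous-agreement teacher onto
majority-agreement data.  A ``tiny`` backbone override keeps the same
code path runnable at CPU scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize
from sklearn.model_selection import StratifiedKFold

from .images import PolarImage
from .nn import LAMB, PRESETS, Tensor, ViTConfig, VisionTransformer

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    backbone: str = "deit_small_patch16_224"
    epochs: int = 100
    batch_size: int = 32
    optimizer: str = "LAMB"
    learning_rate: float = 1e-3
    loss: str = "focal"
    focal_gamma: float = 2.0
    focal_alpha: Optional[Mapping[int, float]] = None  # {0: w_neg, 1: w_pos}
    folds: int = 5
    seed: int = 0
    teacher_checkpoint: Optional[str] = None
    distill_weight: float = 0.5
    distill_temperature: float = 3.0
    input_size: int = 224
    patch_size: int = 16

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.folds) < 1:
            raise ValueError("epochs, batch_size and folds must all be >= 1")
        if self.input_size % self.patch_size != 0:
            raise ValueError("input_size must be divisible by patch_size")

    def vit_config(self) -> ViTConfig:
        if self.backbone not in PRESETS:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; choose from {sorted(PRESETS)}"
            )
        base = PRESETS[self.backbone]
        if base.img_size != self.input_size or base.patch_size != self.patch_size:
            base = replace(base, img_size=self.input_size, patch_size=self.patch_size)
        return base


@dataclass(frozen=True)
class BinaryTask:
    name: str
    positive_classes: Tuple[str, ...]
    negative_classes: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.positive_classes or not self.negative_classes:
            raise ValueError("both task sides must be non-empty")
        if set(self.positive_classes) & set(self.negative_classes):
            raise ValueError("task sides must be disjoint")

    def binarize(self, labels: Sequence[str]) -> np.ndarray:
        """1 for positive-side labels, 0 for negative; others masked to -1."""
        labels = np.asarray(labels)
        out = np.full(labels.shape, -1, dtype=int)
        out[np.isin(labels, self.positive_classes)] = 1
        out[np.isin(labels, self.negative_classes)] = 0
        return out


GS_VS_N = BinaryTask("GS_vs_N", ("G", "S"), ("N",))
G_VS_S = BinaryTask("G_vs_S", ("G",), ("S",))
TASKS = {t.name: t for t in (GS_VS_N, G_VS_S)}


def build_model(config: TrainConfig) -> VisionTransformer:
    """Instantiate the backbone with a single-logit sigmoid head."""
    return VisionTransformer(config.vit_config(), seed=config.seed)


def focal_loss(
    prob: Union[float, np.ndarray],
    label: Union[int, np.ndarray],
    alpha: Union[float, np.ndarray] = 1.0,
    gamma: float = 2.0,
    eps: float = 1e-12,
) -> Union[float, np.ndarray]:
    """Focal loss -alpha * (1 - p_t)^gamma * log(p_t) for binary labels.

    ``p_t`` is the predicted probability of the true label.  At gamma=0,
    alpha=1 this is exactly binary cross-entropy.  Probabilities at
    exactly 0 or 1 are clamped to ``eps`` (logged).
    """
    p = np.asarray(prob, dtype=float)
    y = np.asarray(label, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        logger.info("focal_loss: probabilities at 0/1 clamped by eps=%g", eps)
    p = np.clip(p, eps, 1 - eps)
    p_t = np.where(y == 1, p, 1 - p)
    out = -np.asarray(alpha, dtype=float) * (1 - p_t) ** gamma * np.log(p_t)
    return float(out) if out.ndim == 0 else out


def _focal_loss_tensor(
    logit: Tensor, labels: np.ndarray, alpha: np.ndarray, gamma: float
) -> Tensor:
    p = logit.sigmoid().clip(1e-9, 1 - 1e-9)
    y = Tensor(labels.astype(float))
    p_t = p * y + (1.0 - p) * (1.0 - y)
    return (-(Tensor(alpha) * (1.0 - p_t) ** gamma * p_t.log())).mean()


def stratified_folds(manifest: pd.DataFrame, k: int, seed: int) -> np.ndarray:
    """Fold id per row; per-class counts across folds differ by at most 1."""
    labels = manifest["label"].to_numpy()
    smallest = pd.Series(labels).value_counts().min()
    if k > smallest:
        raise ValueError(
            f"k={k} exceeds the smallest class count ({smallest})"
        )
    folds = np.full(len(manifest), -1, dtype=int)
    if k == 1:
        return np.zeros(len(manifest), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[test_idx] = i
    return folds


def _default_image_loader(size: int) -> Callable[[str], np.ndarray]:
    def load(path: str) -> np.ndarray:
        arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0
        if arr.shape[:2] != (size, size):
            arr = resize(arr, (size, size), order=1, anti_aliasing=True)
        return arr
    return load


def _alpha_weights(labels: np.ndarray, config: TrainConfig) -> Tuple[float, float]:
    """(w_neg, w_pos): configured, or inverse class frequency."""
    if config.focal_alpha is not None:
        return float(config.focal_alpha[0]), float(config.focal_alpha[1])
    n = len(labels)
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    return n / (2.0 * max(n_neg, 1)), n / (2.0 * max(n_pos, 1))


def train(
    task: BinaryTask,
    manifest: pd.DataFrame,
    config: TrainConfig,
    image_loader: Optional[Callable[[str], np.ndarray]] = None,
    images: Optional[np.ndarray] = None,
    out_dir: Optional[Path] = None,
    teacher: Optional[VisionTransformer] = None,
) -> Tuple[VisionTransformer, pd.DataFrame]:
    """Train the task model with the configured recipe.

    Rows whose label is on neither task side are dropped.  With
    ``folds > 1`` a model is trained per stratified fold (the last
    fold's model is returned) and per-epoch validation accuracy is
    logged; with ``folds == 1`` the model trains on every row.  If a
    teacher is supplied (directly or via ``config.teacher_checkpoint``),
    a soft-distillation term at the configured temperature is added on
    the distillation-token logit.
    """
    y_all = task.binarize(manifest["label"])
    keep = y_all >= 0
    rows = manifest.loc[keep].reset_index(drop=True)
    y = y_all[keep]
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError(f"manifest has no rows for one side of task {task.name}")

    if images is not None:
        x = np.asarray(images, dtype=np.float64)[keep]
    else:
        loader = image_loader or _default_image_loader(config.input_size)
        missing = [p for p in rows["path"] if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing images: {missing[:5]}")
        x = np.stack([loader(p) for p in rows["path"]])

    if teacher is None and config.teacher_checkpoint:
        teacher = VisionTransformer.load(config.teacher_checkpoint, config.vit_config())

    w_neg, w_pos = _alpha_weights(y, config)
    if config.folds > 1:
        fold_ids = stratified_folds(rows, config.folds, config.seed)
    else:
        fold_ids = np.zeros(len(rows), dtype=int)

    log: List[dict] = []
    model: Optional[VisionTransformer] = None
    n_folds = config.folds if config.folds > 1 else 1
    for fold in range(n_folds):
        if config.folds > 1:
            tr_idx = np.nonzero(fold_ids != fold)[0]
            va_idx = np.nonzero(fold_ids == fold)[0]
        else:
            tr_idx = np.arange(len(rows))
            va_idx = np.array([], dtype=int)
        model = VisionTransformer(config.vit_config(), seed=config.seed + fold)
        opt = LAMB(model.params, lr=config.learning_rate)
        rng = np.random.default_rng(config.seed * 1000 + fold)
        for epoch in range(config.epochs):
            order = rng.permutation(tr_idx)
            losses = []
            correct = 0
            for start in range(0, len(order), config.batch_size):
                idx = order[start : start + config.batch_size]
                yb = y[idx]
                out = model.forward(x[idx])
                alpha = np.where(yb == 1, w_pos, w_neg)
                loss = _focal_loss_tensor(out["logit"], yb, alpha, config.focal_gamma)
                if teacher is not None:
                    tau = config.distill_temperature
                    t_logit = teacher.forward(x[idx])["logit"].data
                    q = 1.0 / (1.0 + np.exp(-t_logit / tau))
                    ps = (out["dist_logit"] * (1.0 / tau)).sigmoid().clip(1e-9, 1 - 1e-9)
                    soft = -(Tensor(q) * ps.log() + Tensor(1 - q) * (1.0 - ps).log()).mean()
                    loss = loss * (1.0 - config.distill_weight) + soft * (
                        config.distill_weight * tau * tau
                    )
                if not np.isfinite(loss.data):
                    raise FloatingPointError("non-finite training loss")
                model.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                correct += int(((out["prob"].data >= 0.5).astype(int) == yb).sum())
            entry = {
                "fold": fold,
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "train_acc": correct / len(order),
            }
            if len(va_idx):
                pv = model.predict_proba(x[va_idx])
                entry["val_acc"] = float((((pv >= 0.5).astype(int)) == y[va_idx]).mean())
            log.append(entry)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            model.save(out_dir / f"{task.name}_fold{fold}.npz")
    log_df = pd.DataFrame(log)
    if out_dir is not None:
        log_df.to_csv(Path(out_dir) / f"{task.name}_log.csv", index=False)
    return model, log_df


def combine_binary_probabilities(p_gs: float, p_g_given_gs: float) -> Dict[str, float]:
    """Chain the two binary outputs into three-class probabilities.

    p(N) = 1 - p(GS); p(G) = p(GS) * p(G|GS); p(S) = p(GS) * (1 - p(G|GS)).
    The result always lies on the probability simplex.
    """
    p_gs = float(p_gs)
    p_g = float(p_g_given_gs)
    return {"G": p_gs * p_g, "S": p_gs * (1.0 - p_g), "N": 1.0 - p_gs}


def predict_three_class(
    model_gs_n: VisionTransformer,
    model_g_s: VisionTransformer,
    image: Union[np.ndarray, PolarImage],
) -> Dict[str, float]:
    """Probabilities over {G, S, N} for one (polar) image."""
    arr = image.pixels if isinstance(image, PolarImage) else np.asarray(image)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected a single (H, W, 3) image")
    for m in (model_gs_n, model_g_s):
        if m.config.img_size != arr.shape[0] or m.config.img_size != arr.shape[1]:
            raise ValueError(
                f"model expects {m.config.img_size}x{m.config.img_size} input, "
                f"got {arr.shape[:2]}"
            )
    p_gs = float(model_gs_n.predict_proba(arr[None])[0])
    p_g = float(model_g_s.predict_proba(arr[None])[0])
    return combine_binary_probabilities(p_gs, p_g)


def count_macs(cfg: ViTConfig) -> int:
    """Analytic multiply-accumulate count of one forward pass."""
    t = cfg.num_tokens
    d = cfg.embed_dim
    hidden = int(d * cfg.mlp_ratio)
    patch_dim = cfg.patch_size ** 2 * cfg.in_chans
    macs = cfg.num_patches * patch_dim * d  # patch embedding
    per_block = (
        t * d * 3 * d          # qkv projection
        + t * t * d            # attention scores
        + t * t * d            # attention-weighted values
        + t * d * d            # output projection
        + 2 * t * d * hidden   # MLP
    )
    macs += cfg.depth * per_block
    macs += 2 * d  # two single-logit heads
    return int(macs)


def profile_model(config: TrainConfig) -> Dict[str, float]:
    """Trainable parameter and per-forward MAC counts for the backbone."""
    model = build_model(config)
    params = model.num_parameters()
    macs = count_macs(model.config)
    return {
        "parameters": params,
        "parameters_millions": params / 1e6,
        "macs": macs,
        "macs_billions": macs / 1e9,
    }
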