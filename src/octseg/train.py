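"""Training harness: dataset splitting, weighted cross-entropy, the Adam
optimization loop with gradient clipping and cyclic cosine LR, and the
sklearn-style ``UNetSegmenter`` estimator wrapping it all.

Defaults mirror the study protocol: Adam at 1e-4 with weight decay 1e-4 and
a 50-epoch schedule period, 200 epochs, batch size 4, class weights 1.0
(background) / 1.5 (damage), gradient norm clipped at 1.0, 8:1:1 split.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .io import MaskStack, SegmentationMask
from .metrics import (MetricsReport, pooled_confusion, report_from_confusion)
from .nn.autograd import Tensor, log_softmax
from .nn.optim import Adam, clip_grad_norm, cosine_cycle_lr
from .nn.unet import VARIANTS, ModelConfig, UNet, build_model
from .nn.attention import AttentionConfig

__all__ = ["TrainConfig", "TrainHistory", "split_dataset", "weighted_ce_loss",
           "train", "evaluate", "UNetSegmenter", "save_checkpoint",
           "load_checkpoint"]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-4
    lr_period: int = 50
    epochs: int = 200
    batch_size: int = 4
    class_weights: tuple = (1.0, 1.5)   # background, damage
    grad_clip_max_norm: float = 1.0
    split_ratios: tuple = (8, 1, 1)
    seed: int = 0

    def __post_init__(self):
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    val_miou: list = field(default_factory=list)
    val_mpa: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    lr: list = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(1, len(self) + 1),
            "train_loss": self.train_loss, "val_dice": self.val_dice,
            "val_miou": self.val_miou, "val_mpa": self.val_mpa,
            "val_accuracy": self.val_accuracy, "lr": self.lr,
        })


def split_dataset(items: list, ratios: tuple = (8, 1, 1), seed: int = 0):
    """Disjoint, exhaustive shuffled split; val and test get floor(n*r),
    the remainder goes to train."""
    n = len(items)
    if n < 3:
        raise ValueError(f"need at least 3 items to split, got {n}")
    total = float(sum(ratios))
    n_val = int(np.floor(n * ratios[1] / total))
    n_test = int(np.floor(n * ratios[2] / total))
    perm = np.random.default_rng(seed).permutation(n)
    val_idx = perm[:n_val]
    test_idx = perm[n_val:n_val + n_test]
    train_idx = perm[n_val + n_test:]
    pick = lambda idx: [items[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def _label_array(mask) -> np.ndarray:
    return mask.labels if isinstance(mask, SegmentationMask) else np.asarray(mask)


def weighted_ce_loss(logits, mask, class_weights=(1.0, 1.5)) -> Tensor:
    """Mean over pixels of -w_y * log softmax(logits)_y.

    logits: Tensor or array (N, C, H, W) or (C, H, W); mask aligned labels.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    y = _label_array(mask).astype(np.int64)
    if logits.ndim == 3:
        logits = logits.reshape((1,) + logits.shape)
        y = y[None]
    ncls = logits.shape[1]
    if y.min() < 0 or y.max() >= ncls:
        raise ValueError(f"labels outside [0, {ncls - 1}]")
    w = np.asarray(class_weights, dtype=np.float32)
    onehot_w = (np.eye(ncls, dtype=np.float32)[y] * w[None, None, None, :])
    onehot_w = onehot_w.transpose(0, 3, 1, 2)      # N,C,H,W
    ls = log_softmax(logits, axis=1)
    n_pix = y.size
    return -(ls * Tensor(onehot_w)).sum() * (1.0 / n_pix)


def _predict_logits(model: UNet, images: np.ndarray) -> np.ndarray:
    model.eval()
    out = model(Tensor(images[:, None, :, :].astype(np.float32)))
    return out.data


def _val_report(model: UNet, val: list) -> MetricsReport:
    preds, truths = [], []
    for img, msk in val:
        logits = _predict_logits(model, img[None])
        preds.append(np.argmax(logits[0], axis=0))
        truths.append(_label_array(msk))
    return report_from_confusion(pooled_confusion(preds, truths))


def train(model: UNet, datasets, cfg: TrainConfig):
    """Adam loop over (train, val, test) datasets of (image, mask) pairs.

    Keeps the weights of the best-validation-Dice epoch.  Returns
    (model, history); the model carries the best weights on exit.
    """
    train_set, val_set = list(datasets[0]), list(datasets[1])
    if not train_set:
        raise ValueError("empty training set")
    params = model.parameters()
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory()
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        opt.lr = cosine_cycle_lr(cfg.lr, epoch, cfg.lr_period)
        model.train()
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs = np.stack([train_set[i][0] for i in idx])[:, None]
            msks = np.stack([_label_array(train_set[i][1]) for i in idx])
            logits = model(Tensor(imgs.astype(np.float32)))
            loss = weighted_ce_loss(logits, msks, cfg.class_weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}: {float(loss.data)}"
                )
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(params, cfg.grad_clip_max_norm)
            opt.step()
            losses.append(float(loss.data))
        hist.train_loss.append(float(np.mean(losses)))
        hist.lr.append(opt.lr)
        if val_set:
            rep = _val_report(model, val_set)
            hist.val_dice.append(rep.dice)
            hist.val_miou.append(rep.miou)
            hist.val_mpa.append(rep.mpa)
            hist.val_accuracy.append(rep.accuracy)
            if rep.dice > best[0]:
                best = (rep.dice, model.state_dict())
        else:
            hist.val_dice.append(np.nan)
            hist.val_miou.append(np.nan)
            hist.val_mpa.append(np.nan)
            hist.val_accuracy.append(np.nan)
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, hist


def evaluate(model: UNet, dataset) -> dict:
    """Pooled-confusion metrics plus per-image means over a dataset."""
    data = list(dataset)
    if not data:
        raise ValueError("empty evaluation dataset")
    preds, truths, per_image = [], [], []
    for img, msk in data:
        if msk is None:
            raise ValueError("evaluation requires ground-truth masks")
        logits = _predict_logits(model, np.asarray(img)[None])
        pred = np.argmax(logits[0], axis=0)
        preds.append(pred)
        truths.append(_label_array(msk))
        per_image.append(report_from_confusion(
            pooled_confusion([pred], [truths[-1]])))
    pooled = report_from_confusion(pooled_confusion(preds, truths))
    mean = MetricsReport(
        dice=float(np.mean([r.dice for r in per_image])),
        miou=float(np.mean([r.miou for r in per_image])),
        mpa=float(np.mean([r.mpa for r in per_image])),
        accuracy=float(np.mean([r.accuracy for r in per_image])),
    )
    return {"pooled": pooled, "per_image_mean": mean}


def save_checkpoint(path, model: UNet, model_cfg: ModelConfig) -> None:
    import json
    cfg = {
        "in_channels": model_cfg.in_channels,
        "num_classes": model_cfg.num_classes,
        "base_width": model_cfg.base_width,
        "depth": model_cfg.depth,
        "attention_levels": model_cfg.attention_levels,
        "attention": vars(model_cfg.attention).copy(),
    }
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(cfg, default=list),
             **{k.replace("/", "_"): v for k, v in state.items()})


def load_checkpoint(path) -> tuple[UNet, ModelConfig]:
    import json
    data = np.load(path, allow_pickle=False)
    cfg_d = json.loads(str(data["__config__"]))
    att = AttentionConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in cfg_d.pop("attention").items()})
    lvls = cfg_d.pop("attention_levels")
    mcfg = ModelConfig(attention=att,
                       attention_levels=tuple(lvls) if lvls else None,
                       **cfg_d)
    model = build_model(mcfg, seed=0)
    model.load_state_dict({k: data[k] for k in data.files
                           if k != "__config__"})
    return model, mcfg


class UNetSegmenter(BaseEstimator):
    """Sklearn-style estimator for B-scan damage segmentation.

    Parameters mirror the model/training configuration; ``variant`` selects
    the attention topology (unet / tandem / parallel / nested).  ``fit``
    takes images X of shape (n, H, W) in [0,1] and masks y of shape
    (n, H, W) in {0,1}; ``predict`` returns masks of the same shape.
    """

    def __init__(self, variant: str = "parallel", base_width: int = 64,
                 depth: int = 5, num_classes: int = 2, lr: float = 1e-4,
                 weight_decay: float = 1e-4, lr_period: int = 50,
                 epochs: int = 200, batch_size: int = 4,
                 class_weights: tuple = (1.0, 1.5),
                 grad_clip_max_norm: float = 1.0, psa_branches: int = 4,
                 attention_levels: tuple | None = None, seed: int = 0):
        self.variant = variant
        self.base_width = base_width
        self.depth = depth
        self.num_classes = num_classes
        self.lr = lr
        self.weight_decay = weight_decay
        self.lr_period = lr_period
        self.epochs = epochs
        self.batch_size = batch_size
        self.class_weights = class_weights
        self.grad_clip_max_norm = grad_clip_max_norm
        self.psa_branches = psa_branches
        self.attention_levels = attention_levels
        self.seed = seed

    # -- config assembly ----------------------------------------------
    def _model_config(self) -> ModelConfig:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {sorted(VARIANTS)}")
        att = AttentionConfig(mode=VARIANTS[self.variant],
                              psa_branches=self.psa_branches)
        return ModelConfig(num_classes=self.num_classes,
                           base_width=self.base_width, depth=self.depth,
                           attention=att,
                           attention_levels=self.attention_levels)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, weight_decay=self.weight_decay,
                           lr_period=self.lr_period, epochs=self.epochs,
                           batch_size=self.batch_size,
                           class_weights=self.class_weights,
                           grad_clip_max_norm=self.grad_clip_max_norm,
                           seed=self.seed)

    # -- estimator API -------------------------------------------------
    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError("X and y must both have shape (n, H, W)")
        mcfg = self._model_config()
        model = build_model(mcfg, seed=self.seed)
        train_set = list(zip(X, y))
        val_set = ([] if validation_data is None
                   else list(zip(np.asarray(validation_data[0],
                                            dtype=np.float32),
                                 np.asarray(validation_data[1]))))
        model, hist = train(model, (train_set, val_set, []),
                            self._train_config())
        self.model_ = model
        self.model_config_ = mcfg
        self.history_ = hist
        self.n_parameters_ = model.num_parameters()
        self.best_val_dice_ = (max(hist.val_dice) if val_set else None)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        single = X.ndim == 2
        if single:
            X = X[None]
        f = 2 ** (self.depth - 1)
        if X.shape[1] % f or X.shape[2] % f:
            raise ValueError(
                f"input {X.shape[1]}x{X.shape[2]} not divisible by {f}; "
                "run preprocess_geometry first")
        out = []
        for i in range(0, len(X), max(1, self.batch_size)):
            logits = _predict_logits(self.model_, X[i:i + self.batch_size])
            out.append(np.argmax(logits, axis=1))
        masks = np.concatenate(out, axis=0)
        return masks[0] if single else masks

    def predict_stack(self, stack) -> MaskStack:
        """Segment an ImageStack slice by slice, restoring native geometry
        when preprocessing metadata is present."""
        from .io import ImageStack, restore_geometry
        self._check_fitted()
        if isinstance(stack, ImageStack):
            if len(stack) == 0:
                return MaskStack([])
            arr = stack.as_array()
            metas = [dict(s.meta) for s in stack]
        else:
            arr = np.asarray(stack, dtype=np.float32)
            metas = [{} for _ in range(len(arr))]
        preds = self.predict(arr)
        out = [restore_geometry(SegmentationMask(p, meta))
               for p, meta in zip(preds, metas)]
        return MaskStack(out)

    def score(self, X, y) -> float:
        """Pooled Dice coefficient over the given set."""
        preds = self.predict(X)
        y = np.asarray(y)
        from .metrics import dice
        return dice(pooled_confusion(list(preds), list(y)))
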