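"""Encoder-decoder ear segmentation: configuration, training, inference.

The model is a U-Net with a VGG-style encoder (stacked 3x3 convolutions,
four 2x2 max-pools) and a single-convolution bottleneck; see
:mod:`earcount.nn.unet` for the graph. Candidate regions (superpixel crops)
are resized to the network input size, classified pixel-wise, and the
probability maps are resized back and stitched into a full-image map using
each region's ownership mask, so every image pixel is written exactly once.

Training minimizes mean binary cross-entropy with Adam. At full scale the
network takes 224x224 inputs and 64..512 encoder channels; ``width_multiplier``
shrinks every channel count proportionally for desk-scale CPU experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage import transform as sktransform
from sklearn.base import BaseEstimator

from .nn.unet import Adam, UNet
from .slic import RegionInput

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainingHistory",
    "build_model",
    "bce_loss",
    "train",
    "predict_region",
    "predict_regions",
    "stitch_predictions",
    "save_model",
    "load_model",
    "UNetSegmenter",
]

EPS = 1e-7  # probability clipping in the loss


@dataclass
class ModelConfig:
    input_size: tuple[int, int, int] = (224, 224, 3)
    encoder_widths: tuple[int, ...] = (64, 128, 256, 512)
    n_pool: int = 4
    bottleneck_channels: int = 512
    width_multiplier: float = 1.0
    pretrained_encoder: bool = False

    def __post_init__(self):
        if self.n_pool != 4:
            raise ValueError("the architecture uses exactly four max-pooling stages")
        h, w, c = self.input_size
        if c != 3:
            raise ValueError("inputs are three-channel RGB")
        if h % 2**self.n_pool or w % 2**self.n_pool:
            raise ValueError("input spatial size must be divisible by 2^4")
        if not 0 < self.width_multiplier <= 1:
            raise ValueError("width_multiplier must lie in (0, 1]")
        if self.pretrained_encoder:
            raise ValueError(
                "pretrained encoder weights are not bundled; train from scratch "
                "(pretrained_encoder=False)"
            )

    @property
    def scaled_widths(self) -> list[int]:
        return [max(2, int(round(w * self.width_multiplier))) for w in self.encoder_widths]

    @property
    def scaled_bottleneck(self) -> int:
        return max(2, int(round(self.bottleneck_channels * self.width_multiplier)))


@dataclass
class TrainConfig:
    epochs: int = 15
    learning_rate: float = 1e-4
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("epochs, learning_rate and batch_size must be positive")


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)

    def record(self, **kw):
        self.epochs.append(dict(kw))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def build_model(config: ModelConfig, seed: int = 0) -> UNet:
    """Instantiate the network with seeded He-normal weights."""
    model = UNet(config.scaled_widths, config.scaled_bottleneck, seed=seed)
    model.config = config
    return model


def bce_loss(pred: np.ndarray, target: np.ndarray, eps: float = EPS) -> float:
    """Mean binary cross-entropy, predictions clipped to (eps, 1-eps)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, eps, 1 - eps)
    return float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))


def _resize_image(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to (H, W), output float32 in [0, 1]."""
    out = sktransform.resize(
        np.asarray(img, dtype=np.float32) / 255.0, size, order=1,
        mode="edge", anti_aliasing=False, preserve_range=True,
    )
    return out.astype(np.float32)


def _resize_mask(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize keeping the mask binary."""
    out = sktransform.resize(
        np.asarray(mask, dtype=np.float32), size, order=0,
        mode="edge", anti_aliasing=False, preserve_range=True,
    )
    return (out > 0.5).astype(np.float32)


def _prepare(patchset, size):
    X = np.stack([_resize_image(p.image, size) for p in patchset])
    Y = np.stack([_resize_mask(p.mask, size) for p in patchset])
    return X, Y


def _eval(model, X, Y, batch_size):
    losses, accs, n = [], [], len(X)
    for i in range(0, n, batch_size):
        p = model.forward(X[i:i + batch_size])
        t = Y[i:i + batch_size]
        losses.append(bce_loss(p, t) * len(t))
        accs.append(float(((p >= 0.5) == (t >= 0.5)).mean()) * len(t))
    return sum(losses) / n, sum(accs) / n


def train(model: UNet, train_set, val_set, cfg: TrainConfig | None = None):
    """Fit the network on a PatchSet (or any iterable of patches).

    Patches are resized to the model input size (bilinear image, nearest
    mask). Returns ``(model, history)``; raises ``RuntimeError`` if the loss
    diverges to NaN. All shuffling is driven by ``cfg.seed``.
    """
    if cfg is None:
        cfg = TrainConfig()
    size = model.config.input_size[:2]
    Xtr, Ytr = _prepare(train_set, size)
    Xva, Yva = _prepare(val_set, size)
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("train and validation sets must be nonempty")
    opt = Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = TrainingHistory()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xtr))
        tr_loss = tr_acc = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, tb = Xtr[idx], Ytr[idx]
            p = model.forward(xb)
            loss = bce_loss(p, tb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at epoch {epoch}; "
                    "lower the learning rate"
                )
            model.backward(tb)
            opt.step(model.grads)
            tr_loss += loss * len(idx)
            tr_acc += float(((p >= 0.5) == (tb >= 0.5)).mean()) * len(idx)
        va_loss, va_acc = _eval(model, Xva, Yva, cfg.batch_size)
        history.record(
            epoch=epoch + 1,
            train_loss=tr_loss / len(Xtr),
            train_accuracy=tr_acc / len(Xtr),
            val_loss=va_loss,
            val_accuracy=va_acc,
        )
    return model, history


def predict_region(model: UNet, region: RegionInput) -> np.ndarray:
    """Probability map for one candidate region at the network input size."""
    return predict_regions(model, [region])[0]


def predict_regions(model: UNet, regions, batch_size: int = 16) -> list[np.ndarray]:
    """Batched inference over candidate regions (order preserved)."""
    if not hasattr(model, "config"):
        raise ValueError("model has no config; build it with build_model/load_model")
    size = model.config.input_size[:2]
    maps: list[np.ndarray] = []
    regions = list(regions)
    for i in range(0, len(regions), batch_size):
        batch = np.stack([_resize_image(r.crop, size) for r in regions[i:i + batch_size]])
        p = model.forward(batch)
        maps.extend(np.asarray(p[j], dtype=np.float64) for j in range(len(batch)))
    return maps


def stitch_predictions(regions, maps, image_shape) -> np.ndarray:
    """Reassemble per-region probability maps into a full-image map.

    Each map is resized back to its region's bounding box and only the pixels
    owned by the region's mask are written. Raises ``ValueError`` unless every
    image pixel is written exactly once (the regions must partition the image).
    """
    regions, maps = list(regions), list(maps)
    if len(regions) != len(maps):
        raise ValueError("need exactly one probability map per region")
    H, W = image_shape[:2]
    out = np.zeros((H, W), dtype=np.float64)
    cover = np.zeros((H, W), dtype=np.int32)
    for region, pmap in zip(regions, maps):
        x0, y0, x1, y1 = region.box
        local = sktransform.resize(
            np.asarray(pmap, dtype=np.float64), (y1 - y0, x1 - x0), order=1,
            mode="edge", anti_aliasing=False, preserve_range=True,
        )
        m = region.mask.astype(bool)
        out[y0:y1, x0:x1][m] = local[m]
        cover[y0:y1, x0:x1] += m
    if (cover != 1).any():
        bad = int((cover != 1).sum())
        raise ValueError(f"regions do not partition the image ({bad} pixels covered != once)")
    return out


def save_model(path, model: UNet) -> None:
    """Write weights as .npz plus a JSON sidecar with the model configuration."""
    arrays = {f"p{i}": p for i, p in enumerate(model.params)}
    np.savez(path, **arrays)
    cfg = asdict(model.config)
    sidecar = str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump(cfg, fh, indent=2)


def load_model(path) -> UNet:
    """Rebuild a model from :func:`save_model` output; refuses a missing sidecar."""
    p = str(path)
    sidecar = p + ".json" if not p.endswith(".npz") else p[:-4] + ".json"
    with open(sidecar) as fh:
        cfg_dict = json.load(fh)
    cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
    cfg_dict["encoder_widths"] = tuple(cfg_dict["encoder_widths"])
    config = ModelConfig(**cfg_dict)
    model = build_model(config)
    data = np.load(p if p.endswith(".npz") else p + ".npz")
    params = model.params
    if len(data.files) != len(params):
        raise ValueError("checkpoint does not match the model configuration")
    for i, param in enumerate(params):
        arr = data[f"p{i}"]
        if arr.shape != param.shape:
            raise ValueError("checkpoint does not match the model configuration")
        param[...] = arr
    return model


class UNetSegmenter(BaseEstimator):
    """Sklearn-style pixel classifier wrapping the U-Net.

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`. ``fit``
    takes a sequence of RGB patches ``X`` and binary masks ``y`` (each patch
    may have its own size; everything is resized to ``input_size``), trains
    from seeded random weights, and exposes ``model_``, ``config_``,
    ``history_``. ``predict`` returns binary masks and ``predict_proba_map``
    probability maps at the network input size; ``score`` is mean pixel
    accuracy.
    """

    def __init__(
        self,
        input_size: int = 224,
        encoder_widths: tuple[int, ...] = (64, 128, 256, 512),
        bottleneck_channels: int = 512,
        width_multiplier: float = 1.0,
        epochs: int = 15,
        learning_rate: float = 1e-4,
        batch_size: int = 8,
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.input_size = input_size
        self.encoder_widths = encoder_widths
        self.bottleneck_channels = bottleneck_channels
        self.width_multiplier = width_multiplier
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _model_config(self) -> ModelConfig:
        s = int(self.input_size)
        return ModelConfig(
            input_size=(s, s, 3),
            encoder_widths=tuple(self.encoder_widths),
            bottleneck_channels=self.bottleneck_channels,
            width_multiplier=self.width_multiplier,
        )

    def fit(self, X, y):
        from .annotations import BACKGROUND, EAR, Patch, PatchSet, split_train_val

        patches = [
            Patch(img, mask, EAR if np.any(mask) else BACKGROUND)
            for img, mask in zip(X, y)
        ]
        pset = PatchSet(patches)
        train_set, val_set = split_train_val(pset, self.validation_fraction, self.seed)
        self.config_ = self._model_config()
        model = build_model(self.config_, seed=self.seed)
        cfg = TrainConfig(
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=self.seed,
        )
        self.model_, self.history_ = train(model, train_set, val_set, cfg)
        return self

    def predict_proba_map(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        size = self.config_.input_size[:2]
        batch = np.stack([_resize_image(np.asarray(img), size) for img in X])
        return np.asarray(self.model_.forward(batch), dtype=np.float64)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba_map(X) >= 0.5).astype(np.uint8)

    def score(self, X, y) -> float:
        size = self.config_.input_size[:2]
        masks = np.stack([_resize_mask(np.asarray(m), size) for m in y])
        return float((self.predict(X) == masks.astype(np.uint8)).mean())
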