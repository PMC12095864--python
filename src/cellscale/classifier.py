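"""Backbone-agnostic 3-class trainer with dual-background invariance.

The classifier learns the S/M/L size class from local skin-cell crops.
To stop it keying on how much dark background a crop happens to contain,
every training input is duplicated with its background (pixels at HSB
brightness <= 30) forced to 255 and to 0; the loss combines softmax
cross-entropy on the bright-background branch with an MSE penalty on the
difference between the two logit vectors, so a good model must produce
the same answer whatever the background looks like:

    loss = CE(softmax(logits_bg255), y) + w * MSE(logits_bg255, logits_bg0)

Optimization is AdamW; model selection uses the validation score
(weighted F1 + macro F1) / 2, with early stopping after a patience
window without improvement and the best checkpoint restored.

Two input regimes exist: the crop-and-vote regime (one random crop per
image per epoch for training; isometric tiling, dark-ratio filtering
and plurality voting at evaluation) and the bright-field regime (whole
silhouette images rescaled to 1,288 x 214 px to erase absolute size,
no cropping or voting).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

from . import nn
from .cropping import CropSpec, dark_ratio, isometric_crops, sample_random_crop, vote
from .metrics import CLASSES, EvalReport, PredictionSet, class_index, evaluate

#: Fixed rescale applied to every bright-field image before the input
#: resize, chosen so absolute body size cannot leak into the classifier.
BRIGHTFIELD_SHAPE = (214, 1288)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults are the fine-tuning settings of the full-scale pipeline;
    desk-scale runs on the tiny backbone override the learning rate and
    epoch budget (see the methods note).
    """

    learning_rate: float = 1e-5
    weight_decay: float = 1e-2
    batch_size: int = 64
    max_epochs: int = 500
    early_stop_patience: int = 50
    seed: int = 2022
    backbone: str = "tiny_cnn"
    input_side_px: int = 224
    invariance_weight: float = 1.0
    crop_spec: CropSpec | None = None
    vote: bool = True
    width: int = 16
    ce_branch: str = "bg255"

    def __post_init__(self) -> None:
        for name in ("learning_rate", "weight_decay", "batch_size", "max_epochs",
                     "early_stop_patience", "input_side_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.early_stop_patience >= self.max_epochs and self.max_epochs > 1:
            raise ValueError("early_stop_patience must be smaller than max_epochs")
        if self.invariance_weight < 0:
            raise ValueError("invariance_weight must be nonnegative")
        if self.backbone != "tiny_cnn":
            raise ValueError(
                "only the self-contained tiny_cnn backbone is available; "
                f"got {self.backbone!r}"
            )
        if self.ce_branch not in ("bg255", "bg0"):
            raise ValueError("ce_branch must be 'bg255' or 'bg0'")


@dataclass
class LogitPair:
    """The two logit vectors of one dual-background image pair."""

    logits_bg_max: np.ndarray
    logits_bg_min: np.ndarray
    true_class: str

    def __post_init__(self) -> None:
        self.logits_bg_max = np.asarray(self.logits_bg_max, dtype=float)
        self.logits_bg_min = np.asarray(self.logits_bg_min, dtype=float)
        if self.logits_bg_max.shape != (3,) or self.logits_bg_min.shape != (3,):
            raise ValueError("each logit set must be a length-3 vector")


def dual_background(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two copies of an image differing only in their backgrounds.

    Background = pixels with HSB brightness (max RGB channel) <= 30.
    Foreground pixels are untouched; background pixels are set to 255
    in the first copy and 0 in the second.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image")
    bg = img.max(axis=2) <= 30
    hi = img.copy()
    lo = img.copy()
    hi[bg] = 255
    lo[bg] = 0
    return hi, lo


def invariance_loss(pair: LogitPair, invariance_weight: float = 1.0) -> float:
    """CE on the bright-background logits + weighted logit-difference MSE.

    The MSE is averaged over the three logit entries. With weight 0 the
    loss reduces exactly to the cross-entropy term.
    """
    lmax, lmin = pair.logits_bg_max, pair.logits_bg_min
    if not (np.isfinite(lmax).all() and np.isfinite(lmin).all()):
        raise ValueError("non-finite logits")
    p = nn.softmax(lmax[None, :])[0]
    ce = -float(np.log(p[class_index(pair.true_class)] + 1e-12))
    mse = float(((lmax - lmin) ** 2).mean())
    return ce + invariance_weight * mse


def _to_tensor(images: list[np.ndarray], side: int) -> np.ndarray:
    """Stack uint8 RGB images into a (N, 3, side, side) float32 batch."""
    out = np.empty((len(images), 3, side, side), dtype=np.float32)
    for i, img in enumerate(images):
        img = np.asarray(img, dtype=np.float32)
        if img.shape[0] != side or img.shape[1] != side:
            img = resize(img, (side, side, 3), order=1, preserve_range=True,
                         anti_aliasing=False)
        out[i] = (img / 255.0).transpose(2, 0, 1)
    return out


def rescale_brightfield(image: np.ndarray) -> np.ndarray:
    """Rescale a bright-field image to the fixed 214 x 1,288 shape."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    out = resize(img, BRIGHTFIELD_SHAPE + (3,), order=1, preserve_range=True,
                 anti_aliasing=True)
    return np.clip(out, 0, 255).astype(np.uint8)


@dataclass
class TrainingCurves:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_score: list[float] = field(default_factory=list)


class SizeClassifier:
    """A trained size classifier: prediction, voting, and Grad-CAM."""

    def __init__(self, network: nn.Network, config: TrainConfig,
                 curves: TrainingCurves | None = None,
                 best_epoch: int = -1, best_val_score: float = float("nan")):
        self.network = network
        self.config = config
        self.curves = curves or TrainingCurves()
        self.best_epoch = best_epoch
        self.best_val_score = best_val_score

    # -- low-level prediction ------------------------------------------------

    def _branch(self, image: np.ndarray) -> np.ndarray:
        hi, lo = dual_background(image)
        return hi if self.config.ce_branch == "bg255" else lo

    def logits(self, images: list[np.ndarray], chunk: int = 256) -> np.ndarray:
        """Logits for a list of RGB crops/images (CE branch background)."""
        side = self.config.input_side_px
        batch = _to_tensor([self._branch(img) for img in images], side)
        outs = [self.network.predict_logits(batch[i:i + chunk])
                for i in range(0, len(batch), chunk)]
        return np.concatenate(outs, axis=0) if outs else np.zeros((0, 3))

    def predict_whole(self, image: np.ndarray) -> str:
        """Whole-image prediction (the no-voting path)."""
        return CLASSES[int(self.logits([image])[0].argmax())]

    def predict_voted(self, image: np.ndarray, image_id: str = "") -> str:
        """Isometric crops -> dark filter -> per-crop votes -> plurality.

        Falls back to the whole-image prediction when every crop is dark.
        """
        if self.config.crop_spec is None:
            return self.predict_whole(image)
        batch = isometric_crops(image, self.config.crop_spec, image_id=image_id)
        crops = batch.included_crops()
        if not crops:
            return vote(batch, fallback=self.predict_whole(image))
        scores = self.logits(crops)
        batch.predictions = [CLASSES[int(i)] for i in scores.argmax(axis=1)]
        return vote(batch, per_crop_scores=scores)

    def predict(self, image: np.ndarray) -> str:
        return self.predict_voted(image) if self.config.vote else self.predict_whole(image)

    # -- evaluation ----------------------------------------------------------

    def evaluate_images(self, images: list[np.ndarray], labels: list[str],
                        voted: bool | None = None,
                        ids: list[str] | None = None) -> EvalReport:
        voted = self.config.vote if voted is None else voted
        ids = ids or [str(i) for i in range(len(images))]
        preds = [self.predict_voted(img, i) if voted else self.predict_whole(img)
                 for img, i in zip(images, ids)]
        return evaluate(PredictionSet(ids, list(labels), preds))

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Write a checkpoint directory: config JSON + weight arrays."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        config = asdict(self.config)
        crop_spec = config.pop("crop_spec")
        config["crop_spec"] = None if crop_spec is None else dict(crop_spec)
        meta = {
            "config": config,
            "best_epoch": self.best_epoch,
            "best_val_score": self.best_val_score,
        }
        (out / "config.json").write_text(json.dumps(meta, indent=2) + "\n")
        weights = {f"w{i}": w for i, (w, _) in enumerate(self.network.params())}
        np.savez(out / "weights.npz", **weights)

    @classmethod
    def load(cls, path) -> "SizeClassifier":
        import json
        from pathlib import Path

        from . import nn as _nn
        from .cropping import CropSpec as _CropSpec

        src = Path(path)
        meta = json.loads((src / "config.json").read_text())
        config_dict = dict(meta["config"])
        crop_spec = config_dict.pop("crop_spec")
        if crop_spec is not None:
            crop_spec["area_mm2"] = (
                crop_spec["area_mm2"] if crop_spec["area_mm2"] == "full"
                else float(crop_spec["area_mm2"])
            )
            config_dict["crop_spec"] = _CropSpec(**crop_spec)
        else:
            config_dict["crop_spec"] = None
        config = TrainConfig(**config_dict)
        network = _nn.tiny_cnn(seed=config.seed, width=config.width)
        with np.load(src / "weights.npz") as data:
            network.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        clf = cls(network, config,
                  best_epoch=meta["best_epoch"],
                  best_val_score=meta["best_val_score"])
        return clf

    # -- attribution ---------------------------------------------------------

    def grad_cam(self, image: np.ndarray, target_class: str | None = None) -> np.ndarray:
        """Grad-CAM activation map in [0, 255], at the source image size.

        Gradients of the target-class logit are taken at the ReLU output
        of the last conv block; channel weights are their spatial means,
        and the weighted, rectified sum is normalized to 0..255.
        """
        side = self.config.input_side_px
        x = _to_tensor([self._branch(image)], side)
        # forward pass capturing both the caches and the CAM-layer output
        out = x
        caches, act = [], None
        for idx, layer in enumerate(self.network.layers):
            out, cache = layer.forward(out)
            caches.append(cache)
            if idx == self.network.cam_layer:
                act = out
        logits = out
        k = (int(logits[0].argmax()) if target_class is None
             else class_index(target_class))
        dlogits = np.zeros_like(logits)
        dlogits[0, k] = 1.0
        self.network.zero_grad()
        grad_act = self.network.backward(dlogits, caches,
                                         to_layer=self.network.cam_layer)
        alpha = grad_act.mean(axis=(2, 3))  # (1, C)
        cam = np.maximum((alpha[:, :, None, None] * act).sum(axis=1), 0.0)[0]
        if cam.max() > 0:
            cam = cam / cam.max()
        cam = resize(cam, np.asarray(image).shape[:2], order=1,
                     preserve_range=True, anti_aliasing=False)
        return np.clip(np.round(cam * 255.0), 0, 255).astype(np.uint8)


def _epoch_inputs(images, labels, config: TrainConfig, rng: np.random.Generator):
    """One training pass worth of inputs: a random crop per image (crop
    regime) or the images themselves, paired with integer labels."""
    crops, ys = [], []
    for img, lab in zip(images, labels):
        if config.crop_spec is not None:
            crop, _ = sample_random_crop(img, config.crop_spec, rng,
                                         augmentations=True,
                                         with_rotation=config.vote)
            # skip all-dark training crops; they carry no cells
            if dark_ratio(crop) >= 0.65:
                continue
        else:
            crop = img
        crops.append(crop)
        ys.append(class_index(lab))
    return crops, np.array(ys, dtype=int)


def _train_network(config: TrainConfig, train_images, train_labels,
                   val_images, val_labels) -> SizeClassifier:
    rng = np.random.default_rng(config.seed)
    network = nn.tiny_cnn(seed=config.seed, width=config.width)
    optimizer = nn.AdamW(network.params(), lr=config.learning_rate,
                         weight_decay=config.weight_decay)
    side = config.input_side_px
    clf = SizeClassifier(network, config)
    curves = clf.curves
    best_score, best_epoch, best_weights = -np.inf, -1, network.get_weights()
    since_best = 0
    val_labels = list(val_labels)

    for epoch in range(config.max_epochs):
        crops, ys = _epoch_inputs(train_images, train_labels, config, rng)
        order = rng.permutation(len(crops))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size == 0:
                continue
            pairs = [dual_background(crops[i]) for i in idx]
            x_hi = _to_tensor([p[0] for p in pairs], side)
            x_lo = _to_tensor([p[1] for p in pairs], side)
            y = ys[idx]
            network.zero_grad()
            logits_hi, caches_hi = network.forward(x_hi)
            logits_lo, caches_lo = network.forward(x_lo)
            if config.ce_branch == "bg255":
                ce_logits, ce_caches = logits_hi, caches_hi
            else:
                ce_logits, ce_caches = logits_lo, caches_lo
            ce, dce = nn.cross_entropy(ce_logits, y)
            diff = logits_hi - logits_lo
            n = diff.shape[0]
            mse = float((diff**2).mean())
            dmse = 2.0 * diff / (3.0 * n)
            d_hi = config.invariance_weight * dmse
            d_lo = -config.invariance_weight * dmse
            if config.ce_branch == "bg255":
                d_hi = d_hi + dce
            else:
                d_lo = d_lo + dce
            network.backward(d_hi, caches_hi)
            network.backward(d_lo, caches_lo)
            optimizer.step()
            epoch_losses.append(ce + config.invariance_weight * mse)

        # per-epoch model selection on the validation split
        preds = [clf.predict(pimg) for pimg in val_images]
        score = evaluate(PredictionSet(
            [str(i) for i in range(len(val_images))], val_labels, preds
        )).validation_score
        curves.epoch.append(epoch)
        curves.train_loss.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
        curves.val_score.append(score)
        if score > best_score:
            best_score, best_epoch = score, epoch
            best_weights = network.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break

    network.set_weights(best_weights)
    clf.best_epoch = best_epoch
    clf.best_val_score = float(best_score)
    return clf


def train(config: TrainConfig, train_images, train_labels,
          val_images, val_labels) -> SizeClassifier:
    """Train the crop-and-vote (or whole-image) size classifier."""
    if not len(train_images) or not len(val_images):
        raise ValueError("training and validation splits must be nonempty")
    return _train_network(config, train_images, list(train_labels),
                          list(val_images), val_labels)


def train_brightfield(config: TrainConfig, images, labels,
                      val_images, val_labels) -> SizeClassifier:
    """Train the bright-field branch: fixed 1,288 x 214 rescale, no
    cropping or voting. Accepts RGB images or binary silhouette masks
    (masks are rendered as gray body on dark background)."""
    if not len(images) or not len(val_images):
        raise ValueError("training and validation splits must be nonempty")
    config = replace(config, crop_spec=None, vote=False)
    return _train_network(config,
                          [prepare_brightfield(i) for i in images], list(labels),
                          [prepare_brightfield(v) for v in val_images],
                          list(val_labels))


def prepare_brightfield(image: np.ndarray) -> np.ndarray:
    """Render a binary silhouette as gray body on a dark background (RGB
    images pass through) and apply the fixed 1,288 x 214 rescale."""
    img = np.asarray(image)
    if img.dtype == bool or img.ndim == 2:
        body = img.astype(bool)
        rendered = np.full(body.shape + (3,), 12, dtype=np.uint8)
        rendered[body] = 160
        img = rendered
    return rescale_brightfield(img)
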