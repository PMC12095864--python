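"""Random-crop augmentation, isometric tiling, dark filtering, voting.

Training uses one randomly placed sub-crop per image per epoch (520
training images over 167 epochs is how the original ~80,000-crop
augmentation count arises: 520 x 167 = 86,840). Evaluation instead
tiles each image with a deterministic non-overlapping grid of
fixed-size "isometric" crops anchored top-left, discards partial tiles
at the right/bottom edges, drops crops whose dark ratio (fraction of
pixels with HSB brightness <= 30) reaches 0.65, and lets every
surviving crop cast one vote; the plurality class wins. An image whose
crops are all dark falls back to a whole-image prediction.

Crop sizes are stated as physical areas (mm²) and converted to pixels
through each image's µm/px scale: side = round(sqrt(area)·1000/µm_per_px).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters
from skimage.transform import resize, rotate

from .metrics import CLASSES, class_index

#: The standard physical crop areas (mm²); "full" means no cropping.
CROP_AREAS_MM2 = (0.1, 0.05, 0.02, 0.01, 0.006)

DARK_RATIO_LIMIT = 0.65
INTENSITY_THRESHOLD = 30


@dataclass(frozen=True)
class CropSpec:
    """One crop geometry: physical area -> pixel rectangle.

    ``aspect`` handles the axis-trimmed variants: a square of the same
    area is narrowed along one axis and extended along the other
    (x_trimmed: half-width, double-height; y_trimmed the transpose), so
    that the areas and expected cell counts of the three variants match.
    """

    area_mm2: float | str  # one of CROP_AREAS_MM2 or "full"
    um_per_px: float = 465.0 / 192.0
    aspect: str = "square"

    def shape_px(self, image_shape: tuple[int, int]) -> tuple[int, int]:
        """(height, width) of the crop for an image of the given shape."""
        if self.area_mm2 == "full":
            return image_shape[0], image_shape[1]
        side = int(round(np.sqrt(float(self.area_mm2)) * 1000.0 / self.um_per_px))
        if self.aspect == "square":
            h, w = side, side
        elif self.aspect == "x_trimmed":
            h, w = 2 * side, max(1, side // 2)
        elif self.aspect == "y_trimmed":
            h, w = max(1, side // 2), 2 * side
        else:
            raise ValueError(f"unknown aspect {self.aspect!r}")
        if min(h, w) < 32:
            raise ValueError("crop side must be at least 32 px")
        if h > image_shape[0] or w > image_shape[1]:
            raise ValueError("crop does not fit inside the image")
        return h, w


@dataclass
class CropBatch:
    """Tiled crops of one image with dark-ratio bookkeeping."""

    image_id: str
    origins: list[tuple[int, int]]  # (row, col), 0-based top-left
    crops: list[np.ndarray]
    dark_ratios: list[float]
    included: list[bool]
    predictions: list[str] = field(default_factory=list)  # per included crop

    @property
    def n_included(self) -> int:
        return int(sum(self.included))

    def included_crops(self) -> list[np.ndarray]:
        return [c for c, ok in zip(self.crops, self.included) if ok]


def brightness(image: np.ndarray) -> np.ndarray:
    """HSB brightness channel: the per-pixel max over RGB."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(float)
    return img.max(axis=2).astype(float)


def dark_ratio(crop: np.ndarray, intensity_threshold: int = INTENSITY_THRESHOLD) -> float:
    """Fraction of pixels whose brightness is <= the intensity threshold."""
    v = brightness(crop)
    if v.size == 0:
        raise ValueError("empty crop")
    return float((v <= intensity_threshold).mean())


def total_crops(n_images: int, n_epochs: int) -> int:
    """Sub-crops generated by one random crop per image per epoch."""
    return n_images * n_epochs


def augment(crop: np.ndarray, rng: np.random.Generator, with_rotation: bool = False) -> np.ndarray:
    """Training-time augmentation: flips always considered; one of
    gamma/sigmoid contrast with probability 0.3; one of blur/sharpen
    with probability 0.3; rotation in [-30°, 30°] only in the voting
    configuration."""
    out = np.asarray(crop, dtype=float) / 255.0
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    if rng.random() < 0.3:
        if rng.random() < 0.5:
            gamma = rng.uniform(0.7, 1.5)
            out = np.clip(out, 0, 1) ** gamma
        else:
            gain, cutoff = rng.uniform(5, 10), rng.uniform(0.3, 0.6)
            out = 1.0 / (1.0 + np.exp(gain * (cutoff - out)))
    if rng.random() < 0.3:
        if rng.random() < 0.5:
            sigma = rng.uniform(0.3, 1.2)
            out = filters.gaussian(out, sigma=sigma, channel_axis=-1)
        else:
            blurred = filters.gaussian(out, sigma=1.0, channel_axis=-1)
            out = np.clip(out + rng.uniform(0.5, 1.0) * (out - blurred), 0, 1)
    if with_rotation:
        angle = rng.uniform(-30.0, 30.0)
        out = rotate(out, angle, mode="reflect")
    return np.clip(out * 255.0, 0, 255).astype(np.uint8)


def sample_random_crop(
    image: np.ndarray,
    spec: CropSpec,
    rng: np.random.Generator,
    augmentations: bool = True,
    with_rotation: bool = False,
) -> tuple[np.ndarray, tuple[int, int]]:
    """One uniformly placed crop of the image, optionally augmented."""
    img = np.asarray(image)
    ch, cw = spec.shape_px(img.shape[:2])
    row = int(rng.integers(0, img.shape[0] - ch + 1))
    col = int(rng.integers(0, img.shape[1] - cw + 1))
    crop = img[row : row + ch, col : col + cw]
    if augmentations:
        crop = augment(crop, rng, with_rotation=with_rotation)
    return crop, (row, col)


def isometric_crops(
    image: np.ndarray,
    spec: CropSpec,
    image_id: str = "",
    dark_limit: float = DARK_RATIO_LIMIT,
    intensity_threshold: int = INTENSITY_THRESHOLD,
) -> CropBatch:
    """Deterministic non-overlapping grid tiling with dark filtering.

    Tiles are anchored at the top-left corner; partial tiles at the
    right/bottom edges are discarded. A crop is excluded exactly when
    its dark ratio is >= the limit (0.65 means 65% or more dark pixels).
    """
    img = np.asarray(image)
    ch, cw = spec.shape_px(img.shape[:2])
    origins, crops, ratios, included = [], [], [], []
    for row in range(0, img.shape[0] - ch + 1, ch):
        for col in range(0, img.shape[1] - cw + 1, cw):
            crop = img[row : row + ch, col : col + cw]
            r = dark_ratio(crop, intensity_threshold)
            origins.append((row, col))
            crops.append(crop)
            ratios.append(r)
            included.append(r < dark_limit)
    return CropBatch(image_id, origins, crops, ratios, included)


def vote(
    batch: CropBatch,
    per_crop_scores: np.ndarray | None = None,
    fallback: str | None = None,
) -> str:
    """Plurality vote over the included crops of one image.

    ``batch.predictions`` holds one class per included crop. Ties are
    broken by the highest summed class scores over the included crops
    (when ``per_crop_scores``, shape (n_included, 3), is given), then
    by fixed class order S < M < L. With zero included crops the
    ``fallback`` class (a whole-image prediction) is returned.
    """
    if batch.n_included == 0:
        if fallback is None:
            raise ValueError("no included crops and no whole-image fallback prediction")
        return fallback
    if len(batch.predictions) != batch.n_included:
        raise ValueError("need one prediction per included crop")
    counts = np.zeros(3, dtype=int)
    for p in batch.predictions:
        counts[class_index(p)] += 1
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if tied.size == 1:
        return CLASSES[tied[0]]
    if per_crop_scores is not None:
        scores = np.asarray(per_crop_scores, dtype=float)
        if scores.shape != (batch.n_included, 3):
            raise ValueError("per_crop_scores must be (n_included, 3)")
        summed = scores.sum(axis=0)
        tied = sorted(tied, key=lambda i: (-summed[i], i))
        return CLASSES[tied[0]]
    return CLASSES[tied[0]]
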