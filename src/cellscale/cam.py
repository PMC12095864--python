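"""Class-activation-map post-processing into hotspot statistics.

A grayscale CAM (0..255) highlights the crop regions driving a class
prediction. To turn it into a comparable per-crop number, the CAM is
thresholded at 120 (about half the 8-bit range), ANDed with a cleaned
foreground mask (brightness > 30, then a 2x2 erosion to drop isolated
bright specks followed by a 2x2 dilation to restore extent), and the
connected components (8-connectivity) of the surviving pixels are the
"hotspots". The area of the largest hotspot per crop is the statistic
compared between size classes: diffuse clone-wide attention produces
larger hotspots than attention to isolated single cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
from scipy import ndimage
from skimage.transform import resize

CAM_THRESHOLD = 120
BRIGHTNESS_THRESHOLD = 30


@dataclass
class CamImage:
    """One grayscale activation map aligned to its source crop."""

    activation: np.ndarray
    source_image_id: str = ""
    predicted_class: str | None = None

    def __post_init__(self) -> None:
        self.activation = np.asarray(self.activation)
        if self.activation.ndim != 2:
            raise ValueError("activation must be a 2-D grayscale array")


@dataclass
class HotspotStats:
    """Hotspot summary of one crop's thresholded, masked CAM."""

    largest_hotspot_area_px: int
    n_hotspots: int
    peak_activation: int
    class_label: str | None = None


def foreground_mask(image: np.ndarray,
                    brightness_threshold: int = BRIGHTNESS_THRESHOLD) -> np.ndarray:
    """Cell-region mask: brightness > 30, 2x2 erosion, then 2x2 dilation."""
    img = np.asarray(image)
    v = img.max(axis=2) if img.ndim == 3 else img
    mask = v > brightness_threshold
    footprint = np.ones((2, 2), dtype=bool)
    mask = ndimage.binary_erosion(mask, structure=footprint)
    mask = ndimage.binary_dilation(mask, structure=footprint)
    return mask


def hotspot_stats(cam: CamImage, mask: np.ndarray,
                  cam_threshold: int = CAM_THRESHOLD) -> HotspotStats:
    """Connected-component stats of (CAM >= threshold) AND mask."""
    mask = np.asarray(mask).astype(bool)
    if cam.activation.shape != mask.shape:
        raise ValueError("CAM and mask dimensions must match")
    binary = (cam.activation >= cam_threshold) & mask
    labeled, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return HotspotStats(0, 0, 0, cam.predicted_class)
    areas = np.bincount(labeled.ravel())[1:]
    peak = int(cam.activation[binary].max())
    return HotspotStats(int(areas.max()), int(n), peak, cam.predicted_class)


def cam_overlay(cam: CamImage, source: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Jet-colormapped CAM alpha-blended onto its source crop.

    Activation 0 maps to the cold (blue) end of the colormap and 255 to
    the warm (red) end; ``alpha`` = 0 returns the source unchanged.
    """
    src = np.asarray(source, dtype=float)
    if src.ndim == 2:
        src = np.repeat(src[:, :, None], 3, axis=2)
    if cam.activation.shape != src.shape[:2]:
        raise ValueError("CAM and source dimensions must match")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    jet = matplotlib.colormaps["jet"]
    colored = jet(cam.activation.astype(float) / 255.0)[:, :, :3] * 255.0
    out = (1.0 - alpha) * src + alpha * colored
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def assemble_cams(cams: list[CamImage], origins: list[tuple[int, int]],
                  image_shape: tuple[int, int]) -> np.ndarray:
    """Arrange per-crop CAMs back at their grid positions in the source
    image; uncovered pixels stay at 0."""
    canvas = np.zeros(image_shape, dtype=np.uint8)
    for cam, (row, col) in zip(cams, origins):
        h, w = cam.activation.shape
        canvas[row:row + h, col:col + w] = cam.activation
    return canvas


def resize_cam(activation: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Resize a 0..255 CAM to a new spatial shape."""
    out = resize(activation.astype(float), shape, order=1, preserve_range=True,
                 anti_aliasing=False)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
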