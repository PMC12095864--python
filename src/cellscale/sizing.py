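"""Trunk-area measurement, K-means size staging, and data allocation.

The continuous growth readout is the trunk surface area (mm²) measured
from a binary whole-body silhouette. One-dimensional K-means with k=3
groups animals into small (S), medium (M), and large (L) classes; class
cut-offs are the midpoints between the largest member of one cluster
and the smallest member of the next. Animals are then allocated to
train/test at 8:2 and the training portion to train/validation at 9:1,
always at the level of the animal so that the two images of one fish
can never straddle a partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

SIZE_CLASSES = ("S", "M", "L")


@dataclass
class FishRecord:
    """One animal's measurements, class label, and split assignment."""

    fish_id: str
    trunk_area_mm2: float
    standard_length_mm: float | None = None
    size_class: str | None = None
    split: str | None = None
    image_ids: tuple[str, str] = ("", "")
    batch_id: str = ""

    def __post_init__(self) -> None:
        if self.trunk_area_mm2 <= 0:
            raise ValueError("trunk_area_mm2 must be positive")
        if self.size_class is not None and self.size_class not in SIZE_CLASSES:
            raise ValueError("size_class must be one of S, M, L")
        if len(self.image_ids) != 2:
            raise ValueError("each fish carries exactly two image ids")


def measure_area(mask: np.ndarray, um_per_px: float) -> float:
    """Trunk surface area in mm² from a binary silhouette.

    area = (# of foreground pixels) × (µm/px / 1000)²
    """
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no foreground: silhouette mask is empty")
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    return n * (um_per_px / 1000.0) ** 2


@dataclass
class SizeClassModel:
    """Fitted 1-D k=3 size staging with ascending centroids."""

    centroids_mm2: np.ndarray
    cutoffs_mm2: np.ndarray
    kmeans_seed: int = 2022

    def __post_init__(self) -> None:
        self.centroids_mm2 = np.asarray(self.centroids_mm2, dtype=float)
        self.cutoffs_mm2 = np.asarray(self.cutoffs_mm2, dtype=float)
        if self.centroids_mm2.shape != (3,) or self.cutoffs_mm2.shape != (2,):
            raise ValueError("expected 3 centroids and 2 cutoffs")
        c, k = self.centroids_mm2, self.cutoffs_mm2
        if not (c[0] < k[0] < c[1] < k[1] < c[2]):
            raise ValueError("cutoffs must lie strictly between adjacent centroids")

    def classify(self, area_mm2) -> np.ndarray | str:
        """S/M/L for one area or an array of areas; monotone in area."""
        scalar = np.isscalar(area_mm2)
        areas = np.atleast_1d(np.asarray(area_mm2, dtype=float))
        idx = np.searchsorted(self.cutoffs_mm2, areas, side="right")
        labels = np.array(SIZE_CLASSES, dtype=object)[idx]
        return str(labels[0]) if scalar else labels


def fit_size_classes(areas, seed: int = 2022) -> SizeClassModel:
    """k=3 K-means on trunk areas, relabeled S/M/L by ascending centroid."""
    areas = np.asarray(list(areas), dtype=float)
    if np.unique(areas).size < 3:
        raise ValueError("need at least 3 distinct areas for 3 clusters")
    km = KMeans(n_clusters=3, random_state=seed, n_init=10)
    raw = km.fit_predict(areas.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    rank = np.empty(3, dtype=int)
    rank[order] = np.arange(3)
    ranks = rank[raw]
    centroids = np.sort(km.cluster_centers_.ravel())
    # cutoff between cluster i and i+1: midpoint between the largest area
    # of the lower cluster and the smallest area of the upper one
    cutoffs = np.array(
        [
            (areas[ranks == i].max() + areas[ranks == i + 1].min()) / 2.0
            for i in range(2)
        ]
    )
    return SizeClassModel(centroids_mm2=centroids, cutoffs_mm2=cutoffs, kmeans_seed=seed)


def stage_fish(fish: list[FishRecord], seed: int = 2022) -> SizeClassModel:
    """Fit size classes on a cohort and write labels in place."""
    model = fit_size_classes([f.trunk_area_mm2 for f in fish], seed=seed)
    for f in fish:
        f.size_class = model.classify(f.trunk_area_mm2)
    return model


def split_sizes(n: int) -> tuple[int, int, int]:
    """(train, val, test) counts for the 8:2 then 9:1 allocation.

    Round-half-up on the test and validation counts; this is the
    convention under which 361 animals give 260/29/72.
    """
    n_test = int(np.floor(0.2 * n + 0.5))
    n_val = int(np.floor(0.1 * (n - n_test) + 0.5))
    n_train = n - n_test - n_val
    return n_train, n_val, n_test


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` proportional to `targets`."""
    if targets.sum() == 0:
        return np.zeros_like(targets, dtype=int)
    exact = targets / targets.sum() * total
    base = np.floor(exact).astype(int)
    short = total - base.sum()
    # ties broken by class order (stable argsort on negated remainder)
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def allocate_image_splits(image_ids, classes, seed: int = 2022) -> dict[str, str]:
    """Image-level 8:2/9:1 allocation, stratified by class.

    The default (and recommended) allocation is per fish — see
    :func:`allocate_splits` — so a fish's two images can never straddle
    partitions. Image-level allocation is the alternative convention
    for feature-based models evaluated on independent images; it
    ignores fish identity entirely. Returns image_id -> split.
    """
    image_ids, classes = list(image_ids), list(classes)
    if len(image_ids) != len(classes):
        raise ValueError("image_ids and classes must have equal length")
    n = len(image_ids)
    _, n_val, n_test = split_sizes(n)
    by_class = {c: [i for i, cl in zip(image_ids, classes) if cl == c] for c in SIZE_CLASSES}
    class_counts = np.array([len(by_class[c]) for c in SIZE_CLASSES], dtype=float)
    test_per_class = _largest_remainder(class_counts, n_test)
    val_per_class = _largest_remainder(class_counts - test_per_class, n_val)
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for ci, c in enumerate(SIZE_CLASSES):
        members = sorted(by_class[c])
        rng.shuffle(members)
        k_test, k_val = int(test_per_class[ci]), int(val_per_class[ci])
        for i in members[:k_test]:
            out[i] = "test"
        for i in members[k_test : k_test + k_val]:
            out[i] = "val"
        for i in members[k_test + k_val :]:
            out[i] = "train"
    return out


def allocate_splits(fish: list[FishRecord], seed: int = 2022) -> list[FishRecord]:
    """Assign train/val/test at the fish level, stratified by class.

    Per-class test and validation counts are apportioned by largest
    remainder so that overall totals are exact and class proportions are
    preserved as closely as integers allow. Deterministic for a seed.
    """
    if any(f.size_class is None for f in fish):
        raise ValueError("every fish must be classed before allocation")
    n = len(fish)
    n_train, n_val, n_test = split_sizes(n)
    by_class = {c: [f for f in fish if f.size_class == c] for c in SIZE_CLASSES}
    for c, members in by_class.items():
        if 0 < len(members) < 3:
            warnings.warn(
                f"class {c} has only {len(members)} fish; allocation for it "
                "cannot preserve proportions",
                stacklevel=2,
            )
    class_counts = np.array([len(by_class[c]) for c in SIZE_CLASSES], dtype=float)
    test_per_class = _largest_remainder(class_counts, n_test)
    remaining = class_counts - test_per_class
    val_per_class = _largest_remainder(remaining, n_val)
    rng = np.random.default_rng(seed)
    for ci, c in enumerate(SIZE_CLASSES):
        members = sorted(by_class[c], key=lambda f: f.fish_id)
        rng.shuffle(members)
        k_test, k_val = int(test_per_class[ci]), int(val_per_class[ci])
        for f in members[:k_test]:
            f.split = "test"
        for f in members[k_test : k_test + k_val]:
            f.split = "val"
        for f in members[k_test + k_val :]:
            f.split = "train"
    return fish
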