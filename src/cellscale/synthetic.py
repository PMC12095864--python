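"""Seeded synthetic multicolor skin-cell mosaics with clone ground truth.

Emulates brainbow-style multicolor labeling of the superficial epithelial
cell (SEC) layer of larval zebrafish: convex cells tiling a dark field,
heritable random colors, and clones — adjacent same-color cells produced
by divisions of a founder. Cell number and the extent of clonal division
both increase with the latent whole-animal size class (S < M < L), which
is the signal every downstream stage tries to recover. Each synthetic
animal also gets a whole-body silhouette whose area carries the class.

Geometry: founders are placed by Poisson-disc sampling and rasterized as
a Euclidean Voronoi tessellation, giving convex, SEC-like cells. A
founder divides a geometric number of times; each division splits the
clone's largest cell by a random chord, so daughters stay adjacent and
every clone remains a connected color patch. A random fraction of cells
is then shed (reverted to background), and per-pixel color jitter adds
texture. Background pixels stay at brightness <= 30 so the standard
brightness-30 rule separates foreground exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .sizing import FishRecord

#: Default brainbow-like palette: 12 saturated colors, pairwise RGB
#: distance > 30 so a color-distance-10 merge can never bridge founders.
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (230, 60, 60),
    (60, 200, 60),
    (70, 90, 230),
    (230, 180, 50),
    (200, 60, 200),
    (60, 200, 200),
    (240, 130, 40),
    (150, 80, 220),
    (120, 220, 90),
    (220, 100, 140),
    (90, 160, 240),
    (180, 200, 60),
)

#: Physical field of view of one local skin image (µm); two such images
#: are captured per animal.
FIELD_UM = 465.0

DEFAULT_IMAGE_SIZE = (192, 192)
DEFAULT_UM_PER_PX = FIELD_UM / DEFAULT_IMAGE_SIZE[0]

#: Founder counts and expected extra divisions per founder, per size
#: class. Founder counts follow the ~45/80/150-per-field calibration so
#: that total cell counts bracket the observed per-crop densities;
#: division rates make clone size grow with animal size.
CLASS_PRESETS: dict[str, dict[str, float]] = {
    "S": {"n_seed_cells": 40, "clone_division_rate": 0.10},
    "M": {"n_seed_cells": 85, "clone_division_rate": 0.50},
    "L": {"n_seed_cells": 170, "clone_division_rate": 1.20},
}

#: Class-conditional trunk-surface-area distributions (mm², mean and sd)
#: for synthetic silhouettes; well separated so size staging is exact.
SILHOUETTE_AREA_MM2: dict[str, tuple[float, float]] = {
    "S": (6.0, 0.7),
    "M": (10.0, 0.8),
    "L": (14.0, 0.9),
}

#: Default cohort class mix, matching an S-heavy cohort of 218:74:69.
DEFAULT_CLASS_MIX: tuple[float, float, float] = (218 / 361, 74 / 361, 69 / 361)


def validate_palette(palette, min_distance: float = 30.0) -> None:
    """Check a palette is usable: >= 8 colors, pairwise distance > 30."""
    arr = np.asarray(palette, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 8:
        raise ValueError("palette must contain at least 8 RGB triplets")
    diff = arr[:, None, :] - arr[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    if not (dist > min_distance).all():
        raise ValueError(f"palette colors must be pairwise separated by > {min_distance} in RGB")


@dataclass(frozen=True)
class MosaicParams:
    """Generation parameters for one synthetic mosaic."""

    image_size_px: tuple[int, int] = DEFAULT_IMAGE_SIZE
    um_per_px: float = DEFAULT_UM_PER_PX
    size_class: str = "S"
    n_seed_cells: int = 45
    clone_division_rate: float = 0.15
    coverage_fraction: float = 0.95
    palette: tuple = DEFAULT_PALETTE
    color_jitter_sd: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 64 or w < 64:
            raise ValueError("image_size_px must be at least 64 on each side")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.size_class not in ("S", "M", "L"):
            raise ValueError("size_class must be one of S, M, L")
        if self.n_seed_cells < 1:
            raise ValueError("n_seed_cells must be positive")
        # expected extra divisions per founder; rates above 1 are valid
        # for strongly dividing (large-animal) presets
        if self.clone_division_rate < 0:
            raise ValueError("clone_division_rate must be nonnegative")
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must lie in (0, 1]")
        if self.color_jitter_sd < 0:
            raise ValueError("color_jitter_sd must be nonnegative")
        validate_palette(self.palette)

    @classmethod
    def for_class(cls, size_class: str, rng_seed: int = 0, **overrides) -> "MosaicParams":
        """Build params from the default presets of a size class."""
        preset = CLASS_PRESETS[size_class]
        kwargs = {
            "size_class": size_class,
            "n_seed_cells": int(preset["n_seed_cells"]),
            "clone_division_rate": float(preset["clone_division_rate"]),
            "rng_seed": rng_seed,
        }
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class MosaicSample:
    """One synthetic local skin image with full ground truth."""

    image: np.ndarray
    label_map: np.ndarray
    clone_map: np.ndarray
    true_cell_count: int
    true_clone_count: int
    fish_id: str
    params: MosaicParams


@dataclass
class SilhouetteSample:
    """Binary whole-body silhouette with its physical measurements."""

    mask: np.ndarray
    trunk_area_mm2: float
    standard_length_mm: float
    fish_id: str
    um_per_px: float = 10.0


def _poisson_disc(rng: np.random.Generator, shape, n: int) -> np.ndarray:
    """Dart-throwing Poisson-disc sampling of n points; shrinks the
    exclusion radius if the target count cannot be reached."""
    h, w = shape
    radius = 0.75 * np.sqrt(h * w / n)
    points: list[np.ndarray] = []
    attempts = 0
    max_attempts = 400 * n
    while len(points) < n:
        candidate = rng.uniform((0, 0), (h, w))
        if points:
            d2 = ((np.array(points) - candidate) ** 2).sum(axis=1)
            ok = d2.min() >= radius**2
        else:
            ok = True
        if ok:
            points.append(candidate)
        attempts += 1
        if attempts >= max_attempts:
            radius *= 0.8
            attempts = 0
    return np.array(points)


def _split_cell(
    rng: np.random.Generator, label_map: np.ndarray, cell_label: int, new_label: int
) -> bool:
    """Split one cell by a random chord into two connected halves.

    Returns False if no split keeping both halves 4-connected was found
    within a few attempts (the division is then skipped).
    """
    rows, cols = np.nonzero(label_map == cell_label)
    if rows.size < 2:
        return False
    cy, cx = rows.mean(), cols.mean()
    for _ in range(10):
        theta = rng.uniform(0, np.pi)
        s = (rows - cy) * np.cos(theta) + (cols - cx) * np.sin(theta)
        cut = np.quantile(s, rng.uniform(0.35, 0.65))
        side = s > cut
        if not side.any() or side.all():
            continue
        # both halves of a convex cell should stay 4-connected; verify on
        # the pixel grid and retry with a new chord if rasterization broke one
        ok = True
        for half in (side, ~side):
            sub = np.zeros(label_map.shape, dtype=bool)
            sub[rows[half], cols[half]] = True
            _, n_comp = ndimage.label(sub)
            if n_comp != 1:
                ok = False
                break
        if ok:
            label_map[rows[side], cols[side]] = new_label
            return True
    return False


def generate_mosaic(params: MosaicParams) -> MosaicSample:
    """Generate one synthetic mosaic; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_size_px
    founders = _poisson_disc(rng, (h, w), params.n_seed_cells)

    # Euclidean Voronoi rasterization: each pixel takes its nearest founder.
    tree = cKDTree(founders)
    yy, xx = np.mgrid[0:h, 0:w]
    _, nearest = tree.query(np.column_stack([yy.ravel(), xx.ravel()]))
    label_map = (nearest + 1).astype(np.int32).reshape(h, w)
    # a founder can lose every pixel to neighbors at high density; re-index
    present = np.unique(label_map)
    clone_of = {int(lab): int(lab) for lab in present}
    next_label = int(label_map.max()) + 1

    # color clones so that no two adjacent founders share a palette color
    adjacency = _label_adjacency(label_map)
    clone_color_idx = _color_clones(rng, present, adjacency, len(params.palette))

    # clonal divisions: geometric count per founder, chord splits
    division_p = 1.0 / (1.0 + params.clone_division_rate)
    clone_cells: dict[int, list[int]] = {int(lab): [int(lab)] for lab in present}
    for founder in present:
        n_div = int(rng.geometric(division_p) - 1)
        for _ in range(n_div):
            cells = clone_cells[int(founder)]
            sizes = [(label_map == c).sum() for c in cells]
            target = cells[int(np.argmax(sizes))]
            if _split_cell(rng, label_map, target, next_label):
                clone_of[next_label] = int(founder)
                cells.append(next_label)
                clone_color_idx[next_label] = clone_color_idx[int(founder)]
                next_label += 1

    # shedding: delete a random fraction of cells back to background
    all_cells = np.array(sorted(clone_of))
    n_remove = int(round((1.0 - params.coverage_fraction) * all_cells.size))
    if n_remove > 0:
        removed = rng.choice(all_cells, size=n_remove, replace=False)
        label_map[np.isin(label_map, removed)] = 0
        for lab in removed:
            clone_of.pop(int(lab))

    # shedding may disconnect a clone's surviving cells; the planted
    # ground truth is the visible color patches, so split each clone
    # into its 4-connected cell components (colors still follow the
    # founder, only the patch identity changes)
    adjacency_after = _label_adjacency(label_map)
    parent = {lab: lab for lab in clone_of}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in adjacency_after:
        a, b = int(a), int(b)
        if clone_of.get(a) == clone_of.get(b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    patch_of = {lab: find(lab) for lab in clone_of}

    clone_map = np.zeros_like(label_map)
    for lab, patch in patch_of.items():
        clone_map[label_map == lab] = patch

    # render: dark gray background, flat clone colors, per-pixel jitter
    palette = np.asarray(params.palette, dtype=float)
    image = np.repeat(rng.integers(0, 21, (h, w, 1)).astype(float), 3, axis=2)
    foreground = label_map > 0
    for lab, clone in clone_of.items():
        image[label_map == lab] = palette[clone_color_idx[clone] % len(palette)]
    if params.color_jitter_sd > 0:
        image = image + rng.normal(0.0, params.color_jitter_sd, image.shape)
    image = np.clip(image, 0, 255)
    # background must stay at brightness <= 30 after jitter
    image[~foreground] = np.minimum(image[~foreground], 30.0)
    # foreground must stay above the brightness-30 rule
    v = image.max(axis=2)
    dim = foreground & (v <= 30)
    if dim.any():
        image[dim] += (31.0 - v[dim])[:, None]
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    true_cells = np.unique(label_map[label_map > 0])
    true_clones = np.unique(clone_map[clone_map > 0])
    return MosaicSample(
        image=image,
        label_map=label_map,
        clone_map=clone_map,
        true_cell_count=int(true_cells.size),
        true_clone_count=int(true_clones.size),
        fish_id="",
        params=params,
    )


def _label_adjacency(label_map: np.ndarray) -> set[tuple[int, int]]:
    """4-connected adjacency pairs between distinct nonzero labels."""
    pairs: set[tuple[int, int]] = set()
    for a, b in (
        (label_map[:-1, :], label_map[1:, :]),
        (label_map[:, :-1], label_map[:, 1:]),
    ):
        mask = (a != b) & (a > 0) & (b > 0)
        lo = np.minimum(a[mask], b[mask])
        hi = np.maximum(a[mask], b[mask])
        pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def _color_clones(rng, labels, adjacency, n_colors: int) -> dict[int, int]:
    """Greedy graph coloring with random palette choice so adjacent
    founders never share a color (keeps planted clones unambiguous)."""
    neighbors: dict[int, set[int]] = {int(l): set() for l in labels}
    for a, b in adjacency:
        neighbors[int(a)].add(int(b))
        neighbors[int(b)].add(int(a))
    colors: dict[int, int] = {}
    order = list(labels)
    rng.shuffle(order)
    for lab in order:
        lab = int(lab)
        used = {colors[n] for n in neighbors[lab] if n in colors}
        free = [c for c in range(n_colors) if c not in used]
        colors[lab] = int(rng.choice(free)) if free else int(rng.integers(n_colors))
    return colors


def generate_silhouette(
    size_class: str, fish_id: str, rng: np.random.Generator, um_per_px: float = 10.0
) -> SilhouetteSample:
    """Draw an elongated elliptical body silhouette whose area follows
    the class-conditional distribution (S < M < L)."""
    mean, sd = SILHOUETTE_AREA_MM2[size_class]
    target_mm2 = max(0.5, rng.normal(mean, sd))
    area_px = target_mm2 * 1e6 / um_per_px**2
    aspect = rng.uniform(3.5, 4.5)  # body length / depth
    b = np.sqrt(area_px / (np.pi * aspect))
    a = aspect * b
    h = int(2 * b) + 8
    w = int(2 * a) + 8
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    area_mm2 = float(mask.sum()) * (um_per_px / 1000.0) ** 2
    length_mm = 2 * a * um_per_px / 1000.0
    return SilhouetteSample(
        mask=mask,
        trunk_area_mm2=area_mm2,
        standard_length_mm=float(length_mm),
        fish_id=fish_id,
        um_per_px=um_per_px,
    )


@dataclass
class CohortFish:
    """One synthetic animal: its record, two mosaics, one silhouette."""

    record: FishRecord
    mosaics: tuple[MosaicSample, MosaicSample]
    silhouette: SilhouetteSample


def generate_cohort(
    n_fish: int,
    class_mix: tuple[float, float, float] = DEFAULT_CLASS_MIX,
    rng_seed: int = 0,
    mosaic_overrides: dict | None = None,
) -> list[CohortFish]:
    """Generate a seeded cohort: two mosaics per fish (anterior and
    posterior fields drawn from the same per-fish parameters) plus one
    silhouette whose area encodes the class."""
    if n_fish < 3:
        raise ValueError("n_fish must be at least 3")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("class_mix must be 3 nonnegative probabilities summing to 1")
    rng = np.random.default_rng(rng_seed)
    classes = rng.choice(np.array(["S", "M", "L"]), size=n_fish, p=mix)
    overrides = mosaic_overrides or {}
    cohort: list[CohortFish] = []
    for i, size_class in enumerate(classes):
        size_class = str(size_class)
        fish_id = f"fish_{i:04d}"
        preset = CLASS_PRESETS[size_class]
        # mild per-animal variation around the class preset
        n_seed = max(8, int(round(preset["n_seed_cells"] * rng.lognormal(0.0, 0.05))))
        rate = float(np.clip(preset["clone_division_rate"] * rng.lognormal(0.0, 0.10), 0.0, 3.0))
        params = MosaicParams.for_class(
            size_class,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
            n_seed_cells=n_seed,
            clone_division_rate=rate,
            **overrides,
        )
        mosaics = []
        for side in ("A", "P"):
            sample = generate_mosaic(replace(params, rng_seed=int(rng.integers(0, 2**31 - 1))))
            sample.fish_id = fish_id
            mosaics.append(sample)
        silhouette = generate_silhouette(size_class, fish_id, rng)
        record = FishRecord(
            fish_id=fish_id,
            trunk_area_mm2=silhouette.trunk_area_mm2,
            standard_length_mm=silhouette.standard_length_mm,
            size_class=size_class,
            image_ids=(f"{fish_id}_A", f"{fish_id}_P"),
        )
        cohort.append(CohortFish(record, (mosaics[0], mosaics[1]), silhouette))
    return cohort


def write_cohort(cohort: list[CohortFish], out_dir: str | Path) -> Path:
    """Write a cohort to disk: images and label/clone maps as PNG,
    silhouettes as PNG, and a manifest CSV. Returns the manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)
    (out / "clones").mkdir(exist_ok=True)
    (out / "silhouettes").mkdir(exist_ok=True)
    rows = []
    for fish in cohort:
        rec = fish.record
        for image_id, mosaic in zip(rec.image_ids, fish.mosaics):
            iio.imwrite(out / "images" / f"{image_id}.png", mosaic.image)
            iio.imwrite(
                out / "labels" / f"{image_id}.png", mosaic.label_map.astype(np.uint16)
            )
            iio.imwrite(
                out / "clones" / f"{image_id}.png", mosaic.clone_map.astype(np.uint16)
            )
        iio.imwrite(
            out / "silhouettes" / f"{rec.fish_id}.png",
            (fish.silhouette.mask.astype(np.uint8) * 255),
        )
        rows.append(
            {
                "fish_id": rec.fish_id,
                "size_class": rec.size_class,
                "trunk_area_mm2": rec.trunk_area_mm2,
                "standard_length_mm": rec.standard_length_mm,
                "um_per_px": fish.mosaics[0].params.um_per_px,
                "image_a": f"images/{rec.image_ids[0]}.png",
                "image_p": f"images/{rec.image_ids[1]}.png",
                "true_cell_count_a": fish.mosaics[0].true_cell_count,
                "true_cell_count_p": fish.mosaics[1].true_cell_count,
            }
        )
    manifest = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    params = {
        "n_fish": len(cohort),
        "presets": CLASS_PRESETS,
        "silhouette_area_mm2": SILHOUETTE_AREA_MM2,
    }
    (out / "params.json").write_text(json.dumps(params, indent=2))
    return manifest
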