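"""Clone structure and scalar features from an image + cell label map.

Cells come in as an integer segmentation label map (0 = background).
Adjacent cells (sharing at least one 4-connected boundary pixel pair)
whose mean RGB colors lie within a Euclidean distance of 10 are merged
transitively into "clones" / color patches — the connected same-color
groups produced by asynthetic fission. Five scalar features summarize
each image:

    cell coverage            # of nonzero label pixels
    cell count               # of distinct cells
    cell average size        coverage / cell count            (px)
    color patch count        # of clones after merging
    color patch average size coverage / color patch count     (px)

PCA features are the alternative unsupervised representation: images
resized to 224x224x3, flattened to 150,528-long vectors, mean-centered
and projected onto the top principal axes.

Feature-subtracted ablation images isolate what each attribute
contributes: "random color #1" keeps clone structure but removes cell
texture (one flat random color per clone); "random color #2" removes
clone structure too (one flat color per cell); "cell-less" keeps only
coverage (background 0, every cell a flat 127 gray).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.transform import resize
from sklearn.decomposition import PCA

ABLATION_MODES = ("random_color_1", "random_color_2", "cell_less")


@dataclass
class CloneGraph:
    """Cell adjacency + color-merge result for one image."""

    labels: np.ndarray  # distinct nonzero cell labels, sorted
    mean_colors: np.ndarray  # (n_cells, 3) mean RGB per cell
    edges: set[tuple[int, int]]  # adjacent label pairs (lo, hi)
    merged: dict[int, int]  # cell label -> clone id
    color_threshold: float

    @property
    def cell_count(self) -> int:
        return int(self.labels.size)

    @property
    def clone_count(self) -> int:
        return len(set(self.merged.values()))

    def clone_members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for cell, clone in self.merged.items():
            out.setdefault(clone, []).append(cell)
        return out


@dataclass
class FeatureVector:
    """The five segmentation-derived scalar features of one image."""

    cell_coverage: int
    cell_count: int
    cell_average_size: float
    color_patch_count: int
    color_patch_average_size: float

    NAMES = (
        "cell_coverage",
        "cell_count",
        "cell_average_size",
        "color_patch_count",
        "color_patch_average_size",
    )

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.cell_coverage,
                self.cell_count,
                self.cell_average_size,
                self.color_patch_count,
                self.color_patch_average_size,
            ],
            dtype=float,
        )


def label_adjacency(label_map: np.ndarray) -> set[tuple[int, int]]:
    """Pairs of distinct nonzero labels sharing a 4-connected boundary."""
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


def mean_cell_colors(image: np.ndarray, label_map: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean RGB per cell label (float)."""
    img = np.asarray(image, dtype=float)
    flat_labels = label_map.ravel()
    out = np.zeros((labels.size, 3), dtype=float)
    # bincount per channel over the compacted label index
    index = np.searchsorted(labels, flat_labels)
    valid = flat_labels > 0
    counts = np.bincount(index[valid], minlength=labels.size)
    for c in range(3):
        sums = np.bincount(index[valid], weights=img[..., c].ravel()[valid], minlength=labels.size)
        out[:, c] = sums / np.maximum(counts, 1)
    return out


def merge_clones(
    image: np.ndarray, label_map: np.ndarray, color_threshold: float = 10.0
) -> CloneGraph:
    """Merge adjacent cells of near-identical color into clones.

    Two cells merge when they are 4-connected neighbors and the
    Euclidean distance between their mean RGB colors is <= the
    threshold; merging is transitive. A clone id is the smallest cell
    label of its component. An empty label map yields an empty graph.
    """
    label_map = np.asarray(label_map)
    if label_map.shape != np.asarray(image).shape[:2]:
        raise ValueError("label_map must align with image")
    labels = np.unique(label_map[label_map > 0])
    if labels.size == 0:
        return CloneGraph(labels, np.zeros((0, 3)), set(), {}, color_threshold)
    colors = mean_cell_colors(image, label_map, labels)
    edges = label_adjacency(label_map)
    rows, cols = [], []
    for a, b in edges:
        ia, ib = np.searchsorted(labels, [a, b])
        if np.linalg.norm(colors[ia] - colors[ib]) <= color_threshold:
            rows.append(ia)
            cols.append(ib)
    n = labels.size
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, comp = connected_components(graph, directed=False)
    # name each clone by its smallest member label for determinism
    clone_name: dict[int, int] = {}
    merged: dict[int, int] = {}
    for idx in np.argsort(labels):
        c = comp[idx]
        clone_name.setdefault(c, int(labels[idx]))
        merged[int(labels[idx])] = clone_name[c]
    return CloneGraph(labels, colors, edges, merged, color_threshold)


def extract_features(
    image: np.ndarray, label_map: np.ndarray, clone_graph: CloneGraph | None = None
) -> FeatureVector:
    """Compute the five scalar features; all-background maps give zeros."""
    if clone_graph is None:
        clone_graph = merge_clones(image, label_map)
    coverage = int((np.asarray(label_map) > 0).sum())
    n_cells = clone_graph.cell_count
    n_patches = clone_graph.clone_count
    if n_cells == 0:
        warnings.warn("label map contains no cells; features set to zero", stacklevel=2)
        return FeatureVector(0, 0, 0.0, 0, 0.0)
    return FeatureVector(
        cell_coverage=coverage,
        cell_count=n_cells,
        cell_average_size=coverage / n_cells,
        color_patch_count=n_patches,
        color_patch_average_size=coverage / n_patches,
    )


def pca_features(images, n_components: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores of images resized to 224x224x3 and flattened.

    Returns (scores of shape (n_images, n_components), explained
    variance ratios).
    """
    images = list(images)
    if n_components > len(images):
        raise ValueError("n_components cannot exceed the number of images")
    flat = np.empty((len(images), 224 * 224 * 3), dtype=np.float32)
    for i, img in enumerate(images):
        resized = resize(
            np.asarray(img, dtype=float), (224, 224, 3), order=1, anti_aliasing=False
        )
        flat[i] = resized.ravel()
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    scores = pca.fit_transform(flat)
    return scores, pca.explained_variance_ratio_


def _identifier_color(rng: np.random.Generator) -> np.ndarray:
    """A random six-hex-digit identifier interpreted as an RRGGBB color."""
    ident = int(rng.integers(0, 0x1000000))
    return np.array([(ident >> 16) & 0xFF, (ident >> 8) & 0xFF, ident & 0xFF], dtype=np.uint8)


def make_ablation_images(
    image: np.ndarray,
    label_map: np.ndarray,
    clone_graph: CloneGraph | None = None,
    mode: str = "cell_less",
    rng_seed: int = 0,
) -> np.ndarray:
    """Generate one feature-subtracted image.

    random_color_1: every clone painted one flat identifier color —
    clone structure kept, texture removed. random_color_2: every cell
    painted flat; the representative cell of each former clone keeps the
    clone's identifier color, every other cell gets a fresh identifier —
    both clone structure and texture removed. cell_less: background 0,
    all cells flat gray 127 — only coverage remains. All modes preserve
    the set of nonbackground pixels exactly.
    """
    if mode not in ABLATION_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {ABLATION_MODES}")
    label_map = np.asarray(label_map)
    out = np.zeros(label_map.shape + (3,), dtype=np.uint8)
    if mode == "cell_less":
        out[label_map > 0] = 127
        return out
    if clone_graph is None:
        clone_graph = merge_clones(image, label_map)
    rng = np.random.default_rng(rng_seed)
    clone_colors = {clone: _identifier_color(rng) for clone in sorted(set(clone_graph.merged.values()))}
    if mode == "random_color_1":
        for cell, clone in sorted(clone_graph.merged.items()):
            out[label_map == cell] = clone_colors[clone]
        return out
    # random_color_2: the clone id doubles as its representative cell label
    for cell, clone in sorted(clone_graph.merged.items()):
        if cell == clone:
            out[label_map == cell] = clone_colors[clone]
        else:
            out[label_map == cell] = _identifier_color(rng)
    return out
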