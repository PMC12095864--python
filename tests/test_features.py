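"""Clone merging, feature formulas, PCA, and ablation image contracts."""

import itertools

import numpy as np
import pytest
from skimage.transform import resize

import cellscale as cs
from cellscale import features


def two_cell_image(color_a, color_b, adjacent=True):
    """Two 4x4 cells on a 12x12 dark field, optionally touching."""
    image = np.zeros((12, 12, 3), dtype=np.uint8)
    labels = np.zeros((12, 12), dtype=np.int32)
    labels[2:6, 2:6] = 1
    col_b = slice(6, 10) if adjacent else slice(7, 11)
    labels[2:6, col_b] = 2
    image[labels == 1] = color_a
    image[labels == 2] = color_b
    return image, labels


def brute_force_clones(image, label_map, threshold=10.0):
    """All-pairs transitive-closure oracle: start with singleton groups
    and repeatedly merge any two groups linked by an adjacent cell pair
    within the color threshold, until a fixed point."""
    labels = [int(l) for l in np.unique(label_map[label_map > 0])]
    colors = {
        l: np.asarray(image, float)[label_map == l].mean(axis=0) for l in labels
    }
    adjacent = features.label_adjacency(label_map)

    def linked(x, y):
        return (min(x, y), max(x, y)) in adjacent and (
            np.linalg.norm(colors[x] - colors[y]) <= threshold
        )

    groups = [{l} for l in labels]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(groups)), 2):
            if any(linked(x, y) for x in groups[a] for y in groups[b]):
                groups[a] |= groups[b]
                del groups[b]
                changed = True
                break
    clone_ids = {min(g) for g in groups}
    membership = {l: min(g) for g in groups for l in g}
    return clone_ids, membership


class TestMergeClones:
    def test_adjacent_within_threshold_merge(self):
        image, labels = two_cell_image((100, 0, 0), (105, 0, 0), adjacent=True)
        assert cs.merge_clones(image, labels).clone_count == 1

    def test_non_adjacent_same_color_stay_separate(self):
        image, labels = two_cell_image((100, 0, 0), (105, 0, 0), adjacent=False)
        assert cs.merge_clones(image, labels).clone_count == 2

    def test_above_threshold_stay_separate(self):
        image, labels = two_cell_image((100, 0, 0), (111, 0, 0), adjacent=True)
        assert cs.merge_clones(image, labels).clone_count == 2

    def test_empty_label_map_gives_empty_graph(self):
        image = np.zeros((8, 8, 3), dtype=np.uint8)
        graph = cs.merge_clones(image, np.zeros((8, 8), dtype=np.int32))
        assert graph.cell_count == 0 and graph.clone_count == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_transitive_closure(self, seed):
        """Union-find merging equals the all-pairs closure oracle on
        small mosaics (<= 30 cells)."""
        params = cs.MosaicParams.for_class(
            "S", rng_seed=seed, n_seed_cells=12, image_size_px=(64, 64),
            color_jitter_sd=4.0,
        )
        m = cs.generate_mosaic(params)
        assert m.true_cell_count <= 30
        graph = cs.merge_clones(m.image, m.label_map)
        oracle_clones, oracle_map = brute_force_clones(m.image, m.label_map)
        assert graph.clone_count == len(oracle_clones)
        assert graph.merged == oracle_map

    def test_recovers_planted_clones_without_jitter(self):
        """On jitter-free mosaics the merge recovers exactly the planted
        clone count (palette spacing > 30 forbids false merges)."""
        for seed in range(50):
            size_class = ("S", "M", "L")[seed % 3]
            m = cs.generate_mosaic(
                cs.MosaicParams.for_class(size_class, rng_seed=seed, color_jitter_sd=0.0)
            )
            graph = cs.merge_clones(m.image, m.label_map)
            assert graph.cell_count == m.true_cell_count
            assert graph.clone_count == m.true_clone_count


def four_cell_image(merge_all=False):
    """Four 5x5 cells in a row; same color if merge_all."""
    image = np.zeros((9, 24, 3), dtype=np.uint8)
    labels = np.zeros((9, 24), dtype=np.int32)
    colors = [(200, 0, 0)] * 4 if merge_all else [
        (200, 0, 0), (0, 200, 0), (0, 0, 200), (200, 200, 0)
    ]
    for k in range(4):
        labels[2:7, 2 + 5 * k : 7 + 5 * k] = k + 1
        image[labels == k + 1] = colors[k]
    return image, labels


class TestExtractFeatures:
    def test_formula_no_merges(self):
        image, labels = four_cell_image(merge_all=False)
        vec = cs.extract_features(image, labels)
        assert vec.as_array().tolist() == [100, 4, 25, 4, 25]

    def test_formula_all_merged(self):
        image, labels = four_cell_image(merge_all=True)
        vec = cs.extract_features(image, labels)
        assert vec.as_array().tolist() == [100, 4, 25, 1, 100]

    def test_formulas_hold_on_generated_samples(self):
        for seed in (0, 5):
            m = cs.generate_mosaic(cs.MosaicParams.for_class("M", rng_seed=seed))
            graph = cs.merge_clones(m.image, m.label_map)
            vec = cs.extract_features(m.image, m.label_map, graph)
            assert vec.cell_count == m.true_cell_count
            assert vec.cell_coverage == int((m.label_map > 0).sum())
            assert vec.cell_average_size == pytest.approx(vec.cell_coverage / vec.cell_count)
            assert vec.color_patch_average_size == pytest.approx(
                vec.cell_coverage / vec.color_patch_count
            )
            assert vec.color_patch_count <= vec.cell_count

    def test_empty_map_warns_and_zeros(self):
        image = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.warns(UserWarning):
            vec = cs.extract_features(image, np.zeros((8, 8), dtype=np.int32))
        assert vec.as_array().tolist() == [0, 0, 0, 0, 0]


class TestPcaFeatures:
    def test_identical_images_have_zero_variance(self):
        img = np.random.default_rng(0).integers(0, 255, (16, 16, 3)).astype(np.uint8)
        scores, _ = cs.pca_features([img] * 6, n_components=3)
        # float32 pipeline: scores vanish up to rounding of the 0..255
        # data, so the explained variance on every axis is numerically 0
        assert np.allclose(scores, 0, atol=0.05)
        assert np.allclose(scores.var(axis=0), 0, atol=1e-3)

    def test_too_few_images_raises(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            cs.pca_features([img] * 3, n_components=5)

    def test_matches_gram_matrix_oracle(self):
        """Scores agree with a brute-force eigendecomposition of the
        centered Gram matrix (20 small images)."""
        rng = np.random.default_rng(1)
        images = [rng.integers(0, 255, (16, 16, 3)).astype(np.uint8) for _ in range(20)]
        scores, evr = cs.pca_features(images, n_components=5)
        # oracle: replicate the resize+flatten, then Gram eigen-decompose
        flat = np.stack(
            [
                resize(img.astype(float), (224, 224, 3), order=1, anti_aliasing=False).ravel()
                for img in images
            ]
        )
        centered = flat - flat.mean(axis=0)
        gram = centered @ centered.T
        w, v = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1][:5]
        oracle_scores = v[:, order] * np.sqrt(np.maximum(w[order], 0))
        for k in range(5):
            dot = np.abs(np.dot(scores[:, k], oracle_scores[:, k]))
            norms = np.linalg.norm(scores[:, k]) * np.linalg.norm(oracle_scores[:, k])
            # float32 implementation vs float64 oracle: ~1e-4 relative
            assert dot == pytest.approx(norms, rel=2e-3)  # same axis up to sign
            assert np.abs(scores[:, k]).max() == pytest.approx(
                np.abs(oracle_scores[:, k]).max(), rel=2e-3
            )
        total_var = ((centered**2).sum() / (len(images) - 1))
        assert evr[:5].sum() == pytest.approx(
            w[order].sum() / (len(images) - 1) / total_var, rel=2e-3
        )


class TestAblations:
    @pytest.fixture(scope="class")
    def sample(self):
        m = cs.generate_mosaic(cs.MosaicParams.for_class("S", rng_seed=4))
        graph = cs.merge_clones(m.image, m.label_map)
        return m, graph

    def test_cell_less_is_binary_gray(self, sample):
        m, graph = sample
        out = cs.make_ablation_images(m.image, m.label_map, graph, mode="cell_less")
        assert set(np.unique(out)) == {0, 127}

    def test_random_color_1_has_one_color_per_clone(self, sample):
        m, graph = sample
        out = cs.make_ablation_images(
            m.image, m.label_map, graph, mode="random_color_1", rng_seed=7
        )
        fg = out[m.label_map > 0]
        distinct = np.unique(fg.reshape(-1, 3), axis=0)
        assert len(distinct) == graph.clone_count

    def test_random_color_2_flat_within_cells(self, sample):
        m, graph = sample
        out = cs.make_ablation_images(
            m.image, m.label_map, graph, mode="random_color_2", rng_seed=7
        )
        for lab in np.unique(m.label_map[m.label_map > 0])[:20]:
            cell = out[m.label_map == lab]
            assert (cell == cell[0]).all()

    def test_random_color_2_equals_1_without_merges(self):
        m = cs.generate_mosaic(
            cs.MosaicParams.for_class("S", rng_seed=8, clone_division_rate=0.0,
                                      color_jitter_sd=0.0)
        )
        graph = cs.merge_clones(m.image, m.label_map)
        assert graph.clone_count == graph.cell_count  # clone-free mosaic
        a = cs.make_ablation_images(m.image, m.label_map, graph, "random_color_1", rng_seed=3)
        b = cs.make_ablation_images(m.image, m.label_map, graph, "random_color_2", rng_seed=3)
        assert (a == b).all()

    @pytest.mark.parametrize("mode", features.ABLATION_MODES)
    def test_footprint_preserved(self, sample, mode):
        m, graph = sample
        out = cs.make_ablation_images(m.image, m.label_map, graph, mode=mode, rng_seed=1)
        assert ((out.sum(axis=2) > 0) == (m.label_map > 0)).all()

    def test_unknown_mode_rejected(self, sample):
        m, graph = sample
        with pytest.raises(ValueError, match="unknown mode"):
            cs.make_ablation_images(m.image, m.label_map, graph, mode="sepia")
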