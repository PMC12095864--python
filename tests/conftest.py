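"""Shared fixtures: small seeded mosaics and one desk-scale cohort.

The 300-fish cohort, its feature table and the trained crop-and-vote
classifier are session-scoped because several tests probe different
aspects of the same artifacts (baseline comparisons, parameter
recovery, CAM direction); training happens once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cellscale as cs
from cellscale import classifier, features
from cellscale.cropping import CropSpec

#: Desk-scale training configuration for the tiny backbone (see
#: docs/methods.md): from-scratch learning rate and a bounded epoch
#: budget; everything else follows the standard protocol.
DESK_TRAIN_KWARGS = dict(
    learning_rate=1e-3,
    max_epochs=100,
    early_stop_patience=35,
    input_side_px=32,
    width=12,
    vote=True,
)


@pytest.fixture(scope="session")
def mosaic_s():
    return cs.generate_mosaic(cs.MosaicParams.for_class("S", rng_seed=1))


@pytest.fixture(scope="session")
def mosaic_s_clean():
    """Jitter-free small mosaic: mean cell colors equal palette colors."""
    return cs.generate_mosaic(
        cs.MosaicParams.for_class("S", rng_seed=1, color_jitter_sd=0.0)
    )


@pytest.fixture(scope="session")
def cohort300():
    return cs.generate_cohort(300, rng_seed=11)


@pytest.fixture(scope="session")
def staged_cohort300(cohort300):
    """Cohort with K-means staging and fish-level splits applied."""
    records = [f.record for f in cohort300]
    cs.stage_fish(records, seed=2022)
    cs.allocate_splits(records, seed=3)
    return cohort300


@pytest.fixture(scope="session")
def cohort_splits(staged_cohort300):
    """Images and staged labels per split: {split: (images, labels)}."""
    data = {s: ([], []) for s in ("train", "val", "test")}
    for fish in staged_cohort300:
        for mosaic in fish.mosaics:
            data[fish.record.split][0].append(mosaic.image)
            data[fish.record.split][1].append(fish.record.size_class)
    return data


@pytest.fixture(scope="session")
def feature_table(staged_cohort300):
    """Five features per image plus staged class and split."""
    rows = []
    for fish in staged_cohort300:
        for image_id, mosaic in zip(fish.record.image_ids, fish.mosaics):
            graph = features.merge_clones(mosaic.image, mosaic.label_map)
            vec = features.extract_features(mosaic.image, mosaic.label_map, graph)
            row = {
                "image_id": image_id,
                "size_class": fish.record.size_class,
                "split": fish.record.split,
            }
            row.update(dict(zip(features.FeatureVector.NAMES, vec.as_array())))
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def trained_classifier(staged_cohort300, cohort_splits):
    """The crop-and-vote classifier trained on the staged cohort."""
    um_per_px = staged_cohort300[0].mosaics[0].params.um_per_px
    config = classifier.TrainConfig(
        seed=1,
        crop_spec=CropSpec(area_mm2=0.01, um_per_px=um_per_px),
        **DESK_TRAIN_KWARGS,
    )
    return classifier.train(
        config, *cohort_splits["train"], *cohort_splits["val"]
    )


@pytest.fixture(scope="session")
def test_predictions(trained_classifier, cohort_splits):
    """Per-image voted and unvoted predictions on the held-out split."""
    images, labels = cohort_splits["test"]
    voted = [trained_classifier.predict_voted(img) for img in images]
    unvoted = [trained_classifier.predict_whole(img) for img in images]
    return labels, voted, unvoted
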