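"""End-to-end orchestration: synth -> size -> features -> models -> CAM.

One :class:`RunConfig` drives the whole analysis on a synthetic cohort:
generate mosaics and silhouettes, stage sizes by K-means, allocate
fish-level splits, extract clone-resolved features, train and evaluate
the Random Forest baseline and the crop-and-vote deep classifier, and
quantify CAM hotspots on held-out images. Every stage draws its
randomness from a seed derived deterministically from the global seed
and the stage name, so a rerun with the same config reproduces every
CSV/JSON output byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines, cam, classifier, features, sizing, synthetic
from .cropping import CropSpec

ALL_STAGES = ("synth", "size", "features", "baseline", "deep", "cam")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    mix = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(mix.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (desk-scale defaults)."""

    out_dir: str = "runs/default"
    seed: int = 2022
    n_fish: int = 60
    class_mix: tuple[float, float, float] = synthetic.DEFAULT_CLASS_MIX
    stages: tuple[str, ...] = ALL_STAGES
    crop_area_mm2: float = 0.01
    input_side_px: int = 32
    learning_rate: float = 1e-3
    max_epochs: int = 12
    early_stop_patience: int = 6
    backbone_width: int = 8
    n_estimators: int = 100
    write_images: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the
    manifest (also written to ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "outputs": {},
        "reports": {},
    }
    stages = set(config.stages)
    required_order = [s for s in ALL_STAGES if s in stages]
    for stage in ("size", "features", "baseline", "deep", "cam"):
        if stage in stages and "synth" not in stages:
            raise ValueError(f"stage '{stage}' requires upstream stage 'synth'")

    cohort = None
    if "synth" in stages:
        cohort = synthetic.generate_cohort(
            config.n_fish, config.class_mix, rng_seed=stage_seed(config.seed, "synth")
        )
        if config.write_images:
            synthetic.write_cohort(cohort, out / "cohort")
            manifest["outputs"]["cohort_manifest"] = "cohort/cohort.csv"

    records = [f.record for f in cohort] if cohort else []

    if "size" in stages:
        model = sizing.stage_fish(records, seed=2022)
        sizing.allocate_splits(records, seed=stage_seed(config.seed, "size"))
        split_df = pd.DataFrame(
            {
                "fish_id": [r.fish_id for r in records],
                "trunk_area_mm2": [r.trunk_area_mm2 for r in records],
                "size_class": [r.size_class for r in records],
                "split": [r.split for r in records],
            }
        )
        split_df.to_csv(out / "splits.csv", index=False)
        manifest["outputs"]["splits"] = "splits.csv"
        manifest["reports"]["size_model"] = {
            "centroids_mm2": model.centroids_mm2.tolist(),
            "cutoffs_mm2": model.cutoffs_mm2.tolist(),
        }

    um_per_px = cohort[0].mosaics[0].params.um_per_px if cohort else None
    feature_rows = []
    if "features" in stages:
        for fish in cohort:
            for image_id, mosaic in zip(fish.record.image_ids, fish.mosaics):
                graph = features.merge_clones(mosaic.image, mosaic.label_map)
                vec = features.extract_features(mosaic.image, mosaic.label_map, graph)
                row = {"image_id": image_id, "fish_id": fish.record.fish_id,
                       "size_class": fish.record.size_class,
                       "split": fish.record.split}
                row.update(dict(zip(features.FeatureVector.NAMES, vec.as_array())))
                feature_rows.append(row)
        feat_df = pd.DataFrame(feature_rows)
        feat_df.to_csv(out / "features.csv", index=False)
        manifest["outputs"]["features"] = "features.csv"

    if "baseline" in stages:
        feat_df = pd.DataFrame(feature_rows)
        train_df = feat_df[feat_df.split.isin(["train", "val"])]
        test_df = feat_df[feat_df.split == "test"]
        names = list(features.FeatureVector.NAMES)
        forest = baselines.train_random_forest(
            train_df[names], train_df.size_class,
            n_estimators=config.n_estimators,
            seed=stage_seed(config.seed, "baseline"),
        )
        report = baselines.evaluate_forest(
            forest, test_df[names], test_df.size_class,
            ids=list(test_df.image_id),
        )
        manifest["reports"]["random_forest"] = report.to_dict()
        guess = baselines.random_guess_baseline(
            list(test_df.size_class), n_seeds=200,
            seed=stage_seed(config.seed, "baseline"),
        )
        manifest["reports"]["random_guess_weighted_f1"] = guess
        _write_json(out / "baseline_report.json", manifest["reports"]["random_forest"])

    clf = None
    deep_split: dict[str, tuple[list, list]] = {}
    if "deep" in stages or "cam" in stages:
        deep_split = {s: ([], []) for s in ("train", "val", "test")}
        for fish in cohort:
            for mosaic in fish.mosaics:
                deep_split[fish.record.split][0].append(mosaic.image)
                deep_split[fish.record.split][1].append(fish.record.size_class)

    if "deep" in stages:
        spec = CropSpec(area_mm2=config.crop_area_mm2, um_per_px=um_per_px)
        tconf = classifier.TrainConfig(
            learning_rate=config.learning_rate,
            max_epochs=config.max_epochs,
            early_stop_patience=config.early_stop_patience,
            seed=stage_seed(config.seed, "deep"),
            input_side_px=config.input_side_px,
            width=config.backbone_width,
            crop_spec=spec,
            vote=True,
        )
        clf = classifier.train(tconf, *deep_split["train"], *deep_split["val"])
        curves = pd.DataFrame(
            {"epoch": clf.curves.epoch, "train_loss": clf.curves.train_loss,
             "val_score": clf.curves.val_score}
        )
        curves.to_csv(out / "training_curves.csv", index=False)
        manifest["outputs"]["training_curves"] = "training_curves.csv"
        voted = clf.evaluate_images(*deep_split["test"], voted=True)
        unvoted = clf.evaluate_images(*deep_split["test"], voted=False)
        manifest["reports"]["deep_voted"] = voted.to_dict()
        manifest["reports"]["deep_unvoted"] = unvoted.to_dict()
        _write_json(out / "deep_report.json",
                    {"voted": voted.to_dict(), "unvoted": unvoted.to_dict()})

    if "cam" in stages:
        if clf is None:
            raise ValueError("stage 'cam' requires upstream stage 'deep'")
        rows = []
        test_images, test_labels = deep_split["test"]
        for i, (img, lab) in enumerate(zip(test_images, test_labels)):
            activation = clf.grad_cam(img)
            mask = cam.foreground_mask(img)
            stats = cam.hotspot_stats(cam.CamImage(activation, str(i), lab), mask)
            rows.append({"image_index": i, "size_class": lab,
                         "largest_hotspot_area_px": stats.largest_hotspot_area_px,
                         "n_hotspots": stats.n_hotspots,
                         "peak_activation": stats.peak_activation})
        cam_df = pd.DataFrame(rows)
        cam_df.to_csv(out / "cam_hotspots.csv", index=False)
        manifest["outputs"]["cam_hotspots"] = "cam_hotspots.csv"
        by_class = cam_df.groupby("size_class")["largest_hotspot_area_px"].mean()
        manifest["reports"]["cam_mean_largest_hotspot"] = {
            k: float(v) for k, v in by_class.items()
        }

    manifest["stages_run"] = required_order
    _write_json(out / "manifest.json", manifest)
    return manifest
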