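"""End-to-end pipeline: synth -> augment -> split -> train -> detect -> eval -> traits.

Driven by a single YAML/dict run configuration; every stage consumes the run
seed deterministically, writes its artifacts under the work directory and
records their SHA-256 hashes in a manifest, so completed stages are skipped
on re-runs with an unchanged configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .annotations import read_dota, split_dataset, write_dota
from .augment import AugmentSpec, expand_dataset
from .errors import ConfigError, RotPhenexError
from .losses import LossConfig
from .metrics import evaluate_detections
from .model import ModelConfig, TrainConfig, detect, load_checkpoint, train
from .synthdata import SceneSpec, generate_dataset, load_manifest
from .traits import ScaleCalibration, extract_plant

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("synth", "augment", "split", "train", "detect", "eval", "traits")


class RunConfig(dict):
    """Thin dict wrapper with defaulting accessors."""

    def section(self, name: str) -> dict:
        val = self.get(name, {})
        if not isinstance(val, dict):
            raise ConfigError(f"config section {name!r} must be a mapping")
        return val


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _hash_tree(root: Path) -> dict:
    return {
        str(p.relative_to(root)): _sha256(p)
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def run_pipeline(config: RunConfig | dict, workdir) -> dict:
    """Execute all stages in order; returns the artifact manifest."""
    cfg = RunConfig(config)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"seed": seed, "stages": {}}

    def stage_done(name: str, outputs: Path) -> None:
        manifest["stages"][name] = _hash_tree(outputs) if outputs.is_dir() else {}
        (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    current = "synth"
    try:
        # synth
        synth_dir = workdir / "synth"
        scene_cfg = cfg.section("scene")
        spec = SceneSpec(**{**scene_cfg, "seed": seed})
        n_images = int(cfg.get("n_images", 20))
        if not (synth_dir / "manifest.json").exists():
            generate_dataset(n_images, spec, synth_dir)
        records = load_manifest(synth_dir)
        stage_done("synth", synth_dir)

        # augment
        current = "augment"
        aug_cfg = cfg.section("augment")
        if aug_cfg.get("enabled", False):
            aug_spec = AugmentSpec(
                **{k: v for k, v in aug_cfg.items() if k != "enabled"}, seed=seed
            )
            records = expand_dataset(records, aug_spec)
        stage_done("augment", synth_dir)

        # split
        current = "split"
        ratios = tuple(cfg.get("split_ratios", (7, 2, 1)))
        train_set, test_set, val_set = split_dataset(records, ratios, seed=seed)
        if not train_set:
            train_set = records
        if not test_set:
            test_set = records
        stage_done("split", synth_dir)

        # train
        current = "train"
        ckpt = workdir / "model.ckpt.npz"
        mcfg = ModelConfig(**cfg.section("model"), seed=seed)
        loss_cfg = LossConfig(**cfg.section("loss"))
        tr_section = cfg.section("train")
        tcfg = TrainConfig(**tr_section, seed=seed, loss=loss_cfg)
        if ckpt.exists():
            net, _ = load_checkpoint(ckpt)
        else:
            net, _ = train(train_set, mcfg, tcfg, checkpoint_path=ckpt)
        stage_done("train", workdir)

        # detect
        current = "detect"
        pred_dir = workdir / "predictions"
        pred_dir.mkdir(exist_ok=True)
        eval_cfg = cfg.section("eval")
        conf_thr = float(eval_cfg.get("conf_threshold", 0.25))
        preds_by_image, gts_by_image = {}, {}
        for i, rec in enumerate(test_set):
            dets = detect(net, rec, conf_threshold=conf_thr)
            key = f"image_{i:04d}"
            preds_by_image[key] = dets
            gts_by_image[key] = [a.box for a in rec.annotations]
            lines = []
            for box, score in dets:
                from .rotgeom import to_quad

                coords = " ".join(
                    f"{v:.1f}" for xy in to_quad(box).vertices for v in xy
                )
                lines.append(f"{coords} leaf 0 {score:.4f}")
            (pred_dir / f"{key}.txt").write_text("\n".join(lines) + "\n" if lines else "")
        stage_done("detect", pred_dir)

        # eval
        current = "eval"
        iou_thr = float(eval_cfg.get("iou_threshold", 0.5))
        result = evaluate_detections(preds_by_image, gts_by_image, iou_thr)
        (workdir / "eval.json").write_text(json.dumps(result.as_dict(), indent=2))
        stage_done("eval", workdir)

        # traits
        current = "traits"
        scale_cfg = cfg.section("scale")
        scale = (
            ScaleCalibration(float(scale_cfg["mm_per_px"]))
            if "mm_per_px" in scale_cfg
            else None
        )
        tables = []
        for key, dets in preds_by_image.items():
            _, table = extract_plant(
                dets, scale=scale, conf_threshold=conf_thr, image_name=key
            )
            tables.append(table)
        traits_df = (
            pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        )
        traits_df.to_csv(workdir / "traits.csv", index=False)
        stage_done("traits", workdir)
    except RotPhenexError as exc:
        raise RotPhenexError(f"pipeline stage {current!r} failed: {exc}") from exc
    return manifest
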