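"""End-to-end desk-scale reproduction of the analysis.

One call runs: simulate a labeled cohort -> enhance (crop/resize/CLAHE/
gamma) -> train the vessel segmenter on synthetic pairs -> build the
vessel-only "segmented" variant -> nested 5-fold CNN training and
evaluation on BOTH the enhanced and the segmented variants -> Grad-CAM
bifurcation-enrichment attribution on the segmented variant. Everything is
seeded from one global seed; rerunning with the same config reproduces the
metrics CSVs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .attribution import cohort_attribution_report
from .classify import ClassifierConfig, cross_validate, desk_config
from .evaluate import reports_to_frame
from .exceptions import ConfigurationError
from .preprocessing import PreprocessConfig, enhance_cohort
from .segmentation import SegmenterConfig, UNetSegmenter, make_segmented_dataset
from .synthetic import SimulatorConfig, generate_cohort

logger = logging.getLogger("retinavasc")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: global seed + CRC32 of the stage name."""
    return int((int(global_seed) + zlib.crc32(stage.encode())) % (2**31))


@dataclass
class PipelineConfig:
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    preprocess: PreprocessConfig = field(default_factory=lambda: PreprocessConfig(target_side=128))
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    classifier: ClassifierConfig = field(default_factory=desk_config)
    n_per_class: int = 60
    n_segmenter_pairs: int = 30
    attribution_radius: float | None = None  # None -> 2x mean vessel diameter
    folds: int = 5
    group_by_subject: bool = True
    seed: int = 0

    def validate(self):
        if self.n_per_class < 1 or self.n_segmenter_pairs < 1:
            raise ConfigurationError("cohort sizes must be >= 1")
        self.simulator.validate()
        self.preprocess.validate()
        self.segmenter.validate()
        self.classifier.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        for key, sub in (("simulator", SimulatorConfig), ("preprocess", PreprocessConfig),
                         ("segmenter", SegmenterConfig), ("classifier", ClassifierConfig)):
            if key in data and isinstance(data[key], dict):
                payload = dict(data[key])
                for name, value in payload.items():
                    if isinstance(value, list):
                        payload[name] = tuple(value)
                data[key] = sub(**payload)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the run summary (also written to disk)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t_start = time.time()
    summary: dict = {"config_hash": config_hash(config), "stages": {}, "seeds": {}}

    def stage(name):
        seed = derive_seed(config.seed, name)
        summary["seeds"][name] = seed
        logger.info("stage=%s seed=%d", name, seed)
        return seed, time.time()

    try:
        # -- simulate ------------------------------------------------------
        seed, t0 = stage("simulate")
        cohort = generate_cohort(config.simulator, config.n_per_class, seed)
        seg_seed = derive_seed(config.seed, "simulate-segpairs")
        seg_cohort = generate_cohort(config.simulator, config.n_segmenter_pairs, seg_seed)
        summary["stages"]["simulate"] = {"n_records": len(cohort.records),
                                         "wall_s": round(time.time() - t0, 2)}

        # -- preprocess ----------------------------------------------------
        _, t0 = stage("preprocess")
        enhanced = enhance_cohort(cohort, config.preprocess)
        enhanced_pairs = enhance_cohort(seg_cohort, config.preprocess)
        summary["stages"]["preprocess"] = {"wall_s": round(time.time() - t0, 2)}

        # -- segmenter training -------------------------------------------
        seed, t0 = stage("segment-train")
        seg_config = dataclasses.replace(config.segmenter, seed=seed)
        segmenter = UNetSegmenter.from_config(seg_config).fit(
            [r.image for r in enhanced_pairs.records],
            [r.mask for r in enhanced_pairs.records],
        )
        segmenter.save(out / "segmenter.npz")
        summary["stages"]["segment-train"] = {
            "final_loss": segmenter.history_[-1],
            "wall_s": round(time.time() - t0, 2),
        }

        # -- segmented dataset --------------------------------------------
        _, t0 = stage("segment-apply")
        segmented = make_segmented_dataset(segmenter, enhanced)
        summary["stages"]["segment-apply"] = {"wall_s": round(time.time() - t0, 2)}

        # -- classification on both variants ------------------------------
        variants = {"enhanced": enhanced, "segmented": segmented}
        labels = cohort.labels()
        subjects = np.array([r.subject_id for r in cohort.records])
        cv_outputs = {}
        for variant, data in variants.items():
            seed, t0 = stage(f"train-{variant}")
            clf_config = dataclasses.replace(config.classifier, seed=seed)
            reports, fold_scores, models, plan = cross_validate(
                [r.image for r in data.records], labels, subjects, clf_config,
                k=config.folds, group_by_subject=config.group_by_subject,
            )
            frame = reports_to_frame(reports)
            frame.to_csv(out / f"metrics_{variant}.csv", index=False)
            cv_outputs[variant] = (reports, fold_scores, models)
            summary["stages"][f"train-{variant}"] = {
                "folds": len(reports),
                "mean_auc": float(np.mean([r.auc for r in reports])),
                "wall_s": round(time.time() - t0, 2),
            }

        # -- attribution on the segmented variant -------------------------
        _, t0 = stage("explain")
        reports, fold_scores, models = cv_outputs["segmented"]
        frames = []
        for fold, (model, fs) in enumerate(zip(models, fold_scores)):
            frame, fold_summary = cohort_attribution_report(
                model, [segmented.records[i] for i in fs["indices"]],
                radius=config.attribution_radius,
            )
            frame.insert(0, "fold", fold)
            frames.append(frame)
        import pandas as pd

        attribution = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        attribution.to_csv(out / "attribution.csv", index=False)
        summary["stages"]["explain"] = {
            "n_maps": int(len(attribution)),
            "wall_s": round(time.time() - t0, 2),
        }
    except Exception as exc:  # annotate which stage broke, then re-raise
        done = ", ".join(summary["stages"]) or "none"
        logger.error("failed after stages [%s]: %s", done, exc)
        raise

    summary["variants"] = list(variants)
    summary["wall_s"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(
        json.dumps({"config": config.to_dict(), **summary}, indent=1, default=str)
    )
    logger.removeHandler(handler)
    handler.close()
    return summary
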