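"""End-to-end pipeline: simulate -> split -> (augment) -> train ->
evaluate -> Grad-CAM, driven by a single YAML-able config dict.

The resolved configuration (all defaults filled in) is written into the
run directory, and re-running from that file reproduces the run:
manifests and the metric report are byte-stable for a fixed config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .architecture import ModelConfig, build_model, save_checkpoint
from .augment import augment_cohort, default_catalogue
from .data_io import read_manifest, subject_split, write_manifest
from .evaluation import evaluate_model
from .interpret import grad_cam, localization_score
from .phantom import PhantomSpec, generate_cohort, lesion_mask
from .training import TrainConfig, train

__all__ = ["RunConfig", "resolve_config", "run_pipeline"]

_DEFAULTS = {
    "seed": 0,
    "out_dir": "run",
    "phantom": {},
    "split": {"test_fraction": 0.25},
    "augment": {"enabled": False},
    "model": {},
    "train": {},
    "gradcam": {"enabled": True, "layer": "stage4", "target_class": "predicted",
                "max_volumes": 20},
}


class RunConfig(dict):
    """A resolved pipeline configuration (plain dict with helpers)."""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return resolve_config(raw)

    def write_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self), fh, sort_keys=True)


def resolve_config(raw: dict) -> RunConfig:
    """Fill defaults; per-stage seeds derive from the global seed unless set."""
    cfg = RunConfig()
    for key, default in _DEFAULTS.items():
        value = raw.get(key, default)
        if isinstance(default, dict):
            merged = dict(default)
            merged.update(value or {})
            cfg[key] = merged
        else:
            cfg[key] = value
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    seed = int(cfg["seed"])
    cfg["phantom"].setdefault("seed", seed)
    cfg["split"].setdefault("seed", seed)
    cfg["augment"].setdefault("seed", seed)
    cfg["train"].setdefault("seed", seed)
    cfg["model"].setdefault("build_seed", seed)
    # the model input grid follows the phantom grid unless set explicitly
    spec = PhantomSpec.from_dict(cfg["phantom"])
    cfg["phantom"] = spec.to_dict()
    cfg["model"].setdefault("input_grid", list(spec.grid_shape))
    model_fields = dict(cfg["model"])
    build_seed = model_fields.pop("build_seed")
    mc = ModelConfig.from_dict(model_fields)
    cfg["model"] = mc.to_dict()
    cfg["model"]["build_seed"] = build_seed
    tc = TrainConfig.from_dict(cfg["train"])
    cfg["train"] = tc.to_dict()
    return cfg


def run_pipeline(config: RunConfig | dict, out_dir=None) -> Path:
    """Execute the configured stages; returns the run directory."""
    cfg = config if isinstance(config, RunConfig) else resolve_config(dict(config))
    run_dir = Path(out_dir if out_dir is not None else cfg["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(cfg)
    cfg["out_dir"] = str(run_dir)
    cfg.write_yaml(run_dir / "config.resolved.yaml")

    # simulate
    spec = PhantomSpec.from_dict(cfg["phantom"])
    cohort = generate_cohort(spec, run_dir / "phantom")

    # split
    trainc, testc = subject_split(
        cohort, cfg["split"]["test_fraction"], int(cfg["split"]["seed"])
    )
    write_manifest(trainc, run_dir / "train.tsv")
    write_manifest(testc, run_dir / "test.tsv")

    # augment (training side only)
    if cfg["augment"]["enabled"]:
        cat = default_catalogue(seed=int(cfg["augment"]["seed"]))
        trainc = augment_cohort(trainc, cat, run_dir / "augmented")

    # train
    model_fields = dict(cfg["model"])
    build_seed = int(model_fields.pop("build_seed"))
    model_cfg = ModelConfig.from_dict(model_fields)
    train_cfg = TrainConfig.from_dict(cfg["train"])
    model = build_model(model_cfg, seed=build_seed)
    _, history = train(model, trainc, train_cfg, run_dir=str(run_dir))
    save_checkpoint(model, run_dir / "checkpoint")

    # evaluate
    report, curve = evaluate_model(model, testc, batch_size=train_cfg.batch_size)
    payload = {
        "metrics": {k: getattr(report, k) for k in ("SEN", "SPE", "ACC", "F1", "AUC")},
        "counts": report.counts.to_dict(),
        "n_test_scans": report.counts.total,
        "roc": [] if curve is None else curve.points(),
    }

    # Grad-CAM localization against the phantom's known lesion mask;
    # target 'predicted' explains each scan's own classification decision
    if cfg["gradcam"]["enabled"]:
        mask = lesion_mask(spec)
        target = cfg["gradcam"]["target_class"]
        scores = []
        test_vols = testc.load_volumes()[: int(cfg["gradcam"]["max_volumes"])]
        for vol in test_vols:
            if target == "predicted":
                from .evaluation import predict

                cls = int(predict(model, vol.voxels[None, None].astype(np.float32))[0][0])
            else:
                cls = int(target)
            cam = grad_cam(model, vol, target_class=cls, layer=cfg["gradcam"]["layer"])
            scores.append(localization_score(cam, mask))
        payload["gradcam"] = {
            "layer": cfg["gradcam"]["layer"],
            "n_volumes": len(scores),
            "median_localization": float(np.median(scores)) if scores else float("nan"),
        }

    with open(run_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return run_dir
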