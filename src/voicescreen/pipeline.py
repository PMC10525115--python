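"""End-to-end orchestration: synth -> ingest -> featurize -> augment ->
split -> train -> evaluate, from a single seeded configuration.

One global seed deterministically derives every stage seed, so re-running
a config reproduces all CSV outputs bit-identically on CPU.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augment import AugmentConfig
from .evaluate import (
    SplitPlan,
    TrainConfig,
    crossvalidate,
    holdout_evaluate,
    make_splits,
)
from .features import FrameSpec, featurize_manifest, load_png
from .ingest import standardize_manifest
from .metrics import PANEL_FIELDS
from .models import ModelSpec
from .synth import EffectConfig, make_cohort

__all__ = ["RunConfig", "run_all", "stage_seed"]

_FLOAT_FMT = "%.6f"


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a 31-bit per-stage seed from the global seed."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Full pipeline configuration with one global seed."""

    n_per_class: int = 40
    effect: EffectConfig = field(default_factory=EffectConfig)
    frame: FrameSpec = field(default_factory=FrameSpec)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(learning_rate=1e-2))
    split: SplitPlan = field(default_factory=SplitPlan)
    model: ModelSpec = field(default_factory=ModelSpec)
    out_dir: str = "runs/run0"
    seed: int = 0
    paper_mode: bool = False
    use_augmentation: bool = True

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")

    def to_dict(self) -> dict:
        doc = asdict(self)
        return doc

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _panel_row(name: str, protocol: str, panel: dict) -> dict:
    row = {"model": name, "protocol": protocol}
    row.update({k: panel[k] for k in ("tp", "fn", "fp", "tn") if k in panel})
    row.update({k: panel[k] for k in PANEL_FIELDS if k in panel})
    return row


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and write all artifacts under ``cfg.out_dir``.

    Returns the run summary (also written as ``run_summary.json``). Output
    CSVs use fixed column order and float formatting so reruns diff clean.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    try:
        manifest = make_cohort(
            cfg.n_per_class, cfg.effect, stage_seed(cfg.seed, "synth"), out / "wav"
        )
    except Exception as exc:  # pragma: no cover - error path
        fail("synth", exc)
    try:
        std = standardize_manifest(manifest.responses, out / "std")
        std.to_csv(out / "std" / "manifest_std.csv", index=False)
    except Exception as exc:  # pragma: no cover
        fail("ingest", exc)
    try:
        index = featurize_manifest(std, out / "composites", cfg.frame)
    except Exception as exc:  # pragma: no cover
        fail("featurize", exc)

    images = [load_png(p) for p in index["image_path"]]
    aug_cfg = (
        replace(cfg.augment, seed=stage_seed(cfg.seed, "augment"))
        if cfg.use_augmentation
        else None
    )
    train_cfg = replace(cfg.train, seed=stage_seed(cfg.seed, "train"))
    rows, roc_rows, conf_rows = [], [], []
    try:
        if cfg.paper_mode and aug_cfg is not None:
            # original protocol: augment everything, then image-level split
            from .augment import augment_set

            aug_images, aug_labels, prov = augment_set(
                images, (index["group"] == "AD").astype(int).to_numpy(), aug_cfg
            )
            prov.to_csv(out / "augment_provenance.csv", index=False)
            aug_index = pd.DataFrame(
                {
                    "participant_id": index["participant_id"].to_numpy()[
                        prov["source_index"]
                    ],
                    "group": index["group"].to_numpy()[prov["source_index"]],
                }
            )
            plan = replace(cfg.split, unit="image", seed=stage_seed(cfg.seed, "split"))
            eval_images, eval_index, eval_aug = aug_images, aug_index, None
        else:
            plan = replace(cfg.split, seed=stage_seed(cfg.seed, "split"))
            eval_images, eval_index, eval_aug = images, index, aug_cfg

        if plan.mode == "holdout":
            report, history = holdout_evaluate(
                eval_images, eval_index, plan, cfg.model, train_cfg, eval_aug
            )
            rows.append(_panel_row(cfg.model.architecture, "holdout", report.panel()))
            conf_rows.append(
                {"protocol": "holdout", "fold": 0, "tp": report.tp, "fn": report.fn,
                 "fp": report.fp, "tn": report.tn}
            )
            roc_rows += [
                {"protocol": "holdout", "fold": 0, "fpr": f, "tpr": t}
                for f, t in report.roc
            ]
        else:
            reports, mean_panel = crossvalidate(
                eval_images, eval_index, plan, cfg.model, train_cfg, eval_aug
            )
            for i, r in enumerate(reports):
                rows.append(_panel_row(cfg.model.architecture, f"fold{i}", r.panel()))
                conf_rows.append(
                    {"protocol": "kfold", "fold": i, "tp": r.tp, "fn": r.fn,
                     "fp": r.fp, "tn": r.tn}
                )
                roc_rows += [
                    {"protocol": "kfold", "fold": i, "fpr": f, "tpr": t}
                    for f, t in r.roc
                ]
            rows.append(_panel_row(cfg.model.architecture, "kfold_mean", mean_panel))
    except Exception as exc:
        fail("evaluate", exc)

    metrics_df = pd.DataFrame(rows)
    metrics_df.to_csv(out / "metrics.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(conf_rows).to_csv(out / "confusion.csv", index=False)
    pd.DataFrame(roc_rows).to_csv(out / "roc.csv", index=False, float_format=_FLOAT_FMT)

    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_participants": int(2 * cfg.n_per_class),
        "protocol": cfg.split.mode,
        "metrics": [
            {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in r.items()}
            for r in rows
        ],
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
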