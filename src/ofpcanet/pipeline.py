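"""End-to-end pipeline: flow -> stacking -> per-fold PCANet+ -> SVM -> metrics.

The pipeline honors the person-independent protocol strictly: for every
leave-one-subject-out fold the PCA filter bank is retrained from the training
subjects' stacked tensors only, then features are extracted for both sides of
the fold with that bank.  Flow fields are computed once per clip and cached
(optionally on disk as .flo files), since they do not depend on the fold.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .classify_eval import (
    ConfusionMatrix,
    aggregate_clip_feature,
    compute_metrics,
    fit_predict_linear_svm,
    loso_split,
)
from .clip_io import Clip, DatasetIndex, load_clip, read_flo, write_flo
from .exceptions import ConfigError
from .optical_flow import FlowSequence, FlowSolverConfig, estimate_flow_sequence
from .pcanet_plus import LayerConfig, forward_features, train_filter_bank
from .stacking import stack_flow_sequence

logger = logging.getLogger(__name__)


@dataclass
class StackingConfig:
    T: int = 5
    s: int | None = None  # None = auto (T-1)//2, at least 1


@dataclass
class SvmConfig:
    C: float = 1.0
    standardize: bool = True


@dataclass
class EvalConfig:
    aggregation: str = "mean"
    seed: int = 0


@dataclass
class IoConfig:
    target_size: tuple[int, int] = (170, 139)
    cache_dir: str | None = None


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run; YAML round-trippable."""

    flow: FlowSolverConfig = field(default_factory=FlowSolverConfig)
    stacking: StackingConfig = field(default_factory=StackingConfig)
    layers: list[LayerConfig] = field(
        default_factory=lambda: [
            LayerConfig(k=7, n_filters=32, pool_size=3, pool_stride=1),
            LayerConfig(k=9, n_filters=16, pool_size=1, pool_stride=1),
        ]
    )
    svm: SvmConfig = field(default_factory=SvmConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    io: IoConfig = field(default_factory=IoConfig)
    learn_step: int = 1

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigError("at least one PCANet+ layer required")
        self.io.target_size = tuple(self.io.target_size)  # type: ignore[assignment]

    def to_yaml(self) -> str:
        d = asdict(self)
        d["flow"].pop("basis_trajectories", None)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs: dict = {}
        if "flow" in d:
            kwargs["flow"] = FlowSolverConfig(**d["flow"])
        if "stacking" in d:
            kwargs["stacking"] = StackingConfig(**d["stacking"])
        if "layers" in d:
            kwargs["layers"] = [LayerConfig(**lc) for lc in d["layers"]]
        if "svm" in d:
            kwargs["svm"] = SvmConfig(**d["svm"])
        if "eval" in d:
            kwargs["eval"] = EvalConfig(**d["eval"])
        if "io" in d:
            kwargs["io"] = IoConfig(**d["io"])
        if "learn_step" in d:
            kwargs["learn_step"] = d["learn_step"]
        return cls(**kwargs)


def _preset_smic() -> PipelineConfig:
    return PipelineConfig(
        stacking=StackingConfig(T=5),
        layers=[
            LayerConfig(k=7, n_filters=32, pool_size=3, pool_stride=1, pad=3),
            LayerConfig(k=9, n_filters=16, pool_size=1, pool_stride=1, pad=4),
        ],
        io=IoConfig(target_size=(170, 139)),
        learn_step=4,
    )


def _preset_casme2() -> PipelineConfig:
    return PipelineConfig(
        stacking=StackingConfig(T=5),
        layers=[
            LayerConfig(k=7, n_filters=16, pool_size=3, pool_stride=1, pad=3),
            LayerConfig(k=7, n_filters=32, pool_size=3, pool_stride=1, pad=3),
        ],
        io=IoConfig(target_size=(170, 139)),
        learn_step=4,
    )


def _preset_synthetic_small() -> PipelineConfig:
    return PipelineConfig(
        stacking=StackingConfig(T=3),
        layers=[
            LayerConfig(k=5, n_filters=8, pool_size=3, pool_stride=1),
            LayerConfig(k=5, n_filters=8, pool_size=1, pool_stride=1),
        ],
        io=IoConfig(target_size=(64, 64)),
    )


PRESETS = {
    "smic-best": _preset_smic,
    "casme2-best": _preset_casme2,
    "synthetic-small": _preset_synthetic_small,
}


def get_preset(name: str) -> PipelineConfig:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name]()


def compute_clip_flow(
    clip: Clip, config: PipelineConfig, cache_dir: str | Path | None = None
) -> FlowSequence:
    """Flow of one clip, read from / written to the .flo cache if enabled."""
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        n = clip.n_frames - 1
        paths = [cache_dir / f"{clip.clip_id}_{t}.flo" for t in range(1, n + 1)]
        if all(p.exists() for p in paths):
            fields = [read_flo(p) for p in paths]
            return FlowSequence(
                U=np.stack([f[0] for f in fields], axis=2).astype(np.float64),
                V=np.stack([f[1] for f in fields], axis=2).astype(np.float64),
            )
    flow = estimate_flow_sequence(clip, config.flow)
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        for t in range(flow.n_fields):
            write_flo(
                (flow.U[:, :, t], flow.V[:, :, t]),
                cache_dir / f"{clip.clip_id}_{t + 1}.flo",
            )
        # re-read so warm- and cold-cache runs see identical float32 fields
        return compute_clip_flow(clip, config, cache_dir)
    return flow


def run_pipeline(
    config: PipelineConfig,
    index: DatasetIndex,
    *,
    clips: dict[str, Clip] | None = None,
    flows: dict[str, FlowSequence] | None = None,
) -> dict:
    """Execute the full LOSO evaluation and return a results document.

    ``clips`` may supply preloaded clips keyed by clip_id (otherwise each
    manifest path is loaded from disk); ``flows`` may supply precomputed flow
    sequences, which is how parameter sweeps share flow across settings.
    """
    t0 = time.time()
    if clips is None:
        clips = {}
        for e in index.entries:
            clips[e.clip_id] = load_clip(
                e.path,
                config.io.target_size,
                subject_id=e.subject,
                label=e.label,
                clip_id=e.clip_id,
            )
    if flows is None:
        flows = {}
        for e in index.entries:
            flows[e.clip_id] = compute_clip_flow(
                clips[e.clip_id], config, config.io.cache_dir
            )
            logger.info("flow computed for %s", e.clip_id)
    logger.info("flow stage done in %.1fs", time.time() - t0)

    stacks = {
        e.clip_id: stack_flow_sequence(
            flows[e.clip_id], config.stacking.T, config.stacking.s,
            clip_id=e.clip_id,
        )
        for e in index.entries
    }
    labels = {e.clip_id: e.label for e in index.entries}
    folds = loso_split(index)
    fold_records = []
    y_true_all: list[str] = []
    y_pred_all: list[str] = []
    for fold in folds:
        t_fold = time.time()
        train_tensors = [t for c in fold.train_ids for t in stacks[c].tensors]
        bank = train_filter_bank(
            train_tensors, config.layers,
            learn_step=config.learn_step, trained_on=fold.subject,
        )
        feats = {
            c: aggregate_clip_feature(
                [forward_features(t, bank) for t in stacks[c].tensors],
                mode=config.eval.aggregation,
            )
            for c in (*fold.train_ids, *fold.test_ids)
        }
        y_pred = fit_predict_linear_svm(
            np.stack([feats[c] for c in fold.train_ids]),
            np.array([labels[c] for c in fold.train_ids]),
            np.stack([feats[c] for c in fold.test_ids]),
            C=config.svm.C,
            standardize=config.svm.standardize,
            seed=config.eval.seed,
        )
        y_true = [labels[c] for c in fold.test_ids]
        fold_records.append(
            {
                "subject": fold.subject,
                "clip_ids": list(fold.test_ids),
                "y_true": y_true,
                "y_pred": [str(p) for p in y_pred],
            }
        )
        y_true_all.extend(y_true)
        y_pred_all.extend(str(p) for p in y_pred)
        logger.info("fold %s done in %.1fs", fold.subject, time.time() - t_fold)

    cm = ConfusionMatrix.from_predictions(y_true_all, y_pred_all, index.class_names)
    report = compute_metrics(cm)
    return {
        "config": yaml.safe_load(config.to_yaml()),
        "folds": fold_records,
        "confusion_matrix": cm.counts.tolist(),
        "class_names": index.class_names,
        "metrics": report.as_dict(),
        "runtime_s": round(time.time() - t0, 2),
    }


def run_sweep(
    base_config: PipelineConfig,
    index: DatasetIndex,
    grid: list[dict],
    *,
    clips: dict[str, Clip] | None = None,
) -> list[dict]:
    """Re-run the pipeline over a grid of config overrides.

    Each grid entry is a partial config dict merged over the base config
    (e.g. ``{"stacking": {"T": 3}}`` or ``{"layers": [...]}``).  Flow is
    computed once and shared across settings that do not change the flow
    solver.  Returns one row per setting with the overrides and the metrics.
    """
    if clips is None:
        clips = {
            e.clip_id: load_clip(
                e.path, base_config.io.target_size,
                subject_id=e.subject, label=e.label, clip_id=e.clip_id,
            )
            for e in index.entries
        }
    shared_flows: dict[str, FlowSequence] | None = None
    rows = []
    for overrides in grid:
        merged = yaml.safe_load(base_config.to_yaml())
        for key, val in overrides.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
        cfg = PipelineConfig.from_dict(merged)
        flow_changed = asdict(cfg.flow) != asdict(base_config.flow)
        if flow_changed:
            flows = None
        else:
            if shared_flows is None:
                shared_flows = {
                    e.clip_id: compute_clip_flow(clips[e.clip_id], cfg, cfg.io.cache_dir)
                    for e in index.entries
                }
            flows = shared_flows
        result = run_pipeline(cfg, index, clips=clips, flows=flows)
        rows.append({"overrides": overrides, **result["metrics"],
                     "confusion_matrix": result["confusion_matrix"]})
    return rows
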