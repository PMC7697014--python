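"""End-to-end orchestration: preprocess -> extract -> balance -> select ->
classify -> report.

A run is driven by a single nested configuration (YAML on disk or a plain
dict) validated before any stage executes.  Inputs are either a directory
of WAV files with a ``labels.csv`` sidecar (``recording_id,label``) or a
synthetic-dataset block; outputs are the feature table (CSV), the selection
result, the metrics report (JSON), the pooled confusion matrix (CSV) and a
log of every configuration value, all under the report directory.

One run seed feeds every stochastic stage (generation, fold shuffling,
ADASYN), so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import audio_io, emd, denoise, features, balance, selection, model, synthetic
from .audio_io import AudioRecording, FeatureTable

__all__ = ["PipelineConfig", "preprocess_recording", "build_feature_table", "run"]

logger = logging.getLogger("lungsound_dx")


@dataclass
class PipelineConfig:
    # io
    input_dir: Optional[str] = None
    labels_csv: Optional[str] = None
    report_dir: str = "report"
    seed: int = 0
    # synthetic block (used when input_dir is None)
    synth_counts: dict = field(default_factory=lambda: {"COPD": 60, "healthy": 60, "pneumonia": 60})
    synth_duration: float = 21.5
    synth_fs: float = 44100.0
    synth_breath_rate: float = 0.25
    # emd
    emd_enabled: bool = True
    emd_max_imfs: int = 10
    emd_select_imfs: tuple = (2, 3, 4)
    emd_sift_sd_threshold: float = 0.2
    emd_max_sift_iters: int = 100
    # denoise
    denoise_enabled: bool = True
    denoise_wavelet: str = "coif5"
    denoise_level: int = 1
    denoise_threshold_rule: str = "universal"
    denoise_fixed_value: Optional[float] = None
    # balance
    balance_enabled: bool = True
    balance_k_neighbors: int = 5
    balance_pre_split: bool = False  # True: balance the whole table before splitting
    # selection
    selection_method: str = "preset:table5"  # {"backward", "preset:<name>", "none"}
    selection_min_features: int = 1
    selection_cv_folds: int = 3
    # model / eval
    model_type: str = "qda"
    model_reg: float = 1e-6
    eval_protocol: str = "cv"  # {"cv", "holdout"}
    eval_folds: int = 5
    eval_holdout: float = 0.20

    def validate(self) -> None:
        if self.eval_protocol not in ("cv", "holdout"):
            raise ValueError(f"unknown eval protocol {self.eval_protocol!r}")
        if self.selection_method != "none" and self.selection_method != "backward":
            if not self.selection_method.startswith("preset:"):
                raise ValueError(f"unknown selection method {self.selection_method!r}")
            try:
                selection.preset_features(self.selection_method.split(":", 1)[1])
            except KeyError as exc:
                raise ValueError(str(exc)) from exc
        if self.model_type not in ("qda", "lda"):
            raise ValueError(f"unknown model type {self.model_type!r}")
        if self.emd_max_imfs < 1 or self.eval_folds < 2:
            raise ValueError("emd_max_imfs >= 1 and eval_folds >= 2 required")
        if not 0.0 < self.eval_holdout < 1.0:
            raise ValueError("eval_holdout must be in (0, 1)")
        if self.input_dir is not None and self.labels_csv is None:
            raise ValueError("input_dir requires labels_csv")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.emd_select_imfs, list):
            cfg.emd_select_imfs = tuple(cfg.emd_select_imfs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def preprocess_recording(rec: AudioRecording, cfg: PipelineConfig) -> AudioRecording:
    """EMD region-of-interest reconstruction followed by wavelet denoising."""
    out = rec
    if cfg.emd_enabled:
        imfset = emd.sift(
            out,
            max_imfs=cfg.emd_max_imfs,
            stop=emd.SiftStopRule(cfg.emd_sift_sd_threshold, cfg.emd_max_sift_iters),
        )
        available = [i for i in cfg.emd_select_imfs if i <= len(imfset)]
        out = emd.reconstruct(imfset, available)
    if cfg.denoise_enabled:
        dcfg = denoise.DenoiseConfig(
            wavelet=cfg.denoise_wavelet,
            level=cfg.denoise_level,
            threshold_rule=cfg.denoise_threshold_rule,
            fixed_value=cfg.denoise_fixed_value,
        )
        out = denoise.dwt_denoise(out, dcfg)
    return out


def _load_recordings(cfg: PipelineConfig) -> list[AudioRecording]:
    if cfg.input_dir is None:
        spec = synthetic.SyntheticSpec(
            duration=cfg.synth_duration, fs=cfg.synth_fs, breath_rate=cfg.synth_breath_rate
        )
        return synthetic.generate_dataset(cfg.synth_counts, spec, seed=cfg.seed)
    labels = pd.read_csv(cfg.labels_csv)
    if not {"recording_id", "label"} <= set(labels.columns):
        raise ValueError("labels CSV needs columns recording_id,label")
    mapping = dict(zip(labels["recording_id"].astype(str), labels["label"]))
    recs = []
    for name in sorted(os.listdir(cfg.input_dir)):
        if not name.lower().endswith(".wav"):
            continue
        stem = os.path.splitext(name)[0]
        if stem not in mapping:
            logger.warning("no label for %s; skipped", name)
            continue
        rec = audio_io.read_wav(os.path.join(cfg.input_dir, name))
        rec.label = str(mapping[stem])
        recs.append(rec)
    if not recs:
        raise ValueError(f"no labeled WAV files found in {cfg.input_dir}")
    return recs


def build_feature_table(recordings: list[AudioRecording], cfg: PipelineConfig) -> FeatureTable:
    processed = [preprocess_recording(r, cfg) for r in recordings]
    return features.extract_table(processed)


def _make_evaluator(cfg: PipelineConfig):
    def evaluator(matrix: np.ndarray, labels: np.ndarray) -> float:
        tbl = FeatureTable(matrix, labels, [f"f{i}" for i in range(matrix.shape[1])])
        report, _ = model.cross_validate(
            tbl, folds=cfg.selection_cv_folds, seed=cfg.seed,
            reg=cfg.model_reg, model_type=cfg.model_type,
        )
        return report.accuracy

    return evaluator


def run(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written to
    ``report_dir``)."""
    cfg.validate()
    os.makedirs(cfg.report_dir, exist_ok=True)
    logger.info("pipeline config: %s", dataclasses.asdict(cfg))

    stage = "load"
    try:
        recordings = _load_recordings(cfg)
        stage = "extract"
        table = build_feature_table(recordings, cfg)
        audio_io.write_features(table, os.path.join(cfg.report_dir, "features.csv"))

        stage = "balance"
        if cfg.balance_enabled and cfg.balance_pre_split:
            table = balance.adasyn(table, k_neighbors=cfg.balance_k_neighbors, seed=cfg.seed)

        stage = "select"
        selection_info: dict = {"method": cfg.selection_method}
        if cfg.selection_method.startswith("preset:"):
            names = selection.preset_features(cfg.selection_method.split(":", 1)[1])
            table = table.select(names)
            selection_info["retained"] = names
        elif cfg.selection_method == "backward":
            result = selection.backward_eliminate(
                table, _make_evaluator(cfg), min_features=cfg.selection_min_features
            )
            names = [table.feature_names[i] for i in result.retained]
            selection_info.update(
                retained=names,
                history=[(table.feature_names[i], s) for i, s in result.history],
                stop_reason=result.stop_reason,
            )
            table = table.select(names)
        selection_info["n_retained"] = table.n_features

        stage = "evaluate"
        in_fold = cfg.balance_enabled and not cfg.balance_pre_split
        if cfg.eval_protocol == "cv":
            report, per_fold = model.cross_validate(
                table,
                folds=cfg.eval_folds,
                seed=cfg.seed,
                balance_in_fold=in_fold,
                k_neighbors=cfg.balance_k_neighbors,
                reg=cfg.model_reg,
                model_type=cfg.model_type,
            )
            fold_reports = [r.as_dict() for r in per_fold]
        else:
            report = model.holdout_validate(
                table,
                test_fraction=cfg.eval_holdout,
                seed=cfg.seed,
                balance_train=in_fold,
                k_neighbors=cfg.balance_k_neighbors,
                reg=cfg.model_reg,
                model_type=cfg.model_type,
            )
            fold_reports = []
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    run_report = {
        "config": dataclasses.asdict(cfg),
        "n_recordings": len(recordings),
        "selection": selection_info,
        "metrics": report.as_dict(),
        "per_fold": fold_reports,
    }
    with open(os.path.join(cfg.report_dir, "metrics.json"), "w") as fh:
        json.dump(run_report, fh, indent=2, sort_keys=True)
    pd.DataFrame(
        report.confusion.counts,
        index=report.confusion.class_names,
        columns=report.confusion.class_names,
    ).to_csv(os.path.join(cfg.report_dir, "confusion.csv"))
    return run_report
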