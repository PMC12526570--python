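"""End-to-end orchestration: simulate -> preprocess -> windows -> features
-> train -> evaluate, with a validated run configuration and artifact
manifests.  The single global seed deterministically derives every stage's
seed, so a rerun with the same configuration reproduces the same report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .evaluate import evaluate_predictions
from .exceptions import InvalidParameterError
from .model import (
    DualBranchAttentionNet,
    ModelConfig,
    config_from_dict,
    default_config,
    load_checkpoint,
    tiny_config,
)
from .preprocess import PreprocessConfig, preprocess_record
from .spectral import WelchConfig
from .synth import SimParams, make_dataset, save_dataset
from .train import FeatureSet, TrainConfig, TrainHistory, fit
from .windowing import (
    AugmentConfig,
    build_window_sets,
    compute_class_weights,
    stratified_split,
)

__all__ = ["RunConfig", "run_pipeline", "save_features", "load_features"]

_SIMPLE_SIM_FIELDS = {"fs", "duration_s", "noise_sd", "baseline_wander_amp",
                      "baseline_wander_hz", "seed", "amp_jitter_sd",
                      "hr_jitter_sd", "vt_hr_jitter_sd"}


def _build(cls, data: dict, allowed: set[str] | None = None):
    """Construct a flat config dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    if allowed is not None:
        names &= allowed
    unknown = set(data) - names
    if unknown:
        raise InvalidParameterError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**{k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in data.items()})


@dataclass
class RunConfig:
    """Validated, nested run configuration."""

    n_per_class: int = 10
    seed: int = 0
    model_preset: str = "tiny"          # "tiny" | "default"
    epochs: int | None = None           # optional override of train.epochs
    sim: SimParams = None
    preprocess: PreprocessConfig = None
    augment: AugmentConfig = None
    welch: WelchConfig = None
    model: ModelConfig | None = None
    train: TrainConfig = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        errors: list[str] = []
        sections = {}

        def take(key, builder):
            raw = data.pop(key, {}) or {}
            try:
                sections[key] = builder(raw)
            except (InvalidParameterError, TypeError) as exc:
                errors.append(f"{key}: {exc}")

        take("sim", lambda d: _build(SimParams, d, _SIMPLE_SIM_FIELDS))
        take("preprocess", lambda d: _build(PreprocessConfig, d))
        take("augment", lambda d: _build(AugmentConfig, d))
        take("welch", lambda d: _build(WelchConfig, d))
        take("train", lambda d: _build(TrainConfig, d))
        model_raw = data.pop("model", None)
        model_cfg = None
        if model_raw:
            try:
                model_cfg = config_from_dict(model_raw)
            except InvalidParameterError as exc:
                errors.append(f"model: {exc}")
        top = {f.name for f in dataclasses.fields(cls)} - {
            "sim", "preprocess", "augment", "welch", "model", "train"}
        unknown = set(data) - top
        if unknown:
            errors.append(f"unknown top-level keys: {sorted(unknown)}")
        if not errors:
            try:
                sections["sim"].validate()
                sections["preprocess"].validate(sections["sim"].fs)
                sections["augment"].validate()
                sections["welch"].validate()
                sections["train"].validate()
            except InvalidParameterError as exc:
                errors.append(str(exc))
        if errors:
            raise InvalidParameterError(
                "invalid run configuration:\n  " + "\n  ".join(errors))
        return cls(model=model_cfg,
                   **{k: v for k, v in data.items() if k in top},
                   **sections)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def model_config(self) -> ModelConfig:
        if self.model is not None:
            return self.model
        window = int(round(self.augment.window_s * self.sim.fs))
        if self.model_preset == "default":
            return default_config(window_samples=window)
        if self.model_preset == "tiny":
            return tiny_config(window_samples=window)
        raise InvalidParameterError(
            f"unknown model preset {self.model_preset!r}")


def save_features(fs: FeatureSet, path: str | Path) -> None:
    np.savez_compressed(path, x_time=fs.x_time, x_ssm=fs.x_ssm, y=fs.y,
                        source_ids=fs.source_ids.astype(str),
                        split=np.array(fs.split))


def load_features(path: str | Path) -> FeatureSet:
    with np.load(path, allow_pickle=False) as z:
        return FeatureSet(x_time=z["x_time"], x_ssm=z["x_ssm"], y=z["y"],
                          source_ids=z["source_ids"],
                          split=str(z["split"]))


def run_pipeline(cfg: RunConfig, out_dir: str | Path,
                 verbose: bool = False) -> dict:
    """Execute the full pipeline into ``out_dir``; returns artifact paths,
    the training history and the test-set evaluation report.

    Stages whose artifact files already exist in ``out_dir`` are reloaded
    rather than recomputed, so a run is resumable from any completed stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)

    ds_path = out / "dataset.npz"
    if not ds_path.exists():
        records = make_dataset(cfg.n_per_class, sim)
        save_dataset(records, ds_path)
    else:
        from .synth import load_dataset
        records = load_dataset(ds_path)

    feats: dict[str, FeatureSet] = {}
    feat_paths = {s: out / f"features_{s}.npz" for s in ("train", "val",
                                                         "test")}
    if all(p.exists() for p in feat_paths.values()):
        feats = {s: load_features(p) for s, p in feat_paths.items()}
        split_counts = None
    else:
        clean = [preprocess_record(r, cfg.preprocess) for r in records]
        assignment = stratified_split(clean, seed=cfg.seed + 1)
        window_sets = build_window_sets(clean, assignment, cfg.augment)
        split_counts = {s: len(ws) for s, ws in window_sets.items()}
        for split, ws in window_sets.items():
            feats[split] = FeatureSet.from_window_set(ws, cfg.welch)
            save_features(feats[split], feat_paths[split])

    model_cfg = cfg.model_config()
    train_cfg = dataclasses.replace(
        cfg.train, seed=cfg.seed + 3,
        checkpoint_path=str(out / "checkpoint.npz"),
        **({"epochs": cfg.epochs} if cfg.epochs else {}))
    ckpt = out / "checkpoint.npz"
    if ckpt.exists():
        model = load_checkpoint(ckpt)
        history = TrainHistory(checkpoint_path=str(ckpt))
    else:
        model = DualBranchAttentionNet(model_cfg, seed=cfg.seed + 2)
        counts: dict = {}
        for label in feats["train"].y:
            counts[int(label)] = counts.get(int(label), 0) + 1
        weights = compute_class_weights(counts)
        history = fit(model, feats["train"], feats["val"], train_cfg,
                      class_weights=weights, verbose=verbose)

    probs = model.predict_proba(feats["test"].x_time, feats["test"].x_ssm)
    report = evaluate_predictions(feats["test"].y, probs)

    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    report.to_dataframe().to_csv(out / "report.csv", index=False)
    hist_rows = list(zip(history.train_loss, history.train_acc,
                         history.val_loss, history.val_acc, history.lr))
    with open(out / "history.csv", "w") as fh:
        fh.write("epoch,train_loss,train_acc,val_loss,val_acc,lr\n")
        for i, row in enumerate(hist_rows):
            fh.write(f"{i + 1}," + ",".join(f"{v:.6g}" for v in row) + "\n")
    manifest = {
        "seed": cfg.seed,
        "n_per_class": cfg.n_per_class,
        "window_counts": split_counts,
        "ssm_band_edges_hz": np.linspace(
            0.0, sim.fs / 2, cfg.welch.n_bands + 1).tolist(),
        "artifacts": {"dataset": str(ds_path),
                      **{f"features_{s}": str(p)
                         for s, p in feat_paths.items()},
                      "checkpoint": str(ckpt),
                      "report": str(out / "report.json")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"report": report, "history": history, "out_dir": str(out),
            "model": model}
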