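"""End-to-end orchestration: simulate, extract features, train, predict, evaluate.

The pipeline chains the package stages in order (feature extraction ->
standardisation + PCA -> cross-validated ensemble -> evaluation), with a
single YAML-serialisable configuration whose defaults are the workflow's
fixed values.  Every on-disk run writes a resolved copy of its
configuration plus a config hash and the master seed next to its outputs,
so artifacts are reproducible and auditable.  All randomness derives from
one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as features_mod
from .classifier import ShallowEnsembleClassifier
from .image_io import (
    SCLEROTIC,
    AnnotatedRegion,
    DatasetSplit,
    GlomerulusCrop,
    read_annotations,
    load_crops,
    split_by_biopsy,
    write_annotations,
    write_image,
)
from .metrics import classification_metrics, confusion_matrix, round4
from .preprocess import StandardizedPCA
from .synthesis import SynthesisParams, generate_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract-features", "train", "predict", "evaluate")


@dataclass
class PipelineConfig:
    """All tunable parameters of the workflow with their default values."""

    # synthetic data (study conditions)
    synthesis: SynthesisParams = field(default_factory=SynthesisParams)
    # train/test split
    test_fraction: float = 0.2
    # segmentation + texture
    threshold: int = 190
    clean_radius: int = 2
    ac_iterations: int = 200
    kmeans_k: int = 5
    kmeans_replicates: int = 3
    min_region_px: int = 1000
    glcm_distance: int = 1
    glcm_levels: int = 64
    # feature reduction
    pca_variance: float = 0.999
    fit_scope: str = "train_only"  # or "whole_dataset"
    # classifier
    hidden_size: int = 27
    k_folds: int = 10
    inits_per_fold: int = 5
    val_fraction: float = 0.15
    early_stop_window: int = 6
    max_epochs: int = 1000
    threshold_method: str = "b"
    # master seed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fit_scope not in ("train_only", "whole_dataset"):
            raise ValueError("fit_scope must be 'train_only' or 'whole_dataset'")

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthesis"]["glomerulus_radius_range"] = list(
            d["synthesis"]["glomerulus_radius_range"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = dict(d.pop("synthesis", {}))
        if "glomerulus_radius_range" in syn:
            syn["glomerulus_radius_range"] = tuple(syn["glomerulus_radius_range"])
        known = {f.name for f in dataclasses.fields(cls)} - {"synthesis"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(synthesis=SynthesisParams(**syn), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def feature_params(self) -> dict:
        return dict(
            threshold=self.threshold,
            clean_radius=self.clean_radius,
            ac_iterations=self.ac_iterations,
            kmeans_k=self.kmeans_k,
            kmeans_replicates=self.kmeans_replicates,
            min_region_px=self.min_region_px,
            glcm_distance=self.glcm_distance,
            glcm_levels=self.glcm_levels,
        )


# ---------------------------------------------------------------------------
# in-memory experiment (generation -> split -> features -> model -> metrics)


def run_experiment(config: PipelineConfig | None = None, seed: int | None = None) -> dict:
    """Full in-memory run on synthetic data; returns the evaluation report.

    ``seed`` (if given) overrides the master seed; it drives data
    generation, the biopsy-level split and all classifier randomness.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(
            config, seed=seed,
            synthesis=dataclasses.replace(config.synthesis, seed=seed),
        )
    t0 = time.perf_counter()
    crops = generate_dataset(config.synthesis)
    split = split_by_biopsy(crops, config.test_fraction, seed=config.seed)
    logger.info(
        "generated %d crops (%d train / %d test biopsies)",
        len(crops), len(split.train_biopsies), len(split.test_biopsies),
    )
    train_tbl = features_mod.extract_feature_table(
        split.train, **config.feature_params()
    )
    test_tbl = features_mod.extract_feature_table(
        split.test, **config.feature_params()
    )
    report = fit_and_evaluate(train_tbl, test_tbl, config)
    report["runtime_s"] = round(time.perf_counter() - t0, 2)
    report["n_train"] = len(train_tbl)
    report["n_test"] = len(test_tbl)
    return report


def fit_and_evaluate(
    train_tbl: pd.DataFrame, test_tbl: pd.DataFrame, config: PipelineConfig
) -> dict:
    """Reduction + classification + evaluation on pre-extracted features."""
    cols = features_mod.feature_names()
    X_train = train_tbl[cols].to_numpy(float)
    X_test = test_tbl[cols].to_numpy(float)
    y_train = train_tbl["label"].to_numpy()
    y_test = test_tbl["label"].to_numpy()

    reducer = StandardizedPCA(config.pca_variance)
    if config.fit_scope == "whole_dataset":
        reducer.fit(np.vstack([X_train, X_test]))
    else:
        reducer.fit(X_train)
    Z_train = reducer.transform(X_train)
    Z_test = reducer.transform(X_test)

    clf = ShallowEnsembleClassifier(
        hidden_size=config.hidden_size,
        k=config.k_folds,
        inits_per_fold=config.inits_per_fold,
        val_fraction=config.val_fraction,
        early_stop_window=config.early_stop_window,
        max_epochs=config.max_epochs,
        threshold_method=config.threshold_method,
        pos_label=SCLEROTIC,
        random_state=config.seed,
    ).fit(Z_train, y_train)

    y_pred = clf.predict(Z_test)
    cm = confusion_matrix(y_test, y_pred, pos_label=SCLEROTIC)
    metrics = classification_metrics(cm)
    per_biopsy = {}
    for biopsy in sorted(set(test_tbl["biopsy_id"])):
        idx = (test_tbl["biopsy_id"] == biopsy).to_numpy()
        bcm = confusion_matrix(y_test[idx], y_pred[idx], pos_label=SCLEROTIC)
        per_biopsy[biopsy] = {"TP": bcm.TP, "FP": bcm.FP, "FN": bcm.FN, "TN": bcm.TN}
    return {
        "confusion_matrix": {"TP": cm.TP, "FP": cm.FP, "FN": cm.FN, "TN": cm.TN},
        "metrics": {m: round4(metrics[m]) for m in ("accuracy", "precision", "recall", "mcc")},
        "metrics_raw": {m: metrics[m] for m in ("accuracy", "precision", "recall", "mcc")},
        "flags": metrics["flags"],
        "n_pca_components": int(reducer.n_components_),
        "fold_thresholds": [fm.threshold for fm in clf.fold_models_],
        "fold_validation_mcc": [fm.validation_mcc for fm in clf.fold_models_],
        "per_biopsy": per_biopsy,
    }


def stability_experiment(
    config: PipelineConfig | None = None, n_runs: int = 10, base_seed: int = 0
) -> pd.DataFrame:
    """Repeat the full run over independent seeds; mean/std of the metrics."""
    rows = []
    for i in range(n_runs):
        rep = run_experiment(config, seed=base_seed + i)
        rows.append({"seed": base_seed + i, **rep["metrics_raw"]})
    df = pd.DataFrame(rows)
    summary = df[["accuracy", "precision", "recall", "mcc"]].agg(["mean", "std"])
    logger.info("stability over %d runs:\n%s", n_runs, summary)
    return df


# ---------------------------------------------------------------------------
# on-disk staged pipeline


def _stamp(outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    (outdir / "run_info.json").write_text(
        json.dumps({"config_hash": config.config_hash(), "seed": config.seed}, indent=1)
    )


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run the '{producer}' stage first"
        )
    return path


def stage_simulate(config: PipelineConfig, workdir: Path) -> Path:
    """Write synthetic PNG crops plus the annotation JSON."""
    outdir = workdir / "crops"
    outdir.mkdir(parents=True, exist_ok=True)
    crops = generate_dataset(config.synthesis)
    regions = []
    for i, crop in enumerate(crops):
        name = f"glom_{i:04d}.png"
        write_image(crop.pixels, outdir / name)
        h, w = crop.shape
        # inset rectangle whose 1.1-overestimated box recovers the full crop
        mx, my = w / 2 * (1 - 1 / 1.1), h / 2 * (1 - 1 / 1.1)
        regions.append(
            AnnotatedRegion(
                polygon=((mx, my), (w - mx, my), (w - mx, h - my), (mx, h - my)),
                label=crop.label,
                biopsy_id=crop.biopsy_id,
                section_id=crop.section_id,
                slide_path=name,
            )
        )
    write_annotations(regions, outdir / "annotations.json")
    _stamp(workdir, config)
    return outdir


def stage_extract_features(config: PipelineConfig, workdir: Path) -> Path:
    annotations = _require(workdir / "crops" / "annotations.json", "simulate")
    crops = load_crops(read_annotations(annotations))
    t0 = time.perf_counter()
    table = features_mod.extract_feature_table(crops, **config.feature_params())
    logger.info(
        "extracted %d x %d features in %.1fs (%.2fs/crop)",
        len(table), features_mod.N_FEATURES,
        time.perf_counter() - t0, (time.perf_counter() - t0) / max(len(table), 1),
    )
    out = workdir / "features.csv"
    table.to_csv(out, index=False, float_format="%.10g")
    return out


def stage_train(config: PipelineConfig, workdir: Path) -> Path:
    feats = _require(workdir / "features.csv", "extract-features")
    table = pd.read_csv(feats)
    crops_by_row = table["biopsy_id"].to_numpy()
    # biopsy-level split on the feature rows
    dummy = [
        GlomerulusCrop(np.zeros((1, 1, 3), np.uint8), lab, b)
        for lab, b in zip(table["label"], crops_by_row)
    ]
    split = split_by_biopsy(dummy, config.test_fraction, seed=config.seed)
    test_ids = split.test_biopsies
    is_test = table["biopsy_id"].isin(test_ids)
    report = fit_and_evaluate(table[~is_test], table[is_test], config)

    # persist: the report and the split; networks are retrained on demand
    outdir = workdir / "model"
    outdir.mkdir(exist_ok=True)
    (outdir / "split.json").write_text(
        json.dumps({"test_biopsies": sorted(test_ids)}, indent=1)
    )
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    _stamp(workdir, config)
    return outdir


def stage_predict(config: PipelineConfig, workdir: Path) -> Path:
    feats = _require(workdir / "features.csv", "extract-features")
    model_dir = _require(workdir / "model" / "split.json", "train").parent
    table = pd.read_csv(feats)
    test_ids = set(json.loads((model_dir / "split.json").read_text())["test_biopsies"])
    is_test = table["biopsy_id"].isin(test_ids)
    train_tbl, test_tbl = table[~is_test], table[is_test]

    cols = features_mod.feature_names()
    reducer = StandardizedPCA(config.pca_variance)
    X_train = train_tbl[cols].to_numpy(float)
    if config.fit_scope == "whole_dataset":
        reducer.fit(table[cols].to_numpy(float))
    else:
        reducer.fit(X_train)
    clf = ShallowEnsembleClassifier(
        hidden_size=config.hidden_size, k=config.k_folds,
        inits_per_fold=config.inits_per_fold, val_fraction=config.val_fraction,
        early_stop_window=config.early_stop_window, max_epochs=config.max_epochs,
        threshold_method=config.threshold_method, pos_label=SCLEROTIC,
        random_state=config.seed,
    ).fit(reducer.transform(X_train), train_tbl["label"].to_numpy())
    preds = clf.predict(reducer.transform(test_tbl[cols].to_numpy(float)))

    out = workdir / "predictions.csv"
    pd.DataFrame({
        "biopsy_id": test_tbl["biopsy_id"],
        "label": test_tbl["label"],
        "predicted": preds,
    }).to_csv(out, index=False)
    return out


def stage_evaluate(config: PipelineConfig, workdir: Path) -> Path:
    preds = _require(workdir / "predictions.csv", "predict")
    df = pd.read_csv(preds)
    cm = confusion_matrix(df["label"], df["predicted"], pos_label=SCLEROTIC)
    metrics = classification_metrics(cm)
    per_biopsy = {
        b: {k: int(v) for k, v in zip(
            ("TP", "FP", "FN", "TN"),
            (lambda c: (c.TP, c.FP, c.FN, c.TN))(
                confusion_matrix(g["label"], g["predicted"], pos_label=SCLEROTIC)
            ),
        )}
        for b, g in df.groupby("biopsy_id")
    }
    out = workdir / "metrics.json"
    out.write_text(json.dumps({
        "confusion_matrix": {"TP": cm.TP, "FP": cm.FP, "FN": cm.FN, "TN": cm.TN},
        "metrics": {m: round4(metrics[m]) for m in ("accuracy", "precision", "recall", "mcc")},
        "flags": metrics["flags"],
        "per_biopsy": per_biopsy,
    }, indent=1))
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract-features": stage_extract_features,
    "train": stage_train,
    "predict": stage_predict,
    "evaluate": stage_evaluate,
}


def run_pipeline(
    config: PipelineConfig, workdir: str | Path, stages: list[str] | None = None
) -> dict[str, Path]:
    """Execute the requested stages in order; returns artifact paths."""
    workdir = Path(workdir)
    stages = list(stages) if stages else list(STAGES)
    for s in stages:
        if s not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    stages = [s for s in STAGES if s in stages]
    artifacts = {}
    for s in stages:
        t0 = time.perf_counter()
        artifacts[s] = _STAGE_FUNCS[s](config, workdir)
        logger.info("stage %s done in %.1fs", s, time.perf_counter() - t0)
    return artifacts
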