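"""Experiment-grid orchestration: preprocess x selector x model.

``run_experiment`` mirrors the full study design: simulate (or load) the
dataset, hold out whole boxes per variety, then for every combination apply
the stateless preprocessor, select bands on the training partition only,
cross-validate and fit the classifier on training data, and evaluate on the
held-out boxes. Every artifact (selection JSON, metric tables, predictions,
report row) is written under a run directory with a manifest recording the
seeds and a config hash; rerunning a partially completed grid reuses finished
combinations byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import os
import traceback
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import feature_selection as fs
from . import models as mdl
from .acquisition import box_level_split
from .datasets import SpectralDataset
from .evaluation import confusion, metrics
from .preprocessing import PREPROCESS_METHODS, PreprocessConfig, apply_preprocess
from .synthetic_data import NoiseModel, SceneDesign, make_templates, simulate_dataset

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "summarize_best"]

SELECTOR_NAMES = ("NONE", "SPA", "CARS", "UVE", "IVISSA")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment grid."""

    # data source: a dataset CSV path, or synthetic-generation parameters
    dataset_path: str | None = None
    n_varieties: int = 13
    boxes_per_variety: int = 10
    grid_rows: int = 4
    grid_cols: int = 7
    separation_scale: float | None = None  # None -> generator default
    noise: dict = field(default_factory=dict)

    preprocess_methods: list = field(default_factory=lambda: ["SNV"])
    selectors: list = field(default_factory=lambda: ["NONE"])
    models: list = field(default_factory=lambda: ["PLS-DA"])

    test_boxes_per_class: int = 2
    cv_folds: int = 4
    run_cv: bool = True
    selection_on_all: bool = False  # leakage-prone; off by default
    epochs: int = 1000
    seed: int = 0
    out_dir: str = "runs/experiment"
    selector_params: dict = field(default_factory=dict)
    model_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.preprocess_methods and self.selectors and self.models):
            raise ValueError("method lists must be non-empty")
        for m in self.preprocess_methods:
            if m not in PREPROCESS_METHODS:
                raise ValueError(f"unknown preprocess method {m!r}")
        for s in self.selectors:
            if s not in SELECTOR_NAMES:
                raise ValueError(f"unknown selector {s!r}")
        for m in self.models:
            if m not in mdl.MODEL_KINDS:
                raise ValueError(f"unknown model {m!r}")
        if self.dataset_path is not None and not os.path.exists(self.dataset_path):
            raise FileNotFoundError(self.dataset_path)

    @classmethod
    def from_file(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.endswith((".yml", ".yaml")) else json.load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """One row per (preprocess, selector, model) combination."""

    table: pd.DataFrame
    run_dir: str
    manifest: dict

    def successful(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "ok"]


def _load_dataset(cfg: ExperimentConfig) -> SpectralDataset:
    if cfg.dataset_path:
        return SpectralDataset.from_csv(cfg.dataset_path)
    design = SceneDesign(
        n_varieties=cfg.n_varieties,
        boxes_per_variety=cfg.boxes_per_variety,
        grid_rows=cfg.grid_rows,
        grid_cols=cfg.grid_cols,
    )
    kwargs = {} if cfg.separation_scale is None else {"separation_scale": cfg.separation_scale}
    templates = make_templates(cfg.n_varieties, seed=cfg.seed, **kwargs)
    return simulate_dataset(templates, design, NoiseModel(**cfg.noise), seed=cfg.seed)


def _select_bands(name, X, y, seed, params):
    p = X.shape[1]
    kw = dict(params.get(name, {}))
    if name == "NONE":
        return fs.SelectionResult(np.arange(p), np.ones(p), [], "NONE", seed, p)
    if name == "SPA":
        kw.setdefault("n_select", max(2, p // 15))
        kw.setdefault("candidate_starts", np.linspace(0, p - 1, num=min(p, 8), dtype=int))
        return fs.spa(X, y=y, seed=seed, **kw)
    if name == "CARS":
        kw.setdefault("n_runs", 30)
        return fs.cars(X, y, seed=seed, **kw)
    if name == "UVE":
        return fs.uve(X, y, seed=seed, **kw)
    if name == "IVISSA":
        kw.setdefault("n_iterations", 5)
        kw.setdefault("n_submodels", 20)
        return fs.ivissa(X, y, seed=seed, **kw)
    raise ValueError(name)


def _train_model(kind, X, y, cfg: ExperimentConfig):
    kw = dict(cfg.model_params.get(kind, {}))
    if kind == "PLS-DA":
        return mdl.train_plsda(X, y, seed=cfg.seed, **kw)
    if kind == "SVM":
        return mdl.train_svm(X, y, seed=cfg.seed, **kw)
    tc = mdl.TrainConfig(epochs=kw.pop("epochs", cfg.epochs), seed=cfg.seed,
                         **{k: v for k, v in kw.items() if k in ("learning_rate", "dropout", "batch_size")})
    if kind == "1D-CNN":
        return mdl.train_1dcnn(X, y, cfg=tc)
    if kind == "CNN-Transformer":
        return mdl.train_cnn_transformer(X, y, cfg=tc)
    raise ValueError(kind)


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Execute the grid; per-cell failures are recorded, not fatal."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    dataset = _load_dataset(cfg)
    split = box_level_split(dataset, cfg.test_boxes_per_class, seed=cfg.seed)
    train, test = dataset.subset(split.train_idx), dataset.subset(split.test_idx)
    wl = dataset.wavelengths.values

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_train": train.n_samples,
        "n_test": test.n_samples,
        "held_out_boxes": split.held_out_boxes,
        "train_box_ids": sorted(set(train.box_id.tolist())),
    }
    rows = []
    for prep in cfg.preprocess_methods:
        pc = PreprocessConfig(method=prep)
        Xtr = apply_preprocess(train.reflectance, pc, wl)
        Xte = apply_preprocess(test.reflectance, pc, wl)
        sel_X, sel_y = (
            (np.vstack([Xtr, Xte]), np.concatenate([train.labels, test.labels]))
            if cfg.selection_on_all
            else (Xtr, train.labels)
        )
        for selector in cfg.selectors:
            for model_kind in cfg.models:
                key = f"{prep}_{selector}_{model_kind}".replace(" ", "")
                cell_dir = os.path.join(cfg.out_dir, "cells", key)
                row_path = os.path.join(cell_dir, "row.json")
                if os.path.exists(row_path):  # crash-resume: reuse finished cell
                    with open(row_path) as fh:
                        rows.append(json.load(fh))
                    continue
                os.makedirs(cell_dir, exist_ok=True)
                row = {"preprocess": prep, "selector": selector, "model": model_kind}
                try:
                    sel = _select_bands(selector, sel_X, sel_y, cfg.seed, cfg.selector_params)
                    sel.to_json(os.path.join(cell_dir, "selection.json"), wl)
                    bands = sel.selected_idx
                    Xtr_s, Xte_s = Xtr[:, bands], Xte[:, bands]

                    cv_acc = None
                    if cfg.run_cv:
                        cv = mdl.cross_validate(
                            lambda A, b: _train_model(model_kind, A, b, cfg),
                            Xtr_s, train.labels, k=cfg.cv_folds, seed=cfg.seed,
                            groups=train.box_id,
                        )
                        cv_acc = 100 * cv["mean_accuracy"]
                    model = _train_model(model_kind, Xtr_s, train.labels, cfg)

                    y_pred = model.predict(Xte_s)
                    cm = confusion(test.labels, y_pred, labels=np.unique(dataset.labels))
                    rep = metrics(cm, averaging="weighted")
                    cm.to_csv(os.path.join(cell_dir, "confusion.csv"))
                    rep.to_csv(os.path.join(cell_dir, "per_class_metrics.csv"))
                    pd.DataFrame(
                        {"true": test.labels, "predicted": y_pred, "box_id": test.box_id}
                    ).to_csv(os.path.join(cell_dir, "predictions.csv"), index=False)

                    row.update(
                        status="ok",
                        n_selected=sel.n_selected,
                        reduction_pct=fs.reduction_percentage(sel.n_selected, sel.n_bands),
                        cv_accuracy=cv_acc,
                        train_accuracy=100 * model.accuracy(Xtr_s, train.labels),
                        test_accuracy=rep.accuracy,
                        precision=rep.precision,
                        recall=rep.recall,
                        f1=rep.f1,
                    )
                except Exception as exc:  # isolate per-cell failures
                    row.update(status=f"failed: {exc}", n_selected=None, reduction_pct=None,
                               cv_accuracy=None, train_accuracy=None, test_accuracy=None,
                               precision=None, recall=None, f1=None)
                    with open(os.path.join(cell_dir, "error.txt"), "w") as fh:
                        fh.write(traceback.format_exc())
                with open(row_path, "w") as fh:
                    json.dump(row, fh, indent=1)
                rows.append(row)

    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(cfg.out_dir, "report.csv"), index=False)
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return ExperimentReport(table=table, run_dir=cfg.out_dir, manifest=manifest)


def summarize_best(report: ExperimentReport) -> dict:
    """Best grid cell: max test F1; ties broken by test accuracy, then by
    fewer selected bands."""
    ok = report.successful()
    if ok.empty:
        raise ValueError("no successful combinations in the report")
    ranked = ok.sort_values(
        by=["f1", "test_accuracy", "n_selected"],
        ascending=[False, False, True],
        kind="stable",
    )
    return ranked.iloc[0].to_dict()
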