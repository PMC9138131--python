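"""Experiment orchestration: projection x classifier error grid and the
training-position-reduction study.

Two experiments are provided:

* ``run_projection_classifier_grid`` — every pairing of the four
  projections with the seven classifiers, per subject, under five-fold
  cross-validation, plus SI/MSA of each projection's full-data output.
* ``run_position_reduction`` — train on windows from a growing subset of
  placement positions (a fixed 80/20 within-position split), test on the
  held-out windows of those positions plus all windows of the remaining
  positions, and track classification error, SI of the projected training
  data and RI between training and testing class means.

All stochastic stages (generation, fold shuffling, SRELM hidden nodes,
t-SNE and NN initialization) derive from the experiment seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd
import yaml

from emgrasp.classify import (CLASSIFIER_KINDS, ClassifierSpec,
                              _fit_projection, make_classifier, make_folds)
from emgrasp.features import (FeatureDataset, SymmetricMinMaxScaler, extract)
from emgrasp.metrics import (classification_error, mean_semi_principal_axis,
                             repeatability_index, separability_index)
from emgrasp.preprocess import preprocess_and_segment
from emgrasp.projection import (DEFAULT_K, PROJECTION_METHODS, LDAProjector,
                                PCAProjector, SRELMProjector, TSNEEmbedder)
from emgrasp.simulate import GeneratorConfig, generate_dataset

# Position subsets of the reference reduction schedule, best set per count.
POSITION_SCHEDULE: tuple[tuple[str, ...], ...] = (
    ("P5",),
    ("P5", "P9"),
    ("P1", "P5", "P9"),
    ("P1", "P3", "P5", "P9"),
    ("P1", "P3", "P5", "P8", "P9"),
    ("P1", "P3", "P4", "P6", "P7", "P9"),
    ("P1", "P2", "P3", "P4", "P6", "P7", "P9"),
    ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P9"),
    ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "P9"),
)


@dataclass
class ExperimentConfig:
    """Everything needed to rerun an experiment from a seed."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    projections: tuple[str, ...] = PROJECTION_METHODS
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    n_folds: int = 5
    k: int = DEFAULT_K
    window_stride: int = 1
    srelm_nodes: int = 1000
    srelm_alpha: float = 1.0
    tsne_perplexity: float = 30.0
    tsne_iterations: int = 1000
    position_schedule: tuple[tuple[str, ...], ...] = POSITION_SCHEDULE
    reduction_projection: str = "SRELM"
    reduction_classifier: str = "NN"
    seed: int = 0

    def validate(self) -> None:
        self.generator.validate()
        for proj in set(self.projections) | {self.reduction_projection}:
            if proj.upper() not in PROJECTION_METHODS:
                raise ValueError(f"unknown projection {proj!r}")
        for clf in set(self.classifiers) | {self.reduction_classifier}:
            if clf not in CLASSIFIER_KINDS:
                raise ValueError(f"unknown classifier {clf!r}")
        all_positions = set(self.generator.positions)
        for subset in self.position_schedule:
            if not subset:
                raise ValueError("empty position subset in schedule")
            unknown = set(subset) - all_positions
            if unknown:
                raise ValueError(f"unknown positions {sorted(unknown)}")
        if self.window_stride < 1:
            raise ValueError("window_stride must be >= 1")

    def projection_params(self, method: str) -> dict:
        method = method.upper()
        if method == "SRELM":
            return {"L": self.srelm_nodes, "alpha": self.srelm_alpha}
        if method == "TSNE":
            return {"perplexity": self.tsne_perplexity,
                    "n_iter": self.tsne_iterations}
        return {}


_CONFIG_KEYS = {
    "generator", "projections", "classifiers", "n_folds", "k",
    "window_stride", "srelm_nodes", "srelm_alpha", "tsne_perplexity",
    "tsne_iterations", "position_schedule", "reduction_projection",
    "reduction_classifier", "seed",
}
_GENERATOR_KEYS = {
    "n_subjects", "n_reps", "grasp_classes", "positions", "emg_rate",
    "imu_rate", "grasp_duration", "class_separation", "position_effect",
    "noise_sd", "seed",
}


def config_from_dict(raw: dict) -> ExperimentConfig:
    """Build a validated config from a plain mapping (YAML/JSON payload);
    unknown keys are rejected by name."""
    raw = dict(raw)
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key: {sorted(unknown)[0]}")
    gen_raw = dict(raw.pop("generator", {}))
    unknown = set(gen_raw) - _GENERATOR_KEYS
    if unknown:
        raise ValueError(f"unknown config key: generator.{sorted(unknown)[0]}")
    for key in ("grasp_classes", "positions"):
        if key in gen_raw:
            gen_raw[key] = tuple(gen_raw[key])
    if "projections" in raw:
        raw["projections"] = tuple(raw["projections"])
    if "classifiers" in raw:
        raw["classifiers"] = tuple(raw["classifiers"])
    if "position_schedule" in raw:
        raw["position_schedule"] = tuple(
            tuple(subset) for subset in raw["position_schedule"])
    config = ExperimentConfig(generator=GeneratorConfig(**gen_raw), **raw)
    config.validate()
    return config


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a YAML (or JSON, a YAML subset) experiment config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(raw)


@dataclass
class ExperimentResult:
    """Long-format per-cell records plus recomputable aggregates."""

    records: pd.DataFrame
    metrics: pd.DataFrame | None = None

    def aggregate(self, by: list[str] | None = None) -> pd.DataFrame:
        by = by or ["projection", "classifier"]
        return (self.records.groupby(by)["error_percent"]
                .agg(["mean", "std"]).reset_index())

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out_dir / "records.csv", index=False)
        self.aggregate().to_csv(out_dir / "aggregate.csv", index=False)
        if self.metrics is not None:
            self.metrics.to_csv(out_dir / "metrics.csv", index=False)


def build_feature_datasets(config: ExperimentConfig) -> dict[int, FeatureDataset]:
    """Generate, filter, segment and featurize; one dataset per subject."""
    recordings = generate_dataset(config.generator)
    datasets: dict[int, FeatureDataset] = {}
    for subject in sorted({rec.subject for rec in recordings}):
        windows = preprocess_and_segment(
            [rec for rec in recordings if rec.subject == subject],
            window_stride=config.window_stride)
        datasets[subject] = extract(windows)
    return datasets


def _full_data_projection_metrics(config: ExperimentConfig, subject: int,
                                  data: FeatureDataset) -> list[dict]:
    """SI/MSA of each projection fitted on the subject's full dataset."""
    y = data.grasp
    X = SymmetricMinMaxScaler().fit(data.X).transform(data.X)
    rows = []
    for method in config.projections:
        method = method.upper()
        params = config.projection_params(method)
        if method == "PCA":
            Y = PCAProjector(k=config.k).fit(X).transform(X)
        elif method == "LDA":
            Y = LDAProjector(k=config.k).fit(X, y).transform(X)
        elif method == "SRELM":
            Y = SRELMProjector(seed=config.seed, **params).fit(X, y).transform(X)
        else:
            Y = TSNEEmbedder(k=config.k, seed=config.seed,
                             **params).fit_transform(X)
        rows.append({"subject": subject, "projection": method,
                     "SI": separability_index(Y, y),
                     "MSA": mean_semi_principal_axis(Y, y)})
    return rows


def run_projection_classifier_grid(config: ExperimentConfig,
                                   datasets: dict[int, FeatureDataset] | None = None,
                                   compute_metrics: bool = True) -> ExperimentResult:
    """The full projection x classifier error grid, per subject.

    Yields len(projections) * len(classifiers) * n_folds records per
    subject; a failed cell is recorded with error_percent = NaN and the
    exception message rather than dropped.
    """
    config.validate()
    datasets = datasets or build_feature_datasets(config)
    records, metric_rows = [], []
    for subject, data in datasets.items():
        folds = make_folds(data, config.n_folds, seed=config.seed)
        y = data.grasp
        for method in config.projections:
            method = method.upper()
            params = config.projection_params(method)
            for fold_id in sorted(np.unique(folds)):
                test_mask = folds == fold_id
                train_mask = ~test_mask
                # the projection is shared by all classifiers of the cell
                # column, so fit it once per fold
                try:
                    scaler = SymmetricMinMaxScaler().fit(data.X[train_mask])
                    Y_train, Y_test = _fit_projection(
                        method, scaler.transform(data.X[train_mask]),
                        scaler.transform(data.X[test_mask]), y[train_mask],
                        config.k, config.seed, params)
                    projection_error = None
                except Exception as exc:
                    projection_error = exc
                for kind in config.classifiers:
                    record = {"subject": subject, "projection": method,
                              "classifier": kind, "fold": int(fold_id)}
                    try:
                        if projection_error is not None:
                            raise projection_error
                        clf = make_classifier(
                            ClassifierSpec(kind, seed=config.seed))
                        clf.fit(Y_train, y[train_mask])
                        record["error_percent"] = classification_error(
                            y[test_mask], clf.predict(Y_test))
                        record["status"] = "ok"
                    except Exception as exc:  # record failure, keep going
                        record["error_percent"] = np.nan
                        record["status"] = f"failed: {exc}"
                    records.append(record)
        if compute_metrics:
            metric_rows.extend(_full_data_projection_metrics(config, subject, data))
    return ExperimentResult(
        records=pd.DataFrame(records),
        metrics=pd.DataFrame(metric_rows) if metric_rows else None)


def _position_split(data: FeatureDataset, training_positions: tuple[str, ...],
                    seed: int, train_fraction: float = 0.8
                    ) -> tuple[np.ndarray, np.ndarray]:
    """80/20 split within each training position; every window of every
    non-training position goes to the test side."""
    rng = np.random.default_rng(seed)
    positions = data.position
    train_mask = np.zeros(data.n, dtype=bool)
    for pos in training_positions:
        idx = np.flatnonzero(positions == pos)
        if idx.size == 0:
            raise ValueError(f"no windows at position {pos!r}")
        rng.shuffle(idx)
        n_train = int(round(train_fraction * idx.size))
        train_mask[idx[:n_train]] = True
    test_mask = ~train_mask
    return train_mask, test_mask


def run_position_reduction(config: ExperimentConfig,
                           datasets: dict[int, FeatureDataset] | None = None
                           ) -> ExperimentResult:
    """Training-position-reduction experiment along the position schedule.

    For every subset: train the projection + classifier on the subset's
    windows only, evaluate on held-out windows of all nine positions, and
    record the error together with SI (projected training data) and RI
    (training-subset vs full-test class means in projected space).
    """
    config.validate()
    datasets = datasets or build_feature_datasets(config)
    method = config.reduction_projection.upper()
    params = config.projection_params(method)
    spec = ClassifierSpec(config.reduction_classifier, seed=config.seed)
    records = []
    for subject, data in datasets.items():
        y = data.grasp
        for subset in config.position_schedule:
            train_mask, test_mask = _position_split(data, subset, config.seed)
            scaler = SymmetricMinMaxScaler().fit(data.X[train_mask])
            X_train = scaler.transform(data.X[train_mask])
            X_test = scaler.transform(data.X[test_mask])
            if method == "PCA":
                model = PCAProjector(k=config.k).fit(X_train)
                Y_train, Y_test = model.transform(X_train), model.transform(X_test)
            elif method == "LDA":
                model = LDAProjector(k=config.k).fit(X_train, y[train_mask])
                Y_train, Y_test = model.transform(X_train), model.transform(X_test)
            elif method == "SRELM":
                model = SRELMProjector(seed=config.seed, **params).fit(
                    X_train, y[train_mask])
                Y_train, Y_test = model.transform(X_train), model.transform(X_test)
            else:
                stacked = np.vstack([X_train, X_test])
                Y = TSNEEmbedder(k=config.k, seed=config.seed,
                                 **params).fit_transform(stacked)
                Y_train, Y_test = Y[:len(X_train)], Y[len(X_train):]
            clf = make_classifier(spec)
            clf.fit(Y_train, y[train_mask])
            error = classification_error(y[test_mask], clf.predict(Y_test))
            records.append({
                "subject": subject,
                "projection": method,
                "classifier": config.reduction_classifier,
                "n_training_positions": len(subset),
                "training_positions": "-".join(subset),
                "error_percent": error,
                "SI": separability_index(Y_train, y[train_mask]),
                "RI": repeatability_index(Y_train, y[train_mask],
                                          Y_test, y[test_mask]),
            })
    return ExperimentResult(records=pd.DataFrame(records))


def run_manifest(config: ExperimentConfig) -> dict:
    """JSON-serializable record of the configuration and seeds."""
    payload = asdict(config)
    payload["generator"] = asdict(config.generator)
    return {"config": payload,
            "config_hash": hash(json.dumps(payload, sort_keys=True, default=str))}
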