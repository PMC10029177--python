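"""Gradient-boosted-tree pathogenicity classifiers.

Five-tier (benign … pathogenic) and binary (benign vs pathogenic) XGBoost
models are trained separately for loss and gain CNVs. Hyperparameters
(eta, gamma, max_depth, min_child_weight, subsample, nrounds) are tuned by
seeded random search under stratified k-fold cross-validation, maximizing
mean one-vs-rest AUC (plain AUC for the binary task); all other XGBoost
parameters stay at their defaults. Data are split 7:3 into training and
test cohorts, stratified by class.

A trained model is a self-describing text archive: the boosted ensemble
plus task metadata, the imputation medians fitted on its training
partition, the feature-registry fingerprint it expects, and the training
seed. Prediction refuses matrices with a different registry fingerprint
and imputes missing cells with the stored medians. Class ties break toward
the more pathogenic class (clinical conservatism).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold, train_test_split

from .annotate import FeatureMatrix, apply_impute
from .core import FIVE_TIER_ORDER, CNVType, Label
from .metrics import roc_auc

BINARY_ORDER: tuple[Label, ...] = (Label.BENIGN, Label.PATHOGENIC)


@dataclass(frozen=True)
class TaskSpec:
    task: str  # "five_tier" | "binary"
    cnv_type: CNVType

    def __post_init__(self) -> None:
        if self.task not in ("five_tier", "binary"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def classes(self) -> tuple[Label, ...]:
        """Class alphabet ordered least → most pathogenic."""
        return FIVE_TIER_ORDER if self.task == "five_tier" else BINARY_ORDER

    @property
    def positive_class(self) -> Label:
        return Label.PATHOGENIC


@dataclass
class Hyperparameters:
    eta: float = 0.3
    gamma: float = 0.0
    max_depth: int = 6
    min_child_weight: float = 1.0
    subsample: float = 1.0
    nrounds: int = 100

    def to_xgb_params(self) -> dict:
        return {"eta": self.eta, "gamma": self.gamma, "max_depth": self.max_depth,
                "min_child_weight": self.min_child_weight, "subsample": self.subsample}


#: search-space bounds for random search; user-overridable
DEFAULT_SEARCH_SPACE: dict[str, tuple] = {
    "eta": ("loguniform", 0.01, 0.3),
    "gamma": ("uniform", 0.0, 5.0),
    "max_depth": ("int", 2, 10),
    "min_child_weight": ("uniform", 1.0, 10.0),
    "subsample": ("uniform", 0.5, 1.0),
    "nrounds": ("int", 50, 1000),
}


def _encode_labels(labels: Sequence[Label], task: TaskSpec) -> np.ndarray:
    index = {c: i for i, c in enumerate(task.classes)}
    try:
        return np.array([index[Label(l)] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]} outside task alphabet "
                         f"{[c.value for c in task.classes]}") from None


@dataclass
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray


def split_dataset(matrix: FeatureMatrix, labels: Sequence[Label],
                  ratio: float = 0.7, seed: int = 0) -> SplitResult:
    """Stratified train/test split (default 7:3), reproducible for a seed."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"split ratio must be in (0,1), got {ratio}")
    y = np.array([Label(l).value for l in labels], dtype=object)
    if len(y) != len(matrix.ids):
        raise ValueError("labels not aligned to matrix rows")
    classes, counts = np.unique(y, return_counts=True)
    for c, n in zip(classes, counts):
        if n < 2:
            raise ValueError(f"class {c!r} has {n} member(s); cannot stratify")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, train_size=ratio, stratify=y, random_state=seed)
    return SplitResult(np.sort(tr), np.sort(te))


def _fit_booster(X: np.ndarray, y: np.ndarray, task: TaskSpec,
                 hp: Hyperparameters, seed: int) -> xgb.Booster:
    params = hp.to_xgb_params()
    params.update({"seed": int(seed), "nthread": 1, "tree_method": "hist",
                   "verbosity": 0})
    if task.task == "binary":
        params["objective"] = "binary:logistic"
    else:
        params.update({"objective": "multi:softprob",
                       "num_class": len(task.classes)})
    dtrain = xgb.DMatrix(X, label=y)
    return xgb.train(params, dtrain, num_boost_round=hp.nrounds)


def _proba(booster: xgb.Booster, X: np.ndarray, n_classes: int) -> np.ndarray:
    p = booster.predict(xgb.DMatrix(X))
    if p.ndim == 1:  # binary: probability of the pathogenic class
        p = np.column_stack([1.0 - p, p])
    return p


def cv_objective(X: np.ndarray, y: np.ndarray, task: TaskSpec,
                 hp: Hyperparameters, cv_folds: int, seed: int) -> float:
    """Mean cross-validated objective: one-vs-rest AUC averaged over classes
    present in each held-out fold (plain AUC for binary)."""
    classes, counts = np.unique(y, return_counts=True)
    if cv_folds > counts.min():
        raise ValueError(
            f"cv_folds={cv_folds} exceeds smallest class size {counts.min()}")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_scores = []
    for tr, te in skf.split(X, y):
        booster = _fit_booster(X[tr], y[tr], task, hp, seed)
        p = _proba(booster, X[te], len(task.classes))
        aucs = []
        for k in classes:
            truth = (y[te] == k).astype(int)
            if truth.min() == truth.max():
                continue  # class absent (or exhaustive) in this fold
            aucs.append(roc_auc(p[:, k], truth))
        fold_scores.append(float(np.mean(aucs)))
    return float(np.mean(fold_scores))


def _sample_hp(rng: np.random.Generator, space: dict[str, tuple]) -> Hyperparameters:
    kw = {}
    for name, spec in space.items():
        kind, lo, hi = spec
        if kind == "loguniform":
            kw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "uniform":
            kw[name] = float(rng.uniform(lo, hi))
        elif kind == "int":
            kw[name] = int(rng.integers(lo, hi + 1))
        else:
            raise ValueError(f"unknown distribution {kind!r} for {name}")
    return Hyperparameters(**kw)


def tune_hyperparameters(X: np.ndarray, y_labels: Sequence[Label], task: TaskSpec,
                         n_trials: int = 20, cv_folds: int = 10, seed: int = 0,
                         search_space: Optional[dict[str, tuple]] = None
                         ) -> Hyperparameters:
    """Seeded random search over the declared bounds; returns the trial with
    the best mean cross-validated objective (first trial wins ties)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if len(y_labels) == 0:
        raise ValueError("empty training set")
    space = search_space or DEFAULT_SEARCH_SPACE
    y = _encode_labels(y_labels, task)
    rng = np.random.default_rng(seed)
    best_hp, best_score = None, -np.inf
    for _ in range(n_trials):
        hp = _sample_hp(rng, space)
        score = cv_objective(X, y, task, hp, cv_folds, seed)
        if score > best_score:
            best_hp, best_score = hp, score
    return best_hp


@dataclass
class TrainedModel:
    task: TaskSpec
    booster: xgb.Booster
    hyperparameters: Hyperparameters
    medians: dict[str, float]
    registry_fingerprint: str
    seed: int
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def classes(self) -> tuple[Label, ...]:
        return self.task.classes

    def save(self, path: str | Path) -> None:
        """Single-file JSON archive: ensemble + task metadata, versioned."""
        blob = {
            "format_version": 1,
            "task": self.task.task,
            "cnv_type": self.task.cnv_type.value,
            "hyperparameters": asdict(self.hyperparameters),
            "medians": self.medians,
            "registry_fingerprint": self.registry_fingerprint,
            "seed": self.seed,
            "flags": self.flags,
            "booster": bytes(self.booster.save_raw(raw_format="json")).decode(),
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = json.loads(Path(path).read_text())
        if blob.get("format_version") != 1:
            raise ValueError("unsupported model archive version")
        booster = xgb.Booster()
        booster.load_model(bytearray(blob["booster"].encode()))
        return cls(TaskSpec(blob["task"], CNVType(blob["cnv_type"])), booster,
                   Hyperparameters(**blob["hyperparameters"]),
                   {k: float(v) for k, v in blob["medians"].items()},
                   blob["registry_fingerprint"], int(blob["seed"]),
                   dict(blob.get("flags", {})))


def train_model(matrix: FeatureMatrix, labels: Sequence[Label], task: TaskSpec,
                hyperparameters: Optional[Hyperparameters] = None,
                seed: int = 0) -> TrainedModel:
    """Fit the boosted ensemble; deterministic given seed and hyperparameters.

    The matrix must be imputed already (its medians travel with the model
    for safe deployment)."""
    if matrix.missing_mask.any():
        raise ValueError("feature matrix has missing values; impute before training")
    if matrix.medians is None:
        raise ValueError("matrix carries no imputation medians; fit_impute first")
    hp = hyperparameters or Hyperparameters()
    y = _encode_labels(labels, task)
    booster = _fit_booster(matrix.values, y, task, hp, seed)
    return TrainedModel(task, booster, hp, dict(matrix.medians),
                        matrix.registry.fingerprint(), seed, dict(matrix.flags))


def predict(model: TrainedModel, matrix: FeatureMatrix
            ) -> tuple[np.ndarray, list[Label]]:
    """Per-row class probabilities (columns in task class order, least → most
    pathogenic) and argmax labels with ties broken toward the more
    pathogenic class."""
    if matrix.registry.fingerprint() != model.registry_fingerprint:
        raise ValueError("feature-registry fingerprint mismatch between model and matrix")
    if matrix.missing_mask.any():
        matrix = apply_impute(matrix, model.medians)
    probs = _proba(model.booster, matrix.values, len(model.classes))
    # argmax over reversed columns prefers the most pathogenic on ties
    rev = probs[:, ::-1]
    pick = probs.shape[1] - 1 - np.argmax(rev, axis=1)
    labels = [model.classes[i] for i in pick]
    return probs, labels
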