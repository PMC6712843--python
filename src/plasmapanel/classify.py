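"""Stage classification: shallow neural network plus kNN / decision-tree
baselines, trained on the synthetic cohort and deployed on the real pooled
replicates kept out of training.

The network is a single hidden layer (10 tanh units by default) with a
softmax output and cross-entropy loss, early-stopped on held-out validation
performance — the classic pattern-recognition configuration.  Inputs are
z-scored by training-set statistics because peak areas span many orders of
magnitude.  Training runs with BLAS limited to one thread so that a fixed
seed reproduces results bit-for-bit regardless of host core count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted
from threadpoolctl import threadpool_limits

from .augment import SyntheticCohort
from .quantio import CONDITIONS, QuantMatrix


def _canonical_classes(labels) -> list:
    present = list(pd.unique(pd.Series(list(labels))))
    if set(present) <= set(CONDITIONS):
        return [c for c in CONDITIONS if c in present]
    return sorted(present)


# ---------------------------------------------------------------------------
# splitting

@dataclass
class SplitSpec:
    """Train/validation/test fractions (default 70/15/15, stratified)."""

    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-12:
            raise ValueError("split fractions must sum to 1")


@dataclass
class Splits:
    X_train: pd.DataFrame
    y_train: pd.Series
    X_val: pd.DataFrame
    y_val: pd.Series
    X_test: pd.DataFrame
    y_test: pd.Series


def split_cohort(cohort: SyntheticCohort, spec: SplitSpec | None = None) -> Splits:
    """Disjoint exhaustive stratified partition with per-class sizes within
    one of fraction x n; seeded shuffle, deterministic."""
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    y = cohort.labels
    idx_train, idx_val, idx_test = [], [], []
    strata = ([(c, np.asarray(y.index[y == c])) for c in _canonical_classes(y)]
              if spec.stratified else [("all", np.asarray(y.index))])
    for _, idx in strata:
        idx = idx.copy()
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(np.floor(spec.train_frac * n))
        n_va = int(np.floor(spec.val_frac * n))
        n_te = int(np.floor(spec.test_frac * n))
        # hand leftovers to train, then val, then test
        for bucket in ("tr", "va", "te"):
            if n_tr + n_va + n_te == n:
                break
            if bucket == "tr":
                n_tr += 1
            elif bucket == "va":
                n_va += 1
            else:
                n_te += 1
        idx_train.extend(idx[:n_tr])
        idx_val.extend(idx[n_tr:n_tr + n_va])
        idx_test.extend(idx[n_tr + n_va:])
    X = cohort.values
    return Splits(X.loc[idx_train], y.loc[idx_train],
                  X.loc[idx_val], y.loc[idx_val],
                  X.loc[idx_test], y.loc[idx_test])


# ---------------------------------------------------------------------------
# shallow neural network

class ShallowNeuralNetClassifier(BaseEstimator, ClassifierMixin):
    """One-hidden-layer pattern-recognition network.

    10 hidden units by default, tanh activation, softmax/cross-entropy
    output, Adam, early stopping on a held-out validation fraction with the
    given patience.  ``predict`` breaks probability ties toward the lowest
    class index in the canonical (healthy, I, II, III, IV) order.

    After fitting, the scaler statistics and network weights are copied onto
    the estimator (``scaler_mean_``, ``coefs_`` ...) and prediction is a pure
    function of those arrays, which makes JSON round-tripping exact.
    """

    def __init__(self, hidden_units: int = 10, activation: str = "tanh",
                 max_epochs: int = 400, patience: int = 30,
                 validation_fraction: float = 0.15,
                 learning_rate_init: float = 0.01,
                 standardize_inputs: bool = True, random_state: int = 0):
        self.hidden_units = hidden_units
        self.activation = activation
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.learning_rate_init = learning_rate_init
        self.standardize_inputs = standardize_inputs
        self.random_state = random_state

    def _check_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_") and self.feature_names_ is not None:
                X = X[self.feature_names_]
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("inputs must be finite")
        return X

    def fit(self, X, y):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        self.feature_names_ = list(X.columns) if isinstance(X, pd.DataFrame) else None
        Xa = self._check_X(X)
        y = np.asarray(pd.Series(list(y)).astype(str))
        self.classes_ = np.asarray(_canonical_classes(y))
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        if self.standardize_inputs:
            scaler = StandardScaler().fit(Xa)
            self.scaler_mean_ = scaler.mean_.copy()
            self.scaler_scale_ = scaler.scale_.copy()
            Xs = scaler.transform(Xa)
        else:
            self.scaler_mean_ = np.zeros(Xa.shape[1])
            self.scaler_scale_ = np.ones(Xa.shape[1])
            Xs = Xa
        mlp = MLPClassifier(hidden_layer_sizes=(self.hidden_units,),
                            activation=self.activation, solver="adam",
                            max_iter=self.max_epochs, early_stopping=True,
                            validation_fraction=self.validation_fraction,
                            n_iter_no_change=self.patience,
                            learning_rate_init=self.learning_rate_init,
                            random_state=self.random_state)
        with threadpool_limits(limits=1, user_api="blas"):
            mlp.fit(Xs, y)
        self.coefs_ = [w.copy() for w in mlp.coefs_]
        self.intercepts_ = [b.copy() for b in mlp.intercepts_]
        self._mlp_classes_ = np.asarray(mlp.classes_)
        self.training_log_ = {
            "n_epochs": int(mlp.n_iter_),
            "final_loss": float(mlp.loss_),
            "best_validation_score": float(mlp.best_validation_score_),
        }
        self.n_features_in_ = Xa.shape[1]
        return self

    def _forward(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.scaler_mean_) / self.scaler_scale_
        H = Xs @ self.coefs_[0] + self.intercepts_[0]
        if self.activation == "tanh":
            H = np.tanh(H)
        elif self.activation == "relu":
            H = np.maximum(H, 0.0)
        elif self.activation == "logistic":
            H = 1.0 / (1.0 + np.exp(-H))
        else:
            raise ValueError(f"unsupported activation {self.activation!r}")
        Z = H @ self.coefs_[1] + self.intercepts_[1]
        if Z.shape[1] == 1:  # binary network: single logistic output
            p1 = 1.0 / (1.0 + np.exp(-Z[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        Z -= Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        return E / E.sum(axis=1, keepdims=True)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        P = self._forward(self._check_X(X))
        # reorder columns from the fit-time label order to canonical order
        order = [int(np.where(self._mlp_classes_ == c)[0][0]) for c in self.classes_]
        return P[:, order]

    def predict(self, X) -> np.ndarray:
        P = self.predict_proba(X)
        return self.classes_[np.argmax(P, axis=1)]

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "coefs_")
        return json.dumps({
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "mlp_classes": self._mlp_classes_.tolist(),
            "feature_names": self.feature_names_,
            "scaler_mean": self.scaler_mean_.tolist(),
            "scaler_scale": self.scaler_scale_.tolist(),
            "coefs": [w.tolist() for w in self.coefs_],
            "intercepts": [b.tolist() for b in self.intercepts_],
            "training_log": self.training_log_,
        })

    @classmethod
    def from_json(cls, payload: str) -> "ShallowNeuralNetClassifier":
        d = json.loads(payload)
        model = cls(**d["params"])
        model.classes_ = np.asarray(d["classes"])
        model._mlp_classes_ = np.asarray(d["mlp_classes"])
        model.feature_names_ = d["feature_names"]
        model.scaler_mean_ = np.asarray(d["scaler_mean"], dtype=float)
        model.scaler_scale_ = np.asarray(d["scaler_scale"], dtype=float)
        model.coefs_ = [np.asarray(w, dtype=float) for w in d["coefs"]]
        model.intercepts_ = [np.asarray(b, dtype=float) for b in d["intercepts"]]
        model.training_log_ = d["training_log"]
        model.n_features_in_ = len(model.scaler_mean_)
        return model


def train_nn(train: tuple, val: tuple, hidden_units: int = 10,
             random_state: int = 0, **kwargs) -> ShallowNeuralNetClassifier:
    """Fit the shallow network on train+val with the validation fraction
    sized to the supplied validation set.

    sklearn's MLP holds out its own stratified validation subset for early
    stopping, so the caller's (train, val) pair is pooled and the fraction
    set to len(val) / len(train + val).
    """
    X_tr, y_tr = train
    X_va, y_va = val
    X = pd.concat([X_tr, X_va]) if isinstance(X_tr, pd.DataFrame) else np.vstack([X_tr, X_va])
    y = pd.concat([pd.Series(list(y_tr)), pd.Series(list(y_va))], ignore_index=True)
    frac = len(y_va) / len(y)
    model = ShallowNeuralNetClassifier(hidden_units=hidden_units,
                                       validation_fraction=frac,
                                       random_state=random_state, **kwargs)
    return model.fit(X, y)


def train_baseline(train: tuple, val: tuple, kind: str,
                   grid: list | None = None, random_state: int = 0):
    """Fit a kNN or decision-tree baseline, picking the hyperparameter (k or
    max depth) on the validation set over a small grid.

    Returns ``(model, selection_log)``.
    """
    X_tr, y_tr = train
    X_va, y_va = val
    if kind == "knn":
        grid = grid or [1, 3, 5, 7, 9]
        bad = [k for k in grid if k > len(y_tr)]
        if bad:
            raise ValueError(f"k larger than training set: {bad}")
        factory = lambda k: Pipeline([  # noqa: E731
            ("scale", StandardScaler()),
            ("knn", KNeighborsClassifier(n_neighbors=k))])
    elif kind == "tree":
        grid = grid or [2, 3, 5, 8, None]
        factory = lambda d: DecisionTreeClassifier(  # noqa: E731
            max_depth=d, random_state=random_state)
    else:
        raise ValueError("kind must be 'knn' or 'tree'")
    log, best = [], None
    for hp in grid:
        model = factory(hp).fit(X_tr, y_tr)
        score = float(np.mean(model.predict(X_va) == np.asarray(y_va)))
        log.append({"hyperparameter": hp, "val_accuracy": score})
        if best is None or score > best[1]:
            best = (model, score, hp)
    return best[0], {"kind": kind, "chosen": best[2], "grid": log}


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class ConfusionMatrix:
    """Counts of true (rows) vs predicted (columns) class, canonical order."""

    classes: list
    counts: np.ndarray
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct_rate(self) -> float:
        """Correct-classification rate, percent (100 * trace / total)."""
        return 100.0 * float(np.trace(self.counts)) / self.total

    def per_class_rate(self) -> pd.Series:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = 100.0 * np.diag(self.counts) / row
        return pd.Series(rate, index=self.classes, name="correct_percent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def evaluate(model, X, y) -> ConfusionMatrix:
    """Confusion matrix of a fitted classifier on labelled data."""
    y = np.asarray(pd.Series(list(y)).astype(str))
    classes = list(getattr(model, "classes_", _canonical_classes(y)))
    if set(classes) <= set(CONDITIONS):
        classes = [c for c in CONDITIONS if c in classes]
    unseen = sorted(set(y) - set(map(str, classes)))
    if unseen:
        raise ValueError(f"labels unseen by the model: {unseen}")
    pred = model.predict(X)
    counts = _sk_confusion(y, pred, labels=classes)
    return ConfusionMatrix(classes, counts)


def deploy_on_real(model, real: QuantMatrix, panel: list,
                   unit: str = "replicate") -> ConfusionMatrix:
    """Classify the real pooled observations that never entered training.

    ``unit='replicate'`` classifies each technical replicate run independently
    (5 conditions x replicates, 15 items for triplicates);
    ``unit='pooled_mean'`` classifies the per-condition replicate mean
    (5 items).  Features are aligned to the panel by protein id.
    """
    absent = [p for p in panel if p not in real.values.index]
    if absent:
        raise KeyError(f"panel proteins missing from real data: {absent}")
    linear = real.linear_values().loc[list(panel)]
    if unit == "replicate":
        X = linear.T
        y = real.meta.loc[X.index, "condition"]
    elif unit == "pooled_mean":
        conds = [c for c in CONDITIONS if c in set(real.meta["condition"])]
        X = pd.DataFrame({c: linear[real.runs_for(condition=c)].mean(axis=1)
                          for c in conds}).T
        y = pd.Series(conds, index=X.index)
    else:
        raise ValueError("unit must be 'replicate' or 'pooled_mean'")
    X.columns = list(panel)
    cm = evaluate(model, X, y)
    cm.info["unit"] = unit
    cm.info["per_condition_correct"] = cm.per_class_rate().to_dict()
    return cm
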