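"""TRUE/FALSE end classification.

Peaks are labeled TRUE when their dominant position lies within a tolerance
of a same-strand reference end (an end-catalog BED — FANTOM5 / PolyA_DB3
surrogates, or synthetic truth).  Four classifier families (logistic
regression, random forest, RBF-kernel SVM, k-nearest neighbours) are trained
with a fixed protocol: stratified 70/30 train/test split, five-fold
cross-validated hyperparameter selection in two rounds (coarse grid, then a
fine grid around the coarse optimum), final refit on the whole training
split.  Performance is summarized as accuracy, Acc = (TP+TN)/(TP+TN+FP+FN).
"""

from __future__ import annotations

import base64
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix, Normalizer
from .io import dump_json, load_json
from .peaks import TagCluster
from .read_ends import EndType

ALGORITHMS = ("LR", "RF", "SVM", "KNN")


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """Acc = (TP + TN) / (TP + TN + FP + FN)."""
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    return (tp + tn) / total


@dataclass(frozen=True)
class ClassifierMetrics:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def acc(self) -> float:
        return accuracy(self.tp, self.tn, self.fp, self.fn)

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ClassifierMetrics":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int((y_true & y_pred).sum()),
            tn=int((~y_true & ~y_pred).sum()),
            fp=int((~y_true & y_pred).sum()),
            fn=int((y_true & ~y_pred).sum()),
        )


@dataclass(frozen=True)
class TrainingProtocol:
    train_fraction: float = 0.70
    cv_folds: int = 5
    seed: int = 0
    algorithms: tuple[str, ...] = ALGORITHMS

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {a!r}")


@dataclass
class LabeledPeakSet:
    """A feature matrix with aligned TRUE/FALSE labels."""

    features: FeatureMatrix
    labels: pd.Series  # bool, indexed like features.X
    label_tolerance: int

    def __post_init__(self):
        if not self.features.X.index.equals(self.labels.index):
            raise ValueError("labels must align 1:1 with feature matrix rows")
        self.labels = self.labels.astype(bool)


def label_peaks(
    peaks: Sequence[TagCluster],
    reference_ends: pd.DataFrame,
    tolerance: int = 50,
) -> pd.Series:
    """TRUE iff the dominant position is within ``tolerance`` bp of a
    same-strand reference end (BED6 frame: single-base ``[start, start+1)``)."""
    ref: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, strand), sub in reference_ends.groupby(["chrom", "strand"]):
        ref[(str(chrom), str(strand))] = np.sort(sub["start"].to_numpy(dtype=np.int64))
    out = {}
    for p in peaks:
        sites = ref.get((p.chrom, p.strand))
        if sites is None or sites.size == 0:
            out[p.peak_id] = False
            continue
        i = np.searchsorted(sites, p.dominant_pos)
        d = min(
            abs(int(sites[j]) - p.dominant_pos)
            for j in (i - 1, i)
            if 0 <= j < sites.size
        )
        out[p.peak_id] = d <= tolerance
    return pd.Series(out, dtype=bool)


def build_labeled_set(
    features: FeatureMatrix,
    peaks: Sequence[TagCluster],
    reference_ends: pd.DataFrame,
    tolerance: int = 50,
) -> LabeledPeakSet:
    labels = label_peaks(peaks, reference_ends, tolerance).reindex(features.X.index)
    return LabeledPeakSet(features=features, labels=labels, label_tolerance=tolerance)


@dataclass
class EndClassifier:
    """A trained end classifier with its feature-column contract.

    ``predict`` refuses feature matrices whose columns differ from the
    training contract; the training normalizer travels with the model so new
    peak sets can be featurized consistently.
    """

    algorithm: str
    hyperparameters: dict
    model: object
    metrics: ClassifierMetrics
    feature_columns: tuple[str, ...]
    groups: dict[str, str]
    normalizer: Normalizer
    end_type: EndType
    seed: int

    def _check(self, X: pd.DataFrame) -> None:
        if tuple(X.columns) != self.feature_columns:
            raise ValueError("feature columns do not match the model's contract")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check(X)
        return np.asarray(self.model.predict(X.to_numpy()), dtype=bool)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray | None:
        """P(TRUE) per row, or None when the algorithm has no probabilities."""
        self._check(X)
        if not hasattr(self.model, "predict_proba"):
            return None
        proba = self.model.predict_proba(X.to_numpy())
        true_col = list(self.model.classes_).index(True)
        return proba[:, true_col]

    def save(self, path: str | Path) -> None:
        dump_json(
            {
                "format_version": 1,
                "algorithm": self.algorithm,
                "hyperparameters": {k: repr(v) for k, v in self.hyperparameters.items()},
                "metrics": {"tp": self.metrics.tp, "tn": self.metrics.tn,
                            "fp": self.metrics.fp, "fn": self.metrics.fn},
                "feature_columns": list(self.feature_columns),
                "groups": self.groups,
                "normalizer": self.normalizer.to_dict(),
                "end_type": self.end_type.value,
                "seed": self.seed,
                "state": base64.b64encode(pickle.dumps(self.model)).decode("ascii"),
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "EndClassifier":
        d = load_json(path)
        model = pickle.loads(base64.b64decode(d["state"]))
        return cls(
            algorithm=d["algorithm"],
            hyperparameters=model.get_params() if hasattr(model, "get_params") else {},
            model=model,
            metrics=ClassifierMetrics(**d["metrics"]),
            feature_columns=tuple(d["feature_columns"]),
            groups=d["groups"],
            normalizer=Normalizer.from_dict(d["normalizer"]),
            end_type=EndType(d["end_type"]),
            seed=d["seed"],
        )


def _numeric_neighbors(v: float, lo: float | None = None) -> list[float]:
    out = sorted({v / 2, v, v * 2})
    if lo is not None:
        out = [max(lo, x) for x in out]
    return sorted(set(out))


def _search_spec(algo: str, seed: int):
    """(estimator, coarse grid, fine-grid builder) per algorithm."""
    if algo == "RF":
        est = RandomForestClassifier(random_state=seed)
        coarse = {"n_estimators": [100, 300], "max_depth": [None, 10]}

        def fine(best):
            d = best["max_depth"]
            depths = [None, 20] if d is None else sorted({max(2, d // 2), d, d * 2})
            return {"n_estimators": [best["n_estimators"]], "max_depth": depths}

        return est, coarse, fine
    if algo == "LR":
        est = LogisticRegression(max_iter=5000)
        coarse = {"C": list(np.logspace(-2, 2, 5))}

        def fine(best):
            c = best["C"]
            return {"C": sorted({c * f for f in (0.25, 0.5, 1.0, 2.0, 4.0)})}

        return est, coarse, fine
    if algo == "SVM":
        est = SVC(kernel="rbf", random_state=seed)
        coarse = {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]}

        def fine(best):
            g = best["gamma"]
            gammas = ["scale"] if g == "scale" else sorted({g / 3, g, g * 3})
            return {"C": _numeric_neighbors(best["C"], lo=1e-3), "gamma": gammas}

        return est, coarse, fine
    if algo == "KNN":
        est = KNeighborsClassifier()
        coarse = {"n_neighbors": [3, 5, 9, 15, 25]}

        def fine(best):
            k = best["n_neighbors"]
            return {"n_neighbors": sorted({max(1, k - 2), k, k + 2})}

        return est, coarse, fine
    raise ValueError(f"unknown algorithm {algo!r}")


def split_train_test(
    data: LabeledPeakSet, protocol: TrainingProtocol
) -> tuple[pd.Index, pd.Index]:
    """Deterministic stratified 70/30 split of peak ids."""
    idx = data.features.X.index
    train_ids, test_ids = train_test_split(
        idx,
        train_size=protocol.train_fraction,
        random_state=protocol.seed,
        stratify=data.labels.to_numpy(),
    )
    return pd.Index(train_ids), pd.Index(test_ids)


def _fit_one(
    algo: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    protocol: TrainingProtocol,
):
    est, coarse, fine_fn = _search_spec(algo, protocol.seed)
    cv = StratifiedKFold(
        n_splits=protocol.cv_folds, shuffle=True, random_state=protocol.seed
    )
    search1 = GridSearchCV(est, coarse, scoring="accuracy", cv=cv, refit=False)
    search1.fit(X_train, y_train)
    search2 = GridSearchCV(
        est, fine_fn(search1.best_params_), scoring="accuracy", cv=cv, refit=False
    )
    search2.fit(X_train, y_train)
    best = search2.best_params_
    final = clone(est).set_params(**best)
    final.fit(X_train, y_train)
    return final, best


def train(
    data: LabeledPeakSet,
    protocol: TrainingProtocol | None = None,
    algorithms: Sequence[str] | None = None,
) -> dict[str, EndClassifier]:
    """Train one classifier per algorithm under the fixed protocol.

    Deterministic given ``protocol.seed`` and the data.  Raises on
    single-class label sets (nothing to separate).
    """
    protocol = protocol or TrainingProtocol()
    algorithms = tuple(algorithms or protocol.algorithms)
    y = data.labels.to_numpy(dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class; cannot train")
    train_ids, test_ids = split_train_test(data, protocol)
    X_train = data.features.X.loc[train_ids].to_numpy()
    y_train = data.labels.loc[train_ids].to_numpy(dtype=bool)
    X_test = data.features.X.loc[test_ids].to_numpy()
    y_test = data.labels.loc[test_ids].to_numpy(dtype=bool)

    out = {}
    for algo in algorithms:
        model, best = _fit_one(algo, X_train, y_train, protocol)
        metrics = ClassifierMetrics.from_predictions(y_test, model.predict(X_test))
        out[algo] = EndClassifier(
            algorithm=algo,
            hyperparameters=best,
            model=model,
            metrics=metrics,
            feature_columns=tuple(data.features.X.columns),
            groups=dict(data.features.groups),
            normalizer=data.features.normalizer,
            end_type=data.features.end_type,
            seed=protocol.seed,
        )
    return out


def evaluate(model: EndClassifier, heldout: LabeledPeakSet) -> ClassifierMetrics:
    """Accuracy-based evaluation on an independent labeled set."""
    pred = model.predict(heldout.features.X)
    return ClassifierMetrics.from_predictions(heldout.labels.to_numpy(), pred)


def cross_dataset_transfer(model: EndClassifier, other: LabeledPeakSet) -> ClassifierMetrics:
    """Evaluate a trained model on another dataset without refitting; the
    feature-column contract is enforced."""
    return evaluate(model, other)


def ablate_groups(
    data: LabeledPeakSet,
    protocol: TrainingProtocol | None = None,
    groups: Sequence[str] | None = None,
    algorithm: str = "RF",
) -> dict[str, float]:
    """Accuracy drop on the held-out split after removing one feature group
    at a time (full two-round retraining per ablation)."""
    protocol = protocol or TrainingProtocol()
    if groups is None:
        groups = sorted(set(data.features.groups.values()))
    train_ids, test_ids = split_train_test(data, protocol)
    y_train = data.labels.loc[train_ids].to_numpy(dtype=bool)
    y_test = data.labels.loc[test_ids].to_numpy(dtype=bool)

    def acc_with(cols: list[str]) -> float:
        X_train = data.features.X.loc[train_ids, cols].to_numpy()
        X_test = data.features.X.loc[test_ids, cols].to_numpy()
        model, _ = _fit_one(algorithm, X_train, y_train, protocol)
        return ClassifierMetrics.from_predictions(y_test, model.predict(X_test)).acc

    all_cols = list(data.features.X.columns)
    acc_full = acc_with(all_cols)
    drops = {}
    for g in groups:
        kept = [c for c in all_cols if data.features.groups[c] != g]
        if not kept:
            raise ValueError(f"removing group {g!r} would leave no features")
        drops[g] = acc_full - acc_with(kept)
    return drops


def filter_peaks(
    model: EndClassifier,
    peaks: Sequence[TagCluster],
    features: FeatureMatrix,
) -> tuple[list[TagCluster], pd.DataFrame]:
    """Retain peaks predicted TRUE.

    Returns the retained clusters and a per-peak table with the prediction
    and, when available, the model's P(TRUE).
    """
    X = features.X.loc[[p.peak_id for p in peaks]]
    pred = model.predict(X)
    proba = model.predict_proba(X)
    table = pd.DataFrame({"predicted_true": pred}, index=X.index)
    if proba is not None:
        table["prob_true"] = proba
    retained = [p for p, keep in zip(peaks, pred) if keep]
    return retained, table
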