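"""Nearest-neighbor pathway classification with jackknife evaluation and
incremental feature selection (IFS).

The native classifier is the cosine-distance nearest neighbor rule (NNA):
a query pathway gets the class of the training pathway minimizing
1 - cos(x, y); distance ties break toward the lower row index.  Accuracy
is always the jackknife (leave-one-out) overall accuracy — the number of
correctly predicted pathways over the total — which is unique and
deterministic for a given table.

IFS evaluates nested prefixes F_1 c F_2 c ... of a ranked feature list and
reports the accuracy curve and the smallest prefix achieving the maximum.

Model/Results surface: build a :class:`PathwayClassModel` from a feature
table (or a plain DataFrame), call :meth:`~PathwayClassModel.fit`, and
inspect the returned :class:`IFSResults` (curve, best subset, confusion
matrix, ``summary()``, ``plot_ifs()``).  Other classifiers (e.g. an SVM
standing in for SMO) enter through the fit/predict contract via
:class:`SklearnAdapter`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .feature_table import FeatureTable
from .mrmr import RankedFeatureList, rank_features


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - cos(x, y), in [0, 2]; a zero-norm vector is at distance 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 1.0
    return float(1.0 - np.dot(x, y) / (nx * ny))


def _row_normalize(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    return X / safe[:, None]


def nna_predict(train_X: np.ndarray, train_y, query: np.ndarray):
    """Label of the cosine-nearest training row (ties: lowest row index)."""
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    query = np.asarray(query, dtype=float).ravel()
    dists = np.array([cosine_distance(row, query) for row in train_X])
    return np.asarray(train_y)[int(np.argmin(dists))]


@runtime_checkable
class ClassifierContract(Protocol):
    """fit/predict contract every pluggable classifier satisfies."""

    name: str

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierContract": ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


class NearestNeighbor:
    """Native cosine-distance NNA under the classifier contract."""

    name = "NNA"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NearestNeighbor":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sims = _row_normalize(X) @ _row_normalize(self._X).T
        return self._y[np.argmax(sims, axis=1)]


class SklearnAdapter:
    """Wrap any scikit-learn estimator under the classifier contract.

    Lets SMO-style SVMs or Bayesian classifiers plug into the IFS sweep
    without the sweep knowing anything about them.
    """

    def __init__(self, estimator, name: str | None = None):
        self._proto = estimator
        self.name = name or type(estimator).__name__

    def fit(self, X, y) -> "SklearnAdapter":
        from sklearn.base import clone

        self._est = clone(self._proto).fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(self._est.predict(np.atleast_2d(X)))


def jackknife_predictions(X: np.ndarray, y, classifier=None) -> np.ndarray:
    """Leave-one-out predicted label for every row."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if classifier is None or isinstance(classifier, NearestNeighbor):
        # vectorized LOO for NNA: mask the diagonal of the similarity matrix
        Xn = _row_normalize(X)
        sims = Xn @ Xn.T
        np.fill_diagonal(sims, -np.inf)
        return y[np.argmax(sims, axis=1)]
    preds = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        classifier.fit(X[mask], y[mask])
        preds.append(classifier.predict(X[i : i + 1])[0])
        mask[i] = True
    return np.asarray(preds)


def jackknife_accuracy(X: np.ndarray, y, classifier=None) -> float:
    """Jackknife overall accuracy: correct predictions / total pathways."""
    y = np.asarray(y)
    return float(np.mean(jackknife_predictions(X, y, classifier) == y))


@dataclass
class IFSResult:
    """Raw IFS sweep output: the accuracy curve and the best setting."""

    curve: pd.DataFrame  # columns: n_features, classifier, accuracy
    best_n_features: int
    best_classifier: str
    best_accuracy: float
    ranking: RankedFeatureList | None = None

    def write_tsv(self, path) -> None:
        self.curve.to_csv(path, sep="\t", index=False, float_format="%.10g")


def ifs_sweep(
    X: np.ndarray,
    y,
    ranking: RankedFeatureList,
    classifiers: list | None = None,
    depth: int | None = None,
) -> IFSResult:
    """Jackknife accuracy on every prefix of the mRMR list.

    The best report is the maximal accuracy; ties go to the smaller prefix,
    then to classifier order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if classifiers is None:
        classifiers = [NearestNeighbor()]
    order = ranking.mrmr_order
    depth = len(order) if depth is None else min(depth, len(order))
    records = []
    for i in range(1, depth + 1):
        cols = order[:i]
        for clf in classifiers:
            acc = jackknife_accuracy(X[:, cols], y, clf)
            records.append({"n_features": i, "classifier": clf.name, "accuracy": acc})
    curve = pd.DataFrame.from_records(records)
    # max accuracy; ties -> fewer features, then classifier order
    best_idx = max(
        range(len(records)),
        key=lambda r: (records[r]["accuracy"], -records[r]["n_features"], -r),
    )
    best = records[best_idx]
    return IFSResult(
        curve=curve,
        best_n_features=int(best["n_features"]),
        best_classifier=str(best["classifier"]),
        best_accuracy=float(best["accuracy"]),
        ranking=ranking,
    )


class PathwayClassModel:
    """Pathway classification model over a labeled feature table.

    Parameters
    ----------
    endog : array-like of class labels, one per pathway.
    exog : 2-D array of feature values (pathways x features).
    feature_names : optional column names.
    pathway_ids : optional row identifiers.
    """

    def __init__(self, endog, exog, feature_names=None, pathway_ids=None):
        self.endog = np.asarray(endog)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != self.exog.shape[0]:
            raise ValueError("exog must be 2-D with one row per label")
        if np.any([l is None for l in np.atleast_1d(endog)]):
            raise ValueError("every pathway needs a class label")
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(self.exog.shape[1])]
        )
        self.pathway_ids = (
            list(pathway_ids)
            if pathway_ids is not None
            else [f"p{i}" for i in range(self.exog.shape[0])]
        )
        self.classes = np.unique(self.endog)

    @classmethod
    def from_feature_table(cls, table: FeatureTable) -> "PathwayClassModel":
        return cls(
            endog=table.labels,
            exog=table.matrix,
            feature_names=table.feature_names,
            pathway_ids=table.pathway_ids,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label"):
        y = df[label_col].to_numpy()
        X = df.drop(columns=[label_col])
        return cls(endog=y, exog=X.to_numpy(float), feature_names=list(X.columns),
                   pathway_ids=list(df.index.astype(str)))

    def rank_features(self, depth: int = 500) -> RankedFeatureList:
        return rank_features(self.exog, self.endog, self.feature_names, depth=depth)

    def fit(
        self,
        depth: int = 50,
        classifiers: list | None = None,
        ranking: RankedFeatureList | None = None,
    ) -> "IFSResults":
        """Rank features (mRMR) and sweep IFS; returns :class:`IFSResults`."""
        if ranking is None:
            ranking = self.rank_features(depth=depth)
        sweep = ifs_sweep(self.exog, self.endog, ranking, classifiers, depth=depth)
        return IFSResults(self, sweep)


class IFSResults:
    """Fitted results: ranked features, IFS curve and best subset."""

    def __init__(self, model: PathwayClassModel, sweep: IFSResult):
        self.model = model
        self.sweep = sweep
        self.ranking = sweep.ranking
        self.curve = sweep.curve
        self.best_n_features = sweep.best_n_features
        self.best_classifier = sweep.best_classifier
        self.best_accuracy = sweep.best_accuracy
        self._selected_cols = self.ranking.mrmr_order[: self.best_n_features]

    @property
    def selected_features(self) -> list[str]:
        return [self.model.feature_names[i] for i in self._selected_cols]

    def jackknife_report(self) -> pd.DataFrame:
        """Per-pathway true vs predicted labels at the best setting."""
        preds = jackknife_predictions(
            self.model.exog[:, self._selected_cols], self.model.endog
        )
        return pd.DataFrame(
            {
                "pathway_id": self.model.pathway_ids,
                "true": self.model.endog,
                "predicted": preds,
            }
        )

    def confusion_matrix(self) -> pd.DataFrame:
        rep = self.jackknife_report()
        return pd.crosstab(
            rep["true"], rep["predicted"], dropna=False
        ).reindex(index=self.model.classes, columns=self.model.classes, fill_value=0)

    def predict(self, X_new: np.ndarray):
        """Classify new pathways by NNA on the selected features."""
        clf = NearestNeighbor().fit(
            self.model.exog[:, self._selected_cols], self.model.endog
        )
        return clf.predict(np.atleast_2d(X_new)[:, self._selected_cols])

    def summary(self) -> str:
        lines = [
            "Pathway classification — incremental feature selection",
            "=" * 58,
            f"pathways:            {len(self.model.pathway_ids)}",
            f"classes:             {len(self.model.classes)} "
            f"({', '.join(map(str, self.model.classes))})",
            f"features available:  {self.model.exog.shape[1]}",
            f"IFS depth:           {int(self.curve['n_features'].max())}",
            f"best classifier:     {self.best_classifier}",
            f"best subset size:    {self.best_n_features}",
            f"jackknife accuracy:  {self.best_accuracy:.4f}",
            "-" * 58,
            "top features:",
        ]
        for rank, name in enumerate(self.selected_features[:10], start=1):
            lines.append(f"  {rank:2d}. {name}")
        if self.best_n_features > 10:
            lines.append(f"  ... ({self.best_n_features - 10} more)")
        return "\n".join(lines)

    def plot_ifs(self, ax=None):
        """IFS curve: jackknife accuracy vs number of ranked features."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, grp in self.curve.groupby("classifier"):
            ax.plot(grp["n_features"], grp["accuracy"], marker=".", label=name)
        ax.axvline(self.best_n_features, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("number of top-ranked features")
        ax.set_ylabel("jackknife accuracy")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax
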