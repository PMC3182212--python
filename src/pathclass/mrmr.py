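"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

Features are discretized into three states by the mu +/- sigma rule, the
convention of the original mRMR program for continuous data.  Relevance is
the mutual information (bits) between a discretized feature and the class
label; the MaxRel list sorts by relevance alone, while the mRMR list is
built greedily under the MID ("difference") scheme:

    pick argmax_f [ I(f; class) - (1/|S|) * sum_{s in S} I(f; s) ]

Ties break toward the lower column index, so rankings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def discretize(column: np.ndarray) -> np.ndarray:
    """Map a continuous column to states {-1, 0, 1} by mu +/- sigma.

    Population sigma; a constant column is all state 0.
    """
    column = np.asarray(column, dtype=float)
    mu = column.mean()
    sigma = column.std()
    states = np.zeros(len(column), dtype=np.int8)
    states[column > mu + sigma] = 1
    states[column < mu - sigma] = -1
    return states


def discretize_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    states = np.zeros(X.shape, dtype=np.int8)
    states[X > mu + sigma] = 1
    states[X < mu - sigma] = -1
    return states


def _encode(values: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(values, return_inverse=True)
    return codes, int(codes.max()) + 1 if len(codes) else 0


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two discrete sequences."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    xc, nx = _encode(x)
    yc, ny = _encode(y)
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xc, yc), 1.0)
    joint /= len(x)
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def _mi_against_all(X_states: np.ndarray, y_codes: np.ndarray, ny: int) -> np.ndarray:
    """MI (bits) between each column of a 3-state matrix and one sequence."""
    n_rows, n_cols = X_states.shape
    codes = (X_states.astype(np.int64) + 1) * ny + y_codes[:, None]
    counts = np.zeros((n_cols, 3 * ny))
    np.add.at(counts, (np.tile(np.arange(n_cols), (n_rows, 1)), codes), 1.0)
    joint = (counts / n_rows).reshape(n_cols, 3, ny)
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return np.nansum(terms, axis=(1, 2))


@dataclass
class RankedFeatureList:
    """MaxRel and mRMR orderings with their scores."""

    maxrel_order: np.ndarray
    maxrel_scores: np.ndarray
    mrmr_order: np.ndarray
    mrmr_scores: np.ndarray
    feature_names: list[str] | None = None

    def names(self, order: np.ndarray) -> list[str]:
        if self.feature_names is None:
            return [str(i) for i in order]
        return [self.feature_names[i] for i in order]

    def to_frame(self, which: str = "mrmr") -> pd.DataFrame:
        order = self.mrmr_order if which == "mrmr" else self.maxrel_order
        scores = self.mrmr_scores if which == "mrmr" else self.maxrel_scores
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(order) + 1),
                "feature_index": order,
                "feature": self.names(order),
                "score": scores,
            }
        )

    def write_tsv(self, path, which: str = "mrmr") -> None:
        self.to_frame(which).to_csv(path, sep="\t", index=False, float_format="%.10g")


def rank_features(
    X: np.ndarray,
    y,
    feature_names: list[str] | None = None,
    depth: int = 500,
) -> RankedFeatureList:
    """Compute the MaxRel ordering and a depth-limited greedy mRMR ordering.

    Requires at least two classes.  The MaxRel list always covers all
    features; the mRMR list has min(depth, n_features) entries.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes to rank features")
    y_codes = np.searchsorted(classes, y)
    states = discretize_matrix(X)
    relevance = _mi_against_all(states, y_codes, len(classes))

    # stable descending sort, ties toward the lower column index
    maxrel_order = np.argsort(-relevance, kind="stable")
    maxrel_scores = relevance[maxrel_order]

    n_features = X.shape[1]
    depth = min(depth, n_features)
    selected: list[int] = []
    scores: list[float] = []
    redundancy = np.zeros(n_features)
    available = np.ones(n_features, dtype=bool)
    for step in range(depth):
        if step == 0:
            objective = relevance.copy()
        else:
            objective = relevance - redundancy / len(selected)
        objective[~available] = -np.inf
        best = int(np.argmax(objective))  # argmax takes the first (lowest index) tie
        selected.append(best)
        scores.append(float(objective[best]))
        available[best] = False
        if step < depth - 1:
            sel_states = states[:, best]
            sel_codes = sel_states.astype(np.int64) + 1
            redundancy += _mi_against_all(states, sel_codes, 3)
    return RankedFeatureList(
        maxrel_order=maxrel_order,
        maxrel_scores=maxrel_scores,
        mrmr_order=np.array(selected),
        mrmr_scores=np.array(scores),
        feature_names=feature_names,
    )
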