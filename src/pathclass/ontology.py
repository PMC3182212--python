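"""Binary GO vectors and cosine arc weights.

Each protein is represented as a binary vector over the annotation
universe's ordered term list; the weight of an arc between two proteins is
the cosine similarity of the endpoint vectors.  An arc of weight 0 (the
endpoints share no annotation) is a *missing edge*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import AnnotationUniverse, Pathway, ProteinRecord


@dataclass
class WeightedPathwayGraph:
    """A pathway plus a GO-cosine weight in [0, 1] for every arc."""

    pathway: Pathway
    weights: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for arc in self.pathway.arcs:
            w = self.weights.get(arc)
            if w is None:
                raise ValueError(f"arc {arc} has no weight")
            if not 0.0 <= w <= 1.0 + 1e-12:
                raise ValueError(f"arc {arc} weight {w} outside [0, 1]")


def go_vector(protein: ProteinRecord, universe: AnnotationUniverse) -> np.ndarray:
    """Binary annotation vector of the protein over the universe's terms.

    Terms of the protein absent from the universe are ignored (warning).
    """
    vec = np.zeros(len(universe), dtype=float)
    missing = 0
    for t in protein.go_terms:
        idx = universe.index_of(t)
        if idx is None:
            missing += 1
        else:
            vec[idx] = 1.0
    if missing:
        warnings.warn(
            f"protein {protein.id}: {missing} GO term(s) not in the universe",
            stacklevel=2,
        )
    return vec


def cosine_weight(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two equal-length vectors; 0 if either norm is 0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def pathway_go_matrix(
    pathway: Pathway,
    proteins: dict[str, ProteinRecord],
    universe: AnnotationUniverse,
) -> np.ndarray:
    """Stack GO vectors for the pathway's vertices (row order = vertex order)."""
    return np.array(
        [go_vector(proteins[v], universe) for v in pathway.vertices], dtype=float
    )


def cosine_matrix(go_mat: np.ndarray) -> np.ndarray:
    """All-pairs cosine similarity between rows; zero-norm rows give 0."""
    norms = np.linalg.norm(go_mat, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    normed = go_mat / safe[:, None]
    sim = normed @ normed.T
    return np.clip(sim, 0.0, 1.0)


def weight_graph(
    pathway: Pathway,
    proteins: dict[str, ProteinRecord],
    universe: AnnotationUniverse,
) -> WeightedPathwayGraph:
    """Weight every arc by the GO-cosine similarity of its endpoints."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mat = pathway_go_matrix(pathway, proteins, universe)
    if mat.size == 0:
        return WeightedPathwayGraph(pathway=pathway, weights={})
    sim = cosine_matrix(mat)
    index = {v: i for i, v in enumerate(pathway.vertices)}
    weights = {
        (a, b): float(sim[index[a], index[b]]) for a, b in pathway.arcs
    }
    return WeightedPathwayGraph(pathway=pathway, weights=weights)
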