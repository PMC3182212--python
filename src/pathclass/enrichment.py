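"""GO-term enrichment scores: the functional feature block.

For pathway i and GO term j the score is -log10 of the upper-tail
hypergeometric probability P(X >= k) of seeing at least k term-j proteins
among the n_i pathway proteins, given M_j annotated proteins in a
background of N.  Larger scores mean stronger over-representation; k = 0
gives p = 1 and score 0.  Scores are capped so the block stays finite when
the tail probability underflows.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from .datamodel import AnnotationUniverse, Pathway, ProteinRecord

SCORE_CAP = 300.0


def hypergeom_upper_p(N: int, M: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, M, n)."""
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"invalid background: N={N}, M={M}, n={n}")
    if not 0 <= k <= min(M, n):
        raise ValueError(f"k={k} outside [0, min(M={M}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, M, n))


def enrichment_score(N: int, M: int, n: int, k: int, cap: float = SCORE_CAP) -> float:
    """-log10 of the upper-tail p, capped."""
    p = hypergeom_upper_p(N, M, n, k)
    if p <= 0.0:
        return cap
    return float(min(-np.log10(p), cap))


def enrichment_block(
    pathway: Pathway,
    proteins: dict[str, ProteinRecord],
    universe: AnnotationUniverse,
    cap: float = SCORE_CAP,
) -> dict[str, float]:
    """Enrichment score for every universe term, named ``<term>.enrich``.

    k counts distinct pathway proteins annotated with the term; terms
    annotating no pathway protein score 0 without a tail evaluation.
    """
    n = pathway.n_vertices
    N = universe.background_size
    k_counts = np.zeros(len(universe), dtype=int)
    for v in pathway.vertices:
        for t in proteins[v].go_terms:
            idx = universe.index_of(t)
            if idx is not None:
                k_counts[idx] += 1
    M = np.array([universe.term_counts.get(t, 0) for t in universe.terms])
    # clamp k at the background count: a universe built on a different
    # background may undercount M relative to the loaded pathways
    k = np.minimum(k_counts, np.minimum(M, n))
    scores = np.zeros(len(universe))
    hit = k > 0
    if hit.any():
        with np.errstate(divide="ignore"):
            p = hypergeom.sf(k[hit] - 1, N, M[hit], n)
            scores[hit] = np.minimum(-np.log10(np.maximum(p, 0.0)), cap)
    return {f"{t}.enrich": float(s) for t, s in zip(universe.terms, scores)}
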