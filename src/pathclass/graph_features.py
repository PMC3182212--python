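"""Directed-graph topological descriptors of a weighted pathway graph.

Nine feature groups, 88 features in total:

=====================  ==
graph size & density    2
degree statistics       8
edge-weight statistics  4
topology change         7
degree correlation      6
clustering              6
topological overlap    12
singular values         3
local density change   40
=====================  ==

Conventions used throughout (the source descriptions leave them open):
variance is the population variance; statistics of empty sets are 0, never
NaN; weight-cutoff comparisons are strict (w > c); neighbor sets exclude the
vertex itself, so a self-loop contributes to |E| and to the adjacency matrix
but not to degrees or neighborhoods.
"""

from __future__ import annotations

import numpy as np

from .datamodel import AnnotationUniverse, ProteinRecord
from .ontology import WeightedPathwayGraph, cosine_matrix, pathway_go_matrix

TOPOLOGY_CUTOFFS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
LOCAL_DENSITY_CUTOFFS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

N_GRAPH_FEATURES = 88


def _mean(xs) -> float:
    xs = list(xs)
    return float(np.mean(xs)) if xs else 0.0


def _var(xs) -> float:
    xs = list(xs)
    return float(np.var(xs)) if xs else 0.0


def _max(xs) -> float:
    xs = list(xs)
    return float(max(xs)) if xs else 0.0


def _median(xs) -> float:
    xs = list(xs)
    return float(np.median(xs)) if xs else 0.0


def _neighbors(g: WeightedPathwayGraph):
    """(in-neighbor, out-neighbor) sets per vertex, self excluded."""
    vs = g.pathway.vertices
    in_nb = {v: set() for v in vs}
    out_nb = {v: set() for v in vs}
    for a, b in g.pathway.arcs:
        if a != b:
            out_nb[a].add(b)
            in_nb[b].add(a)
    return in_nb, out_nb


def size_density(g: WeightedPathwayGraph) -> dict[str, float]:
    n = g.pathway.n_vertices
    m = g.pathway.n_arcs
    return {
        "size.n_vertices": float(n),
        "size.density": m / n**2 if n else 0.0,
    }


def degree_statistics(g: WeightedPathwayGraph) -> dict[str, float]:
    in_nb, out_nb = _neighbors(g)
    indeg = [len(in_nb[v]) for v in g.pathway.vertices]
    outdeg = [len(out_nb[v]) for v in g.pathway.vertices]
    out = {}
    for name, deg in (("in", indeg), ("out", outdeg)):
        out[f"degree.{name}_mean"] = _mean(deg)
        out[f"degree.{name}_variance"] = _var(deg)
        out[f"degree.{name}_median"] = _median(deg)
        out[f"degree.{name}_max"] = _max(deg)
    return out


def edge_weight_statistics(g: WeightedPathwayGraph) -> dict[str, float]:
    n = g.pathway.n_vertices
    ws = list(g.weights.values())
    # "with missing edges": every ordered pair counts, absent arcs as 0
    full = ws + [0.0] * (n * n - len(ws))
    positive = [w for w in ws if w > 0.0]
    return {
        "weight.mean_with_missing": _mean(full),
        "weight.variance_with_missing": _var(full),
        "weight.mean_without_missing": _mean(positive),
        "weight.variance_without_missing": _var(positive),
    }


def topology_change(g: WeightedPathwayGraph) -> dict[str, float]:
    """Change rate of the arc count between consecutive weight cutoffs."""
    ws = list(g.weights.values())
    counts = [sum(1 for w in ws if w > c) for c in TOPOLOGY_CUTOFFS]
    out = {}
    for k in range(len(TOPOLOGY_CUTOFFS) - 1):
        lo, hi = TOPOLOGY_CUTOFFS[k], TOPOLOGY_CUTOFFS[k + 1]
        out[f"topology_change.c{lo:g}_{hi:g}"] = (
            counts[k] - counts[k + 1]
        ) / max(counts[k], 1)
    return out


def degree_correlation(
    g: WeightedPathwayGraph, neighbor_degree: str = "total"
) -> dict[str, float]:
    """Mean arc count of each vertex's in- and out-neighborhoods.

    ``neighbor_degree="total"`` scores a neighbor by its total degree
    (in + out); ``"directional"`` uses the in-degree of in-neighbors and the
    out-degree of out-neighbors.
    """
    if neighbor_degree not in ("total", "directional"):
        raise ValueError(f"unknown neighbor_degree {neighbor_degree!r}")
    in_nb, out_nb = _neighbors(g)
    a_vals, b_vals = [], []
    for v in g.pathway.vertices:
        if neighbor_degree == "total":
            score_in = score_out = lambda u: len(in_nb[u]) + len(out_nb[u])
        else:
            score_in = lambda u: len(in_nb[u])
            score_out = lambda u: len(out_nb[u])
        a_vals.append(_mean([score_in(u) for u in in_nb[v]]))
        b_vals.append(_mean([score_out(u) for u in out_nb[v]]))
    out = {}
    for name, vals in (("in", a_vals), ("out", b_vals)):
        out[f"degree_correlation.{name}_mean"] = _mean(vals)
        out[f"degree_correlation.{name}_variance"] = _var(vals)
        out[f"degree_correlation.{name}_max"] = _max(vals)
    return out


def clustering(g: WeightedPathwayGraph) -> dict[str, float]:
    """Density of the sub-digraph induced by each vertex's neighborhoods."""
    in_nb, out_nb = _neighbors(g)
    arcs = g.pathway.arcs

    def sub_density(nbhood: set[str]) -> float:
        k = len(nbhood)
        if k == 0:
            return 0.0
        m = sum(1 for a, b in arcs if a in nbhood and b in nbhood)
        return m / k**2

    in_vals = [sub_density(in_nb[v]) for v in g.pathway.vertices]
    out_vals = [sub_density(out_nb[v]) for v in g.pathway.vertices]
    out = {}
    for name, vals in (("in", in_vals), ("out", out_vals)):
        out[f"clustering.{name}_mean"] = _mean(vals)
        out[f"clustering.{name}_variance"] = _var(vals)
        out[f"clustering.{name}_max"] = _max(vals)
    return out


def topological(
    g: WeightedPathwayGraph, t4_denominator: str = "out"
) -> dict[str, float]:
    """Normalized neighborhood-overlap statistics T1..T4.

    For each ordered vertex pair (u_i, u_j), j != i, the in-in / in-out /
    out-in / out-out overlaps are the sizes of the intersections of the
    respective neighbor sets.  T_i1 and T_i2 are the per-i means normalized
    by the in-degree n_i1; T_i3 by the out-degree n_i2.  T_i4 defaults to
    the n_i2 normalization (``t4_denominator="in"`` selects n_i1 instead);
    a zero divisor makes the whole term 0.
    """
    if t4_denominator not in ("out", "in"):
        raise ValueError(f"unknown t4_denominator {t4_denominator!r}")
    in_nb, out_nb = _neighbors(g)
    vs = g.pathway.vertices
    t = {1: [], 2: [], 3: [], 4: []}
    for vi in vs:
        n1, n2 = len(in_nb[vi]), len(out_nb[vi])
        n4 = n2 if t4_denominator == "out" else n1
        sums = [0.0, 0.0, 0.0, 0.0]
        others = [vj for vj in vs if vj != vi]
        for vj in others:
            sums[0] += len(in_nb[vi] & in_nb[vj]) / n1 if n1 else 0.0
            sums[1] += len(in_nb[vi] & out_nb[vj]) / n1 if n1 else 0.0
            sums[2] += len(out_nb[vi] & in_nb[vj]) / n2 if n2 else 0.0
            sums[3] += len(out_nb[vi] & out_nb[vj]) / n4 if n4 else 0.0
        k = len(others)
        for idx in range(4):
            t[idx + 1].append(sums[idx] / k if k else 0.0)
    out = {}
    for idx in (1, 2, 3, 4):
        out[f"topological.T{idx}_mean"] = _mean(t[idx])
        out[f"topological.T{idx}_variance"] = _var(t[idx])
        out[f"topological.T{idx}_max"] = _max(t[idx])
    return out


def singular_values(g: WeightedPathwayGraph) -> dict[str, float]:
    """Three largest singular values of the 0/1 adjacency matrix."""
    vs = g.pathway.vertices
    n = len(vs)
    index = {v: i for i, v in enumerate(vs)}
    adj = np.zeros((n, n))
    for a, b in g.pathway.arcs:
        adj[index[a], index[b]] = 1.0
    sv = np.linalg.svd(adj, compute_uv=False) if n else np.array([])
    padded = np.concatenate([sv, np.zeros(3)])[:3]
    return {f"singular.s{i + 1}": float(padded[i]) for i in range(3)}


def local_density_change(
    g: WeightedPathwayGraph,
    proteins: dict[str, ProteinRecord],
    universe: AnnotationUniverse,
    go_sim: np.ndarray | None = None,
) -> dict[str, float]:
    """Density of GO-similarity subgraphs over each vertex's neighborhoods.

    For each vertex, a complete undirected graph is built on its
    out-neighbors (resp. in-neighbors) with GO-cosine edge weights; for each
    cutoff w, edges of weight > w are kept and the undirected density
    L = 2|E| / (l(l-1)) is computed (0 when the neighborhood has <= 1
    member).  Features: mean and max of L over vertices, per cutoff and
    direction — 10 x 2 x 2 = 40 values.
    """
    vs = g.pathway.vertices
    index = {v: i for i, v in enumerate(vs)}
    if go_sim is None:
        mat = pathway_go_matrix(g.pathway, proteins, universe)
        go_sim = cosine_matrix(mat) if mat.size else np.zeros((len(vs), len(vs)))
    in_nb, out_nb = _neighbors(g)

    def densities(neighborhoods: list[set[str]], cutoff: float) -> list[float]:
        vals = []
        for nbhood in neighborhoods:
            l = len(nbhood)
            if l <= 1:
                vals.append(0.0)
                continue
            idx = [index[u] for u in nbhood]
            kept = 0
            for i in range(l):
                for j in range(i + 1, l):
                    if go_sim[idx[i], idx[j]] > cutoff:
                        kept += 1
            vals.append(2.0 * kept / (l * (l - 1)))
        return vals

    out_hoods = [out_nb[v] for v in vs]
    in_hoods = [in_nb[v] for v in vs]
    out = {}
    for direction, hoods in (("out", out_hoods), ("in", in_hoods)):
        for c in LOCAL_DENSITY_CUTOFFS:
            vals = densities(hoods, c)
            out[f"local_density.{direction}.c{c:g}_mean"] = _mean(vals)
            out[f"local_density.{direction}.c{c:g}_max"] = _max(vals)
    return out


def graph_feature_block(
    g: WeightedPathwayGraph,
    proteins: dict[str, ProteinRecord],
    universe: AnnotationUniverse,
    neighbor_degree: str = "total",
    t4_denominator: str = "out",
) -> dict[str, float]:
    """All 88 graph features, in fixed group order."""
    mat = pathway_go_matrix(g.pathway, proteins, universe)
    n = g.pathway.n_vertices
    go_sim = cosine_matrix(mat) if mat.size else np.zeros((n, n))
    block: dict[str, float] = {}
    block.update(size_density(g))
    block.update(degree_statistics(g))
    block.update(edge_weight_statistics(g))
    block.update(topology_change(g))
    block.update(degree_correlation(g, neighbor_degree=neighbor_degree))
    block.update(clustering(g))
    block.update(topological(g, t4_denominator=t4_denominator))
    block.update(singular_values(g))
    block.update(local_density_change(g, proteins, universe, go_sim=go_sim))
    assert len(block) == N_GRAPH_FEATURES
    return block


def graph_feature_names() -> list[str]:
    """Stable ordered names of the 88 graph features."""
    from .datamodel import Pathway

    dummy = WeightedPathwayGraph(
        Pathway(id="_", vertices=["a"], arcs=set()), weights={}
    )
    return list(graph_feature_block(dummy, {"a": ProteinRecord("a")},
                                    AnnotationUniverse([], 0, {})).keys())
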