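"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops over sets and lists, sharing the
documented conventions (population variance, strict cutoff comparisons,
self-excluded neighborhoods, empty-set statistics = 0) but none of the
package's vectorized code paths.
"""

from __future__ import annotations

import math
import statistics
from fractions import Fraction


def mean(xs):
    xs = list(xs)
    return sum(xs) / len(xs) if xs else 0.0


def pvar(xs):
    xs = list(xs)
    if not xs:
        return 0.0
    m = mean(xs)
    return sum((x - m) ** 2 for x in xs) / len(xs)


def vmax(xs):
    xs = list(xs)
    return max(xs) if xs else 0.0


def set_cosine(a: set, b: set) -> float:
    """|A n B| / sqrt(|A||B|): cosine of binary indicator vectors."""
    if not a or not b:
        return 0.0
    return len(a & b) / math.sqrt(len(a) * len(b))


def naive_graph_features(vertices, arcs, weights, go_sets):
    """All 88 graph features by direct enumeration.

    ``vertices``: ordered list; ``arcs``: set of (src, tgt); ``weights``:
    arc -> GO-cosine weight; ``go_sets``: vertex -> set of GO terms (for
    local density change).
    """
    n = len(vertices)
    feats = {}
    in_nb = {v: {a for (a, b) in arcs if b == v and a != v} for v in vertices}
    out_nb = {v: {b for (a, b) in arcs if a == v and b != a} for v in vertices}

    feats["size.n_vertices"] = float(n)
    feats["size.density"] = len(arcs) / n**2 if n else 0.0

    indeg = [len(in_nb[v]) for v in vertices]
    outdeg = [len(out_nb[v]) for v in vertices]
    for name, deg in (("in", indeg), ("out", outdeg)):
        feats[f"degree.{name}_mean"] = mean(deg)
        feats[f"degree.{name}_variance"] = pvar(deg)
        feats[f"degree.{name}_median"] = float(statistics.median(deg)) if deg else 0.0
        feats[f"degree.{name}_max"] = vmax(deg)

    ws = [weights[a] for a in arcs]
    full = ws + [0.0] * (n * n - len(ws))
    pos = [w for w in ws if w > 0]
    feats["weight.mean_with_missing"] = mean(full)
    feats["weight.variance_with_missing"] = pvar(full)
    feats["weight.mean_without_missing"] = mean(pos)
    feats["weight.variance_without_missing"] = pvar(pos)

    cutoffs = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
    counts = [sum(1 for w in ws if w > c) for c in cutoffs]
    for k in range(7):
        feats[f"topology_change.c{cutoffs[k]:g}_{cutoffs[k + 1]:g}"] = (
            counts[k] - counts[k + 1]
        ) / max(counts[k], 1)

    def total_degree(u):
        return len(in_nb[u]) + len(out_nb[u])

    a_vals = [mean([total_degree(u) for u in in_nb[v]]) for v in vertices]
    b_vals = [mean([total_degree(u) for u in out_nb[v]]) for v in vertices]
    for name, vals in (("in", a_vals), ("out", b_vals)):
        feats[f"degree_correlation.{name}_mean"] = mean(vals)
        feats[f"degree_correlation.{name}_variance"] = pvar(vals)
        feats[f"degree_correlation.{name}_max"] = vmax(vals)

    def sub_density(nbhood):
        if not nbhood:
            return 0.0
        m = sum(1 for (a, b) in arcs if a in nbhood and b in nbhood)
        return m / len(nbhood) ** 2

    in_dens = [sub_density(in_nb[v]) for v in vertices]
    out_dens = [sub_density(out_nb[v]) for v in vertices]
    for name, vals in (("in", in_dens), ("out", out_dens)):
        feats[f"clustering.{name}_mean"] = mean(vals)
        feats[f"clustering.{name}_variance"] = pvar(vals)
        feats[f"clustering.{name}_max"] = vmax(vals)

    t_vals = {1: [], 2: [], 3: [], 4: []}
    for vi in vertices:
        n1, n2 = len(in_nb[vi]), len(out_nb[vi])
        per_j = {1: [], 2: [], 3: [], 4: []}
        for vj in vertices:
            if vj == vi:
                continue
            per_j[1].append(len(in_nb[vi] & in_nb[vj]) / n1 if n1 else 0.0)
            per_j[2].append(len(in_nb[vi] & out_nb[vj]) / n1 if n1 else 0.0)
            per_j[3].append(len(out_nb[vi] & in_nb[vj]) / n2 if n2 else 0.0)
            per_j[4].append(len(out_nb[vi] & out_nb[vj]) / n2 if n2 else 0.0)
        for idx in (1, 2, 3, 4):
            t_vals[idx].append(mean(per_j[idx]))
    for idx in (1, 2, 3, 4):
        feats[f"topological.T{idx}_mean"] = mean(t_vals[idx])
        feats[f"topological.T{idx}_variance"] = pvar(t_vals[idx])
        feats[f"topological.T{idx}_max"] = vmax(t_vals[idx])

    # singular values via eigenvalues of A A^T (independent of the SVD path)
    import numpy as np

    adj = [[1.0 if (u, v) in arcs else 0.0 for v in vertices] for u in vertices]
    if n:
        gram = [
            [sum(adj[i][k] * adj[j][k] for k in range(n)) for j in range(n)]
            for i in range(n)
        ]
        eig = sorted((max(x, 0.0) for x in np.linalg.eigvalsh(gram)), reverse=True)
        floor = 1e-12 * max(1.0, eig[0])  # eigvalsh noise, amplified by sqrt
        sv = [math.sqrt(x) if x > floor else 0.0 for x in eig] + [0.0, 0.0, 0.0]
    else:
        sv = [0.0, 0.0, 0.0]
    for i in range(3):
        feats[f"singular.s{i + 1}"] = sv[i]

    ld_cutoffs = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]

    def local_density(nbhood, cutoff):
        l = len(nbhood)
        if l <= 1:
            return 0.0
        kept = 0
        nb = sorted(nbhood)
        for i in range(l):
            for j in range(i + 1, l):
                if set_cosine(go_sets[nb[i]], go_sets[nb[j]]) > cutoff:
                    kept += 1
        return 2.0 * kept / (l * (l - 1))

    for direction, nbs in (("out", out_nb), ("in", in_nb)):
        for c in ld_cutoffs:
            vals = [local_density(nbs[v], c) for v in vertices]
            feats[f"local_density.{direction}.c{c:g}_mean"] = mean(vals)
            feats[f"local_density.{direction}.c{c:g}_max"] = vmax(vals)
    assert len(feats) == 88
    return feats


def exact_hypergeom_upper(N: int, M: int, n: int, k: int) -> Fraction:
    """P(X >= k) as an exact rational tail sum."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(M, n) + 1):
        acc += math.comb(M, i) * math.comb(N - M, n - i)
    return Fraction(acc, total)


def naive_mutual_information(x, y) -> float:
    """Direct double sum over the observed joint distribution (bits)."""
    n = len(x)
    assert n == len(y)
    xs, ys = sorted(set(x)), sorted(set(y))
    total = 0.0
    for a in xs:
        for b in ys:
            pab = sum(1 for i in range(n) if x[i] == a and y[i] == b) / n
            if pab == 0:
                continue
            pa = sum(1 for i in range(n) if x[i] == a) / n
            pb = sum(1 for i in range(n) if y[i] == b) / n
            total += pab * math.log2(pab / (pa * pb))
    return total


def naive_discretize(column):
    m = mean(column)
    s = math.sqrt(pvar(column))
    return [1 if x > m + s else (-1 if x < m - s else 0) for x in column]


def naive_mrmr(columns, labels, depth=None):
    """Exhaustive greedy MID mRMR on pre-discretized columns."""
    n_feat = len(columns)
    depth = n_feat if depth is None else min(depth, n_feat)
    relevance = [naive_mutual_information(c, labels) for c in columns]
    selected = []
    for _ in range(depth):
        best, best_score = None, None
        for f in range(n_feat):
            if f in selected:
                continue
            red = mean([naive_mutual_information(columns[f], columns[s])
                        for s in selected]) if selected else 0.0
            score = relevance[f] - red
            if best_score is None or score > best_score + 1e-12:
                best, best_score = f, score
        selected.append(best)
    return selected


def naive_ctd_scan(coded: str, classes: str, d_classes: str | None = None):
    """Position-scanning CTD oracle."""
    if d_classes is None:
        d_classes = classes
    L = len(coded)
    out = {}
    for cls in d_classes:
        out[f"C.{cls}"] = 100.0 * sum(1 for c in coded if c == cls) / L
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a, b = classes[i], classes[j]
            count = 0
            for k in range(L - 1):
                pair = coded[k] + coded[k + 1]
                if pair in (a + b, b + a):
                    count += 1
            out[f"T.{a}{b}"] = 100.0 * count / (L - 1) if L > 1 else 0.0
    for cls in d_classes:
        positions = [i + 1 for i, c in enumerate(coded) if c == cls]
        m = len(positions)
        if m == 0:
            vals = [0.0] * 5
        else:
            ranks = [1, max(1, math.ceil(0.25 * m)), max(1, math.ceil(0.5 * m)),
                     max(1, math.ceil(0.75 * m)), m]
            vals = [100.0 * positions[r - 1] / L for r in ranks]
        for q, v in zip(("first", "q25", "q50", "q75", "last"), vals):
            out[f"D.{cls}.{q}"] = v
    return out


def random_digraph(rng, max_n=6, arc_p=0.4, universe_size=8, max_terms=4):
    """A random pathway-like digraph with GO term sets per vertex."""
    n = int(rng.integers(1, max_n + 1))
    vertices = [f"v{i}" for i in range(n)]
    arcs = {
        (a, b)
        for a in vertices
        for b in vertices
        if rng.random() < arc_p
    }
    universe = [f"GO:{i:07d}" for i in range(1, universe_size + 1)]
    go_sets = {
        v: set(rng.choice(universe, size=int(rng.integers(0, max_terms + 1)),
                          replace=False))
        for v in vertices
    }
    return vertices, arcs, go_sets, universe
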