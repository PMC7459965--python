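"""Independent brute-force reference implementations.

Everything here is written from the definitions, in plain Python loops,
deliberately sharing no code with the package: median-of-ratios size
factors, the product-moment correlation, the tie-corrected Kruskal-Wallis
statistic, naive agglomerative clustering, covariance-eigendecomposition
PCA, and the full screen filter.  Tests compare the package against these.
"""

from __future__ import annotations

import math

import numpy as np


def size_factors(counts) -> list[float]:
    """Median-of-ratios from the definition, plain loops."""
    counts = [[float(v) for v in row] for row in counts]
    n_t, n_s = len(counts), len(counts[0])
    ref = [i for i in range(n_t) if all(counts[i][j] > 0 for j in range(n_s))]
    assert ref, "empty reference set"
    geo = {}
    for i in ref:
        geo[i] = math.exp(sum(math.log(v) for v in counts[i]) / n_s)
    out = []
    for j in range(n_s):
        ratios = sorted(counts[i][j] / geo[i] for i in ref)
        k = len(ratios)
        med = ratios[k // 2] if k % 2 else 0.5 * (ratios[k // 2 - 1] + ratios[k // 2])
        out.append(med)
    return out


def pearson(x, y) -> float:
    """Definitional covariance / (sd_x sd_y); NaN if either is constant."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)


def midranks(values) -> list[float]:
    """Average ranks (1-based), ties get the mean of their rank span."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_h(groups) -> float:
    """Rank-sum H with tie correction 1 - sum(t^3 - t)/(N^3 - N)."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r_sum = sum(ranks[start:start + len(g)])
        h += r_sum ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts: dict[float, int] = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    correction = 1.0 - sum(t ** 3 - t for t in counts.values()) / (n ** 3 - n)
    if correction == 0:
        return 0.0
    return h / correction


def _cluster_distance(points_a, points_b, method) -> float:
    dists = [math.dist(p, q) for p in points_a for q in points_b]
    if method == "single":
        return min(dists)
    if method == "complete":
        return max(dists)
    return sum(dists) / len(dists)  # average (UPGMA on points)


def agglomerate(X, method="average") -> list[tuple[int, int, float]]:
    """Naive O(n^3) agglomeration; new cluster k gets id n + k.

    Ties broken by the smallest (id_a, id_b) pair.  Returns merge triples
    (id_a, id_b, height) with id_a < id_b.
    """
    X = [list(map(float, row)) for row in X]
    n = len(X)
    clusters = {i: [X[i]] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                d = _cluster_distance(clusters[a], clusters[b], method)
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def pca_eig(X, n_components):
    """PCA via eigendecomposition of the feature covariance matrix.

    Returns (scores, explained_pct) with no sign convention applied.
    """
    X = np.asarray(X, dtype=float)
    C = X - X.mean(axis=0)
    cov = C.T @ C
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    scores = C @ evecs[:, :n_components]
    total = evals.sum()
    explained = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    return scores, explained


def screen_filter(values, meta, efficiency, base_mean_min=1.0, score_min=1.99):
    """Re-derivation of the full pass/fail filter, one transcript at a time.

    ``values`` is a dict transcript_id -> {sample_id: normalized value},
    ``meta`` a dict sample_id -> (female_id, condition), ``efficiency`` a
    dict female_id -> percent.  Returns the set of passing transcript IDs.
    """
    females = sorted(efficiency)
    eff = [efficiency[f] for f in females]
    passing = set()
    for tid, row in values.items():
        base_mean = sum(row.values()) / len(row)
        rs = []
        for cond in ("control", "gynogenetic"):
            expr = []
            for f in females:
                sids = [s for s, (fem, c) in meta.items() if fem == f and c == cond]
                assert len(sids) == 1
                expr.append(row[sids[0]])
            rs.append(pearson(expr, eff))
        if any(math.isnan(r) for r in rs):
            continue
        score = abs(rs[0]) + abs(rs[1])
        if base_mean > base_mean_min and score > score_min:
            passing.add(tid)
    return passing
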