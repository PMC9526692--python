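"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def anova_bruteforce(groups) -> tuple[float, float]:
    """Textbook sums-of-squares one-way ANOVA."""
    groups = [np.asarray(g, float) for g in groups]
    n = [len(g) for g in groups]
    N, k = sum(n), len(groups)
    grand = sum(g.sum() for g in groups) / N
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f_stat = (ssb / (k - 1)) / (ssw / (N - k))
    return f_stat, float(stats.f.sf(f_stat, k - 1, N - k))


def tukey_bruteforce(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Tukey-Kramer p-values from pooled MSE and the studentized range."""
    names = list(groups)
    arrs = [np.asarray(groups[c], float) for c in names]
    N, k = sum(len(a) for a in arrs), len(arrs)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrs) / (N - k)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[i], arrs[j]
            se = math.sqrt(mse / 2 * (1 / len(a) + 1 / len(b)))
            q = abs(a.mean() - b.mean()) / se
            out[(names[i], names[j])] = float(stats.studentized_range.sf(q, k, N - k))
    return out


def hypergeom_enumerate(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) by direct enumeration (small N only)."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
    ) / total


def shapely_rho(point, centrosome, polygon) -> float:
    """Normalized radius via shapely ray-boundary intersection."""
    from shapely.geometry import LinearRing, LineString, Point

    c = np.asarray(centrosome, float)
    p = np.asarray(point, float)
    d = p - c
    dist = float(np.hypot(*d))
    if dist == 0:
        return 0.0
    u = d / dist
    poly = np.asarray(polygon, float)
    reach = 4 * (np.abs(poly - c).max() + 1)
    seg = LineString([tuple(c), tuple(c + u * reach)])
    inter = seg.intersection(LinearRing(poly))
    if inter.is_empty:
        raise ValueError("ray misses the boundary")
    geoms = list(getattr(inter, "geoms", [inter]))
    pts = []
    for g in geoms:
        if g.geom_type == "Point":
            pts.append(g)
        else:
            pts.extend(Point(xy) for xy in g.coords)
    origin = Point(tuple(c))
    dists = [origin.distance(q) for q in pts if origin.distance(q) > 1e-9]
    return dist / min(dists)


def average_linkage_bruteforce(x: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Naive agglomerative average-linkage (euclidean): merge order + heights."""
    clusters = {i: frozenset([i]) for i in range(len(x))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean(
                    [
                        np.linalg.norm(x[i] - x[j])
                        for i in clusters[a]
                        for j in clusters[b]
                    ]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], float(d)))
        clusters[min(a, b)] = clusters[a] | clusters[b]
        del clusters[max(a, b)]
    return merges
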