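"""Independent brute-force oracles used to verify the fast implementations.

Everything here is written for clarity, not speed: explicit Python loops,
no shared code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def brute_max_projection(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over slices via explicit loops."""
    n, rows, cols = stack.shape
    out = np.empty((rows, cols), dtype=stack.dtype)
    for r in range(rows):
        for c in range(cols):
            best = stack[0, r, c]
            for s in range(1, n):
                if stack[s, r, c] > best:
                    best = stack[s, r, c]
            out[r, c] = best
    return out


def brute_yen_argmax(hist) -> int:
    """Exhaustive-search maximizer of Yen's criterion over all splits.

    For each candidate t the criterion is computed from scratch with
    explicit sums: TC(t) = 2 ln(P1 P2) - ln(G1 G2), with P the class
    masses and G the within-class sums of squared probabilities.
    Returns the lowest maximizing t.
    """
    p = [h / sum(hist) for h in hist]
    n = len(p)
    best_t, best_val = None, -math.inf
    for t in range(n - 1):
        p1 = sum(p[: t + 1])
        p2 = 1.0 - p1
        g1 = sum(x * x for x in p[: t + 1])
        g2 = sum(x * x for x in p[t + 1:])
        if p1 <= 0 or p2 <= 0 or g1 <= 0 or g2 <= 0:
            continue
        val = 2.0 * math.log(p1 * p2) - math.log(g1 * g2)
        if val > best_val:
            best_t, best_val = t, val
    return best_t


def brute_feret(mask: np.ndarray) -> float:
    """O(n^2) maximum pairwise distance between boundary pixel centers."""
    coords = []
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            on_border = (r == 0 or r == rows - 1 or c == 0 or c == cols - 1
                         or not mask[r - 1, c] or not mask[r + 1, c]
                         or not mask[r, c - 1] or not mask[r, c + 1])
            if on_border:
                coords.append((r, c))
    best = 0.0
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            d = math.dist(coords[i], coords[j])
            if d > best:
                best = d
    return best


def brute_glcm(img: np.ndarray, offset: tuple[int, int], n_levels: int,
               symmetric: bool = False) -> np.ndarray:
    """Double-loop pair counting of quantized co-occurrences."""
    dr, dc = offset
    rows, cols = img.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                counts[img[r, c], img[r2, c2]] += 1
                if symmetric:
                    counts[img[r2, c2], img[r, c]] += 1
    return counts / counts.sum()


def brute_texture(P: np.ndarray) -> tuple[float, float, float]:
    """Entropy/contrast/correlation by explicit double sums."""
    n = P.shape[0]
    entropy = 0.0
    contrast = 0.0
    for i in range(n):
        for j in range(n):
            if P[i, j] > 0:
                entropy -= P[i, j] * math.log(P[i, j])
            contrast += P[i, j] * (i - j) ** 2
    mu_i = sum(i * P[i, j] for i in range(n) for j in range(n))
    mu_j = sum(j * P[i, j] for i in range(n) for j in range(n))
    var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(n) for j in range(n))
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    if var_i <= 0 or var_j <= 0:
        corr = float("nan")
    else:
        corr = sum((i - mu_i) * (j - mu_j) * P[i, j]
                   for i in range(n) for j in range(n)) / math.sqrt(var_i * var_j)
    return entropy, contrast, corr


def brute_upgma(X: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) average-linkage agglomeration on rows of X.

    Inter-cluster distance is the mean over all member pairs of Euclidean
    row distances. Returns the merge list [(members_a, members_b, height)].
    """
    n = X.shape[0]
    d = {(i, j): math.dist(X[i], X[j]) for i in range(n) for j in range(i + 1, n)}

    def dist(a: frozenset, b: frozenset) -> float:
        return sum(d[(min(i, j), max(i, j))] for i in a for j in b) / (len(a) * len(b))

    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = dist(clusters[i], clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        a, b = clusters[i], clusters[j]
        merges.append((a, b, h))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(a | b)
    return merges


def brute_pooled_t(g1, g2) -> tuple[float, int]:
    """Pooled-variance t statistic and df via the textbook formulas."""
    n1, n2 = len(g1), len(g2)
    m1 = sum(g1) / n1
    m2 = sum(g2) / n2
    s1 = sum((x - m1) ** 2 for x in g1) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in g2) / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    t = (m1 - m2) / (sp * math.sqrt(1 / n1 + 1 / n2))
    return t, n1 + n2 - 2


def brute_ols(x, y) -> tuple[float, float]:
    """Closed-form normal-equations slope/intercept."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    sxx = sum((xi - mx) ** 2 for xi in x)
    slope = sxy / sxx
    return slope, my - slope * mx
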