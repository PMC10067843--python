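"""Independent brute-force oracles used to cross-check the implementations.

Every oracle here recomputes a quantity from its definition by direct
enumeration or direct evaluation, sharing no code path with the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pearson_two_pass(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r by the textbook two-pass covariance formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.size
    ma, mb = a.sum() / n, b.sum() / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    return cov / np.sqrt(va * vb)


def otsu_exhaustive(values: np.ndarray, bins: int = 256) -> float:
    """Otsu threshold by explicit search over every histogram split.

    Same definition as the implementation (256-bin histogram of min-max
    stretched values, threshold at the upper edge of the best split bin,
    ties to the lowest split) but evaluated with plain Python loops.
    """
    values = np.asarray(values, float)
    vmin, vmax = values.min(), values.max()
    stretched = (values - vmin) / (vmax - vmin)
    counts, edges = np.histogram(stretched, bins=bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    best_var, best_split = -1.0, 0
    for split in range(bins - 1):
        w0 = counts[: split + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: split + 1] * centers[: split + 1]).sum() / w0
        mu1 = (counts[split + 1 :] * centers[split + 1 :]).sum() / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-15:
            best_var, best_split = var, split
    return vmin + edges[best_split + 1] * (vmax - vmin)


def mannwhitney_exact_enumeration(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney (U of sample a, p) by full enumeration.

    Tie-free samples only.  Enumerates every C(n+m, n) assignment of the
    pooled ranks to group a and counts arrangements at least as extreme (in
    either tail) as the observed U.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = a.size, b.size
    u_obs = sum(1 for x in a for y in b if x > y)
    nm = n * m
    lo, hi = min(u_obs, nm - u_obs), max(u_obs, nm - u_obs)
    pooled_ranks = range(n + m)
    count = total = 0
    for positions in combinations(pooled_ranks, n):
        pos = set(positions)
        u = sum(1 for p in positions for q in pooled_ranks if q not in pos and p > q)
        total += 1
        if u <= lo or u >= hi:
            count += 1
    return float(u_obs), count / total


def ks_brute_force(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS D by evaluating both ECDFs at every pooled point."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        d = max(d, abs(fa - fb))
    return float(d)


def naive_average_linkage(dist: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) average-linkage agglomeration from a full distance matrix.

    Returns the merge sequence as (members_i, members_j, height) with the
    average-linkage height = mean pairwise distance between the two clusters.
    """
    n = dist.shape[0]
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for i, j in combinations(sorted(clusters), 2):
            members_i, members_j = clusters[i], clusters[j]
            height = np.mean([dist[p, q] for p in members_i for q in members_j])
            if best is None or height < best[0]:
                best = (height, i, j)
        height, i, j = best
        merges.append((clusters[i], clusters[j], float(height)))
        clusters[next_id] = clusters.pop(i) | clusters.pop(j)
        next_id += 1
    return merges


def correlation_distance_matrix(rows: np.ndarray) -> np.ndarray:
    n = rows.shape[0]
    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        dist[i, j] = dist[j, i] = 1.0 - pearson_two_pass(rows[i], rows[j])
    return dist


def convolve_brute_force(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct convolution with reflective boundary handling (no FFT, no scipy)."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    # edge-inclusive reflection: (c b a | a b c) -- numpy calls this "symmetric"
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode="symmetric")
    flipped = kernel[::-1, ::-1]  # convolution flips the kernel
    out = np.zeros_like(np.asarray(image, float))
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    acc += flipped[i, j] * padded[r + i, c + j]
            out[r, c] = acc
    return out


def percentile_linear_interpolation(values: np.ndarray, q: float) -> float:
    """Percentile by sorting and interpolating between closest ranks."""
    x = np.sort(np.asarray(values, float))
    rank = (q / 100.0) * (x.size - 1)
    lo = int(np.floor(rank))
    hi = int(np.ceil(rank))
    frac = rank - lo
    return float(x[lo] * (1 - frac) + x[hi] * frac)
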