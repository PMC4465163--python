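"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — pure-Python loops and exhaustive
enumeration — and shares no code with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np

OFFSETS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3)
              if d != (0, 0, 0) and d > (0, 0, 0)]
OFFSETS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3)
              if d != (0, 0, 0)]


def naive_glcm_merged(bins: np.ndarray, mask: np.ndarray, n_bins: int
                      ) -> np.ndarray:
    """Triple-loop symmetric pooled-count GLCM over the 13 unit offsets."""
    counts = np.zeros((n_bins, n_bins), dtype=float)
    shape = bins.shape
    for z, y, x in np.argwhere(mask):
        for dz, dy, dx in OFFSETS_13:
            z2, y2, x2 = z + dz, y + dy, x + dx
            if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2] \
                    and mask[z2, y2, x2]:
                i, j = bins[z, y, x] - 1, bins[z2, y2, x2] - 1
                counts[i, j] += 1
                counts[j, i] += 1  # symmetrization == counting both directions
    total = counts.sum()
    return counts / total if total else counts


def naive_glcm_entropy(p: np.ndarray, base: float = 2.0) -> float:
    return -sum(v * math.log(v, base) for v in p.ravel() if v > 0)


def naive_glcm_contrast(p: np.ndarray) -> float:
    n = p.shape[0]
    return sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))


def naive_glcm_correlation(p: np.ndarray) -> float:
    n = p.shape[0]
    marg = p.sum(axis=1)
    mu = sum((i + 1) * marg[i] for i in range(n))
    var = sum((i + 1 - mu) ** 2 * marg[i] for i in range(n))
    if var == 0:
        return 1.0
    return sum((i + 1 - mu) * (j + 1 - mu) * p[i, j]
               for i in range(n) for j in range(n)) / var


def naive_ngtdm(bins: np.ndarray, mask: np.ndarray) -> dict[int, tuple[float, float]]:
    """{level: (p_i, s_i)} by per-voxel neighborhood enumeration."""
    shape = bins.shape
    contributions: dict[int, list[float]] = {}
    n_valid = 0
    for z, y, x in np.argwhere(mask):
        nbrs = []
        for dz, dy, dx in OFFSETS_26:
            z2, y2, x2 = z + dz, y + dy, x + dx
            if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2] \
                    and mask[z2, y2, x2]:
                nbrs.append(bins[z2, y2, x2])
        if not nbrs:
            continue
        n_valid += 1
        lvl = int(bins[z, y, x])
        contributions.setdefault(lvl, []).append(
            abs(lvl - sum(nbrs) / len(nbrs)))
    return {lvl: (len(devs) / n_valid, sum(devs))
            for lvl, devs in contributions.items()}


def naive_coarseness_busyness(table: dict[int, tuple[float, float]],
                              eps: float = 1e-6) -> tuple[float, float]:
    ps = sum(p * s for p, s in table.values())
    coarseness = 1.0 / (eps + ps)
    levels = sorted(table)
    denom = sum(abs(i * table[i][0] - j * table[j][0])
                for i in levels for j in levels if i != j)
    busyness = ps / denom if denom > 0 else 0.0
    return coarseness, busyness


def bfs_component(supra: np.ndarray, seed: tuple[int, int, int],
                  connectivity: int = 26) -> np.ndarray:
    """Breadth-first flood fill of the supra-threshold component at `seed`."""
    if connectivity == 6:
        offs = [d for d in OFFSETS_26 if sum(abs(v) for v in d) == 1]
    elif connectivity == 18:
        offs = [d for d in OFFSETS_26 if sum(abs(v) for v in d) <= 2]
    else:
        offs = OFFSETS_26
    shape = supra.shape
    out = np.zeros(shape, dtype=bool)
    if not supra[seed]:
        return out
    out[seed] = True
    queue = deque([seed])
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offs:
            z2, y2, x2 = z + dz, y + dy, x + dx
            if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2] \
                    and supra[z2, y2, x2] and not out[z2, y2, x2]:
                out[z2, y2, x2] = True
                queue.append((z2, y2, x2))
    return out


def pair_count_auc(scores, labels) -> float:
    """AUC as the fraction of correctly ordered positive-negative pairs,
    ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_corner_cutoff(scores, labels) -> tuple[float, float]:
    """(min distance to (0,1), best cutoff) scanning every candidate
    threshold of the rule `score >= t -> positive`, ties toward higher
    specificity then (arbitrarily) the larger threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    m = (labels == 1).sum()
    n = (labels == 0).sum()
    candidates = np.unique(scores)
    best = None
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / m
        spec = (~pred & (labels == 0)).sum() / n
        d = math.hypot(1 - sens, 1 - spec)
        key = (round(d, 12), round(1 - spec, 12))
        if best is None or key < best[0]:
            best = (key, t, d)
    return best[2], best[1]
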