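"""Independent brute-force oracles used by the test suite.

Everything here is a literal transcription of the defining sums with
explicit Python loops — deliberately slow, deliberately independent of the
vectorized implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

# Offsets (dr, dc) per angular direction at unit distance, matching the
# accumulation convention of compute_glcm (angle theta pairs pixel (r, c)
# with (r + d sin theta, c + d cos theta)); under symmetric accumulation the
# offset sign is irrelevant.
DIRECTION_OFFSETS = {0.0: (0, 1), 45.0: (1, 1), 90.0: (1, 0), 135.0: (1, -1)}


def brute_glcm(image: np.ndarray, levels: int, angle: float,
               distance: int = 1) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one direction."""
    dr, dc = DIRECTION_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = image.shape
    counts = np.zeros((levels, levels), dtype=float)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                i, j = int(image[r, c]), int(image[r2, c2])
                counts[i, j] += 1
                counts[j, i] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_glcm_averaged(image: np.ndarray, levels: int,
                        distance: int = 1) -> np.ndarray:
    mats = [brute_glcm(image, levels, a, distance) for a in DIRECTION_OFFSETS]
    return sum(mats) / len(mats)


def brute_haralick(P: np.ndarray) -> list[float]:
    """The 13 Haralick statistics by explicit double loops, natural logs."""
    G = P.shape[0]
    px = [sum(P[i][j] for j in range(G)) for i in range(G)]
    py = [sum(P[i][j] for i in range(G)) for j in range(G)]
    mux = sum(i * px[i] for i in range(G))
    muy = sum(j * py[j] for j in range(G))
    sx = math.sqrt(sum((i - mux) ** 2 * px[i] for i in range(G)))
    sy = math.sqrt(sum((j - muy) ** 2 * py[j] for j in range(G)))

    p_sum = [0.0] * (2 * G - 1)
    p_diff = [0.0] * G
    for i in range(G):
        for j in range(G):
            p_sum[i + j] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    def ent(ps):
        return -sum(p * math.log(p) for p in ps if p > 0)

    f1 = sum(P[i][j] ** 2 for i in range(G) for j in range(G))
    f2 = sum((i - j) ** 2 * P[i][j] for i in range(G) for j in range(G))
    cross = sum(i * j * P[i][j] for i in range(G) for j in range(G))
    f3 = (cross - mux * muy) / (sx * sy) if sx * sy > 0 else 0.0
    f4 = sum((i - mux) ** 2 * P[i][j] for i in range(G) for j in range(G))
    f5 = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))
    f6 = sum(k * p_sum[k] for k in range(2 * G - 1))
    f7 = sum((k - f6) ** 2 * p_sum[k] for k in range(2 * G - 1))
    f8 = ent(p_sum)
    f9 = ent(P[i][j] for i in range(G) for j in range(G))
    mu_d = sum(k * p_diff[k] for k in range(G))
    f10 = sum((k - mu_d) ** 2 * p_diff[k] for k in range(G))
    f11 = ent(p_diff)

    hx, hy = ent(px), ent(py)
    hxy1 = -sum(P[i][j] * math.log(px[i] * py[j])
                for i in range(G) for j in range(G)
                if px[i] * py[j] > 0)
    hxy2 = ent(px[i] * py[j] for i in range(G) for j in range(G))
    denom = max(hx, hy)
    f12 = (f9 - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - f9))
    f13 = math.sqrt(max(arg, 0.0))
    return [f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13]


def brute_bh(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook procedure."""
    m = len(pvals)
    order = sorted(range(m), key=lambda k: pvals[k])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        k = order[rank - 1]
        val = min(prev, pvals[k] * m / rank, 1.0)
        q[k] = val
        prev = val
    return q


def brute_mean_abs_corr(X: np.ndarray) -> list[float]:
    """Mean |Pearson r| per feature by explicit pairwise computation."""
    n, f = X.shape

    def r(a, b):
        am, bm = a - a.mean(), b - b.mean()
        den = math.sqrt((am ** 2).sum() * (bm ** 2).sum())
        return float((am * bm).sum() / den) if den > 0 else 0.0

    scores = []
    for i in range(f):
        if np.ptp(X[:, i]) == 0:
            scores.append(1.0)
            continue
        vals = [abs(r(X[:, i], X[:, j])) for j in range(f) if j != i]
        scores.append(sum(vals) / len(vals))
    return scores


def brute_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Probability a positive outscores a negative, ties counted half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
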