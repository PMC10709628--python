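"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: the baseline oracle
enumerates all point pairs, the kNN oracle sorts exhaustively, the AUC
oracle counts positive-negative pairs.
"""

from __future__ import annotations

import numpy as np


def lower_hull_baseline_bruteforce(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rubber-band baseline by exhaustive pair enumeration.

    A segment through points (i, j) belongs to the lower-hull envelope iff
    every point lies on or above its line; the baseline at any x between
    x_i and x_j is the maximum over all such valid lines.
    """
    n = x.size
    baseline = np.full(n, -np.inf)
    tol = 1e-9 * max(1.0, float(np.max(np.abs(y))))
    for i in range(n - 1):
        dx = x[i + 1 :] - x[i]
        slopes = (y[i + 1 :] - y[i]) / dx
        # lines[j - i - 1, k] = value at x_k of the line through (i, j)
        lines = y[i] + slopes[:, None] * (x[None, :] - x[i])
        valid = np.all(y[None, :] - lines >= -tol, axis=1)
        for jj in np.nonzero(valid)[0]:
            j = i + 1 + jj
            seg = slice(i, j + 1)
            baseline[seg] = np.maximum(baseline[seg], lines[jj, seg])
    # endpoints are always hull vertices
    baseline[0], baseline[-1] = y[0], y[-1]
    return baseline


def knn_bruteforce(
    train: np.ndarray,
    labels: list[str],
    query: np.ndarray,
    k: int,
    classes: list[str],
    eps: float = 1e-12,
) -> tuple[str, dict[str, float]]:
    """Exhaustive kNN with inverse-distance weights and the documented
    tie-break semantics (rank ties by training index, exact match wins,
    top-class ties lexicographic)."""
    d = np.sqrt(((train - query) ** 2).sum(axis=1))
    order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
    weights = {c: 0.0 for c in classes}
    if any(d[i] == 0.0 for i in order):
        for i in order:
            if d[i] == 0.0:
                weights[labels[i]] += 1.0
    else:
        for i in order:
            weights[labels[i]] += 1.0 / (d[i] + eps)
    total = sum(weights.values())
    weights = {c: w / total for c, w in weights.items()}
    top = sorted(classes, key=lambda c: (-weights[c], c))[0]
    return top, weights


def auc_pair_counting(y: np.ndarray, scores: np.ndarray) -> float:
    """Binary AUC by counting positive-negative score pairs (ties 1/2)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)
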