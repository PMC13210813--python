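"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by the most transparent method
available (transitive closure, double loops, discrete summation) with no
code shared with the implementation under test.
"""

from __future__ import annotations

import numpy as np

NOISE = -1


def dbscan_1d_bruteforce(xs, eps, min_samples):
    """Reference 1-D DBSCAN by explicit density-reachability closure.

    Core points: |{j : |xj - xi| <= eps}| >= min_samples (self included).
    Clusters: transitive closure of eps-adjacency over core points.  A
    non-core point in reach of a core joins the cluster of its nearest
    core point (ties to the smaller coordinate).  Labels are canonicalized
    to 0..k-1 by increasing cluster mean.
    """
    xs = np.asarray(xs, dtype=float)
    n = len(xs)
    labels = np.full(n, NOISE, dtype=int)
    if n == 0:
        return labels
    dist = np.abs(xs[:, None] - xs[None, :])
    neighbor = dist <= eps
    core = neighbor.sum(axis=1) >= min_samples

    # transitive closure over cores
    cluster_of = {}
    next_id = 0
    for i in range(n):
        if not core[i] or i in cluster_of:
            continue
        stack = [i]
        cluster_of[i] = next_id
        while stack:
            u = stack.pop()
            for v in range(n):
                if core[v] and neighbor[u, v] and v not in cluster_of:
                    cluster_of[v] = next_id
                    stack.append(v)
        next_id += 1
    for i, cid in cluster_of.items():
        labels[i] = cid

    # border points -> nearest core, ties to smaller coordinate
    core_indices = [i for i in range(n) if core[i]]
    for i in range(n):
        if core[i] or not core_indices:
            continue
        best = None
        for j in core_indices:
            if dist[i, j] <= eps:
                key = (dist[i, j], xs[j])
                if best is None or key < best[0]:
                    best = (key, j)
        if best is not None:
            labels[i] = labels[best[1]]

    # canonicalize by cluster mean
    ids = sorted(set(labels) - {NOISE}, key=lambda c: xs[labels == c].mean())
    remap = {c: r for r, c in enumerate(ids)}
    return np.array([remap.get(l, NOISE) for l in labels], dtype=int)


def lamp_scores_bruteforce(weights):
    """O(n^2) LAMP scores: for each weight, the denominator sums the
    squares of all weights with strictly larger magnitude plus, among equal
    magnitudes, those at the same or later original index (stable
    ascending-sort tie order)."""
    w = np.asarray(weights, dtype=float)
    n = len(w)
    scores = np.empty(n)
    for u in range(n):
        denom = 0.0
        for v in range(n):
            if abs(w[v]) > abs(w[u]) or (abs(w[v]) == abs(w[u]) and v >= u):
                denom += w[v] ** 2
        scores[u] = w[u] ** 2 / denom
    return scores


def homography_dlt_svd(src, dst):
    """Independent homography estimate: 9-parameter homogeneous DLT solved
    by SVD (null vector of the 8x9 design matrix), normalized to h33 = 1."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    rows = []
    for (x, y), (u, v) in zip(src, dst):
        rows.append([x, y, 1, 0, 0, 0, -u * x, -u * y, -u])
        rows.append([0, 0, 0, x, y, 1, -v * x, -v * y, -v])
    _, _, vt = np.linalg.svd(np.asarray(rows))
    h = vt[-1].reshape(3, 3)
    return h / h[2, 2]


def average_precision_bruteforce(recalls, precisions):
    """All-point-interpolated AP by explicit rectangle summation:
    AP = sum_i (r_i - r_{i-1}) * max_{j : r_j >= r_i} p_j."""
    ap = 0.0
    r_prev = 0.0
    for i, r in enumerate(recalls):
        p_env = max(p for rr, p in zip(recalls, precisions) if rr >= r)
        ap += (r - r_prev) * p_env
        r_prev = r
    return ap
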