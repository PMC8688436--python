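"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition (enumeration,
dense sampling, literal step-up) and never call the package's own code paths
they are checking.
"""
from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def exact_mannwhitney_p(x, y) -> float:
    """Two-sided exact permutation p for the rank-sum U statistic.

    Enumerates every assignment of the pooled values to the two groups and
    counts assignments whose U is at least as far from its null mean as the
    observed U (ties handled through midranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = rankdata(pooled)
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mean = n1 * (n - n1) / 2.0
    combos = np.array(list(combinations(range(n), n1)))
    u = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return float(np.mean(np.abs(u - mean) >= np.abs(obs_u - mean) - 1e-9))


def brute_force_bh(p_values, q: float) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: reject the k smallest p-values
    where k = max{i : p_(i) <= q * i / m}."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    k = 0
    for i in range(1, m + 1):
        if sorted_p[i - 1] <= q * i / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def dense_segment_sphere(p0, p1, center, radius, n_samples: int = 2001) -> bool:
    """Does the segment come within ``radius`` of ``center``? Decided by
    densely sampling the segment."""
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = np.asarray(p0) + ts[:, None] * (np.asarray(p1) - np.asarray(p0))
    d = np.linalg.norm(pts - np.asarray(center), axis=1)
    return bool(d.min() <= radius)


def fact_reference_tracker(field, seed, step, qa_threshold, max_angle_deg, max_len=300.0):
    """Pure peak-following (no smoothing) bidirectional tracker, written
    independently of the package's tracker for the smoothing-zero check."""
    grid = field.grid
    inv = np.linalg.inv(grid.affine)

    def voxel(p):
        v = np.rint(p @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        if (v < 0).any() or (v >= np.asarray(grid.shape)).any():
            return None
        return tuple(v)

    v0 = voxel(np.asarray(seed, float))
    if v0 is None or field.qa[v0] < qa_threshold:
        return None
    d0 = field.direction[v0]
    cos_lim = np.cos(np.radians(max_angle_deg))
    halves = []
    for sign in (1.0, -1.0):
        pts, pos, prev, length = [], np.asarray(seed, float), sign * d0, 0.0
        while length + step <= max_len / 2 + 1e-9:
            nxt = pos + step * prev
            v = voxel(nxt)
            if v is None or field.qa[v] < qa_threshold:
                break
            pts.append(nxt)
            length += step
            peak = field.direction[v]
            if float(peak @ prev) < 0:
                peak = -peak
            if float(prev @ peak) < cos_lim - 1e-12:
                break
            pos, prev = nxt, peak
        halves.append(pts)
    points = halves[1][::-1] + [np.asarray(seed, float)] + halves[0]
    if len(points) < 2:
        return None
    return np.asarray(points)
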