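"""Independent brute-force reference implementations used only by the tests.

Each oracle recomputes a statistic with the most naive traversal possible
(per-event Python loops, exhaustive enumeration, direct eigendecompositions)
so that agreement with the package's vectorized code is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_bin_stats(x, y, z, bin_width, z_threshold=None):
    """Per-bin statistics by a per-event Python loop.

    Returns dict (i, j) -> dict(n_cells, sum_z, n_zpos, sum_zpos).
    """
    bins: dict[tuple[int, int], dict] = {}
    for xi, yi, zi in zip(x, y, z):
        if not (math.isfinite(xi) and math.isfinite(yi)):
            continue
        key = (math.floor(xi / bin_width), math.floor(yi / bin_width))
        rec = bins.setdefault(key, {"n_cells": 0, "sum_z": 0.0, "n_zpos": 0, "sum_zpos": 0.0})
        rec["n_cells"] += 1
        rec["sum_z"] += zi
        if z_threshold is not None and zi >= z_threshold:
            rec["n_zpos"] += 1
            rec["sum_zpos"] += zi
    return bins


def naive_quadrants(x, y, z, x_threshold, y_threshold, z_threshold, layout):
    """Per-quadrant counts by per-event classification."""
    out = {q: {"n_cells": 0, "n_zpos": 0} for q in layout}
    for xi, yi, zi in zip(x, y, z):
        sx = "high" if xi >= x_threshold else "low"
        sy = "high" if yi >= y_threshold else "low"
        for q, sides in layout.items():
            if sides == (sx, sy):
                out[q]["n_cells"] += 1
                if z_threshold is not None and zi >= z_threshold:
                    out[q]["n_zpos"] += 1
    return out


def naive_coexpression(x, y, z1, z2, x_t, y_t, z1_t, z2_t, layout):
    """Joint z1/z2 positivity fractions per quadrant by exhaustive counting."""
    counts = {q: {"z1+z2+": 0, "z1+z2-": 0, "z1-z2+": 0, "z1-z2-": 0, "n": 0}
              for q in layout}
    for xi, yi, a, b in zip(x, y, z1, z2):
        sx = "high" if xi >= x_t else "low"
        sy = "high" if yi >= y_t else "low"
        cat = f"z1{'+' if a >= z1_t else '-'}z2{'+' if b >= z2_t else '-'}"
        for q, sides in layout.items():
            if sides == (sx, sy):
                counts[q][cat] += 1
                counts[q]["n"] += 1
    return counts


def exact_mwu_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all labelings.

    Valid only without ties.  Returns (U_a, p)."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_of(group_a, group_b):
        return sum(1 for va in group_a for vb in group_b if va > vb)

    u_obs = u_of(a, b)
    n_ab = n_a * len(b)
    # two-sided: distance of U from its mean
    dev_obs = abs(u_obs - n_ab / 2)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        dev = abs(u_of(ga, gb) - n_ab / 2)
        total += 1
        if dev >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total


def greedy_ward(points):
    """Brute-force Ward agglomeration (Lance-Williams on squared distances).

    Returns a list of merges (idx_a, idx_b, height, size) mirroring the scipy
    linkage convention (cluster n+k is created by merge k; heights are
    sqrt of the Ward cost).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    active = {i: ([i], points[i].copy(), 1) for i in range(n)}  # id -> (members, centroid, size)
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            _, ci, ni = active[i]
            _, cj, nj = active[j]
            cost = (ni * nj) / (ni + nj) * np.sum((ci - cj) ** 2)
            if best is None or cost < best[0] - 1e-15:
                best = (cost, i, j)
        cost, i, j = best
        mi, ci, ni = active.pop(i)
        mj, cj, nj = active.pop(j)
        size = ni + nj
        centroid = (ni * ci + nj * cj) / size
        active[next_id] = (mi + mj, centroid, size)
        merges.append((i, j, math.sqrt(2 * cost), size))
        next_id += 1
    return merges


def nrs_eig(data, n_components=3):
    """NRS by direct eigendecomposition of the marker covariance matrix."""
    data = np.asarray(data, dtype=float)
    centered = data - data.mean(axis=0)
    cov = centered.T @ centered / (len(data) - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:n_components]
    return np.abs(eigvec[:, order]) @ eigval[order]
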