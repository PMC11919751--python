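"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive — BFS flood fill, explicit per-zone
formula sums, hand-rolled BH — so the tests check the package against code
that shares none of its implementation.
"""

from collections import Counter, deque
from itertools import product

import numpy as np


def neighbor_offsets(connectivity: int):
    """Voxel-neighbour offsets for 6/18/26 connectivity."""
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        manhattan = sum(abs(x) for x in d)
        if connectivity == 6 and manhattan > 1:
            continue
        if connectivity == 18 and manhattan > 2:
            continue
        offs.append(d)
    return offs


def brute_zones(grid: np.ndarray, connectivity: int = 26):
    """Flood-fill zones of a 3D level grid (0 = outside). Returns Counter
    of (level, size) pairs."""
    offs = neighbor_offsets(connectivity)
    visited = np.zeros(grid.shape, dtype=bool)
    zones = Counter()
    for start in np.argwhere(grid > 0):
        start = tuple(start)
        if visited[start]:
            continue
        level = grid[start]
        queue = deque([start])
        visited[start] = True
        size = 0
        while queue:
            v = queue.popleft()
            size += 1
            for d in offs:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if any(c < 0 or c >= s for c, s in zip(w, grid.shape)):
                    continue
                if not visited[w] and grid[w] == level:
                    visited[w] = True
                    queue.append(w)
        zones[(int(level), size)] += 1
    return zones


def brute_features(zones: Counter) -> dict:
    """All 16 GLSZM features from a (level, size) -> count mapping, written
    as explicit sums over observed pairs."""
    Nz = sum(zones.values())
    Np = sum(j * c for (_, j), c in zones.items())
    levels = sorted({i for i, _ in zones})
    sizes = sorted({j for _, j in zones})
    row = {i: sum(c for (ii, _), c in zones.items() if ii == i) for i in levels}
    col = {j: sum(c for (_, jj), c in zones.items() if jj == j) for j in sizes}
    mu = sum(c / Nz * i for (i, _), c in zones.items())
    nu = sum(c / Nz * j for (_, j), c in zones.items())
    out = {
        "small_area_emphasis": sum(c / j**2 for (_, j), c in zones.items()) / Nz,
        "large_area_emphasis": sum(c * j**2 for (_, j), c in zones.items()) / Nz,
        "gray_level_nonuniformity": sum(v**2 for v in row.values()) / Nz,
        "gray_level_nonuniformity_normalized": sum(v**2 for v in row.values()) / Nz**2,
        "size_zone_nonuniformity": sum(v**2 for v in col.values()) / Nz,
        "size_zone_nonuniformity_normalized": sum(v**2 for v in col.values()) / Nz**2,
        "zone_percentage": Nz / Np,
        "gray_level_variance": sum(c / Nz * (i - mu) ** 2 for (i, _), c in zones.items()),
        "zone_variance": sum(c / Nz * (j - nu) ** 2 for (_, j), c in zones.items()),
        "zone_entropy": -sum(
            (c / Nz) * np.log2(c / Nz) for c in zones.values() if c > 0
        ),
        "low_gray_level_zone_emphasis": sum(c / i**2 for (i, _), c in zones.items()) / Nz,
        "high_gray_level_zone_emphasis": sum(c * i**2 for (i, _), c in zones.items()) / Nz,
        "small_area_low_gray_level_emphasis": sum(
            c / (i**2 * j**2) for (i, j), c in zones.items()
        ) / Nz,
        "small_area_high_gray_level_emphasis": sum(
            c * i**2 / j**2 for (i, j), c in zones.items()
        ) / Nz,
        "large_area_low_gray_level_emphasis": sum(
            c * j**2 / i**2 for (i, j), c in zones.items()
        ) / Nz,
        "large_area_high_gray_level_emphasis": sum(
            c * i**2 * j**2 for (i, j), c in zones.items()
        ) / Nz,
    }
    return out


def bh_adjust(pvals):
    """Hand Benjamini–Hochberg step-up: p_(i) * m / i, cumulative min from
    the largest, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj.tolist()


def change_score_ttest(table):
    """Pooled-variance two-sample t on within-subject change (ECT − MED)."""
    from scipy import stats as sps

    wide = table.pivot_table(
        index=["subject_id", "group"], columns="timepoint", values="value", aggfunc="first"
    ).reset_index()
    d = wide["followup"] - wide["baseline"]
    d1 = d[wide["group"] == "ECT"].to_numpy()
    d0 = d[wide["group"] == "MED"].to_numpy()
    n1, n0 = len(d1), len(d0)
    sp2 = ((n1 - 1) * d1.var(ddof=1) + (n0 - 1) * d0.var(ddof=1)) / (n1 + n0 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n0))
    t = (d1.mean() - d0.mean()) / se
    df = n1 + n0 - 2
    p = 2 * sps.t.sf(abs(t), df)
    return float(d1.mean() - d0.mean()), float(t), float(df), float(p)


def rotations24(arr: np.ndarray):
    """The 24 axis-aligned proper rotations of a 3D array."""
    out = []
    for i in range(4):
        out.append(np.rot90(arr, i, (1, 2)))
        out.append(np.rot90(np.rot90(arr, 2, (0, 2)), i, (1, 2)))
        out.append(np.rot90(np.rot90(arr, 1, (0, 2)), i, (1, 2)))
        out.append(np.rot90(np.rot90(arr, -1, (0, 2)), i, (1, 2)))
        out.append(np.rot90(np.rot90(arr, 1, (0, 1)), i, (1, 2)))
        out.append(np.rot90(np.rot90(arr, -1, (0, 1)), i, (1, 2)))
    return out
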