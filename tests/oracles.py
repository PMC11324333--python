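"""Independent brute-force oracles used by the test suite.

Each oracle deliberately re-derives its quantity by the most direct method
available (double loops, exhaustive scans, Monte-Carlo rejection sampling,
explicit cell-mean sums of squares) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_apen(x, m: int, r: float) -> float:
    """Approximate entropy via the textbook O(N^2) double loop."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        count = n - mm + 1
        total = 0.0
        for i in range(count):
            matches = 0
            for j in range(count):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    matches += 1
            total += math.log(matches / count)
        return total / count

    return phi(m) - phi(m + 1)


def winding_number_inside(point, vertices) -> bool:
    """Point-in-polygon via the winding number (nonzero rule)."""
    x, y = point
    wn = 0
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if y1 <= y:
            if y2 > y and (x2 - x1) * (y - y1) - (x - x1) * (y2 - y1) > 0:
                wn += 1
        else:
            if y2 <= y and (x2 - x1) * (y - y1) - (x - x1) * (y2 - y1) < 0:
                wn -= 1
    return wn != 0


def brute_force_hull_vertices(points: np.ndarray) -> set[int]:
    """Indices of convex-hull vertices by the O(n^3) edge test.

    A directed pair (i, j) is a hull edge iff every other point lies
    strictly to its left; endpoint indices of such edges are hull vertices.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    hull: set[int] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            if np.all(cross[mask] > 0):
                hull.add(i)
                hull.add(j)
    return hull


def monte_carlo_polygon_area(vertices: np.ndarray, n_points: int, rng) -> float:
    """Polygon area by rejection sampling in the bounding box."""
    v = np.asarray(vertices, dtype=float)
    lo, hi = v.min(axis=0), v.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_points, 2))
    inside = np.fromiter(
        (winding_number_inside(p, v) for p in pts), dtype=bool, count=n_points
    )
    box_area = np.prod(hi - lo)
    return float(inside.mean() * box_area)


def monte_carlo_polygon_area_fast(vertices: np.ndarray, n_points: int, rng) -> float:
    """Vectorized crossing-number rejection sampling (for large n_points)."""
    v = np.asarray(vertices, dtype=float)
    lo, hi = v.min(axis=0), v.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_points, 2))
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(n_points, dtype=bool)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (x < x_int)
    box_area = np.prod(hi - lo)
    return float(inside.mean() * box_area)


def split_plot_cell_mean_oracle(y: np.ndarray) -> dict:
    """Split-plot sums of squares from a (groups, subjects, times) array.

    Explicit cell-mean computation with Python loops; balanced designs
    only.  Returns SS, df and F for the group, time and interaction
    effects and their error terms.
    """
    a, n, b = y.shape
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    subj_mean = y.mean(axis=2)           # (a, n)
    group_mean = y.mean(axis=(1, 2))     # (a,)
    time_mean = y.mean(axis=(0, 1))      # (b,)
    cell_mean = y.mean(axis=1)           # (a, b)

    ss_subjects = float(b * ((subj_mean - grand) ** 2).sum())
    ss_group = float(n * b * ((group_mean - grand) ** 2).sum())
    ss_subj_within = ss_subjects - ss_group
    ss_time = float(a * n * ((time_mean - grand) ** 2).sum())
    ss_cells = float(n * ((cell_mean - grand) ** 2).sum())
    ss_interaction = ss_cells - ss_group - ss_time
    ss_error_within = ss_total - ss_subjects - ss_time - ss_interaction

    df_group, df_sw = a - 1, a * (n - 1)
    df_time, df_int = b - 1, (a - 1) * (b - 1)
    df_ew = a * (n - 1) * (b - 1)

    def F(ss, df, ss_err, df_err):
        return (ss / df) / (ss_err / df_err)

    return {
        "ss_total": ss_total,
        "ss_group": ss_group, "ss_subj_within": ss_subj_within,
        "ss_time": ss_time, "ss_interaction": ss_interaction,
        "ss_error_within": ss_error_within,
        "df": {"group": (df_group, df_sw), "time": (df_time, df_ew),
               "interaction": (df_int, df_ew)},
        "F_group": F(ss_group, df_group, ss_subj_within, df_sw),
        "F_time": F(ss_time, df_time, ss_error_within, df_ew),
        "F_interaction": F(ss_interaction, df_int, ss_error_within, df_ew),
    }


def one_way_ss_oracle(groups: list[np.ndarray]) -> dict:
    """One-way ANOVA sums of squares by direct summation."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups))
    ss_within = ss_total - ss_between
    k, n = len(groups), len(allv)
    F = (ss_between / (k - 1)) / (ss_within / (n - k))
    return {"ss_between": ss_between, "ss_within": ss_within,
            "ss_total": ss_total, "F": F, "df": (k - 1, n - k)}
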