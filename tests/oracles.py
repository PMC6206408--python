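"""Independent brute-force reference implementations used only by tests.

Each function here is deliberately written from first principles
(explicit loops, textbook formulas) and shares no code with the package
implementation it cross-checks.
"""

from __future__ import annotations

import colorsys
import math

import numpy as np


# ---------------------------------------------------------------------------
# color conversions from the published formulas
# ---------------------------------------------------------------------------

def reference_hsv(r: float, g: float, b: float) -> tuple[float, float, float]:
    h, s, v = colorsys.rgb_to_hsv(r, g, b)
    return h % 1.0, s, v


def _solve_srgb_matrix():
    """Rows of the sRGB->XYZ matrix, from the published chromaticities.

    Solved here by explicit Gaussian elimination on the primaries'
    tristimulus columns scaled to hit the D65 white (0.3127, 0.3290) —
    an independent derivation of the IEC 61966-2-1 matrix.
    """
    prims = [(0.64, 0.33), (0.30, 0.60), (0.15, 0.06)]
    cols = [(x / y, 1.0, (1 - x - y) / y) for x, y in prims]
    wx, wy = 0.3127, 0.3290
    white = (wx / wy, 1.0, (1 - wx - wy) / wy)
    a = np.array(cols, dtype=float).T
    s = np.linalg.solve(a, np.array(white))
    return a * s


_REF_M = _solve_srgb_matrix()
_REF_WHITE = _REF_M.sum(axis=1)


def reference_lab(r: float, g: float, b: float) -> tuple[float, float, float]:
    """sRGB -> XYZ(D65) -> CIE L*a*b*, written out explicitly."""

    def linearize(u: float) -> float:
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    rl, gl, bl = linearize(r), linearize(g), linearize(b)
    x = _REF_M[0, 0] * rl + _REF_M[0, 1] * gl + _REF_M[0, 2] * bl
    y = _REF_M[1, 0] * rl + _REF_M[1, 1] * gl + _REF_M[1, 2] * bl
    z = _REF_M[2, 0] * rl + _REF_M[2, 1] * gl + _REF_M[2, 2] * bl
    xn, yn, zn = _REF_WHITE

    def f(t: float) -> float:
        eps = (6.0 / 29.0) ** 3
        if t > eps:
            return t ** (1.0 / 3.0)
        return t / (3.0 * (6.0 / 29.0) ** 2) + 4.0 / 29.0

    fx, fy, fz = f(x / xn), f(y / yn), f(z / zn)
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


# ---------------------------------------------------------------------------
# region morphology by enumeration
# ---------------------------------------------------------------------------

def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for sr in range(h):
        for sc in range(w):
            if not mask[sr, sc] or seen[sr, sc]:
                continue
            comp = set()
            queue = [(sr, sc)]
            seen[sr, sc] = True
            while queue:
                r, c = queue.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            comps.append(comp)
    return comps


def bfs_fill_holes(pixels: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Fill holes: background cells of the padded bbox not reachable from outside."""
    rows = [p[0] for p in pixels]
    cols = [p[1] for p in pixels]
    top, bottom = min(rows) - 1, max(rows) + 1
    left, right = min(cols) - 1, max(cols) + 1
    outside = set()
    queue = [(top, left)]
    outside.add((top, left))
    while queue:
        r, c = queue.pop()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if top <= rr <= bottom and left <= cc <= right:
                if (rr, cc) not in pixels and (rr, cc) not in outside:
                    outside.add((rr, cc))
                    queue.append((rr, cc))
    filled = set(pixels)
    for r in range(top, bottom + 1):
        for c in range(left, right + 1):
            if (r, c) not in pixels and (r, c) not in outside:
                filled.add((r, c))
    return filled


def gift_wrap_hull(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Convex hull by gift wrapping (Jarvis march); collinear sets -> 2 points."""
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts
    # check for collinearity
    (x0, y0), (x1, y1) = pts[0], pts[-1]
    if all(
        abs((x1 - x0) * (y - y0) - (y1 - y0) * (x - x0)) < 1e-12 for x, y in pts
    ):
        return [pts[0], pts[-1]]
    start = min(pts)
    hull = [start]
    current = start
    while True:
        candidate = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = (candidate[0] - current[0]) * (p[1] - current[1]) - (
                candidate[1] - current[1]
            ) * (p[0] - current[0])
            if cross < 0 or (
                cross == 0
                and math.dist(current, p) > math.dist(current, candidate)
            ):
                candidate = p
        if candidate == start:
            break
        hull.append(candidate)
        current = candidate
    return hull


def _point_in_hull(p, hull, eps=1e-7) -> bool:
    if len(hull) == 1:
        return math.dist(p, hull[0]) <= eps
    if len(hull) == 2:
        a, b = hull
        d = (b[0] - a[0], b[1] - a[1])
        seg2 = d[0] ** 2 + d[1] ** 2
        cross = (p[0] - a[0]) * d[1] - (p[1] - a[1]) * d[0]
        if abs(cross) > eps * math.sqrt(seg2):
            return False
        t = (p[0] - a[0]) * d[0] + (p[1] - a[1]) * d[1]
        return -eps <= t <= seg2 + eps
    n = len(hull)
    for i in range(n):
        o, e = hull[i], hull[(i + 1) % n]
        ev = (e[0] - o[0], e[1] - o[1])
        cross = ev[0] * (p[1] - o[1]) - ev[1] * (p[0] - o[0])
        if cross < -eps * max(1.0, math.hypot(*ev)):
            return False
    return True


def brute_force_region_features(pixels: set[tuple[int, int]]) -> dict[str, float]:
    """All 11 morphology features by direct enumeration."""
    n = len(pixels)
    rows = [p[0] for p in pixels]
    cols = [p[1] for p in pixels]
    top, left = min(rows), min(cols)
    h = max(rows) - top + 1
    w = max(cols) - left + 1
    area = float(n)
    extent = area / (h * w)

    filled = bfs_fill_holes(pixels)
    filled_area = float(len(filled))

    perimeter = 0
    for r, c in pixels:
        if any(
            (r + dr, c + dc) not in pixels
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
        ):
            perimeter += 1

    hull = gift_wrap_hull([(float(r), float(c)) for r, c in pixels])
    convex_area = 0
    for r in range(top, top + h):
        for c in range(left, left + w):
            if _point_in_hull((float(r), float(c)), hull):
                convex_area += 1

    rbar = sum(rows) / n
    cbar = sum(cols) / n
    mu20 = sum((r - rbar) ** 2 for r in rows) / n + 1.0 / 12.0
    mu02 = sum((c - cbar) ** 2 for c in cols) / n + 1.0 / 12.0
    mu11 = sum((r - rbar) * (c - cbar) for r, c in pixels) / n
    disc = math.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    lam1 = (mu20 + mu02 + disc) / 2
    lam2 = (mu20 + mu02 - disc) / 2
    major = 4 * math.sqrt(lam1)
    minor = 4 * math.sqrt(max(lam2, 0.0))
    ecc = math.sqrt(max(0.0, 1 - lam2 / lam1))

    return {
        "area": area,
        "eccentricity": ecc,
        "extent": extent,
        "perimeter": float(perimeter),
        "major_axis_length": major,
        "minor_axis_length": minor,
        "convex_area": float(convex_area),
        "filled_area": filled_area,
        "equiv_diameter": math.sqrt(4 * area / math.pi),
        "solidity": area / convex_area,
        "roundness": min(1.0, 4 * math.pi * filled_area / perimeter**2),
    }


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation via textbook covariance sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy * sxy / (sxx * syy)
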