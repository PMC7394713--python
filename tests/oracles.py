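"""Independent brute-force oracles used to verify the implementation.

Each oracle re-derives a quantity from first principles (colorimetric
formulas, exhaustive search, breadth-first flood fill, normal equations)
without touching the code paths it checks.
"""

import numpy as np
from scipy import stats


def srgb_to_lightness(r, g, b):
    """CIE L* of one 8-bit sRGB triple via the textbook sRGB -> XYZ -> L* route."""

    def lin(u):
        u = u / 255.0
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    rl, gl, bl = lin(r), lin(g), lin(b)
    # Y row of the sRGB D65 matrix
    y = 0.2126729 * rl + 0.7151522 * gl + 0.0721750 * bl
    eps = 216.0 / 24389.0
    kappa = 24389.0 / 27.0
    fy = y ** (1.0 / 3.0) if y > eps else (kappa * y + 16.0) / 116.0
    return 116.0 * fy - 16.0


def exhaustive_otsu(values, nbins=256):
    """Threshold maximizing between-class variance, by exhaustive search.

    Works on the gray-level histogram, as Otsu's criterion is defined: every
    one of the ``nbins`` levels is tried as a split, and the class weights
    and means are accumulated bin by bin in explicit Python loops.  Returns
    the bin center of the best split (first one on ties).
    """
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = values.size
    best_i, best_v = None, -1.0
    for i in range(nbins - 1):
        n0 = hist[: i + 1].sum()
        n1 = hist[i + 1 :].sum()
        if n0 == 0 or n1 == 0:
            continue
        m0 = (hist[: i + 1] * centers[: i + 1]).sum() / n0
        m1 = (hist[i + 1 :] * centers[i + 1 :]).sum() / n1
        v = (n0 / n) * (n1 / n) * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_i = v, i
    return centers[best_i]


def flood_fill_components(mask):
    """8-connected component labels by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    H, W = mask.shape
    for r0 in range(H):
        for c0 in range(W):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            current += 1
            stack = [(r0, c0)]
            labels[r0, c0] = current
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and not labels[rr, cc]:
                            labels[rr, cc] = current
                            stack.append((rr, cc))
    return labels


def count_crossings_bruteforce(skel, curve_rows, gap_tolerance, border_margin):
    """Crossing count by labeling components of the curve/skeleton touch set.

    The curve is assumed to step by at most one row per column, so its
    raster path has exactly one pixel per column.  Touch pixels are path
    pixels whose 3x3 neighborhood contains a skeleton pixel; connected
    components of the touch set give column intervals, which are then merged
    across small gaps and filtered at the borders exactly as the crossing
    definition prescribes.
    """
    skel = np.asarray(skel, dtype=bool)
    H, W = skel.shape
    rows = np.clip(np.rint(np.asarray(curve_rows, dtype=float)), 0, H - 1).astype(int)
    assert np.abs(np.diff(rows)).max(initial=0) <= 1, "oracle needs a gentle curve"
    touch = np.zeros((H, W), dtype=bool)
    for c in range(W):
        r = rows[c]
        r0, r1 = max(r - 1, 0), min(r + 2, H)
        c0, c1 = max(c - 1, 0), min(c + 2, W)
        if skel[r0:r1, c0:c1].any():
            touch[r, c] = True
    labels = flood_fill_components(touch)
    intervals = []
    for lab in range(1, labels.max() + 1):
        cols = np.nonzero(labels == lab)[1]
        intervals.append((cols.min(), cols.max()))
    intervals.sort()
    merged = []
    for a, b in intervals:
        if merged and a - merged[-1][1] - 1 <= gap_tolerance:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    m = border_margin
    return sum(1 for a, b in merged if not (b < m or a >= W - m))


def ols_normal_equations(x, y):
    """Simple linear regression by normal equations plus slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    intercept, slope = beta
    resid = y - X @ beta
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot
    sigma2 = ss_res / (n - 2)
    se_slope = np.sqrt(sigma2 / ((x - x.mean()) ** 2).sum())
    t = slope / se_slope
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return dict(slope=slope, intercept=intercept, r_squared=r2, p_value=p)


def piecewise_linear_eval(points, x):
    """Evaluate a polyline at x by locating its segment explicitly."""
    pts = np.asarray(points, dtype=float)
    if x <= pts[0, 0]:
        return pts[0, 1]
    if x >= pts[-1, 0]:
        return pts[-1, 1]
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        if x0 <= x <= x1:
            if x1 == x0:
                return 0.5 * (y0 + y1)
            return y0 + (y1 - y0) * (x - x0) / (x1 - x0)
    raise AssertionError("unreachable")
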