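"""Independent brute-force references for the morphometry computations.

Each oracle recomputes a quantity by a different route than the package:
convex hulls via shapely on all pixel-corner points, Feret extremes by
exhaustive pairwise distances and a fine angle scan, ellipse axes from
directly accumulated central moments, OLS from the normal equations.
"""

import numpy as np
from scipy import stats


def all_corner_points(mask):
    ys, xs = np.nonzero(np.asarray(mask, bool))
    pts = []
    for dy in (-0.5, 0.5):
        for dx in (-0.5, 0.5):
            pts.append(np.stack([xs + dx, ys + dy], axis=1))
    return np.unique(np.concatenate(pts), axis=0)


def hull_area_perimeter(mask):
    """Convex hull of all pixel corners via shapely."""
    from shapely.geometry import MultiPoint

    hull = MultiPoint(all_corner_points(mask).tolist()).convex_hull
    return hull.area, hull.length


def feret_max_allpairs(mask):
    pts = all_corner_points(mask)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _widths_at(pts, theta):
    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    proj = pts @ dirs.T  # (n_pts, n_angles)
    return proj.max(axis=0) - proj.min(axis=0)


def feret_min_angle_scan(mask, step_deg=0.05):
    """Two-stage angle scan (coarse, then refined around the minimum)."""
    pts = all_corner_points(mask)
    theta = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    widths = _widths_at(pts, theta)
    t0 = theta[int(np.argmin(widths))]
    window = np.deg2rad(step_deg)
    fine = np.linspace(t0 - window, t0 + window, 4001)
    return float(min(widths.min(), _widths_at(pts, fine).min()))


def ellipse_axes_from_moments(mask):
    """Moment-equivalent ellipse axes from raw pixel-center moments."""
    ys, xs = np.nonzero(np.asarray(mask, bool))
    n = len(xs)
    mx, my = xs.mean(), ys.mean()
    mu20 = ((xs - mx) ** 2).mean()
    mu02 = ((ys - my) ** 2).mean()
    mu11 = ((xs - mx) * (ys - my)).mean()
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    lam = np.linalg.eigvalsh(cov)
    return 4.0 * np.sqrt(lam[1]), 4.0 * np.sqrt(lam[0])  # major, minor


def ols_closed_form(x, y):
    """Simple-regression slope/intercept/r2/p from the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = (resid ** 2).sum() / (n - 2)
    se = np.sqrt(s2 / sxx)
    t = slope / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(t), n - 2)
    syy = ((y - y.mean()) ** 2).sum()
    r2 = sxy ** 2 / (sxx * syy) if syy > 0 else 0.0
    return slope, intercept, r2, p
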