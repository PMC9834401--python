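"""Small geometry and interpolation helpers used by several modules.

Conventions (package-wide):

* pixel coordinates are 0-based, pixel-centre, ``(x, y)`` with y increasing
  downward (image row direction);
* azimuths are ``degrees(atan2(dy, dx))`` in those coordinates, so increasing
  azimuth is clockwise on screen;
* angles are degrees everywhere.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import OutOfBoundsError


def wrap_360(angle_deg):
    """Wrap angle(s) to [0, 360)."""
    return np.mod(angle_deg, 360.0)


def wrap_signed_180(angle_deg):
    """Wrap angle(s) to (-180, 180]."""
    a = np.mod(np.asarray(angle_deg, dtype=float), 360.0)
    return np.where(a > 180.0, a - 360.0, a)


def wrap_axial_90(angle_deg):
    """Wrap an undirected-axis rotation to (-90, 90]."""
    a = np.mod(np.asarray(angle_deg, dtype=float), 180.0)
    return np.where(a > 90.0, a - 180.0, a)


def angular_distance(a_deg, b_deg):
    """Smallest absolute separation between two directions, in [0, 180]."""
    return np.abs(wrap_signed_180(np.asarray(a_deg, float) - np.asarray(b_deg, float)))


def ellipse_polar_radius(semi_major, semi_minor, rel_azimuth_deg):
    """Centre-to-boundary distance of an ellipse along a ray.

    ``rel_azimuth_deg`` is measured from the major axis.
    """
    psi = np.radians(rel_azimuth_deg)
    a, b = semi_major, semi_minor
    return a * b / np.hypot(b * np.cos(psi), a * np.sin(psi))


def sample_bilinear(image, xs, ys, context=""):
    """Bilinear interpolation of ``image`` at (x, y) points.

    Raises :class:`OutOfBoundsError` if any point leaves the image frame.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    h, w = image.shape[-2:]
    if (xs.min() < 0) or (ys.min() < 0) or (xs.max() > w - 1) or (ys.max() > h - 1):
        raise OutOfBoundsError(
            f"sampling path leaves the image frame ({context or 'bilinear sampling'}): "
            f"x in [{xs.min():.1f}, {xs.max():.1f}], y in [{ys.min():.1f}, {ys.max():.1f}], "
            f"image is {w}x{h}"
        )
    return map_coordinates(np.asarray(image, dtype=float), [ys, xs], order=1, mode="nearest")


def polygon_area_signed(xy):
    """Signed shoelace area of a closed polygon given as an (N, 2) array."""
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)


def polygon_perimeter(xy):
    """Perimeter of a closed polygon (closing edge included)."""
    xy = np.asarray(xy, dtype=float)
    d = np.roll(xy, -1, axis=0) - xy
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_second_moments(xy):
    """Area, centroid and central second moments of a solid polygon.

    Exact closed forms (Green's theorem). Returns
    ``(area, (cx, cy), (ixx, iyy, ixy))`` where the moments are normalised
    by area, i.e. the covariance of the uniform density over the polygon.
    """
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise ValueError("polygon has zero area")
    cx = np.sum((x + x1) * cross) / (6.0 * area)
    cy = np.sum((y + y1) * cross) / (6.0 * area)
    ixx = np.sum((x * x + x * x1 + x1 * x1) * cross) / (12.0 * area) - cx * cx
    iyy = np.sum((y * y + y * y1 + y1 * y1) * cross) / (12.0 * area) - cy * cy
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / (24.0 * area) - cx * cy
    return abs(area), (cx, cy), (ixx, iyy, ixy)


def resample_polyline(xy, step=1.0, closed=True):
    """Resample a polyline/polygon at uniform arc-length steps.

    Returns an (M, 2) array of points spaced ``step`` apart along the path
    (the last partial step is dropped; for a closed path the start point is
    included once).
    """
    xy = np.asarray(xy, dtype=float)
    pts = np.vstack([xy, xy[:1]]) if closed else xy
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    targets = np.arange(0.0, total, step)
    out_x = np.interp(targets, s, pts[:, 0])
    out_y = np.interp(targets, s, pts[:, 1])
    return np.column_stack([out_x, out_y])
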