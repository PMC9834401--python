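"""Morphometrics of epithelial acini grown in 3D culture.

Operates on an optical section / projection of an acinus: outline and lumen
polygons (drawn manually, or synthetic), a labelled cell mask, and channel
images. Provides lumen counting, Fiji-convention shape descriptors,
normal-lumen calling (single lumen ringed by apically enriched F-actin),
division angles relative to the basement membrane with the planar (0–30°)
bin, and arc-length perimeter intensity profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from skimage.draw import polygon2mask
from skimage.segmentation import find_boundaries

from ._geom import (
    polygon_perimeter,
    polygon_second_moments,
    resample_polyline,
    sample_bilinear,
    wrap_axial_90,
)
from .errors import DegenerateGeometryError
from .spindle_metrics import SpindlePoles

PLANAR_MAX_DEG = 30.0


@dataclass
class AcinusGeometry:
    """Outline, lumen polygons and labelled cell mask of one acinus section."""

    outline: np.ndarray
    lumens: list
    cells: np.ndarray | None = None
    pixel_size_um: float = 1.0


@dataclass(frozen=True)
class ShapeDescriptors:
    """Fiji-convention shape descriptors of a polygon."""

    area_um2: float
    area_px2: float
    perimeter_um: float
    circularity: float   # 4*pi*A / P^2, capped at 1
    roundness: float     # 4*A / (pi * major^2), moment-equivalent ellipse
    major_axis_um: float


@dataclass(frozen=True)
class DivisionAngle:
    """Spindle angle to the basement-membrane tangent, folded to [0, 90]."""

    alpha_deg: float
    planar: bool

    def __post_init__(self):
        if not (0.0 <= self.alpha_deg <= 90.0):
            raise ValueError("alpha_deg must be in [0, 90]")


def _as_polygon(xy) -> Polygon:
    poly = Polygon(np.asarray(xy, dtype=float))
    if not poly.is_valid:
        raise DegenerateGeometryError("polygon is self-intersecting or degenerate")
    return poly


def shape_descriptors(polygon, pixel_size_um: float = 1.0) -> ShapeDescriptors:
    """Area, perimeter, circularity and roundness of a simple closed polygon.

    Area by the shoelace formula; circularity ``4*pi*A/P^2`` capped at 1;
    roundness ``4*A/(pi*major^2)`` where the major axis comes from the
    polygon's moment-equivalent ellipse (the convention Fiji uses when
    fitting an ellipse to a selection).
    """
    xy = np.asarray(polygon, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < 3:
        raise DegenerateGeometryError("polygon needs >= 3 vertices")
    _as_polygon(xy)  # validity check (simple, non-self-intersecting)
    area_px, _center, (ixx, iyy, ixy) = polygon_second_moments(xy)
    perim_px = polygon_perimeter(xy)
    cov = np.array([[ixx, ixy], [ixy, iyy]])
    eig = np.linalg.eigvalsh(cov)
    major_px = 4.0 * np.sqrt(max(eig[-1], 0.0))  # solid ellipse: a = 2*sqrt(lambda)
    circularity = min(4.0 * np.pi * area_px / perim_px**2, 1.0)
    roundness = min(4.0 * area_px / (np.pi * major_px**2), 1.0) if major_px > 0 else 1.0
    s = pixel_size_um
    return ShapeDescriptors(
        area_um2=area_px * s * s,
        area_px2=area_px,
        perimeter_um=perim_px * s,
        circularity=float(circularity),
        roundness=float(roundness),
        major_axis_um=major_px * s,
    )


def count_lumens(geometry: AcinusGeometry, min_area_um2: float = 5.0) -> int:
    """Number of disjoint lumen regions with area >= ``min_area_um2``.

    Overlapping lumen polygons are merged (with a warning) before counting.
    """
    polys = [_as_polygon(l) for l in geometry.lumens]
    if not polys:
        return 0
    merged = unary_union(polys)
    parts = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    if len(parts) < len(polys):
        warnings.warn(
            f"{len(polys) - len(parts)} overlapping lumen polygon(s) merged",
            stacklevel=2,
        )
    s2 = geometry.pixel_size_um**2
    return sum(1 for p in parts if p.area * s2 >= min_area_um2)


def _polygon_mask(shape, poly_xy):
    # polygon2mask takes (row, col) vertex order
    return polygon2mask(shape, np.asarray(poly_xy, float)[:, ::-1])


def _border_assignment(geometry: AcinusGeometry, shape):
    """Split cell-border pixels into apical (lumen-facing) and basal sets.

    A border pixel is apical if it lies nearer to any lumen than to the
    acinus outline (the basement membrane), basal otherwise.
    """
    if geometry.cells is None:
        raise ValueError("geometry.cells label mask required")
    borders = find_boundaries(geometry.cells, mode="inner") & (geometry.cells > 0)

    lumen_mask = np.zeros(shape, dtype=bool)
    for lum in geometry.lumens:
        lumen_mask |= _polygon_mask(shape, lum)
    outside = ~_polygon_mask(shape, np.asarray(geometry.outline, float))

    d_lumen = distance_transform_edt(~lumen_mask) if lumen_mask.any() else np.full(shape, np.inf)
    d_out = distance_transform_edt(~outside)
    apical = borders & (d_lumen < d_out)
    basal = borders & ~apical
    return apical, basal


def classify_normal_lumen(
    geometry: AcinusGeometry,
    apical_channel,
    min_area_um2: float = 5.0,
    enrichment_factor: float = 1.5,
) -> bool:
    """True iff the acinus has one lumen ringed by apically enriched signal.

    Requires exactly one lumen passing the size filter, and the mean
    intensity of apical (lumen-facing) cell-border pixels to exceed the
    basal border mean by ``enrichment_factor``.
    """
    apical_channel = np.asarray(apical_channel, dtype=float)
    if count_lumens(geometry, min_area_um2) != 1:
        return False
    apical, basal = _border_assignment(geometry, apical_channel.shape)
    if not apical.any() or not basal.any():
        return False
    return float(apical_channel[apical].mean()) > enrichment_factor * float(
        apical_channel[basal].mean()
    )


def local_membrane_tangent_deg(outline, point_xy, arc_halfwidth_px: float = 15.0) -> float:
    """Basement-membrane tangent orientation near the boundary point closest
    to ``point_xy``, from a least-squares line through the outline path
    within ±``arc_halfwidth_px`` of arc length."""
    path = resample_polyline(np.asarray(outline, float), step=1.0, closed=True)
    d = np.hypot(path[:, 0] - point_xy[0], path[:, 1] - point_xy[1])
    k = int(np.argmin(d))
    n = len(path)
    idx = (np.arange(-int(arc_halfwidth_px), int(arc_halfwidth_px) + 1) + k) % n
    seg = path[idx]
    seg = seg - seg.mean(axis=0)
    _, _, vt = np.linalg.svd(seg, full_matrices=False)
    return float(np.degrees(np.arctan2(vt[0, 1], vt[0, 0])) % 180.0)


def division_angle_vs_membrane(
    poles: SpindlePoles,
    outline,
    pixel_size_um: float = 1.0,
    arc_halfwidth_px: float = 15.0,
    planar_max_deg: float = PLANAR_MAX_DEG,
) -> DivisionAngle:
    """Spindle angle to the local basement-membrane tangent, folded to [0, 90].

    Poles are projected to the acinus plane; the tangent is estimated at the
    outline point nearest the spindle midpoint. ``planar`` flags angles in
    the 0–``planar_max_deg`` bin.
    """
    p1 = np.asarray(poles.pole1, float)[:2] / pixel_size_um
    p2 = np.asarray(poles.pole2, float)[:2] / pixel_size_um
    mid = (p1 + p2) / 2.0
    poly = _as_polygon(outline)
    if not poly.contains(Point(mid)):
        raise DegenerateGeometryError("spindle midpoint lies outside the acinus outline")
    axis_deg = np.degrees(np.arctan2(p2[1] - p1[1], p2[0] - p1[0]))
    tangent_deg = local_membrane_tangent_deg(outline, mid, arc_halfwidth_px)
    alpha = float(abs(wrap_axial_90(axis_deg - tangent_deg)))
    return DivisionAngle(alpha_deg=alpha, planar=alpha <= planar_max_deg)


@dataclass
class AngleFrequencySummary:
    bin_edges_deg: np.ndarray
    frequencies: np.ndarray
    mean_angle_deg: float
    planar_fraction: float
    n: int


def angle_frequency_summary(
    angles,
    bin_width_deg: float = 10.0,
    planar_max_deg: float = PLANAR_MAX_DEG,
) -> AngleFrequencySummary:
    """Histogram over [0, 90], arithmetic mean angle, and planar fraction."""
    vals = np.asarray(
        [a.alpha_deg if isinstance(a, DivisionAngle) else float(a) for a in angles], float
    )
    if vals.size == 0:
        raise ValueError("no angles supplied")
    edges = np.arange(0.0, 90.0 + bin_width_deg, bin_width_deg)
    freq, _ = np.histogram(vals, bins=edges)
    return AngleFrequencySummary(
        bin_edges_deg=edges,
        frequencies=freq,
        mean_angle_deg=float(vals.mean()),
        planar_fraction=float(np.mean(vals <= planar_max_deg)),
        n=int(vals.size),
    )


def perimeter_intensity_profile(cell_outline, channels: dict, step_px: float = 1.0):
    """Per-channel intensity along a cell's perimeter path.

    The path is the outline resampled at ``step_px`` arc-length steps; every
    channel is sampled (bilinearly) at the *identical* coordinates, matching
    the shared-perimeter convention of multi-channel cortical measurements.
    Returns ``(arc_lengths_px, path_xy, {channel: samples})``.
    """
    if not channels:
        raise ValueError("need at least one channel")
    path = resample_polyline(np.asarray(cell_outline, float), step=step_px, closed=True)
    arc = np.arange(len(path)) * step_px
    out = {
        name: sample_bilinear(img, path[:, 0], path[:, 1], context=f"perimeter profile ({name})")
        for name, img in channels.items()
    }
    return arc, path, out


def average_perimeter_profiles(profiles):
    """Per-acinus average profile: mean over cells, truncated to the shortest path."""
    profiles = [np.asarray(p, float) for p in profiles]
    if not profiles:
        raise ValueError("no profiles supplied")
    n = min(len(p) for p in profiles)
    return np.mean([p[:n] for p in profiles], axis=0)
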