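"""Angular cortical-intensity profiling of mitotic cells.

The workflow mirrors the classic Fiji macro used to quantify cortical
polarity proteins (LGN, NuMA, Gαi, annexins) in metaphase cells:

1. an ellipse is fitted to a hand-drawn cell contour;
2. the cortex is scanned at 180 angular positions (every 2°), reporting at
   each position the maximum intensity along a 30-pixel radial segment
   centred on the ellipse boundary;
3. profiles are background-corrected and averaged across cells
   (mean ± s.e.m.);
4. each profile is assigned one of five cortical-localisation categories —
   *bilateral* (two lateral crescents), *unilateral* (one crescent),
   *central* (signal over the metaphase plate), *circumferential*
   (uniform ring) or *absent*.

Profile coordinates: position 0°/180° face the metaphase plate (central
cortex), 90°/270° face the spindle poles (lateral cortex). The scan starts
at the boundary point intersected by the reference axis and proceeds in the
direction of increasing ``atan2`` azimuth in image coordinates (clockwise
on screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.measure import EllipseModel

from ._geom import angular_distance, ellipse_polar_radius, sample_bilinear
from .errors import DegenerateGeometryError, OutOfBoundsError

CATEGORIES = ("bilateral", "unilateral", "central", "circumferential", "absent")

REFERENCE_METAPHASE_PLATE = "metaphase_plate"
REFERENCE_SHORT_AXIS = "short_axis"


@dataclass(frozen=True)
class FittedEllipse:
    """Least-squares ellipse fitted to a cell contour.

    ``orientation_deg`` is the image-coordinate azimuth of the major axis,
    normalised to [0, 180). ``residual_rms`` is the RMS orthogonal distance
    of the contour points from the fitted boundary (px).
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation_deg: float
    residual_rms: float = 0.0

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")

    def radius_at(self, azimuth_deg):
        """Centre-to-boundary distance along a ray at the given azimuth."""
        return ellipse_polar_radius(
            self.semi_major, self.semi_minor, np.asarray(azimuth_deg, float) - self.orientation_deg
        )

    def boundary_point(self, azimuth_deg):
        """Boundary point(s) hit by a ray from the centre at ``azimuth_deg``."""
        az = np.radians(np.asarray(azimuth_deg, float))
        r = self.radius_at(azimuth_deg)
        return np.stack(
            [self.center[0] + r * np.cos(az), self.center[1] + r * np.sin(az)], axis=-1
        )

    def outward_normal(self, azimuth_deg):
        """Unit outward normal of the boundary at the ray intersection point."""
        p = np.atleast_2d(self.boundary_point(azimuth_deg))
        th = np.radians(self.orientation_deg)
        c, s = np.cos(th), np.sin(th)
        dx = p[:, 0] - self.center[0]
        dy = p[:, 1] - self.center[1]
        # rotate into the ellipse frame, take gradient of the implicit form
        u = c * dx + s * dy
        v = -s * dx + c * dy
        gu = u / self.semi_major**2
        gv = v / self.semi_minor**2
        # rotate the gradient back to image coordinates
        nx = c * gu - s * gv
        ny = s * gu + c * gv
        norm = np.hypot(nx, ny)
        out = np.stack([nx / norm, ny / norm], axis=-1)
        return out if np.asarray(azimuth_deg).ndim else out[0]


@dataclass
class CorticalProfile:
    """One cell's angular cortical-intensity profile (180 samples, 2° apart)."""

    positions_deg: np.ndarray
    intensities: np.ndarray
    background: float = 0.0
    reference: str = REFERENCE_METAPHASE_PLATE
    cell_id: str = ""

    def __post_init__(self):
        self.positions_deg = np.asarray(self.positions_deg, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n = len(self.positions_deg)
        if n < 2 or len(self.intensities) != n:
            raise ValueError("positions and intensities must have equal length >= 2")
        spacing = 360.0 / n
        expected = np.arange(n) * spacing
        if not np.allclose(self.positions_deg, expected):
            raise ValueError(f"positions must be uniform: 0, {spacing}, ... (n={n})")

    @property
    def n_positions(self) -> int:
        return len(self.positions_deg)

    @property
    def spacing_deg(self) -> float:
        return 360.0 / self.n_positions


@dataclass
class AverageProfile:
    """Position-wise mean ± s.e.m. over a set of cortical profiles."""

    positions_deg: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_cells: int


@dataclass
class ClassifierConfig:
    """Thresholds of the cortical-localisation classifier.

    ``lobe_halfwidth_deg``: averaging window half-width around the lateral
    (90°/270°) and central (0°/180°) cortex positions.
    ``cv_threshold``: coefficient-of-variation bound below which a profile
    counts as a uniform (circumferential) ring.
    ``lobe_ratio``: contrast factor a lobe must exceed the opposite region by.
    ``asymmetry_tol``: maximum fold difference between the two lateral lobes
    for a bilateral call.
    ``absent_threshold``: multiple of the profile-scale noise floor below
    which the mean corrected profile counts as no cortical signal.
    """

    lobe_halfwidth_deg: float = 30.0
    cv_threshold: float = 0.15
    lobe_ratio: float = 1.3
    asymmetry_tol: float = 2.0
    absent_threshold: float = 2.0


@dataclass
class LocalisationCall:
    """A cortical-localisation category with its supporting statistics."""

    category: str
    scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def fit_ellipse(contour) -> FittedEllipse:
    """Fit an ellipse to an ordered cell-contour polygon.

    Uses the direct least-squares conic fit with ellipse constraint; no
    initialisation, deterministic. Requires at least 5 non-collinear points.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise DegenerateGeometryError(
            f"ellipse fit needs >= 5 (x, y) points, got shape {pts.shape}"
        )
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("contour points are collinear")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise DegenerateGeometryError(f"ellipse fit failed: {model}")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    orientation = float(np.degrees(theta) % 180.0)
    residual_rms = float(np.sqrt(np.mean(model.residuals(pts) ** 2)))
    return FittedEllipse((float(xc), float(yc)), float(a), float(b), orientation, residual_rms)


def scan_cortex(
    image,
    ellipse: FittedEllipse,
    reference_axis_deg: float,
    n_positions: int = 180,
    radial_len_px: float = 30.0,
    reference: str = REFERENCE_METAPHASE_PLATE,
    cell_id: str = "",
) -> CorticalProfile:
    """Scan the cortex at ``n_positions`` angular positions (default every 2°).

    At each position the intensity reported is the maximum bilinearly
    interpolated value along a radial segment of length ``radial_len_px``
    centred on the ellipse boundary and directed along the local outward
    normal (1-px sample steps). Position 0 is the boundary point intersected
    by the reference axis through the ellipse centre; the scan proceeds in
    the direction of increasing image-coordinate azimuth.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("scan_cortex expects a single 2D intensity plane")
    if not np.isfinite(reference_axis_deg):
        raise ValueError("reference_axis_deg must be finite")
    step = 360.0 / n_positions
    positions = np.arange(n_positions) * step
    azimuths = reference_axis_deg + positions
    boundary = ellipse.boundary_point(azimuths)          # (n, 2)
    normals = ellipse.outward_normal(azimuths)           # (n, 2)
    half = radial_len_px / 2.0
    offsets = np.arange(-half, half + 0.5, 1.0)          # 1-px steps, centred
    xs = boundary[:, None, 0] + offsets[None, :] * normals[:, None, 0]
    ys = boundary[:, None, 1] + offsets[None, :] * normals[:, None, 1]
    h, w = image.shape
    bad = (xs < 0) | (ys < 0) | (xs > w - 1) | (ys > h - 1)
    if bad.any():
        k = int(np.argwhere(bad.any(axis=1))[0][0])
        raise OutOfBoundsError(
            f"radial segment exits the image at position {k} "
            f"({positions[k]:.1f} deg); ellipse must lie inside the image "
            f"with margin >= {half:.0f} px"
        )
    samples = sample_bilinear(image, xs.ravel(), ys.ravel()).reshape(xs.shape)
    intensities = samples.max(axis=1)
    return CorticalProfile(positions, intensities, 0.0, reference, cell_id)


def subtract_background(profile: CorticalProfile, background: float) -> CorticalProfile:
    """Subtract a scalar background from a profile, flooring at zero.

    The subtracted value is accumulated into the profile's ``background``
    field so the correction is recorded.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    corrected = np.maximum(profile.intensities - background, 0.0)
    return replace(
        profile, intensities=corrected, background=profile.background + float(background)
    )


def measure_background(image, roi) -> float:
    """Median intensity of a rectangular background ROI ``(x0, y0, x1, y1)``."""
    x0, y0, x1, y1 = (int(v) for v in roi)
    patch = np.asarray(image, dtype=float)[y0:y1, x0:x1]
    if patch.size == 0:
        raise ValueError(f"background ROI {roi} is empty")
    return float(np.median(patch))


def estimate_profile_noise_floor(image, roi, radial_len_px: float = 30.0) -> float:
    """Noise floor on the *profile* scale from a signal-free ROI.

    Because the cortical scan reports the maximum over ``radial_len_px + 1``
    radial samples, a background-only profile sits well above the median
    background. The floor returned here is the mean of max-statistics over
    groups of that size of the ROI's median-subtracted pixels — the expected
    level of a background-corrected profile where no cortical signal exists.
    """
    x0, y0, x1, y1 = (int(v) for v in roi)
    patch = np.asarray(image, dtype=float)[y0:y1, x0:x1].ravel()
    if patch.size == 0:
        raise ValueError(f"background ROI {roi} is empty")
    group = int(radial_len_px) + 1
    vals = patch - np.median(patch)
    n = (vals.size // group) * group
    if n == 0:
        return float(max(vals.max(), 0.0))
    maxes = vals[:n].reshape(-1, group).max(axis=1)
    return float(max(maxes.mean(), 0.0))


def average_profiles(profiles) -> AverageProfile:
    """Position-wise mean and s.e.m. (sample sd / sqrt(n)) over >= 2 profiles."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles to average (s.e.m. undefined for n=1)")
    refs = {p.reference for p in profiles}
    if len(refs) > 1:
        raise ValueError(f"mixed reference conventions: {sorted(refs)}")
    ns = {p.n_positions for p in profiles}
    if len(ns) > 1:
        raise ValueError(f"profiles have differing sample counts: {sorted(ns)}")
    stack = np.stack([p.intensities for p in profiles])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(profiles))
    return AverageProfile(profiles[0].positions_deg.copy(), mean, sem, len(profiles))


def _robust_noise_floor(intensities):
    # successive-difference robust sigma: insensitive to the smooth signal
    d = np.abs(np.diff(intensities))
    return float(1.4826 * np.median(d) / np.sqrt(2.0))


def classify_localisation(
    profile: CorticalProfile,
    noise_floor: float | None = None,
    config: ClassifierConfig | None = None,
) -> LocalisationCall:
    """Assign a cortical-localisation category to a background-corrected profile.

    Decision statistics:

    * ``L``: mean intensity within ±``lobe_halfwidth_deg`` of 90° and 270°
      (lateral cortex); ``lobe1``/``lobe2`` are the two halves separately;
    * ``C``: same around 0° and 180° (central cortex);
    * ``U``: coefficient of variation over all positions;
    * ``A``: overall mean; ``level``: 90th percentile of the profile (a
      robust peak level, so localized crescents register).

    Rules (first match in tie order central > bilateral > unilateral >
    circumferential): *absent* if ``level <= absent_threshold * noise_floor``;
    *circumferential* if ``U < cv_threshold``; *central* if ``C``
    exceeds ``L`` by ``lobe_ratio``; *bilateral* if both lateral lobes exceed
    ``C`` by ``lobe_ratio`` and agree within ``asymmetry_tol``-fold;
    *unilateral* if only one lobe dominates (or both do but asymmetrically);
    otherwise *circumferential*.

    ``noise_floor`` should be on the profile scale (see
    :func:`estimate_profile_noise_floor`); if omitted, a robust estimate from
    the profile's successive differences is used.
    """
    cfg = config or ClassifierConfig()
    pos = profile.positions_deg
    inten = profile.intensities
    if noise_floor is None:
        noise_floor = _robust_noise_floor(inten)

    lat1 = angular_distance(pos, 90.0) <= cfg.lobe_halfwidth_deg
    lat2 = angular_distance(pos, 270.0) <= cfg.lobe_halfwidth_deg
    cen = (angular_distance(pos, 0.0) <= cfg.lobe_halfwidth_deg) | (
        angular_distance(pos, 180.0) <= cfg.lobe_halfwidth_deg
    )
    lobe1 = float(inten[lat1].mean())
    lobe2 = float(inten[lat2].mean())
    lateral = float(inten[lat1 | lat2].mean())
    central = float(inten[cen].mean())
    overall = float(inten.mean())
    level = float(np.percentile(inten, 90))  # robust peak level of the profile
    cv = float(inten.std() / overall) if overall > 0 else 0.0

    scores = {
        "lateral_mean": lateral,
        "central_mean": central,
        "lobe1": lobe1,
        "lobe2": lobe2,
        "cv": cv,
        "overall_mean": overall,
        "level_p90": level,
        "noise_floor": float(noise_floor),
    }

    # "no cortical signal": even the profile's upper level does not rise
    # above the blank-profile floor; epsilon guards the exact noise-free case
    eps = 1e-9 * max(profile.background, 1.0)
    if level <= cfg.absent_threshold * noise_floor + eps:
        return LocalisationCall("absent", scores)
    if cv < cfg.cv_threshold:
        return LocalisationCall("circumferential", scores)

    central_dominates = central > cfg.lobe_ratio * lateral
    b1 = lobe1 > cfg.lobe_ratio * central
    b2 = lobe2 > cfg.lobe_ratio * central
    symmetric = (
        max(lobe1, lobe2) <= cfg.asymmetry_tol * min(lobe1, lobe2)
        if min(lobe1, lobe2) > 0
        else False
    )

    if central_dominates:
        return LocalisationCall("central", scores)
    if b1 and b2 and symmetric:
        return LocalisationCall("bilateral", scores)
    if b1 or b2:
        return LocalisationCall("unilateral", scores)
    return LocalisationCall("circumferential", scores)


def tabulate_categories(calls, groups):
    """Per-group percentage table over the five localisation categories.

    ``calls`` and ``groups`` are parallel sequences (one label per cell).
    Returns a DataFrame indexed by group with one column per category;
    rows sum to 100.
    """
    import pandas as pd

    calls = list(calls)
    groups = list(groups)
    if len(calls) != len(groups):
        raise ValueError("calls and groups must be parallel sequences")
    if not calls:
        raise ValueError("no localisation calls supplied")
    df = pd.DataFrame(
        {"group": groups, "category": [c.category if isinstance(c, LocalisationCall) else c for c in calls]}
    )
    counts = (
        df.groupby("group")["category"].value_counts().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=CATEGORIES, fill_value=0)
    pct = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    pct.columns.name = None
    return pct
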