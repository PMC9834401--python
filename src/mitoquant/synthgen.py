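"""Synthetic microscopy scenes with attached ground truth.

Every generator here emulates one class of input the analysis modules
consume — fixed metaphase cells with a patterned cortical band, astral
spindles, metaphase angle traces, plate-centroid tracks, and 3D-culture
acini — and attaches the exact parameters it used, so downstream
measurements can be tested as parameter recovery with no external data.

Study-condition defaults: 512x512 px frames at 0.1 µm/px (z-step 0.6 µm for
volumetric quantities), cell ellipse 120x90 px, cortical band sigma 3 px,
crescent FWHM 60°, peak 1000 AU over 100 AU background. Noise is additive
Gaussian; all randomness flows from one integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _draw_line

from ._geom import angular_distance, ellipse_polar_radius, wrap_360
from .dynamics import AngleTrace, Track
from .spindle_metrics import SpindlePoles

PATTERNS = ("bilateral", "unilateral", "central", "circumferential", "absent")

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

DEFAULT_IMAGE_SHAPE = (512, 512)
DEFAULT_PIXEL_SIZE_UM = 0.1
DEFAULT_Z_STEP_UM = 0.6


# --------------------------------------------------------------------------
# truth records


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth of a cortical-pattern metaphase cell."""

    pattern: str
    crescent_center_deg: float = 90.0
    crescent_width_deg: float = 60.0
    peak_intensity: float = 1000.0
    background: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {PATTERNS}")
        if not (0.0 < self.crescent_width_deg <= 360.0):
            raise ValueError("crescent_width_deg must be in (0, 360]")
        if self.background < 0 or self.noise_sd < 0:
            raise ValueError("background and noise_sd must be >= 0")
        if self.pattern == "absent":
            if self.peak_intensity > self.background:
                raise ValueError(
                    "inconsistent truth: pattern 'absent' with peak_intensity > background"
                )
        elif self.peak_intensity <= self.background:
            raise ValueError("require peak_intensity > background for non-absent patterns")


@dataclass(frozen=True)
class AstralTruth:
    """Ground truth of a synthetic astral-spindle cell."""

    spindle_length_um: float
    astral_lengths_um: tuple
    spindle_intensity: float
    astral_intensity: float
    background: float
    noise_sd: float
    seed: int
    # filled in by the generator after rendering:
    I_spindle: float = 0.0
    I_astral: float = 0.0
    astral_over_spindle: float = 0.0
    pole_cortex_d_um: tuple = (0.0, 0.0)
    astral_endpoints_px: tuple = ()


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth of a metaphase angle trace with planted oscillations."""

    n_frames: int
    frame_interval_min: float = 3.0
    baseline_deg: float = 5.0
    event_frames: tuple = ()
    event_magnitudes_deg: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if len(self.event_frames) != len(self.event_magnitudes_deg):
            raise ValueError("event_frames and event_magnitudes_deg must be parallel")
        for f in self.event_frames:
            if not (1 <= f <= self.n_frames - 1):
                raise ValueError(f"event frame {f} outside [1, {self.n_frames - 1}]")
        if len(set(self.event_frames)) != len(self.event_frames):
            raise ValueError("event frames must be distinct")
        for m in self.event_magnitudes_deg:
            if m <= 0:
                raise ValueError("event magnitudes must be > 0")


@dataclass(frozen=True)
class TrackTruth:
    """Ground truth of a plate-centroid track."""

    n_steps: int
    step_length_um: float
    drift_um: tuple
    frame_interval_min: float
    seed: int
    path_length_um: float = 0.0
    displacement_um: float = 0.0


@dataclass(frozen=True)
class AcinusTruth:
    """Ground truth of a synthetic acinus."""

    n_cells: int
    n_lumens: int = 1
    lumen_radii_px: tuple = (110.0,)
    apical_enrichment: float = 3.0
    division_angles_deg: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 3:
            raise ValueError("n_cells must be >= 3")
        if self.n_lumens < 0:
            raise ValueError("n_lumens must be >= 0")
        if len(self.lumen_radii_px) != self.n_lumens:
            raise ValueError("lumen_radii_px must have one radius per lumen")
        if self.apical_enrichment < 1:
            raise ValueError("apical_enrichment must be >= 1")
        for a in self.division_angles_deg:
            if not (0.0 <= a <= 90.0):
                raise ValueError("division angles must lie in [0, 90]")


# --------------------------------------------------------------------------
# scene containers


@dataclass
class CellScene:
    """A rendered single-cell scene: channel images plus geometry and truth."""

    channels: dict
    contour: np.ndarray            # (n, 2) ordered (x, y) px
    plate_axis_deg: float
    poles_um: np.ndarray           # (2, 3)
    pixel_size_um: float
    truth: object
    masks: dict = field(default_factory=dict)


@dataclass
class AcinusScene:
    """A rendered acinus: channel images, outline/lumen polygons, cell labels."""

    channels: dict
    outline: np.ndarray            # (n, 2) px
    lumens: list
    cell_labels: np.ndarray
    pole_pairs: list
    pixel_size_um: float
    truth: AcinusTruth


# --------------------------------------------------------------------------
# analytic angular-intensity model


def angular_intensity(truth: SceneTruth, theta_deg):
    """Ground-truth cortical intensity *above background* at profile angle(s).

    The crescents are Gaussian bumps in angle (sigma from the FWHM
    ``crescent_width_deg``), evaluated on the shortest angular distance —
    smooth, unimodal per crescent. Bilateral adds an antipodal copy.
    This closed form is what the renderer paints along the cortical band, so
    it doubles as the analytic oracle for profile-recovery tests.
    """
    theta = np.asarray(theta_deg, dtype=float)
    amp = truth.peak_intensity - truth.background
    sigma = truth.crescent_width_deg / _FWHM_TO_SIGMA

    def bump(center):
        d = angular_distance(theta, center)
        return np.exp(-(d**2) / (2.0 * sigma**2))

    c = truth.crescent_center_deg
    if truth.pattern == "absent":
        return np.zeros_like(theta)
    if truth.pattern == "circumferential":
        return np.full_like(theta, amp)
    if truth.pattern == "bilateral":
        return amp * (bump(c) + bump(c + 180.0))
    # unilateral and central are both single crescents; they differ only in
    # where the crescent sits relative to the metaphase plate (lateral vs
    # central cortex), i.e. in crescent_center_deg.
    return amp * bump(c)


def default_crescent_center(pattern: str) -> float:
    """Conventional crescent centre per pattern: lateral (90°) except central (0°)."""
    return 0.0 if pattern == "central" else 90.0


# --------------------------------------------------------------------------
# metaphase-cell renderer


def make_metaphase_cell(
    truth: SceneTruth,
    semi_major_px: float = 120.0,
    semi_minor_px: float = 90.0,
    orientation_deg: float = 0.0,
    plate_axis_deg: float | None = None,
    center_px: tuple | None = None,
    image_shape: tuple = DEFAULT_IMAGE_SHAPE,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    band_sigma_px: float = 4.0,
    cytoplasm_intensity: float = 0.0,
    n_contour_points: int = 200,
) -> CellScene:
    """Render a metaphase cell with a patterned cortical band.

    The cortical channel carries ``background`` everywhere plus a band along
    the ellipse outline with Gaussian radial cross-section (sigma
    ``band_sigma_px``) whose peak follows :func:`angular_intensity` in the
    profile coordinate (0° facing the metaphase plate). The DNA channel
    carries a plate bar along ``plate_axis_deg`` (default: the ellipse short
    axis, putting the spindle on the long axis); the spindle channel carries
    two pole blobs.
    """
    if semi_major_px <= 0 or semi_minor_px <= 0:
        raise ValueError("semi-axes must be > 0")
    if semi_minor_px > semi_major_px:
        raise ValueError("require semi_major_px >= semi_minor_px")
    h, w = image_shape
    cx, cy = center_px if center_px is not None else ((w - 1) / 2.0, (h - 1) / 2.0)
    if plate_axis_deg is None:
        plate_axis_deg = orientation_deg + 90.0

    # render the cell signal only inside its bounding window (plus margin)
    margin = 6.0 * band_sigma_px
    x0 = max(int(np.floor(cx - semi_major_px - margin)), 0)
    x1 = min(int(np.ceil(cx + semi_major_px + margin)) + 1, w)
    y0 = max(int(np.floor(cy - semi_major_px - margin)), 0)
    y1 = min(int(np.ceil(cy + semi_major_px + margin)) + 1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    r = np.hypot(dx, dy)
    phi = np.degrees(np.arctan2(dy, dx))
    r_e = ellipse_polar_radius(semi_major_px, semi_minor_px, phi - orientation_deg)

    radial = np.exp(-((r - r_e) ** 2) / (2.0 * band_sigma_px**2))
    radial[np.abs(r - r_e) > 5.0 * band_sigma_px] = 0.0
    theta = wrap_360(phi - plate_axis_deg)
    cortex_win = angular_intensity(truth, theta) * radial
    inside = r <= r_e
    if cytoplasm_intensity > 0:
        cortex_win = cortex_win + cytoplasm_intensity * inside

    # DNA: metaphase plate bar along the plate axis
    th = np.radians(plate_axis_deg)
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    plate_half = 0.45 * ellipse_polar_radius(
        semi_major_px, semi_minor_px, plate_axis_deg - orientation_deg
    )
    dna_win = 800.0 * np.exp(
        -(u**2) / (2.0 * (plate_half / 2.0) ** 2) - (v**2) / (2.0 * 4.0**2)
    )

    # spindle: two pole blobs on the axis perpendicular to the plate
    spindle_az = plate_axis_deg + 90.0
    sa = np.radians(spindle_az)
    pole_r = 0.55 * ellipse_polar_radius(
        semi_major_px, semi_minor_px, spindle_az - orientation_deg
    )
    p1 = np.array([cx - pole_r * np.cos(sa), cy - pole_r * np.sin(sa)])
    p2 = np.array([cx + pole_r * np.cos(sa), cy + pole_r * np.sin(sa)])
    spindle_win = sum(
        800.0 * np.exp(-((xx - p[0]) ** 2 + (yy - p[1]) ** 2) / (2.0 * 4.0**2))
        for p in (p1, p2)
    )

    rng = np.random.default_rng(truth.seed)
    channels = {}
    for name, win in (("cortex", cortex_win), ("spindle", spindle_win), ("dna", dna_win)):
        img = np.full((h, w), float(truth.background))
        img[y0:y1, x0:x1] += win
        if truth.noise_sd > 0:
            img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)
        channels[name] = img

    t = np.linspace(0.0, 2.0 * np.pi, n_contour_points, endpoint=False)
    ct, st = np.cos(np.radians(orientation_deg)), np.sin(np.radians(orientation_deg))
    ex = semi_major_px * np.cos(t)
    ey = semi_minor_px * np.sin(t)
    contour = np.column_stack([cx + ct * ex - st * ey, cy + st * ex + ct * ey])

    poles_um = np.array(
        [[p1[0] * pixel_size_um, p1[1] * pixel_size_um, 0.0],
         [p2[0] * pixel_size_um, p2[1] * pixel_size_um, 0.0]]
    )
    cell_mask = np.zeros((h, w), dtype=bool)
    cyto_mask = np.zeros((h, w), dtype=bool)
    cell_mask[y0:y1, x0:x1] = r <= r_e + 5.0 * band_sigma_px
    cyto_mask[y0:y1, x0:x1] = r <= r_e - 5.0 * band_sigma_px
    masks = {"cell": cell_mask, "cytoplasm": cyto_mask}
    return CellScene(
        channels=channels,
        contour=contour,
        plate_axis_deg=float(plate_axis_deg),
        poles_um=poles_um,
        pixel_size_um=pixel_size_um,
        truth=truth,
        masks=masks,
    )


# --------------------------------------------------------------------------
# astral-spindle renderer


def make_astral_cell(
    spindle_length_um: float,
    astral_lengths_um,
    spindle_intensity: float = 800.0,
    astral_intensity: float = 300.0,
    semi_major_px: float = 120.0,
    semi_minor_px: float = 90.0,
    spindle_offset_px: float = 0.0,
    astral_angle_deg: float = 20.0,
    image_shape: tuple = DEFAULT_IMAGE_SHAPE,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    background: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CellScene:
    """Render a spindle with four astral fibres of known length.

    The spindle is a solid ellipse along the cell's major axis, optionally
    displaced toward one cortex by ``spindle_offset_px``; from each pole two
    1-px astral segments extend outward at ±``astral_angle_deg`` from the
    axis. Ground-truth photon counts (``I_spindle``, ``I_astral``), the
    planted astral/spindle ratio and the pole-to-cortex distances are
    recorded on the returned :class:`AstralTruth`.
    """
    astral_lengths_um = tuple(float(v) for v in astral_lengths_um)
    if len(astral_lengths_um) != 4:
        raise ValueError("need exactly four astral lengths")
    if spindle_length_um <= 0 or any(v <= 0 for v in astral_lengths_um):
        raise ValueError("all lengths must be > 0")
    h, w = image_shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    sx = cx + spindle_offset_px
    half_px = spindle_length_um / 2.0 / pixel_size_um

    yy, xx = np.mgrid[0:h, 0:w]
    r_cell = ellipse_polar_radius(
        semi_major_px, semi_minor_px, np.degrees(np.arctan2(yy - cy, xx - cx))
    )
    cell_mask = np.hypot(xx - cx, yy - cy) <= r_cell
    spindle_mask = ((xx - sx) / half_px) ** 2 + ((yy - cy) / (0.35 * half_px)) ** 2 <= 1.0

    poles_px = np.array([[sx - half_px, cy], [sx + half_px, cy]])
    if poles_px[0, 0] <= cx - semi_major_px or poles_px[1, 0] >= cx + semi_major_px:
        raise ValueError("spindle poles fall outside the cell outline")

    astral = np.zeros((h, w), dtype=bool)
    endpoints = []
    dirs = [180.0 - astral_angle_deg, 180.0 + astral_angle_deg,
            -astral_angle_deg, astral_angle_deg]
    for (pole, az), length_um in zip(
        [(poles_px[0], dirs[0]), (poles_px[0], dirs[1]),
         (poles_px[1], dirs[2]), (poles_px[1], dirs[3])],
        astral_lengths_um,
    ):
        L = length_um / pixel_size_um
        end = pole + L * np.array([np.cos(np.radians(az)), np.sin(np.radians(az))])
        if not (0 <= end[0] <= w - 1 and 0 <= end[1] <= h - 1):
            raise ValueError("astral segment exits the image frame")
        rr, cc = _draw_line(
            int(round(pole[1])), int(round(pole[0])), int(round(end[1])), int(round(end[0]))
        )
        astral[rr, cc] = True
        endpoints.append((float(end[0]), float(end[1])))
    astral &= ~spindle_mask

    image = np.full((h, w), float(background))
    image[spindle_mask] += spindle_intensity
    image[astral] += astral_intensity
    I_spindle = float(spindle_intensity * spindle_mask.sum())
    I_astral = float(astral_intensity * astral.sum())

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)

    d1 = (poles_px[0, 0] - (cx - semi_major_px)) * pixel_size_um
    d2 = ((cx + semi_major_px) - poles_px[1, 0]) * pixel_size_um
    truth = AstralTruth(
        spindle_length_um=float(spindle_length_um),
        astral_lengths_um=astral_lengths_um,
        spindle_intensity=float(spindle_intensity),
        astral_intensity=float(astral_intensity),
        background=float(background),
        noise_sd=float(noise_sd),
        seed=int(seed),
        I_spindle=I_spindle,
        I_astral=I_astral,
        astral_over_spindle=I_astral / I_spindle,
        pole_cortex_d_um=(float(d1), float(d2)),
        astral_endpoints_px=tuple(endpoints),
    )

    t = np.linspace(0.0, 2.0 * np.pi, 200, endpoint=False)
    contour = np.column_stack(
        [cx + semi_major_px * np.cos(t), cy + semi_minor_px * np.sin(t)]
    )
    poles_um = np.array(
        [[poles_px[0, 0] * pixel_size_um, poles_px[0, 1] * pixel_size_um, 0.0],
         [poles_px[1, 0] * pixel_size_um, poles_px[1, 1] * pixel_size_um, 0.0]]
    )
    return CellScene(
        channels={"spindle": image},
        contour=contour,
        plate_axis_deg=90.0,
        poles_um=poles_um,
        pixel_size_um=pixel_size_um,
        truth=truth,
        masks={"cell": cell_mask, "spindle": spindle_mask, "astral": astral},
    )


# --------------------------------------------------------------------------
# pole pairs with planted tilt


def make_tilted_pole_pair(
    alpha_z_deg: float,
    spindle_length_um: float = 10.0,
    azimuth_deg: float = 0.0,
    center_um: tuple = (25.6, 25.6, 9.0),
    voxel_size_um: tuple = (DEFAULT_PIXEL_SIZE_UM, DEFAULT_PIXEL_SIZE_UM, 0.3),
) -> SpindlePoles:
    """A pole pair realising a planted tilt, snapped to the voxel grid.

    Coordinates are quantised to the (anisotropic) voxel size, as they would
    be when read off a microscopy stack, so recovery of ``alpha_z_deg`` is
    exact only up to discretisation. The default z-step is the 0.3 µm
    interval of fixed-cell confocal stacks (live-imaging stacks use the
    coarser 0.6 µm increments).
    """
    if not (0.0 <= alpha_z_deg <= 90.0):
        raise ValueError("alpha_z_deg must be in [0, 90]")
    half = spindle_length_um / 2.0
    a = np.radians(alpha_z_deg)
    az = np.radians(azimuth_deg)
    d = np.array([np.cos(a) * np.cos(az), np.cos(a) * np.sin(az), np.sin(a)]) * half
    c = np.asarray(center_um, float)
    v = np.asarray(voxel_size_um, float)
    p1 = np.round((c - d) / v) * v
    p2 = np.round((c + d) / v) * v
    return SpindlePoles(tuple(p1), tuple(p2))


# --------------------------------------------------------------------------
# angle traces and tracks


def make_angle_trace(
    truth: TraceTruth,
    jitter_bound_deg: float = 3.0,
    threshold_deg: float = 10.0,
    axis: str = "z",
) -> AngleTrace:
    """Angle trace with planted oscillation events and bounded jitter.

    Events are realised as baseline *steps* of alternating sign at the event
    frames (a one-frame spike would register as two consecutive-frame
    deviations). Frame-to-frame jitter is uniform in
    ±``jitter_bound_deg``, so non-event deviations stay strictly below
    ``2 * jitter_bound_deg``. The truth is unambiguous only when every event
    magnitude exceeds ``threshold_deg + 2 * jitter_bound_deg`` and
    ``2 * jitter_bound_deg < threshold_deg``; other inputs are rejected.
    """
    if 2.0 * jitter_bound_deg >= threshold_deg:
        raise ValueError("2 * jitter_bound_deg must be < threshold_deg")
    for m in truth.event_magnitudes_deg:
        if m <= threshold_deg + 2.0 * jitter_bound_deg:
            raise ValueError(
                f"event magnitude {m} deg is ambiguous: must exceed "
                f"threshold + 2 * jitter bound = {threshold_deg + 2 * jitter_bound_deg} deg"
            )
    n = truth.n_frames
    rng = np.random.default_rng(truth.seed)
    jitter = rng.uniform(-jitter_bound_deg, jitter_bound_deg, size=n) if jitter_bound_deg > 0 else np.zeros(n)
    steps = np.zeros(n)
    order = np.argsort(truth.event_frames)
    for i, k in enumerate(order):
        f = truth.event_frames[k]
        steps[f] = truth.event_magnitudes_deg[k] * (1.0 if i % 2 == 0 else -1.0)
    angles = truth.baseline_deg + np.cumsum(steps) + jitter
    times = np.arange(n) * truth.frame_interval_min
    return AngleTrace(times, angles, axis, truth.frame_interval_min, truth=truth)


def make_track(
    n_steps: int,
    step_length_um: float = 0.3,
    drift_um: tuple = (0.0, 0.0),
    frame_interval_min: float = 3.0,
    seed: int = 0,
) -> Track:
    """Random plate-centroid track: isotropic steps of fixed length plus drift.

    The realised cumulative path length and displacement are recorded on the
    attached :class:`TrackTruth`.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_steps)
    steps = step_length_um * np.column_stack([np.cos(theta), np.sin(theta)])
    steps += np.asarray(drift_um, float)
    points = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    path_length = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    displacement = float(np.hypot(*points[-1]))
    truth = TrackTruth(
        n_steps=n_steps,
        step_length_um=float(step_length_um),
        drift_um=tuple(float(v) for v in drift_um),
        frame_interval_min=float(frame_interval_min),
        seed=int(seed),
        path_length_um=path_length,
        displacement_um=displacement,
    )
    times = np.arange(n_steps + 1) * frame_interval_min
    return Track(times, points, truth=truth)


# --------------------------------------------------------------------------
# acinus renderer


def make_acinus(
    truth: AcinusTruth,
    outer_radius_px: float = 170.0,
    ring_thickness_px: float = 60.0,
    image_shape: tuple = DEFAULT_IMAGE_SHAPE,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    membrane_intensity: float = 600.0,
    background: float = 50.0,
    noise_sd: float = 0.0,
    edge_sigma_px: float = 1.5,
    pole_half_px: float = 12.0,
) -> AcinusScene:
    """Render a monolayer acinus: a ring of cells around lumen(s).

    A single lumen fills the cavity (its planted radius becomes the inner
    ring radius); multiple lumens are disjoint circles inside the cavity and
    are rejected if they would overlap the cell ring. The apical (F-actin)
    channel is the membrane channel with lumen-facing borders scaled by
    ``apical_enrichment``; the membrane (E-cadherin) channel has equal
    borders. Mitotic pole pairs realising ``division_angles_deg`` relative to
    the local basement-membrane tangent are placed at evenly spaced cells.
    """
    h, w = image_shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    R_out = float(outer_radius_px)

    if truth.n_lumens == 1:
        R_in = float(truth.lumen_radii_px[0])
        if R_in + 20.0 > R_out:
            raise ValueError("lumen overlaps the cell ring: radius too large")
        lumen_centers = [(cx, cy)]
        lumen_radii = [R_in]
    else:
        R_in = R_out - float(ring_thickness_px)
        lumen_centers, lumen_radii = [], []
        for i, r_l in enumerate(truth.lumen_radii_px):
            if truth.n_lumens == 0:
                break
            ang = 2.0 * np.pi * i / max(truth.n_lumens, 1)
            d = 0.0 if truth.n_lumens == 1 else R_in / 2.0
            c = (cx + d * np.cos(ang), cy + d * np.sin(ang))
            if d + r_l >= R_in - 2.0:
                raise ValueError(f"lumen {i} overlaps the cell ring")
            lumen_centers.append(c)
            lumen_radii.append(float(r_l))
        # pairwise disjointness
        for i in range(len(lumen_centers)):
            for j in range(i + 1, len(lumen_centers)):
                dij = np.hypot(
                    lumen_centers[i][0] - lumen_centers[j][0],
                    lumen_centers[i][1] - lumen_centers[j][1],
                )
                if dij <= lumen_radii[i] + lumen_radii[j]:
                    raise ValueError(f"lumens {i} and {j} overlap")

    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    rho = np.hypot(dx, dy)
    phi = np.degrees(np.arctan2(dy, dx)) % 360.0

    band = (rho >= R_in) & (rho <= R_out)
    sector = 360.0 / truth.n_cells
    cell_labels = np.where(band, 1 + np.floor(phi / sector).astype(int), 0)
    cell_labels[cell_labels > truth.n_cells] = truth.n_cells  # guard phi == 360

    def ring(radius, sigma):
        return np.exp(-((rho - radius) ** 2) / (2.0 * sigma**2))

    # radial cell-cell borders within the band
    phi_mod = np.mod(phi, sector)
    arc = np.minimum(phi_mod, sector - phi_mod) * np.radians(1.0) * rho
    edges = np.where(band, np.exp(-(arc**2) / (2.0 * edge_sigma_px**2)), 0.0)

    outer = ring(R_out, edge_sigma_px)
    inner = ring(R_in, edge_sigma_px)
    lumen_rings = np.zeros((h, w))
    for (lx, ly), r_l in zip(lumen_centers, lumen_radii):
        d_l = np.hypot(xx - lx, yy - ly)
        lumen_rings = np.maximum(
            lumen_rings, np.exp(-((d_l - r_l) ** 2) / (2.0 * edge_sigma_px**2))
        )

    base = np.maximum.reduce([outer, inner, edges, lumen_rings])
    membrane = background + membrane_intensity * base
    apical_borders = np.maximum(inner, lumen_rings)
    apical = background + membrane_intensity * np.maximum(
        np.maximum(outer, edges), truth.apical_enrichment * apical_borders
    )

    rng = np.random.default_rng(truth.seed)
    channels = {}
    for name, img in (("apical", apical), ("membrane", membrane)):
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        channels[name] = img

    t = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    outline = np.column_stack([cx + R_out * np.cos(t), cy + R_out * np.sin(t)])
    lumen_polys = [
        np.column_stack([lx + r_l * np.cos(t), ly + r_l * np.sin(t)])
        for (lx, ly), r_l in zip(lumen_centers, lumen_radii)
    ]

    pole_pairs = []
    n_div = len(truth.division_angles_deg)
    rho_mid = (R_in + R_out) / 2.0
    for i, alpha in enumerate(truth.division_angles_deg):
        cell_idx = int(round(i * truth.n_cells / max(n_div, 1))) % truth.n_cells
        phi_c = (cell_idx + 0.5) * sector
        pc = np.array(
            [cx + rho_mid * np.cos(np.radians(phi_c)), cy + rho_mid * np.sin(np.radians(phi_c))]
        )
        axis_az = phi_c + 90.0 + alpha  # tangent at phi_c is phi_c + 90
        u = np.array([np.cos(np.radians(axis_az)), np.sin(np.radians(axis_az))])
        p1 = (pc - pole_half_px * u) * pixel_size_um
        p2 = (pc + pole_half_px * u) * pixel_size_um
        pole_pairs.append(SpindlePoles((p1[0], p1[1], 0.0), (p2[0], p2[1], 0.0)))

    return AcinusScene(
        channels=channels,
        outline=outline,
        lumens=lumen_polys,
        cell_labels=cell_labels,
        pole_pairs=pole_pairs,
        pixel_size_um=pixel_size_um,
        truth=truth,
    )
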