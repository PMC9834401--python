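"""Fixed-cell spindle geometry and intensity statistics.

Covers the manual-ROI measurements done on fixed metaphase cells:

* spindle tilt to the substratum, ``alpha_z = arctan(|dz| / planar pole
  distance)`` folded into [0, 90] degrees, from voxel-size-scaled pole
  coordinates;
* relative astral-microtubule intensity
  ``I_astral,rel = (I_total - I_spindle) / I_spindle``;
* longer/shorter ratios for astral/comet lengths and pole-to-cortex
  distances;
* cortex-to-cytoplasm enrichment
  ``I_cortex / I_cytoplasm = (I_total - I_cytoplasm) / I_cytoplasm``;
* width-averaged intensity line profiles (the Fiji "line scan" with a
  30-px-wide line).

This module measures; it does not segment. Regions (whole cell, spindle
excluding poles-with-astrals, cytoplasm) arrive as masks, matching a manual
ROI workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geom import sample_bilinear
from .errors import DegenerateGeometryError, OutOfBoundsError


@dataclass(frozen=True)
class SpindlePoles:
    """The two spindle-pole positions in physical units (µm)."""

    pole1: tuple[float, float, float]
    pole2: tuple[float, float, float]

    def __post_init__(self):
        if np.allclose(self.pole1, self.pole2):
            raise DegenerateGeometryError("spindle poles coincide")

    @classmethod
    def from_pixels(cls, p1, p2, voxel_size_um):
        """Build from pixel/plane coordinates and a (dx, dy, dz) voxel size."""
        v = np.asarray(voxel_size_um, dtype=float)
        return cls(tuple(np.asarray(p1, float) * v), tuple(np.asarray(p2, float) * v))

    @property
    def axis_xy_deg(self) -> float:
        """Image-plane azimuth of the pole-pole axis, degrees."""
        d = np.asarray(self.pole2, float) - np.asarray(self.pole1, float)
        return float(np.degrees(np.arctan2(d[1], d[0])))


@dataclass(frozen=True)
class IntensityPartition:
    """Background-corrected summed fluorescence over nested cell regions."""

    I_total: float
    I_spindle: float = 0.0
    I_cytoplasm: float = 0.0

    def __post_init__(self):
        if self.I_total < 0 or self.I_spindle < 0 or self.I_cytoplasm < 0:
            raise ValueError("corrected intensities must be >= 0")
        if self.I_total < self.I_spindle or self.I_total < self.I_cytoplasm:
            raise ValueError("I_total must be >= each sub-region intensity")


@dataclass(frozen=True)
class RatioPair:
    """A longer/shorter ratio of two lengths or distances (µm)."""

    value_long: float
    value_short: float

    @property
    def ratio(self) -> float:
        return self.value_long / self.value_short


def spindle_angle_z(poles: SpindlePoles) -> float:
    """Spindle tilt to the substratum: arctan(|dz| / planar distance), [0, 90]°."""
    d = np.asarray(poles.pole2, float) - np.asarray(poles.pole1, float)
    planar = float(np.hypot(d[0], d[1]))
    return float(np.degrees(np.arctan2(abs(d[2]), planar)))


def astral_relative_intensity(part: IntensityPartition) -> float:
    """(I_total - I_spindle) / I_spindle: astral signal relative to the spindle."""
    if part.I_spindle <= 0:
        raise ValueError("I_spindle must be > 0 after background correction")
    return (part.I_total - part.I_spindle) / part.I_spindle


def cortex_cytoplasm_ratio(part: IntensityPartition) -> float:
    """(I_total - I_cytoplasm) / I_cytoplasm: cortical enrichment of e.g. F-actin."""
    if part.I_cytoplasm <= 0:
        raise ValueError("I_cytoplasm must be > 0 after background correction")
    return (part.I_total - part.I_cytoplasm) / part.I_cytoplasm


def length_ratio(l1: float, l2: float) -> RatioPair:
    """Longer/shorter ratio of two astral-microtubule or comet lengths."""
    if l1 <= 0 or l2 <= 0:
        raise ValueError("lengths must be > 0")
    return RatioPair(float(max(l1, l2)), float(min(l1, l2)))


def pole_cortex_distance_ratio(d1: float, d2: float) -> RatioPair:
    """Longer/shorter ratio of the two pole-to-cortex distances along the axis."""
    return length_ratio(d1, d2)


def measure_partition(
    image,
    cell_mask,
    spindle_mask=None,
    cytoplasm_mask=None,
    background_per_px: float = 0.0,
) -> IntensityPartition:
    """Background-corrected summed intensities over supplied ROI masks.

    Each region intensity is ``sum(image[mask]) - area * background_per_px``,
    floored at 0 (a fully background region corrects to no signal).
    """
    image = np.asarray(image, dtype=float)

    def corrected(mask):
        if mask is None:
            return 0.0
        mask = np.asarray(mask, dtype=bool)
        return max(float(image[mask].sum() - mask.sum() * background_per_px), 0.0)

    return IntensityPartition(
        I_total=corrected(cell_mask),
        I_spindle=corrected(spindle_mask),
        I_cytoplasm=corrected(cytoplasm_mask),
    )


def line_profile(image, p_start, p_end, width_px: int = 30):
    """Width-averaged intensity profile along a straight segment.

    Samples at 1-px steps along the segment; at each step the value is the
    mean of ``width_px`` bilinear samples spaced 1 px apart along the
    perpendicular, centred on the segment. Mirrors the Fiji line-scan with a
    wide line.
    """
    image = np.asarray(image, dtype=float)
    p0 = np.asarray(p_start, dtype=float)
    p1 = np.asarray(p_end, dtype=float)
    d = p1 - p0
    length = float(np.hypot(*d))
    if length == 0:
        raise DegenerateGeometryError("line profile endpoints coincide")
    u = d / length
    perp = np.array([-u[1], u[0]])
    steps = np.arange(0.0, length + 0.5, 1.0)
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0) if width_px > 1 else np.zeros(1)
    xs = p0[0] + steps[:, None] * u[0] + offsets[None, :] * perp[0]
    ys = p0[1] + steps[:, None] * u[1] + offsets[None, :] * perp[1]
    h, w = image.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
        raise OutOfBoundsError("line profile (with width) exits the image frame")
    samples = sample_bilinear(image, xs.ravel(), ys.ravel()).reshape(xs.shape)
    return samples.mean(axis=1)
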