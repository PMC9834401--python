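"""Time-lapse spindle analytics.

Builds signed per-frame angle traces from tracked spindle-pole pairs, counts
oscillation events, and summarises metaphase-plate centroid tracks.

Sign conventions (committed, configurable nowhere):

* ``xy``: the reference is the frame-0 spindle axis. Rotations that are
  clockwise on screen (y down) are positive; the axis is undirected so
  angles are wrapped to (-90, 90].
* ``z``: per-frame magnitude is the tilt to the substratum; the sign stays
  positive while the same physical pole remains the higher (larger z) one,
  and flips whenever the higher-pole identity reverses — the trace reads
  "poles changed direction" as a swap of which pole points up.

An *oscillation event* is a consecutive-frame angle deviation strictly
greater than the threshold (default 10°); the oscillation index is
``100 * n_events / n_frames`` (denominator: total frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geom import wrap_axial_90
from .errors import DegenerateGeometryError
from .spindle_metrics import SpindlePoles, spindle_angle_z


@dataclass
class AngleTrace:
    """Per-frame signed spindle angle over a metaphase time-lapse."""

    times_min: np.ndarray
    angles_deg: np.ndarray
    axis: str  # "z" or "xy"
    frame_interval_min: float
    truth: object = None

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if len(self.times_min) < 2 or len(self.times_min) != len(self.angles_deg):
            raise ValueError("trace needs >= 2 frames with matching times")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.axis not in ("z", "xy"):
            raise ValueError("axis must be 'z' or 'xy'")

    @property
    def n_frames(self) -> int:
        return len(self.angles_deg)


@dataclass
class OscillationSummary:
    n_events: int
    n_frames: int
    oscillation_index: float  # percent
    oscillating: bool


@dataclass
class Track:
    """Metaphase-plate centroid track in the xy plane (µm)."""

    times_min: np.ndarray
    points: np.ndarray  # (n, 2)
    truth: object = None

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.times_min) != len(self.points) or len(self.points) < 2:
            raise ValueError("track needs >= 2 points with matching times")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("track times must be strictly increasing")


@dataclass
class TrackSummary:
    displacement_um: float
    track_length_um: float
    duration_min: float
    velocity_um_per_min: float


def match_pole_order(pole_pairs):
    """Resolve per-frame pole-label swaps by nearest-predecessor matching.

    Returns a list of :class:`SpindlePoles` where each frame's ``pole1``
    is the physical pole closest to the previous frame's ``pole1``.
    """
    pairs = list(pole_pairs)
    if not pairs:
        return []
    out = [pairs[0]]
    for sp in pairs[1:]:
        prev1 = np.asarray(out[-1].pole1, float)
        prev2 = np.asarray(out[-1].pole2, float)
        p1 = np.asarray(sp.pole1, float)
        p2 = np.asarray(sp.pole2, float)
        keep = np.linalg.norm(p1 - prev1) + np.linalg.norm(p2 - prev2)
        swap = np.linalg.norm(p2 - prev1) + np.linalg.norm(p1 - prev2)
        out.append(sp if keep <= swap else SpindlePoles(sp.pole2, sp.pole1))
    return out


def _check_pairs(pole_pairs):
    pairs = list(pole_pairs)
    if len(pairs) < 2:
        raise ValueError("need >= 2 frames of pole pairs")
    for i, sp in enumerate(pairs):
        if np.allclose(sp.pole1, sp.pole2):
            raise DegenerateGeometryError(f"coincident spindle poles at frame {i}")
    return pairs


def angle_trace_xy(pole_pairs, frame_interval_min: float) -> AngleTrace:
    """Signed in-plane rotation of the spindle axis relative to frame 0.

    Frame 0 is 0 by construction; clockwise-on-screen rotations are positive;
    the undirected axis wraps angles to (-90, 90].
    """
    pairs = match_pole_order(_check_pairs(pole_pairs))
    ref = pairs[0].axis_xy_deg
    angles = wrap_axial_90([sp.axis_xy_deg - ref for sp in pairs])
    times = np.arange(len(pairs)) * float(frame_interval_min)
    return AngleTrace(times, angles, "xy", float(frame_interval_min))


def angle_trace_z(pole_pairs, frame_interval_min: float, z_tol_um: float = 1e-9) -> AngleTrace:
    """Signed spindle tilt trace.

    Magnitude per frame is the tilt to the substratum. Angles are positive
    until the higher pole (larger z) changes identity relative to the last
    non-planar frame; each such reversal flips the sign of subsequent angles.
    Planar frames (|dz| <= ``z_tol_um``) report 0 and do not update the
    reversal state.
    """
    pairs = match_pole_order(_check_pairs(pole_pairs))
    sign = 1.0
    last_higher = None
    angles = []
    for sp in pairs:
        dz = sp.pole2[2] - sp.pole1[2]
        if abs(dz) <= z_tol_um:
            angles.append(0.0)
            continue
        higher = 2 if dz > 0 else 1
        if last_higher is not None and higher != last_higher:
            sign = -sign
        last_higher = higher
        angles.append(sign * spindle_angle_z(sp))
    times = np.arange(len(pairs)) * float(frame_interval_min)
    return AngleTrace(times, angles, "z", float(frame_interval_min))


def count_oscillations(trace: AngleTrace, threshold_deg: float = 10.0) -> OscillationSummary:
    """Count oscillation events and the oscillation index of a trace.

    An event is a consecutive-frame pair whose absolute angle deviation is
    strictly greater than ``threshold_deg``; the index is
    ``100 * n_events / n_frames``.
    """
    dt = np.diff(trace.times_min)
    if not np.allclose(dt, dt[0]):
        warnings.warn(
            "non-uniform frame spacing; oscillation events counted on "
            "consecutive frame pairs regardless",
            stacklevel=2,
        )
    deviations = np.abs(np.diff(trace.angles_deg))
    n_events = int(np.sum(deviations > threshold_deg))
    n_frames = trace.n_frames
    return OscillationSummary(
        n_events=n_events,
        n_frames=n_frames,
        oscillation_index=100.0 * n_events / n_frames,
        oscillating=n_events >= 1,
    )


def summarise_track(track: Track) -> TrackSummary:
    """Displacement, cumulative path length, duration and velocity of a track.

    Velocity is total track length divided by the tracking duration
    (metaphase-plate congression time).
    """
    pts = track.points
    duration = float(track.times_min[-1] - track.times_min[0])
    if duration <= 0:
        raise ValueError("track duration must be > 0")
    steps = np.diff(pts, axis=0)
    track_length = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    displacement = float(np.hypot(*(pts[-1] - pts[0])))
    return TrackSummary(
        displacement_um=displacement,
        track_length_um=track_length,
        duration_min=duration,
        velocity_um_per_min=track_length / duration,
    )


def origin_align(tracks):
    """Translate each track so its first point is the origin; shapes unchanged."""
    out = []
    for t in tracks:
        out.append(Track(t.times_min.copy(), t.points - t.points[0], truth=t.truth))
    return out


def nebd_to_anaphase(nebd_frame: int, anaphase_frame: int, frame_interval_min: float) -> float:
    """Minutes from nuclear-envelope breakdown to anaphase onset."""
    if anaphase_frame <= nebd_frame:
        raise ValueError(
            f"anaphase frame ({anaphase_frame}) must be after NEBD frame ({nebd_frame})"
        )
    return (anaphase_frame - nebd_frame) * float(frame_interval_min)
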