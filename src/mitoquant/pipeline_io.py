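"""Shared plumbing: configuration, TIFF/CSV/JSON readers and writers, and
end-to-end pipeline orchestration from synthetic scene to summary tables.

Output conventions: angles in degrees (``_deg`` suffix), lengths in µm
(``_um``), percentages ``_pct``; CSV with a header row and '.' decimals;
truth sidecars and run manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import FormatError

logger = logging.getLogger("mitoquant")


@dataclass
class RunConfig:
    """Run parameters; the defaults are the standard acquisition/analysis
    constants (2° angular sampling via 180 positions, 30-px radial segment,
    10° oscillation threshold, 30° planar bound, 0.6 µm z-step)."""

    pixel_size_um: float = 0.1
    z_step_um: float = 0.6
    frame_interval_min: float = 3.0
    n_positions: int = 180
    radial_len_px: float = 30.0
    oscillation_threshold_deg: float = 10.0
    planar_max_deg: float = 30.0
    classifier: dict = field(default_factory=dict)
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in (
            "pixel_size_um",
            "z_step_um",
            "frame_interval_min",
            "n_positions",
            "radial_len_px",
            "oscillation_threshold_deg",
            "planar_max_deg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_json(cls, path, **overrides):
        """Load a config file and apply keyword overrides (overrides win)."""
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def read_stack(path):
    """Read a TIFF into a (channel, z, y, x) array plus metadata.

    Axes are normalised to CZYX; missing axes get length 1. Unlabelled
    leading axes are treated as Z. Raises :class:`FormatError` on unreadable
    files.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
    except (tifffile.TiffFileError, OSError, IndexError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path!r}: {exc}") from exc
    axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if data.ndim != len(axes):
        raise FormatError(f"axis string {axes!r} does not match array rank {data.ndim}")
    if "Y" not in axes or "X" not in axes:
        raise FormatError(f"TIFF {path!r} has no YX image axes ({axes!r})")
    for missing in "CZ":
        if missing not in axes:
            data = data[np.newaxis]
            axes = missing + axes
    order = [axes.index(ax) for ax in "CZYX"]
    extra = [i for i in range(data.ndim) if i not in order]
    if extra:  # collapse any remaining singleton axes (e.g. T of length 1)
        for i in sorted(extra, reverse=True):
            if data.shape[i] != 1:
                raise FormatError(f"unsupported non-singleton axis {axes[i]!r} in {path!r}")
            data = np.squeeze(data, axis=i)
        return read_stack_from_array(data)
    data = np.transpose(data, order)
    meta = {"axes": "CZYX", "path": str(path)}
    return data, meta


def read_stack_from_array(data):
    """Normalise an in-memory array of rank 2–4 to (C, Z, Y, X)."""
    data = np.asarray(data)
    while data.ndim < 4:
        data = data[np.newaxis]
    if data.ndim != 4:
        raise FormatError(f"cannot interpret array of rank {data.ndim} as CZYX")
    return data, {"axes": "CZYX"}


def write_stack(path, array):
    """Write a (C, Z, Y, X) (or lower-rank) array as an ImageJ-style TIFF."""
    arr, _ = read_stack_from_array(np.asarray(array))
    # ImageJ hyperstacks store axes in TZCYXS order
    zcyx = np.transpose(arr, (1, 0, 2, 3))
    tifffile.imwrite(path, zcyx.astype(np.float32), imagej=True, metadata={"axes": "ZCYX"})


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_truth_sidecar(path, truth):
    """Write a generator truth record as a JSON sidecar."""
    record = {"type": type(truth).__name__, **_jsonable(asdict(truth))}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)


def write_contour_csv(path, contour):
    pd.DataFrame(np.asarray(contour), columns=["x_px", "y_px"]).to_csv(path, index=False)


def read_contour_csv(path):
    df = pd.read_csv(path)
    for col in ("x_px", "y_px"):
        if col not in df.columns:
            raise FormatError(f"contour CSV {path!r} lacks column {col!r}")
    return df[["x_px", "y_px"]].to_numpy(dtype=float)


def read_poles_csv(path, voxel_size_um):
    """Per-frame pole CSV (frame, x1, y1, z1, x2, y2, z2) -> list of SpindlePoles."""
    from .spindle_metrics import SpindlePoles

    df = pd.read_csv(path)
    needed = ["frame", "x1", "y1", "z1", "x2", "y2", "z2"]
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"pole CSV {path!r} lacks column {col!r}")
    df = df.sort_values("frame")
    v = np.asarray(voxel_size_um, float)
    return [
        SpindlePoles(tuple(np.array([r.x1, r.y1, r.z1]) * v), tuple(np.array([r.x2, r.y2, r.z2]) * v))
        for r in df.itertuples()
    ]


def write_manifest(out_dir, config: RunConfig, mode: str):
    manifest = {
        "software": "mitoquant",
        "version": __version__,
        "mode": mode,
        "seed": config.seed,
        "config": _jsonable(asdict(config)),
    }
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


# --------------------------------------------------------------------------
# orchestration


def run_pipeline(config: RunConfig, mode: str, out_dir) -> dict:
    """Execute one module chain and write its result tables.

    ``mode`` is one of ``simulate``, ``profile``, ``spindle``, ``dynamics``,
    ``acinus`` or ``verify`` (simulate + analyse + truth-vs-measured
    comparison). Returns the result tables as DataFrames keyed by name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runner = {
        "simulate": _run_simulate,
        "verify": _run_verify,
    }.get(mode)
    if runner is None:
        raise ValueError(f"unknown pipeline mode {mode!r} (file-driven modes run via the CLI)")
    try:
        tables = runner(config, out_dir)
    except Exception:
        logger.exception("pipeline mode %r failed", mode)
        raise
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    write_manifest(out_dir, config, mode)
    return tables


def _run_simulate(config: RunConfig, out_dir: Path):
    """Write one example scene of every kind, with truth sidecars."""
    from . import synthgen

    truth = synthgen.SceneTruth(pattern="bilateral", seed=config.seed)
    scene = synthgen.make_metaphase_cell(truth, pixel_size_um=config.pixel_size_um)
    stack = np.stack([scene.channels[c] for c in ("cortex", "spindle", "dna")])
    write_stack(out_dir / "metaphase_cell.tif", stack)
    write_truth_sidecar(out_dir / "metaphase_cell.truth.json", truth)
    write_contour_csv(out_dir / "metaphase_cell.contour.csv", scene.contour)

    trace = synthgen.make_angle_trace(
        synthgen.TraceTruth(
            n_frames=40,
            frame_interval_min=config.frame_interval_min,
            event_frames=(8, 20, 31),
            event_magnitudes_deg=(20.0, 20.0, 20.0),
            seed=config.seed,
        )
    )
    trace_df = pd.DataFrame(
        {"frame": np.arange(trace.n_frames), "time_min": trace.times_min, "angle_deg": trace.angles_deg}
    )
    track = synthgen.make_track(30, seed=config.seed, frame_interval_min=config.frame_interval_min)
    track_df = pd.DataFrame(
        {"time_min": track.times_min, "x_um": track.points[:, 0], "y_um": track.points[:, 1]}
    )
    return {"trace": trace_df, "track": track_df}


def _run_verify(config: RunConfig, out_dir: Path):
    """Generate seeded scenes, run the matching analysis on each, and emit a
    truth-vs-measured comparison table. A row fails when the measurement
    misses its stated tolerance."""
    from . import acinus_morpho, cortex_profile, dynamics, spindle_metrics, synthgen

    rows = []

    def check(stage, quantity, truth_val, measured, tol):
        rows.append(
            {
                "stage": stage,
                "quantity": quantity,
                "truth": float(truth_val),
                "measured": float(measured),
                "tolerance": float(tol),
                "passed": bool(abs(float(measured) - float(truth_val)) <= tol),
            }
        )

    seed = config.seed

    # cortical profiling: noise-free pattern recovery
    for i, pattern in enumerate(synthgen.PATTERNS):
        truth = synthgen.SceneTruth(
            pattern=pattern,
            crescent_center_deg=synthgen.default_crescent_center(pattern),
            peak_intensity=1000.0 if pattern != "absent" else 100.0,
            seed=seed + i,
        )
        scene = synthgen.make_metaphase_cell(truth, pixel_size_um=config.pixel_size_um)
        ellipse = cortex_profile.fit_ellipse(scene.contour)
        profile = cortex_profile.scan_cortex(
            scene.channels["cortex"],
            ellipse,
            scene.plate_axis_deg,
            n_positions=config.n_positions,
            radial_len_px=config.radial_len_px,
        )
        bg = cortex_profile.measure_background(scene.channels["cortex"], (0, 0, 64, 64))
        corrected = cortex_profile.subtract_background(profile, bg)
        floor = cortex_profile.estimate_profile_noise_floor(
            scene.channels["cortex"], (0, 0, 64, 64), config.radial_len_px
        )
        call = cortex_profile.classify_localisation(corrected, noise_floor=floor)
        check(
            "profile",
            f"category_match[{pattern}]",
            1.0,
            1.0 if call.category == pattern else 0.0,
            0.0,
        )

    # fixed-cell spindle: astral intensity and tilt recovery
    astral = synthgen.make_astral_cell(8.0, (2.0, 2.5, 3.0, 3.5), seed=seed)
    part = spindle_metrics.measure_partition(
        astral.channels["spindle"],
        astral.masks["cell"],
        astral.masks["spindle"],
        background_per_px=astral.truth.background,
    )
    check(
        "spindle",
        "astral_relative_intensity",
        astral.truth.astral_over_spindle,
        spindle_metrics.astral_relative_intensity(part),
        0.01 * astral.truth.astral_over_spindle,
    )
    for j, alpha in enumerate((10.0, 30.0, 60.0)):
        poles = synthgen.make_tilted_pole_pair(alpha)
        check("spindle", f"alpha_z[{alpha:.0f}]", alpha, spindle_metrics.spindle_angle_z(poles), 2.0)

    # dynamics: event counts and track summaries
    trace_truth = synthgen.TraceTruth(
        n_frames=40, event_frames=(5, 17, 29), event_magnitudes_deg=(20.0, 22.0, 25.0), seed=seed
    )
    trace = synthgen.make_angle_trace(trace_truth, threshold_deg=config.oscillation_threshold_deg)
    summ = dynamics.count_oscillations(trace, config.oscillation_threshold_deg)
    check("dynamics", "n_events", len(trace_truth.event_frames), summ.n_events, 0.0)
    track = synthgen.make_track(50, seed=seed)
    tsumm = dynamics.summarise_track(track)
    check("dynamics", "track_length_um", track.truth.path_length_um, tsumm.track_length_um, 1e-9)

    # acinus: lumen count and division angles
    ac_truth = synthgen.AcinusTruth(
        n_cells=12, division_angles_deg=(10.0, 20.0, 40.0, 70.0), seed=seed
    )
    ac = synthgen.make_acinus(ac_truth)
    geometry = acinus_morpho.AcinusGeometry(
        ac.outline, ac.lumens, ac.cell_labels, config.pixel_size_um
    )
    check("acinus", "n_lumens", ac_truth.n_lumens, acinus_morpho.count_lumens(geometry), 0.0)
    for poles, alpha in zip(ac.pole_pairs, ac_truth.division_angles_deg):
        da = acinus_morpho.division_angle_vs_membrane(
            poles, ac.outline, pixel_size_um=config.pixel_size_um,
            planar_max_deg=config.planar_max_deg,
        )
        check("acinus", f"division_angle[{alpha:.0f}]", alpha, da.alpha_deg, 2.0)

    df = pd.DataFrame(rows)
    n_fail = int((~df["passed"]).sum())
    if n_fail:
        logger.warning("%d verification check(s) failed", n_fail)
    return {"comparison": df}
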