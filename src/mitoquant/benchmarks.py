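"""Seeded parameter-recovery experiments over the synthetic generators.

Each function generates scenes with known ground truth, runs the matching
analysis chain, and reports how well the planted parameters are recovered.
They back the package's `verify` mode and its acceptance checks; all
randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import acinus_morpho, cortex_profile, dynamics, spindle_metrics, synthgen

BACKGROUND_ROI = (0, 0, 64, 64)


def classify_metaphase_scene(scene) -> cortex_profile.LocalisationCall:
    """Full profiling chain for one rendered metaphase cell.

    Fits the ellipse to the contour, scans the cortex, subtracts the
    background (median of a cell-free ROI), and classifies the corrected
    profile with a noise floor estimated from the same ROI.
    """
    img = scene.channels["cortex"]
    ellipse = cortex_profile.fit_ellipse(scene.contour)
    profile = cortex_profile.scan_cortex(img, ellipse, scene.plate_axis_deg)
    bg = cortex_profile.measure_background(img, BACKGROUND_ROI)
    corrected = cortex_profile.subtract_background(profile, bg)
    floor = cortex_profile.estimate_profile_noise_floor(img, BACKGROUND_ROI)
    return cortex_profile.classify_localisation(corrected, noise_floor=floor)


def classifier_accuracy(n_per_pattern: int = 200, snr: float = 10.0, seed: int = 0) -> float:
    """Fraction of synthetic cells whose localisation category is recovered.

    Cells are rendered at the study defaults with additive Gaussian noise of
    sd ``(peak - background) / snr``; every pattern contributes
    ``n_per_pattern`` seeded cells.
    """
    peak, background = 1000.0, 100.0
    noise_sd = (peak - background) / snr
    correct = 0
    total = 0
    for i, pattern in enumerate(synthgen.PATTERNS):
        for j in range(n_per_pattern):
            truth = synthgen.SceneTruth(
                pattern=pattern,
                crescent_center_deg=synthgen.default_crescent_center(pattern),
                peak_intensity=peak if pattern != "absent" else background,
                background=background,
                noise_sd=noise_sd,
                seed=seed + i * n_per_pattern + j,
            )
            scene = synthgen.make_metaphase_cell(truth)
            call = classify_metaphase_scene(scene)
            correct += call.category == pattern
            total += 1
    return correct / total


def fixed_cell_angle_errors(n: int = 100, seed: int = 0) -> np.ndarray:
    """|recovered - planted| spindle tilt over voxel-quantised pole pairs (deg)."""
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n):
        alpha = float(rng.uniform(0.0, 90.0))
        poles = synthgen.make_tilted_pole_pair(alpha, azimuth_deg=float(rng.uniform(0, 360)))
        errors.append(abs(spindle_metrics.spindle_angle_z(poles) - alpha))
    return np.asarray(errors)


def acinus_angle_errors(n_acini: int = 10, seed: int = 0) -> np.ndarray:
    """|recovered - planted| division angle over synthetic acini (deg)."""
    rng = np.random.default_rng(seed)
    errors = []
    for k in range(n_acini):
        angles = tuple(np.round(rng.uniform(0.0, 90.0, size=5), 2))
        truth = synthgen.AcinusTruth(
            n_cells=12, division_angles_deg=angles, seed=seed + k
        )
        scene = synthgen.make_acinus(truth)
        for poles, alpha in zip(scene.pole_pairs, angles):
            da = acinus_morpho.division_angle_vs_membrane(
                poles, scene.outline, pixel_size_um=scene.pixel_size_um
            )
            errors.append(abs(da.alpha_deg - alpha))
    return np.asarray(errors)


def trace_event_recovery(n_traces: int = 100, seed: int = 0):
    """Planted vs recovered oscillation-event counts over seeded traces.

    Returns ``(n_exact, n_traces, max_index_error)`` where the index error is
    measured against the closed form ``100 * k / n_frames``.
    """
    rng = np.random.default_rng(seed)
    exact = 0
    max_index_err = 0.0
    for k in range(n_traces):
        n_frames = int(rng.integers(20, 60))
        n_events = int(rng.integers(0, 6))
        frames = tuple(
            sorted(rng.choice(np.arange(1, n_frames), size=n_events, replace=False))
        )
        mags = tuple(rng.uniform(17.0, 30.0, size=n_events))
        truth = synthgen.TraceTruth(
            n_frames=n_frames,
            event_frames=frames,
            event_magnitudes_deg=mags,
            seed=seed + 1000 + k,
        )
        trace = synthgen.make_angle_trace(truth, jitter_bound_deg=3.0, threshold_deg=10.0)
        summary = dynamics.count_oscillations(trace, threshold_deg=10.0)
        exact += summary.n_events == n_events
        max_index_err = max(
            max_index_err,
            abs(summary.oscillation_index - 100.0 * n_events / n_frames),
        )
    return exact, n_traces, max_index_err


def recovered_oscillation_threshold(lo: float = 5.0, hi: float = 20.0, tol: float = 1e-9) -> float:
    """The event threshold recovered behaviourally, by bisecting on the
    smallest consecutive-frame deviation that registers as an event."""

    def is_event(deviation: float) -> bool:
        trace = dynamics.AngleTrace([0.0, 3.0], [0.0, deviation], "z", 3.0)
        return dynamics.count_oscillations(trace).n_events == 1

    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if is_event(mid):
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2.0


def recovered_planar_bound(lo: float = 10.0, hi: float = 60.0, tol: float = 1e-9) -> float:
    """The planar-division angle bound recovered behaviourally, by bisecting
    on spindle axes at known angles to a locally straight basement membrane."""
    outline = [(0.0, 0.0), (200.0, 0.0), (200.0, 200.0), (0.0, 200.0)]

    def is_planar(alpha: float) -> bool:
        a = np.radians(alpha)
        d = (10.0 * np.cos(a), 10.0 * np.sin(a))
        poles = spindle_metrics.SpindlePoles(
            (100.0 - d[0], 20.0 - d[1], 0.0), (100.0 + d[0], 20.0 + d[1], 0.0)
        )
        return acinus_morpho.division_angle_vs_membrane(poles, outline).planar

    # bisect on the largest angle still flagged planar
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if is_planar(mid):
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def radial_capture_extent(offsets=range(-25, 26)) -> tuple:
    """Probe-pixel experiment: which radial offsets from the ellipse boundary
    the cortical scan captures. Returns (min_captured, max_captured), in px."""
    captured = []
    for d in offsets:
        img = np.zeros((129, 129))
        img[64, 64 + 30 + d] = 100.0
        circle = cortex_profile.FittedEllipse((64.0, 64.0), 30.0, 30.0, 0.0)
        profile = cortex_profile.scan_cortex(img, circle, 0.0)
        if profile.intensities[0] > 0:
            captured.append(d)
    return min(captured), max(captured)
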