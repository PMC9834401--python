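# mitoquant

Quantitative image analysis of mitotic spindle orientation in epithelial
cells — the measurement side of studies that ask how cortical polarity
machinery (LGN/GPSM2, NuMA, Gαi and their regulators such as annexin A1)
steers the mitotic spindle, in 2D culture and in 3D acini. It is written for
cell biologists who already have microscopy data (or none at all: every
analysis stage has a matched synthetic-scene generator with exact ground
truth, so the whole pipeline can be exercised and validated without a single
acquired image).

## What it measures

**Cortical intensity profiles** (`mitoquant.cortex_profile`). An ellipse is
fitted to the cell contour and the cortex is scanned at 180 angular
positions (every 2°); at each position the reported intensity is the maximum
along a 30-px radial segment centred on the ellipse boundary. Positions
0°/180° face the metaphase plate (central cortex), 90°/270° face the spindle
poles (lateral cortex). Profiles are background-corrected, averaged as
mean ± s.e.m., and classified into the five cortical-localisation
categories: *bilateral*, *unilateral*, *central*, *circumferential*,
*absent*.

**Fixed-cell spindle metrics** (`mitoquant.spindle_metrics`). Spindle tilt
to the substratum `α_z = arctan(|Δz| / d_xy)` folded to [0°, 90°]; relative
astral-microtubule intensity `I_astral,rel = (I_total − I_spindle) /
I_spindle`; cortical F-actin enrichment `I_cortex / I_cytoplasm = (I_total −
I_cytoplasm) / I_cytoplasm`; longer/shorter ratios for astral lengths and
pole-to-cortex distances; width-averaged line profiles.

**Time-lapse dynamics** (`mitoquant.dynamics`). Signed α_z and α_xy traces
from tracked pole pairs (clockwise-positive in-plane rotation relative to
the frame-0 axis; z-sign flips when the higher pole changes identity),
oscillation events (consecutive-frame deviation strictly > 10°), the
oscillation index `100 · n_events / n_frames`, and metaphase-plate track
summaries (displacement, path length, velocity = path length / congression
time).

**Acinus morphometrics** (`mitoquant.acinus_morpho`). Lumen counts, Fiji
shape descriptors (circularity `4πA/P²`, roundness `4A/(π·major²)`),
normal-lumen calling (single lumen ringed by apically enriched F-actin),
spindle angle to the local basement-membrane tangent with the planar
(0–30°) bin, and arc-length perimeter intensity profiles shared across
channels.

**Synthetic scenes** (`mitoquant.synthgen`). Metaphase cells with patterned
cortical bands, astral spindles with known photon counts, angle traces with
planted oscillation events, centroid tracks, and ring acini — each carrying
its generating parameters, so downstream measurements are testable as
parameter recovery.

## Worked example

```python
import numpy as np
from mitoquant import synthgen, cortex_profile

truth = synthgen.SceneTruth(pattern="bilateral", peak_intensity=1000,
                            background=100, noise_sd=90, seed=1)
scene = synthgen.make_metaphase_cell(truth)

ellipse = cortex_profile.fit_ellipse(scene.contour)
profile = cortex_profile.scan_cortex(scene.channels["cortex"], ellipse,
                                     scene.plate_axis_deg)
bg = cortex_profile.measure_background(scene.channels["cortex"], (0, 0, 64, 64))
corrected = cortex_profile.subtract_background(profile, bg)
floor = cortex_profile.estimate_profile_noise_floor(scene.channels["cortex"],
                                                    (0, 0, 64, 64))
call = cortex_profile.classify_localisation(corrected, noise_floor=floor)

print(profile.n_positions, profile.spacing_deg)
print(np.argmax(corrected.intensities[:90]) * 2,
      180 + np.argmax(corrected.intensities[90:]) * 2)
print(call.category)
```

prints

```
180 2.0
86 274
bilateral
```

— the scan has 180 positions spaced 2° apart, the two crescent peaks land
within two samples of the lateral cortex (90° and 270°, the positions facing
the spindle poles; noise at SNR 10 jitters the argmax slightly), and the
classifier recovers the planted *bilateral* pattern.

The same loop in one shot, with a truth-vs-measured comparison table across
all stages:

```sh
mitoquant verify --seed 1 --out-dir verify_out
```

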