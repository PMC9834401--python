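import numpy as np
import pytest

from mitoquant import synthgen
from mitoquant.benchmarks import classify_metaphase_scene

classify_scene = classify_metaphase_scene


def scene_for_pattern(pattern: str, seed: int, noise_sd: float = 0.0) -> synthgen.CellScene:
    """A metaphase cell of the given cortical pattern at study defaults."""
    truth = synthgen.SceneTruth(
        pattern=pattern,
        crescent_center_deg=synthgen.default_crescent_center(pattern),
        peak_intensity=1000.0 if pattern != "absent" else 100.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    return synthgen.make_metaphase_cell(truth)


@pytest.fixture(scope="session")
def noise_free_scenes():
    """One noise-free scene per cortical pattern."""
    return {p: scene_for_pattern(p, seed=7) for p in synthgen.PATTERNS}


@pytest.fixture(scope="session")
def bilateral_scene(noise_free_scenes):
    return noise_free_scenes["bilateral"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
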