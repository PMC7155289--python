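import numpy as np
import pytest

import panosim as ps


@pytest.fixture(scope="session")
def small_layout() -> ps.MosaicLayout:
    return ps.MosaicLayout(rows=3, cols=3, tile_px=96, overlap_frac=0.25,
                           pixel_size_nm=100.0)


@pytest.fixture(scope="session")
def pattern96() -> ps.PatternSet:
    return ps.make_line_patterns(96, 8, 4)


@pytest.fixture(scope="session")
def integer_scene() -> np.ndarray:
    """Integer-valued texture scene: blend arithmetic on crops is exact."""
    return np.round(ps.make_scene("texture", 400, seed=9))


def all_on_pattern(tile_px: int, n_phases: int = 2) -> ps.PatternSet:
    """Duty-1 pattern: every pixel illuminated in every phase."""
    return ps.PatternSet(
        period_px=2, n_phases=n_phases, orientation_deg=0.0, duty=1.0,
        masks=np.ones((n_phases, tile_px, tile_px)),
    )


@pytest.fixture(scope="session")
def noiseless_stacks(small_layout, pattern96, integer_scene):
    """Noise-free, vignette-free, PSF-free acquisition of the integer scene
    under a duty-1 pattern: each phase image is exactly the scene crop."""
    truth = ps.SceneGroundTruth(scene=integer_scene, seed=9)
    return ps.simulate_mosaic(truth, small_layout, all_on_pattern(96))
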