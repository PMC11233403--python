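import numpy as np
import pytest

from glycovol import SceneConfig, SegMask, generate_scene


@pytest.fixture(scope="session")
def toy_masks():
    """4×4 hand-built pair: 8 px label 1 (2 granule px), 8 px label 2 (0)."""
    loc = np.array(
        [
            [1, 1, 1, 1],
            [1, 1, 1, 1],
            [2, 2, 2, 2],
            [2, 2, 2, 2],
        ],
        dtype=np.uint8,
    )
    gran = np.zeros((4, 4), dtype=np.uint8)
    gran[0, 0] = 1
    gran[1, 2] = 1
    return (
        SegMask(loc, 0.8, "locations"),
        SegMask(gran, 0.8, "granules"),
    )


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 256² synthetic scene (image, locations, granules)."""
    return generate_scene(SceneConfig(size_px=256, seed=7))


@pytest.fixture(scope="session")
def tiny_scenes():
    """Two 64² scenes for fast segmenter tests."""
    out = []
    for seed in (11, 12):
        cfg = SceneConfig(
            size_px=64,
            sarcomere_period_nm=40.0,
            region_granule_vf={1: 0.02, 2: 0.08, 5: 0.12},
            seed=seed,
        )
        out.append(generate_scene(cfg))
    return out
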