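import numpy as np
import pytest

from alsquant.histology import SceneConfig, build_scene, render_section
from alsquant.ihc import QuantConfig


@pytest.fixture(scope="session")
def small_scene_cfg():
    # small canvas keeps unit tests fast; acceptance uses full-size scenes
    return SceneConfig(
        canvas_px=(512, 512),
        n_cells=12,
        n_touching_pairs=2,
        # somata alone cover ~12% of this small canvas; target must exceed that
        diffuse_fraction=0.15,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_scene(small_scene_cfg):
    truth = build_scene(small_scene_cfg)
    return truth, render_section(truth, small_scene_cfg), small_scene_cfg


@pytest.fixture(scope="session")
def quant_config():
    return QuantConfig()


@pytest.fixture(scope="session")
def small_cohort():
    from alsquant.cohort import CohortConfig, simulate_cohort

    config = CohortConfig(n_per_arm=20, seed=42)
    mice, truth = simulate_cohort(config)
    return config, mice
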