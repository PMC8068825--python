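import numpy as np
import pytest

from trapcount.synthetic import SceneConfig, generate_scene

# Reduced-scale geometry used throughout the tests: one quarter of the
# full 6000 x 4000 trap, preserving the insect:window and overlap:insect
# ratios (window 500 -> 125, overlap 100 -> 25, insect 60 -> 15).
SCALE = 0.25
WINDOW = 125
OVERLAP = 25


@pytest.fixture(scope="session")
def reduced_template() -> SceneConfig:
    return SceneConfig().scaled(SCALE)


def make_scene(n_insects, seed, *, cluster_fraction=0.0, n_distractors=0, scale=SCALE):
    """A reduced-scale scene; cluster-free and distractor-free by default."""
    cfg = SceneConfig(
        n_insects=n_insects,
        cluster_fraction=cluster_fraction,
        n_distractors=n_distractors,
        seed=seed,
    ).scaled(scale)
    return generate_scene(cfg)


@pytest.fixture()
def small_scene():
    """A 1500 x 1000 scene with 40 well-separated insects."""
    return make_scene(40, seed=11)
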