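import numpy as np
import pytest

from plaquekit import (
    ClassifierConfig,
    SceneSpec,
    TrialSimSpec,
    classify_pixels,
    render_scene,
    simulate_trial,
)
from plaquekit.trial_stats import timelines_to_frame


@pytest.fixture(scope="session")
def clean_scene():
    """A deterministic noise-free scene with 20% visible / 15% non-visible."""
    return render_scene(SceneSpec(seed=7))


@pytest.fixture(scope="session")
def clean_scene_labels(clean_scene):
    cfg = ClassifierConfig(closeness_margin=clean_scene.spec.closeness_margin)
    return classify_pixels(
        clean_scene.image,
        clean_scene.tooth_mask,
        clean_scene.reference_image,
        cfg,
    )


@pytest.fixture(scope="session")
def default_timelines():
    """One simulated trial at the default calibration (24 + 26 subjects)."""
    return simulate_trial(TrialSimSpec(seed=11))


@pytest.fixture(scope="session")
def default_frame(default_timelines):
    return timelines_to_frame(default_timelines)


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
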