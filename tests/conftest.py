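import numpy as np
import pytest

from shapecat import synth


@pytest.fixture(scope="session")
def design54():
    """The canonical 9-shape x 6-category design."""
    return synth.generate_design()


@pytest.fixture(scope="session")
def design54_masks(design54):
    return synth.generate_silhouettes(design54, H=48, W=48, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed population, reused by read-only tests."""
    design = synth.generate_design()
    spec = synth.PopulationSpec(
        n_channels=24, trials_min=10, trials_max=12, seed=5
    )
    data, gt = synth.generate_trials(design, spec)
    return data, gt


def make_dataset(**kwargs):
    """Dataset factory for tests that need custom populations."""
    defaults = dict(n_channels=12, trials_min=10, trials_max=12, seed=0)
    defaults.update(kwargs)
    design = synth.generate_design()
    return synth.generate_trials(design, synth.PopulationSpec(**defaults))
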