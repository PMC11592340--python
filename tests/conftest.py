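import numpy as np
import pytest

from exogait.curves import design_empirical_curve
from exogait.synthetic import (GaitTemplateConfig, default_condition_effects,
                               make_emg_dataset, make_force_templates)


@pytest.fixture(scope="session")
def templates():
    """Noise-free default artificial-muscle force templates."""
    return make_force_templates(GaitTemplateConfig())


@pytest.fixture(scope="session")
def designed_curve(templates):
    ham, rf = templates
    return design_empirical_curve(ham, rf)


@pytest.fixture(scope="session")
def small_dataset():
    """4 subjects x 4 conditions x 5 muscles, light noise, fixed seed."""
    return make_emg_dataset(n_subjects=4, effects=default_condition_effects(),
                            n_steps=10, noise_sd=0.01, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
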