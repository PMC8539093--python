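"""Shared fixtures: synthetic folds, simulated datasets, trained models.

The trained-model fixtures run the scaled-down curriculum once per session
(a few minutes on one CPU) and are shared by every test that needs a
trained network.
"""

import numpy as np
import pytest

from massreg.config import EvalTrainConfig, RegTrainConfig
from massreg.fixtures import make_demo_fold
from massreg.regnet import RegistrationNet, train_registration
from massreg.siamese import SiameseNet, train_siamese
from massreg.simulate import build_dataset


@pytest.fixture(scope="session")
def demo_fold():
    """25 training masks and 8 held-out masks, seed 0."""
    return make_demo_fold(25, 8, seed=0)


@pytest.fixture(scope="session")
def sim1(demo_fold):
    train, _ = demo_fold
    return build_dataset("sim1", train, np.random.default_rng((0, 1)))


@pytest.fixture(scope="session")
def sim2(demo_fold):
    train, _ = demo_fold
    return build_dataset("sim2", train, np.random.default_rng((0, 2)))


@pytest.fixture(scope="session")
def sim3(demo_fold):
    train, _ = demo_fold
    return build_dataset("sim3", train, np.random.default_rng((0, 3)))


@pytest.fixture(scope="session")
def trained_regnet(sim1):
    """Registration net after the scaled-down first training stage."""
    cfg = RegTrainConfig(epochs_exp1=5, seed=0)
    model = RegistrationNet(cfg)
    model, history = train_registration(model, sim1, cfg, "exp1")
    return model, history


@pytest.fixture(scope="session")
def trained_siamese(sim2):
    """Siamese net after the scaled-down third training stage."""
    cfg = EvalTrainConfig(epochs_per_stage=200, seed=0)
    model = SiameseNet(cfg)
    model, history = train_siamese(model, "exp3", sim2, cfg)
    return model, history
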