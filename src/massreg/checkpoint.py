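"""Model checkpoints: flat numpy archives of parameter arrays."""

from __future__ import annotations

import numpy as np

from .config import EvalTrainConfig, RegTrainConfig
from .regnet import AffineNet, RegistrationNet
from .siamese import SiameseNet
from .types import FormatError


def save_model(path, model) -> None:
    np.savez(
        path,
        kind=np.str_(type(model).__name__),
        **{f"p{i}": p.data for i, p in enumerate(model.params)},
    )


def load_model(path, config: RegTrainConfig | EvalTrainConfig | None = None):
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as data:
        kind = str(data["kind"])
        state = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    builders = {
        "RegistrationNet": RegistrationNet,
        "AffineNet": AffineNet,
        "SiameseNet": SiameseNet,
    }
    if kind not in builders:
        raise FormatError(f"unknown checkpoint kind {kind!r}")
    model = builders[kind](config)
    model.load_state(state)
    return model
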