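"""Run configuration: every tunable in one serializable place.

Configs round-trip through plain YAML; the CLI mirrors each key as a flag
and flags override file values.  All randomness downstream derives from
``RunConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .types import DEFAULT_PIXEL_SPACING_MM, ValidationError


@dataclass
class RegTrainConfig:
    """Training schedule for the registration half.

    The two-stage curriculum first learns rigid error correction on
    simulated unimodal pairs (20 epochs), then fine-tunes on multi-modal
    pairs (30 epochs), both at batch size 11 with Adam.
    """

    epochs_exp1: int = 20
    batch_exp1: int = 11
    epochs_exp2: int = 30
    batch_exp2: int = 11
    learning_rate: float = 1e-4
    smoothness_weight: float = 0.01
    enc_filters: tuple = (16, 32, 32, 32)
    dec_filters: tuple = (32, 32, 32, 32, 16, 16)
    seed: int = 0

    def validate(self):
        for name in ("epochs_exp1", "batch_exp1", "epochs_exp2", "batch_exp2"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.learning_rate <= 0 or self.smoothness_weight < 0:
            raise ValidationError("learning_rate > 0 and smoothness_weight >= 0 required")
        return self


@dataclass
class EvalTrainConfig:
    """Training schedule for the similarity (Siamese) half.

    Each stage runs ``epochs_per_stage`` optimisation epochs at batch 32
    with Adam and binary cross-entropy; 70% of the stage data trains and
    30% validates via 20-way one-shot trials every ``one_shot_interval``
    epochs.
    """

    epochs_per_stage: int = 2000
    batch: int = 32
    learning_rate: float = 1e-4
    val_fraction: float = 0.30
    one_shot_interval: int = 200
    one_shot_k: int = 20
    one_shot_trials: int = 50
    conv_filters: tuple = (32, 64, 64, 128)
    embedding_dim: int = 1024
    seed: int = 0

    def validate(self):
        if not (0.0 < self.val_fraction < 1.0):
            raise ValidationError("val_fraction must be in (0, 1)")
        if self.one_shot_k < 2:
            raise ValidationError("one_shot_k must be >= 2")
        if self.epochs_per_stage < 1 or self.batch < 1:
            raise ValidationError("epochs and batch must be positive")
        return self


@dataclass
class NoiseConfig:
    """Default amplitudes for the three synthetic noise families."""

    gaussian_sigma: float = 0.1
    periodic_amplitude: float = 0.2
    periodic_freq_range: tuple = (2.0, 8.0)
    perlin_amplitude: float = 0.3
    perlin_octave_range: tuple = (2, 4)


@dataclass
class RunConfig:
    """Top-level configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "massreg_out"
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    n_train_masks: int = 25
    n_test_masks: int = 8
    n_virtual_cores: int = 10
    reg: RegTrainConfig = field(default_factory=RegTrainConfig)
    eval: EvalTrainConfig = field(default_factory=EvalTrainConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def validate(self):
        if self.pixel_spacing_mm <= 0:
            raise ValidationError("pixel_spacing_mm must be positive")
        if self.n_train_masks < 1 or self.n_test_masks < 1:
            raise ValidationError("fold sizes must be positive")
        self.reg.validate()
        self.eval.validate()
        return self

    def rng(self, salt: int = 0) -> np.random.Generator:
        """Seeded generator; all stochastic stages must draw from these."""
        return np.random.default_rng((int(self.seed), int(salt)))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    sub = {
        "reg": RegTrainConfig,
        "eval": EvalTrainConfig,
        "noise": NoiseConfig,
    }
    kwargs = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in data:
            continue
        val = data[f.name]
        if f.name in sub:
            val = sub[f.name](**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in val.items()})
        kwargs[f.name] = val
    cfg = RunConfig(**kwargs)
    return cfg.validate()


def config_hash(config: RunConfig) -> str:
    import hashlib

    return hashlib.sha256(
        yaml.safe_dump(_to_plain(config), sort_keys=True).encode()
    ).hexdigest()[:16]
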