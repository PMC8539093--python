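"""Synthetic phantoms: everything tests and demos need, no downloads.

A phantom sample is a stained-core histology rendering, a matching
DESI-like spectrum cube, and the ground-truth core mask.  Demo folds
reproduce the study's fold shape (25 training masks, 8 held-out masks,
patient-exclusive by core identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import generate_virtual_core
from .types import SpectrumCube, ValidationError

# stain tint of the rendered tissue (pink/purple over a white slide)
_STAIN_RGB = np.array([0.80, 0.38, 0.62])


@dataclass
class PhantomSpec:
    """Parameters of one synthetic sample.

    n_channels defaults to 900 m/z bins (the dimensionality a DESI spectrum
    is reduced from); tissue_signal_channels are the bins carrying tissue
    signal; background_noise_level scales uniform background counts.
    """

    canvas: int = 96
    n_channels: int = 900
    tissue_signal_channels: tuple | None = None
    background_noise_level: float = 0.05
    mz_range: tuple = (100.0, 1000.0)
    pixel_spacing_mm: float = 0.05
    seed: int = 0

    # relative positions on the m/z axis where tissue signal appears when
    # no explicit channel set is given
    _SIGNAL_FRACTIONS = (0.011, 0.133, 0.411, 0.617, 0.778)

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValidationError("need at least 2 m/z channels")
        if self.tissue_signal_channels is None:
            self.tissue_signal_channels = tuple(
                sorted({int(f * self.n_channels) for f in self._SIGNAL_FRACTIONS})
            )
        if any(c >= self.n_channels for c in self.tissue_signal_channels):
            raise ValidationError("tissue_signal_channels out of range")


def make_phantom_slide(spec: PhantomSpec):
    """One synthetic sample: (histology RGB, SpectrumCube, truth mask).

    The histology image renders the core in a pink stain on a white slide;
    the cube carries elevated intensity in the tissue signal channels
    inside the core footprint plus uniform background counts everywhere.
    Deterministic per spec.seed.
    """
    rng = np.random.default_rng((int(spec.seed), 404))
    mask = generate_virtual_core(spec.canvas, rng)
    inside = mask > 0

    # histology: white slide, stained core with mild per-pixel variation
    rgb = np.ones((spec.canvas, spec.canvas, 3))
    jitter = rng.normal(0.0, 0.03, size=(spec.canvas, spec.canvas, 3))
    rgb[inside] = np.clip(_STAIN_RGB + jitter[inside], 0.0, 1.0)

    # spectrum cube: tissue peaks inside the footprint, noise everywhere
    cube = np.zeros((spec.canvas, spec.canvas, spec.n_channels))
    if spec.background_noise_level > 0:
        cube += rng.uniform(
            0.0, spec.background_noise_level, size=cube.shape
        )
    n_tissue = int(inside.sum())
    for ch in spec.tissue_signal_channels:
        cube[inside, ch] += rng.uniform(0.8, 1.2, size=n_tissue)
    mz_axis = np.linspace(spec.mz_range[0], spec.mz_range[1], spec.n_channels)
    return rgb, SpectrumCube(cube, mz_axis, spec.pixel_spacing_mm), mask


def make_demo_fold(n_train: int = 25, n_test: int = 8, seed: int = 0):
    """Disjoint train/test mask sets matching the study's fold shape."""
    rng = np.random.default_rng((int(seed), 505))
    masks = [generate_virtual_core(64, rng) for _ in range(n_train + n_test)]
    return masks[:n_train], masks[n_train:]


def make_crossval_folds(n_folds: int = 10, n_cores: int = 33, n_test: int = 8, seed: int = 0):
    """Core-exclusive cross-validation folds over one synthetic cohort.

    Every fold holds out n_test cores (by identity, emulating
    patient-exclusive folds) and trains on the rest.
    """
    rng = np.random.default_rng((int(seed), 606))
    cores = [generate_virtual_core(64, rng) for _ in range(n_cores)]
    folds = []
    for _ in range(n_folds):
        order = rng.permutation(n_cores)
        test_idx = set(order[:n_test].tolist())
        train = [cores[i] for i in range(n_cores) if i not in test_idx]
        test = [cores[i] for i in sorted(test_idx)]
        folds.append((train, test))
    return folds
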