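"""Domain containers shared across the package.

Coordinate convention (used everywhere): 0-based (row, col), origin at the
top-left, row index increasing downward.  Contour images are 64x64 float
arrays in [0, 1]; binary masks use exactly {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IMAGE_SIZE = 64  # side length of every registration-ready contour image
DEFAULT_PIXEL_SPACING_MM = 0.05  # DESI raster resolution, 50 um per pixel


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed in the named dialect."""


class DegeneratePCAError(ValidationError):
    """Raised when a spectral cube has no variance to decompose."""


def as_contour_image(pixels: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Validate and return a 64x64 float array in [0, 1]."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.shape != (IMAGE_SIZE, IMAGE_SIZE):
        raise ValidationError(
            f"{name} must be {IMAGE_SIZE}x{IMAGE_SIZE}, got {arr.shape}"
        )
    if np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1:
        raise ValidationError(f"{name} values must lie in [0, 1]")
    return arr


@dataclass
class SpectrumCube:
    """A grid of mass spectra: one spectrum of C channels per pixel.

    intensities : (H, W, C) non-negative ion counts (arbitrary units)
    mz_axis     : (C,) strictly increasing m/z values shared by all pixels
    pixel_spacing_mm : physical raster spacing, default 0.05 mm (50 um)
    """

    intensities: np.ndarray
    mz_axis: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be H x W x C")
        if self.mz_axis.ndim != 1 or self.mz_axis.size != self.intensities.shape[2]:
            raise ValidationError("mz_axis length must equal the channel count")
        if self.mz_axis.size < 2:
            raise ValidationError("a spectrum cube needs at least 2 channels")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValidationError("mz_axis must be strictly increasing")
        if np.any(self.mz_axis <= 0):
            raise ValidationError("m/z values must be positive")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")
        if self.pixel_spacing_mm <= 0:
            raise ValidationError("pixel_spacing_mm must be positive")

    @property
    def shape(self):
        return self.intensities.shape


@dataclass
class MisalignmentSpec:
    """A rigid perturbation: rotation in degrees, integer translation in px.

    Rotations are either 0 or in [3, 10] degrees; per-axis translations are
    integers with magnitude at most 12 pixels.
    """

    rotation_deg: float = 0.0
    translation_px: tuple[int, int] = (0, 0)  # (rows, cols)

    def __post_init__(self):
        r = float(self.rotation_deg)
        if r != 0.0 and not (3.0 <= abs(r) <= 10.0):
            raise ValidationError(
                f"rotation must be 0 or in [3, 10] degrees, got {r}"
            )
        tr, tc = self.translation_px
        if tr != int(tr) or tc != int(tc):
            raise ValidationError("translations must be integers")
        if max(abs(int(tr)), abs(int(tc))) > 12:
            raise ValidationError("translation magnitude is capped at 12 px")
        self.translation_px = (int(tr), int(tc))


@dataclass
class NoiseSpec:
    """Parameters of one synthetic noise family.

    kind      : gaussian (i.i.d. additive normal), periodic (2D sinusoid) or
                perlin (gradient-lattice noise)
    amplitude : noise strength; sigma for gaussian, peak amplitude otherwise
    frequency : cycles per frame (periodic only)
    octaves   : number of lattice octaves (perlin only)
    """

    kind: str = "gaussian"
    amplitude: float = 0.1
    frequency: float = 4.0
    octaves: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("gaussian", "periodic", "perlin"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")


@dataclass
class LabeledPair:
    """A (fixed, moving) contour-image pair with a similarity label.

    label is in [0, 1]; registered_flag is 1 only for untransformed
    (perfectly aligned) pairs.  provenance records how the pair was built.
    """

    fixed: np.ndarray
    moving: np.ndarray
    label: float
    registered_flag: int
    rotation_deg: float = 0.0
    translation_px: tuple[int, int] = (0, 0)
    noise_kind: str = "none"
    pair_id: str = ""

    def __post_init__(self):
        if not (0.0 <= self.label <= 1.0):
            raise ValidationError("label must lie in [0, 1]")
        if self.registered_flag not in (0, 1):
            raise ValidationError("registered_flag must be 0 or 1")


@dataclass
class FiducialSet:
    """Corresponding landmark points on fixed and moved images.

    Three (row, col) points per image by default; pixel spacing converts the
    registration error to millimetres.
    """

    points_fixed: np.ndarray
    points_moved: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self):
        self.points_fixed = np.atleast_2d(np.asarray(self.points_fixed, float))
        self.points_moved = np.atleast_2d(np.asarray(self.points_moved, float))
        if self.points_fixed.shape != self.points_moved.shape:
            raise ValidationError("fixed and moved point counts must match")
        if self.points_fixed.shape[1] != 2:
            raise ValidationError("points must be (row, col) pairs")
        if self.pixel_spacing_mm <= 0:
            raise ValidationError("pixel_spacing_mm must be positive")
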