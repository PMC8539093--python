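"""Preprocessing: both modalities down to registration-ready 64x64 images.

Histology RGB scans become binary tissue masks (the *fixed* image):
saturation-channel thresholding, symmetric zero-padding to a square, and a
nearest-neighbour resize to 64x64.

DESI spectrum cubes become grayscale tissue-contour images (the *moving*
image): lock-mass calibration, total-ion-current normalisation, per-pixel
PCA to 3 components, automatic selection and orientation of the component
that best separates tissue from background, intensity capping at 1, then
the same pad-and-resize step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.transform import resize
from sklearn.decomposition import PCA

from .types import (
    IMAGE_SIZE,
    DegeneratePCAError,
    SpectrumCube,
    ValidationError,
)

log = logging.getLogger("massreg")


@dataclass
class PreprocessParams:
    """Knobs of the preprocessing pipeline.

    histology_threshold : "auto" (Otsu on the saturation channel) or a fixed
        threshold in [0, 1]
    pca_components      : number of principal components kept (default 3)
    pca_component_choice: "auto" (maximal Otsu between-class variance) or an
        explicit component index
    invert              : "auto" (make tissue bright) or an explicit bool
    lockmass_reference_mz / lockmass_window_da : internal-standard mass and
        the half-width of the search window around it
    """

    histology_threshold: str | float = "auto"
    pca_components: int = 3
    pca_component_choice: str | int = "auto"
    invert: str | bool = "auto"
    lockmass_reference_mz: float = 556.2771  # leucine enkephalin [M-H]-
    lockmass_window_da: float = 0.5

    def __post_init__(self):
        if self.pca_components < 1:
            raise ValidationError("pca_components must be >= 1")
        if self.lockmass_window_da <= 0:
            raise ValidationError("lockmass_window_da must be positive")


def pad_to_square(img: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Zero-pad a 2D image to a square, splitting the margin symmetrically."""
    h, w = img.shape
    side = max(h, w)
    top = (side - h) // 2
    left = (side - w) // 2
    out = np.full((side, side), fill, dtype=img.dtype)
    out[top : top + h, left : left + w] = img
    return out


def _resize_to_frame(img: np.ndarray, binary: bool) -> np.ndarray:
    order = 0 if binary else 1
    out = resize(
        img.astype(np.float64),
        (IMAGE_SIZE, IMAGE_SIZE),
        order=order,
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def histology_to_mask(rgb: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Binary tissue mask (1 = stained tissue, 0 = slide background).

    The stain is separated from the white slide on the HSV saturation
    channel; the threshold is Otsu's unless overridden.  The mask is padded
    to a square before the 64x64 resize so the core keeps its aspect ratio.
    """
    params = params or PreprocessParams()
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.size == 0:
        raise ValidationError("histology input must be a non-empty H x W x 3 raster")
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    sat = rgb2hsv(rgb)[:, :, 1]
    if params.histology_threshold == "auto":
        if np.ptp(sat) < 1e-12:
            log.warning("histology image has uniform saturation; empty mask")
            return np.zeros((IMAGE_SIZE, IMAGE_SIZE))
        thr = threshold_otsu(sat)
    else:
        thr = float(params.histology_threshold)
    mask = (sat > thr).astype(np.float64)
    if mask.sum() == 0:
        log.warning("no pixel passed the histology threshold; empty mask")
        return np.zeros((IMAGE_SIZE, IMAGE_SIZE))
    mask = pad_to_square(mask)
    out = _resize_to_frame(mask, binary=True)
    return (out > 0.5).astype(np.float64)


def lock_mass_calibrate(cube: SpectrumCube, params: PreprocessParams | None = None) -> SpectrumCube:
    """Align each pixel spectrum so its reference peak sits at the lock mass.

    For every spectrum the local intensity maximum within +/- the window of
    the reference m/z defines a constant m/z shift; the shifted spectrum is
    re-binned onto the common axis by linear interpolation.  Spectra with no
    peak in the window are left untouched.
    """
    params = params or PreprocessParams()
    mz = cube.mz_axis
    ref = float(params.lockmass_reference_mz)
    if not (mz[0] <= ref <= mz[-1]):
        raise ValidationError(
            f"lock-mass reference {ref} outside the m/z axis range "
            f"[{mz[0]}, {mz[-1]}]"
        )
    lo = np.searchsorted(mz, ref - params.lockmass_window_da, side="left")
    hi = np.searchsorted(mz, ref + params.lockmass_window_da, side="right")
    H, W, C = cube.intensities.shape
    out = np.empty_like(cube.intensities)
    n_skipped = 0
    for r in range(H):
        for c in range(W):
            spec = cube.intensities[r, c]
            window = spec[lo:hi]
            if window.size == 0 or window.max() <= 0:
                out[r, c] = spec
                n_skipped += 1
                continue
            peak_mz = mz[lo + int(np.argmax(window))]
            shift = ref - peak_mz
            if shift == 0.0:
                out[r, c] = spec
                continue
            out[r, c] = np.interp(mz - shift, mz, spec, left=0.0, right=0.0)
    if n_skipped:
        log.info("lock-mass calibration: %d spectra had no peak in the window", n_skipped)
    return SpectrumCube(np.clip(out, 0.0, None), mz.copy(), cube.pixel_spacing_mm)


def tic_normalize(cube: SpectrumCube) -> SpectrumCube:
    """Divide every pixel spectrum by its total ion current.

    Nonzero spectra sum to 1 afterwards; all-zero spectra pass through.
    """
    tic = cube.intensities.sum(axis=2, keepdims=True)
    n_zero = int((tic == 0).sum())
    if n_zero:
        log.info("tic_normalize: %d empty spectra passed through", n_zero)
    safe = np.where(tic > 0, tic, 1.0)
    return SpectrumCube(
        cube.intensities / safe, cube.mz_axis.copy(), cube.pixel_spacing_mm
    )


def _otsu_between_class_variance(values: np.ndarray) -> float:
    """Between-class variance at the Otsu threshold of a flat sample."""
    if np.ptp(values) < 1e-12:
        return 0.0
    thr = threshold_otsu(values)
    lo, hi = values[values <= thr], values[values > thr]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    w0, w1 = lo.size / values.size, hi.size / values.size
    return w0 * w1 * (lo.mean() - hi.mean()) ** 2


def desi_to_contour(cube: SpectrumCube, params: PreprocessParams | None = None) -> np.ndarray:
    """Reduce a (TIC-normalised) spectrum cube to a 64x64 contour image.

    The C-channel spectrum at each pixel is projected onto 3 principal
    components; the component whose Otsu between-class variance is largest
    (i.e. the one that best splits tissue from background) is kept, oriented
    so tissue is bright, rescaled so the maximum intensity is 1, padded to a
    square and resized.  Output values lie in [0, 1] but are not binary.
    """
    params = params or PreprocessParams()
    H, W, C = cube.intensities.shape
    flat = cube.intensities.reshape(H * W, C)
    if H * W < params.pca_components:
        raise ValidationError("cube has fewer pixels than PCA components")
    if float(flat.var(axis=0).sum()) < 1e-18:
        raise DegeneratePCAError("spectrum cube has no variance: PCA is degenerate")
    n_comp = min(params.pca_components, min(flat.shape) - 1) or 1
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(flat)
    scores = scores.reshape(H, W, n_comp)

    if params.pca_component_choice == "auto":
        variances = [
            _otsu_between_class_variance(scores[:, :, k].ravel())
            for k in range(n_comp)
        ]
        k = int(np.argmax(variances))
    else:
        k = int(params.pca_component_choice)
        if not (0 <= k < n_comp):
            raise ValidationError(f"component index {k} out of range 0..{n_comp - 1}")
    comp = scores[:, :, k]

    # orient: the (smaller) tissue class must be brighter than background
    if params.invert == "auto":
        thr = threshold_otsu(comp.ravel()) if np.ptp(comp) > 0 else comp.mean()
        above = comp > thr
        minority_is_bright = above.sum() <= (~above).sum()
        invert = not minority_is_bright
    else:
        invert = bool(params.invert)
    if invert:
        comp = -comp

    comp = comp - comp.min()
    peak = comp.max()
    if peak > 0:
        comp = comp / peak  # cap the maximum intensity at 1
    # background pixels sit at the minimum only up to float round-off, and
    # downstream binarisation treats any intensity above 0 as tissue — snap
    # negligible values to exact zero
    comp[comp < 1e-6] = 0.0
    comp = pad_to_square(comp)
    return _resize_to_frame(comp, binary=False)


def preprocess_pair(
    histology_rgb: np.ndarray,
    cube: SpectrumCube,
    params: PreprocessParams | None = None,
    calibrate: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline for one sample: (fixed mask, moving contour)."""
    params = params or PreprocessParams()
    fixed = histology_to_mask(histology_rgb, params)
    if calibrate and cube.mz_axis[0] <= params.lockmass_reference_mz <= cube.mz_axis[-1]:
        cube = lock_mass_calibrate(cube, params)
    moving = desi_to_contour(tic_normalize(cube), params)
    return fixed, moving
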