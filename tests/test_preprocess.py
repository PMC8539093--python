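"""Preprocessing: histology masking and DESI contour extraction."""

import numpy as np
import pytest

from massreg.preprocess import (
    PreprocessParams,
    desi_to_contour,
    histology_to_mask,
    lock_mass_calibrate,
    pad_to_square,
    tic_normalize,
)
from massreg.types import DegeneratePCAError, SpectrumCube, ValidationError


def _hand_saturation(rgb):
    """Independent per-pixel saturation: (max - min) / max, 0 where black."""
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / mx, 0.0)
    return sat


def _hand_otsu(values, bins=256):
    """Exhaustive-threshold Otsu: maximise between-class variance."""
    edges = np.linspace(values.min(), values.max(), bins)
    best_t, best_v = edges[0], -1.0
    for t in edges[1:-1]:
        lo, hi = values[values <= t], values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestHistologyToMask:
    def test_pure_white_gives_empty_mask(self):
        rgb = np.ones((100, 80, 3))
        mask = histology_to_mask(rgb)
        assert mask.shape == (64, 64)
        assert mask.sum() == 0

    def test_pink_ellipse_matches_per_pixel_oracle(self):
        h, w = 100, 200
        rr, cc = np.mgrid[0:h, 0:w]
        inside = ((rr - 50) / 30.0) ** 2 + ((cc - 100) / 70.0) ** 2 < 1
        rgb = np.ones((h, w, 3))
        rgb[inside] = [0.85, 0.45, 0.65]
        mask = histology_to_mask(rgb)
        # oracle: hand-computed saturation, exhaustive Otsu, pad, NN-resize
        sat = _hand_saturation(rgb)
        oracle = (sat > _hand_otsu(sat.ravel())).astype(float)
        oracle = pad_to_square(oracle)
        side = oracle.shape[0]
        idx = (np.arange(64) + 0.5) * side / 64 - 0.5
        nearest = np.clip(np.round(idx).astype(int), 0, side - 1)
        oracle64 = oracle[np.ix_(nearest, nearest)]
        # resampling may disagree on a handful of boundary pixels only
        assert np.mean(mask != oracle64) < 0.01
        assert mask[32, 32] == 1 and mask[1, 1] == 0

    def test_non_square_input_yields_64x64(self):
        rgb = np.ones((37, 211, 3))
        rgb[10:20, 50:150] = [0.8, 0.3, 0.6]
        out = histology_to_mask(rgb)
        assert out.shape == (64, 64)
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_commutes_with_90_degree_rotation_for_square_input(self):
        rng = np.random.default_rng(3)
        rgb = np.ones((120, 120, 3))
        blob = rng.uniform(size=(120, 120)) > 0.9
        rgb[blob] = [0.7, 0.2, 0.5]
        a = histology_to_mask(np.rot90(rgb).copy())
        b = np.rot90(histology_to_mask(rgb))
        np.testing.assert_array_equal(a, b)

    def test_rejects_non_rgb(self):
        with pytest.raises(ValidationError):
            histology_to_mask(np.ones((10, 10)))


class TestSpectrumPipeline:
    def test_tic_uniform_spectrum(self):
        cube = SpectrumCube(np.full((1, 1, 10), 3.7), np.arange(1, 11, dtype=float))
        out = tic_normalize(cube)
        np.testing.assert_allclose(out.intensities, 0.1)

    def test_tic_zero_spectrum_passthrough(self):
        cube = SpectrumCube(np.zeros((2, 1, 4)), np.arange(1, 5, dtype=float))
        out = tic_normalize(cube)
        assert out.intensities.sum() == 0.0

    def test_tic_random_sums_to_one(self):
        rng = np.random.default_rng(0)
        cube = SpectrumCube(rng.uniform(0.1, 2.0, (3, 3, 20)),
                            np.sort(rng.uniform(100, 900, 20)))
        sums = tic_normalize(cube).intensities.sum(axis=2)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_lockmass_already_calibrated_unchanged(self):
        mz = np.arange(550.0, 560.0, 0.1)
        spec = np.zeros_like(mz)
        ref = mz[40]
        spec[40] = 5.0
        cube = SpectrumCube(spec[None, None], mz)
        out = lock_mass_calibrate(cube, PreprocessParams(lockmass_reference_mz=ref))
        np.testing.assert_allclose(out.intensities, cube.intensities)

    def test_lockmass_shifts_displaced_peak_to_reference(self):
        mz = np.arange(550.0, 560.0, 0.1)
        ref = mz[40]
        spec = np.exp(-0.5 * ((mz - (ref + 0.2)) / 0.05) ** 2)
        cube = SpectrumCube(spec[None, None], mz)
        params = PreprocessParams(lockmass_reference_mz=ref, lockmass_window_da=0.5)
        out = lock_mass_calibrate(cube, params)
        lo = np.searchsorted(mz, ref - 0.5)
        hi = np.searchsorted(mz, ref + 0.5, side="right")
        window = out.intensities[0, 0, lo:hi]
        assert mz[lo + int(np.argmax(window))] == pytest.approx(ref)

    def test_lockmass_reference_outside_axis_errors(self):
        cube = SpectrumCube(np.ones((1, 1, 5)), np.arange(100.0, 105.0))
        with pytest.raises(ValidationError):
            lock_mass_calibrate(cube, PreprocessParams(lockmass_reference_mz=999.0))


class TestDesiToContour:
    def _footprint_cube(self, flipped=False, c=8):
        rng = np.random.default_rng(4)
        h = w = 40
        rr, cc = np.mgrid[0:h, 0:w]
        inside = np.abs(rr - cc) < 5  # diagonal band
        cube = np.zeros((h, w, c))
        if flipped:
            cube[~inside, 0] = 1.0
        else:
            cube[inside, 0] = 1.0
        return SpectrumCube(cube, np.arange(1.0, c + 1)), inside

    def test_recovers_tissue_footprint(self):
        cube, inside = self._footprint_cube()
        contour = desi_to_contour(tic_normalize(cube))
        idx = (np.arange(64) + 0.5) * 40 / 64 - 0.5
        nearest = np.clip(np.round(idx).astype(int), 0, 39)
        truth = inside[np.ix_(nearest, nearest)]
        overlap = 2 * ((contour > 0.5) & truth).sum() / ((contour > 0.5).sum() + truth.sum())
        assert overlap > 0.9

    def test_contrast_sign_flip_gives_same_contour(self):
        a, _ = self._footprint_cube(flipped=False)
        b, _ = self._footprint_cube(flipped=True)
        ca = desi_to_contour(tic_normalize(a))
        cb = desi_to_contour(tic_normalize(b))
        np.testing.assert_allclose(ca, cb, atol=1e-6)

    def test_constant_cube_degenerate(self):
        cube = SpectrumCube(np.full((5, 5, 4), 2.0), np.arange(1.0, 5.0))
        with pytest.raises(DegeneratePCAError):
            desi_to_contour(cube)

    def test_invariant_to_global_intensity_scale(self):
        cube, _ = self._footprint_cube()
        scaled = SpectrumCube(cube.intensities * 37.5, cube.mz_axis)
        a = desi_to_contour(tic_normalize(cube))
        b = desi_to_contour(tic_normalize(scaled))
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_output_shape_and_range(self):
        rng = np.random.default_rng(5)
        cube = SpectrumCube(rng.uniform(size=(17, 31, 6)), np.arange(1.0, 7.0))
        out = desi_to_contour(tic_normalize(cube))
        assert out.shape == (64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0
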