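"""File I/O: spectrum cubes, raster images, labelled pair sets.

Spectrum cubes are stored either as imzML (continuous mode, via pyimzml)
or as a single-archive "matrix" container (numpy .npz holding the intensity
array, the m/z axis and the pixel spacing).  Pair sets are a directory of
PNG images plus a CSV manifest.  Every writer/reader pair round-trips
losslessly for masks and labels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .types import FormatError, LabeledPair, SpectrumCube, ValidationError

log = logging.getLogger("massreg")

MANIFEST_COLUMNS = [
    "pair_id",
    "fixed_path",
    "moving_path",
    "label",
    "registered_flag",
    "rotation_deg",
    "translation_px",
    "noise_kind",
]


# ---------------------------------------------------------------------------
# spectrum cubes
# ---------------------------------------------------------------------------


def write_spectrum_cube(path, cube: SpectrumCube, format: str = "matrix") -> None:
    path = Path(path)
    if format == "matrix":
        np.savez(
            path,
            intensities=cube.intensities,
            mz_axis=cube.mz_axis,
            pixel_spacing_mm=np.float64(cube.pixel_spacing_mm),
        )
    elif format == "imzml":
        from pyimzml.ImzMLWriter import ImzMLWriter

        H, W, _ = cube.intensities.shape
        with ImzMLWriter(str(path), mode="continuous") as writer:
            for r in range(H):
                for c in range(W):
                    # imzML coordinates are 1-based (x, y); x is the column
                    writer.addSpectrum(
                        cube.mz_axis, cube.intensities[r, c], (c + 1, r + 1)
                    )
    else:
        raise ValidationError(f"unknown cube format {format!r}")


def read_spectrum_cube(path, format: str = "matrix") -> SpectrumCube:
    """Read a spectrum cube; grid order is row-major, origin top-left."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "matrix":
        try:
            with np.load(path) as data:
                intensities = data["intensities"]
                mz_axis = data["mz_axis"]
                spacing = float(data["pixel_spacing_mm"])
        except (KeyError, OSError, ValueError) as exc:
            raise FormatError(f"not a matrix cube container: {path} ({exc})") from exc
    elif format == "imzml":
        try:
            from pyimzml.ImzMLParser import ImzMLParser

            parser = ImzMLParser(str(path))
            coords = np.asarray(parser.coordinates)
            W = int(coords[:, 0].max())
            H = int(coords[:, 1].max())
            mz_axis, first = parser.getspectrum(0)
            mz_axis = np.asarray(mz_axis, float)
            intensities = np.zeros((H, W, mz_axis.size))
            for i, (x, y, *_) in enumerate(parser.coordinates):
                mzs, ints = parser.getspectrum(i)
                intensities[y - 1, x - 1] = ints
            spacing = 0.05
        except FileNotFoundError:
            raise
        except Exception as exc:  # malformed XML / binary stream
            raise FormatError(f"unparseable imzML file: {path} ({exc})") from exc
    else:
        raise ValidationError(f"unknown cube format {format!r}")
    if np.any(intensities < 0):
        raise ValidationError(f"negative intensity in {path}")
    return SpectrumCube(intensities, mz_axis, spacing)


# ---------------------------------------------------------------------------
# raster images
# ---------------------------------------------------------------------------


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as float in [0, 1] (grayscale or RGB)."""
    arr = iio.imread(Path(path))
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def write_image(path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 8-bit PNG/TIFF."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise ValidationError("image values must lie in [0, 1]")
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# labelled pair sets
# ---------------------------------------------------------------------------


def write_pairset(out_dir, pairs: list[LabeledPair]) -> Path:
    """Write pairs as PNGs plus a CSV manifest; returns the manifest path.

    Labels are stored in the manifest at full precision (the PNGs carry the
    8-bit images only).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, pair in enumerate(pairs):
        pid = pair.pair_id or f"pair{i:05d}"
        fixed_path = f"{pid}_fixed.png"
        moving_path = f"{pid}_moving.png"
        write_image(out_dir / fixed_path, pair.fixed)
        write_image(out_dir / moving_path, pair.moving)
        rows.append(
            {
                "pair_id": pid,
                "fixed_path": fixed_path,
                "moving_path": moving_path,
                "label": repr(float(pair.label)),
                "registered_flag": pair.registered_flag,
                "rotation_deg": pair.rotation_deg,
                "translation_px": f"{pair.translation_px[0]};{pair.translation_px[1]}",
                "noise_kind": pair.noise_kind,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_pairset(path) -> list[LabeledPair]:
    """Read a pair set from a manifest CSV (or its containing directory)."""
    path = Path(path)
    manifest = path / "manifest.csv" if path.is_dir() else path
    if not manifest.exists():
        raise FileNotFoundError(manifest)
    df = pd.read_csv(manifest, dtype={"label": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    base = manifest.parent
    pairs = []
    for row in df.itertuples(index=False):
        for p in (row.fixed_path, row.moving_path):
            if not (base / p).exists():
                raise ValidationError(f"manifest references missing image file: {p}")
        tr, tc = str(row.translation_px).split(";")
        pairs.append(
            LabeledPair(
                fixed=read_image(base / row.fixed_path),
                moving=read_image(base / row.moving_path),
                label=float(row.label),
                registered_flag=int(row.registered_flag),
                rotation_deg=float(row.rotation_deg),
                translation_px=(int(tr), int(tc)),
                noise_kind=str(row.noise_kind),
                pair_id=str(row.pair_id),
            )
        )
    return pairs
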