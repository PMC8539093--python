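"""Synthetic training data: augmentation, misalignment, cores, noise.

This module manufactures everything the two networks train on:

* 10-fold augmentation (rotations of 0/45/90/180/270 degrees, each with and
  without mirroring, applied identically to both images of a pair);
* graded rigid misalignments with similarity labels on a linear scale
  (3 degrees -> 0.875, 10 degrees -> 0; 2 px -> 0.8, 10 px -> 0; no
  transform -> 1);
* procedurally drawn virtual biopsy cores (elongated, gently curved bands);
* three noise families (Gaussian, periodic, Perlin) that turn clean
  unimodal mask pairs into multi-modal-looking ones;
* assembly of the three simulated datasets used by the training curriculum
  (250 / 600 / 500 pairs from a 25-mask training fold).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

from .config import NoiseConfig
from .types import (
    IMAGE_SIZE,
    LabeledPair,
    MisalignmentSpec,
    NoiseSpec,
    ValidationError,
)

log = logging.getLogger("massreg")

AUGMENT_ANGLES = (0.0, 45.0, 90.0, 180.0, 270.0)


def _is_binary(img: np.ndarray) -> bool:
    return bool(np.isin(img, (0.0, 1.0)).all())


def _rotate(img: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the image centre; binary inputs stay binary."""
    if angle % 360 == 0:
        return img.copy()
    binary = _is_binary(img)
    if angle % 90 == 0:
        out = np.rot90(img, k=int(angle // 90) % 4).copy()
    else:
        out = _sk_rotate(img, angle, order=1, preserve_range=True)
        out = np.clip(out, 0.0, 1.0)
    if binary and angle % 90 != 0:
        out = (out >= 0.5).astype(np.float64)
    return out


def _translate(img: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Integer shift filling vacated pixels with zero (no wrap-around)."""
    if shift == (0, 0):
        return img.copy()
    return ndimage.shift(img, shift, order=0, cval=0.0, prefilter=False)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _refit(images: list[np.ndarray], size: int) -> list[np.ndarray]:
    """Crop/rescale rotated canvases back to `size`, keeping all foreground.

    All images share one crop window (computed on their combined foreground)
    so that a transformed pair stays aligned.
    """
    canvas = images[0].shape[0]
    fg = np.zeros_like(images[0], dtype=bool)
    for im in images:
        fg |= im > 0
    if not fg.any():
        c0 = (canvas - size) // 2
        return [im[c0 : c0 + size, c0 : c0 + size].copy() for im in images]
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    h = rows[-1] - rows[0] + 1
    w = cols[-1] - cols[0] + 1
    if h > size or w > size:  # shrink around the bounding box, 1 px margin
        from skimage.transform import resize

        scale = (size - 2) / max(h, w)
        out = []
        for im in images:
            crop = im[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
            binary = _is_binary(im)
            small = resize(
                crop,
                (max(1, round(h * scale)), max(1, round(w * scale))),
                order=1,
                anti_aliasing=False,
                preserve_range=True,
            )
            if binary:
                small = (small >= 0.5).astype(np.float64)
            frame = np.zeros((size, size))
            t = (size - small.shape[0]) // 2
            l = (size - small.shape[1]) // 2
            frame[t : t + small.shape[0], l : l + small.shape[1]] = small
            out.append(frame)
        return out
    # prefer the central window; nudge it just enough to cover the bbox
    top = (canvas - size) // 2
    left = (canvas - size) // 2
    top = min(max(top, rows[-1] + 1 - size), rows[0])
    left = min(max(left, cols[-1] + 1 - size), cols[0])
    return [im[top : top + size, left : left + size].copy() for im in images]


def _transform_group(images: list[np.ndarray], angle: float, mirror: bool) -> list[np.ndarray]:
    size = images[0].shape[0]
    out = [np.fliplr(im).copy() if mirror else im.copy() for im in images]
    if angle % 360 == 0:
        return out
    if angle % 90 == 0:
        return [_rotate(im, angle) for im in out]
    # 45-degree rotations could clip the frame corners: rotate on a larger
    # canvas, then re-fit, so the whole core stays inside the frame
    pad = int(np.ceil(size * 0.25))
    padded = [np.pad(im, pad) for im in out]
    rotated = [_rotate(im, angle) for im in padded]
    return _refit(rotated, size)


def augment(items: list) -> list:
    """Expand each input into 10 variants: 5 rotations x {plain, mirrored}.

    `items` may contain single images, (fixed, moving) tuples, or
    LabeledPair objects; both images of a pair are transformed identically
    so the pair stays matched.  Foreground is never clipped at the frame
    edge.
    """
    out = []
    for item in items:
        if isinstance(item, LabeledPair):
            group = [item.fixed, item.moving]
        elif isinstance(item, tuple):
            group = list(item)
        else:
            group = [item]
        for mirror in (False, True):
            for angle in AUGMENT_ANGLES:
                tr = _transform_group(group, angle, mirror)
                if isinstance(item, LabeledPair):
                    out.append(
                        LabeledPair(
                            fixed=tr[0],
                            moving=tr[1],
                            label=item.label,
                            registered_flag=item.registered_flag,
                            rotation_deg=item.rotation_deg,
                            translation_px=item.translation_px,
                            noise_kind=item.noise_kind,
                        )
                    )
                elif isinstance(item, tuple):
                    out.append(tuple(tr))
                else:
                    out.append(tr[0])
    return out


# ---------------------------------------------------------------------------
# misalignment and similarity labels
# ---------------------------------------------------------------------------


def similarity_label(rotation_deg: float, translation_px: tuple[int, int]) -> float:
    """Linear similarity score for a rigid misalignment.

    Rotation: 3 degrees scores 0.875, falling linearly to 0 at 10 degrees
    (an unrotated image scores 1).  Translation: the per-axis maximum t
    scores 1 - t/10, floored at 0 (so 11-12 px also score 0).  When both
    are applied the worse of the two sub-scores is taken.
    """
    r = abs(float(rotation_deg))
    s_rot = 1.0 if r == 0.0 else float(np.clip((10.0 - r) / 8.0, 0.0, 1.0))
    t = max(abs(translation_px[0]), abs(translation_px[1]))
    s_trans = float(np.clip(1.0 - t / 10.0, 0.0, 1.0))
    return min(s_rot, s_trans)


def make_misaligned_pair(mask: np.ndarray, spec: MisalignmentSpec) -> LabeledPair:
    """Rigidly perturb `mask` and label the resulting (fixed, moving) pair.

    The moving image is the mask rotated about the image centre and then
    translated; the fixed image is the original.  The label follows
    :func:`similarity_label`; registered_flag is 1 only for the identity
    transform.
    """
    if not isinstance(spec, MisalignmentSpec):
        spec = MisalignmentSpec(*spec)
    moving = _translate(_rotate(mask, spec.rotation_deg), spec.translation_px)
    r, t = spec.rotation_deg, spec.translation_px
    return LabeledPair(
        fixed=np.asarray(mask, float).copy(),
        moving=moving,
        label=similarity_label(r, t),
        registered_flag=int(r == 0 and t == (0, 0)),
        rotation_deg=float(r),
        translation_px=t,
    )


# ---------------------------------------------------------------------------
# virtual cores
# ---------------------------------------------------------------------------


def generate_virtual_core(canvas: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one synthetic biopsy core: an elongated, gently curved band.

    The core is a quadratic Bezier spine of random length (60-90% of the
    canvas), orientation and curvature, thickened to a random width (8-15%
    of the canvas).  The result is binary, 8-connected, and keeps a clear
    1-px border.
    """
    if canvas < 32:
        raise ValidationError("canvas must be at least 32 px")
    n = canvas
    length = rng.uniform(0.60, 0.90) * n
    width = rng.uniform(0.08, 0.15) * n
    theta = rng.uniform(0.0, np.pi)
    d = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-d[1], d[0]])
    centre = np.array([(n - 1) / 2.0, (n - 1) / 2.0])
    p0 = centre - 0.5 * length * d
    p1 = centre + 0.5 * length * d
    ctrl = centre + rng.uniform(-0.15, 0.15) * length * perp
    margin = width / 2.0 + 2.0
    p0, p1, ctrl = (np.clip(p, margin, n - 1 - margin) for p in (p0, p1, ctrl))
    t = np.linspace(0.0, 1.0, 4 * n)[:, None]
    spine = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1
    rr, cc = np.mgrid[0:n, 0:n]
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    d2 = ((pix[:, None, :] - spine[None, :, :]) ** 2).sum(-1).min(axis=1)
    mask = (d2 < (width / 2.0) ** 2).reshape(n, n).astype(np.float64)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = 0.0
    return mask


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


def _perlin_layer(shape: tuple[int, int], cells: int, rng: np.random.Generator) -> np.ndarray:
    """Classic 2D gradient-lattice (Perlin) noise in roughly [-1, 1]."""
    h, w = shape
    grad = rng.normal(size=(cells + 1, cells + 1, 2))
    grad /= np.linalg.norm(grad, axis=2, keepdims=True)
    ys = np.linspace(0.0, cells, h, endpoint=False)
    xs = np.linspace(0.0, cells, w, endpoint=False)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    y0 = yy.astype(int)
    x0 = xx.astype(int)
    fy = yy - y0
    fx = xx - x0

    def dot(dy, dx):
        g = grad[y0 + dy, x0 + dx]
        return g[..., 0] * (fy - dy) + g[..., 1] * (fx - dx)

    def fade(u):
        return u**3 * (u * (u * 6 - 15) + 10)

    uy, ux = fade(fy), fade(fx)
    top = dot(0, 0) * (1 - ux) + dot(0, 1) * ux
    bot = dot(1, 0) * (1 - ux) + dot(1, 1) * ux
    return np.sqrt(2.0) * (top * (1 - uy) + bot * uy)


def add_noise(img: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Add one noise family to an image; output clipped to [0, 1].

    gaussian: i.i.d. additive normal with sigma = amplitude
    periodic: additive 2D sinusoid, random orientation and phase, at the
              spec frequency (cycles per frame)
    perlin:   additive multi-octave gradient-lattice noise
    Deterministic given spec.seed; amplitude 0 returns the input unchanged.
    """
    img = np.asarray(img, dtype=np.float64)
    if spec.amplitude == 0:
        return img.copy()
    rng = np.random.default_rng(spec.seed)
    h, w = img.shape
    if spec.kind == "gaussian":
        noise = rng.normal(0.0, spec.amplitude, size=img.shape)
    elif spec.kind == "periodic":
        phi = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2 * np.pi)
        rr, cc = np.mgrid[0:h, 0:w]
        u = (np.cos(phi) * cc + np.sin(phi) * rr) / max(h, w)
        noise = spec.amplitude * np.sin(2 * np.pi * spec.frequency * u + phase)
    elif spec.kind == "perlin":
        noise = np.zeros_like(img)
        amp = 1.0
        cells = 2
        for _ in range(int(spec.octaves)):
            noise += amp * _perlin_layer(img.shape, cells, rng)
            amp *= 0.5
            cells *= 2
        noise *= spec.amplitude
    else:  # pragma: no cover - NoiseSpec already validates
        raise ValidationError(f"unknown noise kind {spec.kind!r}")
    return np.clip(img + noise, 0.0, 1.0)


def _random_noise_spec(noise: NoiseConfig, rng: np.random.Generator) -> NoiseSpec:
    kind = rng.choice(["gaussian", "periodic", "perlin"])
    seed = int(rng.integers(0, 2**31 - 1))
    if kind == "gaussian":
        return NoiseSpec("gaussian", noise.gaussian_sigma, seed=seed)
    if kind == "periodic":
        freq = rng.uniform(*noise.periodic_freq_range)
        return NoiseSpec("periodic", noise.periodic_amplitude, frequency=freq, seed=seed)
    octaves = int(rng.integers(noise.perlin_octave_range[0], noise.perlin_octave_range[1] + 1))
    return NoiseSpec("perlin", noise.perlin_amplitude, octaves=octaves, seed=seed)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def _random_misalignment(rng: np.random.Generator) -> MisalignmentSpec:
    """Uniform draw over the documented misalignment ranges.

    One of three modes is chosen uniformly: rotation only (3-10 degrees),
    translation only, or both; translations are signed integers up to 12 px
    per axis, never (0, 0) on their own.
    """
    mode = rng.integers(0, 3)
    rot = 0.0
    trans = (0, 0)
    if mode in (0, 2):
        rot = float(rng.integers(3, 11))
    if mode in (1, 2):
        while trans == (0, 0):
            trans = (int(rng.integers(-12, 13)), int(rng.integers(-12, 13)))
    return MisalignmentSpec(rot, trans)


def _aligned_pair(mask: np.ndarray) -> LabeledPair:
    return LabeledPair(
        fixed=mask.copy(), moving=mask.copy(), label=1.0, registered_flag=1
    )


def _with_noise(pair: LabeledPair, noise: NoiseConfig, rng: np.random.Generator) -> LabeledPair:
    """Moving image gets noise (emulating the noisy DESI modality)."""
    spec = _random_noise_spec(noise, rng)
    return LabeledPair(
        fixed=pair.fixed,
        moving=add_noise(pair.moving, spec),
        label=pair.label,
        registered_flag=pair.registered_flag,
        rotation_deg=pair.rotation_deg,
        translation_px=pair.translation_px,
        noise_kind=spec.kind,
    )


def build_dataset(
    which: str,
    base_masks: list[np.ndarray],
    rng: np.random.Generator,
    noise: NoiseConfig | None = None,
    n_virtual_cores: int = 10,
) -> list[LabeledPair]:
    """Assemble one of the three simulated training datasets.

    sim1: one rigidly misaligned pair per augmented mask (250 from 25).
    sim2: sim1-style misaligned pairs + aligned duplicates of the augmented
          masks + aligned virtual-core pairs (600 from 25 masks + 10 cores).
    sim3: noise-added aligned duplicates + noise-added misaligned pairs
          (500 from 25 masks); noise kind drawn uniformly per pair.
    """
    if which not in ("sim1", "sim2", "sim3"):
        raise ValidationError(f"unknown dataset {which!r}")
    noise = noise or NoiseConfig()
    if len(base_masks) != 25:
        log.warning(
            "build_dataset expects a 25-mask training fold, got %d; "
            "pair counts scale proportionally",
            len(base_masks),
        )
    augmented = augment(list(base_masks))
    misaligned = [make_misaligned_pair(m, _random_misalignment(rng)) for m in augmented]

    if which == "sim1":
        pairs = misaligned
    elif which == "sim2":
        aligned = [_aligned_pair(m) for m in augmented]
        cores = [
            generate_virtual_core(IMAGE_SIZE, rng) for _ in range(n_virtual_cores)
        ]
        core_pairs = [_aligned_pair(m) for m in augment(cores)]
        pairs = misaligned + aligned + core_pairs
    else:  # sim3
        noisy_aligned = [
            _with_noise(_aligned_pair(m), noise, rng) for m in augmented
        ]
        noisy_misaligned = [_with_noise(p, noise, rng) for p in misaligned]
        pairs = noisy_aligned + noisy_misaligned

    for i, p in enumerate(pairs):
        p.pair_id = f"{which}_{i:05d}"
    return pairs


def make_multimodal_standin(
    base_masks: list[np.ndarray],
    rng: np.random.Generator,
    noise: NoiseConfig | None = None,
) -> list[LabeledPair]:
    """Noisy-moving pairs standing in for real DESI/histology pairs.

    The real study data is unavailable, so the multi-modal fine-tuning and
    manual-registration stages can train on these instead: clean fixed
    masks against noisy (aligned-or-misaligned) moving images.
    """
    log.warning("real image pairs unavailable: using the simulated multi-modal stand-in")
    return build_dataset("sim3", base_masks, rng, noise=noise)
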