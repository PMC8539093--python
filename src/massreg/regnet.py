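"""Unsupervised deformable registration: U-Net, warping layer, losses.

The registration model is a fully convolutional encoder/decoder with skip
connections that maps a (fixed, moving) image pair to a dense deformation
field — one (d_row, d_col) displacement vector per pixel.  The moving image
is resampled through a differentiable bilinear warping layer, and training
minimises mean squared error between the fixed and moved images plus a
smoothness penalty on the spatial gradient of the field.  No ground-truth
transforms are ever used.

An affine variant (localisation CNN -> 6 transform parameters -> affine
sampling grid) trained with normalised cross-correlation and SGD is
provided for comparison.
"""

from __future__ import annotations

import logging

import numpy as np

from . import nn
from .config import RegTrainConfig
from .types import IMAGE_SIZE, LabeledPair, ValidationError

log = logging.getLogger("massreg")


def _base_grid(n: int, size: int = IMAGE_SIZE) -> np.ndarray:
    rr, cc = np.meshgrid(
        np.arange(size, dtype=np.float32),
        np.arange(size, dtype=np.float32),
        indexing="ij",
    )
    return np.broadcast_to(np.stack([rr, cc])[None], (n, 2, size, size)).copy()


# ---------------------------------------------------------------------------
# deformable model
# ---------------------------------------------------------------------------


class RegistrationNet:
    """U-Net that predicts a deformation field from a stacked image pair.

    Encoder levels are stride-2 convolutions (default filters 16/32/32/32);
    the decoder upsamples with skip connections (32/32/32/32/16/16) and a
    final zero-initialised convolution emits the 2-channel field, so the
    untrained model predicts the identity transform.
    """

    def __init__(self, config: RegTrainConfig | None = None):
        cfg = config or RegTrainConfig()
        self.config = cfg
        rng = np.random.default_rng((int(cfg.seed), 101))
        enc, dec = list(cfg.enc_filters), list(cfg.dec_filters)
        if len(dec) != len(enc) + 2:
            raise ValidationError(
                "dec_filters must have exactly two more entries than enc_filters"
            )
        self.enc_filters, self.dec_filters = enc, dec
        self.params: list[nn.Tensor] = []

        def conv_param(cin, cout):
            w = nn.he_init(rng, (cout, cin, 3, 3), fan_in=cin * 9)
            b = nn.Tensor(np.zeros(cout), requires_grad=True)
            self.params += [w, b]
            return w, b

        self._enc = []
        cin = 2
        for f in enc:
            self._enc.append(conv_param(cin, f))
            cin = f
        # decoder: conv at the bottleneck, then one conv per upsampling with
        # the matching encoder skip, then two full-resolution convs
        self._dec = []
        skips = [2] + enc[:-1]  # channels concatenated after each upsample
        cin = enc[-1]
        for i, f in enumerate(dec[: len(enc)]):
            self._dec.append(conv_param(cin, f))
            cin = f + skips[len(enc) - 1 - i]
        self._dec_full = []
        for f in dec[len(enc) :]:
            self._dec_full.append(conv_param(cin, f))
            cin = f
        wf = nn.Tensor(np.zeros((2, cin, 3, 3)), requires_grad=True)
        bf = nn.Tensor(np.zeros(2), requires_grad=True)
        self.params += [wf, bf]
        self._flow = (wf, bf)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def forward(self, fixed: nn.Tensor, moving: nn.Tensor) -> nn.Tensor:
        """(N,1,64,64) x 2 -> deformation field (N,2,64,64)."""
        x = nn.concat([fixed, moving], axis=1)
        skips = [x]
        for w, b in self._enc:
            x = nn.conv2d(x, w, b, stride=2, padding=1).leaky_relu(0.2)
            skips.append(x)
        skips.pop()  # bottleneck itself is not a skip
        for w, b in self._dec:
            x = nn.conv2d(x, w, b, stride=1, padding=1).leaky_relu(0.2)
            x = nn.concat([nn.upsample2(x), skips.pop()], axis=1)
        for w, b in self._dec_full:
            x = nn.conv2d(x, w, b, stride=1, padding=1).leaky_relu(0.2)
        wf, bf = self._flow
        return nn.conv2d(x, wf, bf, stride=1, padding=1)

    def predict_field(self, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
        """Numpy convenience: (64,64) pair -> (64,64,2) field."""
        f = nn.Tensor(fixed[None, None])
        m = nn.Tensor(moving[None, None])
        field = self.forward(f, m).data[0]
        return np.moveaxis(field, 0, -1).astype(np.float64)

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state, strict=True):
            p.data = s.astype(np.float32).copy()


# ---------------------------------------------------------------------------
# warping and losses
# ---------------------------------------------------------------------------


def warp_batch(img: nn.Tensor, field: nn.Tensor) -> nn.Tensor:
    """Differentiable warp: sample img at (position + displacement)."""
    n = img.data.shape[0]
    coords = field + nn.Tensor(_base_grid(n, img.data.shape[2]))
    return nn.bilinear_sample(img, coords)


def _bilinear_np(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Float64 bilinear sampling; positions outside the frame read zero.

    Mirrors the differentiable sampler in :mod:`massreg.nn` but keeps full
    precision, so sampling at integer positions reproduces pixel values
    exactly (the zero-field warp is the identity, not an approximation).
    """
    h, w = img.shape
    r0 = np.floor(rows).astype(np.int64)
    c0 = np.floor(cols).astype(np.int64)
    fr = rows - r0
    fc = cols - c0
    out = np.zeros_like(rows, dtype=np.float64)
    for dr, wr in ((0, 1.0 - fr), (1, fr)):
        for dc, wc in ((0, 1.0 - fc), (1, fc)):
            ri, ci = r0 + dr, c0 + dc
            valid = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
            vals = img[np.clip(ri, 0, h - 1), np.clip(ci, 0, w - 1)]
            out += wr * wc * np.where(valid, vals, 0.0)
    return out


def warp(img: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Warp a (64,64) image by a (64,64,2) displacement field.

    output(p) is the bilinear sample of img at p + field(p); positions
    outside the frame read zero.
    """
    img = np.asarray(img, float)
    field = np.asarray(field, float)
    if field.shape != img.shape + (2,):
        raise ValidationError(
            f"field shape {field.shape} does not match image {img.shape}"
        )
    rr, cc = np.meshgrid(
        np.arange(img.shape[0], dtype=np.float64),
        np.arange(img.shape[1], dtype=np.float64),
        indexing="ij",
    )
    return _bilinear_np(img, rr + field[:, :, 0], cc + field[:, :, 1])


def _smoothness(field: nn.Tensor) -> nn.Tensor:
    """Mean over pixels of the squared field gradient.

    Forward differences along rows and columns; the squared-gradient norm
    sums over the two displacement components before averaging.
    """
    dr = field[:, :, 1:, :] - field[:, :, :-1, :]
    dc = field[:, :, :, 1:] - field[:, :, :, :-1]
    return (dr**2).sum(axis=1).mean() + (dc**2).sum(axis=1).mean()


def registration_loss(fixed, moved, field, smoothness_weight: float = 0.01):
    """MSE(fixed, moved) + lambda * mean squared field gradient.

    Accepts numpy arrays (returns a float) or Tensors (returns a Tensor,
    for use inside training).
    """
    if isinstance(fixed, nn.Tensor):
        mse = ((fixed - moved) ** 2).mean()
        return mse + smoothness_weight * _smoothness(field)
    f = nn.Tensor(np.asarray(fixed, float)[None, None])
    m = nn.Tensor(np.asarray(moved, float)[None, None])
    fl = nn.Tensor(np.moveaxis(np.asarray(field, float), -1, 0)[None])
    return float(registration_loss(f, m, fl, smoothness_weight).item())


def ncc(a, b) -> float | nn.Tensor:
    """Normalised cross-correlation over the full frame, per sample.

    Returns the batch-mean NCC in [-1, 1]; identical images give 1.
    """
    tensor_mode = isinstance(a, nn.Tensor)
    if not tensor_mode:
        a = nn.Tensor(np.asarray(a, float)[None, None])
        b = nn.Tensor(np.asarray(b, float)[None, None])
    am = a - a.mean(axis=(2, 3), keepdims=True)
    bm = b - b.mean(axis=(2, 3), keepdims=True)
    num = (am * bm).sum(axis=(2, 3))
    den = ((am**2).sum(axis=(2, 3)) * (bm**2).sum(axis=(2, 3)) + 1e-8).sqrt()
    out = (num / den).mean()
    return out if tensor_mode else float(out.item())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _stack_pairs(pairs: list[LabeledPair]):
    fixed = np.stack([p.fixed for p in pairs])[:, None].astype(np.float32)
    moving = np.stack([p.moving for p in pairs])[:, None].astype(np.float32)
    return nn.Tensor(fixed), nn.Tensor(moving)


def train_registration(
    model: RegistrationNet,
    dataset: list[LabeledPair] | None,
    config: RegTrainConfig | None = None,
    stage: str = "exp1",
) -> tuple[RegistrationNet, list[float]]:
    """Train the registration model for one curriculum stage.

    Stage "exp1" (rigid-error pre-training on simulated unimodal pairs)
    runs ``epochs_exp1`` epochs; stage "exp2" (multi-modal fine-tuning)
    runs ``epochs_exp2`` more epochs on the model's existing weights.
    Returns the model and the per-epoch mean training loss.
    """
    cfg = (config or model.config).validate()
    if stage not in ("exp1", "exp2"):
        raise ValidationError(f"unknown stage {stage!r}")
    if not dataset:
        if stage == "exp2":
            raise ValidationError(
                "experiment 2 requires real multi-modal pairs; none were "
                "supplied — pass simulate.make_multimodal_standin(...) "
                "explicitly to train on the simulated stand-in"
            )
        raise ValidationError("empty training dataset")
    epochs = cfg.epochs_exp1 if stage == "exp1" else cfg.epochs_exp2
    batch = cfg.batch_exp1 if stage == "exp1" else cfg.batch_exp2
    rng = np.random.default_rng((int(cfg.seed), 7 if stage == "exp1" else 8))
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    history: list[float] = []
    n = len(dataset)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            pairs = [dataset[i] for i in order[start : start + batch]]
            fixed, moving = _stack_pairs(pairs)
            field = model.forward(fixed, moving)
            moved = warp_batch(moving, field)
            loss = registration_loss(fixed, moved, field, cfg.smoothness_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        log.info("train-reg %s epoch %d/%d loss %.5f", stage, epoch + 1, epochs, history[-1])
    return model, history


def register(model: RegistrationNet, fixed: np.ndarray, moving: np.ndarray):
    """Register one pair: returns (moved image, deformation field)."""
    field = model.predict_field(np.asarray(fixed, float), np.asarray(moving, float))
    return warp(np.asarray(moving, float), field), field


# ---------------------------------------------------------------------------
# affine variant (spatial transformer)
# ---------------------------------------------------------------------------


class AffineNet:
    """Localisation CNN predicting a 2x3 affine transform (output->input).

    The final layer is initialised to the identity transform.  Trained with
    NCC loss under plain SGD, mirroring the curriculum of the deformable
    model.
    """

    def __init__(self, config: RegTrainConfig | None = None):
        cfg = config or RegTrainConfig()
        self.config = cfg
        rng = np.random.default_rng((int(cfg.seed), 202))
        self.params: list[nn.Tensor] = []

        def conv_param(cin, cout):
            w = nn.he_init(rng, (cout, cin, 3, 3), fan_in=cin * 9)
            b = nn.Tensor(np.zeros(cout), requires_grad=True)
            self.params += [w, b]
            return w, b

        self._convs = [conv_param(2, 8), conv_param(8, 16), conv_param(16, 32)]
        flat = 32 * 8 * 8
        self._w1 = nn.glorot_init(rng, (flat, 64), flat, 64)
        self._b1 = nn.Tensor(np.zeros(64), requires_grad=True)
        self._w2 = nn.Tensor(np.zeros((64, 6)), requires_grad=True)
        self._b2 = nn.Tensor(np.array([1, 0, 0, 0, 1, 0], float), requires_grad=True)
        self.params += [self._w1, self._b1, self._w2, self._b2]

    def forward(self, fixed: nn.Tensor, moving: nn.Tensor) -> nn.Tensor:
        x = nn.concat([fixed, moving], axis=1)
        for w, b in self._convs:
            x = nn.conv2d(x, w, b, stride=2, padding=1).leaky_relu(0.2)
        x = x.reshape(x.shape[0], -1)
        x = nn.dense(x, self._w1, self._b1).leaky_relu(0.2)
        return nn.dense(x, self._w2, self._b2)  # (N, 6)

    def predict_theta(self, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
        out = self.forward(nn.Tensor(fixed[None, None]), nn.Tensor(moving[None, None]))
        return out.data[0].astype(np.float64)

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state, strict=True):
            p.data = s.astype(np.float32).copy()


def _affine_coords(theta: nn.Tensor, size: int) -> nn.Tensor:
    """Sampling positions induced by 2x3 transforms about the image centre."""
    n = theta.data.shape[0]
    c = (size - 1) / 2.0
    rr, cc = np.meshgrid(
        np.arange(size, dtype=np.float32) - c,
        np.arange(size, dtype=np.float32) - c,
        indexing="ij",
    )
    ones = np.ones_like(rr)
    basis = np.stack([rr.ravel(), cc.ravel(), ones.ravel()])  # (3, size*size)
    mat = theta.reshape(n, 2, 3)
    coords = mat @ nn.Tensor(basis)  # (N, 2, size*size)
    return coords.reshape(n, 2, size, size) + c


def affine_warp(img, theta):
    """Warp an image through the sampling grid of a 2x3 affine transform.

    theta is row-major (a, b, t_row, c, d, t_col), mapping output to input
    coordinates about the image centre; the identity is (1,0,0,0,1,0).
    Accepts numpy (returns numpy) or Tensors (differentiable).
    """
    if isinstance(img, nn.Tensor):
        coords = _affine_coords(theta, img.data.shape[2])
        bad = ~np.isfinite(coords.data)
        if bad.any():
            log.warning("affine sampling grid not finite; clamping")
            coords.data[bad] = 0.0
        return nn.bilinear_sample(img, coords)
    img = np.asarray(img, float)
    mat = np.asarray(theta, float).reshape(2, 3)
    size = img.shape[0]
    c = (size - 1) / 2.0
    rr, cc = np.meshgrid(
        np.arange(size, dtype=np.float64) - c,
        np.arange(size, dtype=np.float64) - c,
        indexing="ij",
    )
    rows = mat[0, 0] * rr + mat[0, 1] * cc + mat[0, 2] + c
    cols = mat[1, 0] * rr + mat[1, 1] * cc + mat[1, 2] + c
    return _bilinear_np(img, rows, cols)


def train_affine(
    model: AffineNet,
    dataset: list[LabeledPair] | None,
    config: RegTrainConfig | None = None,
    stage: str = "exp1",
    sgd_lr: float = 0.01,
) -> tuple[AffineNet, list[float]]:
    """Train the affine variant with NCC loss and SGD, same curriculum."""
    cfg = (config or model.config).validate()
    if stage not in ("exp1", "exp2"):
        raise ValidationError(f"unknown stage {stage!r}")
    if not dataset:
        raise ValidationError("empty training dataset")
    epochs = cfg.epochs_exp1 if stage == "exp1" else cfg.epochs_exp2
    batch = cfg.batch_exp1 if stage == "exp1" else cfg.batch_exp2
    rng = np.random.default_rng((int(cfg.seed), 9 if stage == "exp1" else 10))
    opt = nn.SGD(model.params, lr=sgd_lr)
    history: list[float] = []
    n = len(dataset)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            pairs = [dataset[i] for i in order[start : start + batch]]
            fixed, moving = _stack_pairs(pairs)
            theta = model.forward(fixed, moving)
            moved = affine_warp(moving, theta)
            loss = 1.0 - ncc(fixed, moved)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        log.info("train-affine %s epoch %d/%d loss %.5f", stage, epoch + 1, epochs, history[-1])
    return model, history
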