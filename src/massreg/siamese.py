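"""Siamese similarity network: twin encoders scoring registration quality.

Two weight-sharing convolutional branches embed the fixed and moved images;
the element-wise absolute difference of the embeddings feeds a single
sigmoid unit, so the score lies in [0, 1] (reported as a percentage) and is
symmetric under swapping the two inputs by construction.  Training follows
a three-stage curriculum (clean simulated pairs, noisy simulated pairs,
manually registered pairs or their simulated stand-in) with binary targets
— 1 for a successful registration, 0 otherwise — under binary cross-entropy
and Adam, monitored by 20-way one-shot validation trials.
"""

from __future__ import annotations

import logging

import numpy as np

from . import nn
from .config import EvalTrainConfig
from .types import IMAGE_SIZE, LabeledPair, ValidationError

log = logging.getLogger("massreg")


class SiameseNet:
    """Twin CNN branches with shared weights and an |difference| head.

    Branch: 4 conv blocks (3x3 kernels, default filters 32/64/64/128, each
    followed by 2x2 max-pooling), then a dense sigmoid embedding (default
    width 1024).  Head: element-wise absolute difference of the two branch
    embeddings into one dense sigmoid unit.
    """

    def __init__(self, config: EvalTrainConfig | None = None):
        cfg = config or EvalTrainConfig()
        self.config = cfg
        rng = np.random.default_rng((int(cfg.seed), 303))
        self.params: list[nn.Tensor] = []

        def conv_param(cin, cout):
            w = nn.he_init(rng, (cout, cin, 3, 3), fan_in=cin * 9)
            b = nn.Tensor(np.zeros(cout), requires_grad=True)
            self.params += [w, b]
            return w, b

        self._convs = []
        cin = 1
        side = IMAGE_SIZE
        for f in cfg.conv_filters:
            self._convs.append(conv_param(cin, f))
            cin = f
            side //= 2
        flat = cin * side * side
        self._we = nn.glorot_init(rng, (flat, cfg.embedding_dim), flat, cfg.embedding_dim)
        self._be = nn.Tensor(np.zeros(cfg.embedding_dim), requires_grad=True)
        self._wo = nn.glorot_init(rng, (cfg.embedding_dim, 1), cfg.embedding_dim, 1)
        self._bo = nn.Tensor(np.zeros(1), requires_grad=True)
        self.params += [self._we, self._be, self._wo, self._bo]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def embed(self, x: nn.Tensor) -> nn.Tensor:
        for w, b in self._convs:
            x = nn.maxpool2(nn.conv2d(x, w, b, stride=1, padding=1).relu())
        x = x.reshape(x.shape[0], -1)
        return nn.dense(x, self._we, self._be).sigmoid()

    def forward(self, a: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
        """Similarity scores (N, 1) in (0, 1) for two image batches."""
        diff = (self.embed(a) - self.embed(b)).abs()
        return nn.dense(diff, self._wo, self._bo).sigmoid()

    def predict_batch(self, fixed: np.ndarray, moved: np.ndarray) -> np.ndarray:
        out = self.forward(
            nn.Tensor(fixed[:, None].astype(np.float32)),
            nn.Tensor(moved[:, None].astype(np.float32)),
        )
        return out.data[:, 0].astype(np.float64)

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state, strict=True):
            p.data = s.astype(np.float32).copy()


def predict_similarity(model: SiameseNet, fixed: np.ndarray, moved: np.ndarray) -> float:
    """Similarity score in [0, 1] for one (fixed, moved) pair."""
    fixed = np.asarray(fixed, float)
    moved = np.asarray(moved, float)
    if fixed.shape != (IMAGE_SIZE, IMAGE_SIZE) or moved.shape != fixed.shape:
        raise ValidationError(
            f"expected two {IMAGE_SIZE}x{IMAGE_SIZE} images, got "
            f"{fixed.shape} and {moved.shape}"
        )
    return float(model.predict_batch(fixed[None], moved[None])[0])


# ---------------------------------------------------------------------------
# one-shot validation
# ---------------------------------------------------------------------------


def _as_scorer(model_or_scorer):
    if isinstance(model_or_scorer, SiameseNet):
        m = model_or_scorer

        def scorer_batch(fixed_stack, moved_stack):
            return m.predict_batch(fixed_stack, moved_stack)

        return scorer_batch

    f = model_or_scorer

    def scorer_batch(fixed_stack, moved_stack):
        return np.array([f(a, b) for a, b in zip(fixed_stack, moved_stack)])

    return scorer_batch


def one_shot_validate(
    model_or_scorer,
    valset: list[LabeledPair],
    k: int = 20,
    trials: int = 50,
    rng: np.random.Generator | None = None,
) -> float:
    """k-way one-shot accuracy of a scorer on a validation pair set.

    Each trial pits the true moving partner of a randomly chosen fixed
    image against k-1 moving images from other pairs; the trial succeeds
    when the true partner receives the highest score.  Ties are broken
    uniformly at random.  Returns the fraction of successful trials.
    """
    rng = rng or np.random.default_rng(0)
    if len(valset) < k:
        raise ValidationError(
            f"one-shot validation needs at least k={k} candidate pairs, "
            f"got {len(valset)}"
        )
    scorer = _as_scorer(model_or_scorer)
    # anchors must have a genuinely registered partner when any exists
    anchor_pool = [i for i, p in enumerate(valset) if p.registered_flag == 1]
    if not anchor_pool:
        anchor_pool = list(range(len(valset)))
    wins = 0
    for _ in range(trials):
        a = int(rng.choice(anchor_pool))
        others = np.setdiff1d(np.arange(len(valset)), [a])
        idx = np.concatenate([[a], rng.choice(others, size=k - 1, replace=False)])
        anchor = valset[a]
        candidates = [valset[i].moving for i in idx]  # index 0 is the partner
        fixed_stack = np.stack([anchor.fixed] * k)
        scores = np.asarray(scorer(fixed_stack, np.stack(candidates)))
        best = np.flatnonzero(scores == scores.max())
        if rng.choice(best) == 0:
            wins += 1
    return wins / trials


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _bce(pred: nn.Tensor, target: np.ndarray) -> nn.Tensor:
    t = nn.Tensor(target.astype(np.float32))
    eps = 1e-7
    p = pred.clip(eps, 1.0 - eps)
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def split_train_val(
    dataset: list[LabeledPair], val_fraction: float, rng: np.random.Generator
):
    """Deterministic (per rng) 70/30-style split of a stage dataset."""
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(val_fraction * len(dataset))))
    val = [dataset[i] for i in order[:n_val]]
    train = [dataset[i] for i in order[n_val:]]
    return train, val


def train_siamese(
    model: SiameseNet,
    stage: str,
    dataset: list[LabeledPair] | None,
    config: EvalTrainConfig | None = None,
) -> tuple[SiameseNet, dict]:
    """Train the similarity network for one curriculum stage.

    Targets are binary: registered pairs (registered_flag 1) are labelled
    1, misaligned pairs 0.  Each epoch draws one batch from the training
    split; one-shot accuracy on the validation split is recorded every
    ``one_shot_interval`` epochs and at the end.  Weights are carried in
    the supplied model across stages.
    """
    cfg = (config or model.config).validate()
    stages = ("exp3", "exp4", "exp5")
    if stage not in stages:
        raise ValidationError(f"unknown stage {stage!r}")
    if not dataset:
        if stage == "exp5":
            raise ValidationError(
                "experiment 5 requires manually registered real pairs; none "
                "were supplied — pass simulate.make_multimodal_standin(...) "
                "explicitly to train on the simulated stand-in"
            )
        raise ValidationError("empty training dataset")
    salt = 20 + stages.index(stage)
    rng = np.random.default_rng((int(cfg.seed), salt))
    train, val = split_train_val(dataset, cfg.val_fraction, rng)
    fixed_all = np.stack([p.fixed for p in train])[:, None].astype(np.float32)
    moving_all = np.stack([p.moving for p in train])[:, None].astype(np.float32)
    targets = np.array([[float(p.registered_flag)] for p in train], np.float32)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    bce_history: list[float] = []
    one_shot_history: list[tuple[int, float]] = []
    k = min(cfg.one_shot_k, len(val))
    for epoch in range(1, cfg.epochs_per_stage + 1):
        idx = rng.choice(len(train), size=min(cfg.batch, len(train)), replace=False)
        pred = model.forward(
            nn.Tensor(fixed_all[idx]), nn.Tensor(moving_all[idx])
        )
        loss = _bce(pred, targets[idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
        bce_history.append(loss.item())
        if epoch % cfg.one_shot_interval == 0 or epoch == cfg.epochs_per_stage:
            acc = one_shot_validate(
                model, val, k=k, trials=cfg.one_shot_trials,
                rng=np.random.default_rng((int(cfg.seed), salt, epoch)),
            )
            one_shot_history.append((epoch, acc))
            log.info(
                "train-eval %s epoch %d/%d bce %.4f one-shot %.2f",
                stage, epoch, cfg.epochs_per_stage, loss.item(), acc,
            )
    return model, {"bce": bce_history, "one_shot": one_shot_history}
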