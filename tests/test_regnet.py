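"""Registration network, warping layer, losses, affine variant."""

import numpy as np
import pytest

from massreg import nn
from massreg.config import RegTrainConfig
from massreg.regnet import (
    AffineNet,
    RegistrationNet,
    affine_warp,
    ncc,
    register,
    registration_loss,
    train_affine,
    train_registration,
    warp,
)
from massreg.simulate import generate_virtual_core, make_misaligned_pair
from massreg.types import MisalignmentSpec, ValidationError


def _pairs(n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        core = generate_virtual_core(64, rng)
        spec = MisalignmentSpec(float(rng.integers(3, 11)), (0, 0))
        out.append(make_misaligned_pair(core, spec))
    return out


class TestModel:
    def test_field_shape_contract(self):
        model = RegistrationNet()
        rng = np.random.default_rng(0)
        field = model.predict_field(
            rng.uniform(size=(64, 64)), rng.uniform(size=(64, 64))
        )
        assert field.shape == (64, 64, 2)
        assert np.isfinite(field).all()

    def test_zero_initialised_head_gives_zero_field(self):
        model = RegistrationNet()
        rng = np.random.default_rng(1)
        field = model.predict_field(
            rng.uniform(size=(64, 64)), rng.uniform(size=(64, 64))
        )
        assert np.all(field == 0.0)

    def test_parameter_count_matches_layer_by_layer_oracle(self):
        enc = [16, 32, 32, 32]
        dec = [32, 32, 32, 32, 16, 16]
        expected = 0
        cin = 2
        for f in enc:  # stride-2 encoder convs
            expected += f * cin * 9 + f
            cin = f
        skips = [2] + enc[:-1]
        cin = enc[-1]
        for i, f in enumerate(dec[:4]):  # decoder convs with skip concats
            expected += f * cin * 9 + f
            cin = f + skips[3 - i]
        for f in dec[4:]:  # full-resolution convs
            expected += f * cin * 9 + f
            cin = f
        expected += 2 * cin * 9 + 2  # flow head
        assert RegistrationNet().n_parameters() == expected

    def test_same_seed_same_init(self):
        a = RegistrationNet(RegTrainConfig(seed=5))
        b = RegistrationNet(RegTrainConfig(seed=5))
        for p, q in zip(a.params, b.params):
            np.testing.assert_array_equal(p.data, q.data)


class TestWarp:
    def test_zero_field_is_identity(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(size=(64, 64))
        np.testing.assert_array_equal(warp(img, np.zeros((64, 64, 2))), img)

    def test_unit_column_field_equals_integer_roll_interior(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(size=(64, 64))
        field = np.zeros((64, 64, 2))
        field[:, :, 1] = 1.0  # sample one column to the right
        out = warp(img, field)
        rolled = np.roll(img, -1, axis=1)
        np.testing.assert_allclose(out[:, :-1], rolled[:, :-1], atol=1e-6)

    def test_field_outside_frame_reads_zero(self):
        img = np.ones((64, 64))
        field = np.full((64, 64, 2), 500.0)
        assert warp(img, field).sum() == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            warp(np.ones((64, 64)), np.zeros((32, 32, 2)))


class TestRegistrationLoss:
    def test_perfect_alignment_zero_field_gives_zero(self):
        img = np.random.default_rng(4).uniform(size=(64, 64))
        assert registration_loss(img, img, np.zeros((64, 64, 2))) == 0.0

    def test_zero_field_reduces_to_plain_mse(self):
        rng = np.random.default_rng(5)
        a, b = rng.uniform(size=(64, 64)), rng.uniform(size=(64, 64))
        loss = registration_loss(a, b, np.zeros((64, 64, 2)), 0.5)
        assert loss == pytest.approx(np.mean((a - b) ** 2), rel=1e-5)

    def test_smoothness_matches_loop_oracle(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(size=(64, 64))
        field = np.zeros((64, 64, 2))
        field[:, :, 0] = np.linspace(0, 3, 64)[:, None]  # linear ramp in rows
        field[:, :, 1] = rng.uniform(size=(64, 64))
        loss = registration_loss(img, img, field, smoothness_weight=1.0)
        # brute-force forward differences, averaged per difference array
        acc = 0.0
        for comp in range(2):
            dr = [
                (field[i + 1, j, comp] - field[i, j, comp]) ** 2
                for i in range(63)
                for j in range(64)
            ]
            dc = [
                (field[i, j + 1, comp] - field[i, j, comp]) ** 2
                for i in range(64)
                for j in range(63)
            ]
            acc += np.mean(dr) + np.mean(dc)
        assert loss == pytest.approx(acc, rel=1e-4)

    def test_loss_nonnegative(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            loss = registration_loss(
                rng.uniform(size=(64, 64)),
                rng.uniform(size=(64, 64)),
                rng.normal(size=(64, 64, 2)),
            )
            assert loss >= 0.0


class TestTraining:
    def test_loss_decreases_on_small_run(self):
        cfg = RegTrainConfig(epochs_exp1=3, seed=0)
        model = RegistrationNet(cfg)
        model, history = train_registration(model, _pairs(22), cfg, "exp1")
        assert history[-1] < history[0]

    def test_training_is_bit_reproducible(self):
        results = []
        for _ in range(2):
            cfg = RegTrainConfig(epochs_exp1=1, seed=3)
            model = RegistrationNet(cfg)
            model, history = train_registration(model, _pairs(11, seed=1), cfg, "exp1")
            results.append((history[0], sum(float(p.data.sum()) for p in model.params)))
        assert results[0] == results[1]

    def test_exp2_without_data_requires_explicit_standin(self):
        model = RegistrationNet(RegTrainConfig(seed=0))
        with pytest.raises(ValidationError, match="stand-in"):
            train_registration(model, None, stage="exp2")

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            train_registration(RegistrationNet(), [], stage="exp1")

    def test_register_returns_moved_and_field(self):
        model = RegistrationNet()
        pair = _pairs(1)[0]
        moved, field = register(model, pair.fixed, pair.moving)
        assert moved.shape == (64, 64) and field.shape == (64, 64, 2)


class TestAffine:
    def test_identity_theta_is_exact_identity(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(size=(64, 64))
        out = affine_warp(img, np.array([1, 0, 0, 0, 1, 0], float))
        np.testing.assert_array_equal(out, img)

    def test_pure_translation_matches_constant_field_warp(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(size=(64, 64))
        theta = np.array([1, 0, 3, 0, 1, 0], float)  # sample 3 rows down
        a = affine_warp(img, theta)
        field = np.zeros((64, 64, 2))
        field[:, :, 0] = 3.0
        b = warp(img, field)
        np.testing.assert_allclose(a[:-3, :], b[:-3, :], atol=1e-5)

    def test_untrained_localizer_predicts_identity(self):
        model = AffineNet()
        rng = np.random.default_rng(10)
        theta = model.predict_theta(
            rng.uniform(size=(64, 64)), rng.uniform(size=(64, 64))
        )
        np.testing.assert_allclose(theta, [1, 0, 0, 0, 1, 0], atol=1e-6)

    def test_ncc_self_correlation_is_one(self):
        img = np.random.default_rng(11).uniform(size=(64, 64))
        assert ncc(img, img) == pytest.approx(1.0, abs=1e-4)

    def test_affine_training_reduces_ncc_loss(self):
        cfg = RegTrainConfig(epochs_exp1=3, seed=0)
        model = AffineNet(cfg)
        model, history = train_affine(model, _pairs(22, seed=2), cfg, "exp1")
        assert history[-1] < history[0]
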