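"""Data simulation: augmentation, misalignment labels, cores, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.measure import label as cc_label

from massreg.config import NoiseConfig
from massreg.simulate import (
    add_noise,
    augment,
    build_dataset,
    generate_virtual_core,
    make_misaligned_pair,
    similarity_label,
)
from massreg.types import LabeledPair, MisalignmentSpec, NoiseSpec, ValidationError


def _core(seed=0, canvas=64):
    return generate_virtual_core(canvas, np.random.default_rng(seed))


class TestAugment:
    def test_25_pairs_become_250(self):
        masks = [_core(s) for s in range(25)]
        pairs = [LabeledPair(m, m.copy(), 1.0, 1) for m in masks]
        assert len(augment(pairs)) == 250

    def test_centered_disk_is_augmentation_invariant(self):
        rr, cc = np.mgrid[0:64, 0:64]
        c = 31.5
        disk = (((rr - c) ** 2 + (cc - c) ** 2) < 20**2).astype(float)
        outputs = augment([disk])
        assert len(outputs) == 10
        for out in outputs:
            # lattice-preserving transforms are exact; 45-degree rotations
            # may flip a ring of boundary pixels during resampling
            assert np.mean(out != disk) < 0.01

    def test_lattice_augmentations_exact_for_disk(self):
        rr, cc = np.mgrid[0:64, 0:64]
        c = 31.5
        disk = (((rr - c) ** 2 + (cc - c) ** 2) < 18**2).astype(float)
        outputs = augment([disk])
        exact = [o for o in outputs if np.array_equal(o, disk)]
        assert len(exact) >= 8  # all but the two 45-degree variants

    def test_foreground_count_preserved_within_2pct(self):
        core = _core(0)
        n0 = core.sum()
        for out in augment([core]):
            assert abs(out.sum() / n0 - 1) < 0.02

    def test_pair_images_transformed_identically(self):
        core = _core(1)
        pair = LabeledPair(core, core.copy(), 1.0, 1)
        for out in augment([pair]):
            np.testing.assert_array_equal(out.fixed, out.moving)

    def test_no_foreground_lost_at_frame_edge(self):
        # a core pressed against one border must survive every augmentation
        # without being clipped (the 45-degree variants re-fit the canvas)
        core = _core(2)
        shifted = np.zeros_like(core)
        rows = np.flatnonzero(core.any(axis=1))
        shifted[: 64 - rows[0], :] = core[rows[0] :, :]
        n0 = shifted.sum()
        for out in augment([shifted]):
            assert out.sum() > 0.9 * n0


class TestSimilarityLabel:
    @pytest.mark.parametrize(
        "rot,trans,expected",
        [
            (3, (0, 0), 0.875),
            (0, (0, 2), 0.8),
            (0, (0, 0), 1.0),
            (10, (0, 0), 0.0),
            (10, (5, 5), 0.0),
            (0, (0, 10), 0.0),
            (0, (11, 0), 0.0),
        ],
    )
    def test_printed_anchor_values(self, rot, trans, expected):
        assert similarity_label(rot, trans) == pytest.approx(expected)

    def test_monotone_over_full_grid(self):
        rotations = [0] + list(range(3, 11))
        for t in range(13):
            labels = [similarity_label(r, (0, t)) for r in rotations]
            assert all(a >= b for a, b in zip(labels, labels[1:]))
        for r in rotations:
            labels = [similarity_label(r, (0, t)) for t in range(13)]
            assert all(a >= b for a, b in zip(labels, labels[1:]))

    @given(
        r=st.sampled_from([0] + list(range(3, 11))),
        tr=st.integers(-12, 12),
        tc=st.integers(-12, 12),
    )
    @settings(deadline=None, max_examples=60)
    def test_label_always_in_unit_interval(self, r, tr, tc):
        assert 0.0 <= similarity_label(r, (tr, tc)) <= 1.0


class TestMisalignedPair:
    def test_registered_flag_only_for_identity(self):
        core = _core(3)
        p = make_misaligned_pair(core, MisalignmentSpec(0, (0, 0)))
        assert p.label == 1.0 and p.registered_flag == 1
        q = make_misaligned_pair(core, MisalignmentSpec(3, (0, 0)))
        assert q.registered_flag == 0 and q.label == pytest.approx(0.875)

    def test_out_of_range_spec_rejected(self):
        with pytest.raises(ValidationError):
            MisalignmentSpec(2.0, (0, 0))
        with pytest.raises(ValidationError):
            MisalignmentSpec(11.0, (0, 0))
        with pytest.raises(ValidationError):
            MisalignmentSpec(0.0, (13, 0))

    def test_inverse_transform_recovers_mask(self):
        from massreg.simulate import _rotate, _translate

        core = _core(4)
        spec = MisalignmentSpec(7, (4, -3))
        p = make_misaligned_pair(core, spec)
        undone = _rotate(_translate(p.moving, (-4, 3)), -7)
        inter = ((undone > 0) & (core > 0)).sum()
        union = ((undone > 0) | (core > 0)).sum()
        assert inter / union > 0.95

    def test_translation_does_not_wrap(self):
        core = _core(5)
        p = make_misaligned_pair(core, MisalignmentSpec(0, (0, 12)))
        assert p.moving[:, :12].sum() == 0


class TestVirtualCore:
    @pytest.mark.parametrize("seed", range(8))
    def test_single_connected_component(self, seed):
        mask = _core(seed)
        assert cc_label(mask > 0, connectivity=2).max() == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_border_clear_and_binary(self, seed):
        mask = _core(seed)
        assert set(np.unique(mask)) <= {0.0, 1.0}
        assert mask[0].sum() == mask[-1].sum() == 0
        assert mask[:, 0].sum() == mask[:, -1].sum() == 0

    def test_ten_cores_augment_to_100_aligned_pairs(self):
        cores = [_core(s) for s in range(10)]
        pairs = [LabeledPair(m, m.copy(), 1.0, 1) for m in augment(cores)]
        assert len(pairs) == 100
        assert all(p.label == 1.0 for p in pairs)

    def test_canvas_floor(self):
        with pytest.raises(ValidationError):
            generate_virtual_core(16, np.random.default_rng(0))


class TestNoise:
    def test_zero_amplitude_is_identity(self):
        img = _core(6)
        for kind in ("gaussian", "periodic", "perlin"):
            out = add_noise(img, NoiseSpec(kind, amplitude=0.0, seed=1))
            np.testing.assert_array_equal(out, img)

    @pytest.mark.parametrize("kind", ["gaussian", "periodic", "perlin"])
    def test_deterministic_per_seed(self, kind):
        img = _core(7)
        a = add_noise(img, NoiseSpec(kind, amplitude=0.2, seed=9))
        b = add_noise(img, NoiseSpec(kind, amplitude=0.2, seed=9))
        np.testing.assert_array_equal(a, b)
        c = add_noise(img, NoiseSpec(kind, amplitude=0.2, seed=10))
        assert not np.array_equal(a, c)

    def test_gaussian_moments_match_generator(self):
        img = np.full((64, 64), 0.5)
        out = add_noise(img, NoiseSpec("gaussian", amplitude=0.1, seed=0))
        assert 0.08 < (out - img).std() < 0.12

    def test_output_clipped_to_unit_interval(self):
        img = _core(8)
        for kind in ("gaussian", "periodic", "perlin"):
            out = add_noise(img, NoiseSpec(kind, amplitude=0.8, seed=3))
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            NoiseSpec("salt_and_pepper", 0.1)


class TestBuildDataset:
    def test_sim1_count(self, sim1):
        assert len(sim1) == 250
        assert all(p.registered_flag == 0 for p in sim1)

    def test_sim2_count_and_composition(self, sim2):
        assert len(sim2) == 600
        assert sum(p.registered_flag for p in sim2) == 350  # 250 dup + 100 cores

    def test_sim3_count_and_noise(self, sim3):
        assert len(sim3) == 500
        kinds = {p.noise_kind for p in sim3}
        assert kinds <= {"gaussian", "periodic", "perlin"}
        assert len(kinds) == 3

    def test_reproducible_given_equal_seed(self, demo_fold):
        train, _ = demo_fold
        a = build_dataset("sim1", train, np.random.default_rng((0, 1)))
        b = build_dataset("sim1", train, np.random.default_rng((0, 1)))
        for p, q in zip(a, b):
            assert p.label == q.label and p.translation_px == q.translation_px
            np.testing.assert_array_equal(p.moving, q.moving)

    def test_wrong_base_count_warns_and_scales(self, caplog):
        masks = [_core(s) for s in range(5)]
        with caplog.at_level("WARNING", logger="massreg"):
            pairs = build_dataset("sim1", masks, np.random.default_rng(0))
        assert len(pairs) == 50
        assert any("25-mask" in r.message for r in caplog.records)
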