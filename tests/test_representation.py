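"""Tests for augmentation, NT-Xent, encoder training and ensemble distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abmcal.fixtures import RingTumorSpec, make_family_pair
from abmcal.imaging import SimplifiedImage
from abmcal.nn import Conv2D, Dense, Flatten, ReLU, Sequential
from abmcal.representation import (
    AugmentationPolicy,
    Encoder,
    EncoderConfig,
    EncoderEnsemble,
    augment,
    ensemble_distance,
    ensemble_distances,
    load_ensemble,
    nt_xent_loss,
    save_ensemble,
    train_encoder,
    train_ensemble,
)


def toy_images(rng, n=64, size=8, channels=2):
    return rng.random((n, size, size, channels))


class TestAugment:
    def test_identity_draw_returns_input(self, rng):
        img = rng.random((6, 6, 2))
        policy = AugmentationPolicy(p_hflip=0.0, p_vflip=0.0, rotate=False)
        assert np.array_equal(augment(img, policy, rng), img)

    def test_horizontal_flip_is_an_involution(self, rng):
        img = rng.random((6, 6, 2))
        policy = AugmentationPolicy(p_hflip=1.0, p_vflip=0.0, rotate=False)
        once = augment(img, policy, rng)
        twice = augment(once, policy, rng)
        assert not np.array_equal(once, img)
        assert np.array_equal(twice, img)

    def test_non_square_with_rotation_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(rng.random((4, 6, 1)), AugmentationPolicy(), rng)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_pixel_multiset_preserved_per_channel(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((5, 5, 3))
        out = augment(img, AugmentationPolicy(), rng)
        for c in range(3):
            assert np.array_equal(np.sort(out[:, :, c], axis=None),
                                  np.sort(img[:, :, c], axis=None))


def brute_force_nt_xent(z, tau):
    """Explicit double loop over the published formula."""
    z = np.asarray(z, float)
    n = len(z)
    u = z / np.linalg.norm(z, axis=1, keepdims=True)
    total = 0.0
    for i in range(n):
        p = i ^ 1
        num = np.exp(u[i] @ u[p] / tau)
        den = sum(np.exp(u[i] @ u[k] / tau) for k in range(n) if k != i)
        total += -np.log(num / den)
    return total / n


class TestNtXent:
    def test_hand_computed_two_pair_case(self):
        # positives identical, negatives orthogonal, tau = 0.5
        z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        tau = 0.5
        e2, e0 = np.exp(2.0), np.exp(0.0)
        expected = -np.log(e2 / (e2 + 2 * e0))
        assert nt_xent_loss(z, tau) == pytest.approx(expected, rel=1e-12)

    def test_identical_embeddings_closed_form(self):
        for N in (2, 5, 16):
            z = np.tile([0.3, -0.4], (2 * N, 1))
            assert nt_xent_loss(z, 0.7) == pytest.approx(np.log(2 * N - 1), rel=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            z = rng.normal(size=(12, 2))
            tau = float(rng.uniform(0.1, 1.0))
            assert nt_xent_loss(z, tau) == pytest.approx(brute_force_nt_xent(z, tau), abs=1e-6)

    def test_pair_permutation_symmetry(self, rng):
        z = rng.normal(size=(8, 2))
        perm = np.array([4, 5, 0, 1, 6, 7, 2, 3])  # permute pairs, keep partners adjacent
        assert nt_xent_loss(z[perm], 0.5) == pytest.approx(nt_xent_loss(z, 0.5), rel=1e-12)

    def test_scale_invariance_per_vector(self, rng):
        z = rng.normal(size=(8, 2))
        scales = rng.uniform(0.5, 3.0, size=(8, 1))
        assert nt_xent_loss(z * scales, 0.5) == pytest.approx(nt_xent_loss(z, 0.5), rel=1e-10)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            nt_xent_loss(np.ones((2, 2)), 0.5)  # N < 2
        z = rng.normal(size=(6, 2))
        z[3] = 0.0
        with pytest.raises(ValueError):
            nt_xent_loss(z, 0.5)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        z = rng.normal(size=(8, 2))
        tau = 0.5
        _, grad = nt_xent_loss(z, tau, return_grad=True)
        eps = 1e-6
        for i, j in [(0, 0), (3, 1), (7, 0)]:
            zp, zm = z.copy(), z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            num = (nt_xent_loss(zp, tau) - nt_xent_loss(zm, tau)) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestNetworkGradients:
    def test_full_network_gradient_matches_finite_differences(self, rng):
        net = Sequential([
            Conv2D(2, 3, k=3, stride=2, pad=1, rng=rng), ReLU(),
            Flatten(), Dense(3 * 4 * 4, 5, rng=rng), ReLU(), Dense(5, 2, rng=rng),
        ])
        x = rng.random((8, 8, 8, 2))
        tau = 0.5

        def loss():
            return nt_xent_loss(net.forward(x), tau)

        base_loss, dz = nt_xent_loss(net.forward(x), tau, return_grad=True)
        net.zero_grad()
        net.backward(dz)
        eps = 1e-6
        rng2 = np.random.default_rng(0)
        for p in net.params():
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            for idx in rng2.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert gflat[idx] == pytest.approx(num, rel=1e-3, abs=1e-7)


class TestTrainAndProject:
    CFG = EncoderConfig(conv_channels=(4, 8), hidden=16, batch_size=16, epochs=2, lr=1e-3)

    def test_training_is_deterministic_in_the_seed(self, rng):
        images = toy_images(rng)
        a = train_encoder(images, self.CFG, seed=1)
        b = train_encoder(images, self.CFG, seed=1)
        for wa, wb in zip(a.net.get_weights(), b.net.get_weights()):
            assert np.array_equal(wa, wb)
        c = train_encoder(images, self.CFG, seed=2)
        assert any(
            not np.array_equal(wa, wc)
            for wa, wc in zip(a.net.get_weights(), c.net.get_weights())
        )

    def test_projection_is_2d_deterministic_and_batch_transparent(self, rng):
        images = toy_images(rng)
        enc = train_encoder(images, self.CFG, seed=3)
        one = enc.project(images[0])
        assert one.shape == (2,)
        assert np.array_equal(one, enc.project(images[0]))
        batch = enc.project(images[:5])
        assert batch.shape == (5, 2)
        for i in range(5):
            assert np.allclose(batch[i], enc.project(images[i]))

    def test_shape_mismatch_rejected(self, rng):
        enc = train_encoder(toy_images(rng), self.CFG, seed=3)
        with pytest.raises(ValueError):
            enc.project(np.zeros((9, 9, 2)))

    def test_too_few_images_rejected(self, rng):
        with pytest.raises(ValueError):
            train_encoder(toy_images(rng, n=16), self.CFG, seed=0)

    def test_fixed_weight_forward_matches_manual_arithmetic(self):
        # 2x2 input, one 3x3 stride-2 conv (8 taps off the image), then dense
        enc_net = Sequential([
            Conv2D(1, 1, k=3, stride=2, pad=1, rng=np.random.default_rng(0)),
            Flatten(),
            Dense(1, 2, rng=np.random.default_rng(0)),
        ])
        conv, _, dense = enc_net.layers
        conv.W.value[:] = np.arange(9).reshape(9, 1)  # taps in (di, dj, c) order
        conv.b.value[:] = 0.5
        dense.W.value[:] = np.array([[2.0, -1.0]])
        dense.b.value[:] = np.array([0.1, 0.2])
        x = np.array([[1.0, 2.0], [3.0, 4.0]])[None, :, :, None]
        # padded image, single output pixel at stride-2 position (0,0):
        # taps (di,dj) over rows 0..2, cols 0..2 of the padded image
        padded = np.pad(x[0, :, :, 0], 1)
        acc = sum(padded[di, dj] * (di * 3 + dj) for di in range(3) for dj in range(3))
        conv_out = acc + 0.5
        expected = np.array([2.0 * conv_out + 0.1, -1.0 * conv_out + 0.2])
        enc = Encoder(net=enc_net, config=self.CFG, input_shape=(2, 2, 1))
        assert np.allclose(enc.project(x[0]), expected)

    def test_separates_two_visually_distinct_families(self):
        ring = RingTumorSpec(outer_radius=600, dead_core_radius=350, cell_spacing=30, seed=0)
        disk = RingTumorSpec(outer_radius=600, dead_core_radius=80, cell_spacing=30, seed=0)
        fam_a, fam_b = make_family_pair(ring, disk, n=24, seed=5)
        images = np.stack([im.values for im in fam_a + fam_b])
        cfg = EncoderConfig(conv_channels=(4, 8), hidden=16, batch_size=16, epochs=25, lr=1e-3)
        enc = train_encoder(images, cfg, seed=0)
        za = enc.project(images[:24])
        zb = enc.project(images[24:])
        within = np.mean([np.linalg.norm(p - q) for p in za for q in za]) + np.mean(
            [np.linalg.norm(p - q) for p in zb for q in zb]
        )
        between = 2 * np.mean([np.linalg.norm(p - q) for p in za for q in zb])
        assert within < between
        assert enc.meta["heldout_loss_final"] <= enc.meta["heldout_loss_initial"]


class StubEncoder:
    """Encoder stand-in with hand-set projections keyed by image identity."""

    input_shape = (2, 2, 1)

    def __init__(self, mapping):
        self.mapping = mapping  # bytes -> 2-vector

    def project(self, imgs):
        arr = imgs.values if isinstance(imgs, SimplifiedImage) else np.asarray(imgs)
        if arr.ndim == 3:
            return np.asarray(self.mapping[arr.tobytes()], dtype=float)
        return np.stack([np.asarray(self.mapping[a.tobytes()], dtype=float) for a in arr])


class TestEnsembleDistance:
    def test_hand_set_three_member_average(self):
        a = np.zeros((2, 2, 1))
        b = np.ones((2, 2, 1))
        members = [
            StubEncoder({a.tobytes(): (1, 0), b.tobytes(): (0, 0)}),
            StubEncoder({a.tobytes(): (0, 3), b.tobytes(): (0, 0)}),
            StubEncoder({a.tobytes(): (0, 0), b.tobytes(): (0, 0)}),
        ]
        ens = EncoderEnsemble(members=members)
        assert ensemble_distance(ens, a, b) == pytest.approx((1 + 3 + 0) / 3)

    def test_pseudo_metric_properties_and_triangle(self, rng):
        images = toy_images(rng, n=16, size=8)
        cfg = EncoderConfig(conv_channels=(4,), hidden=8, batch_size=8, epochs=1)
        ens = train_ensemble(images, cfg, n_members=3, seed=0)
        a, b, c = images[0], images[1], images[2]
        assert ensemble_distance(ens, a, a) == 0.0
        dab = ensemble_distance(ens, a, b)
        assert dab == pytest.approx(ensemble_distance(ens, b, a))
        assert dab >= 0.0
        # triangle inequality on random triples (averaged norms satisfy it)
        for _ in range(10):
            i, j, k = rng.integers(0, 16, 3)
            dij = ensemble_distance(ens, images[i], images[j])
            djk = ensemble_distance(ens, images[j], images[k])
            dik = ensemble_distance(ens, images[i], images[k])
            assert dik <= dij + djk + 1e-9

    def test_batched_distances_match_pairwise_calls(self, rng):
        images = toy_images(rng, n=16, size=8)
        cfg = EncoderConfig(conv_channels=(4,), hidden=8, batch_size=8, epochs=1)
        ens = train_ensemble(images, cfg, n_members=2, seed=1)
        target = images[0]
        batched = ensemble_distances(ens, target, images)
        for i in range(16):
            assert batched[i] == pytest.approx(ensemble_distance(ens, target, images[i]))

    def test_member_and_ensemble_rankings_correlate(self, rng):
        from scipy.stats import spearmanr

        images = toy_images(rng, n=32, size=8)
        cfg = EncoderConfig(conv_channels=(4, 8), hidden=16, batch_size=16, epochs=15)
        ens = train_ensemble(images, cfg, n_members=3, seed=2)
        target = images[0]
        full = ensemble_distances(ens, target, images[1:])
        single = ensemble_distances(EncoderEnsemble(members=ens.members[:1]), target, images[1:])
        rho = spearmanr(full, single).statistic
        assert rho > 0.0

    def test_empty_ensemble_rejected(self, rng):
        with pytest.raises(ValueError):
            ensemble_distance(EncoderEnsemble(members=[]), np.zeros((2, 2, 1)), np.zeros((2, 2, 1)))

    def test_save_load_round_trip(self, tmp_path, rng):
        images = toy_images(rng, n=16, size=8)
        cfg = EncoderConfig(conv_channels=(4,), hidden=8, batch_size=8, epochs=1)
        ens = train_ensemble(images, cfg, n_members=2, seed=4)
        save_ensemble(ens, tmp_path / "ens")
        back = load_ensemble(tmp_path / "ens")
        for m1, m2 in zip(ens.members, back.members):
            assert np.allclose(m1.project(images), m2.project(images))
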