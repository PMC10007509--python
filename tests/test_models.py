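"""Loss components, sliced-Wasserstein estimator, and the shared backbone."""

import math

import numpy as np
import pytest

from usanomaly import (
    ModelConfig,
    PriorSampler,
    ReconstructionModel,
    kld_gaussian,
    l1_loss,
    mse_loss,
    reparameterize,
    sliced_wasserstein_distance,
    swae_loss,
    vae_loss,
)


class TestReconstructionLosses:
    def test_l1_hand_value(self):
        assert l1_loss(np.array([0.0, 0.5]), np.array([0.25, 0.25])) == pytest.approx(0.5)

    def test_l1_identity_and_symmetry(self):
        x = np.random.default_rng(0).uniform(size=(8, 8))
        y = np.random.default_rng(1).uniform(size=(8, 8))
        assert l1_loss(x, x) == 0.0
        assert l1_loss(x, y) == pytest.approx(l1_loss(y, x))

    def test_l1_mean_recovers_sum(self):
        x = np.random.default_rng(0).uniform(size=(8, 8))
        y = np.random.default_rng(1).uniform(size=(8, 8))
        assert l1_loss(x, y, "mean") * x.size == pytest.approx(l1_loss(x, y))

    def test_mse_hand_value_and_bound(self):
        x, y = np.array([0.0, 1.0]), np.array([1.0, 1.0])
        assert mse_loss(x, y) == pytest.approx(0.5)
        assert mse_loss(x, y) <= np.abs(x - y).max() ** 2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            mse_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestKldGaussian:
    def test_zero_at_prior(self):
        assert kld_gaussian(np.zeros(4), np.ones(4)) == 0.0

    def test_hand_values(self):
        assert kld_gaussian(np.array([1.0]), np.array([1.0])) == pytest.approx(0.5)
        # mu=0, sigma^2=2  ->  (1 - ln 2) / 2
        assert kld_gaussian(np.array([0.0]), np.array([math.sqrt(2.0)])) == pytest.approx(
            0.5 * (1 - math.log(2)), abs=1e-12
        )

    def test_nonnegative_on_random_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            mu = rng.uniform(-2, 2, size=6)
            sigma = rng.uniform(0.5, 2, size=6)
            assert kld_gaussian(mu, sigma) >= 0.0

    def test_batched_input_gives_per_sample_values(self):
        mu = np.array([[0.0, 0.0], [1.0, 0.0]])
        sigma = np.ones((2, 2))
        np.testing.assert_allclose(kld_gaussian(mu, sigma), [0.0, 0.5])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            kld_gaussian(np.zeros(2), np.array([1.0, 0.0]))


class TestReparameterize:
    def test_degenerate_noise_returns_mu(self):
        mu = np.array([0.3, -0.7])
        z = reparameterize(mu, np.full(2, 1e-12), seed=0)
        assert np.abs(z - mu).max() < 1e-6

    def test_monte_carlo_moments(self):
        n = 10**5
        z = reparameterize(np.zeros(n), np.ones(n), seed=1)
        assert abs(z.mean()) < 3 / math.sqrt(n)
        assert abs(z.std() - 1.0) < 0.02

    def test_seeded_deterministic(self):
        mu, sigma = np.array([0.1, 0.2]), np.array([1.0, 2.0])
        np.testing.assert_array_equal(
            reparameterize(mu, sigma, seed=3), reparameterize(mu, sigma, seed=3)
        )


class TestSlicedWasserstein:
    def test_identical_sets_are_zero(self):
        a = np.random.default_rng(0).standard_normal((16, 4))
        for n_proj in (1, 10, 100):
            assert sliced_wasserstein_distance(a, a, n_proj, seed=1) == 0.0

    def test_1d_hand_value(self):
        a = np.array([[0.0], [2.0]])
        b = np.array([[1.0], [3.0]])
        assert sliced_wasserstein_distance(a, b, 10, seed=0) == pytest.approx(1.0)

    def test_symmetry_under_shared_projections(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((12, 3)), rng.standard_normal((12, 3))
        assert sliced_wasserstein_distance(a, b, 64, seed=7) == pytest.approx(
            sliced_wasserstein_distance(b, a, 64, seed=7)
        )

    def test_projection_count_shrinks_monte_carlo_error(self):
        # empirical sd over seeds should fall by ~2x from L to 4L projections
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal((20, 5)), rng.standard_normal((20, 5)) + 0.5
        est_l = [sliced_wasserstein_distance(a, b, 25, seed=s) for s in range(40)]
        est_4l = [sliced_wasserstein_distance(a, b, 100, seed=s) for s in range(40)]
        ratio = np.std(est_l) / np.std(est_4l)
        assert 1.5 < ratio < 2.5

    def test_unequal_sizes_rejected(self):
        with pytest.raises(ValueError):
            sliced_wasserstein_distance(np.zeros((3, 2)), np.zeros((4, 2)), 10, seed=0)


class TestCompositeLosses:
    def test_vae_loss_degenerate_weights(self):
        x = np.random.default_rng(0).uniform(size=(4, 4))
        xhat = np.random.default_rng(1).uniform(size=(4, 4))
        mu, sigma = np.array([0.4, -0.2]), np.array([0.9, 1.2])
        assert vae_loss(x, xhat, mu, sigma, beta=0.0) == pytest.approx(l1_loss(x, xhat))
        assert vae_loss(x, x, np.zeros(2), np.ones(2)) == 0.0

    def test_vae_loss_additivity(self):
        x = np.random.default_rng(2).uniform(size=(4, 4))
        xhat = np.random.default_rng(3).uniform(size=(4, 4))
        mu, sigma = np.array([0.4, -0.2]), np.array([0.9, 1.2])
        expected = l1_loss(x, xhat) + 2.5 * kld_gaussian(mu, sigma)
        assert vae_loss(x, xhat, mu, sigma, beta=2.5) == pytest.approx(expected, abs=1e-9)

    def test_swae_loss_additivity_and_degenerate_weight(self):
        rng = np.random.default_rng(4)
        x, xhat = rng.uniform(size=(6, 16)), rng.uniform(size=(6, 16))
        z = rng.standard_normal((6, 3))
        prior = PriorSampler(dim=3, seed=0)
        total = swae_loss(x, xhat, z, prior, lam=10.0, n_projections=40, seed=9)
        p = prior.sample(6, seed=9)
        swd = sliced_wasserstein_distance(z, p, 40, seed=10)
        assert total == pytest.approx(mse_loss(x, xhat) + 10.0 * swd, abs=1e-9)
        assert swae_loss(x, xhat, z, prior, lam=0.0, seed=9) == pytest.approx(
            mse_loss(x, xhat)
        )

    def test_swae_loss_zero_on_identity(self):
        prior = PriorSampler(dim=3, seed=0)
        z = prior.sample(6, seed=5)
        x = np.random.default_rng(6).uniform(size=(6, 16))
        assert swae_loss(x, x, z, prior, lam=10.0, seed=5) == 0.0


class TestBackbone:
    @pytest.mark.parametrize("kind", ["ae", "vae", "swae"])
    def test_encode_decode_contracts(self, kind):
        cfg = ModelConfig(kind=kind, image_size=(32, 32), in_channels=1,
                          channels=(4, 8), latent_dim=8)
        model = ReconstructionModel(cfg, seed=0)
        x = np.random.default_rng(0).uniform(size=(2, 1, 32, 32))
        if kind == "vae":
            mu, sigma = model.encode(x)
            assert mu.shape == (2, 8)
            assert np.all(sigma > 0)
            z = mu
        else:
            z = model.encode(x)
            assert z.shape == (2, 8)
        out = model.decode(z)
        assert out.shape == x.shape
        assert np.all((out > 0) & (out < 1))  # sigmoid range

    def test_encode_deterministic_and_input_sensitive(self, untrained_model):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(size=(32, 32)), rng.uniform(size=(32, 32))
        za = untrained_model.encode(a)
        np.testing.assert_array_equal(za, untrained_model.encode(a))
        assert not np.array_equal(za, untrained_model.encode(b))

    def test_decode_extreme_latents_stay_in_range(self, untrained_model):
        out = untrained_model.decode(np.full((1, 8), 5.0))
        assert np.all((out > 0) & (out < 1))
        # far outside the prior the sigmoid may saturate at float64, but
        # never leaves [0, 1]
        out = untrained_model.decode(np.full((1, 8), 50.0))
        assert np.all((out >= 0) & (out <= 1))

    def test_wrong_latent_dim_rejected(self, untrained_model):
        with pytest.raises(ValueError):
            untrained_model.decode(np.zeros((1, 5)))

    def test_wrong_image_size_rejected(self, untrained_model):
        with pytest.raises(ValueError):
            untrained_model.reconstruct(np.zeros((16, 16)))

    def test_conv_stacks_identical_across_kinds(self):
        counts = set()
        for kind in ("ae", "vae", "swae"):
            cfg = ModelConfig(kind=kind, image_size=(32, 32), in_channels=1,
                              channels=(4, 8), latent_dim=8)
            counts.add(ReconstructionModel(cfg, seed=0).conv_stack_param_count())
        assert len(counts) == 1

    def test_spatial_bottleneck_mode(self):
        cfg = ModelConfig(kind="ae", image_size=(32, 32), in_channels=1,
                          channels=(4, 8), latent_dim=8, spatial_bottleneck=True)
        model = ReconstructionModel(cfg, seed=0)
        x = np.random.default_rng(0).uniform(size=(2, 1, 32, 32))
        z = model.encode(x)
        assert z.shape == (2, 8, 8, 8)  # code keeps its spatial layout
        assert model.decode(z).shape == x.shape
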