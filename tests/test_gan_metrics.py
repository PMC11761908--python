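import numpy as np
import pytest

from dsunet.errors import InvalidInputError, ShapeError
from dsunet.gan_metrics import (GaussianStats, MiniGANConfig, adain,
                                discriminator_losses,
                                discriminator_probability, embed_images,
                                feature_matching_loss, fid_score,
                                gradient_penalty, train_mini_gan)
from dsunet.synthetic_data import (make_lesion_mask, render_modality,
                                   sample_lesion_spec)


class TestAdain:
    def test_standardizes_then_restyles(self, rng):
        x = rng.standard_normal(500) * 3 + 7
        out = adain(x, ys=2.0, yb=-1.0)
        assert out.mean() == pytest.approx(-1.0, abs=1e-9)
        assert out.std() == pytest.approx(2.0, abs=1e-6)

    def test_inverse_recovers_input(self, rng):
        x = rng.standard_normal(200) * 1.7 + 0.3
        out = adain(x, ys=x.std(), yb=x.mean())
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_constant_channel_stabilized(self):
        x = np.full(64, 3.0)
        out = adain(x, ys=1.0, yb=5.0)
        np.testing.assert_allclose(out, 5.0)

    def test_too_small_channel_rejected(self):
        with pytest.raises(InvalidInputError):
            adain(np.array([1.0]), 1.0, 0.0)


class TestDiscriminatorLosses:
    def test_zero_logits_give_log_two_per_term(self):
        l_real, l_fake, l_total = discriminator_losses(np.zeros(8), np.zeros(8))
        assert l_real == pytest.approx(np.log(2))
        assert l_fake == pytest.approx(np.log(2))
        assert l_total == pytest.approx(2 * np.log(2))

    def test_confident_real_drives_loss_to_zero(self):
        l_real, _, _ = discriminator_losses(np.full(4, 50.0), np.zeros(4))
        assert l_real == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_scalar_evaluation(self, rng):
        dr = rng.standard_normal(32) * 3
        df = rng.standard_normal(32) * 3
        l_real, l_fake, l_total = discriminator_losses(dr, df)
        sig = lambda z: 1.0 / (1.0 + np.exp(-z))
        assert l_real == pytest.approx(float(np.mean(-np.log(sig(dr)))))
        assert l_fake == pytest.approx(float(np.mean(-np.log(1 - sig(df)))))
        assert l_total == pytest.approx(l_real + l_fake)

    def test_probability_map(self):
        assert discriminator_probability(np.array([0.0]))[0] == pytest.approx(0.5)
        assert discriminator_probability(np.array([40.0]))[0] == pytest.approx(1.0)
        x = np.array([1.3, -2.1, 0.4])
        p = discriminator_probability(x)
        q = discriminator_probability(-x)
        np.testing.assert_allclose(p + q, 1.0)
        assert np.all((p > 0) & (p < 1))


class TestFeatureMatching:
    def test_identical_means_zero(self, rng):
        v = rng.standard_normal(16)
        assert feature_matching_loss(v, v) == 0.0

    def test_unit_difference(self):
        assert feature_matching_loss([1.0, 0.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_equals_sum_of_squared_differences(self, rng):
        a, b = rng.standard_normal(24), rng.standard_normal(24)
        assert feature_matching_loss(a, b) == pytest.approx(float(((a - b) ** 2).sum()))

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            feature_matching_loss(np.zeros(3), np.zeros(4))


@pytest.mark.parametrize("norms,expected", [
    (np.ones(8), 0.0),
    (np.full(8, 2.0), 1.0),
    (np.zeros(8), 1.0),
])
def test_gradient_penalty_closed_forms(norms, expected):
    assert gradient_penalty(norms) == pytest.approx(expected)


class TestFID:
    def test_identical_stats_zero(self, rng):
        X = rng.standard_normal((50, 4))
        s = GaussianStats.from_embeddings(X)
        assert fid_score(s, s) == pytest.approx(0.0, abs=1e-10)

    def test_1d_shifted_unit_gaussians(self):
        a = GaussianStats(mu=np.array([0.0]), sigma=np.array([[1.0]]), n=10)
        b = GaussianStats(mu=np.array([1.0]), sigma=np.array([[1.0]]), n=10)
        assert fid_score(a, b) == pytest.approx(1.0)

    def test_matches_scipy_sqrtm_oracle(self, rng):
        from scipy import linalg
        for _ in range(5):
            X = rng.standard_normal((200, 3)) @ rng.standard_normal((3, 3))
            Y = rng.standard_normal((200, 3)) @ rng.standard_normal((3, 3)) + 0.5
            sa = GaussianStats.from_embeddings(X)
            sb = GaussianStats.from_embeddings(Y)
            covmean = linalg.sqrtm(sa.sigma @ sb.sigma)
            if np.iscomplexobj(covmean):
                covmean = covmean.real
            diff = sa.mu - sb.mu
            ref = float(diff @ diff + np.trace(sa.sigma) + np.trace(sb.sigma)
                        - 2 * np.trace(covmean))
            assert fid_score(sa, sb) == pytest.approx(ref, abs=1e-6)

    def test_symmetry_and_translation_invariance(self, rng):
        X = rng.standard_normal((100, 5))
        Y = 2.0 * rng.standard_normal((100, 5)) + 1.0
        sa = GaussianStats.from_embeddings(X)
        sb = GaussianStats.from_embeddings(Y)
        assert fid_score(sa, sb) == pytest.approx(fid_score(sb, sa), rel=1e-9)
        shift = rng.standard_normal(5)
        sa2 = GaussianStats.from_embeddings(X + shift)
        sb2 = GaussianStats.from_embeddings(Y + shift)
        assert fid_score(sa2, sb2) == pytest.approx(fid_score(sa, sb), rel=1e-6)

    def test_dimension_mismatch_rejected(self):
        a = GaussianStats(mu=np.zeros(2), sigma=np.eye(2), n=5)
        b = GaussianStats(mu=np.zeros(3), sigma=np.eye(3), n=5)
        with pytest.raises(ShapeError):
            fid_score(a, b)


def _render_set(label, n, size, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = sample_lesion_spec(label, "USI", size, rng)
        out.append(render_modality(make_lesion_mask(spec, size), "USI", rng) / 255.0)
    return np.asarray(out)


class TestEmbedImages:
    def test_pixel_embedding_shape(self, rng):
        imgs = rng.random((5, 8, 8, 3))
        emb = embed_images(imgs)
        assert emb.shape == (5, 8 * 8 * 3)

    def test_identical_sets_identical_stats(self, rng):
        imgs = rng.random((10, 8, 8))
        s1 = GaussianStats.from_embeddings(embed_images(imgs))
        s2 = GaussianStats.from_embeddings(embed_images(imgs.copy()))
        np.testing.assert_array_equal(s1.mu, s2.mu)
        np.testing.assert_array_equal(s1.sigma, s2.sigma)

    def test_same_distribution_closer_than_cross_class(self):
        benign_a = _render_set("benign", 200, 32, seed=1)
        benign_b = _render_set("benign", 200, 32, seed=2)
        malignant = _render_set("malignant", 200, 32, seed=3)
        s_a = GaussianStats.from_embeddings(embed_images(benign_a))
        s_b = GaussianStats.from_embeddings(embed_images(benign_b))
        s_m = GaussianStats.from_embeddings(embed_images(malignant))
        assert fid_score(s_a, s_b) < fid_score(s_a, s_m)

    def test_unknown_embedding_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            embed_images(rng.random((4, 8, 8)), embedding="inception")


class TestMiniGAN:
    def test_gp_weight_gradients_match_finite_differences(self):
        from dsunet.gan_metrics import _Discriminator
        rng = np.random.default_rng(0)
        D = _Discriminator(16, MiniGANConfig(base_channels=4), rng)
        x = np.random.default_rng(1).random((3, 1, 16, 16))

        def gp_value():
            D.forward(x)
            g = D.backward(np.ones(3))
            n = np.sqrt((g ** 2).sum(axis=(1, 2, 3)) + 1e-24)
            return gradient_penalty(n), g, n

        params = D.params()
        for p in params:
            p.zero_grad()
        _, g_in, norms = gp_value()
        for p in params:
            p.zero_grad()
        u0 = (2.0 * (norms - 1.0) / (norms * 3))[:, None, None, None] * g_in
        D.gp_second_pass(u0)
        analytic = [p.grad.copy() for p in params]
        eps = 1e-6
        for p, ga in zip(params, analytic):
            idx = np.unravel_index(np.argmax(np.abs(ga)), ga.shape)
            p.value[idx] += eps
            v1, _, _ = gp_value()
            p.value[idx] -= 2 * eps
            v2, _, _ = gp_value()
            p.value[idx] += eps
            assert ga[idx] == pytest.approx((v1 - v2) / (2 * eps), rel=1e-4, abs=1e-9)

    def test_seeded_runs_identical_loss_traces(self):
        imgs = _render_set("benign", 100, 16, seed=5)
        cfg = MiniGANConfig(steps=25, batch_size=8, fid_every=25, fid_samples=50)
        b1 = train_mini_gan(imgs, cfg, seed=3)
        b2 = train_mini_gan(imgs, cfg, seed=3)
        assert b1.losses == b2.losses
        assert b1.fid_trace == b2.fid_trace

    def test_500_steps_finite_losses_and_fid_improves(self):
        imgs = _render_set("benign", 120, 32, seed=9)
        cfg = MiniGANConfig(steps=500, fid_every=250)
        bundle = train_mini_gan(imgs, cfg, seed=0)
        assert len(bundle.losses) == 500
        for rec in bundle.losses:
            assert all(np.isfinite(v) for v in rec.values())
        assert bundle.fid_trace[-1][1] < bundle.fid_trace[0][1]

    def test_too_few_images_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            train_mini_gan(rng.random((50, 16, 16)), MiniGANConfig(steps=1))
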