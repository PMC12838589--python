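"""Trilevel adaptation losses: closed forms, oracles, and dynamics."""

import numpy as np
import pytest

from damlm.autograd import Tensor
from damlm import adaptation as da


class TestDiscriminator:
    def test_zero_weights_give_half(self):
        disc = da.Discriminator(8, seed=0)
        for p in disc.parameters():
            p.data[...] = 0.0
        out = disc(Tensor(np.random.default_rng(0).normal(size=(4, 8))))
        assert np.allclose(out.data, 0.5)

    def test_output_in_open_unit_interval(self):
        disc = da.Discriminator(8, seed=1)
        g = Tensor(np.random.default_rng(1).normal(size=(16, 8)) * 5)
        out = disc(g).data
        assert np.all(out > 0) and np.all(out < 1)

    def test_gradient_finite_differences(self):
        rng = np.random.default_rng(2)
        disc = da.Discriminator(8, seed=2)
        g = Tensor(rng.normal(size=(3, 8)))
        y = np.array([0.0, 1.0, 0.0]).reshape(3, 1)

        def loss():
            return da.discriminator_loss(disc(g), y)

        loss_val = loss()
        disc.zero_grad()
        loss_val.backward()
        for p in disc.parameters():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p.data[idx]
            eps = 1e-6
            p.data[idx] = orig + eps
            lp = loss().item()
            p.data[idx] = orig - eps
            lm = loss().item()
            p.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - p.grad[idx]) / max(abs(fd), 1e-6) < 1e-5


class TestLossClosedForms:
    def test_disc_loss_symmetric_point(self):
        half = Tensor(np.array([[0.5]]))
        for y in (0.0, 1.0):
            assert da.discriminator_loss(half, np.array([[y]])).item() == \
                pytest.approx(np.log(2))

    def test_disc_loss_correct_prediction_vanishes(self):
        almost = Tensor(np.array([[1.0 - 1e-15]]))
        assert da.discriminator_loss(almost, np.array([[1.0]])).item() == \
            pytest.approx(0.0, abs=1e-9)

    def test_disc_loss_hand_value(self):
        assert da.discriminator_loss(Tensor(np.array([[0.8]])),
                                     np.array([[1.0]])).item() == \
            pytest.approx(-np.log(0.8))

    def test_confusion_loss_minimum_at_half(self):
        assert da.adversarial_confusion_loss(Tensor(np.array([[0.5]]))).item() == \
            pytest.approx(np.log(2))
        for p in (0.1, 0.3, 0.7, 0.9):
            val = da.adversarial_confusion_loss(Tensor(np.array([[p]]))).item()
            assert val > np.log(2)

    def test_confusion_loss_symmetry(self):
        for p in (0.2, 0.35, 0.6):
            a = da.adversarial_confusion_loss(Tensor(np.array([[p]]))).item()
            b = da.adversarial_confusion_loss(Tensor(np.array([[1 - p]]))).item()
            assert a == pytest.approx(b)

    def test_confusion_loss_hand_value(self):
        val = da.adversarial_confusion_loss(Tensor(np.array([[0.9]]))).item()
        assert val == pytest.approx(-0.5 * (np.log(0.9) + np.log(0.1)))

    def test_confusion_gradient_zero_at_half(self):
        y = Tensor(np.array([[0.5]]), requires_grad=True)
        da.adversarial_confusion_loss(y).backward()
        assert y.grad[0, 0] == pytest.approx(0.0, abs=1e-12)


class TestSimilarity:
    def test_self_similarity(self):
        z = Tensor(np.array([[3.0, 4.0]]))
        assert da.similarity(z, z, 0.1).item() == pytest.approx(10.0)

    def test_orthogonal(self):
        a = Tensor(np.array([[1.0, 0.0]]))
        b = Tensor(np.array([[0.0, 1.0]]))
        assert da.similarity(a, b, 0.1).item() == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel(self):
        a = Tensor(np.array([[1.0, 0.0]]))
        b = Tensor(np.array([[-2.0, 0.0]]))
        assert da.similarity(a, b, 0.5).item() == pytest.approx(-2.0)


class TestContrastive:
    def test_uniform_similarities_log_k_plus_one(self):
        """All similarities equal with 3 negatives -> ln 4."""
        # all pairwise similarities 0 via mutual orthogonality, temperature 1
        anchor = Tensor(np.eye(5)[[0]])
        positive = Tensor(np.eye(5)[[1]])
        negatives = Tensor(np.eye(5)[2:5])
        val = da.contrastive_loss_single(anchor, positive, negatives, 1.0)
        assert val.item() == pytest.approx(np.log(4))

    def test_confident_positive_limit(self):
        anchor = Tensor(np.array([[1.0, 0.0]]))
        positive = anchor
        negatives = Tensor(np.array([[0.0, 1.0]]))
        val = da.contrastive_loss_single(anchor, positive, negatives, 0.01)
        assert val.item() == pytest.approx(0.0, abs=1e-9)

    def test_hand_value_two_negatives(self):
        """s+ = 2, two negatives at 0 -> -log(e^2 / (e^2 + 2))."""
        t = 0.5
        anchor = Tensor(np.array([[1.0, 0.0]]))
        positive = anchor  # cos 1 / 0.5 = 2
        negatives = Tensor(np.array([[0.0, 1.0], [0.0, -1.0]]))
        val = da.contrastive_loss_single(anchor, positive, negatives, t)
        expected = -np.log(np.exp(2) / (np.exp(2) + 2))
        assert val.item() == pytest.approx(expected)

    def test_no_negatives_rejected(self):
        a = Tensor(np.ones((1, 4)))
        with pytest.raises(ValueError):
            da.contrastive_loss(a, a)

    def test_monotone_in_positive_similarity(self):
        """Fixed negatives, increasing anchor-positive alignment -> loss falls."""
        rng = np.random.default_rng(3)
        anchors = Tensor(rng.normal(size=(4, 8)))
        base = rng.normal(size=(4, 8))
        losses = []
        for alpha in (0.0, 0.5, 1.0):
            pos = Tensor(alpha * anchors.data + (1 - alpha) * base)
            losses.append(da.contrastive_loss(anchors, pos, 0.5,
                                              symmetric=False).item())
        assert losses[0] > losses[1] > losses[2]


def covariance_oracle(feats):
    """Explicit double-loop unbiased covariance."""
    n, c = feats.shape
    mean = feats.mean(axis=0)
    cov = np.zeros((c, c))
    for i in range(n):
        d = feats[i] - mean
        for a in range(c):
            for b in range(c):
                cov[a, b] += d[a] * d[b]
    return cov / (n - 1)


class TestCovariance:
    def test_identical_batches_zero(self):
        f = Tensor(np.random.default_rng(4).normal(size=(5, 4)))
        assert da.covariance_loss(f, f).item() == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = Tensor(rng.normal(size=(6, 4)))
        b = Tensor(rng.normal(size=(5, 4)))
        assert da.covariance_loss(a, b).item() == \
            pytest.approx(da.covariance_loss(b, a).item())

    def test_two_point_toy_equals_eight(self):
        a = Tensor(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        b = Tensor(np.array([[0.0, 1.0], [0.0, -1.0]]))
        assert da.covariance_loss(a, b).item() == pytest.approx(8.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            f = rng.normal(size=(5, 4))
            est = da.covariance(Tensor(f)).data
            assert np.allclose(est, covariance_oracle(f), atol=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            da.covariance_loss(Tensor(np.ones((1, 4))), Tensor(np.ones((3, 4))))

    def test_gradient_descent_aligns_linear_map(self):
        """Minimizing L_cov over a linear map drives the Frobenius gap
        below 1% of its initial value within 500 steps."""
        rng = np.random.default_rng(7)
        src = rng.normal(size=(64, 4))
        tgt_base = rng.normal(size=(64, 4)) @ np.diag([2.0, 0.5, 1.5, 0.8])
        W = Tensor(np.eye(4), requires_grad=True)
        init = da.covariance_loss(Tensor(src), Tensor(tgt_base)).item()
        lr = 0.01
        for _ in range(500):
            W.zero_grad()
            loss = da.covariance_loss(Tensor(src), Tensor(tgt_base) @ W)
            loss.backward()
            W.data -= lr * W.grad
        final = da.covariance_loss(Tensor(src), Tensor(tgt_base) @ W).item()
        assert final < 0.01 * init


class TestCombineAndWeights:
    def test_zero_weights(self):
        w = da.AdaptationWeights(0.0, 0.0, 0.0)
        assert da.combine_domain_losses(1.0, 1.0, 1.0, w).item() == 0.0

    def test_default_weights_unit_losses(self):
        w = da.AdaptationWeights()
        assert (w.lambda_adv, w.lambda_con, w.lambda_cov) == (0.5, 1.0, 0.1)
        assert da.combine_domain_losses(1.0, 1.0, 1.0, w).item() == \
            pytest.approx(1.6)

    def test_single_term_ablations(self):
        for zeroed, expected in (("lambda_adv", 1.1), ("lambda_con", 0.6),
                                 ("lambda_cov", 1.5)):
            w = da.AdaptationWeights(**{zeroed: 0.0})
            assert da.combine_domain_losses(1.0, 1.0, 1.0, w).item() == \
                pytest.approx(expected)

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ValueError):
            da.AdaptationWeights(temperature=0.0)


class TestAdversarialContract:
    def test_discriminator_learns_separable_domains(self):
        """Frozen encoder, linearly separable embeddings: L_disc decreases
        monotonically (in trend) over 100 steps."""
        rng = np.random.default_rng(8)
        g = np.vstack([rng.normal(-2, 0.3, size=(16, 8)),
                       rng.normal(+2, 0.3, size=(16, 8))])
        y = np.array([0.0] * 16 + [1.0] * 16).reshape(-1, 1)
        disc = da.Discriminator(8, seed=3)
        losses = []
        for _ in range(100):
            disc.zero_grad()
            loss = da.discriminator_loss(disc(Tensor(g)), y)
            loss.backward()
            for p in disc.parameters():
                p.data -= 0.05 * p.grad
            losses.append(loss.item())
        assert losses[-1] < 0.1 * losses[0]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_grl_matches_confusion_loss_updates(self):
        """The reversed-gradient path produces encoder updates equal to the
        explicit confusion loss at matched weight."""
        rng = np.random.default_rng(9)
        disc = da.Discriminator(4, seed=4)
        g1 = Tensor(rng.normal(size=(6, 4)), requires_grad=True)
        da.adversarial_confusion_loss(disc(g1)).backward()
        g2 = Tensor(g1.data.copy(), requires_grad=True)
        da.grl_encoder_loss(disc(g2)).backward()
        assert np.allclose(g1.grad, g2.grad, atol=1e-6)

    def test_alternation_moves_predictions_toward_half(self):
        """One adversarial alternation on a 2-point toy moves the mean
        domain prediction toward 1/2."""
        rng = np.random.default_rng(10)
        emb = Tensor(np.array([[-3.0, 0.0], [3.0, 0.0]]), requires_grad=True)
        disc = da.Discriminator(2, seed=5)
        y = np.array([[0.0], [1.0]])
        # train discriminator briefly so it separates the two points
        for _ in range(200):
            disc.zero_grad()
            da.discriminator_loss(disc(emb.detach()), y).backward()
            for p in disc.parameters():
                p.data -= 0.1 * p.grad
        before = abs(disc(emb).data.mean() - 0.5)
        emb.zero_grad()
        da.adversarial_confusion_loss(disc(emb)).backward()
        emb.data -= 0.5 * emb.grad
        after = abs(disc(emb).data.mean() - 0.5)
        assert after < before

    def test_discriminator_gradient_isolated_from_encoder(self):
        """Encoder embeddings detached for the discriminator step receive
        no gradient from L_disc."""
        g = Tensor(np.random.default_rng(11).normal(size=(4, 8)),
                   requires_grad=True)
        disc = da.Discriminator(8, seed=6)
        da.discriminator_loss(disc(g.detach()),
                              np.array([[0.], [1.], [0.], [1.]])).backward()
        assert g.grad is None
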