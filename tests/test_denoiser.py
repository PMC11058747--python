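"""Denoiser network, Jacobian machinery, and certification tests."""

import numpy as np
import pytest

from coil.denoiser import (
    ConvNet,
    DenoiserSpec,
    LinearQ,
    ResidualQ,
    TrainingConfig,
    certify_fne,
    denoise,
    jacobian_spectral_norm,
    load_denoiser,
    save_denoiser,
    train_denoiser,
)
from coil.fixtures import generate_training_patches
from coil.metrics import psnr
from coil.oracles import dense_spectral_norm


def _nonzero_net(depth=3, features=4, seed=1):
    net = ConvNet(depth=depth, features=features, seed=seed)
    rng = np.random.default_rng(seed + 100)
    net.convs[-1].w = 0.1 * rng.standard_normal(net.convs[-1].w.shape)
    return net


class TestConvNetCalculus:
    def test_backward_matches_finite_differences(self, rng):
        net = _nonzero_net()
        x = rng.standard_normal((2, 1, 8, 8))
        tgt = rng.standard_normal((2, 1, 8, 8))

        def loss():
            return 0.5 * np.sum((net.forward(x) - tgt) ** 2)

        g = net.forward(x) - tgt
        _, grads = net.backward(g)
        eps = 1e-6
        for li in range(net.depth):
            w = net.convs[li].w
            idx = tuple(rng.integers(0, s) for s in w.shape)
            w[idx] += eps
            lp = loss()
            w[idx] -= 2 * eps
            lm = loss()
            w[idx] += eps
            assert abs((lp - lm) / (2 * eps) - grads[li][0][idx]) < 1e-6
            b = net.convs[li].b
            j = int(rng.integers(0, b.size))
            b[j] += eps
            lp = loss()
            b[j] -= 2 * eps
            lm = loss()
            b[j] += eps
            assert abs((lp - lm) / (2 * eps) - grads[li][1][j]) < 1e-6

    def test_jvp_vjp_are_adjoint(self, rng):
        net = _nonzero_net()
        q = ResidualQ(net)
        x = rng.standard_normal((2, 1, 8, 8))
        q.prepare(x)
        t = rng.standard_normal(x.shape)
        u = rng.standard_normal(x.shape)
        lhs = np.sum(q.jvp(t) * u)
        rhs = np.sum(t * q.vjp(u))
        assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1.0)

    def test_jvp_backward_matches_finite_differences(self, rng):
        net = _nonzero_net()
        q = ResidualQ(net)
        x = rng.standard_normal((1, 1, 8, 8))
        t = rng.standard_normal(x.shape)
        c = rng.standard_normal(x.shape)
        q.prepare(x)
        q.jvp(t)
        jg = net.jvp_backward(c)  # grads of <c, jvp_net(t)>
        eps = 1e-6
        for li in range(net.depth):
            w = net.convs[li].w
            idx = tuple(rng.integers(0, s) for s in w.shape)
            w[idx] += eps
            q.prepare(x)
            vp = np.sum(c * q.jvp(t))
            w[idx] -= 2 * eps
            q.prepare(x)
            vm = np.sum(c * q.jvp(t))
            w[idx] += eps
            # d<c, Q-jvp>/dW = -d<c, net-jvp>/dW
            assert abs((vp - vm) / (2 * eps) - (-jg[li][idx])) < 1e-6


class TestJacobianSpectralNorm:
    def test_exact_on_diagonal_linear_map(self):
        q = LinearQ(np.diag([0.5, 2.0]))
        assert jacobian_spectral_norm(q, np.zeros((1, 2)), n_iters=50) == \
            pytest.approx(2.0, rel=1e-12)

    def test_exact_on_identity(self):
        q = LinearQ(np.eye(5))
        assert jacobian_spectral_norm(q, np.zeros((1, 5)), n_iters=10) == \
            pytest.approx(1.0, rel=1e-12)

    def test_matches_dense_jacobian_svd_on_tiny_net(self, rng):
        # materialize the full Jacobian column by column, take its top
        # singular value, compare with the power-method estimate
        net = _nonzero_net(depth=2, features=6, seed=3)
        q = ResidualQ(net)
        z = rng.standard_normal((8, 8))
        q.prepare(z[None, None])
        jac = np.zeros((64, 64))
        for j in range(64):
            e = np.zeros(64)
            e[j] = 1.0
            jac[:, j] = q.jvp(e.reshape(1, 1, 8, 8)).ravel()
        sv = dense_spectral_norm(jac)
        pm = jacobian_spectral_norm(q, z, n_iters=3000, seed=0)
        assert pm == pytest.approx(sv, rel=1e-4)

    def test_requires_positive_iterations(self):
        with pytest.raises(ValueError):
            jacobian_spectral_norm(LinearQ(np.eye(2)), np.zeros((1, 2)), n_iters=0)


class TestDenoiseMap:
    def test_zero_network_gives_identity_resolvent(self, rng):
        # N = 0 (zero-initialized last layer) => Q = Id => J = Id
        net = ConvNet(depth=3, features=4, seed=0)
        spec = DenoiserSpec(net=net)
        x = rng.standard_normal((12, 12))
        assert np.allclose(denoise(spec, x), x, atol=1e-12)

    def test_flat_vector_input_roundtrip(self, rng):
        net = ConvNet(depth=3, features=4, seed=0)
        spec = DenoiserSpec(net=net)
        x = rng.standard_normal(64)
        assert denoise(spec, x).shape == (64,)

    def test_nonfinite_input_raises(self):
        spec = DenoiserSpec(net=ConvNet(depth=2, features=2, seed=0))
        with pytest.raises(ValueError):
            denoise(spec, np.array([[np.nan, 0.0], [0.0, 0.0]]))

    def test_negated_identity_q_maps_to_zero(self, rng):
        # J = (x + Q(x))/2 with Q = -Id collapses everything to 0
        q = LinearQ(-np.eye(16))
        j = lambda x: 0.5 * (x + q(x))
        assert np.allclose(j(rng.standard_normal(16)), 0.0)

    def test_operator_rescaling_roundtrip(self, rng):
        net = ConvNet(depth=3, features=4, seed=0)
        spec = DenoiserSpec(net=net)  # identity map
        op = spec.as_operator((8, 8), input_range=(0.0, 1.0))
        x = rng.random(64)
        assert np.allclose(op(x), x, atol=1e-12)


class TestCertifyFne:
    def test_identity_passes(self):
        rec = certify_fne(lambda x: x, probes=200, seed=0)
        assert rec["passed"] and rec["n_failures"] == 0

    def test_expansive_map_fails_and_is_flagged(self):
        rec = certify_fne(lambda x: 2.0 * x, probes=200, seed=0)
        assert not rec["passed"]
        assert rec["n_failures"] > 0
        assert rec["worst_margin"] < 0

    def test_resolvent_of_orthogonal_q_passes(self, rng):
        # Q orthogonal (1-Lipschitz) => (Id+Q)/2 firmly nonexpansive
        qmat, _ = np.linalg.qr(rng.standard_normal((256, 256)))
        q = LinearQ(qmat)
        rec = certify_fne(lambda x: 0.5 * (x + q(x)), probes=500, seed=2,
                          patch_size=16)
        assert rec["passed"]


class TestTraining:
    @pytest.fixture(scope="class")
    def small_spec(self):
        patches = generate_training_patches(400, 16, seed=3)
        cfg = TrainingConfig(upsilon=10.0, epochs=3, patch_size=16,
                             batch_size=20, seed=3, cert_power_iters=30)
        return train_denoiser(patches, cfg)

    def test_certification_record_is_populated(self, small_spec):
        cert = small_spec.certification
        assert "holdout_max_jacobian" in cert
        # the search starts at the documented default and only grows
        assert cert["lambda_schedule"][0]["lambda"] == pytest.approx(
            TrainingConfig().lambda_reg)
        lams = [row["lambda"] for row in cert["lambda_schedule"]]
        assert all(b >= a for a, b in zip(lams, lams[1:]))

    def test_default_delta_margin(self):
        assert TrainingConfig().delta_margin == 0.05

    def test_training_improves_psnr_at_training_noise(self, small_spec):
        rng = np.random.default_rng(17)
        clean = generate_training_patches(30, 16, seed=55)
        noisy = clean + 10.0 * rng.standard_normal(clean.shape)
        den = small_spec.j_theta(noisy[:, None])[:, 0]
        assert psnr(den, clean) > psnr(noisy, clean)

    def test_j_theta_is_half_identity_plus_q(self, small_spec, rng):
        z = rng.standard_normal((1, 1, 16, 16)) * 20 + 120
        q = small_spec.q
        assert np.allclose(small_spec.j_theta(z), 0.5 * (z + q(z)), atol=1e-10)

    def test_dataset_smaller_than_batch_raises(self):
        with pytest.raises(ValueError):
            train_denoiser(np.zeros((3, 16, 16)),
                           TrainingConfig(batch_size=20, patch_size=16))

    def test_roundtrip_serialization(self, small_spec, tmp_path, rng):
        save_denoiser(small_spec, tmp_path / "spec")
        back = load_denoiser(tmp_path / "spec")
        z = rng.standard_normal((10, 10))
        assert np.allclose(back.j_theta(z), small_spec.j_theta(z), atol=1e-12)
        assert back.training_noise_sigma == small_spec.training_noise_sigma
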