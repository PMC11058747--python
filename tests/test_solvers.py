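"""Primal-dual solver tests against independent reference solutions."""

import numpy as np
import pytest

from coil.oracles import admm_constrained_l1
from coil.patterns import MeasurementModel, Measurements
from coil.sara import SaraDictionary, project_nonneg, update_weights
from coil.solvers import (
    SolverConfig,
    check_inclusion_residual,
    pnp_primal_dual,
    sara_coil,
    solve_weighted_l1,
)


def _identity_dictionary(n):
    """Dirac-only debug dictionary (levels/bases unused)."""
    return SaraDictionary(
        image_size=(1, n), levels=0, bases=["dirac"], frame_constant=1.0,
        analysis=lambda x: np.asarray(x, dtype=float).copy(),
        synthesis=lambda v: np.asarray(v, dtype=float).copy(),
    )


def _unit_weights(s):
    return update_weights(np.zeros(s), 1.0)


class TestSolveWeightedL1:
    def test_large_ball_gives_zero_solution(self, dict16, instance16):
        meas = Measurements(y=instance16.y,
                            epsilon=2 * np.linalg.norm(instance16.y))
        cfg = SolverConfig.from_norm(
            np.sqrt(instance16.model.norm_estimate ** 2 + 1),
            epsilon=meas.epsilon, max_iter=500)
        res = solve_weighted_l1(meas, instance16.model, dict16,
                                _unit_weights(dict16.n_coeffs), cfg)
        assert np.linalg.norm(res.x_hat) < 1e-8

    def test_matches_admm_reference_on_dense_instance(self, dict16, instance16):
        orc = instance16.solve_oracle(psi_dense=dict16.to_dense())
        cfg = SolverConfig.from_norm(
            np.sqrt(instance16.model.norm_estimate ** 2 + 1),
            epsilon=instance16.epsilon, max_iter=5000, rel_tol=1e-6)
        res = solve_weighted_l1(instance16.measurements, instance16.model,
                                dict16, _unit_weights(dict16.n_coeffs), cfg)
        obj = np.sum(np.abs(dict16.analysis(res.x_hat)))
        assert abs(obj - orc.objective) <= 1e-3 * orc.objective
        resid = np.linalg.norm(instance16.model.forward(res.x_hat) - instance16.y)
        assert resid <= instance16.epsilon * (1 + 1e-6)

    def test_2d_debug_case_matches_grid_search(self):
        # Phi = I, Dirac dictionary, unit weights:
        # min ||x||_1 s.t. ||x - y|| <= 0.1, x >= 0, y = (1, 0.05)
        model = MeasurementModel(matrix=np.eye(2))
        model.norm_estimate = 1.0
        y = np.array([1.0, 0.05])
        meas = Measurements(y=y, epsilon=0.1)
        d = _identity_dictionary(2)
        cfg = SolverConfig.from_norm(np.sqrt(2.0), epsilon=0.1,
                                     max_iter=20000, rel_tol=1e-10)
        res = solve_weighted_l1(meas, model, d, _unit_weights(2), cfg)
        # brute-force grid oracle
        g = np.linspace(0, 1.2, 1201)
        xx, yy_ = np.meshgrid(g, g, indexing="ij")
        feas = (xx - 1.0) ** 2 + (yy_ - 0.05) ** 2 <= 0.1 ** 2
        obj = np.where(feas, xx + yy_, np.inf)
        k = np.unravel_index(np.argmin(obj), obj.shape)
        best = np.array([xx[k], yy_[k]])
        assert np.allclose(res.x_hat, best, atol=5e-3)

    def test_step_size_violation_raises_before_iterating(self, dict16, instance16):
        cfg = SolverConfig(tau=1.0, sigma=1.0, epsilon=instance16.epsilon)
        with pytest.raises(ValueError, match="step-size"):
            solve_weighted_l1(instance16.measurements, instance16.model, dict16,
                              _unit_weights(dict16.n_coeffs), cfg)


class TestSaraCoil:
    def test_single_unweighted_pass_equals_inner_solver(self, dict16, instance16):
        cfg = SolverConfig.from_norm(
            np.sqrt(instance16.model.norm_estimate ** 2 + 1),
            epsilon=instance16.epsilon, max_iter=2000, rel_tol=1e-6)
        a = sara_coil(instance16.measurements, instance16.model, dict16,
                      n_reweights=1, cfg=cfg)
        b = solve_weighted_l1(instance16.measurements, instance16.model, dict16,
                              _unit_weights(dict16.n_coeffs), cfg)
        assert np.allclose(a.x_hat, b.x_hat, atol=1e-8)

    def test_log_sum_proxy_nonincreasing_over_reweights(self, dict16, instance16):
        cfg = SolverConfig.from_norm(
            np.sqrt(instance16.model.norm_estimate ** 2 + 1),
            epsilon=instance16.epsilon, max_iter=2000, rel_tol=1e-6)
        alpha0 = 50.0
        proxies = []
        alpha = alpha0
        res = None
        from coil.solvers import solve_weighted_l1 as inner
        weights = _unit_weights(dict16.n_coeffs)
        res = inner(instance16.measurements, instance16.model, dict16, weights, cfg)
        for _ in range(3):
            coeffs = dict16.analysis(res.x_hat)
            proxies.append(np.sum(np.log(np.abs(coeffs) + alpha)))
            weights = update_weights(coeffs, alpha)
            res = inner(instance16.measurements, instance16.model, dict16,
                        weights, cfg, x0=res.x_hat, u0=res.state.u, v0=res.state.v)
        coeffs = dict16.analysis(res.x_hat)
        proxies.append(np.sum(np.log(np.abs(coeffs) + alpha)))
        diffs = np.diff(proxies)
        assert np.all(diffs <= 1e-6 * np.abs(proxies[0]))

    def test_noiseless_orthogonal_operator_recovers_truth(self, rng):
        # M = N orthogonal Phi: the epsilon-ball around y maps to an
        # epsilon-ball around the truth, so any solution recovers x_bar.
        n = 64
        q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        model = MeasurementModel(matrix=q)
        model.norm_estimate = 1.0
        x_true = np.maximum(rng.standard_normal(n), 0)
        meas = Measurements(y=model.forward(x_true), epsilon=1e-7)
        d = _identity_dictionary(n)
        cfg = SolverConfig.from_norm(np.sqrt(2.0), epsilon=1e-7,
                                     max_iter=20000, rel_tol=1e-12)
        res = sara_coil(meas, model, d, n_reweights=2, cfg=cfg)
        assert np.linalg.norm(res.x_hat - x_true) < 1e-6 * max(1, np.linalg.norm(x_true))


class TestPnpPrimalDual:
    def test_identity_denoiser_reaches_feasibility(self, instance16):
        cfg = SolverConfig.from_norm(instance16.model.norm_estimate,
                                     epsilon=instance16.epsilon,
                                     max_iter=5000, rel_tol=1e-7)
        res = pnp_primal_dual(instance16.measurements, instance16.model,
                              lambda x: x, cfg)
        resid = np.linalg.norm(instance16.model.forward(res.x_hat) - instance16.y)
        assert resid <= instance16.epsilon * (1 + 1e-6)

    def test_nonneg_projector_denoiser(self, instance16):
        cfg = SolverConfig.from_norm(instance16.model.norm_estimate,
                                     epsilon=instance16.epsilon,
                                     max_iter=5000, rel_tol=1e-8)
        res = pnp_primal_dual(instance16.measurements, instance16.model,
                              project_nonneg, cfg)
        assert res.x_hat.min() >= 0
        assert res.constraint_violation <= instance16.epsilon * 1e-6
        assert res.fixed_point_residual < 1e-6

    def test_soft_threshold_denoiser_matches_admm_and_tau_scaling(self, instance16):
        t = 5.0
        model = instance16.model
        norm = model.norm_estimate

        def run(t_, tau_):
            cfg = SolverConfig.from_norm(norm, epsilon=instance16.epsilon,
                                         tau=tau_, max_iter=60000, rel_tol=1e-13)
            den = lambda x: np.sign(x) * np.maximum(np.abs(x) - t_, 0.0)
            return pnp_primal_dual(instance16.measurements, model, den, cfg), cfg

        tau = np.sqrt(0.99) / norm
        res, cfg = run(t, tau)
        # limit solves min (t/tau)||x||_1 s.t. ball constraint (no sign constraint)
        orc = admm_constrained_l1(model.matrix, instance16.y, instance16.epsilon,
                                  psi=None, delta=(t / cfg.tau) * np.ones(model.shape[1]),
                                  nonneg=False, tol=1e-10)
        obj = (t / cfg.tau) * np.sum(np.abs(res.x_hat))
        assert abs(obj - orc.objective) <= 1e-3 * max(orc.objective, 1e-12)
        # tau-scaling law: (2t, 2tau) gives the same minimizer, because the
        # learned/plugged regularizer enters the inclusion as tau^{-1} B
        res2, _ = run(2 * t, 2 * tau)
        diff = np.linalg.norm(res2.x_hat - res.x_hat)
        assert diff <= 1e-6 * max(1.0, np.linalg.norm(res.x_hat))

    def test_inclusion_residual_zero_at_exact_fixed_point(self, instance16):
        from coil.solvers import ReconstructionResult, SolverState

        model = instance16.model
        cfg = SolverConfig.from_norm(model.norm_estimate,
                                     epsilon=instance16.epsilon)
        x = np.zeros(model.shape[1])
        u = np.zeros(model.shape[0])
        res = ReconstructionResult(x_hat=x, converged=True, iterations=0,
                                   constraint_violation=0.0,
                                   state=SolverState(x=x, u=u))
        # denoiser that maps everything to zero has x=0, u=0 as fixed point
        assert check_inclusion_residual(res, model, lambda z: 0 * z, cfg) == 0.0

    def test_unconverged_run_has_larger_residual(self, instance16):
        den = lambda x: np.sign(x) * np.maximum(np.abs(x) - 1.0, 0.0)
        model = instance16.model

        def run(iters):
            cfg = SolverConfig.from_norm(model.norm_estimate,
                                         epsilon=instance16.epsilon,
                                         max_iter=iters, rel_tol=1e-10)
            return pnp_primal_dual(instance16.measurements, model, den, cfg)

        assert run(2).fixed_point_residual > run(3000).fixed_point_residual

    def test_divergent_iterates_raise_with_step_product(self, instance16):
        # an expansive "denoiser" blows the iteration up -> explicit error
        cfg = SolverConfig.from_norm(instance16.model.norm_estimate,
                                     epsilon=instance16.epsilon, max_iter=2000)
        with pytest.raises(FloatingPointError, match="tau\\*sigma"):
            pnp_primal_dual(instance16.measurements, instance16.model,
                            lambda x: 1e8 * x + 1e8, cfg)


def test_solver_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(tau=-1.0, sigma=1.0, epsilon=1.0)
    cfg = SolverConfig.from_norm(10.0, epsilon=1.0)
    assert cfg.tau * cfg.sigma * 100.0 < 1.0
    with pytest.raises(ValueError):
        cfg.validate_against(1000.0)
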