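"""Primal-dual solvers for constrained single-pixel image reconstruction.

Two reconstruction routes share the same Morozov (constrained) data model
``||Phi x - y|| <= epsilon``:

* ``solve_weighted_l1`` / ``sara_coil`` — the variational route: minimize
  ``||Delta Psi x||_1`` over ``x >= 0`` subject to the epsilon-ball
  constraint, solved by Condat-Vu primal-dual splitting with two dual
  blocks (wavelet coefficients and measurements).  ``sara_coil`` wraps it
  in the reweighting loop that approximates the log-sum prior.

* ``pnp_primal_dual`` — the plug-and-play route: the proximity step of the
  regularizer is replaced by a firmly nonexpansive (FNE) denoiser
  ``J = (Id + Q)/2`` with ``Q`` 1-Lipschitz.  The iteration

      x~_k    = x_k - tau Phi^T u_k
      x_{k+1} = J(x~_k)
      u~_k    = u_k + sigma Phi (2 x_{k+1} - x_k)
      u_{k+1} = u~_k - sigma proj_{B2(y,eps)}(u~_k / sigma)

  converges, for tau*sigma*||Phi||^2 < 1, to a point x_hat satisfying the
  monotone inclusion ``0 in Phi^T N_{B2(y,eps)}(Phi x_hat) + (1/tau) B(x_hat)``
  where ``B = J^{-1} - Id``.  Note the primal step size tau rescales the
  learned regularizer, so it is part of the model, not just a tuning knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .patterns import MeasurementModel, Measurements
from .sara import (
    SaraDictionary,
    WeightMatrix,
    project_l2_ball,
    project_nonneg,
    prox_weighted_l1,
    update_weights,
)

__all__ = [
    "SolverConfig",
    "SolverState",
    "ReconstructionResult",
    "solve_weighted_l1",
    "sara_coil",
    "pnp_primal_dual",
    "check_inclusion_residual",
]


@dataclass
class SolverConfig:
    """Step sizes and stopping rules for the primal-dual iterations.

    The product ``tau * sigma * L^2`` (with ``L`` the norm of the stacked
    linear operator) must stay below 1; ``from_norm`` picks
    ``tau = sigma = sqrt(safety) / L`` which saturates the bound at
    ``safety < 1``.
    """

    tau: float
    sigma: float
    epsilon: float
    max_iter: int = 5000
    rel_tol: float = 1e-5
    safety: float = 0.99
    # optional extra stopping condition: only stop once the data residual
    # is within epsilon*(1 + feas_tol); None = iterate-change test alone
    feas_tol: Optional[float] = None

    def __post_init__(self):
        if self.tau <= 0 or self.sigma <= 0:
            raise ValueError("tau and sigma must be > 0")
        if not (0 < self.safety < 1):
            raise ValueError("safety must lie in (0, 1)")

    @classmethod
    def from_norm(
        cls,
        operator_norm: float,
        epsilon: float,
        safety: float = 0.99,
        tau: Optional[float] = None,
        **kwargs,
    ) -> "SolverConfig":
        """Choose step sizes from an operator-norm estimate.

        If ``tau`` is given (it shapes the PnP solution set), sigma is set
        to ``safety / (tau * L^2)``.
        """
        L = max(operator_norm, 1e-300)
        if tau is None:
            tau = np.sqrt(safety) / L
            sigma = np.sqrt(safety) / L
        else:
            sigma = safety / (tau * L ** 2)
        return cls(tau=float(tau), sigma=float(sigma), epsilon=float(epsilon),
                   safety=float(safety), **kwargs)

    def validate_against(self, operator_norm: float) -> None:
        if self.tau * self.sigma * operator_norm ** 2 >= 1.0:
            raise ValueError(
                f"step-size condition violated: tau*sigma*||L||^2 = "
                f"{self.tau * self.sigma * operator_norm ** 2:.6g} >= 1"
            )


@dataclass
class SolverState:
    """Iterates and per-iteration diagnostics of a primal-dual run."""

    x: np.ndarray
    u: np.ndarray
    v: Optional[np.ndarray] = None
    k: int = 0
    history: dict = field(default_factory=lambda: {
        "rel_change": [], "data_residual": [], "objective": [],
    })


@dataclass
class ReconstructionResult:
    """Final reconstruction with convergence certificates."""

    x_hat: np.ndarray
    converged: bool
    iterations: int
    constraint_violation: float
    fixed_point_residual: float = float("nan")
    state: Optional[SolverState] = field(default=None, repr=False)

    def image(self, shape: tuple[int, int]) -> np.ndarray:
        return self.x_hat.reshape(shape)


def _data_residual(model: MeasurementModel, x: np.ndarray, y: np.ndarray) -> float:
    return float(np.linalg.norm(model.forward(x) - y))


def solve_weighted_l1(
    meas: Measurements,
    model: MeasurementModel,
    dictionary: SaraDictionary,
    weights: WeightMatrix,
    cfg: SolverConfig,
    x0: Optional[np.ndarray] = None,
    u0: Optional[np.ndarray] = None,
    v0: Optional[np.ndarray] = None,
) -> ReconstructionResult:
    """Condat-Vu solver for  min_{x>=0} ||Delta Psi x||_1  s.t. ||Phi x - y|| <= eps.

    Primal prox is the nonnegativity projection; the two dual blocks are
    handled through Moreau decompositions of the weighted soft-threshold
    (Psi block) and of the epsilon-ball projection (Phi block).  The
    stacked operator ``L = [Phi; Psi]`` has ``||L||^2 <= ||Phi||^2 + 1``
    since Psi is a Parseval frame.
    """
    m, n = model.shape
    s = dictionary.n_coeffs
    stacked_norm_sq = model.norm_estimate ** 2 + dictionary.frame_constant
    if cfg.tau * cfg.sigma * stacked_norm_sq >= 1.0:
        raise ValueError(
            f"step-size condition violated: tau*sigma*(||Phi||^2 + 1) = "
            f"{cfg.tau * cfg.sigma * stacked_norm_sq:.6g} >= 1"
        )
    y, eps = meas.y, cfg.epsilon
    tau, sig = cfg.tau, cfg.sigma

    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    u = np.zeros(m) if u0 is None else np.asarray(u0, dtype=float).copy()
    v = np.zeros(s) if v0 is None else np.asarray(v0, dtype=float).copy()
    st = SolverState(x=x, u=u, v=v)

    converged = False
    for k in range(cfg.max_iter):
        grad = model.adjoint(u) + dictionary.synthesis(v)
        x_new = project_nonneg(x - tau * grad)
        xbar = 2.0 * x_new - x

        b = u + sig * model.forward(xbar)
        u_new = b - sig * project_l2_ball(b / sig, y, eps)

        c = v + sig * dictionary.analysis(xbar)
        v_new = c - sig * prox_weighted_l1(c / sig, weights, 1.0 / sig)

        # combined primal/dual iterate change: the primal alone can stall
        # (e.g. a thresholding prox holding x at 0 while the duals ramp up)
        rel = max(
            float(np.linalg.norm(x_new - x) / max(np.linalg.norm(x), 1e-300)),
            float(np.linalg.norm(u_new - u) / max(np.linalg.norm(u), 1e-300)),
            float(np.linalg.norm(v_new - v) / max(np.linalg.norm(v), 1e-300)),
        )
        x, u, v = x_new, u_new, v_new
        st.history["rel_change"].append(rel)
        st.k = k + 1
        if rel < cfg.rel_tol and k > 0:
            if cfg.feas_tol is not None and _data_residual(model, x, y) > \
                    eps * (1.0 + cfg.feas_tol):
                continue
            converged = True
            break

    st.x, st.u, st.v = x, u, v
    resid = _data_residual(model, x, y)
    st.history["data_residual"].append(resid)
    st.history["objective"].append(float(np.sum(
        weights.delta * np.abs(dictionary.analysis(x)))))
    violation = max(0.0, resid - eps)
    converged = converged and violation <= eps * 1e-6
    return ReconstructionResult(
        x_hat=x, converged=converged, iterations=st.k,
        constraint_violation=violation, state=st,
    )


def sara_coil(
    meas: Measurements,
    model: MeasurementModel,
    dictionary: SaraDictionary,
    n_reweights: int = 5,
    alpha0: Optional[float] = None,
    cfg: Optional[SolverConfig] = None,
    alpha_decay: float = 0.5,
    alpha_floor: Optional[float] = None,
) -> ReconstructionResult:
    """Reweighted-l1 (SARA) outer loop approximating the log-sum prior.

    Starts unweighted (weights all ones), then refreshes the weights from
    the analysis coefficients of the current solution with a geometrically
    decaying smoothing parameter alpha, warm-starting each inner solve.
    ``alpha0`` defaults to the maximum absolute coefficient of the first
    solution (so the first reweighting is gentle); ``alpha_floor`` defaults
    to an estimate of the coefficient-domain noise level
    ``epsilon / sqrt(S)``.
    """
    if n_reweights < 1:
        raise ValueError("n_reweights must be >= 1")
    if cfg is None:
        cfg = SolverConfig.from_norm(
            np.sqrt(model.norm_estimate ** 2 + 1.0), epsilon=meas.epsilon)
    if alpha_floor is None:
        alpha_floor = max(meas.epsilon / np.sqrt(dictionary.n_coeffs), 1e-8)

    weights = update_weights(np.zeros(dictionary.n_coeffs), alpha=1.0)  # all ones
    result = solve_weighted_l1(meas, model, dictionary, weights, cfg)
    alpha = alpha0
    for _ in range(1, n_reweights):
        coeffs = dictionary.analysis(result.x_hat)
        if alpha is None:
            alpha = float(np.max(np.abs(coeffs))) or 1.0
        alpha = max(alpha, alpha_floor)
        weights = update_weights(coeffs, alpha)
        result = solve_weighted_l1(
            meas, model, dictionary, weights, cfg,
            x0=result.x_hat, u0=result.state.u, v0=result.state.v,
        )
        alpha = alpha * alpha_decay
    return result


def pnp_primal_dual(
    meas: Measurements,
    model: MeasurementModel,
    denoiser: Callable[[np.ndarray], np.ndarray],
    cfg: SolverConfig,
    x0: Optional[np.ndarray] = None,
    u0: Optional[np.ndarray] = None,
) -> ReconstructionResult:
    """Plug-and-play primal-dual iteration with an FNE denoiser.

    ``denoiser`` maps a length-N image vector to a length-N image vector
    and must be firmly nonexpansive for the convergence guarantee to hold.
    No nonnegativity projection is applied inside the loop (composing two
    resolvents would void the monotone-operator interpretation); clamp for
    display only.
    """
    m, n = model.shape
    cfg.validate_against(model.norm_estimate)
    y, eps = meas.y, cfg.epsilon
    tau, sig = cfg.tau, cfg.sigma

    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    u = np.zeros(m) if u0 is None else np.asarray(u0, dtype=float).copy()
    st = SolverState(x=x, u=u)

    converged = False
    for k in range(cfg.max_iter):
        x_tilde = x - tau * model.adjoint(u)
        x_new = np.asarray(denoiser(x_tilde), dtype=float).ravel()
        if not np.all(np.isfinite(x_new)):
            raise FloatingPointError(
                "divergence: non-finite iterate at k={}; step-size product "
                "tau*sigma*||Phi||^2 = {:.6g}".format(
                    k, tau * sig * model.norm_estimate ** 2)
            )
        u_tilde = u + sig * model.forward(2.0 * x_new - x)
        u_new = u_tilde - sig * project_l2_ball(u_tilde / sig, y, eps)

        # combined primal/dual iterate change (primal alone can stall while
        # the dual is still ramping, e.g. under a strongly thresholding J)
        rel = max(
            float(np.linalg.norm(x_new - x) / max(np.linalg.norm(x), 1e-300)),
            float(np.linalg.norm(u_new - u) / max(np.linalg.norm(u), 1e-300)),
        )
        x, u = x_new, u_new
        st.history["rel_change"].append(rel)
        st.k = k + 1
        if rel < cfg.rel_tol and k > 0:
            if cfg.feas_tol is not None and _data_residual(model, x, y) > \
                    eps * (1.0 + cfg.feas_tol):
                continue
            converged = True
            break

    st.x, st.u = x, u
    resid = _data_residual(model, x, y)
    st.history["data_residual"].append(resid)
    violation = max(0.0, resid - eps)
    result = ReconstructionResult(
        x_hat=x, converged=converged and violation <= eps * 1e-6,
        iterations=st.k, constraint_violation=violation, state=st,
    )
    result.fixed_point_residual = check_inclusion_residual(
        result, model, denoiser, cfg)
    return result


def check_inclusion_residual(
    result: ReconstructionResult,
    model: MeasurementModel,
    denoiser: Callable[[np.ndarray], np.ndarray],
    cfg: SolverConfig,
) -> float:
    """Numerical certificate for the limit-point inclusion.

    At an exact solution the primal iterate is a fixed point of one more
    half-step, so ``||x - J(x - tau Phi^T u)|| / max(1, ||x||)`` measures
    how far the returned point is from satisfying the characterization
    ``0 in Phi^T N_{B2}(Phi x) + (1/tau) B(x)``.
    """
    x, u = result.x_hat, result.state.u
    z = np.asarray(denoiser(x - cfg.tau * model.adjoint(u)), dtype=float).ravel()
    return float(np.linalg.norm(x - z) / max(1.0, np.linalg.norm(x)))
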