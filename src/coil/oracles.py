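"""Reference solvers for cross-checking the primal-dual reconstructions.

These solve the same constrained problems as :mod:`coil.solvers` but by a
different route — scaled ADMM with an exact dense linear-algebra x-update —
so agreement between the two is evidence of correctness of both.  They are
restricted to small dense instances (N <= a few hundred) and are not meant
for production reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve


@dataclass
class OracleSolution:
    x: np.ndarray
    objective: float
    data_residual: float
    iterations: int
    primal_residual: float
    dual_residual: float


def admm_constrained_l1(
    phi: np.ndarray,
    y: np.ndarray,
    epsilon: float,
    psi: Optional[np.ndarray] = None,
    delta: Optional[np.ndarray] = None,
    nonneg: bool = True,
    rho: float = 1.0,
    max_iter: int = 20000,
    tol: float = 1e-9,
) -> OracleSolution:
    """Solve  min ||delta . (Psi x)||_1  s.t. ||Phi x - y|| <= eps [, x >= 0].

    Scaled ADMM on the splitting ``c = Psi x``, ``r = Phi x`` (and ``s = x``
    when ``nonneg``), with the x-update solved exactly through a cached
    Cholesky factorization.  ``psi=None`` means the identity dictionary
    (plain l1 on the pixels); ``delta=None`` means unit weights.
    """
    phi = np.asarray(phi, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, n = phi.shape
    ident_psi = psi is None
    if not ident_psi:
        psi = np.asarray(psi, dtype=float)
    s_dim = n if ident_psi else psi.shape[0]
    w = np.ones(s_dim) if delta is None else np.asarray(delta, dtype=float).ravel()

    # Normal matrix Psi^T Psi + Phi^T Phi (+ I); Psi is either the identity
    # or a Parseval frame, Psi^T Psi = I in both cases, but keep it general.
    gram = phi.T @ phi
    if ident_psi:
        gram = gram + np.eye(n)
    else:
        gram = gram + psi.T @ psi
    if nonneg:
        gram = gram + np.eye(n)
    chol = cho_factor(gram)

    def apply_psi(x):
        return x if ident_psi else psi @ x

    def apply_psi_t(v):
        return v if ident_psi else psi.T @ v

    x = np.zeros(n)
    c = np.zeros(s_dim)
    r = np.zeros(m)
    s = np.zeros(n)
    uc = np.zeros(s_dim)
    ur = np.zeros(m)
    us = np.zeros(n)

    pres = dres = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        rhs = apply_psi_t(c - uc) + phi.T @ (r - ur)
        if nonneg:
            rhs = rhs + (s - us)
        x = cho_solve(chol, rhs)

        psix = apply_psi(x)
        phix = phi @ x
        c_old, r_old, s_old = c, r, s

        v = psix + uc
        thr = w / rho
        c = np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)

        d = phix + ur - y
        nrm = np.linalg.norm(d)
        r = y + (d if nrm <= epsilon else (epsilon / nrm) * d)

        uc = uc + psix - c
        ur = ur + phix - r
        if nonneg:
            s = np.maximum(x + us, 0.0)
            us = us + x - s

        if it % 50 == 0 or it == max_iter:
            pr = np.linalg.norm(psix - c) ** 2 + np.linalg.norm(phix - r) ** 2
            dr = (np.linalg.norm(apply_psi_t(c - c_old)) ** 2
                  + np.linalg.norm(phi.T @ (r - r_old)) ** 2)
            if nonneg:
                pr += np.linalg.norm(x - s) ** 2
                dr += np.linalg.norm(s - s_old) ** 2
            scale = max(1.0, np.linalg.norm(x))
            pres = np.sqrt(pr) / scale
            dres = rho * np.sqrt(dr) / scale
            if pres < tol and dres < tol:
                break

    # Report the objective at a strictly feasible rendering of the iterate.
    x_feas = np.maximum(x, 0.0) if nonneg else x.copy()
    d = phi @ x_feas - y
    nrm = np.linalg.norm(d)
    obj = float(np.sum(w * np.abs(apply_psi(x_feas))))
    return OracleSolution(
        x=x_feas, objective=obj, data_residual=float(nrm),
        iterations=it, primal_residual=float(pres), dual_residual=float(dres),
    )


def dense_spectral_norm(mat: np.ndarray) -> float:
    """Largest singular value via full SVD (oracle for power iteration)."""
    return float(np.linalg.svd(np.asarray(mat, dtype=float), compute_uv=False)[0])
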