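"""Firmly nonexpansive learned denoiser with Jacobian spectral-norm control.

The denoiser is parameterized as the resolvent of a maximally monotone
operator:  J(z) = (z + Q(z)) / 2, where Q is a residual convolutional
network.  If Q is 1-Lipschitz, J is firmly nonexpansive (FNE) and the
plug-and-play primal-dual iteration using J converges.  1-Lipschitzness is
promoted during training by penalizing the spectral norm of the Jacobian
of Q at the noisy training inputs,

    loss_i = || J(z_i) - x_i ||^2 / n_pix  +  lambda * max(||dQ(z_i)||_S^2, 1 - delta),

with the spectral norm computed by a power method whose forward/adjoint
directional derivatives (JVP/VJP) are differentiated with respect to the
weights, mirroring the power-method-with-backpropagation recipe.  The
regularization weight lambda is grown by doubling until the held-out
maximum Jacobian norm drops below 1.

The network is a compact DnCNN-style residual predictor implemented
directly in numpy (forward, backward, JVP and VJP are all hand-written so
the Jacobian machinery stays self-contained and CPU-cheap): Q(z) = z - N(z)
where N is a stack of 3x3 convolutions with ReLU activations operating on
grey levels in [0, 255].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._convkernels import BufferPool, col2im, im2col

__all__ = [
    "Conv2D",
    "ConvNet",
    "ResidualQ",
    "LinearQ",
    "DenoiserSpec",
    "TrainingConfig",
    "jacobian_spectral_norm",
    "train_denoiser",
    "certify_fne",
    "denoise",
    "save_denoiser",
    "load_denoiser",
    "fne_margin",
]


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class Conv2D:
    """3x3 'same' convolution with zero padding, channels-last (B, H, W, C).

    Implemented as im2col + one GEMM; the channels-last layout keeps the
    im2col gather and scatter contiguous so the layer runs at BLAS speed
    on a single CPU core.  ``dtype`` controls the compute precision
    (float32 for training throughput, float64 for certification math).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 weight_scale: float = 0.05, dtype=np.float64):
        self.w = (weight_scale * rng.standard_normal((c_out, c_in, 3, 3))).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.x_cols = None      # cache from forward, (B*H*W, 9*C_in)
        self.t_cols = None      # cache from jvp
        self._shape = None      # (B, H, W) of the last input
        self._pool = BufferPool()

    @property
    def dtype(self):
        return self.w.dtype

    def astype(self, dtype) -> "Conv2D":
        self.w = self.w.astype(dtype)
        self.b = self.b.astype(dtype)
        return self

    def _im2col(self, x: np.ndarray, tag: str) -> np.ndarray:
        return im2col(np.ascontiguousarray(x, dtype=self.dtype), self._pool, tag)

    def _wmat(self) -> np.ndarray:
        # (9*C_in, C_out): row index (dy*3+dx)*C_in + c_in, matching im2col
        return np.ascontiguousarray(
            self.w.transpose(2, 3, 1, 0).reshape(-1, self.w.shape[0]))

    def _gw_from_cols(self, cols: np.ndarray, gmat: np.ndarray) -> np.ndarray:
        return (cols.T @ gmat).reshape(
            3, 3, self.w.shape[1], self.w.shape[0]).transpose(3, 2, 0, 1)

    def _col2im(self, gcols: np.ndarray) -> np.ndarray:
        return col2im(gcols, self._shape, self.w.shape[1], self._pool)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, _ = x.shape
        self._shape = (b, h, w)
        self.x_cols = self._im2col(x, "x_cols")
        return (self.x_cols @ self._wmat() + self.b).reshape(b, h, w, -1)

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (grad_input, grad_w, grad_b) for upstream gradient g."""
        gmat = g.reshape(-1, g.shape[-1])
        gw = self._gw_from_cols(self.x_cols, gmat)
        gb = gmat.sum(axis=0)
        return self._col2im(gmat @ self._wmat().T), gw, gb

    def jvp(self, t: np.ndarray) -> np.ndarray:
        """Directional derivative wrt the input (bias drops out)."""
        b, h, w, _ = t.shape
        self.t_cols = self._im2col(t, "t_cols")
        return (self.t_cols @ self._wmat()).reshape(b, h, w, -1)

    def vjp(self, g: np.ndarray) -> np.ndarray:
        return self._col2im(g.reshape(-1, g.shape[-1]) @ self._wmat().T)

    def jvp_backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backprop through the JVP pass: weight grads use tangent inputs."""
        gmat = g.reshape(-1, g.shape[-1])
        gw = self._gw_from_cols(self.t_cols, gmat)
        return self._col2im(gmat @ self._wmat().T), gw


class ConvNet:
    """Plain conv/ReLU stack N(z); Q(z) = z - N(z) is built on top.

    ``depth`` convolution layers with ``features`` channels in the hidden
    layers, ReLU between them, no nonlinearity after the last layer.
    """

    def __init__(self, depth: int = 4, features: int = 16, seed: int = 0,
                 dtype=np.float64):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(seed)
        chans = [1] + [features] * (depth - 1) + [1]
        self.convs = [Conv2D(chans[i], chans[i + 1], rng, dtype=dtype)
                      for i in range(depth)]
        # Zero-init the last layer: the network starts as the zero map, so
        # Q starts exactly at the identity (spectral norm 1).
        self.convs[-1].w[:] = 0.0
        self.depth = depth
        self.features = features
        self.masks: list[np.ndarray] = []

    @property
    def dtype(self):
        return self.convs[0].dtype

    def astype(self, dtype) -> "ConvNet":
        for c in self.convs:
            c.astype(dtype)
        return self

    # (B, 1, H, W) <-> channels-last (B, H, W, 1); both are the same memory
    # order for a single channel, so the reshapes are free.
    @staticmethod
    def _to_cl(x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        assert c == 1
        return x.reshape(b, h, w, 1)

    @staticmethod
    def _from_cl(x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        return x.reshape(b, c, h, w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.masks = []
        h = self._to_cl(np.asarray(x).astype(self.dtype, copy=False))
        for i, conv in enumerate(self.convs):
            h = conv.forward(h)
            if i < self.depth - 1:
                mask = h > 0
                self.masks.append(mask)
                h = h * mask
        return self._from_cl(h)

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, list]:
        g = self._to_cl(np.asarray(g).astype(self.dtype, copy=False))
        grads = [None] * self.depth
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                g = g * self.masks[i]
            g, gw, gb = self.convs[i].backward(g)
            grads[i] = (gw, gb)
        return self._from_cl(g), grads

    def jvp(self, t: np.ndarray) -> np.ndarray:
        """Jacobian-vector product at the last forward() point."""
        t = self._to_cl(np.asarray(t).astype(self.dtype, copy=False))
        for i, conv in enumerate(self.convs):
            t = conv.jvp(t)
            if i < self.depth - 1:
                t = t * self.masks[i]
        return self._from_cl(t)

    def vjp(self, g: np.ndarray) -> np.ndarray:
        """Transposed-Jacobian-vector product at the last forward() point."""
        g = self._to_cl(np.asarray(g).astype(self.dtype, copy=False))
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                g = g * self.masks[i]
            g = self.convs[i].vjp(g)
        return self._from_cl(g)

    def jvp_backward(self, g: np.ndarray) -> list:
        """Weight gradients of <g, jvp(t)> for the last jvp() pass."""
        g = self._to_cl(np.asarray(g).astype(self.dtype, copy=False))
        grads = [None] * self.depth
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                g = g * self.masks[i]
            g, gw = self.convs[i].jvp_backward(g)
            grads[i] = gw
        return grads

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out = []
        for c in self.convs:
            out.extend([c.w, c.b])
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {}
        for i, c in enumerate(self.convs):
            d[f"conv{i}.w"] = c.w
            d[f"conv{i}.b"] = c.b
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for i, c in enumerate(self.convs):
            c.w = np.array(d[f"conv{i}.w"], dtype=float)
            c.b = np.array(d[f"conv{i}.b"], dtype=float)


# --------------------------------------------------------------------------
# Q operators (things with a Jacobian)
# --------------------------------------------------------------------------

class ResidualQ:
    """Q(z) = z - N(z) for a ConvNet N; dQ = Id - dN."""

    def __init__(self, net: ConvNet):
        self.net = net

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return z - self.net.forward(z)

    def prepare(self, z: np.ndarray) -> None:
        self.net.forward(z)

    def jvp(self, t: np.ndarray) -> np.ndarray:
        return t - self.net.jvp(t)

    def vjp(self, g: np.ndarray) -> np.ndarray:
        return g - self.net.vjp(g)


class LinearQ:
    """Linear map Q(z) = A z on flattened inputs (testing/reference)."""

    def __init__(self, a: np.ndarray):
        self.a = np.asarray(a, dtype=float)

    def __call__(self, z: np.ndarray) -> np.ndarray:
        shp = z.shape
        return (self.a @ np.ravel(z)).reshape(shp)

    def prepare(self, z: np.ndarray) -> None:
        pass

    def jvp(self, t: np.ndarray) -> np.ndarray:
        return self(t)

    def vjp(self, g: np.ndarray) -> np.ndarray:
        shp = g.shape
        return (self.a.T @ np.ravel(g)).reshape(shp)


def jacobian_spectral_norm(
    q_net, z: np.ndarray, n_iters: int = 50, seed: int = 0
) -> float:
    """Spectral norm of the Jacobian of ``q_net`` at ``z`` by power method.

    ``q_net`` exposes ``prepare(z)`` (run the forward pass, fixing the
    linearization point), ``jvp`` and ``vjp``.  Power iteration on
    ``dQ^T dQ`` returns the square root of its dominant eigenvalue.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    z = np.asarray(z, dtype=float)
    single = z.ndim <= 2
    zb = z[None, None] if single else z
    q_net.prepare(zb)
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(zb.shape)
    while np.linalg.norm(u) == 0:  # pragma: no cover - measure-zero event
        u = rng.standard_normal(zb.shape)
    sigma = 0.0
    for _ in range(n_iters):
        u = u / max(np.linalg.norm(u), 1e-300)
        a = q_net.jvp(u)
        sigma = np.linalg.norm(a)
        if sigma == 0:
            return 0.0
        u = q_net.vjp(a)
    return float(sigma)


def _batched_power_method(q: ResidualQ, z: np.ndarray, n_iters: int,
                          rng: np.random.Generator,
                          u0: Optional[np.ndarray] = None):
    """Per-sample power method, vectorized over the batch.

    Returns (sigma_sq, a, u) where for each sample b ``u[b]`` is the final
    unit singular vector and ``a[b] = dQ(z_b) u[b]`` so that
    ``sigma_sq[b] = ||a[b]||^2``.  Assumes ``q.prepare(z)`` was called.
    ``u0`` warm-starts the iteration (e.g. the singular vector from the
    previous epoch), which sharpens the estimate when the spectrum of
    ``dQ^T dQ`` is clustered.
    """
    u = rng.standard_normal(z.shape) if u0 is None else u0.astype(
        z.dtype, copy=True)
    axes = (1, 2, 3)
    a = None
    for _ in range(n_iters):
        nrm = np.sqrt(np.sum(u * u, axis=axes, keepdims=True))
        u = u / np.maximum(nrm, 1e-300)
        a = q.jvp(u)
        u = q.vjp(a)
    # one clean final evaluation at the normalized vector
    nrm = np.sqrt(np.sum(u * u, axis=axes, keepdims=True))
    u = u / np.maximum(nrm, 1e-300)
    a = q.jvp(u)
    sigma_sq = np.sum(a * a, axis=axes)
    return sigma_sq, a, u


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Hyperparameters for denoiser training on [0, 255] grey levels."""

    upsilon: float = 10.0          # noise std in grey levels
    # The denoising loss is a per-pixel mean, so the reference per-patch
    # sum-loss weight 1e-3 maps to about 1e-3 * (32*32) = 1 here; the
    # doubling search still selects the smallest certifying value.
    lambda_reg: float = 1.0        # starting Jacobian-penalty weight
    delta_margin: float = 0.05     # keep ||dQ||_S below sqrt(1 - delta)
    batch_size: int = 25
    patch_size: int = 32
    learning_rate: float = 1e-3
    lr_decay: float = 1.0          # optional per-round step-size anneal
    epochs: int = 5
    finetune_epochs: int = 1       # extra epochs per lambda doubling
    power_iters: int = 10          # during training
    cert_power_iters: int = 50     # during certification
    penalty_fraction: float = 0.5  # fraction of each batch in the penalty term
    augment: bool = False          # random flips/right-angle rotations
    max_doublings: int = 12
    depth: int = 4
    features: int = 16
    holdout_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.delta_margin < 1):
            raise ValueError("delta_margin must lie in (0, 1)")
        if not self.lambda_reg > 0:
            raise ValueError("lambda_reg must be > 0")


@dataclass
class DenoiserSpec:
    """Trained resolvent denoiser J(z) = (z + Q(z))/2 with its certificate."""

    net: ConvNet = field(repr=False)
    training_noise_sigma: float = 10.0
    lambda_reg: float = 1e-3
    delta_margin: float = 0.05
    certification: dict = field(default_factory=dict)
    data_range: tuple[float, float] = (0.0, 255.0)

    @property
    def q(self) -> ResidualQ:
        return ResidualQ(self.net)

    def j_theta(self, z: np.ndarray) -> np.ndarray:
        """Resolvent map (z + Q(z))/2 = z - N(z)/2 on (B,1,H,W) or (H,W)."""
        z = np.asarray(z, dtype=float)
        single = z.ndim == 2
        zb = z[None, None] if single else z
        out = zb - 0.5 * self.net.forward(zb)
        return out[0, 0] if single else out

    def as_operator(self, image_shape: tuple[int, int],
                    input_range: Optional[tuple[float, float]] = None,
                    relaxation: float = 1.0):
        """Vector-to-vector FNE operator for the PnP solver.

        If the solver works on a different grey-level range than the
        training range, the denoiser is conjugated by the affine rescaling
        between the two ranges (which preserves firm nonexpansiveness).

        ``relaxation`` in (0, 1] blends toward the identity,
        ``J_r = r J + (1-r) Id``; this equals ``(Id + Q_r)/2`` with
        ``Q_r = r Q + (1-r) Id`` still nonexpansive, so the relaxed
        operator remains firmly nonexpansive and acts as a regularizer-
        strength control (weaker prior for smaller r).
        """
        if not (0.0 < relaxation <= 1.0):
            raise ValueError("relaxation must lie in (0, 1]")
        h, w = image_shape
        lo_t, hi_t = self.data_range
        if input_range is None or input_range == self.data_range:
            scale, off = 1.0, 0.0
        else:
            lo, hi = input_range
            scale = (hi_t - lo_t) / (hi - lo)
            off = lo_t - scale * lo

        def op(xvec: np.ndarray) -> np.ndarray:
            img = np.asarray(xvec, dtype=float).reshape(h, w)
            z = scale * img + off
            out = self.j_theta(z)
            if relaxation < 1.0:
                out = relaxation * out + (1.0 - relaxation) * z
            return ((out - off) / scale).ravel()

        return op


def denoise(spec: DenoiserSpec, x: np.ndarray) -> np.ndarray:
    """Apply the resolvent denoiser to an image (2-D) or square image vector."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input to denoise must be finite")
    if x.ndim == 1:
        side = int(round(np.sqrt(x.size)))
        if side * side != x.size:
            raise ValueError("1-D input must be a flattened square image")
        return spec.j_theta(x.reshape(side, side)).ravel()
    return spec.j_theta(x)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _flatten_grads(mse_grads: list, jac_grads: Optional[list]) -> list[np.ndarray]:
    out = []
    for i, (gw, gb) in enumerate(mse_grads):
        if jac_grads is not None and jac_grads[i] is not None:
            gw = gw + jac_grads[i]
        out.extend([gw, gb])
    return out


def _train_epochs(net: ConvNet, q: ResidualQ, data: np.ndarray,
                  cfg: TrainingConfig, lam: float, epochs: int,
                  rng: np.random.Generator, opt: _Adam,
                  u_store: Optional[np.ndarray] = None) -> float:
    """Run SGD epochs of the denoising + Jacobian loss; return last loss.

    ``u_store`` holds one persistent singular-vector estimate per training
    sample; warm-starting the per-step power method from it makes the
    spectral-norm estimates converge across epochs.
    """
    n = data.shape[0]
    npix = cfg.patch_size ** 2
    thresh = 1.0 - cfg.delta_margin
    last = np.nan
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = data[idx][:, None]                      # (B,1,P,P)
            if cfg.augment:
                x = x.copy()
                flips = rng.integers(0, 2, size=(x.shape[0], 2))
                quarts = rng.integers(0, 4, size=x.shape[0])
                for bi in range(x.shape[0]):
                    patch = x[bi, 0]
                    if flips[bi, 0]:
                        patch = patch[::-1]
                    if flips[bi, 1]:
                        patch = patch[:, ::-1]
                    x[bi, 0] = np.rot90(patch, quarts[bi])
            z = x + cfg.upsilon * rng.standard_normal(x.shape)
            b = x.shape[0]

            resid = net.forward(z)                      # N(z)
            j = z - 0.5 * resid                         # J(z)
            err = j - x
            mse = float(np.mean(err ** 2))
            # dL/d resid = -err / (b * npix)   (J = z - resid/2)
            g_resid = -err / (b * npix)
            _, mse_grads = net.backward(g_resid)

            # Jacobian penalty: per-sample sigma^2, hinged at 1 - delta,
            # estimated on a random sub-batch (unbiased; the power method
            # dominates the step cost).
            bp = max(1, int(round(cfg.penalty_fraction * b)))
            sub = rng.choice(b, size=bp, replace=False)
            zp = np.ascontiguousarray(z[sub])
            q.prepare(zp)
            u0 = None if u_store is None else u_store[idx[sub], None]
            sig_sq, a, u_fin = _batched_power_method(
                q, zp, cfg.power_iters, rng, u0=u0)
            if u_store is not None:
                u_store[idx[sub]] = u_fin[:, 0]
            active = sig_sq > thresh
            jac_grads = None
            if np.any(active):
                # d sigma_b^2 / dtheta = -2 <a_b, d (dN) u_b / dtheta>
                gmask = np.where(active[:, None, None, None], a, 0.0)
                jac_grads = net.jvp_backward(-2.0 * lam / bp * gmask)
            last = mse + lam * float(np.mean(np.maximum(sig_sq, thresh)))
            opt.step(_flatten_grads(mse_grads, jac_grads))
    return last


def _float64_copy(net: ConvNet) -> ConvNet:
    out = ConvNet(depth=net.depth, features=net.features, seed=0)
    out.load_state_dict(net.state_dict())
    return out


def _holdout_max_jacobian(net: ConvNet, patches: np.ndarray, upsilon: float,
                          n_iters: int, rng: np.random.Generator,
                          quick: bool = False) -> float:
    """Held-out max ||dQ||_S over noisy inputs at the training noise level.

    ``quick=True`` evaluates in the training dtype (used inside the lambda
    search); the final certificate runs on a float64 copy of the network.
    """
    q = ResidualQ(net if quick else _float64_copy(net))
    z = patches[:, None] + upsilon * rng.standard_normal(
        (patches.shape[0], 1) + patches.shape[1:])
    if quick:
        z = z.astype(net.dtype)
    q.prepare(z)
    sig_sq, _, _ = _batched_power_method(q, z, n_iters, rng)
    return float(np.sqrt(np.max(sig_sq)))


def train_denoiser(dataset: np.ndarray, cfg: TrainingConfig) -> DenoiserSpec:
    """Train the resolvent denoiser on a patch corpus, doubling lambda
    until the held-out maximum Jacobian norm is <= 1.

    ``dataset`` is an (n, P, P) array of clean patches in [0, 255].  A
    held-out fraction is reserved for the Lipschitz certification; the
    returned spec carries the certification record (max Jacobian norm,
    lambda schedule, losses).
    """
    data = np.asarray(dataset, dtype=float)
    if data.ndim != 3:
        raise ValueError("dataset must be an (n, P, P) patch stack")
    if data.shape[0] < cfg.batch_size:
        raise ValueError("dataset smaller than one batch")
    rng = np.random.default_rng(cfg.seed)
    n_hold = max(int(cfg.holdout_fraction * data.shape[0]), cfg.batch_size)
    perm = rng.permutation(data.shape[0])
    hold, train = data[perm[:n_hold]], data[perm[n_hold:]]

    # float32 compute for throughput; certification runs on a float64 copy
    net = ConvNet(depth=cfg.depth, features=cfg.features, seed=cfg.seed,
                  dtype=np.float32)
    q = ResidualQ(net)
    opt = _Adam(net.parameters(), cfg.learning_rate)

    # persistent per-sample singular-vector estimates (warm-started power
    # method); float32 to match the training dtype
    u_store = rng.standard_normal(train.shape).astype(np.float32)

    lam = cfg.lambda_reg
    schedule = []
    n_quick = min(hold.shape[0], 64)
    loss = _train_epochs(net, q, train, cfg, lam, cfg.epochs, rng, opt, u_store)
    # Cheap in-dtype screening during the lambda search; the full float64
    # certificate at cert_power_iters is recomputed whenever the screen
    # passes, and the search continues if the rigorous check disagrees.
    rounds = 0
    while True:
        quick_sig = _holdout_max_jacobian(
            net, hold[:n_quick], cfg.upsilon, 30,
            np.random.default_rng(cfg.seed + 1), quick=True)
        if quick_sig <= 1.0:
            max_sig = _holdout_max_jacobian(
                net, hold, cfg.upsilon, cfg.cert_power_iters,
                np.random.default_rng(cfg.seed + 1))
            schedule.append({"lambda": lam, "holdout_max_jacobian": max_sig,
                             "loss": loss})
            if max_sig <= 1.0:
                break
        else:
            schedule.append({"lambda": lam, "holdout_max_jacobian": quick_sig,
                             "loss": loss, "screen_only": True})
        if rounds >= cfg.max_doublings:
            max_sig = _holdout_max_jacobian(
                net, hold, cfg.upsilon, cfg.cert_power_iters,
                np.random.default_rng(cfg.seed + 1))
            schedule.append({"lambda": lam, "holdout_max_jacobian": max_sig,
                             "loss": loss})
            break
        lam *= 2.0
        rounds += 1
        # anneal the step size so late high-lambda rounds refine rather
        # than wash out the denoising fit
        opt.lr *= cfg.lr_decay
        loss = _train_epochs(net, q, train, cfg, lam, cfg.finetune_epochs,
                             rng, opt, u_store)

    spec = DenoiserSpec(
        net=_float64_copy(net), training_noise_sigma=cfg.upsilon, lambda_reg=lam,
        delta_margin=cfg.delta_margin,
        certification={
            "holdout_max_jacobian": max_sig,
            "lipschitz_certified": bool(max_sig <= 1.0),
            "lambda_schedule": schedule,
            "cert_power_iters": cfg.cert_power_iters,
            "n_holdout": int(hold.shape[0]),
        },
    )
    return spec


# --------------------------------------------------------------------------
# certification
# --------------------------------------------------------------------------

def fne_margin(j, x: np.ndarray, y: np.ndarray) -> float:
    """Slack of the FNE inequality <x-y, Jx-Jy> - ||Jx-Jy||^2 (>= 0 if FNE)."""
    dj = np.ravel(j(x)) - np.ravel(j(y))
    dx = np.ravel(x) - np.ravel(y)
    return float(dx @ dj - dj @ dj)


def certify_fne(
    spec,
    probes: int = 10_000,
    seed: int = 0,
    patch_source: Optional[np.ndarray] = None,
    patch_size: int = 32,
    tol: float = 1e-8,
) -> dict:
    """Check the firm-nonexpansiveness inequality on seeded random pairs.

    ``spec`` is a :class:`DenoiserSpec` or any callable image->image map.
    Pairs are drawn near the training distribution: a base patch (from
    ``patch_source`` if given, else smooth random fields in [0, 255]) plus
    two independent noise perturbations at a mix of amplitudes.  Failures
    are recorded, not raised.
    """
    if probes < 1:
        raise ValueError("probes must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(spec, DenoiserSpec):
        jmap = spec.j_theta
        sigma = spec.training_noise_sigma
    else:
        jmap, sigma = spec, 10.0

    worst = np.inf
    n_fail = 0
    batch = 100
    done = 0
    while done < probes:
        b = min(batch, probes - done)
        if patch_source is not None:
            base = patch_source[rng.integers(0, patch_source.shape[0], b)]
        else:
            from scipy.ndimage import gaussian_filter
            base = np.stack([
                gaussian_filter(rng.standard_normal((patch_size, patch_size)), 3.0)
                for _ in range(b)])
            base = 127.5 + 80.0 * base / max(np.abs(base).max(), 1e-12)
        amp = sigma * rng.uniform(0.2, 3.0, size=(b, 1, 1))
        x = base + amp * rng.standard_normal(base.shape)
        y = base + amp * rng.standard_normal(base.shape)
        if isinstance(spec, DenoiserSpec):
            jx = spec.j_theta(x[:, None])[:, 0]
            jy = spec.j_theta(y[:, None])[:, 0]
        else:
            jx = np.stack([np.asarray(jmap(xi)) for xi in x])
            jy = np.stack([np.asarray(jmap(yi)) for yi in y])
        dj = (jx - jy).reshape(b, -1)
        dx = (x - y).reshape(b, -1)
        margins = np.einsum("bi,bi->b", dx, dj) - np.einsum("bi,bi->b", dj, dj)
        worst = min(worst, float(margins.min()))
        n_fail += int(np.sum(margins < -tol))
        done += b
    record = {
        "n_pairs": probes,
        "n_failures": n_fail,
        "worst_margin": worst,
        "passed": n_fail == 0,
        "tolerance": tol,
        "seed": seed,
    }
    if isinstance(spec, DenoiserSpec):
        spec.certification.setdefault("fne_pairs", record)
    return record


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def save_denoiser(spec: DenoiserSpec, stem: Path | str) -> None:
    """Write ``<stem>.npz`` (weights) + ``<stem>.json`` (metadata)."""
    stem = Path(stem)
    np.savez(stem.with_suffix(".npz"), **spec.net.state_dict())
    meta = {
        "depth": spec.net.depth,
        "features": spec.net.features,
        "training_noise_sigma": spec.training_noise_sigma,
        "lambda_reg": spec.lambda_reg,
        "delta_margin": spec.delta_margin,
        "data_range": list(spec.data_range),
        "certification": spec.certification,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=float))


def load_denoiser(stem: Path | str) -> DenoiserSpec:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    net = ConvNet(depth=meta["depth"], features=meta["features"], seed=0)
    with np.load(stem.with_suffix(".npz")) as d:
        net.load_state_dict(dict(d))
    return DenoiserSpec(
        net=net,
        training_noise_sigma=meta["training_noise_sigma"],
        lambda_reg=meta["lambda_reg"],
        delta_margin=meta["delta_margin"],
        certification=meta.get("certification", {}),
        data_range=tuple(meta.get("data_range", (0.0, 255.0))),
    )
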