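"""Synthetic multimode light patterns and the single-pixel measurement model.

A multicore fiber feeding a photonic lantern projects one multimode speckle
pattern per excited core; a single-pixel detector records the inner product
of each projected pattern with the object.  Stacking the ``M`` patterns as
rows gives the linear operator ``Phi``, and a measurement vector

    y = Phi x_bar + w,        ||w||_2 <= epsilon,

where ``x_bar`` is the vectorized object and ``w`` is noise of bounded
energy.  The reference instrument has 121 single-mode cores in an 11x11
array; rotating the fiber 9 times by 40 degrees about the optical axis
multiplies the pattern count to 1,089.

Patterns here are synthesized, not measured: each core gets an independent
speckle field (squared magnitude of a low-pass-filtered complex Gaussian
field) weighted by a broad envelope centred on the core position, which
reproduces speckle-like, mutually weakly correlated rows without any optical
propagation model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "PatternSet",
    "MeasurementModel",
    "Measurements",
    "generate_speckle_patterns",
    "build_measurement_model",
    "estimate_operator_norm",
    "simulate_measurements",
    "epsilon_chi2",
    "save_pattern_set",
    "load_pattern_set",
]


@dataclass
class PatternSet:
    """Stack of M nonnegative intensity patterns forming the rows of Phi."""

    patterns: np.ndarray  # (M, H, W), nonnegative
    core_grid: tuple[int, int]
    rotations: list[float]
    seed: int
    normalization: str = "energy"

    def __post_init__(self):
        p = np.asarray(self.patterns, dtype=float)
        if p.ndim != 3:
            raise ValueError("patterns must be an (M, H, W) stack")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("pattern intensities must be finite and >= 0")
        self.patterns = p

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def image_size(self) -> tuple[int, int]:
        return self.patterns.shape[1], self.patterns.shape[2]


@dataclass
class MeasurementModel:
    """Linear map Phi with forward/adjoint actions and a norm estimate.

    Images are flattened row-major (C order); ``forward`` maps a length-N
    image vector to the M detector readings, ``adjoint`` is the transpose.
    """

    matrix: np.ndarray = field(repr=False)  # (M, N) dense
    shape: tuple[int, int] = None
    norm_estimate: float = 0.0

    def __post_init__(self):
        self.matrix = np.ascontiguousarray(self.matrix, dtype=float)
        self.shape = self.matrix.shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.shape[1]:
            raise ValueError(
                f"image vector has length {x.size}, model expects {self.shape[1]}"
            )
        return self.matrix @ x

    def adjoint(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float).ravel()
        if u.size != self.shape[0]:
            raise ValueError(
                f"measurement vector has length {u.size}, model expects {self.shape[0]}"
            )
        return self.matrix.T @ u


@dataclass
class Measurements:
    """Detector readings y with an l2 noise-energy bound epsilon."""

    y: np.ndarray
    epsilon: float
    input_snr_db: Optional[float] = None
    noise_seed: Optional[int] = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")


def generate_speckle_patterns(
    core_grid: tuple[int, int],
    image_size: tuple[int, int],
    n_rotations: int = 1,
    seed: int = 0,
    correlation_length: float = 2.0,
    normalization: str = "energy",
) -> PatternSet:
    """Synthesize one speckle pattern per core, replicated by rotations.

    Each base pattern is ``|G_sigma * (a + ib)|^2`` with ``a, b`` i.i.d.
    standard normal fields and ``G_sigma`` a Gaussian low-pass filter of
    width ``correlation_length`` pixels (the speckle grain size), then
    weighted by a broad Gaussian envelope centred on the core's position in
    the image plane.  Rotated copies use bilinear interpolation about the
    image centre with zero padding, angle step ``360 / n_rotations`` degrees
    (40 degrees for the reference 9-rotation setting).

    ``normalization``: ``"energy"`` scales each pattern to unit l2 norm,
    ``"none"`` keeps raw intensities.
    """
    rows, cols = int(core_grid[0]), int(core_grid[1])
    h, w = int(image_size[0]), int(image_size[1])
    if rows < 1 or cols < 1:
        raise ValueError("core_grid entries must be >= 1")
    if h < 8 or w < 8:
        raise ValueError("image_size must be at least 8x8")
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    if normalization not in ("energy", "none"):
        raise ValueError("normalization must be 'energy' or 'none'")

    rng = np.random.default_rng(seed)
    n_base = rows * cols
    base = np.empty((n_base, h, w))
    # Core positions mapped onto the interior of the image plane.
    ys = np.linspace(h * 0.15, h * 0.85, rows)
    xs = np.linspace(w * 0.15, w * 0.85, cols)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    env_sigma = 0.45 * max(h, w)
    k = 0
    for r in range(rows):
        for c in range(cols):
            re = ndimage.gaussian_filter(rng.standard_normal((h, w)), correlation_length)
            im = ndimage.gaussian_filter(rng.standard_normal((h, w)), correlation_length)
            envelope = np.exp(-((yy - ys[r]) ** 2 + (xx - xs[c]) ** 2) / (2 * env_sigma ** 2))
            base[k] = (re ** 2 + im ** 2) * envelope
            k += 1

    angle_step = 360.0 / n_rotations
    rotations = [i * angle_step for i in range(n_rotations)]
    stack = np.empty((n_base * n_rotations, h, w))
    for i, ang in enumerate(rotations):
        if ang == 0.0:
            rot = base
        else:
            rot = np.stack(
                [rotate_pattern(p, ang) for p in base]
            )
        stack[i * n_base:(i + 1) * n_base] = rot
    stack = np.maximum(stack, 0.0)

    if normalization == "energy":
        norms = np.linalg.norm(stack.reshape(stack.shape[0], -1), axis=1)
        norms[norms == 0] = 1.0
        stack /= norms[:, None, None]

    return PatternSet(
        patterns=stack,
        core_grid=(rows, cols),
        rotations=rotations,
        seed=int(seed),
        normalization=normalization,
    )


def rotate_pattern(p: np.ndarray, angle_deg: float) -> np.ndarray:
    """Bilinear rotation about the image centre, zero padding outside."""
    return ndimage.rotate(p, angle_deg, reshape=False, order=1, mode="constant", cval=0.0)


def build_measurement_model(p: PatternSet) -> MeasurementModel:
    """Assemble Phi whose m-th row is the m-th pattern flattened row-major."""
    if p.n_patterns == 0:
        raise ValueError("pattern set is empty")
    m = p.n_patterns
    mat = p.patterns.reshape(m, -1)
    model = MeasurementModel(matrix=mat)
    model.norm_estimate = estimate_operator_norm(model)
    return model


def estimate_operator_norm(
    m: MeasurementModel, tol: float = 1e-9, max_iter: int = 500, seed: int = 0
) -> float:
    """Spectral norm ||Phi|| by power iteration on Phi^T Phi."""
    if not tol > 0:
        raise ValueError("tol must be > 0")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(m.shape[1])
    x /= np.linalg.norm(x)
    est = 0.0
    for _ in range(max_iter):
        z = m.adjoint(m.forward(x))
        nz = np.linalg.norm(z)
        if nz == 0:
            return 0.0
        new_est = np.sqrt(nz)
        x = z / nz
        if est > 0 and abs(new_est - est) < tol * est:
            est = new_est
            break
        est = new_est
    return float(est)


def simulate_measurements(
    m: MeasurementModel,
    x_true: np.ndarray,
    input_snr_db: float = 30.0,
    noise_seed: int = 0,
    epsilon: Optional[float] = None,
) -> Measurements:
    """Simulate ``y = Phi x_true + w`` at an exact input SNR.

    The Gaussian noise draw is rescaled so that
    ``20 log10(||Phi x_true|| / ||w||) = input_snr_db`` holds exactly for
    the realization; ``epsilon`` defaults to the realized ``||w||_2``
    (the oracle noise bound).  ``input_snr_db = inf`` gives noiseless data,
    in which case an explicit ``epsilon`` must be supplied for any
    constrained solve (stored bound defaults to a tiny positive number).
    """
    x_true = np.asarray(x_true, dtype=float).ravel()
    y_clean = m.forward(x_true)
    if np.any(x_true < 0):
        import warnings

        warnings.warn("x_true has negative entries; the imaging model assumes "
                      "nonnegative intensities", stacklevel=2)
    if np.isinf(input_snr_db):
        eps = epsilon if epsilon is not None else 1e-12
        return Measurements(y=y_clean, epsilon=eps,
                            input_snr_db=float("inf"), noise_seed=noise_seed)
    rng = np.random.default_rng(noise_seed)
    w = rng.standard_normal(y_clean.size)
    target = np.linalg.norm(y_clean) * 10.0 ** (-input_snr_db / 20.0)
    w *= target / np.linalg.norm(w)
    eps = float(np.linalg.norm(w)) if epsilon is None else float(epsilon)
    return Measurements(
        y=y_clean + w, epsilon=eps,
        input_snr_db=float(input_snr_db), noise_seed=noise_seed,
    )


def epsilon_chi2(sigma: float, m: int) -> float:
    """Chi-square upper bound ``sigma * sqrt(M + 2 sqrt(2M))`` for unknown noise.

    Two standard deviations above the mean of the chi-square with M degrees
    of freedom; use when the noise std is known but the realization is not.
    """
    return float(sigma * np.sqrt(m + 2.0 * np.sqrt(2.0 * m)))


def save_pattern_set(p: PatternSet, stem: Path | str) -> None:
    """Write ``<stem>.npy`` (M x H x W float64) + ``<stem>.json`` sidecar."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), p.patterns)
    meta = {
        "core_grid": list(p.core_grid),
        "rotations": list(p.rotations),
        "seed": p.seed,
        "normalization": p.normalization,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_pattern_set(stem: Path | str) -> PatternSet:
    stem = Path(stem)
    patterns = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return PatternSet(
        patterns=patterns,
        core_grid=tuple(meta["core_grid"]),
        rotations=list(meta["rotations"]),
        seed=int(meta["seed"]),
        normalization=meta.get("normalization", "energy"),
    )
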