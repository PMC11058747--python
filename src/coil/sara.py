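"""Sparsity-averaging (SARA) dictionary and proximity/projection operators.

The SARA prior measures sparsity in the concatenation of the first eight
orthonormal Daubechies wavelet bases (db1..db8) and the Dirac (identity)
basis.  With each sub-transform scaled by 1/3 the stacked analysis operator
``Psi`` is a Parseval tight frame: ``Psi^T Psi = Id``, so the coefficient
vector has length ``S = 9 N`` and synthesis inverts analysis exactly.

The reweighted-l1 scheme approximates a log-sum penalty
``sum_s log(|v_s| + alpha)`` by solving a sequence of weighted-l1 problems
whose weights ``delta_s = alpha / (alpha + |v_s|)`` are refreshed from the
current coefficient estimate (the standard majorize-minimize weight for the
log-sum function).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt

__all__ = [
    "SaraDictionary",
    "WeightMatrix",
    "build_sara_dictionary",
    "update_weights",
    "project_l2_ball",
    "project_nonneg",
    "prox_weighted_l1",
]

_DAUBECHIES = ["db1", "db2", "db3", "db4", "db5", "db6", "db7", "db8"]


@dataclass
class SaraDictionary:
    """Analysis/synthesis pair for the 9-basis SARA frame.

    ``analysis`` maps an image vector of length ``N`` to a coefficient
    vector of length ``S = 9 N`` (eight wavelet blocks followed by the
    Dirac block, each scaled by 1/3); ``synthesis`` is its transpose.
    """

    image_size: tuple[int, int]
    levels: int
    bases: list[str]
    frame_constant: float
    analysis: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    synthesis: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    _slices: list = field(default=None, repr=False)

    @property
    def n_pixels(self) -> int:
        return self.image_size[0] * self.image_size[1]

    @property
    def n_coeffs(self) -> int:
        return len(self.bases) * self.n_pixels

    _dense: np.ndarray = field(default=None, repr=False)

    def to_dense(self) -> np.ndarray:
        """Materialize Psi as an ``S x N`` matrix (small images only)."""
        if self._dense is not None:
            return self._dense
        n = self.n_pixels
        if n > 4096:
            raise ValueError("dense Psi only supported for N <= 4096")
        out = np.empty((self.n_coeffs, n))
        e = np.zeros(n)
        for j in range(n):
            e[j] = 1.0
            out[:, j] = self.analysis(e)
            e[j] = 0.0
        self._dense = out
        return out

    def densify(self) -> "SaraDictionary":
        """Swap analysis/synthesis for cached dense-matrix products.

        Worth it for small images where BLAS matvecs beat repeated wavelet
        transforms inside iterative solvers; a no-op on the math.
        """
        mat = self.to_dense()
        self.analysis = lambda x: mat @ np.asarray(x, dtype=float).ravel()
        self.synthesis = lambda v: mat.T @ np.asarray(v, dtype=float).ravel()
        return self


@dataclass
class WeightMatrix:
    """Diagonal of the weight matrix used by the weighted-l1 subproblem."""

    delta: np.ndarray
    alpha: float

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if np.any(self.delta <= 0) or np.any(self.delta > 1):
            raise ValueError("weights must lie in (0, 1]")


def build_sara_dictionary(
    image_size: tuple[int, int], levels: int = 4, dense: bool | None = None
) -> SaraDictionary:
    """Build the tight-frame SARA dictionary for ``image_size`` images.

    Each side of the image must be divisible by ``2**levels`` so the
    decimated periodized wavelet transforms are orthonormal with exactly
    ``N`` coefficients per basis.  ``dense`` switches the operator to a
    cached dense matrix (default: automatic for N <= 1024, where it is
    much faster inside iterative solvers).
    """
    h, w = int(image_size[0]), int(image_size[1])
    if levels < 1:
        raise ValueError("levels must be >= 1")
    d = 2 ** levels
    if h % d or w % d:
        raise ValueError(
            f"image size {h}x{w} is not divisible by 2^levels={d}; "
            "reduce levels or pad the image"
        )
    n = h * w
    scale = 1.0 / 3.0

    def _wavedec(img, name):
        # Periodized orthonormal DWT stays orthogonal at any depth; silence
        # pywt's boundary-effect warning for deep levels on small images.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return pywt.wavedec2(img, name, mode="periodization", level=levels)

    # Pre-compute coefficient layouts once; they are identical across calls.
    slices = []
    probe = np.zeros((h, w))
    for name in _DAUBECHIES:
        _, sl = pywt.coeffs_to_array(_wavedec(probe, name))
        slices.append(sl)

    def analysis(x: np.ndarray) -> np.ndarray:
        img = np.asarray(x, dtype=float).reshape(h, w)
        out = np.empty(9 * n)
        for i, name in enumerate(_DAUBECHIES):
            arr, _ = pywt.coeffs_to_array(_wavedec(img, name))
            out[i * n:(i + 1) * n] = scale * arr.ravel()
        out[8 * n:] = scale * img.ravel()
        return out

    def synthesis(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.size != 9 * n:
            raise ValueError(f"expected coefficient vector of length {9 * n}")
        acc = np.zeros((h, w))
        for i, name in enumerate(_DAUBECHIES):
            arr = v[i * n:(i + 1) * n].reshape(h, w)
            coeffs = pywt.array_to_coeffs(arr, slices[i], output_format="wavedec2")
            acc += pywt.waverec2(coeffs, name, mode="periodization")
        acc += v[8 * n:].reshape(h, w)
        return (scale * acc).ravel()

    out = SaraDictionary(
        image_size=(h, w),
        levels=levels,
        bases=list(_DAUBECHIES) + ["dirac"],
        frame_constant=1.0,
        analysis=analysis,
        synthesis=synthesis,
        _slices=slices,
    )
    if dense is None:
        dense = n <= 1024
    if dense:
        out.densify()
    return out


def update_weights(coeffs: np.ndarray, alpha: float) -> WeightMatrix:
    """Log-sum majorize-minimize weights ``delta_s = alpha/(alpha+|v_s|)``.

    With ``coeffs = 0`` every weight is 1, so the first reweighting pass
    solves the plain (unweighted) l1 problem.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    coeffs = np.asarray(coeffs, dtype=float)
    return WeightMatrix(delta=alpha / (alpha + np.abs(coeffs)), alpha=float(alpha))


def project_l2_ball(u: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection onto the ball ``{z : ||z - center|| <= radius}``."""
    if not radius > 0:
        raise ValueError("radius must be > 0")
    u = np.asarray(u, dtype=float)
    center = np.asarray(center, dtype=float)
    if u.shape != center.shape:
        raise ValueError("u and center must have equal length")
    d = u - center
    nrm = np.linalg.norm(d)
    if nrm <= radius:
        return u.copy()
    return center + (radius / nrm) * d


def project_nonneg(x: np.ndarray) -> np.ndarray:
    """Projection onto the nonnegative orthant (elementwise clamp at 0)."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def prox_weighted_l1(v: np.ndarray, weights: WeightMatrix, threshold: float) -> np.ndarray:
    """Proximity operator of ``threshold * sum_s delta_s |v_s|``.

    Elementwise soft-thresholding at ``threshold * delta_s``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    v = np.asarray(v, dtype=float)
    t = threshold * weights.delta
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)
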