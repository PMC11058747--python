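"""Synthetic inputs: geometric phantoms, training patches, oracle instances.

Everything here is generated programmatically and is bitwise-deterministic
per seed.  Phantoms are piecewise-constant compositions of crosses, dots,
bars and polygons on a dark background in [0, 255] — the same family of
targets as the real cross/dots objects imaged through the fiber — so they
are genuinely sparse in the wavelet dictionary the SARA prior uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, polygon

from .oracles import OracleSolution, admm_constrained_l1
from .patterns import (
    MeasurementModel,
    Measurements,
    build_measurement_model,
    generate_speckle_patterns,
    simulate_measurements,
)
from .sara import build_sara_dictionary

__all__ = [
    "PhantomSet",
    "OracleInstance",
    "generate_geometric_phantoms",
    "generate_training_patches",
    "make_oracle_instance",
]


@dataclass
class PhantomSet:
    """Grayscale geometric phantoms in [0, 255]."""

    images: np.ndarray  # (n, H, W)
    kinds: list[list[str]]
    seed: int

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)


def _draw_shape(img: np.ndarray, kind: str, rng: np.random.Generator) -> None:
    h, w = img.shape
    val = rng.uniform(100, 255)
    cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
    if kind == "dots":
        for _ in range(rng.integers(2, 5)):
            r = rng.uniform(0.03, 0.08) * min(h, w)
            yy, xx = disk((rng.uniform(0.15, 0.85) * h, rng.uniform(0.15, 0.85) * w),
                          r, shape=img.shape)
            img[yy, xx] = rng.uniform(100, 255)
    elif kind == "cross":
        th = max(1, int(rng.uniform(0.04, 0.1) * min(h, w)))
        half = int(rng.uniform(0.15, 0.35) * min(h, w))
        y0, y1 = int(max(cy - half, 0)), int(min(cy + half, h))
        x0, x1 = int(max(cx - half, 0)), int(min(cx + half, w))
        img[y0:y1, int(cx) - th // 2:int(cx) + (th + 1) // 2] = val
        img[int(cy) - th // 2:int(cy) + (th + 1) // 2, x0:x1] = val
    elif kind == "bars":
        for _ in range(rng.integers(1, 4)):
            th = max(1, int(rng.uniform(0.04, 0.12) * h))
            y0 = rng.integers(0, max(h - th, 1))
            x0 = rng.integers(0, w // 2)
            x1 = rng.integers(w // 2, w)
            img[y0:y0 + th, x0:x1] = rng.uniform(100, 255)
    elif kind == "polygon":
        k = rng.integers(3, 7)
        ang = np.sort(rng.uniform(0, 2 * np.pi, k))
        rad = rng.uniform(0.1, 0.3) * min(h, w)
        yy, xx = polygon(cy + rad * np.sin(ang), cx + rad * np.cos(ang),
                         shape=img.shape)
        img[yy, xx] = val
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unknown shape kind {kind!r}")


_KINDS = ("cross", "dots", "bars", "polygon")


def generate_geometric_phantoms(
    n: int = 50, size: tuple[int, int] = (64, 64), seed: int = 0
) -> PhantomSet:
    """Seeded compositions of crosses, dots, bars and polygons on black."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = int(size[0]), int(size[1])
    images = np.zeros((n, h, w))
    kinds: list[list[str]] = []
    for i in range(n):
        img = np.full((h, w), rng.uniform(0, 15))
        chosen = list(rng.choice(_KINDS, size=rng.integers(1, 4), replace=True))
        for kind in chosen:
            _draw_shape(img, kind, rng)
        images[i] = np.clip(img, 0, 255)
        kinds.append(chosen)
    return PhantomSet(images=images, kinds=kinds, seed=int(seed))


def generate_training_patches(
    n: int = 2000, patch_size: int = 64, seed: int = 0
) -> np.ndarray:
    """Mixture corpus of clean patches in [0, 255] for denoiser training.

    Three families in roughly equal proportion: smoothed Gaussian random
    fields (soft intensity gradients), geometric-shape patches (edges and
    flat regions), and oriented sinusoidal textures with mild smooth
    background.  The mixture keeps the corpus mean mid-grey and the
    contrast non-degenerate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = int(patch_size)
    out = np.empty((n, p, p))
    yy, xx = np.meshgrid(np.arange(p), np.arange(p), indexing="ij")
    for i in range(n):
        fam = i % 3
        if fam == 0:
            f = gaussian_filter(rng.standard_normal((p, p)), rng.uniform(2, 6))
            f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
            lo, hi = rng.uniform(10, 90), rng.uniform(150, 245)
            out[i] = lo + (hi - lo) * f
        elif fam == 1:
            img = np.full((p, p), rng.uniform(20, 110))
            for kind in rng.choice(_KINDS, size=rng.integers(1, 3)):
                _draw_shape(img, kind, rng)
            out[i] = np.clip(img, 0, 255)
        else:
            freq = rng.uniform(0.05, 0.35)
            theta = rng.uniform(0, np.pi)
            grating = np.sin(2 * np.pi * freq * (np.cos(theta) * xx + np.sin(theta) * yy))
            backg = gaussian_filter(rng.standard_normal((p, p)), 4.0)
            backg = backg / max(np.abs(backg).max(), 1e-12)
            amp = rng.uniform(30, 80)
            out[i] = np.clip(127.5 + amp * grating + 25.0 * backg, 0, 255)
    return out


@dataclass
class OracleInstance:
    """Small dense problem instance with a cached reference solution."""

    dense_phi: np.ndarray
    x_true: np.ndarray
    y: np.ndarray
    epsilon: float
    image_size: tuple[int, int]
    seed: int
    model: MeasurementModel = field(repr=False, default=None)
    measurements: Measurements = field(repr=False, default=None)
    solution_cache: Optional[OracleSolution] = field(repr=False, default=None)

    def solve_oracle(self, psi_dense: Optional[np.ndarray] = None,
                     **kwargs) -> OracleSolution:
        """ADMM reference solution of the unit-weight constrained problem.

        Deterministic, so repeated calls with the same instance reproduce
        the cache bit-identically.
        """
        if self.solution_cache is None:
            if psi_dense is None:
                side = min(self.image_size)
                levels = max(1, min(4, int(np.log2(side))))
                psi_dense = build_sara_dictionary(
                    self.image_size, levels=levels).to_dense()
            self.solution_cache = admm_constrained_l1(
                self.dense_phi, self.y, self.epsilon, psi=psi_dense,
                nonneg=True, **kwargs)
        return self.solution_cache


def make_oracle_instance(
    m: int,
    image_size: tuple[int, int] = (16, 16),
    input_snr_db: float = 30.0,
    seed: int = 0,
) -> OracleInstance:
    """Dense synthetic instance: speckle patterns, sparse phantom, noisy data.

    The measurement count ``m`` is realized as an approximately square core
    grid with one rotation; epsilon is the realized noise norm.
    """
    h, w = int(image_size[0]), int(image_size[1])
    n = h * w
    if m * n > 100_000:
        raise ValueError("instance too large to stay dense-solvable (m*N > 1e5)")
    rows = int(np.floor(np.sqrt(m)))
    while m % rows:
        rows -= 1
    cols = m // rows
    pset = generate_speckle_patterns((rows, cols), (h, w), n_rotations=1,
                                     seed=seed, correlation_length=1.5)
    model = build_measurement_model(pset)
    phantom = generate_geometric_phantoms(1, (h, w), seed=seed + 1).images[0]
    x_true = phantom.ravel()
    meas = simulate_measurements(model, x_true, input_snr_db=input_snr_db,
                                 noise_seed=seed + 2)
    return OracleInstance(
        dense_phi=model.matrix, x_true=x_true, y=meas.y,
        epsilon=meas.epsilon, image_size=(h, w), seed=int(seed),
        model=model, measurements=meas,
    )
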