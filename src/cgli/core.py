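"""Shared field primitives for signed-pressure-force level-set evolution.

All grids are 2-D ``numpy`` arrays indexed row-major: axis 0 is y (rows),
axis 1 is x (columns), 0-based.  The level-set field ``phi`` (also called
``u`` in the evolution loop) shares the image grid; its zero level set is
the contour, and the convention throughout the package is

    phi > 0  <=>  inside the contour (object / vessel).

The contour is regularized not by signed-distance reinitialization but by
the selective-binary scheme: the field is snapped to {-rho, +rho} and
smoothed with a Gaussian kernel each iteration (see :mod:`cgli.evolution`).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

__all__ = [
    "DegeneratePartitionError",
    "ContourCollapseError",
    "TAU",
    "heaviside",
    "dirac",
    "gaussian_kernel",
    "smooth",
    "region_means",
    "initialize_level_set",
]

#: Floor applied to every denominator / max-normalization.  Keeps flat
#: images from producing 0/0 while leaving ordinary inputs bit-unchanged.
TAU = 1e-12


class DegeneratePartitionError(ValueError):
    """One side of the contour has (numerically) vanished."""


class ContourCollapseError(DegeneratePartitionError):
    """The evolving contour collapsed mid-run: every pixel has one sign."""


def _as_field(z, name: str = "field") -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError(f"{name} contains non-finite values")
    return z


def heaviside(z, epsilon: float = 0.5):
    """Regularized Heaviside H_eps(z) = (1 + (2/pi) arctan(z/eps)) / 2.

    Strictly increasing, H(0) = 1/2, and antisymmetric in the sense
    H(-z) = 1 - H(z).  Values lie in the open interval (0, 1) for finite z.

    Parameters
    ----------
    z : array_like or float
        Level-set values.
    epsilon : float
        Smoothness scale of the transition (> 0).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    z = _as_field(z, "z")
    out = 0.5 * (1.0 + (2.0 / math.pi) * np.arctan(z / epsilon))
    return float(out) if out.ndim == 0 else out


def dirac(z, epsilon: float = 0.5):
    """Regularized Dirac delta, the derivative of :func:`heaviside`.

    delta_eps(z) = (1/pi) * eps / (eps^2 + z^2); even in z, maximal at 0,
    integrating to 1 over the real line.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    z = _as_field(z, "z")
    out = (epsilon / math.pi) / (epsilon**2 + z**2)
    return float(out) if out.ndim == 0 else out


def gaussian_kernel(sigma: float, radius: int | None = None) -> np.ndarray:
    """Discrete normalized 2-D Gaussian K_sigma, truncated at ``radius``.

    The kernel is sampled on an integer grid, truncated at
    ``radius = ceil(2 * sigma)`` by default, and normalized to unit sum so
    that convolving a constant field returns it exactly.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius is None:
        radius = math.ceil(2.0 * sigma)
    if radius < 1:
        raise ValueError("radius must be a positive integer")
    x = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k2 = np.outer(k1, k1)
    return k2 / k2.sum()


def smooth(field: np.ndarray, sigma: float, radius: int | None = None) -> np.ndarray:
    """Convolve a 2-D field with K_sigma, replicating edge values.

    Replicate (nearest) padding avoids artificial dark borders biasing the
    local fitting fields near the image rim / FOV boundary.
    """
    field = _as_field(field)
    if field.ndim != 2:
        raise ValueError("expected a 2-D field")
    return ndimage.convolve(field, gaussian_kernel(sigma, radius), mode="nearest")


def region_means(img: np.ndarray, phi: np.ndarray, epsilon: float = 0.5):
    """Heaviside-weighted mean intensities inside/outside the contour.

    Returns ``(c1, c2)`` with

        c1 = sum(I * H(phi)) / sum(H(phi))        (inside,  phi > 0)
        c2 = sum(I * (1-H(phi))) / sum(1-H(phi))  (outside, phi < 0)

    Both means are convex combinations of image values and therefore lie in
    ``[img.min(), img.max()]``.

    Raises
    ------
    DegeneratePartitionError
        If the smoothed Heaviside mass on either side vanishes.
    """
    img = _as_field(img, "img")
    phi = _as_field(phi, "phi")
    if img.shape != phi.shape:
        raise ValueError(f"shape mismatch: img {img.shape} vs phi {phi.shape}")
    h = heaviside(phi, epsilon)
    m1 = h.sum()
    m2 = (1.0 - h).sum()
    if m1 < TAU or m2 < TAU:
        raise DegeneratePartitionError(
            "one side of the contour carries no Heaviside mass"
        )
    c1 = float((img * h).sum() / m1)
    c2 = float((img * (1.0 - h)).sum() / m2)
    return c1, c2


def initialize_level_set(mask: np.ndarray, rho: float = 1.0) -> np.ndarray:
    """Binary level-set initialization: +rho inside the mask, -rho outside.

    No signed distance function is involved: the selective-binary
    regularization used during evolution only ever needs the sign and a
    bounded magnitude.

    Raises
    ------
    DegeneratePartitionError
        If the mask is all-true or all-false (no contour to evolve).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if rho <= 0:
        raise ValueError("rho must be positive")
    mask = mask.astype(bool)
    if mask.all() or not mask.any():
        raise DegeneratePartitionError(
            "initialization mask must contain both interior and exterior pixels"
        )
    return np.where(mask, float(rho), -float(rho))
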