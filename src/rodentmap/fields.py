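"""Stationary Gaussian random-field simulators used by the synthetic scenes
and by the spatial-statistics recovery tests.

Two generators are provided: a cheap smoothed-white-noise field (Gaussian
autocorrelation, used for habitat patch structure and nuisance covariates)
and an exact circulant-embedding sampler for fields with exponential
covariance (used when the true correlation length must be known analytically,
e.g. for variogram-recovery experiments).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["smoothed_gaussian_field", "exponential_field"]


def smoothed_gaussian_field(
    shape: tuple[int, int],
    smoothing_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """White noise convolved with a Gaussian kernel, re-standardised to
    zero mean and unit variance.

    ``smoothing_px`` is the kernel sigma in pixels; 0 returns plain i.i.d.
    standard-normal noise.
    """
    z = rng.standard_normal(shape)
    if smoothing_px > 0:
        z = ndimage.gaussian_filter(z, sigma=smoothing_px, mode="wrap")
        z = (z - z.mean()) / z.std()
    return z


def exponential_field(
    shape: tuple[int, int],
    correlation_length_px: float,
    rng: np.random.Generator,
    variance: float = 1.0,
) -> np.ndarray:
    """Sample a stationary Gaussian field with covariance
    ``C(h) = variance * exp(-h / a)`` (h in pixels, a = correlation_length_px)
    by circulant embedding on a doubled torus.

    The corresponding semivariogram is ``gamma(h) = variance * (1 - e^(-h/a))``
    with effective range (95 % of sill) ``3 a``.
    """
    if correlation_length_px <= 0:
        return rng.standard_normal(shape) * np.sqrt(variance)
    ny, nx = shape
    # Embed on a torus large enough that wrap-around correlation is negligible.
    m, n = 2 * ny, 2 * nx
    iy = np.minimum(np.arange(m), m - np.arange(m))
    ix = np.minimum(np.arange(n), n - np.arange(n))
    h = np.hypot(iy[:, None], ix[None, :])
    cov = variance * np.exp(-h / correlation_length_px)
    lam = np.fft.fft2(cov).real
    # Tiny negative eigenvalues from imperfect embedding are clipped; for the
    # exponential kernel at these sizes they are at round-off level.
    lam = np.clip(lam, 0.0, None)
    noise = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
    f = np.fft.fft2(noise * np.sqrt(lam / (m * n)))
    return f.real[:ny, :nx]
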