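"""Edge-preserving smoothers: ILS, rolling guidance, and their hybrid.

ILS minimises  sum (u - f)^2 + lam * sum phi_p(grad u)  with the concave
penalty phi_p(x) = (x^2 + eps)^(p/2), 0 < p < 1, by iterating a
half-quadratic surrogate: each step computes the auxiliary gradient
field mu from the current solution and solves one screened-Poisson-like
least-squares problem in the Fourier domain (periodic boundaries).

The rolling guidance filter (RGF) is an iterated joint bilateral filter
that removes structures smaller than sigma_s while its rolling update of
the guidance image recovers large-scale edges.

The hybrid RGF-ILS runs the ILS iteration but regularises the gradient
fields through the RGF before forming mu, so fine texture no longer
feeds the edge-preservation term and is smoothed away while genuine
edges (large, RGF-surviving gradients) are kept.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import ndimage

from .config import ILSConfig, RGFConfig
from .decompose import kernel_spectrum

__all__ = ["ils_smooth", "ils_energy", "rgf", "rgf_ils_smooth"]


def _grad_spectra(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    kx = kernel_spectrum(np.array([[-1.0, 1.0]]), shape)
    ky = kernel_spectrum(np.array([[-1.0], [1.0]]), shape)
    return kx, ky


def _spectral_grad(u_hat: np.ndarray, k: np.ndarray) -> np.ndarray:
    return np.real(np.fft.ifft2(u_hat * k))


def _mu(grad: np.ndarray, cfg: ILSConfig) -> np.ndarray:
    # derivative-matching auxiliary variable of the half-quadratic split
    return (cfg.c * grad
            - cfg.p * grad * (grad ** 2 + cfg.epsilon) ** (cfg.p / 2.0 - 1.0))


def _ils_iterations(f: np.ndarray, cfg: ILSConfig,
                    grad_hook: Callable[[np.ndarray], np.ndarray] | None,
                    ) -> np.ndarray:
    kx, ky = _grad_spectra(f.shape)
    denom = 1.0 + cfg.c * cfg.lam / 2.0 * (np.abs(kx) ** 2 + np.abs(ky) ** 2)
    f_hat = np.fft.fft2(f)
    u = f.copy()
    for _ in range(cfg.n_iter):
        u_hat = np.fft.fft2(u)
        gx = _spectral_grad(u_hat, kx)
        gy = _spectral_grad(u_hat, ky)
        if grad_hook is not None:
            gx = grad_hook(gx)
            gy = grad_hook(gy)
        mux_hat = np.fft.fft2(_mu(gx, cfg))
        muy_hat = np.fft.fft2(_mu(gy, cfg))
        numer = f_hat + cfg.lam / 2.0 * (np.conj(kx) * mux_hat
                                         + np.conj(ky) * muy_hat)
        u = np.real(np.fft.ifft2(numer / denom))
    return u


def ils_smooth(f: np.ndarray, cfg: ILSConfig | None = None) -> np.ndarray:
    """Iterative least-squares edge-preserving smoothing of ``f``."""
    cfg = cfg or ILSConfig()
    cfg.validate()
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("input contains non-finite pixels")
    return _ils_iterations(f, cfg, None)


def ils_energy(u: np.ndarray, f: np.ndarray, cfg: ILSConfig) -> float:
    """Value of the ILS objective at ``u`` (periodic gradients)."""
    kx, ky = _grad_spectra(f.shape)
    u_hat = np.fft.fft2(u)
    gx = _spectral_grad(u_hat, kx)
    gy = _spectral_grad(u_hat, ky)
    phi = ((gx ** 2 + cfg.epsilon) ** (cfg.p / 2.0)
           + (gy ** 2 + cfg.epsilon) ** (cfg.p / 2.0))
    return float(np.sum((u - f) ** 2) + cfg.lam * np.sum(phi))


def _disk_offsets(radius: float) -> list[tuple[int, int]]:
    r = int(np.ceil(radius))
    offsets = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dy * dy + dx * dx <= radius * radius:
                offsets.append((dy, dx))
    return offsets


def _joint_bilateral(image: np.ndarray, guide: np.ndarray,
                     cfg: RGFConfig) -> np.ndarray:
    """One joint bilateral pass; neighbourhoods truncate at the frame."""
    h, w = image.shape
    num = np.zeros_like(image)
    den = np.zeros_like(image)
    inv_2ss = 1.0 / (2.0 * cfg.sigma_s ** 2)
    inv_sr2 = 1.0 / cfg.sigma_r ** 2
    for dy, dx in _disk_offsets(2.0 * cfg.sigma_s):
        ty0, ty1 = max(0, -dy), h - max(0, dy)
        tx0, tx1 = max(0, -dx), w - max(0, dx)
        if ty0 >= ty1 or tx0 >= tx1:
            continue
        sy0, sy1 = ty0 + dy, ty1 + dy
        sx0, sx1 = tx0 + dx, tx1 + dx
        diff = guide[ty0:ty1, tx0:tx1] - guide[sy0:sy1, sx0:sx1]
        wgt = np.exp(-(dy * dy + dx * dx) * inv_2ss - diff * diff * inv_sr2)
        num[ty0:ty1, tx0:tx1] += wgt * image[sy0:sy1, sx0:sx1]
        den[ty0:ty1, tx0:tx1] += wgt
    return num / den


def rgf(image: np.ndarray, cfg: RGFConfig | None = None) -> np.ndarray:
    """Rolling guidance filtering of ``image``.

    The guidance starts as a Gaussian blur of the input (scale sigma_s)
    and each of the ``eta`` iterations joint-bilateral-filters the
    original input against the current guidance.  ``eta = 0`` is the
    identity.
    """
    cfg = cfg or RGFConfig()
    cfg.validate()
    image = np.asarray(image, dtype=float)
    if cfg.eta == 0:
        return image.copy()
    guide = ndimage.gaussian_filter(image, cfg.sigma_s, mode="nearest")
    for _ in range(cfg.eta):
        guide = _joint_bilateral(image, guide, cfg)
    return guide


def rgf_ils_smooth(f: np.ndarray, ils: ILSConfig | None = None,
                   rgf_cfg: RGFConfig | None = None) -> np.ndarray:
    """Hybrid smoother: ILS with RGF-regularised gradient fields.

    Identical to :func:`ils_smooth` when ``rgf_cfg.eta == 0``.
    """
    ils = ils or ILSConfig()
    rgf_cfg = rgf_cfg or RGFConfig()
    ils.validate()
    rgf_cfg.validate()
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("input contains non-finite pixels")
    hook = None if rgf_cfg.eta == 0 else (lambda g: rgf(g, rgf_cfg))
    return _ils_iterations(f, ils, hook)
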