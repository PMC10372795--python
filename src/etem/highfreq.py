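"""High-frequency subband fusion by gradient-difference / entropy saliency.

The detail bands are fused pixelwise by a winner-take-all rule driven by
a saliency operator.  The default operator GE combines, per pixel, the
local-window maximum of the detail-band gradient magnitude with a local
contrast term from the source image amplified by the Shannon entropy of
the gradient magnitudes in the window:

    GE(i,j) = locmax|grad f_h| * C / (max locmax|grad f_h| - min locmin|grad f_h|)
    C(i,j)  = (locmax f - locmin f) * exp(0.3 * locEntropy(|grad f_h|))

The global denominator rescales by the full gradient dynamic range of
the band; a flat band yields GE == 0.  Classic focus measures (energy of
Laplacian, sum-modified Laplacian, structure tensor) plug in through the
same operator interface for ablation studies.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .config import HighFusionConfig

__all__ = [
    "local_window_stats",
    "local_entropy",
    "gradient_magnitude",
    "ge_operator",
    "eol_operator",
    "sml_operator",
    "sto_operator",
    "saliency_operator",
    "fuse_high",
]


def local_window_stats(arr: np.ndarray, psi: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel max and min over a centred psi x psi replicate-padded window."""
    if psi % 2 == 0:
        raise ValueError("psi must be odd")
    arr = np.asarray(arr, dtype=float)
    size = (psi, psi)
    return (ndimage.maximum_filter(arr, size=size, mode="nearest"),
            ndimage.minimum_filter(arr, size=size, mode="nearest"))


def _windows(arr: np.ndarray, psi: int) -> np.ndarray:
    """(H, W, psi*psi) view of replicate-padded centred windows."""
    pad = psi // 2
    padded = np.pad(np.asarray(arr, dtype=float), pad, mode="edge")
    view = sliding_window_view(padded, (psi, psi))
    return view.reshape(arr.shape[0], arr.shape[1], psi * psi)


def local_entropy(grad_mag: np.ndarray, psi: int, bins: int) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) of windowed gradient magnitudes.

    Each psi x psi window is histogrammed into ``bins`` equal-width bins
    spanning that window's own [min, max] range; a constant window has a
    single occupied bin and entropy 0.
    """
    win = _windows(grad_mag, psi)
    lo = win.min(axis=2, keepdims=True)
    hi = win.max(axis=2, keepdims=True)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    idx = np.minimum((win - lo) / safe * bins, bins - 1).astype(np.int64)
    idx[np.broadcast_to(span == 0, idx.shape)] = 0

    h, w, m = win.shape
    flat = idx.reshape(-1, m) + np.arange(h * w)[:, None] * bins
    counts = np.bincount(flat.ravel(), minlength=h * w * bins)
    p = counts.reshape(h * w, bins) / m
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    return terms.sum(axis=1).reshape(h, w)


def gradient_magnitude(arr: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude with replicate borders."""
    padded = np.pad(np.asarray(arr, dtype=float), 1, mode="edge")
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    return np.hypot(gx, gy)


def ge_operator(high: np.ndarray, source: np.ndarray,
                cfg: HighFusionConfig | None = None) -> np.ndarray:
    """Gradient-difference + entropy saliency of one detail band."""
    cfg = cfg or HighFusionConfig()
    cfg.validate()
    high = np.asarray(high, dtype=float)
    source = np.asarray(source, dtype=float)
    if high.shape != source.shape:
        raise ValueError("detail band and source shapes differ")

    grad = gradient_magnitude(high)
    gmax, gmin = local_window_stats(grad, cfg.psi)
    denom = float(gmax.max() - gmin.min())
    if denom == 0.0:
        return np.zeros_like(high)

    smax, smin = local_window_stats(source, cfg.psi)
    entropy = local_entropy(grad, cfg.psi, cfg.entropy_bins)
    contrast = (smax - smin) * np.exp(0.3 * entropy)
    return gmax * contrast / denom


def eol_operator(high: np.ndarray, source: np.ndarray,
                 cfg: HighFusionConfig | None = None,
                 window: int = 5) -> np.ndarray:
    """Energy of Laplacian: windowed sum of squared Laplacian responses."""
    high = np.asarray(high, dtype=float)
    lap = ndimage.laplace(high, mode="nearest")
    return ndimage.uniform_filter(lap ** 2, size=window, mode="nearest") * window ** 2


def sml_operator(high: np.ndarray, source: np.ndarray,
                 cfg: HighFusionConfig | None = None,
                 window: int = 5) -> np.ndarray:
    """Sum-modified Laplacian: |d2/dx2| + |d2/dy2|, window-summed."""
    padded = np.pad(np.asarray(high, dtype=float), 1, mode="edge")
    ml = (np.abs(2 * padded[1:-1, 1:-1] - padded[1:-1, :-2] - padded[1:-1, 2:])
          + np.abs(2 * padded[1:-1, 1:-1] - padded[:-2, 1:-1] - padded[2:, 1:-1]))
    return ndimage.uniform_filter(ml, size=window, mode="nearest") * window ** 2


def sto_operator(high: np.ndarray, source: np.ndarray,
                 cfg: HighFusionConfig | None = None,
                 sigma: float = 1.0) -> np.ndarray:
    """Structure-tensor trace: Gaussian-pooled squared gradient energy."""
    high = np.asarray(high, dtype=float)
    padded = np.pad(high, 1, mode="edge")
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    jxx = ndimage.gaussian_filter(gx * gx, sigma, mode="nearest")
    jyy = ndimage.gaussian_filter(gy * gy, sigma, mode="nearest")
    return jxx + jyy


_OPERATORS = {
    "GE": ge_operator,
    "EOL": eol_operator,
    "SML": sml_operator,
    "STO": sto_operator,
}


def saliency_operator(high: np.ndarray, source: np.ndarray,
                      cfg: HighFusionConfig) -> np.ndarray:
    """Dispatch to the configured saliency operator."""
    cfg.validate()
    return _OPERATORS[cfg.operator](high, source, cfg)


def fuse_high(highs: tuple[np.ndarray, np.ndarray],
              saliencies: tuple[np.ndarray, np.ndarray],
              ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Winner-take-all fusion of the two detail bands.

    Ties resolve to the first source, so the two binary maps always
    partition the frame.  Returns the fused band FH and the maps.
    """
    h1, h2 = (np.asarray(h, dtype=float) for h in highs)
    s1, s2 = saliencies
    if h1.shape != h2.shape or s1.shape != h1.shape or s2.shape != h1.shape:
        raise ValueError("shape mismatch in fuse_high")
    hmp1 = (s1 >= s2).astype(float)
    hmp2 = 1.0 - hmp1
    fh = h1 * hmp1 + h2 * hmp2
    return fh, (hmp1, hmp2)
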