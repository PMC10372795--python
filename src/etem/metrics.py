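"""Fusion-quality metrics.

All metrics operate on [0, 1] grayscale arrays of equal shape:

* Q_MI  — sum over the two sources of 2 * I(S; F) / (H(S) + H(F)) on
  256-bin joint histograms (information transferred into the fusion;
  equals 2 when F copies both sources exactly).
* Q_NCIE — nonlinear correlation information entropy: eigenvalues of
  the 3x3 nonlinear-correlation matrix of (A, B, F), with off-diagonal
  entries H(X) + H(Y) - H(X, Y) in base-256 entropies.
* AG — mean central-difference gradient magnitude of F.
* SF — spatial frequency sqrt(RF^2 + CF^2) from row/column first
  differences.
* PSNR — 10 log10(1 / mean MSE) against the average of the per-source
  MSEs (peak 1 on the unit scale).
* SSIM — structural similarity of F against each source, averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricsReport", "evaluate",
           "q_mi", "q_ncie", "average_gradient", "spatial_frequency",
           "psnr", "ssim_pair"]

_BINS = 256


@dataclass
class MetricsReport:
    q_mi: float
    q_ncie: float
    ag: float
    sf: float
    psnr: float
    ssim: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(img, dtype=float) * (_BINS - 1), 0,
                   _BINS - 1).astype(np.int64)


def _entropy(counts: np.ndarray, base: float) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def _joint_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    joint = np.bincount(x.ravel() * _BINS + y.ravel(),
                        minlength=_BINS * _BINS)
    return joint.reshape(_BINS, _BINS)


def q_mi(fused: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Normalised mutual information transferred from both sources."""
    f_q = _quantize(fused)
    total = 0.0
    for src in (a, b):
        s_q = _quantize(src)
        joint = _joint_counts(s_q, f_q)
        h_s = _entropy(joint.sum(axis=1), 2.0)
        h_f = _entropy(joint.sum(axis=0), 2.0)
        h_sf = _entropy(joint.ravel(), 2.0)
        mi = h_s + h_f - h_sf
        denom = h_s + h_f
        total += 2.0 * mi / denom if denom > 0 else 1.0
    return total


def _ncc(x: np.ndarray, y: np.ndarray) -> float:
    """Nonlinear correlation coefficient (base-256 entropies)."""
    joint = _joint_counts(x, y)
    h_x = _entropy(joint.sum(axis=1), 256.0)
    h_y = _entropy(joint.sum(axis=0), 256.0)
    h_xy = _entropy(joint.ravel(), 256.0)
    return h_x + h_y - h_xy


def q_ncie(fused: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Nonlinear correlation information entropy of (A, B, F)."""
    imgs = [_quantize(a), _quantize(b), _quantize(fused)]
    r = np.eye(3)
    for i in range(3):
        for j in range(i + 1, 3):
            r[i, j] = r[j, i] = _ncc(imgs[i], imgs[j])
    lam = np.clip(np.linalg.eigvalsh(r), 1e-12, None)
    frac = lam / 3.0
    return float(1.0 + np.sum(frac * np.log(frac) / np.log(256.0)))


def average_gradient(img: np.ndarray) -> float:
    img = np.asarray(img, dtype=float)
    padded = np.pad(img, 1, mode="edge")
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    return float(np.mean(np.hypot(gx, gy)))


def spatial_frequency(img: np.ndarray) -> float:
    img = np.asarray(img, dtype=float)
    rf = np.sqrt(np.mean(np.diff(img, axis=1) ** 2))
    cf = np.sqrt(np.mean(np.diff(img, axis=0) ** 2))
    return float(np.hypot(rf, cf))


def psnr(fused: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Peak SNR against the mean of the two per-source MSEs."""
    fused = np.asarray(fused, dtype=float)
    mse = 0.5 * (np.mean((fused - a) ** 2) + np.mean((fused - b) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(1.0 / mse))


def ssim_pair(fused: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    fused = np.asarray(fused, dtype=float)
    return float(np.mean([
        structural_similarity(np.asarray(s, dtype=float), fused,
                              data_range=1.0)
        for s in (a, b)]))


def evaluate(fused: np.ndarray, a: np.ndarray, b: np.ndarray) -> MetricsReport:
    """All fusion-quality metrics of ``fused`` against sources ``a, b``."""
    fused = np.asarray(fused, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (fused.shape == a.shape == b.shape):
        raise ValueError("metric inputs must share one shape")
    return MetricsReport(
        q_mi=q_mi(fused, a, b),
        q_ncie=q_ncie(fused, a, b),
        ag=average_gradient(fused),
        sf=spatial_frequency(fused),
        psnr=psnr(fused, a, b),
        ssim=ssim_pair(fused, a, b),
    )
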