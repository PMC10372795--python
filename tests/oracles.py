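"""Independent brute-force reference implementations.

Everything here is written as literal per-pixel loops or dense linear
algebra, deliberately sharing no code path with the package, so each
vectorised / spectral operation can be checked against a transcription
of its defining formula.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------- circulant

def _circulant_pair(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Dense matrices of circular convolution with [-1, 1] and its transpose.

    Matches the spectral convention: (k * f)[i, j] = -f[i, j] + f[i, j-1]
    for the horizontal kernel embedded at the origin.
    """
    n = h * w

    def idx(i: int, j: int) -> int:
        return (i % h) * w + (j % w)

    gx = np.zeros((n, n))
    gy = np.zeros((n, n))
    for i in range(h):
        for j in range(w):
            row = idx(i, j)
            gx[row, idx(i, j)] -= 1.0
            gx[row, idx(i, j - 1)] += 1.0
            gy[row, idx(i, j)] -= 1.0
            gy[row, idx(i - 1, j)] += 1.0
    return gx, gy


def dense_decompose_low(image: np.ndarray, beta: float) -> np.ndarray:
    """Low band via the materialised normal equations (periodic)."""
    h, w = image.shape
    gx, gy = _circulant_pair(h, w)
    system = np.eye(h * w) + beta * (gx.T @ gx + gy.T @ gy)
    return np.linalg.solve(system, image.ravel()).reshape(h, w)


def dense_ils_step(f: np.ndarray, p: float, epsilon: float,
                   lam: float) -> np.ndarray:
    """One ILS iteration from u0 = f via dense least squares."""
    h, w = f.shape
    gx, gy = _circulant_pair(h, w)
    c = p * epsilon ** (p / 2.0 - 1.0)
    u = f.ravel()
    rhs = u.copy()
    lhs = np.eye(h * w)
    for g in (gx, gy):
        grad = g @ u
        mu = c * grad - p * grad * (grad ** 2 + epsilon) ** (p / 2.0 - 1.0)
        rhs = rhs + lam / 2.0 * (g.T @ mu)
        lhs = lhs + c * lam / 2.0 * (g.T @ g)
    return np.linalg.solve(lhs, rhs).reshape(h, w)


# ------------------------------------------------------------ sliding window

def naive_window_stats(arr: np.ndarray, psi: int):
    h, w = arr.shape
    r = psi // 2
    mx = np.empty_like(arr, dtype=float)
    mn = np.empty_like(arr, dtype=float)
    for i in range(h):
        for j in range(w):
            vals = [arr[min(max(i + di, 0), h - 1),
                        min(max(j + dj, 0), w - 1)]
                    for di in range(-r, r + 1) for dj in range(-r, r + 1)]
            mx[i, j] = max(vals)
            mn[i, j] = min(vals)
    return mx, mn


def naive_local_entropy(arr: np.ndarray, psi: int, bins: int) -> np.ndarray:
    h, w = arr.shape
    r = psi // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            vals = [arr[min(max(i + di, 0), h - 1),
                        min(max(j + dj, 0), w - 1)]
                    for di in range(-r, r + 1) for dj in range(-r, r + 1)]
            lo, hi = min(vals), max(vals)
            counts = [0] * bins
            for v in vals:
                if hi == lo:
                    k = 0
                else:
                    k = min(int((v - lo) / (hi - lo) * bins), bins - 1)
                counts[k] += 1
            total = len(vals)
            ent = 0.0
            for cnt in counts:
                if cnt:
                    pk = cnt / total
                    ent -= pk * np.log2(pk)
            out[i, j] = ent
    return out


def naive_ge(high: np.ndarray, source: np.ndarray, psi: int,
             bins: int) -> np.ndarray:
    """Literal scalar transcription of the GE saliency operator."""
    h, w = high.shape
    padded = np.pad(high, 1, mode="edge")
    grad = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            gy = (padded[i + 2, j + 1] - padded[i, j + 1]) / 2.0
            gx = (padded[i + 1, j + 2] - padded[i + 1, j]) / 2.0
            grad[i, j] = np.hypot(gx, gy)
    gmax, gmin = naive_window_stats(grad, psi)
    denom = gmax.max() - gmin.min()
    if denom == 0:
        return np.zeros((h, w))
    smax, smin = naive_window_stats(source, psi)
    ent = naive_local_entropy(grad, psi, bins)
    return gmax * (smax - smin) * np.exp(0.3 * ent) / denom


def naive_consistency(m: np.ndarray, window: int) -> np.ndarray:
    h, w = m.shape
    r = window // 2
    out = np.zeros((h, w))
    half = window * window / 2.0
    for i in range(h):
        for j in range(w):
            total = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    total += m[min(max(i + di, 0), h - 1),
                               min(max(j + dj, 0), w - 1)]
            out[i, j] = 1.0 if total >= half else 0.0
    return out


# -------------------------------------------------------------- guided filter

def naive_guided_filter(guide: np.ndarray, src: np.ndarray, r: int,
                        eps: float) -> np.ndarray:
    """Windowed linear regression with frame-intersection windows."""
    h, w = guide.shape
    a = np.zeros((h, w))
    b = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            ys = slice(max(0, i - r), min(h, i + r + 1))
            xs = slice(max(0, j - r), min(w, j + r + 1))
            g = guide[ys, xs].ravel()
            s = src[ys, xs].ravel()
            mg, ms = g.mean(), s.mean()
            cov = (g * s).mean() - mg * ms
            var = (g * g).mean() - mg * mg
            a[i, j] = cov / (var + eps)
            b[i, j] = ms - a[i, j] * mg
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            ys = slice(max(0, i - r), min(h, i + r + 1))
            xs = slice(max(0, j - r), min(w, j + r + 1))
            out[i, j] = a[ys, xs].mean() * guide[i, j] + b[ys, xs].mean()
    return np.clip(out, 0.0, 1.0)


# -------------------------------------------------------------- random walker

def absorbing_chain_probability(guide: np.ndarray, y_a: np.ndarray,
                                y_b: np.ndarray, sigma: float) -> np.ndarray:
    """P(absorb at class A) via the fundamental matrix of the chain.

    Two virtual absorbing states attach to every pixel with the soft
    seed weights; transition probabilities normalise edge + seed
    weights per pixel; u = (I - Q)^{-1} r_A.
    """
    h, w = guide.shape
    n = h * w

    def idx(i, j):
        return i * w + j

    weight = np.zeros((n, n))
    for i in range(h):
        for j in range(w):
            for di, dj in ((0, 1), (1, 0)):
                ii, jj = i + di, j + dj
                if ii < h and jj < w:
                    wgt = np.exp(-((guide[i, j] - guide[ii, jj]) ** 2)
                                 / sigma ** 2)
                    weight[idx(i, j), idx(ii, jj)] = wgt
                    weight[idx(ii, jj), idx(i, j)] = wgt
    degree = weight.sum(axis=1)
    norm = degree + y_a.ravel() + y_b.ravel()
    q = weight / norm[:, None]
    r_a = y_a.ravel() / norm
    return np.linalg.solve(np.eye(n) - q, r_a).reshape(h, w)


# ----------------------------------------------------------------- bilateral

def naive_rgf_once(image: np.ndarray, sigma_s: float,
                   sigma_r: float) -> np.ndarray:
    """One rolling-guidance iteration by literal double loops."""
    guide = ndimage.gaussian_filter(image, sigma_s, mode="nearest")
    h, w = image.shape
    out = np.zeros((h, w))
    radius = 2.0 * sigma_s
    for i in range(h):
        for j in range(w):
            num = den = 0.0
            for ii in range(h):
                for jj in range(w):
                    d2 = (i - ii) ** 2 + (j - jj) ** 2
                    if d2 > radius * radius:
                        continue
                    wgt = np.exp(-d2 / (2 * sigma_s ** 2)
                                 - (guide[i, j] - guide[ii, jj]) ** 2
                                 / sigma_r ** 2)
                    num += wgt * image[ii, jj]
                    den += wgt
            out[i, j] = num / den
    return out


# ----------------------------------------------------------------- entropy/MI

def scalar_q_mi(fused: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Q_MI by explicit joint-count entropy arithmetic."""
    def quant(x):
        return np.clip(x * 255, 0, 255).astype(int)

    def ent(counts):
        total = counts.sum()
        out = 0.0
        for cnt in counts.ravel():
            if cnt:
                pk = cnt / total
                out -= pk * np.log2(pk)
        return out

    fq = quant(fused)
    total = 0.0
    for src in (a, b):
        sq = quant(src)
        joint = np.zeros((256, 256))
        for x, y in zip(sq.ravel(), fq.ravel()):
            joint[x, y] += 1
        h_s, h_f, h_sf = ent(joint.sum(1)), ent(joint.sum(0)), ent(joint)
        total += 2.0 * (h_s + h_f - h_sf) / (h_s + h_f)
    return total
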