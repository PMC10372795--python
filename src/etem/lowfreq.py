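"""Low-frequency (base band) fusion.

Energy information concentrates in the base bands, so fusion starts
from winner-take-all maps on pixel energy (LMP), on local-phase-
coherence sharpness of the base bands (SMP), and on the raw sources
(SLMP); SMP and SLMP merge into TLMP.  The first source's LMP and TLMP
are edge-aware smoothed by a guided filter, the two soft maps are
arbitrated by a seeded random walker on the image lattice (confident
pixels of either map act as soft seeds), a 9x9 consistency vote removes
isolated decisions, and the final binary map selects between the two
base bands.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .config import LowFusionConfig

__all__ = [
    "InitialMaps",
    "initial_maps",
    "guided_filter",
    "random_walk_combine",
    "consistency_filter",
    "fuse_low",
]


class InitialMaps(NamedTuple):
    lmp: tuple[np.ndarray, np.ndarray]
    smp: tuple[np.ndarray, np.ndarray]
    slmp: tuple[np.ndarray, np.ndarray]
    tlmp: tuple[np.ndarray, np.ndarray]


def _argmax_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binary partition maps; ties go to the first source."""
    first = (a >= b).astype(float)
    return first, 1.0 - first


def initial_maps(lows: tuple[np.ndarray, np.ndarray],
                 sources: tuple[np.ndarray, np.ndarray],
                 lpc_maps: tuple[np.ndarray, np.ndarray],
                 cfg: LowFusionConfig | None = None) -> InitialMaps:
    """Winner-take-all decision maps feeding the base-band fusion.

    ``tlmp_mode='literal'`` reproduces the selection rule exactly as
    stated (which reduces to the source-intensity map SLMP);
    ``'union'`` additionally claims pixels where the sharpness map SMP
    votes for a source, SMP taking priority on conflicts.
    """
    cfg = cfg or LowFusionConfig()
    cfg.validate()
    lmp = _argmax_pair(*lows)
    smp = _argmax_pair(*lpc_maps)
    slmp = _argmax_pair(*sources)
    if cfg.tlmp_mode == "literal":
        tlmp = slmp
    else:
        t1 = np.where(smp[0] + slmp[0] > 0, 1.0, 0.0)
        t1 = np.where(smp[1] == 1.0, 0.0, t1)  # SMP priority on conflict
        tlmp = (t1, 1.0 - t1)
    return InitialMaps(lmp=lmp, smp=smp, slmp=slmp, tlmp=tlmp)


def _box_mean(arr: np.ndarray, r: int) -> np.ndarray:
    """Mean over the (2r+1)^2 window intersected with the frame."""
    h, w = arr.shape
    ones = np.ones((h, w))
    pad = [(r + 1, r), (r + 1, r)]
    ii = np.cumsum(np.cumsum(np.pad(arr, pad), axis=0), axis=1)
    cc = np.cumsum(np.cumsum(np.pad(ones, pad), axis=0), axis=1)

    def window_sum(i: np.ndarray) -> np.ndarray:
        y0, y1 = slice(0, h), slice(2 * r + 1, h + 2 * r + 1)
        x0, x1 = slice(0, w), slice(2 * r + 1, w + 2 * r + 1)
        return i[y1, x1] - i[y0, x1] - i[y1, x0] + i[y0, x0]

    return window_sum(ii) / window_sum(cc)


def guided_filter(guide: np.ndarray, src: np.ndarray,
                  r: int = 5, eps: float = 0.3) -> np.ndarray:
    """Edge-aware smoothing of ``src`` under a local linear model on ``guide``.

    Per window, out = a * guide + b with a = cov(guide, src) /
    (var(guide) + eps); the per-pixel (a, b) are window-averaged.
    Output clipped to [0, 1].
    """
    guide = np.asarray(guide, dtype=float)
    src = np.asarray(src, dtype=float)
    if guide.shape != src.shape:
        raise ValueError("guide/src shape mismatch")
    mean_g = _box_mean(guide, r)
    mean_s = _box_mean(src, r)
    cov = _box_mean(guide * src, r) - mean_g * mean_s
    var = _box_mean(guide * guide, r) - mean_g * mean_g
    a = cov / (var + eps)
    b = mean_s - a * mean_g
    out = _box_mean(a, r) * guide + _box_mean(b, r)
    return np.clip(out, 0.0, 1.0)


def _seed_weights(gmp: np.ndarray, cfg: LowFusionConfig) -> np.ndarray:
    """Soft unary seeds: confident (extreme) map values anchor the walk."""
    y = np.zeros_like(gmp)
    hi = gmp > cfg.seed_high
    lo = gmp < cfg.seed_low
    y[hi] = gmp[hi]
    y[lo] = 1.0 - gmp[lo]
    return y


def _lattice_laplacian(guide: np.ndarray, sigma: float) -> sparse.csr_matrix:
    """Graph Laplacian of the 4-connected lattice with Gaussian affinities."""
    h, w = guide.shape
    n = h * w
    idx = np.arange(n).reshape(h, w)
    rows, cols, vals = [], [], []
    for (s0, s1) in (((slice(None), slice(0, -1)), (slice(None), slice(1, None))),
                     ((slice(0, -1), slice(None)), (slice(1, None), slice(None)))):
        a, b = idx[s0].ravel(), idx[s1].ravel()
        d = guide[s0].ravel() - guide[s1].ravel()
        wgt = np.exp(-(d ** 2) / sigma ** 2)
        rows.extend((a, b))
        cols.extend((b, a))
        vals.extend((wgt, wgt))
    adj = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    deg = sparse.diags(np.asarray(adj.sum(axis=1)).ravel())
    return (deg - adj).tocsr()


def random_walk_combine(gmp_a: np.ndarray, gmp_b: np.ndarray,
                        guide: np.ndarray,
                        cfg: LowFusionConfig | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Arbitrate two soft maps with a seeded random walker.

    Each pixel carries soft seed weights y_A, y_B derived from the
    confident values of the respective map; the absorption probability
    u at class A solves (L + diag(y_A + y_B)) u = y_A on the 4-connected
    lattice weighted by guide-intensity affinities.  Returns (M, u)
    where M picks GMP_A wherever u >= 0.5 and GMP_B elsewhere (the tie
    at exactly 0.5 — symmetric seeding — resolves to the first source,
    as every other tie in the pipeline does).
    """
    cfg = cfg or LowFusionConfig()
    cfg.validate()
    gmp_a = np.asarray(gmp_a, dtype=float)
    gmp_b = np.asarray(gmp_b, dtype=float)
    guide = np.asarray(guide, dtype=float)
    if not (gmp_a.shape == gmp_b.shape == guide.shape):
        raise ValueError("shape mismatch in random_walk_combine")

    y_a = _seed_weights(gmp_a, cfg)
    y_b = _seed_weights(gmp_b, cfg)
    total = y_a + y_b
    if not np.any(total > 0):
        warnings.warn("no random-walker seeds; falling back to first map",
                      stacklevel=2)
        return gmp_a.copy(), np.ones_like(gmp_a)

    lap = _lattice_laplacian(guide, cfg.rw_sigma)
    system = (lap + sparse.diags(total.ravel())).tocsc()
    lu = sparse.linalg.splu(system)
    rhs = y_a.ravel()
    u = lu.solve(rhs)
    u += lu.solve(rhs - system @ u)  # one refinement step: the system is
    # barely regularised where seeds are sparse, so polish the residual
    u = np.clip(u.reshape(guide.shape), 0.0, 1.0)
    # half-ulp slack so the symmetric-seeding tie (u == 0.5 up to solver
    # round-off) deterministically resolves to the first source
    m = np.where(u >= 0.5 - 1e-12, gmp_a, gmp_b)
    return m, u


def consistency_filter(m: np.ndarray, window: int = 9) -> np.ndarray:
    """Majority vote of ``m`` over a centred window (replicate padding).

    A pixel keeps the first source iff the window sum of the soft map
    reaches half the window area.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    m = np.asarray(m, dtype=float)
    pad = window // 2
    padded = np.pad(m, pad, mode="edge")
    sums = sliding_window_view(padded, (window, window)).sum(axis=(2, 3))
    return (sums >= window * window / 2.0).astype(float)


def fuse_low(lows: tuple[np.ndarray, np.ndarray],
             flmp: np.ndarray) -> np.ndarray:
    """Select the fused base band pixelwise by the final decision map."""
    l1, l2 = (np.asarray(x, dtype=float) for x in lows)
    flmp = np.asarray(flmp, dtype=float)
    if l1.shape != l2.shape or flmp.shape != l1.shape:
        raise ValueError("shape mismatch in fuse_low")
    return l1 * flmp + l2 * (1.0 - flmp)
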