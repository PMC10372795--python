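"""End-to-end fusion pipelines for grayscale and colour source pairs.

Grayscale flow: two-band decomposition of each source, saliency-driven
fusion of the detail bands, map-driven fusion of the base bands,
RGF-ILS filtering of the fused base band into an energy layer,
error-texture re-extraction and re-fusion, and the final sum
F = FH + FT + FL_bar.  Every intermediate is retained on the returned
:class:`FusionResult` so each stage can be inspected and tested.

Colour flow (functional + anatomical): the colour source converts to
YUV, its luminance fuses with the anatomical image through the
grayscale flow, and the untouched chrominance planes are recombined, so
the functional colour coding survives fusion exactly (up to the final
RGB clip).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import highfreq, lowfreq, texture
from .config import EtemConfig
from .decompose import decompose
from .lpc import build_bank, lpc_strength
from .smoothing import rgf_ils_smooth

__all__ = ["FusionResult", "fuse_gray", "fuse_color",
           "rgb_to_yuv", "yuv_to_rgb"]

logger = logging.getLogger(__name__)

# BT.601 full-range analog YUV: U, V rows derived exactly from the luma
# row (U = 0.492(B - Y), V = 0.877(R - Y)) so gray inputs have
# identically zero chroma
_KR, _KG, _KB = 0.299, 0.587, 0.114
_RGB_TO_YUV = np.array([
    [_KR, _KG, _KB],
    [0.492111 * -_KR, 0.492111 * -_KG, 0.492111 * (1.0 - _KB)],
    [0.877283 * (1.0 - _KR), 0.877283 * -_KG, 0.877283 * -_KB],
])
_YUV_TO_RGB = np.linalg.inv(_RGB_TO_YUV)


def rgb_to_yuv(rgb: np.ndarray) -> np.ndarray:
    return np.asarray(rgb, dtype=float) @ _RGB_TO_YUV.T


def yuv_to_rgb(yuv: np.ndarray) -> np.ndarray:
    return np.asarray(yuv, dtype=float) @ _YUV_TO_RGB.T


@dataclass
class FusionResult:
    """Fused image plus every named intermediate of the pipeline."""

    fused: np.ndarray           # F = FH + FT + FL_bar (unclipped)
    fh: np.ndarray              # fused detail band
    fl: np.ndarray              # fused base band
    fl_bar: np.ndarray          # RGF-ILS energy layer of fl
    ft: np.ndarray              # fused error texture
    initial_fusion: np.ndarray  # IF = FL + FH (pre texture correction)
    flmp: np.ndarray
    tmp: np.ndarray
    hmps: tuple[np.ndarray, np.ndarray]
    maps: lowfreq.InitialMaps | None = None
    soft: dict = field(default_factory=dict)  # GMPs, u, M, saliencies, LPC

    @property
    def clipped(self) -> np.ndarray:
        return np.clip(self.fused, 0.0, 1.0)


def _stage(name: str, arr: np.ndarray) -> None:
    logger.debug("%s: min=%.4f max=%.4f mean=%.4f", name,
                 arr.min(), arr.max(), arr.mean())


def fuse_gray(a: np.ndarray, b: np.ndarray,
              cfg: EtemConfig | None = None) -> FusionResult:
    """Fuse two co-registered grayscale images on the [0, 1] scale."""
    cfg = cfg or EtemConfig()
    cfg.validate()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            "source shapes differ; the pipeline requires co-registered "
            f"inputs of one shape, got {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("fuse_gray expects 2-D grayscale arrays")
    if min(a.shape) < 8:
        raise ValueError("images must be at least 8x8")

    # two-band decomposition
    bands_a = decompose(a, cfg.decompose)
    bands_b = decompose(b, cfg.decompose)
    _stage("low_a", bands_a.low)

    # detail-band fusion
    sal_a = highfreq.saliency_operator(bands_a.high, a, cfg.high)
    sal_b = highfreq.saliency_operator(bands_b.high, b, cfg.high)
    fh, hmps = highfreq.fuse_high((bands_a.high, bands_b.high),
                                  (sal_a, sal_b))
    _stage("fh", fh)

    # base-band decision maps
    bank = build_bank(*a.shape, cfg.lpc)
    sfp_a = lpc_strength(bands_a.low, bank, cfg.lpc)
    sfp_b = lpc_strength(bands_b.low, bank, cfg.lpc)
    maps = lowfreq.initial_maps((bands_a.low, bands_b.low), (a, b),
                                (sfp_a, sfp_b), cfg.low)
    gmp_a = lowfreq.guided_filter(a, maps.lmp[0],
                                  cfg.low.gf_radius, cfg.low.gf_eps)
    gmp_b = lowfreq.guided_filter(a, maps.tlmp[0],
                                  cfg.low.gf_radius, cfg.low.gf_eps)
    m, u = lowfreq.random_walk_combine(gmp_a, gmp_b, a, cfg.low)
    flmp = lowfreq.consistency_filter(m, cfg.low.consistency_window)
    fl = lowfreq.fuse_low((bands_a.low, bands_b.low), flmp)
    _stage("fl", fl)

    # error-texture elimination and reconstruction
    fl_bar = rgf_ils_smooth(fl, cfg.ils, cfg.rgf)
    tes = texture.extract_textures((bands_a.low, bands_b.low), fl_bar)
    ft, tmp = texture.fuse_texture(tes)
    fused = texture.reconstruct(fh, ft, fl_bar)
    _stage("fused", fused)

    return FusionResult(
        fused=fused, fh=fh, fl=fl, fl_bar=fl_bar, ft=ft,
        initial_fusion=fl + fh, flmp=flmp, tmp=tmp, hmps=hmps, maps=maps,
        soft={"gmp_a": gmp_a, "gmp_b": gmp_b, "m": m, "u": u,
              "saliency_a": sal_a, "saliency_b": sal_b,
              "sfp_a": sfp_a, "sfp_b": sfp_b,
              "te_a": tes[0], "te_b": tes[1]},
    )


def fuse_color(func: np.ndarray, anat: np.ndarray,
               cfg: EtemConfig | None = None) -> np.ndarray:
    """Fuse a colour functional image with a grayscale anatomical one.

    Returns the fused RGB image clipped to [0, 1]; the chrominance of
    ``func`` passes through untouched.
    """
    cfg = cfg or EtemConfig()
    func = np.asarray(func, dtype=float)
    anat = np.asarray(anat, dtype=float)
    if func.ndim != 3 or func.shape[-1] != 3:
        raise ValueError("functional image must be (H, W, 3) RGB")
    if func.shape[:2] != anat.shape:
        raise ValueError("spatial shapes of the two sources differ")
    yuv = rgb_to_yuv(func)
    fused_y = fuse_gray(yuv[..., 0], anat, cfg).fused
    out = yuv.copy()
    out[..., 0] = fused_y
    return np.clip(yuv_to_rgb(out), 0.0, 1.0)
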