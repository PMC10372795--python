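"""Error-texture extraction and final reconstruction.

The fused base band FL may carry texture selected from the wrong
source ("error texture").  Filtering FL with the RGF-ILS smoother
yields the pure energy layer FL_bar; subtracting FL_bar from each
source's base band re-exposes the candidate textures, which are fused
by a winner-take-all on signed pixel value and added back:

    TE_t = f_t_low - FL_bar
    FT   = TE_1 * TMP + TE_2 * (1 - TMP)
    F    = FH + FT + FL_bar

Because the texture difference is taken against the same FL_bar that
re-enters the sum, fusing an image with itself reproduces it exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["extract_textures", "fuse_texture", "reconstruct"]


def extract_textures(lows: tuple[np.ndarray, np.ndarray],
                     fl_bar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed texture residuals of each base band against the energy layer."""
    l1, l2 = (np.asarray(x, dtype=float) for x in lows)
    fl_bar = np.asarray(fl_bar, dtype=float)
    if l1.shape != l2.shape or fl_bar.shape != l1.shape:
        raise ValueError("shape mismatch in extract_textures")
    return l1 - fl_bar, l2 - fl_bar


def fuse_texture(tes: tuple[np.ndarray, np.ndarray],
                 use_abs: bool = False,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Winner-take-all texture fusion; ties go to the first source.

    ``use_abs`` compares magnitudes instead of signed values (a
    sensitivity-analysis variant, off by default).
    """
    t1, t2 = (np.asarray(x, dtype=float) for x in tes)
    if t1.shape != t2.shape:
        raise ValueError("shape mismatch in fuse_texture")
    if use_abs:
        tmp = (np.abs(t1) >= np.abs(t2)).astype(float)
    else:
        tmp = (t1 >= t2).astype(float)
    ft = t1 * tmp + t2 * (1.0 - tmp)
    return ft, tmp


def reconstruct(fh: np.ndarray, ft: np.ndarray,
                fl_bar: np.ndarray) -> np.ndarray:
    """Assemble the fused image F = FH + FT + FL_bar (unclipped)."""
    fh = np.asarray(fh, dtype=float)
    ft = np.asarray(ft, dtype=float)
    fl_bar = np.asarray(fl_bar, dtype=float)
    if not (fh.shape == ft.shape == fl_bar.shape):
        raise ValueError("shape mismatch in reconstruct")
    return fh + ft + fl_bar
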