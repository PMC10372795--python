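"""Image reading/writing and the normalisation contract.

All pipeline math runs on float arrays in [0, 1].  8-bit files are
divided by 255 on read; 16-bit by 65535 (with a notice).  Writing clips
to [0, 1] and rescales to 8-bit, so an unprocessed read -> write round
trip is lossless for 8-bit data.  RGB stays 3-channel — grayscale
conversion is never implicit; colour images must go through the YUV
fusion path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["ImageRecord", "read_image", "write_image", "to_uint8"]

logger = logging.getLogger(__name__)


@dataclass
class ImageRecord:
    pixels: np.ndarray  # float in [0, 1]; (H, W) or (H, W, 3)
    bit_depth: int
    path: str
    scale: float  # divisor applied on read

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3


def read_image(path: str | Path) -> ImageRecord:
    """Read PNG/TIFF/JPEG into a normalised float record."""
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError, RuntimeError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc

    if raw.ndim == 3 and raw.shape[-1] == 4:  # drop alpha
        raw = raw[..., :3]
    if raw.ndim == 3 and raw.shape[-1] not in (3,):
        raise IOError(f"unsupported channel count in {path}: {raw.shape}")
    if raw.ndim not in (2, 3):
        raise IOError(f"unsupported image layout in {path}: {raw.shape}")

    if raw.dtype == np.uint8:
        depth, scale = 8, 255.0
    elif raw.dtype == np.uint16:
        depth, scale = 16, 65535.0
        logger.info("16-bit input %s scaled by 65535", path)
    elif np.issubdtype(raw.dtype, np.floating):
        depth, scale = 0, 1.0
    else:
        raise IOError(f"unsupported dtype {raw.dtype} in {path}")

    pixels = raw.astype(float) / scale
    return ImageRecord(pixels=pixels, bit_depth=depth, path=str(path),
                       scale=scale)


def to_uint8(array: np.ndarray) -> np.ndarray:
    """Clip to [0, 1] and rescale to 8 bit (round-half-even)."""
    clipped = np.clip(np.asarray(array, dtype=float), 0.0, 1.0)
    return np.rint(clipped * 255.0).astype(np.uint8)


def write_image(data: ImageRecord | np.ndarray, path: str | Path) -> None:
    """Write an array or record as an 8-bit PNG/TIFF/JPEG."""
    array = data.pixels if isinstance(data, ImageRecord) else data
    iio.imwrite(Path(path), to_uint8(array))
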