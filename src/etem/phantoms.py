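"""Synthetic co-registered multimodal brain-like phantom pairs.

Deterministic, seed-reproducible image pairs that emulate the contrast
relationships of clinical multimodal pairs without any anatomy:

* ``ct-mri``   — A: bright elliptical skull ring with a flat, faintly
  shaded interior (bone-dominant contrast); B: dark ring with a
  band-limited-noise soft-tissue texture and embedded dot/line
  structures (tissue-dominant contrast).  Region masks (ring, tissue,
  background) partition the frame.
* ``pet-mri`` / ``spect-mri`` — A: smooth pseudo-coloured Gaussian-blob
  activity map (RGB); B: the textured grayscale anatomy.
* ``step-texture`` — A: clean step edge; B: the same step plus fine
  additive texture (smoothing-filter fixture).
* ``blur-ladder`` — A: textured patch; B: its Gaussian blur (sharpness
  fixture); :func:`blur_ladder` produces the full sigma ladder.

The band-limited texture is filtered white noise (difference of
Gaussians), giving a controllable amplitude and correlation length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "make_pair", "blur_ladder", "bandlimited_texture"]

KINDS = ("ct-mri", "pet-mri", "spect-mri", "step-texture", "blur-ladder")


@dataclass
class PhantomSpec:
    kind: str = "ct-mri"
    size: int = 256
    seed: int = 0
    texture_amplitude: float = 0.15
    ring_intensity: float = 0.95
    n_blobs: int = 3
    blur_sigma: float = 3.0

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.size < 64:
            raise ValueError("phantom size must be >= 64")


def bandlimited_texture(shape: tuple[int, int], rng: np.random.Generator,
                        amplitude: float, lo: float = 1.0,
                        hi: float = 4.0) -> np.ndarray:
    """Zero-mean band-limited noise with RMS ``amplitude``."""
    noise = rng.standard_normal(shape)
    band = (ndimage.gaussian_filter(noise, lo, mode="wrap")
            - ndimage.gaussian_filter(noise, hi, mode="wrap"))
    rms = float(np.sqrt(np.mean(band ** 2)))
    return band / rms * amplitude if rms > 0 else band


def _ellipse(shape: tuple[int, int], ry: float, rx: float) -> np.ndarray:
    h, w = shape
    y = (np.arange(h) - (h - 1) / 2.0)[:, None]
    x = (np.arange(w) - (w - 1) / 2.0)[None, :]
    return (y / ry) ** 2 + (x / rx) ** 2 <= 1.0


def _head_masks(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    outer = _ellipse((n, n), 0.44 * n, 0.38 * n)
    inner = _ellipse((n, n), 0.38 * n, 0.32 * n)
    ring = outer & ~inner
    tissue = inner
    background = ~outer
    return ring, tissue, background


def _mri_like(n: int, rng: np.random.Generator, amplitude: float,
              masks: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    ring, tissue, _ = masks
    img = np.zeros((n, n))
    img[ring] = 0.10
    base = np.broadcast_to(
        0.45 + 0.1 * np.cos(np.linspace(0, np.pi, n))[:, None], (n, n))
    img[tissue] = base[tissue]
    img[tissue] += bandlimited_texture((n, n), rng, amplitude)[tissue]
    # embedded dot and line structures (lesion-like landmarks)
    for _ in range(4):
        cy, cx = rng.integers(int(0.35 * n), int(0.65 * n), size=2)
        rr = _ellipse((n, n), 0.02 * n, 0.02 * n)
        rr = np.roll(np.roll(rr, cy - n // 2, axis=0), cx - n // 2, axis=1)
        img[rr & tissue] = 0.9
    row = int(0.55 * n)
    line = np.zeros((n, n), dtype=bool)
    line[row:row + 2, int(0.3 * n):int(0.7 * n)] = True
    img[line & tissue] = 0.85
    return np.clip(img, 0.0, 1.0)


def _ct_like(n: int, ring_intensity: float,
             masks: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    ring, tissue, _ = masks
    img = np.zeros((n, n))
    img[ring] = ring_intensity
    shade = 0.15 + 0.04 * np.sin(np.linspace(0, 2 * np.pi, n))[None, :]
    img[tissue] = np.broadcast_to(shade, (n, n))[tissue]
    return ndimage.gaussian_filter(img, 0.8, mode="nearest")


def _activity_rgb(n: int, rng: np.random.Generator,
                  n_blobs: int) -> np.ndarray:
    """Smooth pseudo-coloured blob activity map in [0, 1] RGB."""
    y = np.arange(n)[:, None]
    x = np.arange(n)[None, :]
    activity = np.zeros((n, n))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.3 * n, 0.7 * n, size=2)
        sig = rng.uniform(0.05 * n, 0.12 * n)
        activity += rng.uniform(0.5, 1.0) * np.exp(
            -((y - cy) ** 2 + (x - cx) ** 2) / (2 * sig ** 2))
    activity = activity / max(float(activity.max()), 1e-12)
    # hot-metal style colour ramp: low=blue, mid=red, high=yellow
    r = np.clip(2.0 * activity, 0, 1)
    g = np.clip(2.0 * activity - 1.0, 0, 1)
    b = np.clip(1.0 - 2.0 * activity, 0, 1) * 0.6
    return np.stack([r, g, b], axis=-1)


def make_pair(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate a co-registered phantom pair and its region masks.

    Returns ``(image_a, image_b, masks)``; ``image_a`` is RGB for the
    functional kinds and grayscale otherwise.  Identical specs produce
    bit-identical arrays.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.size

    if spec.kind == "ct-mri":
        masks = _head_masks(n)
        a = _ct_like(n, spec.ring_intensity, masks)
        b = _mri_like(n, rng, spec.texture_amplitude, masks)
        ring, tissue, background = masks
        return a, b, {"ring": ring, "tissue": tissue,
                      "background": background}

    if spec.kind in ("pet-mri", "spect-mri"):
        masks = _head_masks(n)
        b = _mri_like(n, rng, spec.texture_amplitude, masks)
        a = _activity_rgb(n, rng, spec.n_blobs)
        ring, tissue, background = masks
        blob = a.sum(axis=-1) > 0.5
        return a, b, {"ring": ring, "tissue": tissue,
                      "background": background, "blob": blob}

    if spec.kind == "step-texture":
        a = np.full((n, n), 0.3)
        a[:, n // 2:] = 0.7
        b = a + bandlimited_texture((n, n), rng, spec.texture_amplitude)
        left = np.zeros((n, n), dtype=bool)
        left[:, :n // 2] = True
        return a, np.clip(b, 0.0, 1.0), {"left": left, "right": ~left}

    if spec.kind == "blur-ladder":
        a = np.clip(0.5 + bandlimited_texture((n, n), rng,
                                              spec.texture_amplitude), 0, 1)
        b = ndimage.gaussian_filter(a, spec.blur_sigma, mode="nearest")
        full = np.ones((n, n), dtype=bool)
        return a, b, {"all": full, "none": ~full}

    raise AssertionError("unreachable")


def blur_ladder(spec: PhantomSpec,
                sigmas: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0),
                ) -> list[np.ndarray]:
    """Progressively blurred copies of the textured phantom."""
    base, _, _ = make_pair(PhantomSpec(kind="blur-ladder", size=spec.size,
                                       seed=spec.seed,
                                       texture_amplitude=spec.texture_amplitude))
    return [base if s == 0 else
            ndimage.gaussian_filter(base, s, mode="nearest") for s in sigmas]
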