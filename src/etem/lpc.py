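"""Local phase coherence (LPC) sharpness maps from a log-Gabor bank.

Blur disturbs the alignment of band-pass phases across scales, so the
coherence of log-Gabor phases is a no-reference sharpness measure: at a
clean edge the phases of octave-spaced filters satisfy a linear relation
and the weighted cross-scale product lands on the positive real axis; a
blurred edge scatters it.  The per-pixel strength is the cosine of the
phase-prediction error, averaged over orientations with first-scale
magnitude weights.
"""

from __future__ import annotations

import numpy as np

from .config import LPCConfig

__all__ = ["LogGaborBank", "build_bank", "lpc_strength", "lpc_map"]

_TINY = 1e-30


class LogGaborBank:
    """Frequency-domain log-Gabor transfer functions, scale x orientation.

    ``filters[s][o]`` is the H x W complex transfer function at scale s
    (octave spacing from ``min_wavelength``) and orientation o (evenly
    spaced over the full circle, so o and o + M/2 are reflections).
    Every filter has an exactly zero DC bin.
    """

    def __init__(self, filters: list[list[np.ndarray]], shape: tuple[int, int],
                 cfg: LPCConfig):
        self.filters = filters
        self.shape = shape
        self.cfg = cfg

    @property
    def n_scales(self) -> int:
        return len(self.filters)

    @property
    def n_orientations(self) -> int:
        return len(self.filters[0])


def _frequency_grids(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0  # avoid log(0); DC is zeroed explicitly afterwards
    theta = np.arctan2(-fy, fx)
    return radius, theta


def build_bank(h: int, w: int, cfg: LPCConfig | None = None) -> LogGaborBank:
    """Construct the N x M log-Gabor bank for an H x W image."""
    cfg = cfg or LPCConfig()
    cfg.validate()
    if h < 8 or w < 8:
        raise ValueError("bank requires H, W >= 8")
    radius, theta = _frequency_grids(h, w)
    sigma_theta = cfg.angular_spread_factor * np.pi / cfg.orientations
    log_sigma = np.log(cfg.sigma_on_f)

    filters: list[list[np.ndarray]] = []
    for s in range(cfg.scales):
        wavelength = cfg.min_wavelength * cfg.scale_ratio ** s
        f0 = 1.0 / wavelength
        radial = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * log_sigma ** 2))
        radial[0, 0] = 0.0
        row: list[np.ndarray] = []
        for o in range(cfg.orientations):
            angle = 2.0 * np.pi * o / cfg.orientations
            # wrapped angular distance to the filter axis
            diff = np.arctan2(np.sin(theta - angle), np.cos(theta - angle))
            angular = np.exp(-(diff ** 2) / (2.0 * sigma_theta ** 2))
            row.append((radial * angular).astype(complex))
        filters.append(row)
    return LogGaborBank(filters, (h, w), cfg)


def _responses(image: np.ndarray, bank: LogGaborBank) -> list[list[np.ndarray]]:
    spectrum = np.fft.fft2(image)
    return [[np.fft.ifft2(spectrum * t) for t in row] for row in bank.filters]


def lpc_strength(image: np.ndarray, bank: LogGaborBank,
                 cfg: LPCConfig | None = None) -> np.ndarray:
    """Per-pixel LPC strength of ``image``, normalised to [0, 1].

    Per orientation the weighted cross-scale product with weights
    (1, -3, 2) is formed as ``z = C1 * conj(C2)**3 * C3**2`` (negative
    weights enter as conjugate powers, so magnitudes never divide);
    perfect coherence means arg(z) = 0 and strength Re(z)/|z| = 1.
    Orientations are combined by a |C1|-weighted average with the
    absolute constant V added to the denominator, so low first-scale
    energy (flat or blur-attenuated regions) drags the score to 0;
    each orientation strength lies in [0, 1], hence so does the map,
    and maps of different images stay directly comparable.
    """
    cfg = cfg or bank.cfg
    image = np.asarray(image, dtype=float)
    if image.shape != bank.shape:
        raise ValueError("bank shape does not match image")
    coeffs = _responses(image, bank)
    n_or = bank.n_orientations

    weighted_sum = np.zeros(image.shape)
    weight_total = np.zeros(image.shape)
    for o in range(n_or):
        z = np.ones(image.shape, dtype=complex)
        for s, w_s in enumerate(cfg.weights):
            c = coeffs[s][o]
            if w_s >= 0:
                z = z * c ** w_s
            else:
                z = z * np.conj(c) ** (-w_s)
        strength = np.clip(np.real(z) / (np.abs(z) + _TINY), 0.0, 1.0)
        mag1 = np.abs(coeffs[0][o])
        weighted_sum += mag1 * strength
        weight_total += mag1

    return weighted_sum / (weight_total + cfg.v_const)


def lpc_map(image: np.ndarray, cfg: LPCConfig | None = None) -> np.ndarray:
    """Convenience wrapper: build the bank for ``image`` and score it."""
    cfg = cfg or LPCConfig()
    bank = build_bank(*image.shape, cfg)
    return lpc_strength(image, bank, cfg)
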