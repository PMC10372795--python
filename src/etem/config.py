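"""Configuration objects for every stage of the fusion pipeline.

All tunables the method exposes live here, grouped per stage, with the
defaults used throughout: decomposition weight ``beta=3``, saliency window
``psi=3``, guided-filter ``(r, eps)=(5, 0.3)``, random-walker ``sigma=0.1``
with seed thresholds 0.8/0.2, a 9x9 consistency window, ILS
``(p, epsilon, n, lam)=(0.8, 1e-4, 3, 1.0)`` and rolling-guidance
``(sigma_s, sigma_r, eta)=(10, 0.008, 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class DecomposeConfig:
    """Two-band gradient-penalised least-squares decomposition.

    beta
        Regularisation weight on the gradient energy of the low band.
        Larger beta -> smoother low band, more energy in the residual.
    pad
        Replicate-pad margin (pixels) applied before the periodic FFT
        solve and cropped afterwards, to suppress wrap-around halos.
        0 keeps the literal circular-boundary solve.
    """

    beta: float = 3.0
    pad: int = 0

    def validate(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")


@dataclass
class LPCConfig:
    """Log-Gabor bank for local-phase-coherence sharpness.

    scales >= 3 are needed for the three-term cross-scale phase
    prediction; weights (1, -3, 2) cancel the phase of any structure
    whose phase is linear across octave-spaced scales, so coherent
    (sharp) structure scores 1 and blur degrades the score.
    """

    scales: int = 3
    orientations: int = 8
    min_wavelength: float = 4.0
    scale_ratio: float = 2.0
    sigma_on_f: float = 0.55  # radial log-Gaussian bandwidth ratio
    angular_spread_factor: float = 0.85  # sigma_theta = factor * pi / M
    weights: tuple = (1.0, -3.0, 2.0)
    # Absolute stabilising constant (unit intensity scale).  It must be
    # absolute, not image-relative: blur attenuates the first-scale
    # magnitudes that weight the orientation average, and only a fixed
    # floor in the denominator lets that attenuation pull the pooled
    # score down — the mechanism that makes the measure blur-sensitive.
    # 0.1 is roughly a tenth of the pooled first-scale magnitude of a
    # full-contrast sharp edge.
    v_const: float = 0.1

    def validate(self) -> None:
        if self.scales < 3:
            raise ValueError("at least 3 scales are required")
        if len(self.weights) != self.scales:
            raise ValueError("one weight per scale is required")
        if self.v_const <= 0:
            raise ValueError("v_const must be positive")


@dataclass
class HighFusionConfig:
    """Gradient-difference + entropy saliency for the detail bands."""

    psi: int = 3
    entropy_bins: int = 8
    operator: str = "GE"  # one of GE | EOL | SML | STO

    def validate(self) -> None:
        if self.psi < 3 or self.psi % 2 == 0:
            raise ValueError("psi must be odd and >= 3")
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")
        if self.operator not in ("GE", "EOL", "SML", "STO"):
            raise ValueError(f"unknown operator {self.operator!r}")


@dataclass
class LowFusionConfig:
    """Base-band fusion: guided filtering, random walker, consistency."""

    gf_radius: int = 5
    gf_eps: float = 0.3
    rw_sigma: float = 0.1
    seed_high: float = 0.8
    seed_low: float = 0.2
    consistency_window: int = 9
    tlmp_mode: str = "literal"  # literal | union

    def validate(self) -> None:
        if not 0 < self.seed_low < self.seed_high < 1:
            raise ValueError("need 0 < seed_low < seed_high < 1")
        if self.consistency_window % 2 == 0:
            raise ValueError("consistency window must be odd")
        if self.tlmp_mode not in ("literal", "union"):
            raise ValueError(f"unknown tlmp_mode {self.tlmp_mode!r}")


@dataclass
class ILSConfig:
    """Iterative least-squares edge-preserving smoother.

    The sparseness power p in (0,1) makes the gradient penalty
    concave, so large (edge) gradients are penalised less than an L2
    term would; c = p * epsilon**(p/2 - 1) is the curvature bound of
    the surrogate quadratic.
    """

    p: float = 0.8
    epsilon: float = 1e-4
    n_iter: int = 3
    lam: float = 1.0

    @property
    def c(self) -> float:
        return self.p * self.epsilon ** (self.p / 2.0 - 1.0)

    def validate(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if self.epsilon <= 0 or self.lam <= 0:
            raise ValueError("epsilon and lam must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class RGFConfig:
    """Rolling guidance filter (iterated joint bilateral)."""

    sigma_s: float = 10.0
    sigma_r: float = 0.008
    eta: int = 2

    def validate(self) -> None:
        if self.sigma_s <= 0 or self.sigma_r <= 0:
            raise ValueError("sigma_s and sigma_r must be positive")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


@dataclass
class EtemConfig:
    """Aggregate configuration for the full fusion pipeline."""

    decompose: DecomposeConfig = field(default_factory=DecomposeConfig)
    lpc: LPCConfig = field(default_factory=LPCConfig)
    high: HighFusionConfig = field(default_factory=HighFusionConfig)
    low: LowFusionConfig = field(default_factory=LowFusionConfig)
    ils: ILSConfig = field(default_factory=ILSConfig)
    rgf: RGFConfig = field(default_factory=RGFConfig)
    color_matrix: str = "bt601"

    def validate(self) -> None:
        for sub in (self.decompose, self.lpc, self.high, self.low,
                    self.ils, self.rgf):
            sub.validate()
        if self.color_matrix != "bt601":
            raise ValueError(f"unknown color matrix {self.color_matrix!r}")
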