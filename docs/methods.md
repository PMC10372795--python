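# Methods

This note records the model, the parameter choices, the numerical
conventions, and what the synthetic phantoms do and do not establish.

## Pipeline overview

All computation happens on float arrays in [0, 1]; 8-bit files are
divided by 255 on read and clipped/rescaled on write. For a grayscale
pair (f₁, f₂) the stages are:

1. **Two-band decomposition.** The base band minimises
   ‖f − u‖² + β(‖gₐ∗u‖² + g_b analogously) with two-tap difference
   kernels; the normal equations are diagonal in the 2-D DFT, so
   u = IFFT[FFT(f) / (1 + β(|FFT(gₐ)|² + |FFT(g_b)|²))]. The residual
   is the detail band, so additivity is exact by construction.
   β = 3 balances energy separation against halo width; larger β moves
   more structure into the detail band.
2. **Detail fusion (GE operator).** Saliency =
   locmax|∇f^h| · (locmax f − locmin f) · exp(0.3·H_w) / (global
   gradient range), where H_w is the base-2 Shannon entropy of the
   gradient magnitudes in the ψ×ψ window, histogrammed into 8
   equal-width bins over the window's own range (windows hold ψ² = 9
   samples, so few bins are appropriate). ψ = 3. A flat detail band
   yields zero saliency by a guarded denominator. Classic focus
   measures (EOL, SML, structure-tensor trace) plug into the same
   interface for ablations.
3. **Base fusion.** Winner-take-all maps on base-band energy (LMP),
   LPC sharpness of the base bands (SMP), and raw sources (SLMP); the
   selection rule integrating SMP and SLMP reduces, read literally, to
   SLMP — the default `literal` mode implements exactly that, and a
   `union` mode (either map's vote, SMP priority on conflict) is
   provided for the integrating reading. LMP₁ and TLMP₁ are smoothed
   by a guided filter (r = 5, ε = 0.3) on guide f₁, arbitrated by a
   seeded random walker, consistency-voted over 9×9, and the resulting
   binary map selects between the base bands.
4. **Error-texture elimination.** The fused base band is filtered by
   RGF-ILS into an energy layer FL̄; per-source textures
   TE_t = f_t^l − FL̄ are re-fused by signed winner-take-all, and
   F = FH + FT + FL̄. Self-fusion is exact because the same FL̄ is
   subtracted and re-added.

Colour pairs convert to BT.601 full-range YUV (U and V rows derived
exactly from the luma row so gray inputs have identically zero
chroma); only Y is fused and chroma passes through bit-identically
before the final RGB clip.

## Local phase coherence

Sharpness is measured as cross-scale phase coherence of a log-Gabor
bank: 3 scales (wavelengths 4, 8, 16 px; σ_r/f₀ = 0.55), 8
orientations over the full circle (angular σ = 0.85·π/M), DC bins
exactly zero. Per orientation the weighted product with weights
(1, −3, 2) is formed as z = C₁·conj(C₂)³·C₃², whose phase
φ₁ − 3φ₂ + 2φ₃ vanishes for any structure with phase linear in
frequency across octave-spaced scales; negative weights enter as
conjugate powers so small magnitudes never divide. The strength
Re(z)/|z| is rectified at 0, giving a per-orientation score in [0, 1],
and orientations are pooled by a |C₁|-weighted average with an
absolute constant V in the denominator.

**Why V is absolute, not image-relative.** Gaussian blur is zero-phase:
it attenuates magnitudes but leaves phases — and hence the cosine
score — intact over a wide halo, so a V that rescales with the image's
own peak coefficient cancels out of the sharp/blurred comparison and
can invert it. Only a fixed magnitude floor lets blur-attenuated
coefficients drag the pooled score down. V = 0.1 on the unit intensity
scale (about a tenth of the pooled first-scale magnitude of a
full-contrast edge) is the least compressive value for which the
sharp-versus-blurred ordering holds robustly (verified across
V ∈ {0.1, 0.5, 1, 2}).

## ILS, RGF and the hybrid

ILS minimises Σ(u−f)² + λΣφ_p(∇u), φ_p(x) = (x²+ε)^{p/2}, by a
half-quadratic surrogate: μ = c∇u − p∇u((∇u)²+ε)^{p/2−1} with
c = p·ε^{p/2−1}, then one screened least-squares solve per iteration in
the Fourier domain (periodic gradients, the same two-tap kernels as
the decomposition). Defaults p = 0.8, ε = 10⁻⁴, n = 3, λ = 1 (λ is a
free smoothing weight; 1 is the neutral default). The concave penalty
(p < 1) under-penalises large gradients, which is what preserves
edges.

The rolling guidance filter iterates a joint bilateral pass of the
*original* input against an evolving guidance, initialised as a
Gaussian blur at scale σ_s; σ_s = 10 px, σ_r = 0.008, η = 2.
Neighbourhoods truncate at radius 2σ_s and at the frame (no padding);
the spatial kernel uses the ‖p−q‖²/2σ_s² convention in both numerator
and normaliser. η = 0 is the identity, which gives a clean degenerate
check: the hybrid with η = 0 equals plain ILS bit-for-bit.

RGF-ILS replaces the raw gradients feeding μ with their RGF-filtered
versions, each gradient field filtered independently. Fine texture is
removed from the edge-preservation term, so ILS smooths it away, while
large RGF-surviving gradients keep their edges; measured on a
step-plus-texture phantom this removes ≥ 50% of the texture standard
deviation while retaining the step height within 10%.

## Random walker

Pixels are nodes of the 4-connected lattice with affinities
exp(−(g_i−g_j)²/σ²), g the first source, σ = 0.1. Guided-map values
above 0.8 (or below 0.2, as 1−value) act as soft seeds y for their
class; the absorption probability solves (L + diag(y_A+y_B))u = y_A,
a sparse SPD system solved by LU with one iterative-refinement step
(the system is barely regularised where seeds are sparse; the polish
keeps the solution at oracle precision). The combined map takes
GMP_A where u ≥ 0.5; the tie at exactly 0.5 — symmetric seeding —
resolves to the first source, as every other tie in the pipeline
does (all argmax ties resolve to source 1, making the output fully
deterministic).

## Quality metrics

Q_MI sums 2·I(S;F)/(H(S)+H(F)) over the two sources (256-bin
histograms); Q_NCIE uses the 3×3 nonlinear-correlation matrix with
base-256 entropies and unit diagonal; AG is the mean central-difference
gradient magnitude; SF the root-sum-square of row/column first-
difference energies; PSNR is taken against the mean of the two
per-source MSEs (peak 1; an exact triple match reports +inf); SSIM
averages the scikit-image structural similarity against each source.

## Synthetic phantoms

The generator emulates the contrast logic of clinical pairs, not
anatomy: a CT-like image (bright elliptical skull ring, intensity
0.95, faintly shaded flat interior), an MRI-like image (dark ring,
band-limited-noise tissue texture of RMS amplitude 0.15 with embedded
dot/line landmarks), and smooth pseudo-coloured Gaussian-blob activity
maps for PET/SPECT. Texture is difference-of-Gaussians filtered seeded
white noise, giving reproducible amplitude and correlation length.
Ring/tissue/background masks partition the frame. All outputs are
bit-reproducible from the seed.

What passing tests on phantoms establish: the algebraic contracts
(additivity, self-fusion identity, dominance, chroma pass-through),
oracle-exactness of each operator, and the qualitative complementarity
behaviour (ring brightness from the CT-like source, texture from the
MRI-like source). What they do not establish: performance on real
acquisitions with noise, bias fields, registration error, or genuine
anatomy — the phantoms contain none of these.

## Numerical choices and edge cases

- Periodic (DFT) boundaries for the decomposition and ILS solves; a
  replicate-pad variant (`DecomposeConfig.pad`) is available to
  suppress wrap-around halos.
- Window operators (local max/min/entropy, consistency vote) use
  replicate padding; the guided filter and RGF use frame-intersection
  windows.
- Entropy bins span each window's own [min, max]; a constant window
  has entropy 0.
- All argmax ties resolve to the first source; outputs are therefore
  bit-deterministic for identical inputs and configuration.
- Constant images are exact fixed points of every smoother; an
  all-flat detail band yields zero saliency rather than 0/0.
- Problem sizes in the test-suite and the acceptance script (8–16 px
  oracle problems, 96–256 px phantoms) were chosen so each contract is
  exercised at the smallest size where the behaviour is representative.

## Known limitations

- The selection rule for TLMP, read literally, collapses to the
  source-intensity map; the `union` mode covers the integrating
  reading but is not the default.
- Texture re-fusion compares signed values (an `use_abs` flag exists
  for magnitude comparison); signed comparison favours positive
  textures when both candidates are strong.
- Q_MI rewards copying a single source (a perfect self-information
  term); on strongly geometry-sharing pairs a faithful fusion can
  score marginally below a source reused as "fusion" even when AG and
  SF clearly exceed both sources.
- No registration: inputs must be co-registered and equally sized;
  2-D single-slice only.
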