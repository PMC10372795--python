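# etem

Multimodal brain-image fusion with error-texture elimination and
salient feature detection.

Clinically co-registered image pairs carry complementary information:
CT shows bone brightly, MRI resolves soft-tissue texture, PET/SPECT
encode function as pseudo-colour. Fusion merges one pair into a single
image that keeps the skull luminance of CT, the tissue texture of MRI,
and — for functional pairs — the colour coding untouched. The catch
addressed here is *error texture*: fusion rules that pick base-band
pixels by energy alone drag along texture from the wrong source. This
package removes it explicitly.

## Method

Each source `f_t` is split into a base band and a detail residual by a
Tikhonov-regularised least-squares low-pass,

    f_t^l = argmin_u ||f_t − u||² + β(||g_a * u||² + ||g_b * u||²),
    f_t^h = f_t − f_t^l,                      g_a = [−1 1],  g_b = g_aᵀ,

solved in one DFT division (β = 3). The two detail bands are fused
winner-take-all under a saliency operator combining the local-window
maximum of the gradient magnitude with a source-contrast term amplified
by the local Shannon entropy of the gradients (ψ = 3 windows). The base
bands are fused through a chain of decision maps: pixel-energy and
local-phase-coherence (log-Gabor) winner maps, guided-filter smoothing
(r = 5, ε = 0.3), a seeded random walker on the 4-connected lattice
(ω_ij = exp(−(g_i−g_j)²/σ²), σ = 0.1; confident map values act as soft
seeds), and a 9×9 consistency vote. The fused base band is then
filtered by RGF-ILS — an iterative least-squares smoother
(p = 0.8, ε = 10⁻⁴, 3 iterations) whose gradient fields are regularised
by a rolling guidance filter (σ_s = 10, σ_r = 0.008, 2 iterations) —
leaving a pure energy layer `FL̄`. Per-source textures
`TE_t = f_t^l − FL̄` are re-fused by signed winner-take-all and the
result is assembled as

    F = FH + FT + FL̄.

Because the texture differences are taken against the same `FL̄` that
re-enters the sum, fusing an image with itself returns it exactly.
Colour pairs route through YUV: only luminance is fused, chrominance
passes through bit-identically.

## Worked example

```python
import numpy as np
from etem import EtemConfig, PhantomSpec, evaluate, fuse_gray, make_pair

a, b, masks = make_pair(PhantomSpec(kind="ct-mri", size=256, seed=7))
result = fuse_gray(a, b, EtemConfig())
fused = result.clipped

ring = masks["ring"]
print(f"ring mean   CT={a[ring].mean():.3f}  fused={fused[ring].mean():.3f}")
report = evaluate(fused, a, b)
for name, value in report.as_dict().items():
    print(f"{name:7s} {value:.4f}")
```

prints

```
ring mean   CT=0.916  fused=0.914
q_mi    1.3797
q_ncie  0.8229
ag      0.0591
sf      0.1243
psnr    11.4488
ssim    0.6979
```

The fused skull ring retains the CT brightness to within 0.3%, and the
gradient-based scores (`ag`, `sf`) exceed those of either source alone
(0.017/0.048 and 0.072/0.107 respectively) because the fusion carries
both the ring edges and the tissue texture. `result` also exposes every
intermediate (`fh`, `fl`, `fl_bar`, `ft`, decision maps, random-walker
probabilities) for inspection.

The same pipeline is available from the shell:

```sh
etem phantom --kind ct-mri -o pair/ --seed 7
etem fuse pair/a.png pair/b.png -o fused.png
etem metrics fused.png pair/a.png pair/b.png --json
etem fuse --color pet.png mri.png -o fused_color.png
```

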