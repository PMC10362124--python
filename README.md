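# hyperfilt

Special-function image-enhancement filters for edge extraction in noisy
grayscale images, with the classical baselines and synthetic phantoms needed
to evaluate them quantitatively.

Low-contrast, heavily degraded images — the motivating case is near-infrared
(NIR) fluorescence imaging of a dye-filled tube through scattering tissue —
defeat classical edge operators once impulse noise becomes dense. This
package implements four nonlinear filters built from elementary special
functions that remain usable under such degradation:

**Spatial (pointwise) filters.** With `tt(m,n)` the input pixel value,

- **exp filter**: `u = a · exp(−q · (tt − b)^{n₂} / c²)`.
  For even `n₂` this is a Gaussian-like band selector around the offset `b`;
  for odd `n₂` the exponent changes sign across `tt = b` and the output is
  globally brighter — the parity effect.
- **sinh-asinh-r filter**: `r = tt/η`;
  `z = sinh(a₁ · asinh(r + a₂) · r^{a₃})`; `u₄ = z^{a₄}`,
  with sign-preserving fractional powers. Only `a₃` changes the rendering
  appreciably.

**Frequency-domain filters.** Over the center-shifted 2-D spectrum, with the
distance map `D(i,j) = |i − m₁|^{n₃} + |j − n₁|^{n₃}` and reference distance
`D₀` (default 5 % of the half-height), both filters are Chebyshev-type gains
in `u = D₀/D`:

- **cosh-acosh**: `CNx = |cosh(N · acosh u)|^{n₅}`,
  `H = 1 / (1 + ε² · CNx^{n₄})` — suppresses the DC neighbourhood
  monotonically (edge extraction, "printmaking" rendering).
- **sech-asech**: `CNx₂ = |sech(λ · asech u)|^{nn}`,
  `H = 1 / (1 + ε² · CNx₂²)` — passes high frequencies and ripples below
  `D₀` (the corrugated bands).

`cosh(N·acosh u)` is continued by `cos(N·acos u)` for `u < 1`; both branches
join into the Chebyshev polynomial `T_N(u)`. With `ε = 0` either frequency
filter is an exact FFT round-trip.

Also included: seeded salt-and-pepper / additive-Gaussian noise injection;
Sobel, Prewitt, Roberts, Laplacian-of-Gaussian, Gabor-bank and oriented
matched-filter baselines; phantom generators (geometric shapes, step edges,
NIR tube) with analytic edge masks; and PSNR / boundary-F1 scoring so visual
claims become measurable orderings.

## Worked example

```python
import hyperfilt as hf

ph = hf.make_shapes_phantom(256, 256, seed=1)

# parity effect: odd n2 brightens, even n2 darkens
for n2 in (8, 9):
    u = hf.exp_filter(ph.image, hf.ExpParams(n2=n2))
    print(n2, round(hf.mean_brightness(u), 6))

# edge recovery under 90% salt-and-pepper noise, scored against the mask
noisy = hf.add_noise(ph.image, hf.NoiseSpec(density=0.9, seed=1))
from hyperfilt.pipeline import binarize_enhanced
mask = binarize_enhanced(hf.exp_filter(noisy))
print(round(hf.edge_f1(mask, ph.edge_mask, tolerance_px=1).f1, 4))
```

prints

```
8 0.998799
9 1.000456
0.0563
```

The exp-filtered image is brighter for `n₂ = 9` than for `n₂ = 8`
(mean 1.000456 vs 0.998799), and even at 90 % pixel replacement the
binarized exp output still matches a nonzero fraction of the true shape
boundaries (F1 = 0.0563 at 1-px tolerance for this seed).

The same workflows are scriptable from the shell:

```sh
hyperfilt synth --kind shapes --seed 1 --out shapes
hyperfilt enhance shapes.png out.png --filter cosh-acosh --set eps=1 --set order=4
hyperfilt compare --kind shapes --density 0.9 --seed 1 --out scores.csv
```

Every `enhance` run writes a JSON sidecar with all parameters, so a run is
reproducible from the sidecar alone.

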