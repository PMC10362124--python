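# Methods

## The filters

All computation is double precision on 2-D gray images with a nominal
intensity range of [0, 1]; RGB input is converted with ITU-R BT.601 luma
weights (0.299, 0.587, 0.114), the conventional broadcast-video default.
Filter outputs are allowed to leave [0, 1]; they are min-max rescaled only
at save/display time or immediately before binarization, never before a
metric that does not require it.

### Pointwise filters

The exp filter maps each pixel `tt` to `a·exp(−q·(tt−b)^{n2}/c²)`. Its
behavior is governed entirely by the exponent's parity and scale:

- even `n2`, `q > 0`: the exponent is ≤ 0 everywhere, so `0 < u ≤ a` with
  the maximum `a` attained exactly at `tt = b` — a band selector around the
  offset. The output is pointwise non-increasing in `q` wherever `tt ≠ b`,
  which is the precise form of "larger q washes out the edges".
- odd `n2`: the exponent is positive for `tt < b`, so those pixels map above
  `a` and the image mean exceeds the adjacent even-`n2` mean — the parity
  brightness effect, tested on the shapes phantom for the pairs (8, 9) and
  (28, 29).

The sinh-asinh-r filter is `r = tt/η`, `z = sinh(a1·asinh(r + a2)·r^{a3})`,
`u4 = z^{a4}`. Two typesetting ambiguities had to be resolved:

- grouping: the three factors `a1`, `asinh(r + a2)` and `r^{a3}` all
  multiply inside the outer sinh (this matches the pseudo-code rendering of
  the defining algorithm);
- the outer operation is an `a4`-th power, implemented sign-preservingly
  (`sign(z)·|z|^{a4}`) so fractional exponents on negative values stay real.
  The same rule covers `r^{a3}` for negative `r` (possible when η < 0).

Both pointwise filters are also available with a `paper_loop` flag that
reproduces the original pseudo-code's literal iteration range
(`m = 3..h−1`, 1-based), which leaves a 2-pixel top/left and 1-pixel
bottom/right border untouched. Since the transform is pointwise this border
skipping is a quirk of the pseudo-code, and the default applies the
transform to every pixel.

Overflow policy: odd exponents can push `exp`/`sinh` past the double range;
overflowed pixels saturate to the largest finite double with a logged
warning. NaN is never produced for finite input.

### Frequency-domain filters

Both operate on the center-shifted spectrum: `fft2 → fftshift → ×H →
ifftshift → ifft2 → real part`. The centered convention is adopted because
the distance map is defined around the half-size indices; the imaginary
residue after inversion is asserted to be < 1e−9 of the real magnitude
(guaranteed by H's 180° rotation symmetry about the center, which holds by
construction from `|i − center|` distances, for even and odd sizes alike).

The distance map is `D = |i−m1|^{n3} + |j−n1|^{n3}` with
`m1 = floor(h/2)`, `n1 = floor(w/2)`, 0-based. Absolute values are used
because a signed power is ill-defined for odd `n3` and D must be a
nonnegative distance for `D0/D` to be meaningful.

`chebyshev_cosh(N, u)` evaluates `cosh(N·acosh u)` for `u ≥ 1` and its real
continuation `cos(N·acos u)` for `0 ≤ u < 1`; at integer N both branches
coincide with the Chebyshev polynomial `T_N(u)` (verified against the
recurrence `T_{k+1} = 2u·T_k − T_{k−1}` to < 1e−9 over [0, 3]).

Gains (with `u = D0/D`):

- cosh-acosh: `CNx = |chebyshev_cosh(order, u)|^{n5}`,
  `H = 1/(1 + ε²·CNx^{n4})`.
- sech-asech: `CNx2 = |1/chebyshev_cosh(lam, 1/u)|^{nn}`,
  `H = 1/(1 + ε²·CNx2²)`, using `sech(λ·asech u) = 1/cosh(λ·acosh(1/u))`.

Branch structure and the resulting shapes: for D < D0 (u > 1) cosh-acosh is
on its hyperbolic branch, so its radial profile decays monotonically to ~0
at DC; sech-asech is there on the cosine branch and its gain ripples (the
corrugated bands), with hard dips where the cosine factor crosses zero. For
D > D0 the roles swap: sech-asech rises monotonically to 1 while the
cosh-acosh profile oscillates. The ripple/monotone test therefore probes the
D < D0 region for both filters, where each filter's characteristic behavior
(sech ripple, cosh monotone decay) lives.

Numerical guards: the absolute value is taken before the fractional powers
`n5`/`nn` so H stays real and in (0, 1]; the single zero of D at the grid
center is floored at `D0·1e−12`; zeros of the cosine branch in the sech
denominator saturate the base to the largest finite double (H ≈ 0 at that
frequency, logged); overflowing powers saturate likewise, so H underflows
gracefully toward (but never below) the smallest positive double.

Two of the defining constants needed interpretation:

- the symbol used for the cosh order collides with the half-width symbol of
  the distance map. Using the literal half-width (e.g. 128) as the order
  drives the gain to 0 everywhere, inconsistent with the non-trivial outputs
  the filters are known to produce, so the order is an independent parameter
  (default 4).
- "D0 is 0.05 pixels" is read as 5 % of the half-height in distance-map
  units (`D0 = 0.05·m1`, configurable): a literal 0.05-pixel cutoff leaves
  the filter a near-identity, again inconsistent with the strong reported
  effects.

### Defaults

The constant values behind the filters' known renderings are not recoverable,
so defaults are unit-scale values centered on the nominal intensity range,
chosen once: exp `a=1, q=2, b=0.5, n2=8, c=1`; sinh-asinh-r
`η=1, a1=1, a2=0.1, a3=2, a4=1`; cosh-acosh `order=4, n5=1, n4=2, ε=1`;
sech-asech `λ=4, nn=24, ε=1`; distance map `n3=2, D0=0.05·m1`. All are
overridable via YAML config or CLI `--set`. Consequently only qualitative
behaviors (parity, ripple, noise-robustness orderings) are testable, not
figure-faithful reproduction.

## Noise model

The stress tests use "density" vocabulary and describe white impulse spots,
so the default family is salt-and-pepper: each pixel is independently
replaced with probability d, half of the replacements by 0 and half by 1.
An additive Gaussian family (mean/variance, clipped to [0, 1]) is provided
for the literal reading of "Gaussian noise with density d". Both are
deterministic given the seed. The replaced-pixel fraction concentrates at d
within binomial 3σ, verified over 20 seeds at d = 0.5 and 0.9.

## Baselines

Sobel/Prewitt/Roberts use the standard unnormalized kernel pairs (unit
vertical step peaks: 4, 3) with reflective padding; LoG takes zero crossings
of the Gaussian-smoothed Laplacian, with a pixel's strength defined as the
largest opposite-sign jump to a 4-neighbor; the Gabor bank takes the
pixelwise maximum modulus over zero-DC complex kernels (defaults: 4
orientations × frequencies {0.1, 0.2} cycles/px); the matched filter uses
zero-mean oriented kernels with a Gaussian cross-profile (σ = 2) constant
along a 9-px segment over 12 orientations, in the classic line-detection
style. The kernels are built for bright lines on dark background (positive
Gaussian profile, mean-subtracted, response floored at 0) because the tube
phantom is bright; this is the same matched filter as the dark-vessel
convention up to sign.

Binarization is never specified in the source comparisons, so a single
deterministic, scale-free rule is used everywhere: threshold at
mean + 1 std of the response. Special-function filter outputs are min-max
rescaled to [0, 1] and binarized by the same rule, so filters and operators
are scored on equal footing.

## Phantoms and what they do (not) show

Generators are pure functions of their arguments, seed included. The edge
rasterization rule, used by every generator and by scoring: a pixel is an
edge pixel iff some 4-neighbor carries a different region label and the
pixel's own label is not the background label; generators without a
background (the step edge) use only non-background labels, so both sides of
the discontinuity are marked.

- shapes: 3–6 non-overlapping rectangles/disks, distinct gray levels on an
  even grid over [0.2, 0.9], background 0.1, 2-px clearance.
- step: two half-planes, degenerate contrast allowed.
- NIR tube: a rotated bright bar (peak 0.9) over a dim background (0.1)
  carrying mild multiplicative texture, Gaussian-blurred (σ = 3) to mimic
  tissue scattering; the blur uses a wrap boundary so its normalized kernel
  conserves total image energy exactly. The edge mask is the pre-blur tube
  boundary.

Default phantom size is 256×256 — large enough for the frequency-domain
gains to resolve their transition region, small enough for sub-second
tests; the noise-robustness comparisons average over 10 phantom/noise seeds
and the noise statistics over 20.

These phantoms emulate the *geometry* of the evaluation targets (piecewise
constant regions, a blurred bright tube), not their photometry: no shot
noise, no camera transfer curve, no real tissue autofluorescence, no
texture inside regions. Passing tests show the filters' mathematical
behaviors and their relative orderings under impulse noise on such scenes;
they do not certify performance on real photographs or clinical NIR frames.

## Metrics

PSNR is `10·log10(1/MSE)` for [0, 1] images, with identical images reported
as a capped 99 dB. Boundary F1 matches predicted to true edge pixels within
a Chebyshev radius (default 1 px) by greedy one-to-one assignment without
replacement (scan order, nearest unmatched candidate first); two empty
masks score 1, one empty mask scores 0. At radius 0 the score is symmetric
in its arguments. The 1-px default tolerance absorbs the half-pixel
ambiguity of rasterized boundaries without rewarding coarse localization.

## Known limitations

- The noise-robustness margin of the exp filter over Sobel at density 0.9
  is real but small (≈ 0.002–0.004 mean F1 over the 10-seed families used
  here); at 90 % pixel replacement both methods are close to the floor, and
  individual seeds can order either way.
- The sech-asech gain's cosine-branch zeros make its low-frequency response
  non-smooth; this is inherent to the defining function, not a numerical
  artifact.
- Frequency filters assume periodic image extension (plain FFT, no
  windowing); strong border discontinuities can ring.
- JPEG output is lossy; quantitative work should use PNG/TIFF (16-bit
  round-trips are exact to 1/65535 per pixel).
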