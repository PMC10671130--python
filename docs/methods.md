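# Methods

## Color pathway

Spectra are converted to CIE 1931 tristimulus values by trapezoid
integration against the 2° color-matching functions, embedded at a 5 nm
grid (380–780 nm) and linearly interpolated onto the spectrum's own
wavelengths. For transmittance spectra the integrand is weighted by the
illuminant power (D65 table or equal-energy E); emission spectra are
integrated directly. A single scalar — 1 / ∫ I(λ) ȳ(λ) dλ over the full
table — normalizes the result so that the illuminant alone (equivalently a
transmittance of 1) maps to its white point with Y = 1. Integrating D65
against the embedded tables reproduces the canonical white point
(0.9505, 1.0000, 1.0888) to 1 × 10⁻⁴, which bounds the table error
relevant here.

sRGB follows IEC 61966-2-1: the standard linear matrix (its inverse is
computed numerically, so the round trip is exact to machine precision) and
the piecewise gamma. Out-of-gamut values are clipped to [0, 1] after
companding and flagged; CIELAB is always computed from the *unclipped* XYZ,
which is why LAB coordinates printed from a saturated spectrum need not
round-trip through the clipped RGB triple. CIELAB uses the D65/2° white
(0.95047, 1, 1.08883) — the white sRGB itself is defined against — and the
standard cube-root function with the linear segment below (6/29)³.
LCh is the cylindrical form: C = √(a² + b²), h = atan2(b, a) mapped to
[0, 360), with h = 0 by convention for achromatic colors. 8-bit
quantization rounds half-up, floor(255x + 0.5): this reproduces the
observed 0.57 → 145 mapping of the free-dye color.

## Pixel classification

A scanned layer holds four pixel kinds. The rules, in order:

1. **Achromatic** if the maximum pairwise channel difference is ≤
   `gray_tol` (default 20 levels). This is the diagonal band of a
   two-channel histogram — scanner noise, white background, black marks.
   The test runs before the white rule so a near-white melted square with
   negligible chroma is excluded either way.
2. **White domain** if every channel ≥ `white_floor` (default 245): the
   melted-polymer squares that bind little gelatin and hence little dye.
3. **Chromatic** otherwise.

Only chromatic pixels whose blue channel strictly exceeds both red and
green ("blue-dominant" — the minimal operational reading of "blue pixels")
enter the blue-channel histogram (256 bins of width 1, no information loss
on 8-bit data). The histogram is deconvolved as

n · [w φ(x; μ₁, σ₁) + (1 − w) φ(x; μ₂, σ₂)]

fitted to the bin counts by unweighted nonlinear least squares
(trust-region reflective, bounds 0 ≤ μ ≤ 255, σ ≥ 1, 10⁻⁶ ≤ w ≤ 1 − 10⁻⁶).
Initialization is deterministic — the two most prominent local maxima of a
moving-average-smoothed histogram (window 5), with segment moments for the
σ and w starts — so repeated fits are bit-identical. The saturated boundary
bins 0 and 255 are excluded from both the peak search and the residuals:
8-bit saturation piles all out-of-range mass into them, which would
otherwise bias a component sitting near the range limit (the light shade
around 240 with σ ≈ 10 loses ~10 % of its mass to bin 255). Fits with
fewer than 100 pixels are refused. A result whose means are closer than
the wider σ, or with less than 2 % of the mass in one component, is
flagged degenerate (effectively unimodal) with a warning.

Pixels are assigned to the darker (bound) or lighter (free) shade by
maximum posterior under the fitted mixture, evaluated from a 256-entry
log-posterior lookup; exact ties go to the darker shade. On synthetic scans
the confusion rate against ground truth tracks the analytic Bayes error of
the generating mixture (≈ 7 × 10⁻⁴ at the default means 195/240 and
σ 8/6), and the vectorized assignment is tested to agree with a per-pixel
brute-force posterior on every pixel.

## Profiles across the membrane thickness

The per-layer fraction of shade-class pixels over all pixels is the
surrogate for local dye concentration; layer 1 faces the source solution.
The unbound-dye interface is fitted with a 4-parameter logistic
f(i) = lower + (upper − lower)/(1 + e^{−k(i − m)}) over the layer index
(per-layer thickness is uniform by construction, so index and depth are
equivalent). Fitting uses bounded least squares with deterministic
edge-mean initialization; the parameterization is canonicalized to
lower ≤ upper (swapping asymptotes negates the steepness without changing
the curve), which makes the fit equivariant under layer-order reversal:
midpoint reflects about the stack center, steepness changes sign. The
bounds are symmetric under that reflection, and they also stop the
steepness from wandering when a flat profile leaves it unidentifiable. A
fitted range (upper − lower) below 0.05 declares the profile
interface-free — the thin-membrane regime where the dye has equilibrated.
The 0.05 threshold is a design choice: it cleanly separates the flat and
interface regimes on synthetic stacks at realistic counting noise.

Bound dye follows the gelatin, which accumulates at both edges of the dried
stack, so its profile is edge-peaked rather than sigmoidal. Regime labeling
therefore checks the U-shape first (edge mean exceeding the central mean by
0.05, with the two edges agreeing better than they differ from the center)
and otherwise lets the logistic fit decide between interface and uniform.

Bound-dye fraction vs gelatin weight per area uses the Pearson coefficient
(the claim under test is proportionality, with axes aligned at zero) plus
the least-squares line of fraction on weight. Pooled (weight, fraction)
pairs from several stacks are split into two groups by 2-means on
standardized coordinates with deterministic farthest-pair initialization
(lexicographic tie-breaks keep the result invariant to input order); the
smaller group is labeled the outlier cluster. No significance test is
attached to the two-cluster structure — none is claimed.

## Diffusion traces

The receiving-cell concentration trace is segmented into first wave,
plateau, and optional second wave. The first wave ends where the smoothed
local slope (centered differences, moving average of 3) stays below
`slope_tol` (default 0.15) times the median first-wave slope for two
consecutive samples; the boundary is then sharpened by a local
rise-then-flat broken-stick fit. The second wave is typically an order of
magnitude slower than the first, so its onset cannot be found with the
same threshold: instead a flat-then-rise broken-stick model is fitted over
the whole post-wave-1 tail by breakpoint grid search. The rise is accepted
only if its slope exceeds 3 standard errors, accumulates at least 5
residual standard deviations by the end of the trace, and the
flat-then-rise model beats the rise-then-flat alternative — a monotone
saturating tail fits the latter better and is rejected, as is a flat tail.

Each wave's coefficient is D_eff = (dn/dt) · l / Δc with dn/dt the
least-squares slope over the segment and Δc evaluated at the segment's
midpoint *time* (interpolated between samples; the midpoint minimizes the
secant bias of a changing difference, and interpolation removes the
half-sample bias of picking a discrete midpoint index). The trace stores
concentration, so dn/dt is a concentration rate and the cell volume/area
factors are deliberately absorbed into the user-supplied trace: the
reported coefficient is on the conventional scale the trace was calibrated
to. "Per single layer" means division by the layer count, equivalent to
using the single-layer thickness — consistent with per-layer values being
smaller than whole-membrane ones. Estimates require ≥ 3 points, a positive
slope, and Δc > 0.

## Synthetic data: what it emulates, and what it does not

Scans: white background, axis-aligned white squares on a regular grid
(pitch 64 px, size 24 px — the bonding pattern is regular in the real
textile), two shade populations with Gaussian blue channels (defaults
μ = 195 and 240, σ = 8 and 6, inside the observed dark-shade range 180–210
and light cloud near 240), and achromatic noise pixels (v, v, v) with
uniform v (default 2 % of pixels). Shade pixels carry red = 0.33·blue and
green = 0.37·blue, bracketing the channel ratios of both resonance-state
colors while guaranteeing blue dominance and a chroma spread of 0.67·blue,
far above the gray tolerance. Gaussian draws are clipped to the valid
range rather than redrawn; the induced bias is negligible for σ ≤ 12 at
the default means and the boundary-bin exclusion in the fit removes the
rest. Class counts are rounded from the target fractions and placed
uniformly at random, so realized fractions are exact to one pixel.
Not modeled: fiber texture, illumination gradients, scanner optics,
geometric structure in where each shade occurs. Passing tests show the
estimator chain is correct under the assumed statistical structure, not
that real scans satisfy that structure.

Traces: the first wave is c(t) = c₀(1 − e^{−kt}) with k = D_eff,true / l,
whose initial slope D_eff,true · c₀ / l inverts the quasi-steady relation;
the trace is cut to a plateau while the receiving cell is still well below
the source (default cut at k·t ≈ 0.5, i.e. ≈ 39 % of c₀), which is the
regime where the relation applies and where the plateau physically arises
from gelatin uptake rather than equilibrium. The second wave is linear
(the release of bound dye is modeled as a constant-rate process), with
Gaussian noise (default sd 2 × 10⁻⁴ g dm⁻³, ≈ 1 % of the trace range)
added throughout. Defaults emulate an 8-layer membrane: per-layer
coefficient 26 × 10⁻⁹ m² s⁻¹ (inside the reported 25–28 × 10⁻⁹ band),
thickness 1 mm, source 0.04 g dm⁻³, 5-minute sampling over 4 h. The
5-minute interval is a design choice matching manual spectrophotometer
sampling; it also sets the resolution at which change points are
detectable against the noise. Gelatin weights are fraction / 0.1 g m⁻²
plus Gaussian noise, floored at zero (a fraction of 0.3 ↔ 3 g m⁻², the
order of the fabric's own 17 g m⁻² areal weight).

All generators are pure functions of (recipe, seed).

## Numerical and interface choices

* Mixture fitting is unweighted least squares on counts; with 10⁵ pixels
  and well-separated peaks the difference from Poisson weighting is far
  below the ±2-level acceptance band, and unweighted is more robust to
  empty bins.
* The 2-D histogram channel pair is a parameter (`ch_x`, `ch_y`); red–blue
  and green–blue views are both in use for the same diagnostic purpose.
* Whether a supplied spectrum is absorbance or transmittance is not always
  recorded; both modes are supported and the caller chooses.
* The CLI writes classified maps as indexed PNG (white / dark blue / light
  blue), profiles and counts as CSV, and a JSON summary embedding the
  package version, every parameter, and a hash of the configuration, so a
  rerun with the same config is byte-identical.
* Problem sizes in the test suite (scan edges 128–500 px, 10⁵-pixel
  histograms, 100-replicate grids) are chosen so the full suite runs in
  well under a minute of CPU per property while keeping binomial counting
  error an order of magnitude below every acceptance band.

## Known limitations

* The coefficient scale absorbs cell geometry (volume, exposed area); the
  printed m² s⁻¹ unit is conventional unless the input trace is calibrated
  for it. Comparisons *within* a study (between waves, across layer
  counts) are unaffected.
* The printed hue h = 281 of the bound-shade color is not reproducible
  from its own printed LAB coordinates (6, −17), which give h ≈ 289; only
  the chroma is asserted for that color.
* Gray rejection by channel spread cannot distinguish a genuinely gray
  sample region from scanner noise; the method assumes the membrane's
  signal is chromatic.
* Two-Gaussian deconvolution assumes exactly two shades. Heavily
  overlapping populations (|μ₂ − μ₁| below the wider σ) are flagged
  degenerate rather than resolved.
* The sigmoid interface is fitted on layer index, not physical depth, and
  assumes uniform per-layer thickness.
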