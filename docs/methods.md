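# Methods

## Model and assumptions

An X-ray angiogram projects contrast-filled vessels onto a 2D detector; the
beam path through a cylindrical vessel is longest at its axis, so vessels
appear as dark tubes whose intensity rises from the centerline to the edge.
The pipeline assumes (i) vessels are locally tubular, so the intensity
Hessian has one small eigenvalue along the vessel and one large positive
eigenvalue across it (dark tube), and (ii) centerlines are ridge lines of
the *vesselness* image, i.e. curves along which the enhancement response is
maximal in the transverse direction.

### Scale-space derivatives

All derivatives are Gaussian derivatives: the image is convolved with
sampled derivative-of-Gaussian kernels (separable, mirror borders, support
truncated at 4σ) and order-k responses are multiplied by σᵏ
(γ-normalization with γ = 2), without which the cross-scale maximum of the
multiscale filter would systematically favour small scales. The sampled
kernels are moment-corrected: the order-1 and order-2 kernels are adjusted
to have exactly zero sum and exact unit response to x and x²/2. This is not
cosmetic — the ridge criterion below tests the *sign* of derivative fields,
and the ~5·10⁻⁴ residual sum of a naively sampled second-derivative kernel
at σ = 1 fabricates curvature proportional to the local mean, firing the
criterion across entire flat regions. Truncation at 4σ costs about 0.4 % of
the second-moment mass; the closed-form scale-space values are reproduced
to that accuracy and the sign structure exactly.

The 2×2 symmetric Hessian is eigen-decomposed in closed form
(λ = mean ± √(((a−c)/2)² + b²)); both ordering conventions are provided
because the two consumers need different ones: the Frangi response uses
magnitude ordering (|λ₁| ≤ |λ₂|), the ridge criterion algebraic ordering
(λ₁ ≤ λ₂, λ₁ the most negative = across-ridge curvature). Pixels with
coincident eigenvalues (relative gap ≤ 1e−12) are flagged degenerate, given
axis-aligned eigenvectors, and excluded from ridge cells, since their
eigenvector direction is meaningless.

### Vesselness

The single-scale response is implemented exactly as stated in the model:
zero when λ₂ < 0 (and at λ₂ = 0, the zero-structure limit), otherwise
`exp(−λ₁²/(2α²λ₂²)) · (1 − exp(−(λ₁²+λ₂²)/(2β²)))`. Defaults: α = 0.5 and
β = 10 (midpoints of the standard sensitivity ranges [0.25, 1] and
[5, 20]); scales linear in σ over [1, 4] with 7 samples, covering vessel
radii of roughly 2–5 px; ties in the scale maximum go to the smallest σ so
outputs are deterministic. β is in units of γ-normalized curvature of the
input intensity — for 8-bit angiograms with vessel contrast ~100 gray
levels, centerline λ₂ is a few tens, putting β = 10 in the sensitive range.
The final image is linearly rescaled so its maximum is 255 (`rescale_255`,
default on): the downstream seed-count threshold τ = 30 presupposes an
8-bit-like range.

### Ridge-cell detection

A ridge point satisfies v₁ᵀ∇I = 0 with λ₁ < 0. Ridge points lie at subpixel
positions, so each 2×2 cell is tested on its four corners: sign change of
v₁ᵀ∇I (strict max > 0 and min < 0) plus λ₁ < 0 at all corners implies, by
continuity and the intermediate value theorem, a ridge point inside the
cell; the anchor (top-left) pixel is emitted, trading subpixel accuracy for
zero interpolation cost. Eigenvectors carry an arbitrary sign, so corner
vectors are aligned against the anchor's before the sign test. A pixel
where v₁ᵀ∇I is exactly zero with λ₁ < 0 is itself a ridge point and is
emitted directly. The derivative fields of the vesselness image are taken
at σ_r = 1 (the Gaussian smoothing that restores the differentiability the
continuity argument requires; derivative-of-Gaussian filtering at σ_r
subsumes a separate pre-smoothing pass).

Two numerical guards make the criterion robust:

* **Machine-noise floor.** The sign tests are amplitude-invariant, so
  convolution roundoff (relative ~1e−15) in flat areas would fire cells on
  noise that is not in the data. Dot products and curvatures below 1e−9 of
  their field-wide maximum are snapped to zero first.
* **Positive-response gate (pipeline only).** The enhancement declares
  λ₂ < 0 pixels non-vessels by assigning response exactly 0; large
  background areas are therefore flat plateaus whose boundary creases still
  satisfy the cell criterion, yielding zero-response "seeds" that are
  non-vessels by the filter's own verdict and that drag the refinement
  median to 0. The pipeline therefore requires a strictly positive response
  at the anchor. The generic cell detector used on arbitrary analytic
  fields applies no such gate.

### Refinement

With P the vesselness values at all candidate seeds, the threshold is
T = median(P) − ω·MAD(P) and seeds with value ≥ T are kept (ties kept;
deterministic). ω defaults to 3; larger ω keeps more seeds. T ≤ median(P)
for every ω ≥ 0, so refinement always keeps at least half the candidates —
a structural property with consequences discussed under Limitations. P can
alternatively be sampled from the raw image (`refine_source="raw"`), though
for dark vessels the separation is far better in vesselness space.

### Metrics

TP/FP split the *refined* seeds by the ground-truth vessel mask; FN counts
in-vessel candidates the refinement wrongly discarded, making recall a
property of the refinement stage. NDSP counts detected seeds with response
strictly above τ = 30; NPSP counts detected seeds on background; FDR is
their ratio NDSP/NPSP as defined in the evaluation protocol — note that as
defined it *increases* when detection improves, so the reciprocal (pseudo
seeds per detection) is reported alongside. N1 is the refined seed count
and N2 the number of distinct branch labels holding at least one refined
seed. Ratios are kept at full precision and rounded to 3 decimals only at
report time.

## The phantom generator

Phantoms emulate: dark polyline tubes with circular-projection
(`√(1−(d/r)²)`, the ideal cylinder chord length — the default) or Gaussian
(std r/2) cross-sections; branch radii, depths and layouts including bends
and bifurcations; additive white Gaussian noise (a mandatory RNG seed, no
global state); and exact ground truth (centerline points, distance-based
mask, first-branch-wins labels). The standard bifurcation phantom is
512×512 with radii 2.5–5 px, contrast (depth) 100 on background 200, and
contrast-to-noise ratio 5 (noise σ = 20) — a deliberately harsh noise
condition; see Limitations. They do not emulate: anatomy-realistic trees,
cardiac motion, scatter, quantum (Poisson) noise, detector blur, or the
spatially correlated background texture of real fluoroscopy.

Sizes used by the test suite and acceptance script — 128–512 px phantoms,
7-scale enhancement, 64-point (α, β) sweeps — run in seconds on one core
and were chosen as the smallest instances that exercise every stage at the
standard conditions.

## Known limitations

* **Amplitude-blind detection on stochastic backgrounds.** The cell
  criterion fires wherever the smoothed vesselness has a ridge line,
  regardless of ridge height. White pixel noise of *any* nonzero amplitude
  textures the background response, and its smoothed field has ridge lines
  crossing ~30 % of cells; on the standard 512² phantom (vessel mask 2.2 %
  of pixels) background candidates outnumber vessel candidates ~80:1 at
  CNR 5 — and nearly as badly at CNR 50, since lowering the noise lowers
  the ridges but does not remove them.
* **The median-anchored threshold cannot reject a majority.** Because
  T ≤ median(P), refinement removes at most the lower half of the candidate
  population. When background candidates dominate, precision is capped near
  twice the true-candidate fraction (measured ≈ 0.013 on the CNR-5 phantom,
  independent of ω). The refinement model implicitly assumes candidates are
  mostly true seeds — which holds on clinical angiograms whose enhanced
  background is effectively flat (and quantized to a constant in 8-bit
  storage), and on noise-free phantoms (precision 1.0, all seeds within
  2 px of the centerline, all branches found), but not under white pixel
  noise. Passing tests on noise-free phantoms therefore validate the
  geometry of detection, not robustness to uncorrelated pixel noise.
* **Thresholded-count trends can invert.** On the noisy phantom the count
  of seeds above τ rises with α (the blob factor exp(−λ₁²/(2α²λ₂²)) is
  pointwise non-decreasing in α, and rescaling is anchored at a
  α-insensitive centerline maximum) and falls with β, while the
  *un-thresholded* candidate count and the background count NPSP move the
  opposite way (fewer, smoother background ridges). Which direction a
  reported NDSP trend takes thus depends on the background share of the
  candidate pool.
* **Saturation squeezes the refinement margin.** On clean phantoms the
  response saturates near the rescaled maximum along the entire centerline,
  so MAD(P) is tiny and T sits just below the median, discarding ~20 % of
  centerline seeds (recall ≈ 0.75–0.84). A response with more dynamic range
  across vessels (clinical images; the multiscale-tree phantom) widens the
  margin.
* **Borders.** Mirror reflection makes monotone intensity at the image edge
  look locally ridge-like; detection within a kernel radius of the border
  is less reliable.
* 2D only; a single global ω; no spatial regularization or linking of seeds
  into centerlines (downstream tracking's job).
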