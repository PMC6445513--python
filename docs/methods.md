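# Methods

## Forward model

RICM intensity at radial distance *r* from a sphere's contact axis is
modelled as two-beam interference between the coverslip reflection and the
probe reflection, with a finite illumination aperture:

```
p_template(r) = sinc(y) · cos(2 k h(r) · (1 − sin²(α/2)) + θ)
y            = 2 k h(r) · sin²(α/2)
k            = 2 π n / λ,   α = asin(INA / n)
h(r)         = max(0, d + p − √(p² − r²))
```

The clamp in *h* crops the sphere at the coverslip plane: for *d* ≤ 0 the
gap is exactly zero inside the contact circle of radius
`r_c = √(2 p |d| − d²)`, producing the flat core whose value is cos θ
(−1 for the standard θ = π). Deviations of the outer fringes from this
ideal model are absorbed by an empirical envelope
`exp(−dec · (r/r_max)²)`; `dec` is a free search parameter, not a physical
constant. The exponent is normalized by `r_max²` so that the standard
range dec ∈ [0, 10] spans identity to e⁻¹⁰ attenuation at the profile
edge — the un-normalized reading would annihilate every fringe.

Model assumptions worth keeping in mind: the probe is a perfect sphere
(neck deformation and menisci at the contact line are ignored), the
reflection geometry is planar (no slope-dependent reflectivity), and the
absolute height is ambiguous modulo the interference period
`λ/(2n)·(1 − sin²(α/2))` ≈ 0.185 µm for the standard optics. For adhering
probes (*d* ≤ 0) the flat core removes the ambiguity, which is why the
reported relative height uses phase index i = 0.

### Parameters (standard values)

| symbol | meaning | default |
|---|---|---|
| u | pixel length | 0.067 µm/px |
| λ | wavelength | 0.53 µm |
| INA | illumination numerical aperture | 0.67 |
| n | medium refractive index | 1.332 |
| θ | phase shift | π |
| r_max | template radius | 100 px |
| d | particle height (search) | −0.45 … 0 µm, step 0.01 |
| p | particle radius (search) | 10 … 30 µm, step 1 |
| dec | decay strength (search) | 0 … 10, step 1 |
| m | rays per position | 90 |
| c | candidate percentage | 1 % |
| a | minimum profile amplitude | 0.05 of image range |
| t₁ | minimum best correlation | 0.9 |
| t₂ | minimum ray-to-mean correlation | 0.5 |

Templates are sampled at integer pixel radii 1…r_max (the on-axis value is
not stored; at r = 0 all rays would read the same pixel). The constraint
p ≥ r_max·u keeps the sampled extent inside the sphere. Note the standard
search space keeps every grid point *identifiable*: the largest contact
radius (5.18 µm at d = −0.45, p = 30) stays inside the 6.7 µm sampled
extent, so fringes always remain visible beyond the flat core. Shrinking
r_max (as some fast tests do) breaks this and collapses distinct (d, p)
onto identical all-core profiles.

## Pipeline

**Preselection.** Sobel gradients (3×3 kernels, edge replication) vote for
centers: every pixel whose gradient magnitude exceeds 5 % of the image
maximum draws a line r_max px in both directions along its gradient
orientation into an accumulator. Lines are rasterized by stepping along
the dominant axis (Bresenham-equivalent; each pixel counted once per
line); bidirectional drawing is required because fringe-edge gradients
alternate between pointing toward and away from the center. The brightest
c % of accumulator pixels (ties included, zeros excluded) become match
candidates.

**Matching.** At each candidate, m rays of length r_max px are sampled
with bilinear interpolation (ray i points along (sin 2πi/m, cos 2πi/m) in
(x, y)); out-of-bounds points are excluded and positions with < 50 %
coverage rejected (zero-padding would fabricate symmetry). The ray mean
p_mean is gated by amplitude ≥ a·(observed image range) — Pearson
correlation is amplitude-blind, so flat noise would otherwise match — and
by mean ray-to-p_mean correlation ≥ t₂, a radial-symmetry test. Survivors
are correlated against the bank; the best index and correlation enter a
map. Zero-variance vectors correlate 0 by convention; correlation ties
break to the lowest bank index. Per-position results are independent, so
the map is a pure function of its inputs.

**Extraction.** Iteratively: take the map maximum, suppress a disc of
radius r_max, repeat until the maximum falls below t₁ or max_iterations
(default 100) is reached. Each accepted position gets a second,
extrema-focused matching pass: the slope-synchronism score counts radial
steps where profile and template rise/fall together, normalized by r_max
(only r_max − 1 differences exist, so the maximum score is 0.99). Fringe
extrema positions encode the particle size directly, which makes this
pass the size estimator; its template replaces the first-pass template for
all derived measurements. Ties break to higher Pearson correlation, then
lowest index.

*Flatness tolerance.* Template slopes are exact (undecayed contact cores
are exactly flat), but a measured profile is never exactly flat under
noise; with a literal sign comparison the true flat-core template would
earn zero credit in its core while oscillating templates earn ~50 % by
chance. The refinement therefore classifies measured slopes below 5 % of
the profile's steepest slope as flat. The 5 % value was fixed by a
tolerance sweep (0/0.05/0.1/0.2) on exploratory simulations covering both
decayed and flat-core scenes and is not exposed as a search parameter.

**Derived measurements.** Contact radius from the refined (d, p);
diameter 2p; relative height d (i = 0, ambiguity noted above); adhesion
energy from JKR only when E and v are supplied (absent otherwise, never
silently zero). Microns are converted to meters only at the JKR boundary.

## Contact-radius validation

The intensity-based reference grows a 1-D region outward along p_mean
from the center reference intensity I₀ (mean of the first three radial
samples — the innermost samples are the noisiest because radial averaging
degenerates near r = 0) while the intensity stays below
I₀ + threshold·(profile amplitude). The radius is the last accepted pixel
radius times u; a sweep of 40 thresholds from 1 % to 40 % reproduces the
sensitivity/overestimation trade-off, and the 30 % threshold is the
default operating point. Region growing systematically stops past the
geometric contact edge (the gap opens gradually), so it overestimates —
most strongly for shallow contacts on large spheres, where the gap opens
slowest. The OLS of model on intensity radius (slope ≈ 1.07, intercept
≈ −0.5 µm, adjusted R² ≈ 0.989 on the synthetic cohorts) quantifies the
agreement; adjusted R² uses the single-predictor correction
`1 − (1 − R²)(n − 1)/(n − 2)`.

## Synthetic scenes

The generator renders the forward model directly: pixel value =
background + contrast · Σ particles (template intensity × decay), then a
multiplicative radial vignette `1 − s·(ρ/ρ_max)²`, then i.i.d. Gaussian
noise, clipped to [0, 1]. Defaults: background 0.5, contrast 0.25 (the
model never states a camera mapping; this affine choice gives visibly
dark cores), noise σ 0.02 of the dynamic range, vignette 0. Particle
parameters are drawn uniformly from the search-grid values so exact
recovery is possible; centers are real-valued (sub-pixel) with an r_max
margin. Scenes are bit-reproducible from their seed.

The validation cohorts are: 50 single-particle 512×512 scenes for
localization/size/match-quality, and 200 adhering-particle 256×256 scenes
for the contact-radius regression. The contact cohort is rendered with
dec = 0, i.e. a genuinely flat dark core: the decay envelope is an
empirical correction for *outer-fringe* amplitudes, and multiplying it
into the core (as the literal template formula does) brightens the core
radially until the region-growing criterion trips far before the contact
edge — a rendering artifact, not a property of real adhering probes,
whose cores are flat. The detection bank still spans the full decay
range.

What the synthetic scenes do **not** emulate: contact-line necks and
menisci, slope-dependent reflectivity, shot noise and camera nonlinearity,
clutter (dust, bubbles), and model mismatch in general. Passing the
closed-loop tests therefore demonstrates the pipeline's correctness and
noise robustness under the model's own assumptions, not robustness to
real-image artifacts. One consequence is measurable: on on-model scenes
the first-pass Pearson match is already a near-perfect size estimator, so
the extrema-focused second pass — whose advantage on real images comes
from its robustness to model mismatch — cannot improve on it here (its
MAE is ~0.3 µm vs ~0.1 µm for the first pass; both far inside the µm-level
accuracy the method targets).

## Numerical choices and edge cases

- Bilinear interpolation for ray sampling (nearest-neighbor distorts the
  fine inner fringes, whose period approaches 4 px).
- Image range for the amplitude gate = observed max − min after bit-depth
  normalization, robust to under-exposed frames; batch normalization is by
  bit depth so intensities are comparable across a batch.
- Accumulator percentile threshold is computed over all pixels, with ties
  kept: the candidate count may slightly exceed c %.
- Degenerate inputs: constant images yield zero gradients, an empty
  candidate set, and no detections; constant profiles raise on region
  growing (undefined amplitude) and correlate 0 with everything.
- Detections never sit closer than r_max px (suppression is asserted by
  construction) and never carry correlation < t₁.
- The pipeline is deterministic; randomness exists only in scene
  generation and derives entirely from explicit seeds.

## Known limitations

- Integer-pixel localization; no sub-pixel center refinement.
- Absolute height is reported only as the i = 0 offset.
- Sizes snap to the search grid (1 µm steps in p); off-grid truth
  resolves to a neighboring grid point.
- The slope-synchronism pass loses discrimination when strong decay
  (dec ≳ 7) pushes outer-fringe slopes below the noise floor; sizes may
  then be off by one grid step.
- E and v are user-supplied constants; the package does not fit them.
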