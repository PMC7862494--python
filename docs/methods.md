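# Methods

## Model and assumptions

A myelinated fiber is idealised as a circular cylinder whose axis deviates
from the nerve-bundle axis by a dispersion (tilt) angle θ ∈ [0°, 90°). A
transverse section then cuts the fiber in an ellipse with semi-minor axis
`r` equal to the cylinder's base radius and semi-major axis `R = r/cos θ`.
Two consequences drive the whole package:

1. the section area is inflated by `ρ = 1/cos θ` relative to the base
   circle, so area- and perimeter-based circle-equivalent diameters
   overestimate fiber size, increasingly and non-linearly with tilt;
2. the minor diameter of the section equals the base diameter `2r` at every
   tilt, so a tilt-independent size estimate exists.

Since an ellipse is uniquely determined by its (area, perimeter) pair, `r`
is recoverable from the two measurements standard segmentation software
exports. The inversion combines `A = πrR` with the Gauss–Kummer series
`p = π(r+R) Σ binom(½,n)² hⁿ`, `h = (R−r)²/(R+r)²`, truncated at four terms
after substituting `R = A/(πr)`:

    p(r; A) = π (A/(πr) + r) (1 + h/4 + h²/64 + h³/256),
    h = ((A − πr²)/(A + πr²))².

The model deliberately ignores non-elliptical (crenated) profiles beyond
what the (area, perimeter) pair encodes, axial caliber fluctuation, and any
3-D trajectory estimation.

## Numerical choices

- **Root finding.** `p(r; A)` is strictly decreasing in `r` on
  `(0, r₀ = √(A/π)]`, diverging as `r → 0⁺` and attaining its minimum
  `2√(πA)` (the isoperimetric bound) at `r₀`. The solver runs a safeguarded
  Newton iteration with an analytic derivative, initialised at `r₀`, keeping
  a bracket and substituting a bisection step whenever the Newton step
  leaves it; since `dp/dr = 0` exactly at `r₀`, the first step is always the
  bisection safeguard. Convergence is declared on the radius step
  (relative 1e-10, max 100 iterations) rather than on the residual: near
  the circular limit the residual is quadratically flat in `r`, and a
  residual criterion would leave radius errors around 1e-5. A bisection
  oracle agrees with the solver to 1e-8 relative on randomized inputs.
- **Infeasible inputs.** Measured perimeters below `2√(πA)` cannot arise
  from any ellipse (they occur through upstream smoothing artifacts); such
  records are clamped to the circle-equivalent diameter with
  `feasible=False` and counted, never dropped.
- **Series length.** Four terms match the truncation used in the inversion
  equation; `n_terms` is exposed, and `ellipse_perimeter_exact` (complete
  elliptic integral of the second kind) serves as the sub-ppm reference.
  At `R/r = 3.9` (θ = 75°) the four-term truncation perturbs the recovered
  diameter by ~4e-5 relative — negligible against the 0.1% round-trip
  tolerance.
- **Angles** are degrees at every interface, radians internally.
- **Feret diameters** are computed on the convex hull: the maximum as the
  largest pairwise hull-vertex distance, the minimum by rotating calipers
  over hull-edge normals, which is exact for polygons (the minimum width is
  attained perpendicular to a hull edge). No angular sampling is involved.
- **Assignment.** Centroid distances feed
  `scipy.optimize.linear_sum_assignment`. Among equal-cost matchings the
  lexicographically smallest (axon, fiber) index sequence is selected by a
  constrain-and-resolve pass, exact for problems up to 64×64; larger
  problems return scipy's (deterministic) solution directly. Real centroid
  data essentially never ties.
- **Pair filtering.** Default distance cut-off is the candidate fiber's own
  SAE radius — the centroid of a correctly segmented axon lies inside its
  fiber. An optional point-in-polygon containment check is off by default.
  Pairs with g-ratio ≥ 1 are flagged invalid, reported, and excluded from
  myelin statistics; dropped and unmatched structures are always reported.
- **Kernel smoothing** uses a Gaussian kernel with the normal-reference
  (Silverman) bandwidth, evaluated on a grid extending five bandwidths past
  the data range so the density integrates to 1 within 1e-3.
- **Size classes** are right-closed as printed: (0–4], (4–10], (10, ∞) µm.
- **Overestimation** of a traditional method versus SAE is reported on two
  bases: the mean basis `100·(mean_m − mean_sae)/mean_sae` (primary,
  matching the mean ± SE reporting convention) and the per-fiber median
  `100·median(d_m/d_sae − 1)`. The median is taken per fiber because the
  design is paired — every fiber is measured by all four methods — whereas
  a ratio of pooled medians is unstable for multimodal size distributions
  (the pooled median can sit on either side of the inter-mode trough).

## Synthetic generator

`sample_population` draws fibers from a Gaussian size mixture, a tilt model
(uniform on [0, θmax] by default, folded-normal available), and a g-ratio
model whose mean rises linearly with fiber diameter (defaults 0.60 +
0.006/µm, sd 0.04, clipped to (0.05, 0.95) — placeholders in the
physiological band, as no numeric slope is established). The default
mixture approximates ventral-root composition: small autonomic (~2.5 µm),
γ-motor (~4 µm) and α-motor (~11 µm) components. Inner (axon) contours are
the outer contour scaled by the g-ratio about the shared centroid, so
pairing and g-ratio recovery have exact ground truth. Fibers sit on a
jittered grid to keep centroids distinct. Everything derives from one
seeded generator; populations are bit-reproducible.

**Boundary noise and vertex density.** Noise is multiplicative and radial —
each vertex radius is scaled by `1 + noise·u`, `u ~ U(−1,1)` independently
per vertex — which preserves star-convexity, hence simplicity, for any
amplitude < 1. Because the perturbation is white across vertices, its
effect on the measured perimeter grows with vertex density (relative
inflation ≈ ε²n²/12π² for amplitude ε and n vertices), while polygon
discretization deficits shrink as 1/n²; for ε = 2% the combined perimeter
error is minimised near n ≈ 26. The default `vertices_per_contour = 32`
(the smallest supported) therefore treats the noise as click-placement
jitter at manual-tracing granularity (~0.3–1 µm point spacing across the
2–12 µm fiber range). Noise-free validation contours use fine polygons
(360–3600 vertices), where discretization error is negligible.

**What the generator does not emulate:** crenated or locally concave
myelin profiles, spatially correlated tracing error, Remak-bundle geometry,
partial or merged segmentations, and degeneration/regeneration morphology.
Passing tests therefore demonstrate correctness of the geometry and of the
inversion under the stated error model, not robustness to every failure
mode of real segmentation.

## Parameters that matter

| parameter | default | unit | role |
|---|---|---|---|
| `tolerance` (solver) | 1e-10 | relative | Newton step convergence |
| `max_iter` | 100 | — | Newton/bisection budget |
| `n_terms` | 4 | — | truncation of the perimeter series |
| `boundary_noise` | 0.02 | fraction | radial vertex jitter amplitude |
| `vertices_per_contour` | 32 | — | tracing point density |
| `max_distance` (pairing) | fiber SAE radius | µm | pair plausibility cut-off |
| `bin_width` | 0.5 | µm | histogram resolution |
| `um_per_pixel` | 1.0 | µm/px | input scale (never guessed) |

## Known limitations

- The inversion is ill-conditioned near the circular limit: at θ = 0 the
  perimeter is stationary in `r`, so a relative perimeter error δ maps to a
  relative diameter error ≈ √(4δ/3). Perimeter over-measurement (jagged
  boundaries, dense noisy vertices) therefore biases SAE diameters low,
  most strongly for untilted fibers; the ~0.5% residual error on noiseless
  1800-vertex polygons is exactly this discretization-driven effect.
- The dispersion angle printed alongside each solution is the inversion
  `arccos(r/R)` of the recovered ellipse; for non-elliptical profiles it is
  an effective, not a physical, angle.
- Shape descriptors are computed from scalar measurements, so tables
  lacking Feret columns yield NaN for the Feret-based descriptors rather
  than imputed values.
- Multi-axon (Remak) bundles violate the one-axon-per-fiber assumption of
  the assignment step and are out of scope.
- Validation sizes are chosen to keep the suite fast (populations of
  2000 fibers, bundles of 20–50, assignment matrices to 7×7); all
  population-level checks are stated as properties of those sizes.
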