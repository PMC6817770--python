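# Methods

## Problem and approach

Small cerebral vessels (arterioles and venules in the 10–40 μm range)
are hard to tell apart in single cross-sections: both carry smooth
muscle cells and pericytes, so immunostaining is ambiguous, and the
classical criterion — lumen diameter divided by wall thickness — breaks
down for venules of arteriole-like size.  TEM morphometry of canine
cerebral vessels showed that the **lumen:wall area ratio**

    R_A = A_L / A_W

separates the two classes cleanly: venules occupied 1.89–10.96 (mean
3.9489, n = 81), arterioles 0.27–1.57 (mean 0.9317, n = 31), with no
overlap and a rank-test difference at p < 0.001, while the classical
**diameter:thickness ratio**

    R_D = D_L / T_W

overlapped heavily between groups (1.58–22.66 vs 1.40–11.63) and could
not separate vessels below the arteriole-group mean of 4.97 (p = 0.817).

`vesselmorph` implements that measurement pipeline over segmented
3-label cross-section masks (background / lumen / wall) and validates
every stage against a synthetic generator with exact analytic ground
truth, because the original image set is not publicly deposited.

## Synthetic vessel model

A vessel is a pair of closed curves, star-shaped about a common centre:

* **Lumen boundary** `R_in(θ)` — an ellipse radius (semi-axes a ≥ b)
  multiplied by `1 + Σ ε_k cos(kθ + φ_k)` with two Fourier orders drawn
  from {3, 4, 5} and total amplitude ≤ 0.2, so lumens are flattened and
  irregular but never self-intersecting (the radius stays positive by
  construction).
* **Outer boundary** `R_out(θ) = R_in(θ) + t(θ)` with radial thickness
  `t(θ) = t0·(1 + m·cos(kθ + ψ))`, k ∈ {1, 2}, m ≤ 0.5 — walls may be
  strongly eccentric (thin on one side), as real vessel walls are.

Thickness is defined **radially** (along rays from the construction
centre) rather than along the local normal.  This is a deliberate
modelling choice: it matches the measurement geometry of the ray-casting
estimator, keeps both boundaries star-shaped (fast, exact-centre
rasterization), and makes the wall area *exactly quadratic* in `t0`, so
the base thickness that realises a target area ratio has a closed-form
solution.  The cost is that for elongated lumens the radial thickness
exceeds the normal thickness at oblique points — which is also true of
the ray estimator applied to real walls, and is why the
distance-transform cross-check (a normal-thickness measure) is reported
alongside.

Both radii are trigonometric polynomials, and all areas are computed by
the midpoint rule on a uniform 4096-point angular grid, which is exact
for trigonometric polynomials of degree < 2048.  Truth areas are
therefore exact to floating-point rounding; nothing in the truth record
comes from the raster.

**Ratio-targeted construction.**  The generator's controlled primitive
is the true area ratio: for each vessel a target `R_A` is drawn, the
lumen is drawn from the group's nuisance distributions, and `t0` is
solved from `A_W(t0) = B·t0 + C·t0² = A_L / R_A` (positive root).  The
generator asserts the realised ratio is within 1e-6 of the target; in
practice it is exact to machine precision.

**Rasterization.**  A pixel belongs to a region iff its centre lies
inside it (no anti-aliasing); pixel centres sit at integer row/column
coordinates, the construction centre at the image centre.  Areas are
pixel counts × (μm/px)².  At the default 0.05 μm/px, raster areas agree
with truth to well under 1 %.

## Default study conditions

The default population reproduces the published study design:

| parameter | group 1 (venule-like) | group 2 (arteriole-like) |
|---|---|---|
| n | 81 | 31 |
| true R_A law | scaled Beta on [1.89, 10.96], mean 3.9489 | scaled Beta on [0.27, 1.57], mean 0.9317 |
| lumen equivalent radius | U[4.8, 8.0] μm | U[3.9, 5.5] μm |
| lumen aspect ratio a/b | U[1.2, 4.0] | U[1.0, 1.6] |
| boundary perturbation | U[0, 0.15] | U[0, 0.12] |
| thickness modulation m | U[0.1, 0.5] | U[0.05, 0.3] |

Choices where the source reports nothing:

* **Beta concentration κ = α + β = 5** for both ratio laws.  The Beta
  family is the natural bounded law; κ = 5 gives a right-skewed group-1
  distribution (density rising toward the lower bound with a long upper
  tail, consistent with the reported "exponential increase in ratio with
  the largest vessels") while staying unimodal for group 2.
* **Absolute lumen sizes** are unreported beyond the 70 μm² floor; the
  ranges above give total vessel areas of roughly 80–450 μm², safely
  above the floor for every admissible ratio, so the default study never
  trips the exclusion filter (matching the published accounting of
  112 analysed vessels).
* **Venule lumens are flattened** (aspect up to 4), arteriole lumens
  near-round — venules collapse readily at low transmural pressure,
  arterioles have a thick supporting media.
* Per-vessel RNG streams derive from
  `SeedSequence(master_seed, spawn_key=(group, index))`, so vessels are
  independent of population size and runs are bit-reproducible.

What the generator does **not** emulate: TEM texture and noise,
segmentation error (masks are clean by construction), oblique sections,
pathology as image content (the pathology flag only exercises the
exclusion plumbing), sub-compartments of the wall (endothelium, basement
membrane and intramural cells are one closed region).  Passing the
recovery tests therefore validates the *measurement and inference*
chain, not robustness to segmentation noise.

## Estimators

* **Areas**: label pixel counts × pixel area.  Total area is the exact
  pixel-arithmetic sum of lumen and wall.
* **Lumen diameter**: equivalent circular diameter `D_L = 2√(A_L/π)` by
  default.  Small-vessel lumens are rarely circular, so a caliper width
  is ill-defined; max- and min-Feret diameters (rotating calipers on
  the convex hull) are available via `diameter_method`.
* **Wall thickness**: 360 equally spaced rays from the lumen centroid;
  along each ray the labels must read lumen → wall → background with
  exactly one crossing of each boundary; crossings are located at the
  midpoint of the flanking quarter-pixel samples; `T_W` is the mean over
  valid rays, and the valid-ray fraction is recorded.  When the centroid
  falls outside a strongly non-convex (e.g. crescent) lumen or fewer
  than half the rays are valid, the estimator falls back, with a
  warning, to a distance-transform measure: 2 × the mean distance to the
  nearest boundary over the wall's medial axis.  The fallback value is
  always computed as a cross-check and both are reported when they
  disagree by more than 10 %.
  A third option, `thickness_method="local"` (the first valid ray
  only), deliberately emulates the historical single-line manual
  protocol; see below.
* **Exclusion filter**: applied in order — pathology flag, then
  non-transverse section, then total area strictly below 70 μm² (the
  floor that removes capillaries and post-capillary venules; 70.0 μm²
  exactly is kept, per the strict "less than" wording of the source
  protocol).  Excluded vessels are measured and flagged, never dropped.

Estimator accuracy on the default population (asserted in the tests):
areas within 1 % of truth; thickness within 5 % for near-uniform walls.
For strongly eccentric walls (m close to 0.5) the ray mean is taken
about the lumen centroid while the truth mean is about the construction
centre, which re-weights the angular average; errors up to ~10 % occur
there, and the tests assert a 12 % envelope for those vessels.

## Classification and statistics

The area-ratio rule assigns arteriole for `R_A ≤ 1.57`, venule for
`R_A ≥ 1.89`, and an explicit **indeterminate** for the open gap — the
empirical evidence supports separation only outside the observed ranges,
so inventing a boundary inside the gap would overstate it.  A binary
mode (threshold = geometric midpoint ≈ 1.723, configurable) exists for
users who need two-way output.  The diameter-ratio classifier encodes
the negative result: venule above threshold (default 4.97), otherwise
indeterminate.  (The source reports the arteriole-group mean diameter
ratio as 4.348 in its results text but uses 4.97 in the below-threshold
re-test; both constants are exposed, the re-test default is 4.97.)

The Mann–Whitney U test is implemented from first principles: U from
midrank sums; exact two-sided p by full enumeration of the
C(n1+n2, n1) label arrangements for pooled sizes ≤ 16; otherwise the
normal approximation with tie-corrected variance and 0.5 continuity
correction.  Two-sided p throughout.  All-tied input degenerates to
p = 1 with a warning.  The implementation is cross-checked in the tests
against an independent pair-counting permutation oracle and against
`scipy.stats.mannwhitneyu`.

## Why the diameter-ratio ranges do **not** overlap under mean-based estimators

The published data show heavy R_D overlap between groups.  Under this
package's default estimators that overlap *cannot* occur, and the reason
is a small theorem rather than a bug:

For a star-shaped region, the mean radial wall thickness satisfies
`T̄ ≈ A_W / (2π r̄_mid)`, and by Cauchy–Schwarz the mean radius of any
star-shaped domain is at most its equivalent radius (`r̄ ≤ √(A/π)`).
Combining the two, every vessel obeys

    R_D  ≤  2 / (√(1 + 1/R_A) − 1),

the circular-annulus curve, with equality for circles; non-circular
shapes only *reduce* R_D (by ≤ ~20 % for aspect ratios up to 5).  The
curve maps the disjoint R_A supports to R_D ≥ 8.45 (group 1) versus
R_D ≤ 7.16 (group 2): an 18 % gap that shape variation cannot bridge.
So with equivalent diameters and any mean-type thickness, disjoint
area-ratio supports force disjoint diameter-ratio ranges — the
acceptance check expecting majority overlap at defaults fails, and is
left failing.

The published numbers themselves confirm that the original measurements
were not means: the reported group-2 maximum R_D of 11.63 *exceeds* the
annulus bound of 7.16 attainable for any R_A ≤ 1.57.  A single manual
line measurement samples the wall at one spot; on an eccentric wall
(m = 0.5) that spot can be half or double the mean.  The package's
`thickness_method="local"` emulates exactly that, and with it the
default populations do produce overlapping R_D ranges in most seeds
(demonstrated in the test suite).  This strengthens, rather than
weakens, the substantive conclusion: the classical criterion is
unreliable partly *because* wall thickness is usually measured locally.

## Numerical and reproducibility notes

* Angular grid 4096 nodes; ray estimator 360 rays at 0.25 px steps.
* Default raster: 0.05 μm/px on a 960-px canvas (48 μm field), sized so
  the largest admissible default vessel (flattened venule, semi-major
  ~16 μm, plus wall) always fits; the generator raises a sizing error
  rather than cropping.
* The medial-axis computation uses a fixed tie-breaking RNG so pipeline
  outputs are byte-identical across runs; no output file contains
  timestamps.
* The 20-seed validation studies (tests and acceptance script) use
  20 × 112 vessels; at default resolution a full 20-seed sweep runs in
  ~2–3 minutes on one core.
* Degenerate inputs: empty groups, all-background masks, non-positive
  areas, empty restricted subgroups and unsatisfiable geometry all raise
  typed errors naming the offending vessel or group.

## Known limitations

* Masks are assumed correct; no segmentation-noise model.
* Radial thickness semantics differ from normal thickness for elongated
  lumens (documented above; the distance-transform cross-check exposes
  the difference, typically 10–25 % for aspect ≥ 2.5).
* Oblique-section correction is out of scope; non-transverse vessels are
  excluded, not corrected.
* The Feret min estimator uses the convex hull, so for strongly concave
  lumens it measures the hull's width, not the true minimal caliper of
  the region.
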