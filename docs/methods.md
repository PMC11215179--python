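# Methods

This note records the measurement model, the defaults that matter, what the
synthetic generator does and does not emulate, and the numerical choices
made where the underlying procedure was open.

## Dish calibration

All physical indices are denominated through the dish, not through camera
metadata: the dish is a circle of known physical radius `Rp` (default
45 mm, the standard 90-mm plate), so the fitted rim supplies the
millimetre-per-pixel scale `mm_per_px = 2Rp / diameter_px`, the rim pixel
count `np` and the interior pixel count `NP`. This makes every index
invariant to camera distance and resolution (verified: rendering one scene
at 2× pixel density changes R, L, A by < 2 %).

The default detector thresholds the Sobel edge magnitude at half the Otsu
level (half, so that a high-contrast colony cannot push the threshold above
the fainter dish-rim gradient), pools the edge map by block-maximum onto a
coarse grid (~128 px on the short side), and runs a circular Hough
transform over radii between 18 % and 49 % of the short image side. Because
a textured colony interior supports many spurious high-score small circles,
the dish is taken as the *outermost* radius whose best normalized
accumulator reaches 85 % of the global maximum — not the highest peak. A
second strong centre at that radius, more than half a radius away, raises
an ambiguity error (two dishes in frame). The winning circle is refined by
an algebraic least-squares (Kåsa) fit to the full-resolution edge pixels
within a band around it, which lands the centre within ~2 px and the
diameter within 1 % on generator output.

Rim pixels `np` are counted on the 1-px midpoint (Bresenham) rasterization
of the fitted circle. Whether a photographed rim's inner or outer edge
"is" the dish is not observable at our accuracy; the fitted-circle
convention is reproducible and independent of rim thickness.

## Segmentation and boundary convention

The colony is segmented inside the dish interior (eroded by 3 px to exclude
the rim) by gray-level thresholding: both Otsu's method and the triangle
method are evaluated and the candidate with the stronger
foreground/background mean separation wins. Otsu handles the common
balanced case; the triangle method covers small faint colonies whose
foreground class is too rare for Otsu's between-class criterion. A
segmentation whose foreground/background contrast falls below 10 gray
levels is declared *empty* and flagged rather than raised — near-blank
degraded plates are legitimate inputs. When the interior is uniform, the
gray level outside the dish is used as a background reference to
distinguish a colony that fills the dish from a blank plate. Cleaning is
morphological closing (disk radius 2), hole filling, and largest
8-connected component.

Boundary pixels (`nv`) are mask pixels 4-adjacent to background — the
8-connected digitized contour. For a digitized disk this count is ≈ 0.90 ·
2πr, the same constant the Bresenham rim count carries (≈ 0.90 · πd), so
the ratio `nv/np` in the perimeter formula cancels the digitization bias.
Counting instead the pixels with *any* background 8-neighbour would give
≈ 1.27 · 2πr and a systematically inflated perimeter.

## Index conventions

* All lengths are millimetres; areas mm². The radius is
  `mm_per_px·(ZL+ZS)/4` — the mean half-extent of the axis-aligned bounding
  box — so a circular colony's R equals its true radius, and an ellipse
  reports the mean of its semi-axes.
* Roundness `L²/(4πA)` is exactly 1 for analytic circles; digitized-circle
  masks land in [0.95, 1.10] because of the boundary-count convention.
* Negative growth/change rates are reported with a warning, never clamped:
  a regressing degraded colony is signal, and clamping would also hide
  segmentation faults.

## Groove depth (GLCM contrast)

The co-occurrence matrix is restricted to the colony region (both pixels of
a pair must lie in the mask — stock rectangular-window implementations
cannot do this, so counting is done directly and is cross-checked against
the standard implementation on full rectangles). Defaults: 8 quantization
levels over [0, 255] (`level = ⌊g·8/256⌋`), the four unit offsets
(0,1), (1,0), (1,1), (1,−1), symmetric, normalized, contrast averaged over
offsets. All settings are echoed into the analysis metadata since
magnitudes are only comparable at fixed settings.

At unit offsets the contrast of a radial-groove pattern grows with groove
*amplitude* but also with local spatial frequency: grooves sinusoidal in
polar angle get wider (lower contrast) as the colony radius grows at fixed
groove count. Within a cohort analyzed at one configuration the index is a
monotone readout of groove strength at comparable colony sizes; across very
different colony sizes it mixes amplitude and scale. Density `WB` is the
raw mean intensity over the mask (brighter = denser, the white-mycelium
convention), so it is exactly invariant to anything outside the mask.

## Synthetic plate generator

Each plate is: uniform background (default gray 55), a 3-px dish rim
annulus darker than background (gray 15) at a known pixel diameter, an
elliptical colony of given semi-axes with base gray, an intensity
modulation `amplitude · sin(count·θ + φ)` emulating radial grooves, and
clipped additive Gaussian noise. Identical spec + seed is bit-identical.
Ground truth carries the exact masks, analytic radius/perimeter, mask-count
area and the mm/px scale.

The generator emulates what the measurement chain consumes — calibratable
rim, controllable contrast, groove texture, noise — and deliberately not
what it does not: no illumination gradients, no condensation or reflections,
no aerial hyphae height, no lobed/sectored outlines beyond ellipticity, no
agar color. Passing tests therefore demonstrate correctness of the
*measurement pipeline* on plates whose truth is known, not robustness to
every pathology of real photographs.

Cohort simulation draws per-sample parameters uniformly from per-group
ranges. The four presets are ordered qualitatively like a
subculture-degeneration panel — the 14th-passage group largest but
sparsest/darkest with the shallowest grooves, the degenerated group
smallest but dense and grooved, day-2 radii around 5–8.5 mm growing to
15–35 mm by day 8 — with noise σ = 3 gray levels. The preset numbers are
free generator parameters chosen once for plausibility, not measurements.
Default cohort plates render at 640×512 px with a 420-px dish; the
geometry-recovery checks use the full 1280×980 frame with an 800-px dish.
The acceptance cohort is 4 groups × 30 samples × 2 days (240 images,
~35 s on one CPU).

## Enzyme calculators

Cellulase: the standard curve is inverted
(`x = (ΔA + 0.0462)/2.5090` mg/mL), scaled by the reaction volume βf,
corrected to the whole extract by βt/βs, and normalized per minute and per
gram: the composed prefactor at the published parameters is
1000·βf·βt/(slope·βs·T) = **79.71**, matching the published rounded 79.6
within 0.2 %. Laccase uses the published simplified endpoint form
78.52·ΔA/W by default. Composing the laccase formula from its stated
parameters (ε = 36 L·mmol⁻¹·cm⁻¹, d = 0.5 cm, βf = 0.3, βs = 0.045,
βt = 1 mL, T = 20 min) instead yields a constant of 18.52; the two do not
reconcile under any grouping we attempted, so the parameter pathway is
exposed (`use_simplified=False`) but documented as unverified. Negative ΔA
passes through unclamped.

## Group statistics

The F statistic comes from the classical between/within sums-of-squares
decomposition with p from F(k−1, N−k); results agree with the reference
implementation to 1e-8 and the null rejection rate at α = 0.05 calibrates
to 0.03–0.07 over 1000 replicates. Pairwise comparisons default to
pooled-variance t tests (the classical Bonferroni post hoc; Welch
available), adjusted p = min(1, raw·k(k−1)/2). Compact letters use the
insert-and-absorb algorithm with groups ranked by descending mean, so the
largest group receives "a"; the letter display provably reproduces the
thresholded significance relation. Degenerate inputs: identical data in
all groups is an error; zero within-group variance with unequal means
reports F = ∞, p = 0 with a warning; single-observation groups report
SD = 0 with a warning. Because F is invariant under affine maps of the
response, index pairs related by fixed linear transforms (radius vs growth
rate at fixed timepoints) share one F value — a useful internal
consistency check on summary tables.

## Known limitations

* One dish, one colony per frame; multi-colony plates and lens distortion
  are out of scope.
* The perimeter estimate inherits the digitized-boundary convention; on
  very small colonies (< ~10 px radius) quantization dominates.
* Groove depth is configuration-dependent (levels/offsets) and mixes
  amplitude with spatial scale across colony sizes.
* The laccase parameter pathway is published-form-first (see above).
* The segmentation reference-background heuristic for saturated plates
  assumes the area outside the dish is visible and darker/brighter than the
  mat in the same direction as the agar.
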