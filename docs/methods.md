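# Methods

This package implements an object-based image analysis (OBIA) workflow for
detecting medusahead (*Elymus caput-medusae*), an invasive annual grass that
stays green after the surrounding Mediterranean annual grassland has
senesced, in very-high-resolution (0.15 m) four-band visible/near-infrared
imagery. Because no public imagery/field dataset exists for this problem,
the package ships a synthetic-scene generator that emulates the study
conditions — a senescent-grass matrix, green medusahead patches, and the
confuser vegetation types that make the detection hard — together with a
simulated transect survey, so that every stage of the pipeline is testable
end to end against known truth.

## Pipeline

1. **Derived layers.** NDVI = (NIR − red)/(NIR + red) as a greenness proxy,
   and local Moran's I in a 3×3 moving window as a per-pixel
   local-heterogeneity metric. Moran's I uses binary (not row-standardized)
   weights over the 8 window neighbours and global standardization,
   `I_i = (x_i − x̄)/s² · Σ_j w_ij (x_j − x̄)`; edge pixels sum over the
   neighbours that exist. The layer it is computed on defaults to NDVI and
   is configurable. With these weights a two-colour checkerboard has
   interior I exactly 0 (diagonal and axial neighbours cancel); negative
   values mark genuine local contrast.

2. **Segmentation.** Bottom-up region merging from single-pixel objects.
   A merge of objects 1 and 2 into *m* costs
   `f = (1 − w_shape)·Δh_color + w_shape·Δh_shape` with
   `Δh_color = Σ_b w_b [n_m σ_b(m) − n_1 σ_b(1) − n_2 σ_b(2)]` and the
   shape term blending compactness (perimeter/√area) and smoothness
   (perimeter/bounding-box perimeter), each size-weighted the same way. A
   merge executes only while `f < scale²`; merging proceeds by mutual best
   fitting (a pair merges when each is the other's cheapest neighbour, ties
   broken by object id), which makes runs deterministic without a seed. A
   scale scan (mean within-object standard deviation and its percent rate
   of change over increasing scales, peaks flagged) reproduces the usual
   scale-selection diagnostic. Nested segmentation runs coarse→fine with
   fine merges forbidden to cross coarse boundaries, giving a strict object
   hierarchy (parent map).

   *Scale semantics.* The published scale parameters for this problem
   (10/176/390, shape and compactness weights 0.1) were tuned on 8-bit-like
   digital numbers. The generator emits unitless [0, 1] reflectance, so
   layers entering segmentation are affinely mapped to a 0–255 range (bands
   ×255, NDVI (v+1)/2·255, Moran's I clipped to ±8 then scaled). This keeps
   the published scale values meaningful; it is a units choice, not a
   tuning knob.

3. **Object attributes.** Per object: means of every layer, standard
   deviations of blue and green, all-direction GLCM entropy of NIR and
   green (symmetric co-occurrence over the four distance-1 offsets,
   restricted to pixel pairs inside the object; min–max quantization per
   object; natural log; 0·ln 0 = 0), area and perimeter.

   *Quantization depth.* The object table uses 16 gray levels, not the 64
   of the generic entropy routine's default. GLCM entropy is bounded by
   ln(number of co-occurrence pairs); primitive objects at 0.15 m offer so
   few pairs that at 64 levels every texture — smooth canopy and strong
   mosaic alike — saturates near that bound and the statistic stops
   discriminating. At 16 levels the smooth/mosaic contrast is ~0.5 nats
   with a third of the spread.

   *Feature families.* Spectral = object means of the four original bands
   ("the individual input image bands"). NDVI and Moran's I are derived
   layers: mean NDVI is used by the hierarchy's greenness tiers but is not
   a single-run spectral feature — as a nonlinear band ratio its object
   mean carries a Jensen bias under sub-pixel modulation, which would leak
   texture information into a nominally spectral comparison. Mean Moran's I
   is a spatial-heterogeneity quantity and belongs to the texture family,
   with the standard deviations and GLCM entropies.

4. **Classifiers.** Three single-run supervised algorithms — 1-NN (k
   configurable), Gaussian naive Bayes with equal priors (training counts
   are design-balanced, not prevalence estimates), and a linear-kernel SVM
   with C = 1 and one-vs-one margins — under a three-class
   (medusahead / other green / other non-green) and a seven-class
   vegetation scheme, with and without the texture features; features are
   standardized by training statistics. Unsupervised: seeded k-means
   (best of 10 restarts) scanned over 10–30 clusters with the
   within-cluster variance curve recorded and local second-difference
   deviations flagged; clusters capturing ≥ 5 % (θ, configurable) of the
   medusahead training samples are labelled medusahead — an explicit
   numeric stand-in for a visual cluster-identification step, deliberately
   permissive.

5. **Hierarchical classification.** Five steps over the nested
   segmentation: (i) coarse objects with mean NDVI < 0.15 *and* farther
   than 30 m from every medusahead training sample are excluded; (ii)
   coarse objects with NIR GLCM entropy ≥ 4.65 are isolated as the
   vetch/ryegrass mosaic communities, which do not host medusahead; (iii)
   mid-scale objects are classed as canarygrass (green-band entropy
   ≥ 4.85), storksbill (taken verbatim from an optional mask polygon), or
   split into the wild-oat / clover-brome medusahead associations by the
   configured supervised algorithm on band means plus blue/green standard
   deviations; (iv) fine objects within each association are split into
   three NDVI tiers by one two-threshold Otsu run per association, the
   least green tier leaving as non-medusahead; (v) the rest are classified
   into medusahead / barbed goatgrass / other on exactly mean red, mean
   NDVI and NIR GLCM entropy. Every fine object gets a terminal label and a
   provenance record naming the step that fixed it, so the containment
   guarantee (no medusahead inside excluded or mosaic-isolated regions) is
   auditable. The entropy/NDVI thresholds were calibrated once on a
   packaged fixture scene and live in `HierarchyConfig`; recalibration for
   other conditions is a config edit.

6. **Fuzzy accuracy.** Test plots carry a best (maximal-cover) class and
   any other class at ≥ 5 % cover as acceptable. Samples are evaluated as
   1 m × 1 m squares centred on the recorded (GPS-jittered) points. MAX =
   proportion of predicted-target samples whose best class is the target;
   RIGHT = proportion whose best-or-acceptable classes include it;
   diff = RIGHT − MAX; producer's accuracy = proportion of best-target
   samples whose square contains ≥ 1 classified-target pixel. "Classified
   as target" uses the centre pixel for MAX/RIGHT and any-pixel-in-square
   for producer, matching the asymmetry of the two questions; both supports
   are configurable. RIGHT ≥ MAX is asserted on every report, and 0/0 is
   reported as NA with a zero count, never as 0.

7. **Transect validation.** Classified medusahead is sampled along each
   transect at half-pixel steps; maximal runs are extended to half-step
   cell boundaries (a centre-to-centre estimate would bias every gap up by
   one step) and merged across gaps ≤ 20 cm, the same separation rule the
   field protocol uses. Two metric sets per length category (≤ 0.5,
   0.5–2, 2–7, > 7 m; closed upper bounds): intersections with the field
   segments (under-prediction) and with the full transect lines
   (over-prediction), each as counts and mean lengths against the field
   statistics.

## Synthetic scenes: what they emulate, and what they do not

Cover fractions are tracked per pixel (always summing to 1); reflectance is
the cover-weighted mixture of class spectra plus class-specific texture and
spatially correlated noise (canopy micro-texture is smooth at 0.15 m, so
white noise would be wrong — and would also destroy the GLCM contrast
between smooth cover and true mosaics). Patches are random ellipses whose
length distribution puts ≈ 3× the weight on the ≤ 0.5 m category relative
to the mid categories, with a thin tail above 7 m. The confusers follow
their field descriptions: barbed goatgrass with near-medusahead spectra;
canarygrass as clumped green/gap structure whose object means sit between
green and dry grass; vetch and ryegrass mixtures as bright, fine,
per-pixel-varying mosaics (continuous variation — a binary mosaic is
*lower* entropy under min–max quantization than a smooth gradient, an
instructive failure of the first implementation); clover-brome at
intermediate greenness, half its patches carrying 5–35 % subdominant
medusahead; wild oat as tall senescent grass that can hide understory
medusahead rendered at 45 % greenness. Texture fields are mean-centred over
each class's own cover so class means equal the configured palette exactly.

Three palette presets are study conditions, not knobs: `realistic` (the
default, all confusers active), `separable` (all palettes pushed apart and
layered canopy mixing off — a 50/50 two-species canopy pixel is a mixture
no palette separation can disambiguate, so it cannot probe spectral
separability; clover-brome subdominant mixing stays because the
acceptable-class test stratum needs it), and `texture_only` (canarygrass
given medusahead's exact band means, differing only in weak clump structure
plus fine per-pixel modulation kept below the region-merging threshold and
in the bands with radiometric headroom, so only texture attributes can
separate the pair at object level).

The survey simulator lays out 20 transects (five groups of three, one of
four, one single; headings random, the base point drawn uniformly from the
exact feasible box) with ten 0.5 m plots at 10 m spacing each, records
medusahead crossings with the > 20 cm separation rule, reads plot cover
from a 0.5 m window, and jitters recorded locations uniformly within a
0.3 m GPS radius (clamped to the site). Off-transect "walkabout"
candidates add uniform points plus deliberate visits inside known patches;
candidates whose centre-pixel dominant class differs from the windowed best
class are discarded by default — surveyors centre reference plots inside
stands, and uniformly dropped edge-straddling plots turned out to dominate
the apparent commission error. Sample designation takes the highest-cover
examples per class at the design counts (50/50/50/50/40/30/30 = 300
training) and a stratified test set (best-medusahead / non-medusahead /
non-medusahead-with-medusahead-acceptable, 50 each).

Not emulated: topography and illumination, radiative transfer, sensor PSF
and calibration, phenological time series, spatially autocorrelated class
placement (patches are placed independently), and surveyor misjudgement of
patch identity. Passing tests therefore demonstrate that the *workflow* is
correct and that its error structure responds to mixing, texture and
geolocation noise the way the method's logic predicts — not that any
particular accuracy level would be attained on real imagery.

## Numerical choices

- **Otsu thresholds** maximize between-class variance over a 256-bin
  histogram (64 in some oracles), exhaustively; the optimal partition is
  chosen with ties to the lexicographically smallest cut, and each cut is
  reported as the midpoint of the empty histogram gap it falls in (every
  cut inside a gap is equally optimal; the midpoint is the canonical
  representative). Three greenness categories use one two-threshold run,
  not two sequential binary ones.
- **Merging order** is mutual best fitting with a deterministic tie-break;
  if no mutual pair is admissible while admissible edges remain, the single
  globally cheapest admissible edge merges (progress guarantee).
- **Degenerate inputs**: constant layers raise for Moran's I and Otsu;
  empty regions raise for GLCM entropy; constant regions have entropy 0;
  single-pixel objects get sd = 0 and entropy = 0; associations with < 3
  distinct NDVI means pass through the tier step un-tiered, flagged.
- **Conflicting training labels** exclude the object (with a warning)
  rather than majority-voting; boundary-straddling co-occurrence pairs are
  discarded rather than clamped.
- **Seeds**: every stochastic step takes an explicit seed; per-method child
  seeds derive from the master seed by method index, so adding a method
  never perturbs another's result. Benchmark harnesses re-draw a scene
  deterministically when a 0.23 ha draw cannot fill the sampling design
  (site selection), and split texture benchmarks across scenes because
  objects of one scene share patch-level texture offsets a within-scene
  split would leak.

## Problem sizes

Default experiment scene 96 m × 48 m (0.46 ha, 640 × 320 px) with the full
300/150 sample design; benchmark scenes 48 m × 48 m (0.23 ha) with a
scaled design (12/8/8/10/8/6/6 training, 15/15/15 test strata); detection
recovery averages 10 scenes, texture necessity pools 12, the transect
signature pools 4 surveyed scenes. These sizes keep a full run in the
minutes range on one core while leaving every patch-length category
populated.

## Known limitations

- The region merger follows the published fusion-criterion formulation;
  object-for-object agreement with any proprietary implementation is not a
  goal (and not testable).
- MAX is structurally capped for overclassification-prone methods whenever
  test plots carry subdominant medusahead: detecting genuinely present
  5–35 % medusahead counts against MAX while RIGHT credits it. The
  three-class linear SVM sits lowest for exactly this reason, and Gaussian
  Bayes under the three-class scheme absorbs medium-cover stands into the
  multimodal other-green class — both mirror the published finding that the
  collapsed class scheme is not necessarily beneficial.
- The transect-signature comparison is soft: field "small" segments include
  short edge chords of large patches, which adds noise in both directions
  of the mean-length comparison; only the large-category undercount is a
  robust direction under the packaged degradation model.
- GLCM entropy on objects of a few dozen pixels is a high-variance
  statistic even at 16 levels; texture-based discrimination needs object
  support (the texture benchmarks segment at scale 30 for this reason).
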