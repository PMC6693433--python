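# Methods

`wbrtplan` implements a three-stage automatic planning workflow for
tangential-field whole-breast radiotherapy (WBRT) with electronic tissue
compensation (ECOMP), exercised entirely on procedurally generated thorax
phantoms with a self-contained linear dose engine.  This note records the
models, the parameters that matter, the numerical choices, and what a green
test does and does not establish.

## The planning problem

Post-lumpectomy WBRT delivers 50 Gy in 25 fractions of 2 Gy through two
nearly parallel-opposed "tangential" photon fields (medial and lateral) that
graze the chest wall, sparing lung and heart.  Because the breast presents a
strongly varying thickness to the beams, a flat fluence produces an
inhomogeneous dose; in ECOMP planning the planner paints a per-beamlet
fluence map for each beam until the 3-D dose is uniform.  Large-separation
patients additionally receive part of their fluence at a higher energy
(6 MV + 15 MV, "mixed energy", ME) because the harder beam has a flatter
depth-dose curve.  The automated workflow replaces the three manual
decisions:

1. **Energy selection** — DRRs (ray-cast thickness projections) are rendered
   for both beams, reduced to a pooled gray-level histogram, and classified
   SE vs ME in the space of the first two principal components of the
   training cohort's histograms.
2. **Fluence estimation** — a random forest (150 trees) maps per-beamlet
   anatomy features to the fluence intensity a trained planner would have
   painted, learned from "teacher" plans.  For ME plans the predicted total
   fluence is split into 6 MV / 15 MV components by a learned monotone
   function of the beamlet's penetration depth through the breast.
3. **Fine-tuning** — dose anchor points on the transverse isocenter plane
   are balanced between the beams (centrality correction) and the fluence is
   iteratively rescaled until every anchor dose is within tolerance of
   prescription; this is also the interactive lever for patient-specific
   coverage or hot-spot adjustments.

## Synthetic world

No clinical data is shipped or downloaded; the phantom generator is a
first-class, tested module.

* **Anatomy.** Chest = elliptical cylinder (semi-axes ~130 x 90 mm, 5%
  per-patient jitter); breast = half-ellipsoid fused to the antero-lateral
  chest surface.  The *separation* (chest-wall chord between medial and
  lateral field entries, 14-27 cm across the cohort) sets the base width of
  the half-ellipsoid.  Anterior protrusion and superior-inferior extent
  follow the separation allometrically (`ap = 0.42 s - 1.4 cm`,
  `si = 0.6 s + 2.0 cm`, 6% relative jitter): larger breasts protrude
  proportionally more, which is what keeps the per-patient-normalized DRR
  histograms class-separable.  Ipsilateral lung (relative electron density
  0.25) is a shrunken ellipse kept >= 18 mm (chest wall) from the skin;
  the heart (always left-sided) hugs the antero-medial chest wall.  Breast
  tissue density is 0.95, body and heart 1.00, all configurable.
* **Evaluation target.** The breast half-ellipsoid cropped 5 mm from the
  skin, the standard convention for breast target evaluation; without the
  crop the build-up shell dominates coverage statistics.
* **Cohort labels.** SE separations are drawn U(14, 20) cm, ME U(21, 27) cm;
  the 1 cm class gap is a modeling choice (the clinical assignment criterion
  is not anatomically defined) that makes the toy task learnable and lets
  the label be exactly `separation >= 21 cm`.
* **Teacher plans.** The ECOMP-style initial fluence (uniform per-beam dose
  at 40% depth) tuned to convergence (tolerance 1%, <= 50 iterations) by this
  package's own fine-tuner.  This circularity is deliberate: the forest is
  validated as *mimicking its training policy on unseen anatomy*, which is
  exactly the premise of learning fluence from prior plans.  ME teacher
  plans split fluence by the logistic rule
  `f_low(d) = 1 / (1 + exp((d - 11 cm)/2 cm))` in breast penetration depth;
  the split-model recovery test asks whether fitting recovers this rule.

What the generator does **not** emulate: CT texture and noise, contralateral
anatomy, couch/immobilization hardware, realistic lung in-field volumes (the
convex chest ellipse plus 18 mm clearance keeps the tangents clear of lung,
so lung V10/V20/V95 are ~0 on most phantoms and those endpoints are
degenerate in cohort comparisons), and scatter-mediated skin dose.  A green
cohort test therefore establishes internal consistency of the method on
separation-driven anatomy variation — not clinical dosimetric accuracy.

## Dose engine

A divergent pencil model, linear in fluence by construction (the fine-tuner
and the superposition tests rely on this):

    dose(v) = w(pixel(v)) * C_E * PDD_E(d_rad(v)) * ((SSD_ref + d_max)/r(v))^2

with `PDD(d) = N (1 - e^{-kd}) e^{-mu d}` normalized to peak 1 at
`d_max = ln((k+mu)/mu)/k`.  Defaults: 6 MV `mu = 0.050 /cm, k = 2.0 /cm`
(d_max 1.86 cm); 15 MV `mu = 0.035 /cm, k = 1.2 /cm` (d_max 2.97 cm);
calibration `C_E` = 200 cGy per weight-unit at d_max, SSD 90 cm, so teacher
plans land near prescription without rescaling surprises.  Radiological
depth is accumulated on a beam-aligned "fan" (one ray per fluence pixel,
trapezoidal integration at 2 mm steps, trilinear interpolation everywhere),
which is shared by DRR rendering, feature extraction, anchor bookkeeping and
dose computation.  Fluence lookup is nearest-pixel (beamlets are piecewise
constant), with an optional Gaussian beamlet spread (sigma 3 mm, applied
once to the incident fluence in BEV coordinates — equivalent to a per-depth
convolution for a depth-constant kernel and exactly linear).  The central
beamlet on a water slab matches the closed form to < 1e-3 relative; the
trapezoid phase error at the skin ramp is the limiting term, which is why
that oracle runs at 1 mm fan steps.

The engine makes no attempt to match a commercial algorithm: the workflow
only requires a dose operator that is monotone and linear in fluence, and
the pluggable `EngineConfig` is the contract for swapping it.

## Beam geometry

IEC 61217 gantry scale, point source at SAD 1000 mm, patient coordinates in
mm (x right->left, y anterior->posterior, z inferior->superior), voxel
centers as positions.  Tangential gantry angles are found by a coarse/fine
1-D search (3 deg then 1 deg) minimizing in-field ipsilateral-lung volume
with a small in-field-body tiebreak toward the most grazing pair; the
aperture is the target projection hole-filled, dilated by a 7 mm margin and
extended 20 mm past the skin on the open-air side (skin flash).  Exact
per-voxel ray tracing (plane-crossing traversal) backs the unit oracles;
the sampled fan backs everything vectorized.

## Fine-tuning numerics

Anchors: 10 mm lattice on the iso-plane, >= 5 mm inside the target
(in-plane distance transform), then centrality correction moves each anchor
along the segment joining its two skin-entry points to the
penetration-balanced position (the original position stays admissible, so
imbalance never increases).  Anchors that collapse onto the same
beamlet-pixel pair are deduplicated (best-balanced representative), because
two anchors pulling one beamlet toward different doses create an artificial
convergence floor.

Update rule per iteration: (1) one global fluence rescale
`g = mean(targets)/mean(doses)` — exact under the linear operator, so local
updates only handle residual shape; (2) per anchor, multiply a Gaussian
neighborhood (sigma 7.5 mm) of its associated beamlet in *both* beams by
`(target/dose)^0.5`, with overlapping-anchor exponents normalized so
compounding neighbors cannot destabilize the update, and per-iteration
factors clipped to [1/4, 4] (a zero-dose anchor is flagged and capped, not
fatal); (3) 3x3 mean smoothing of the *multiplier*, aperture-weighted.  Two
numerical lessons are baked into (3): smoothing the accumulated fluence
instead of the update diffuses the compensator profile in rows no anchor
pushes back on, and a plain (non-aperture-weighted) moving average erodes
the field edge by one pixel per iteration.  Under this scheme the recorded
per-iteration max anchor deviation is non-increasing on the default suite,
and a single anchor with relaxation 1 and no smoothing converges in one
iteration (exact proportional solve).

Hot-spot accounting: the "tuning never increases V105cc" property is
evaluated on the raw dose pair the tuner manipulates.  Re-normalizing the
*untuned* RF dose to anchor-mean (a quantity the tuning stage itself
defines) cancels the tuner's global output correction and can mechanically
inflate the post-tuning hot spot; on raw doses the property holds on the
full held-out cohort.

Plan normalization for metric evaluation scales the final dose so the mean
anchor dose equals prescription (target median as fallback); it is
idempotent and separate from the dose operator.

## Learned components

* **PCA/LDA energy model.** Exact SVD of the mean-centered 20 x 64 histogram
  matrix (deterministic, no stochastic solver); PC1 sign oriented so the SE
  class mean is negative; a 2-D Fisher discriminant (pooled within-class
  covariance, tiny ridge) between the class clouds.  `boundary_angle_deg`
  reports how far the fitted boundary tilts from the degenerate PC1 = 0
  rule; ties classify as SE (the simpler plan).  64 bins keep the PCA
  well-conditioned for ~20-case cohorts.
* **Random forest.** sklearn `RandomForestRegressor`, 150 trees, unlimited
  depth, one-third features per split, bootstrap on, OOB score logged —
  library-typical regression defaults pinned for reproducibility.  Pixels
  are pooled across cases and beams with no per-case weighting (larger
  apertures contribute more pixels — accepted); pools above 60k pixels are
  subsampled uniformly, which preserves proportional contribution.  The
  seven-feature schema (gray level, breast/lung penetration depth,
  radiological path, signed field-edge distance, axis distance, SI offset)
  is versioned; prediction refuses schema mismatches.  Predictions are
  aperture-masked, 3x3 mean smoothed (aperture-weighted) and clipped >= 0.
* **Energy split.** Low-energy fraction vs breast penetration depth: 0.5 cm
  binned means, isotonic non-increasing projection, linear interpolation,
  flat extrapolation, clamped to [0, 1].  `high = total - low` guarantees
  recomposition to within one rounding ulp (bitwise equality is not an IEEE
  guarantee for `a + (b - a)`).

## Statistics

Eight endpoints (target V100%, V105%, V105cc, lung V10Gy/V20Gy/V95%, heart
mean %, plan max %) are compared pairwise with a one-sided Wilcoxon
signed-rank test in the "auto-plan is worse" direction per endpoint, at the
Bonferroni-adjusted level 0.05/8 = 0.00625 (printed 0.006).  Zeros are
dropped (classical convention), ties get mid-ranks; for n <= 25 the null
distribution of W+ is computed exactly by convolution over doubled ranks
(validated against full 2^n sign enumeration to 1e-12), beyond that by the
normal approximation whose variance term `sum r_i^2 / 4` absorbs the tie
correction, without continuity correction.  V-metrics use closed lower
bounds and voxel-count volumes (no partial-volume interpolation) so counts
are bit-stable; V90/V95 are computed and reported alongside but are not part
of the eight-endpoint test family.

## Known limitations

* Plan maximum doses (125-150% of prescription in thin near-skin slivers)
  exceed clinical practice: the scatter-free engine cannot blur grazing-ray
  peaks, and the compensator cap (3x median weight) only bounds them.
* Lung endpoints are degenerate (~0) on most phantoms, as noted above; the
  comparison machinery handles the all-zero-difference case (p = 1 with a
  warning) but those rows carry no information.
* Anchors default to the single iso-plane; `plane_offsets_mm` extends them
  to multiple planes, but the off-plane dose profile is then governed by the
  compensation shape, not by anchors.
* Heart doses are penumbra-level only; the systematic ~0.1% heart-mean
  differences a clinical cohort shows are below this engine's physics.
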