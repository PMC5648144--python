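# Methods

`enmfactorial` re-creates, end to end and on synthetic worlds, a factorial
experiment in ecological niche modeling (ENM): how does the choice of
environmental predictor family — climate-only (C), edaphic/soil-only (E),
or both (CE) — interact with the choice of modeling algorithm (GAM,
maximum entropy with linear+quadratic features, random forest, RBF-SVM)?
Every stage of the original workflow is implemented as tested, reusable
code; because the synthetic worlds have known ground truth, the pipeline's
qualitative conclusions can be checked against truth rather than intuition.

## The synthetic world

Real bioclimatic surfaces are smooth and vary over hundreds of kilometres;
soil properties vary over kilometres with great spatial complexity.  The
generator reproduces exactly this contrast and nothing more:

* **Fields.**  Each environmental layer is seeded white noise convolved
  with an isotropic Gaussian kernel (wrap-around boundaries), then
  standardized to mean 0, SD 1.  The kernel scale (in cells) is the
  `autocorr_range`: default 40 cells for climate-like layers, 4 for
  edaphic-like layers.  Convolution was chosen over spectral simulation
  because it seeds exactly, is O(n) per layer, and gives direct control of
  the autocorrelation range.
* **Collinearity.**  Real bioclim/soil stacks are strongly collinear (a
  handful of PCs carries >95% of their variance).  A shared latent field is
  mixed into every member of a family with weight `sqrt(rho)` (defaults:
  rho = 0.6 within climate, 0.3 within soil), which reproduces that
  behaviour.
* **Geographic gradients.**  Climate-like layers additionally carry a
  planar geographic trend (default 50% of their variance; shared
  orientation per family, random sign per layer), because real climate
  varies along broad monotone gradients — temperature with latitude above
  all.  A purely stationary random field would make equal-climate regions
  recur all over the map, so a climatic tolerance envelope would have a
  scattered geographic footprint that no real species' range shows.
  Soil-like layers carry no trend.
* **Coverage gaps.**  An optional `mask_hole_fraction` punches cells out of
  every edaphic layer only, mimicking soil products that lack data where
  climate grids do not (lakes, ice).  All statistics honour the joint
  validity mask.
* **Geometry.**  Grids are unprojected geographic degrees, north-up,
  square cells (default 0.5°), with the study-window top-left corner at
  (-120°, 35°).  Cells use half-open intervals (left/top edge inclusive)
  so every point belongs to exactly one cell.

* **Virtual species.**  A species is a product of Gaussian responses,
  `suit(x) = prod_k exp(-(x_k - opt_k)^2 / (2 b_k^2))`, on named layers;
  suitability is 1 at the joint optimum and strictly unimodal.  The default
  roster gives each species responses on two edaphic layers with breadth
  0.5 (in field SD units).  That breadth makes species specialists
  occupying roughly 5–10% of the study area — chosen because the
  presence/background contrast of such a species is strongly learnable
  (the true-suitability ranking alone reaches AUC ≈ 0.9 against uniform
  pseudo-absences), so differences between predictor sets and algorithms
  are visible above noise; a breadth of 1.0 produces near-cosmopolites
  (~45% of the area suitable) whose Bayes-optimal AUC is only ≈ 0.68,
  leaving every model near chance.  A broad tolerance envelope
  (`envelope_breadth`, default 1.0 on two climate layers) adds wide
  Gaussian responses on layers of the other family: ecologically, soil
  structures suitability locally *inside* a wide climatic tolerance —
  precisely the premise under which adding edaphic data to climatic ENMs
  is interesting.  Without the envelope, climate-only models of a
  soil-specialist are pure noise, and a noise-level random forest
  binarizes to salt-and-pepper maps whose shape index swamps the
  predictor-set comparison (see Limitations).
* **Occurrences.**  Records are drawn cell-wise with probability
  proportional to suitability (times an optional bias layer) and placed
  uniformly inside the drawn cell, with replacement across draws — like
  herbarium data, several records can fall in one cell before thinning.

What the generator does **not** emulate: dispersal limitation and range
occupancy dynamics, sampling bias along roads (available via the bias
layer but off by default), non-Gaussian niches, interactions between
variables, and temporal trends.  Passing tests therefore demonstrate the
pipeline's internal correctness and its ability to recover known
direction-of-effect under idealized sampling, not performance on real
herbarium data.

## Pipeline stages

1. **Cleaning** — records outside the study window, exact duplicate
   coordinates, and (when a collection window is declared) out-of-window
   years are dropped.  Undated records are kept unless `strict_years` is
   set.  **Thinning** — one record per cell of a systematic grid (default
   resolution = the model grid's cell size), the retained record chosen
   uniformly at random under a seed.  Thinning is idempotent and
   order-deterministic (output sorted by coordinates).
2. **Predictors** — each family is standardized over jointly valid cells
   and eigendecomposed via its correlation matrix; the minimal number of
   leading components with cumulative explained variance strictly above
   0.95 is retained.  Correlation (not covariance) PCA because the
   emulated variables mix °C, mm, % and cmolc/kg; covariance PCA would be
   unit-dominated.  Component signs are pinned (largest-|loading| element
   positive).  The PCA is fitted on all valid cells of the study area,
   not only occurrence cells.
3. **Design** — pseudo-absences at prevalence 1 (one per presence) at the
   centers of valid, presence-free cells of a soil-derived mask, sampled
   without replacement.  The 2-fold spatial partition is a checkerboard of
   square blocks; 30 candidate block sizes (0.5° to 15° in 0.5° steps) are
   scored, infeasible candidates (an empty bin) are discarded, and the
   feasible candidate with minimal presence imbalance wins; ties go to the
   finest resolution (most conservative spatial separation).  Per-bin
   prevalence 1 is restored by re-sampling surplus pseudo-absences into
   blocks of the deficient bin (`spatial` mode; a `relabel` mode that only
   reassigns labels is provided because the original procedure is
   ambiguous between the two readings).
4. **Models** — four sklearn-style estimators (fit / predict_proba):
   * *GAM*: binomial likelihood, logit link, one penalized B-spline smooth
     per predictor (df 9, cubic), no interactions or term selection.  A
     single shared penalty weight is optimized by bounded scalar
     minimization of GCV over log10(alpha) in [-4, 7]; perfect separation
     falls back to a heavy penalty with a warning instead of crashing.
     Predictions outside the training range use constant extrapolation
     (inputs clipped to the training hull).
   * *MElq*: native maximum-entropy model.  Features are each predictor
     and its square, min–max scaled to [0, 1] over the background;
     presences are added to the background before normalization (this
     keeps the L1-regularized likelihood bounded and matches standard
     practice).  The Gibbs weights minimize the regularized negative mean
     presence log-likelihood by L-BFGS-B on the positive/negative split of
     λ (convex).  Default per-feature penalties follow the published
     schedules — linear: (10, 1.0), (30, 0.2), (100, 0.05); quadratic:
     (10, 1.3), (17, 0.8), (30, 0.5), (100, 0.05) — interpolated in the
     presence count and scaled by sqrt(var/m) of each feature over
     presences.  Logistic output `e^H q / (1 + e^H q)` with H the entropy
     of the fitted background distribution, so the featureless model
     outputs 0.5 everywhere.  Background capped at 10 000 cells; the
     iteration cap (1 000) produces a warning, not an error.
   * *RF*: 500-tree classification forest.  mtry starts at floor(sqrt(p))
     and walks by factors of 2 while the out-of-bag error improves by more
     than 5%; the candidate with minimum OOB error is the final model
     (each candidate is already a full 500-tree forest under the same
     seed, so no refit is needed).
   * *SVM*: RBF kernel, C = 1, kernel width 1/median(pairwise squared
     distance) on (a capped sample of) the training points, Platt-scaled
     probabilities.  Zero-variance predictors are dropped with a warning.
5. **Evaluation** — per treatment, each fold's model picks the threshold
   maximizing sensitivity + specificity on its *training* points
   (selecting on test would leak), then TPR/TSS at that threshold and
   rank-based AUC are computed on the held-out fold; results are averaged
   over the two folds.  The shape index `SI = Σ 0.25 p_i / sqrt(a_i)` is
   measured on the full-extent binarized prediction of each fold (patches
   by rook connectivity; an 8-connectivity flag exists) and averaged.
   Whole-map similarity uses Kendall tau-b over jointly valid cells.  The
   mean of the two fold maps is the treatment's suitability surface for
   the tau comparisons.
6. **Statistics** — two-factor within-subject ANOVA (subjects = species;
   factors = predictor set, algorithm), each effect tested against its own
   subject×effect error stratum.  Mauchly's W per effect (chi-square
   approximation with the standard small-sample factor); when it rejects
   at α = 0.05 the degrees of freedom are multiplied by the
   Greenhouse–Geisser ε̂ = (Σλ)²/(q Σλ²).  TSS is arcsine-transformed
   before the ANOVA; the default transform is arcsin(x) because TSS can be
   negative (the arcsin(sqrt(x)) proportion variant is available behind a
   flag).  For the balanced complete design produced here, Type I and
   Type III sums of squares coincide.  Post-hoc mixed-model contrasts and
   FDR correction are deliberately not re-implemented: the evaluation
   table is exported in the long format any mixed-model routine consumes.

## Reproducibility

Every treatment derives its seed as CRC32(global seed, species, predictor,
algorithm) mod 2³¹, so serial, parallel, and single-treatment re-runs from
the manifest agree bit-for-bit.  Two runs with the same configuration
produce identical evaluation tables.

## Problem sizes

The default demo world is 150×150 cells (0.5°), 6 climate-like + 8
edaphic-like layers, 24 species of 60 records.  The test suite and the
acceptance script use scaled-down versions of the same conditions — 50–60
cell grids, 7 species per world replicate across 3 replicate worlds
(21 distinct virtual species), 30–35 records per species — which keep every
statistical property of interest measurable while a full run stays cheap.

## Known limitations

* A random forest whose predictors resolve only part of the niche has
  vote fractions hovering near the binarization threshold over wide
  areas, and the thresholded map fragments into many small patches with a
  very large shape index.  Climate-only RF maps of soil-specialist
  species sit in exactly this regime (SI(C, RF) ≈ 40–55 versus
  SI(CE, RF) ≈ 23–28 under the default conditions), which inflates the
  mean SI of the C predictor set above CE even though the ordering
  SI(E) > SI(CE) > SI(C) holds cleanly for the three non-memorizing
  algorithms.  This is an artifact of binarizing an uncertain memorizing
  learner, not of the predictor grain the shape index is meant to
  capture; it does not arise when climate-only models are decisively
  skilled, as they are for real plants against real (gradient-dominated)
  climate surfaces.
* GCV-optimized smoothing is a stand-in for full REML/Newton per-term
  optimization; with one shared penalty the GAM is slightly stiffer than a
  per-term-penalized fit.
* Mauchly's p uses the first-order chi-square approximation; packages
  adding the second-order term differ in the third decimal.
* The minimum-convex-polygon extent (GE) counts cell centers covered by
  the hull (boundary inclusive); degenerate hulls fall back to the count
  of occupied cells.
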