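# Methods

## Segmentation

Each SHG tile is modelled as a mixture of Gaussians over the flattened
intensity histogram (intensity only, no spatial or texture terms). EM is
initialised by k-means with a fixed seed, tolerance 1e-4 on the per-sample
lower bound, at most 200 iterations; non-convergence returns the model with
`converged=False` and a warning rather than failing. Components are sorted
by ascending mean, pixels take the maximum-posterior component, and
everything above the dimmest component is collagen. With two components this
is provably a single intensity threshold (monotone likelihood ratio), which
the tests confirm by brute force over all 4096 intensity values.
`n_components` defaults to 2 (collagen vs background) but is configurable,
e.g. to absorb bright-spot artifacts into a third component. Objects smaller
than 5 px are removed by default — isolated suprathreshold noise pixels
otherwise seed spurious one-pixel fibers.

A constant tile is rejected: a mixture over a single intensity value is
degenerate and no collagen/background boundary exists.

## Fiber network

The mask is reduced to a one-pixel topology-preserving skeleton
(Zhang-style thinning) and annotated with the Euclidean distance transform
of the mask. Endpoint branches shorter than 5 px that terminate at a
junction are pruned as skeletonization artifacts. The remaining skeleton
graph (8-connectivity) is decomposed into branch segments between
endpoints and junction clusters (connected groups of pixels with degree
≥ 3). At each junction, segment ends are paired greedily by smallest turn
angle — the angle between the arrival direction (averaged over ~5 px) and
the candidate departure direction — accepting pairs below 45°; ties prefer
the longer continuation. Paired segments merge into one fiber whose vertex
list passes through the junction (shortest path through the cluster
pixels); unpaired ends terminate at the junction and adopt the adjacent
junction pixel. A config switch (`join_through_junctions=False`) instead
splits at every junction, since whether a tracked "fiber" continues through
a crossing is a genuine modelling choice that rescales the count and length
features. Fibers shorter than 10 px (path length) are discarded.

Vertex order is canonical (lexicographically smaller endpoint first), so
identical masks give identical networks.

**Arc length.** Summing unit/diagonal steps along a pixel chain
overestimates oblique lines by up to ~8% (staircase effect), so a fiber's
path length is measured by chords through every 4th vertex. On straight
synthetic fibers this recovers the drawn length within ~2%.

**Width.** A fiber's width is `2·median(EDT along its vertices) − 1`: the
−1 is the discrete medial-axis correction (a one-pixel line has distance 1
and width 1), and the median discards the tapered values near fiber ends.
On drawn bars 4–8 px tall this lands within 1 px of the true height.

**Cross-links.** A coordinate appearing in two or more fibers' vertex lists
is a cross-link; shared coordinates within 2 px (Euclidean, single linkage)
merge into one cross-link so a thick junction cluster counts once. The
representative coordinate is the lexicographically smallest member. Tests
compare against a brute-force scan over all fiber pairs.

Discrete skeletonization is not exactly equivariant under 90° rotation at
junctions: crossing-free scenes rotate cleanly (fiber count preserved,
total path length within 1%), but junction decomposition can differ by a
fiber or a cross-link on rotated crossing scenes.

## Features

Definitions as in the README table. Policy decisions:

- A feature undefined for an ROI (no fibers; no fiber with ≥ 2 cross-links;
  constant image) is **NaN, never 0** — zero-filling would bias patient
  means toward "less collagen" where nothing was measurable. Patient
  aggregation is the unweighted arithmetic mean over the ROIs where the
  feature is defined; a patient-level value is missing only if every ROI is.
- fea2 is a raw count per tile and fea6 cross-links per fiber; per-mm²
  normalisation is available when a physical pixel size is supplied, but the
  defaults need no physical calibration.
- Lengths are reported in pixels (no acquisition pixel size is assumed).
- fea8 is the axial order parameter `R = |Σ p(θ)·e^{2iθ}| / Σ p(θ)` of the
  centred FFT power spectrum restricted to an annulus of radii 3%–25% of
  the smaller image dimension. The inner cut removes DC and the coarse
  angular resolution near it; the outer cut removes edge-pixelation power,
  which is isotropic and dilutes the index; the annulus sits inside the
  inscribed disc so all directions are sampled equally. The doubled angle
  handles the 180° axial ambiguity. By default fea8 is computed on the
  binary mask (making all eight features invariant to intensity rescaling);
  an intensity mode is available. Parallel stripes score ~1.0, aligned
  synthetic scenes ≥ 0.9, isotropic scenes ≤ 0.2.
- Closed-loop fibers (coincident endpoints) are excluded from straightness
  with a warning; the end-to-end/path ratio is meaningless for loops.

## Feature-score

The published eight-weight linear formula is shipped as a frozen constant
and applied to **raw** feature values, exactly as printed (it states no
standardisation). Missing features are an error naming the feature.

Refitting uses a ridge-penalised Cox partial likelihood — survival is the
only outcome the score is used for — on z-scored features (training-cohort
mean/SD stored with the coefficients). The penalty is selected from a
logarithmic grid (default 1e-3…1e3, 13 points) by k-fold (default 5)
cross-validation maximising the mean held-out partial log-likelihood; fold
assignment is a deterministic function of the seed. At n=1000 a sparse
generating signal is recovered within 0.15 on the causal weight and 0.1 on
the null weights, and at negligible penalty the weights agree with an
independent Cox implementation (scikit-survival) within 0.02.

The entry point is statsmodels-style: `FeatureScoreModel(cohort).fit()` (or
`.fit_published()`) returns a results object with the coefficient table,
CV path, `predict()` and `summary()`.

## Survival statistics

- Cox models use Efron tie handling and Wald CIs; no multiple-testing
  correction, α = 0.05 two-sided. Categorical covariates are encoded
  against fixed reference levels (age ≤ 50, female, TNM ≤ IIA,
  differentiation I, no PNI, no LVI, head location); levels unobserved in a
  cohort are dropped. Rank-deficient designs and separation raise errors
  naming the covariates.
- ROC outcome defaults to vital status at end of follow-up; a time-horizon
  mode (dead by t vs alive at t, censored-before-t excluded) is a switch.
  AUC is the empirical (trapezoidal) estimate with a DeLong 95% CI. The
  Youden cutoff maximises sensitivity + specificity − 1 over midpoints
  between consecutive observed scores, ties broken toward higher
  specificity; scores **above** the cutoff are high risk.
- Nomogram points for a covariate level x are
  `100·(β·x − min_level β·x)/max_range`, where `max_range` is the widest
  per-covariate span of β·x, so the most influential covariate spans
  exactly 0–100 and total points are strictly increasing in the Cox linear
  predictor (anchoring at the reference category instead would break that
  monotonicity whenever coefficients have mixed signs). Total points map to
  survival through the model's baseline survival function.
- Calibration bins patients into quantile bins (default 4) of predicted
  survival at the horizon and compares with the within-bin Kaplan–Meier
  estimate; identical predictions collapse bins.

## Synthetic data

Fibrous phantoms: fibers are smoothed random walks (step 2 px; per-step
heading noise with SD = `waviness` radians), with axial orientations from a
von Mises distribution on the doubled angle (κ = 0 isotropic, κ → ∞
parallel), lengths and widths Gaussian, rasterized and thickened to the
sampled width via the distance transform (stadium caps). Intensities are
foreground/background plateaus plus additive Gaussian noise, clipped to
[0, 4095] and rounded (12-bit). With `crossing_allowed=False` a 2-px
clearance keeps fibers individually traceable. Ground truth records
centerlines, widths, orientations, the exact mask and centerline crossing
points. Defaults (512×512 tiles, ~1500 vs ~150 intensity, noise SD 80)
emulate the two stromal phenotypes — ordered/aligned vs sparse/disordered —
at a contrast where segmentation is near-perfect; tests and study
simulations use 128–256 px tiles, which keeps every suite fast without
changing any estimator's behaviour.

What the phantoms do **not** model: optical point-spread blur, stitching
artifacts, intensity inhomogeneity, partial-volume edges, or cell-channel
(TPEF) signal. Passing recovery tests therefore shows the morphometric
chain is correct on its own terms, not that it is robust to every
real-acquisition artifact.

Cohorts: the eight features are Gaussian with configurable means/SDs;
clinical covariates are drawn at the prevalences of a typical PDAC
resection cohort (e.g. 80% age > 50, 58% TNM ≥ IIB, 77% PNI). Event times
are exponential with hazard `λ0·exp(features·β + clinical·β)`; censoring is
independent uniform on [0, T_max] with T_max bisected so the realised
censoring fraction matches the request. With zero effects and no censoring
the Kaplan–Meier curve tracks `exp(−λ0·t)` within the DKW 95% band at
n = 2000.

The pipeline's simulated study (`make_alignment_study`) varies the
orientation concentration κ across patients and ties the log-hazard to the
standardised κ, so strongly aligned collagen shortens survival; the
end-to-end test recovers the induced negative fea8–OS correlation and a
worse Kaplan–Meier curve in the Youden-defined high-risk group. Study-level
scoring uses the ridge-Cox refit: the published weights encode the original
cohort's feature scales, which a synthetic cohort does not share, so only a
refit score is expected to rank simulated risk. When a patient-level
feature is undefined in every ROI of a patient (e.g. no cross-links
anywhere), the pipeline imputes the cohort mean before scoring and reports
the number of imputed values in the run manifest.

## Known limitations

- The junction-joining rule is one reasonable reading of skeleton-based
  fiber tracking; real tracker implementations differ, which rescales fea2,
  fea3 and fea6 (hence the `join_through_junctions` switch).
- The published coefficient magnitudes imply feature scales of the original
  (undeposited) data; scores computed on other data are internally
  consistent but not comparable to the original cohort's cutoff values.
- Cross-link spacing uses raw pixel-chain arc positions (no chord
  correction), a ≤ ~8% overestimate on oblique fibers.
- DeLong CIs assume independent patients; clustered ROIs within patients
  are aggregated before any inference.
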