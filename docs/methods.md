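# Methods

This note documents the statistical models behind `morphomod`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
recorded. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Superimposition

**GPA.** Each configuration is centred, scaled to unit centroid size
(`CS = √Σ‖x_i − x̄‖²`, recorded pre-scaling) and rotated onto the current
mean by orthogonal Procrustes; the mean is recomputed until it changes by
less than 1e-9 (max 200 iterations). Reflections are never admitted: the
rotation's determinant is forced to +1, because bilateral asymmetry is
handled by mirror-filling, not by reflection alignment. The aligned
coordinates are therefore invariant (to numerical tolerance) under any
similarity transform of any input specimen and under specimen reordering,
up to one global rotation.

**Mirror-filling.** Right-side points are reflected through the
least-squares plane (total least squares via SVD) fitted to the declared
midline points, per specimen; at least three non-collinear midline points
are required. Mirrored points participate in GPA and sliding and are
dropped afterwards, so all statistics see midline + right-side points
only.

**Sliding semilandmarks.** Sliding minimises the thin-plate-spline
bending energy of the deformation from the current Procrustes mean to
each specimen. For a 3-D reference the TPS kernel is `U(r) = −r`, the
sign that makes the bending-energy quadratic form positive semi-definite
and exactly zero on affine deformations (verified numerically during
development). Curve semilandmarks move only along the chord through
their curve neighbours; surface semilandmarks move in a tangent plane
estimated by local PCA of the 8 nearest reference points (configurable;
meshes are out of scope, so tangents come from the point cloud itself).
Displacements solve the exact normal equations of the quadratic energy in
the slide parameters (minimum-norm least squares, which also tames the
affine null space of the bending-energy matrix), so energy cannot
increase; a numerical guard skips any update that would. After each pass
the configurations are re-aligned by GPA. Default: 3 passes, stopping
early when the largest displacement falls below 1e-6. Curve and surface
points slide jointly in one solve per specimen (the separate-pass order
is not exposed because the joint solve dominates it at equal cost).
Sliding is referenced to the Procrustes mean rather than a designated
template; the reference is recomputed every pass.

**Missing regions.** A region absent in a specimen is encoded, before
GPA, by copying the coordinates of a declared anchor landmark onto every
point of the region — an infinitesimal surface of the correct
dimensionality, keeping all specimens and regions in every analysis. The
anchor is data (a column of the region-map file), not code; if the
declared anchor is itself missing, the first finite landmark of the
specimen stands in. Whole-region NaN blocks in input files are detected
and treated as absences, so absences survive plain CSV round trips.
TPS interpolation of missing coordinates is deliberately not offered.

## Modularity

**Congruence coefficients.** Integration between points p and q is
`r = Σ A∘B / √(ΣA²ΣB²)` over the two points' observation × 3 blocks,
each column centred over observations — a cosine correlation that uses
all three coordinates at once. Observations are specimens (raw variant),
allometric residuals (each coordinate regressed on log centroid size,
`n_eff = n − 1`), or independent contrasts (phylogenetic variant,
`n_eff = n − 1`).

**Likelihood model selection.** For each candidate partition, the
off-diagonal |r| cells are classed within-module (one class per module)
or between-module (per-pair by default, since between-module
correlations are reported pairwise; a single shared class is available).
On the Fisher scale `z = atanh|r|` with sd `1/√(n_eff − 3)`, the ML
estimate per class is `ρ̂ = tanh(z̄)` in closed form, and the model
log-likelihood is the sum of Normal log-densities. Models are ranked by
`AICc = −2logL + 2k + 2k(k+1)/(n_cells − k − 1)` with sample size equal
to the number of cells `P(P−1)/2`, and Akaike weights are reported. The
parameter count excludes a variance nuisance term by default
(`count_variance_param=True` switches conventions). The 15 shipped
candidate models (`data/candidate_models_synthetic.csv`) span one-module
to fully partitioned structures over the default 16 region ids; they are
constructed for the default simulation layout, and user models load from
the same CSV schema.

**Post-hoc merging.** Regions a, b join when
`min(ρ̂_within,a, ρ̂_within,b) − ρ̂_between(a,b) ≤ 0.2` (threshold
configurable); merged modules are the connected components of the
resulting graph. Components were chosen over any non-transitive reading
because they are deterministic and order-independent; the provenance
records the threshold. When merging collapses everything into one module
the pipeline falls back to the finest region partition for the
statistics that need at least two groups (CR, rate ratios, per-module
table) and flags this in provenance.

**Covariance ratio.** With S the specimen covariance of the flattened
coordinates, `CR(a,b) = √( tr(S_abᵀS_ab) / √(tr(S̃_a²)·tr(S̃_b²)) )`
where S̃ zeroes the within-block diagonal; the overall CR is the mean
over module pairs, and the null permutes whole points (x, y, z moving
together) across modules with sizes fixed. Values well below 1 indicate
modularity; p-values count permuted CR ≤ observed.

**Jackknife.** Robustness to the low specimen-to-variable ratio is
assessed by resampling the point set down to a fraction (default 10%,
100 iterations) and refitting the region-level correlations; means and
SDs over iterations are reported, with modules reduced to fewer than two
points contributing nothing that iteration.

## Phylogenetic comparative machinery

The Brownian covariance `C[i,j]` is the shared root-to-MRCA path length,
accumulated edge-by-edge. `C^{−1/2}` is computed by symmetric
eigendecomposition so results do not depend on tip ordering. Contrasts
follow Felsenstein's pruning with branch-length augmentation; polytomies
are resolved to zero-length branches with a warning, and zero-length
denominators are guarded at 1e-12.

`K_mult` is the ratio of observed to Brownian-expected phylogenetic
structure; it equals 1 exactly when C ∝ I and averages ≈ 1 under BM on
the analysis tree (both are asserted in the acceptance suite).
Phylogenetic regression and ANOVA premultiply response and design by
`C^{−1/2}` and report R² as model over total sum of squares on the
transformed scale, summed over all columns; significance permutes
phenotype rows across tips (the quoted permutation scheme of the
workflow this reimplements; residual randomization is not the default).
Tips with missing trait values are dropped and the tree pruned before an
ANOVA. All permutation p-values are `(b+1)/(m+1)`.

## Rates and disparity

Disparity is Procrustes variance `Σ‖Y_i − Ȳ‖²/n` (divisor n, matching
the standard toolchain; note this makes the two-specimen case `d²/4`),
divided by the point count when comparing modules. Pairwise module
differences are tested, by default, by permuting whole points between the
two modules and comparing |disparity difference|, with BH adjustment
across pairs — a permutation scheme was preferred because applying an
honest-significant-difference test to variances is statistically
irregular; that legacy recipe remains available as `method="tukey"` and
is flagged in the result object.

`σ²_mult` is the GLS-centred, C⁻¹-weighted mean squared displacement per
unit time per landmark. Its small-sample expectation is `3σ²(n−1)/n` per
landmark for per-coordinate rate σ², i.e. a bias of −1/n (≈ 3% at 35
tips), well inside the 10% calibration asserted in the acceptance suite.
Rate heterogeneity across modules is tested with the max/min ratio
against single-rate BM simulation with identity trait covariance (999
simulations by default); the ratio statistic is scale-free, so the
pooled-rate plug-in does not affect the null distribution. Two-group
comparisons (e.g. aquatic vs non-aquatic tips) use each group's rows of
the whitened residuals, report the focal/other ratio, and test with the
max/min form; tip exclusion is supported for leave-one-out sensitivity
checks.

**Per-landmark maps and the BM band.** Each point's rate uses its three
columns (L = 1) and its variance is the uncorrected per-point Procrustes
variance, so per-point variances sum exactly to the whole-configuration
value. The BM expectation for the rate–variance relation is simulated by
splitting each point's rate equally over three independent coordinates
(no trait covariation) — 100 simulations by default. The fitted line
(mean simulated variance on rate) summarises the expectation, but the
95% band bounds are the per-point empirical simulation quantiles rather
than a prediction interval from that regression: the mean-variance
regression is nearly residual-free (the expectation is exactly linear in
rate), so its prediction interval would be far too narrow to bound a
single BM realisation, and a direct experiment during development showed
it flagging most points under exact BM. The quantile band is calibrated
by construction (≈5% of points outside under BM, asserted in the
acceptance suite).

## The synthetic-data generator

The generator emulates the statistical structure of a dense comparative
shape study; it makes no attempt at anatomically realistic geometry.

* **Tree**: pure-birth, ultrametric, depth scaled to 1, tips `t1..tn`.
* **Layout**: 16 regions named after cranial elements, each with 3 fixed
  landmarks, one 5-point curve (anchored on two landmarks) and 4 surface
  points — 192 points by default, a deliberate scale-down of the
  ~1500-point density such studies reach, keeping the full pipeline and
  test suite desk-scale. Three regions carry midline landmarks so a
  mirror plane exists.
* **Shape evolution**: tip coordinate vectors are matrix-normal with row
  covariance C and a per-axis column covariance built from a block
  correlation matrix — `ρ_within` for point pairs sharing a true module,
  `ρ_between` otherwise, the same correlation on each axis and axes
  mutually independent (the simplest structure at the congruence
  coefficient's measurement level). Non-positive-definite requests fail
  loudly; a nearest-PD projection exists but is off by default.
* **Defaults as study conditions**: per-coordinate BM variance 1e-2
  (≈10% relative shape variation, the scale implied by per-landmark
  Procrustes variances of a few × 10⁻⁶ on ~1500-point unit-size
  configurations); `ρ_within = 0.8`, `ρ_between = 0.1` (a strongly
  modular system, the regime the recovery experiments stipulate); a
  ten-module true partition over the 16 regions; the quadrate–squamosal
  "cheek" module at 2× rate; allometry as a mean displacement along a
  fixed random unit direction in shape space, slope 2.5 per unit log CS
  (≈15% of shape variance at log-CS sd 0.4); fossoriality offsets of
  magnitude 0.5 (a small, ~4% effect).
* **Covariates evolve on the tree.** Log centroid size is BM (sd 0.4 at
  depth 1) and the categorical traits derive from BM liabilities
  (fossoriality: five equal-frequency bins) or a clade (obligate aquatic:
  the clade closest to ~9% of tips), with occasional missing
  reproduction/life-history states. This is deliberate: independent
  contrasts amplify non-phylogenetic variance on short branches, so
  i.i.d. covariates would (and in development did) swamp the trait
  correlations with whitened mean-shift noise — and real size and
  ecology are themselves phylogenetically structured.
* **Raw specimens**: uniform random rotations (det +1), translations,
  and small (2%) log-scale jitter — tomographic specimens carry
  calibrated absolute scale. Region absences are restricted by default
  to the variably present elements (stapes at ~9%, pterygoid at ~6% of
  specimens, the frequencies such elements actually go missing at) and
  follow a Brownian liability thresholded on the tree, so element loss
  is phylogenetically clustered as real absences are. The anchor
  landmark that stands in for an absent region is the spatially nearest
  landmark of another region in the mean configuration.

**What passing tests do and do not show.** The generator matches the
analysis model almost exactly (matrix-normal BM, linear allometry,
additive group effects), so green tests demonstrate the estimators and
tests are implemented correctly and calibrated under their own
assumptions. They do not probe non-Brownian evolution, measurement error
beyond similarity transforms, digitisation error correlated along
curves, allometry that bends in shape space, or module boundaries that
disagree between correlation and rate structure. Encoded region absences
are genuinely large local shape effects — in synthetic and real data
alike they attenuate phylogenetic signal and inflate the rates of the
modules that house them, which is visible in the worked example's
rate ratio.

## Numerical and reproducibility choices

* Master seed spawns per-stage seeds via
  `SeedSequence((master, stage_index))` with a documented stage table, so
  any stage re-runs in isolation with the seed it would receive in the
  full pipeline; per-module loops offset the stage seed by the module
  index. All seeds stay below 2³¹.
* Reports carry statistics at full double precision in JSON; the TSV
  table prints p-values to 4 decimals and statistics to 3 significant
  figures.
* |r| = 1 congruence cells are clipped to 1 − 1e-6 before the Fisher
  transform, with a warning.
* Eigenvector signs in PCA are fixed by making each column's
  largest-magnitude loading positive.
* Degenerate inputs fail with named offenders: ragged CSV rows name the
  specimen, non-numeric cells name the row/column, name mismatches list
  the offending ids, coincident TPS reference points name the points,
  and zero-variance points name the point.

## Known limitations

* No Ornstein–Uhlenbeck or time-varying rate models; Brownian motion
  throughout.
* No mesh handling: surface-point tangents come from the point cloud,
  and no template-to-mesh patching is performed.
* Module subsetting uses the global alignment (retaining relative
  position and scale); locally re-aligned subsets are not produced.
* The max/min rate-ratio test assumes identity trait covariance in its
  null simulation; strongly integrated data inflate its type-I error, a
  known property of this class of test (its size is calibrated in the
  suite under the independent-trait null it states).
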