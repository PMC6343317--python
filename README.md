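# morphomod

High-density geometric morphometrics and phylogenetic comparative analysis
of modular structures, built for studies that quantify the shape of a
complex anatomical system (such as a vertebrate cranium) with dense
landmark, curve-semilandmark and surface-semilandmark sampling across many
species, and then ask how that shape variation is organised: into which
modules, under which phylogenetic, allometric and ecological influences,
and at which evolutionary rates.

The intended users are evolutionary morphologists working with
Procrustes shape data on a time-calibrated phylogeny — the same audience
that reaches for `geomorph`, `Morpho` or `EMMLi` in R — who want a single
tested Python pipeline from raw coordinates to a comparative report, plus a
synthetic-data generator so every stage can be validated against known
ground truth.

## What it computes

Given per-specimen 3-D coordinates, a point-to-region map, a dated tree
and an ecological trait table, the pipeline runs:

1. **Superimposition** — curve resampling to equidistant semilandmarks,
   mirror-filling of bilateral points through the midline plane,
   generalised Procrustes analysis (GPA), sliding of semilandmarks to
   minimise thin-plate-spline bending energy against the Procrustes mean,
   encoding of absent regions as anchor-collapsed "infinitesimal
   surfaces", and removal of mirrored points.
2. **Modularity** — trait correlations as congruence coefficients
   `r_pq = Σ A·B / √(ΣA² ΣB²)` between centered per-point coordinate
   blocks; maximum-likelihood comparison of candidate module partitions on
   the Fisher-z scale (`ρ̂ = tanh(mean z)` per class, sd `1/√(n_eff−3)`),
   ranked by AICc; post-hoc merging of regions whose between-region
   correlation comes within 0.2 of the weaker within-region correlation;
   jackknife robustness resampling; and the covariance-ratio (CR) test by
   permutation of whole points across modules.
3. **Phylogenetic comparative methods** — Felsenstein independent
   contrasts; multivariate phylogenetic signal
   `K_mult = [Σ‖Y_i−â‖² / Σ‖U_i‖²] / [(tr C − n/(1ᵀC⁻¹1))/(n−1)]`
   with `U = C^{−1/2}(Y − 1âᵀ)`; phylogenetic GLS regression (evolutionary
   allometry on log centroid size) and phylogenetic ANOVA, with
   significance by permuting phenotypes across tips; Benjamini–Hochberg
   correction.
4. **Rates and disparity** — Procrustes variance per module
   (per-landmark corrected); net Brownian-motion rates
   `σ²_mult = tr[(Y−1âᵀ)ᵀC⁻¹(Y−1âᵀ)]/(nL)`; max/min rate-ratio tests
   against single-rate BM simulation; two-group rate shifts for ecological
   transitions; per-landmark rate and disparity maps with a simulated BM
   prediction band.
5. **Ordination** — covariance PCA of shape, extreme-shape
   reconstruction along axes, and a phylomorphospace via ML ancestral
   states (weighted squared-change parsimony).

All permutation and simulation p-values use the `(b+1)/(m+1)` convention
and every stochastic stage consumes a deterministic child seed, so a run
is a pure function of its inputs and master seed.

## Worked example

Simulate a study under the default conditions (35 species on a pure-birth
tree, 16 cranial regions × 12 points with a ten-module correlation
structure, a doubled-rate "cheek" module, allometry, ecological effects,
rigid-transform noise and occasional absent regions), then run the full
pipeline:

```python
import morphomod as mm

sim = mm.simulate_study(mm.SimConfig(seed=1))
config = mm.AnalysisConfig(n_permutations=999, n_sim_rates=999, seed=1)
bundle = mm.run_pipeline(config, sim.dataset, sim.region_map,
                         sim.phylogeny, sim.traits)
g = bundle.global_stats
print(f"modules after merging: {g['n_modules']}")
print(f"K_mult = {g['k_mult']:.2f} (p = {g['p_k_mult']:.4f})")
print(f"allometry R^2 = {g['allometry_r2']:.3f} (p = {g['p_allometry']:.4f})")
print(f"CR = {g['cr']:.2f} (p = {g['p_cr']:.4f})")
print(f"rate ratio max/min = {g['rate_ratio_max_min']:.2f} "
      f"(p = {g['p_rate_ratio']:.4f})")
```

Output:

```
modules after merging: 8
K_mult = 0.93 (p = 0.0010)
allometry R^2 = 0.064 (p = 0.0440)
CR = 0.75 (p = 0.0010)
rate ratio max/min = 2.30 (p = 0.0010)
```

Reading the numbers: the 16 regions merge into 8 modules (the generating
truth groups them into 10 — at this seed superimposition-induced
covariance merges two pairs of true modules, e.g. the cheek with the
vomer–basale complex); shape carries strong phylogenetic signal slightly
below the Brownian expectation of 1, as expected after sliding and
missing-region encoding; evolutionary allometry is small but significant;
CR well below 1 confirms modular structure; and the max/min rate ratio of
2.3 recovers the generating 2x rate of the quadrate–squamosal "cheek"
module.

The same pipeline is available from the shell:

```bash
morphomod simulate --seed 1 --out demo/
morphomod run --landmarks demo/landmarks.csv --regions demo/regions.csv \
    --tree demo/tree.nwk --traits demo/traits.csv --out demo/report/
```

which writes `report.json` (full precision) and `module_table.tsv` (the
human-readable per-module summary). Subcommands `superimpose`,
`modularity` and `rates` run individual stages.

## Layout

```
src/morphomod/
  datatypes.py          # LandmarkDataset, AlignedShapes, RegionMap, ...
  synthetic_data.py     # trees, modular BM shapes, raw-specimen noise
  superimposition.py    # resampling, mirroring, GPA, sliding, missing regions
  modularity.py         # congruence, EMMLi-style fits, merging, jackknife, CR
  phylo_comparative.py  # contrasts, K_mult, PGLS, phylogenetic ANOVA, BH
  rates_disparity.py    # Procrustes variance, sigma^2_mult, rate tests, BM band
  ordination.py         # PCA, extreme shapes, phylomorphospace
  pipeline_io.py        # CSV/Newick/YAML IO, seeding, run_pipeline, report
  cli.py                # morphomod run/superimpose/modularity/rates/simulate
docs/methods.md         # model assumptions, defaults, numerical choices
```
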