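# Methods

## Model and procedure

`bbpls` implements behavioral PLS correlation between a block of ordinal
symptom items and a block of multimodal imaging features, plus the
inferential and contextual machinery a multi-site developmental cohort
requires. The stages, in pipeline order:

1. **Matched split.** Participants are divided 2:1 into discovery and
   replication subsamples by stratified randomization on site × sex ×
   age tertile × overall-psychopathology tertile, where overall
   psychopathology is the first principal component of the item table.
   Singleton strata go to discovery. A balance report (standardized mean
   differences) is attached to the assignment.
2. **Item filtering.** Items with zero variance *in the given subsample*
   are dropped before residualization (the two subsamples may drop
   different items; out-of-sample projection intersects them).
3. **Confound regression.** Every column of every block is replaced by
   its OLS residual against intercept, age, age², sex, reference-coded
   site and ethnicity dummies, plus modality extras: mean FD and mean
   DVARS for FC blocks, intracranial volume for thickness and volume,
   total surface area for surface area, nothing extra for behavior and
   tract metrics. Residualization is fitted within each subsample
   separately, so no replication information reaches the discovery model.
4. **Dimensionality reduction.** Per-modality PCA on mean-centered (not
   variance-scaled) residuals; the smallest k whose cumulative variance
   fraction reaches the threshold (default 50%) is retained, with an
   eigenvalue tie at the cut keeping the degenerate partner. Scores are
   concatenated in the fixed order (area, thickness, volume, rest FC)
   with a block index map for modality attribution.
5. **PLS.** After z-scoring both blocks (denominator n−1), `R = Yᵀ X_pca`
   is decomposed by full SVD. Signs are fixed per component so the column
   sum of the behavioral weights is non-negative (a "general factor"
   component then appears with all-positive loadings); `corr(LX_l, LY_l)`
   is automatically non-negative because `LYᵀLX = diag(S)`. Loadings are
   correlations of *residualized original* features (FC at the edge
   level) with the composite scores.
6. **Inference.** Component significance: singular values of the first
   five components against a null in which behavior rows are permuted
   within site only; `p = (1 + #{null ≥ obs}) / (1 + n_perm)` (add-one
   convention, lower bound `1/(n_perm+1)`), BH-FDR across the five.
   Loading stability: site-constrained bootstrap; replicate components
   are aligned to the originals by greedy maximal-|dot| matching on `U`
   before sign fixing; FC loadings are block-averaged over the 171
   unordered pairs of 18 networks before the SD is taken; `z = observed /
   bootstrap SD`, two-sided normal p, BH-FDR per component across all
   features of the run.
7. **Gradients.** Group-mean cortical FC (full sample; raw averaging,
   Fisher-z optional), top-10% row threshold (ties at the cutoff kept),
   cosine affinity with negatives clipped to zero, diffusion-map
   embedding: `W' = D^{-α} A D^{-α}` with α = 0.5, Markov operator
   `P = D'^{-1} W'`, eigendecomposition through the symmetric conjugate,
   trivial eigenvector dropped. Variance explained is `λ_i / Σ λ_j` over
   retained non-trivial eigenvalues. Orthogonal Procrustes alignment to a
   reference gradient set is available; the pipeline's default reference
   is its own unaligned embedding (a synthetic stand-in — no external
   reference is distributed).
8. **Spatial nulls.** Spin tests at the parcel level: a uniform random
   rotation is applied to left-hemisphere centroids and its x-mirrored
   counterpart to the right; each parcel takes the value of the nearest
   rotated source parcel (duplicates permitted). The loading map is spun
   while the gradient map stays fixed; two-sided p by absolute-value
   comparison with the add-one convention.
9. **Generalizability.** Replication blocks are z-scored with their own
   statistics, projected through discovery PCA coefficients and PLS
   weights, and the resulting loadings correlated with discovery loadings
   (behavior: plain Pearson; cortical structural maps: spin-corrected;
   FC: at the 171-block level). Held-out modalities (three task-FC sets,
   35-tract FA and MD) are correlated with the fitted composite scores
   and stabilized by the same bootstrap machinery. Covariate post hocs
   test composite scores against sex (t-test) and age/age² (Pearson),
   FDR-corrected as one family.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `variance_threshold` | 0.5 | per-modality PCA retention rule |
| `n_perm` | 10,000 | site-aware permutations (tests/acceptance use 199–499) |
| `n_boot` | 1,000 | site-aware bootstraps (tests/acceptance use ≤ 200) |
| `n_spins` | 1,000 | spin rotations (tests/acceptance use 99–199) |
| `n_components` | 5 | components carried into inference |
| `split_ratio` | 2/3 | discovery fraction |
| `fdr_q` | 0.05 | BH level for all families |
| `GradientConfig.alpha` | 0.5 | density normalization of the diffusion kernel |
| `GradientConfig.diffusion_time` | 0 | t = 0 ⇒ multi-scale scaling λ/(1−λ) |
| `GradientConfig.row_density` | 0.10 | per-row FC threshold before cosine affinity |

The full-scale resampling counts are the design defaults; test and
acceptance runs use the smaller counts listed so the whole suite stays at
desk scale, and every count is a config field.

## The synthetic cohort

The generator emulates the statistical skeleton of a multi-site
parcellated cohort study. Latent factor scores `F` (participants ×
n_latent, standard normal) drive all blocks:

- **Items**: liabilities `(F·diag(s))Bᵀ` + per-site offsets + age/sex
  effects + Gaussian noise, standardized and discretized at fixed normal
  quantiles giving level prevalences ≈ 70/20/10% (skewed symptom
  endorsement; item-level prevalences of real instruments vary, so this
  is a fixture choice, not an empirical claim). Column 1 of `B` is
  all-positive (a general factor); a configurable number of items is
  forced constant at zero, emulating never-endorsed items.
- **Structure**: parcel maps are kernel-smoothed white noise on the
  sphere (homotopically correlated across hemispheres via folded
  coordinates), so loading maps carry realistic spatial autocorrelation —
  the property spin tests must respect.
- **FC**: a fixed network block-model baseline (higher within-network
  correlation, plus a smooth decay along a planted 1-D network axis that
  makes the principal gradient recover the axis) plus additive rank-one
  edge perturbations per latent factor and noise, clipped to [−1, 1],
  symmetric with unit diagonal. Edge patterns are *additive* in node
  values, `(a_i + a_j)/2`, so a parcel's mean edge loading tracks its own
  position on the pattern — the linear profile the gradient-correlation
  analysis targets.
- **Confounds**: additive site offsets (drawn once per dataset), age and
  sex effects, and deterministic ICV / total-surface-area couplings, the
  simplest structures that site-aware resampling and covariate regression
  must handle.
- **Held-out blocks** share the same `F` with modality-specific noise.

Default scale: 600 participants, 5 sites, 100 cortical + 19 subcortical
parcels, 18 networks (one subcortical), 119 items, 3 latent components
with strengths (4.0, 2.5, 1.6). The strengths are spaced so the three
planted singular values are well separated (squared gaps 16 / 6.25 /
2.56) and the weakest factor remains recoverable at n = 600 through the
ordinal discretization — the generator's purpose is parameter-recovery
validation, so recoverability at the default scale is a design
requirement, not an observation. A 400-cortical-parcel configuration is
supported for full-scale bookkeeping (87,571 FC edges).

What the generator does *not* emulate: fMRI time series, scanner-specific
artifacts, motion traces, non-additive site effects, item response
heterogeneity, family structure, or missingness. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
stated generative model, not robustness to every pathology of real data.

## Numerical choices

- PCA and PLS sign conventions are deterministic (largest-|entry| rule
  for PCA coefficients and gradient columns; non-negative behavioral
  weight sum for PLS components) so fixtures reproduce bit-identically.
- `latent_strengths` is validated as non-increasing and non-negative;
  the all-zero vector is allowed for null-calibration cohorts.
- Zero-variance columns: rejected by `zscore_columns` (degenerate items
  must be filtered upstream); inside bootstrap replicates a resampled
  column that collapses to a constant is zeroed instead (it carries no
  information in that replicate); zero-variance features get NaN
  loadings, excluded from summaries.
- Permuted singular values are compared component-by-component without
  Procrustes rotation of the null singular vectors — the direct
  comparison of the permuted spectrum; a rotation-based null is a known
  alternative and deliberately not implemented.
- The diffusion embedding rejects disconnected affinity graphs
  (component sizes reported), asymmetric or negative affinities, and
  leading eigenvalues above 1; the diagonal is zeroed before the Markov
  construction.
- The `t = 0` convention is the multi-scale eigenvalue scaling
  λ/(1−λ); raw eigenvector scaling is available via a nonzero
  `diffusion_time`.
- Every stochastic stage of `run_pipeline` draws from
  `SeedSequence([master_seed, crc32(stage_name)])`, so stages are
  independent and a config reruns bit-identically; the manifest hash
  excludes the output directory.

## Design choices on genuinely open points

- Site enters the confound model as fixed-effect dummies (the standard
  reading of "regressed out"); no empirical-Bayes site harmonization.
- PCA inputs are centered but not variance-scaled: the downstream PLS
  z-scores the concatenated scores, and double scaling would distort the
  within-modality variance rule.
- Behavioral loadings are computed against residualized items, matching
  the imaging side for internal consistency.
- Replication blocks are z-scored with replication-sample statistics,
  mirroring within-sample residualization.
- Between-network FC loadings are collapsed to a parcel map as the mean
  loading over a parcel's cross-network edges (within-network likewise);
  this per-parcel-mean reading is an interpretation, flagged here.
- The FDR family for bootstrap loading tests is one family per component
  across all features/blocks of the run; component significance is its
  own five-test family; covariate post hocs are their own family.

## Limitations

- Parcel-level spins (rotating centroids, duplicates allowed) are
  coarser than vertex-level spinning; calibration is verified on the
  synthetic parcellation but parcel counts below ~50 leave few effective
  rotations.
- Group-mean gradients only; no individual-level embeddings.
- No cross-cohort replication, longitudinal modeling, or family-aware
  resampling.
- The permutation null permutes behavior rows only; X-block structure is
  held fixed (exchangeability within site is assumed on the behavior
  side).
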