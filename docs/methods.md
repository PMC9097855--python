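# Methods

## The model

`connmed` treats the structural connectome as a *composition*: subject
*i*'s representation is ωᵢ on the (K−1)-simplex, the fraction of their
streamlines falling in each of K population-level endpoint clusters.  Two
linear layers connect genotype, connectome and trait:

- screen layer, per SNP g and cluster k:
  ω_{ik} = β₀ + x_{ig} β_k + Zᵢ'γ_k + ε_{ik}, ε ~ N(0, σ₁²) i.i.d.;
- outcome layer, per screened SNP and trait:
  Yᵢ = η₀ + x_{ig} η + Σ_{k∈S^g} ω_{ik} α_k + Zᵢ'ξ + εᵢ, ε ~ N(0, σ₂²).

Both are ordinary least squares with exact t-based inference.  ADE = η̂,
AIE = Σ α̂_k β̂_k with β̂_k reused from the screen fit (same confounders,
not refit jointly), and %GE = 100·|AIE|/(|ADE|+|AIE|).  The absolute-value
form keeps the ratio in [0, 100] when direct and indirect effects have
opposite signs; when ADE = AIE = 0 the percentage is reported as undefined
(NaN with a flag), never as 0.

Assumptions worth stating: homoscedastic Gaussian errors in both layers; no
exposure–mediator interaction; the active-set mediators enter additively;
confounding of both layers is captured by age, sex and the top two genotype
PCs; and the two layers are estimated on the same subjects, so the AIE is a
product of estimates whose sampling error we assess by delta-method
intervals and by the subject-resampling bootstrap rather than analytically.

The indirect-path test is *joint significance*: a path k is called
significant iff both H₁₀: β_k = 0 and H₂₀: α_k = 0 are rejected at the
working level (default two-sided 0.05).  No Sobel-type variance formula is
used.  Case labels (direct-only / indirect-only / both / neither) gate on
raw p-values by default; BH-adjusted columns are emitted alongside and can
gate instead.

## Pipeline details and numerical choices

- **Endpoint canonicalization.**  "Order by coordinate value" is made
  precise as lexicographic comparison (x, then y, then z), which makes the
  6-vector invariant to tracking direction; ties (closed loops) are benign.
- **Mini-batch K-means** is implemented in-package: k-means++ seeding from
  a single numpy `Generator`, uniform batches drawn *without* replacement
  (capped at the sample count), per-centre streaming learning rate
  1/(cumulative count), default batch 1024 and 200 iterations, one
  initialization per seed.  With batch ≥ M this makes the K = 1 centroid
  exactly the data mean — a useful exactness anchor for tests.  Clusters
  that end empty are re-seeded from the farthest point (logged).  Labels
  are arbitrary; after fitting they are relabeled by descending fiber mass
  purely for report stability, and all downstream logic is
  permutation-safe.  K defaults to 10, exposed in config.
- **Coordinates** are used as stored (scanner-space mm); no registration is
  performed — real use assumes spatially normalized tractograms.
- **QC order**: subjects with >10% missing genotypes, then variants with
  >10% missingness, then variants with 1-df chi-square HWE p < 1e-7
  (monomorphic variants return p = 1 by convention; an exact test would be
  nearly equivalent at this threshold and is left as future work).
- **Screen regressions** use Frisch–Waugh residualization on the
  [1, Z] base design — algebraically exact OLS, one matmul for the whole
  SNP × cluster grid; subjects missing a dosage are dropped per SNP
  (pairwise deletion), and SNPs monomorphic after subsetting are emitted
  with p = 1 and a degenerate flag.  Missing dosages are mean-imputed only
  for PCA; PCA scales columns by √(2p̂(1−p̂)), drops zero-variance columns,
  and fixes each component's sign by its largest-magnitude loading.
- **FDR** is Benjamini–Hochberg (via statsmodels), applied within each
  cluster's p-value family separately.  **LD pruning** is greedy: selected
  SNPs ordered by best p (ties by id), accepted iff r² ≤ 0.1 against all
  previously accepted, with r² the squared Pearson correlation over
  pairwise-complete subjects.
- **Collinearity guard**: all K simplex columns plus an intercept are
  exactly singular (Σ_k ω_{ik} = 1); the outcome model detects rank
  deficiency and raises with guidance to drop one cluster.
- **Bootstrap**: subjects resampled with replacement, both layers refit per
  replicate, percentile 95% CIs, sign-based two-sided p-values; degenerate
  replicates are skipped and counted.  Default 500 replicates.
- **Robustness utilities**: a seeded random equal split with per-half
  refits and a both-halves concordance report, and one-per-family
  subsampling (uniform choice within family), which doubles as
  keep-one-MZ-twin when MZ pairs are labeled as families.

## The synthetic cohorts

The generator's purpose is to give every downstream stage data with the
exact statistical structure the two layers assume, plus the geometry the
clustering stage consumes.

- Genotypes are Hardy–Weinberg: dosage ~ Binomial(2, MAF), MAF uniform in
  (0.05, 0.5] by default, entry-wise missingness optional.  Covariates: age
  uniform on 22–36 years, sex Bernoulli(½), optional sibling-pair families.
- Cluster geometry: endpoint-pair centers on a 60 mm Fibonacci sphere
  (pairwise separations ≫ the 4 mm endpoint spread), uniform baseline
  proportions 1/K.  Streamlines carry 4–60 linearly interpolated interior
  points; only the endpoints carry information, matching the pipeline.
- Proportions: the screen layer's linear predictor is clipped at 1e-6 and
  renormalized onto the simplex.  A linear model on a composition cannot
  hold exactly; this mapping is one admissible choice, adopted because it
  preserves the linear effect structure while guaranteeing valid rows.  The
  built-in scenarios additionally plant **compositional** genotype effects
  (+β on the target cluster, −β/(K−1) on the rest): a variant that shifts
  fiber mass into one bundle must draw it from others, and since the
  row-sum is then dosage-free, renormalization leaves the planted slope
  unattenuated — which is what makes unbiased-recovery checks meaningful.
- Traits: the outcome layer evaluated on the true proportions, with the
  direct effects summed over all SNPs carrying one.

Default effect sizes (β = 0.005 proportion/allele, α = 55 trait-units per
unit proportion, η = 2 trait-units/allele, σ₁ = 0.02, σ₂ = 10, planted-SNP
MAF fixed at 0.3, trait intercept 100 on an NIH-toolbox-like scale) were
calibrated analytically from the delta-method standard errors so that the
joint-significance indirect power at n = 870 is ≈ 0.85, and the planted
(SNP, cluster) pair survives the per-cluster FDR screen at n = 2000 with
probability ≈ 1 — the latter so that recovery studies measure estimation
bias rather than selection effects.  A single master seed is split into
per-stage child seeds (SeedSequence.spawn), so any stage can be regenerated
independently and every generator is bit-reproducible.

What the cohorts do *not* emulate: LD between SNPs (variants are
independent, so LD pruning is exercised on constructed correlated blocks in
tests, not in scenarios), population stratification (the PCs included in
the models are noise covariates there), twin genetic correlation beyond
shared family ids, realistic DWI signal or tractography failure modes, and
non-Gaussian trait noise.  Passing tests therefore certify the estimators
and procedures under their stated assumptions — not robustness to the
violations real cohort data exhibit.

## Study sizes used by the test suite

Replicated checks run at the sizes their claims require: null calibration
at 100 replicates of n = 500 with 500 SNPs and K = 10; full-screen recovery
at 100 replicates of n = 2000 with 500 SNPs; bootstrap consistency on one
n = 870 cohort with 500 replicates; power and coverage invariants that do
not depend on the screen run with few SNPs per cohort (the screen is the
only stage whose cost grows with SNP count).  The whole suite completes in
a couple of minutes on one CPU.

One calibration fact worth recording: under the global null, each
per-cluster BH family at q = 0.05 still selects at least one SNP with
probability exactly q (Simes' equality on independent p-values), so with
K = 10 clusters some replicate-level selections are expected —
P(zero selections anywhere) ≈ 0.95¹⁰ ≈ 0.60.  FDR control is a per-family
guarantee; the suite asserts it as such (≈ 95% of cluster families select
nothing) and treats downstream consequences (a near-empty, not always
empty, null mediation table) accordingly.

## Known limitations

- β̂_k enters the AIE from the screen fit; post-selection inflation of
  |β̂| is negligible at the calibrated power but would bias AIE upward for
  marginally-powered pathways (winner's curse).
- The compositional effect convention is a modelling choice of the
  generator, not of the estimators; user-supplied `beta_map`s that do not
  sum to zero across clusters are attenuated slightly by renormalization.
- No mixed-model/kinship adjustment: family structure is handled only by
  exclusion or subsampling.
- The clustering objective is non-convex; different seeds can land in
  different local optima (the recovery tests use well-separated geometry,
  where the global optimum is reliably found).
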