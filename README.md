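# connmed

Connectome-mediated imaging genetics: does a genetic variant influence a
cognitive trait directly, or by reshaping the brain's white-matter
architecture?  `connmed` implements a complete analysis chain for that
question, aimed at statisticians and imaging-genetics researchers working
with tractography, SNP arrays and behavioral scores:

1. **Compositional connectome.** Every streamline of every subject is
   reduced to its two 3-D endpoints, canonically ordered and pooled into a
   population matrix `C` (6 × Σmᵢ).  Mini-batch K-means partitions `C`
   into K clusters, and subject *i*'s connectome is the simplex vector
   ωᵢ = (ω_{i1}, …, ω_{iK}), ω_{ik} = (fibers of *i* in cluster *k*) / mᵢ.
2. **Per-cluster GWAS screen.** For each SNP *g* (additive minor-allele
   dosage x_{ig} ∈ {0,1,2}) and cluster *k*:
   ω_{ik} = β₀ + x_{ig} β_k + Zᵢ' γ_k + ε_{ik}, with age, sex and the top 2
   genotype PCs as confounders Z.  H₀: β_k = 0 is tested per pair;
   Benjamini–Hochberg FDR control is applied within each cluster
   separately; surviving SNPs are greedily LD-pruned (r² ≤ 0.1) to lead
   SNPs, and each selected SNP carries an active cluster set S^g.
3. **Mediation decomposition.** Per (SNP, trait):
   Yᵢ = η₀ + x_{ig} η + Σ_{k∈S^g} ω_{ik} α_k + Zᵢ' ξ + εᵢ.
   The average direct effect is ADE = η̂; the average indirect effect is
   the product-of-coefficients sum AIE = Σ_{k∈S^g} α̂_k β̂_k; and the
   percent mediated is %GE = 100·|AIE| / (|ADE| + |AIE|), which stays in
   [0, 100] even when the two effects oppose each other.  Each pair is
   classified by joint significance into direct-only / indirect-only /
   both / neither, with a subject-resampling bootstrap and split-half and
   one-per-family robustness utilities.

A first-class synthetic-data module generates complete cohorts
(Hardy–Weinberg genotypes, covariates with sibling structure, endpoint
clouds around ground-truth cluster centers, and traits) with planted
β, η, α effects under four canonical truth states (`null`, `direct_only`,
`indirect_only`, `full_mediation`), so the entire chain is testable
without any restricted data.

## Worked example

```python
import connmed
from connmed import genetics as gen
from connmed.mediation import outcome_model, compute_effects

# synthetic cohort at the study scale: n=870, 500 SNPs, K=10 clusters,
# a planted SNP->cluster->trait pathway plus a direct effect
b = connmed.scenario("full_mediation", 870, seed=1, n_snps=500)

Z = gen.make_covariate_table(b.covariates, b.genotypes)   # age, sex, PC1, PC2
assoc = gen.fdr_select(gen.cluster_gwas(b.proportions, b.genotypes, Z))
amap = gen.active_sets(assoc)
print(amap)  # {'snp00000': [0]} -- the planted pair survives the screen

S = amap["snp00000"]
om = outcome_model(b.traits.cogscore.to_numpy(),
                   b.genotypes.dosages[:, 0],
                   b.proportions.weights[:, S], Z, clusters=S)
beta = {int(r.cluster): (r.beta_hat, r.p)
        for r in assoc[assoc.snp == "snp00000"].itertuples()}
s = compute_effects(om, {k: beta[k] for k in S}, snp="snp00000")
print(f"ADE={s.ade:.3f}  AIE={s.aie:.3f}  %GE={s.pct_mediated:.2f}")
```

prints (seed 1):

```
{'snp00000': [0]}
ADE=2.308  AIE=0.137  %GE=5.61
```

i.e. the variant raises the trait by ≈2.3 points per minor allele directly,
and ≈0.14 points per allele through the connectome cluster it reshapes —
about 6% of its total effect is carried by brain structure (the planted
truth is η = 2, αβ = 0.275; a single cohort at n = 870 estimates both with
visible sampling error, which the replicated tests average away).

The same chain is available from the shell:

```bash
connmed simulate --scenario full_mediation --n-subjects 870 --out-dir work
connmed run-all --seed 1 --out-dir work
connmed split-half --seed 1 --out-dir work
```

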