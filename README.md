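# methimmune

Reference-based immune profiling of tumors from DNA methylation: estimate the
infiltration fractions of seven immune cell types (CD4+ T, CD8+ T, CD56+ NK,
CD19+ B, CD14+ monocytes, neutrophils, eosinophils) in bulk tissue methylomes,
group tumors into immune subtypes, and relate those subtypes to clinical and
transcriptome data.

## Who this is for

Computational biologists with (i) a purified-immune-cell methylation reference
panel (gene x sample beta values with cell-type labels, e.g. a sorted-leukocyte
450K panel) and (ii) bulk tumor/normal beta matrices with sample metadata.
Everything travels as plain delimited text; a bundled synthetic-cohort
generator with full ground truth supports validation and benchmarking without
any external data.

## The method

1. **Marker selection (Shannon entropy).** For each gene, the relative
   methylation profile across the N = 7 cell-type means,
   `p_s = (beta_s + eps) / sum_t (beta_t + eps)`, is scored by
   `H0 = -sum_s p_s * log2(p_s)`. A flat profile attains the maximum
   `log2 N`; a cell-type-specific gene concentrates the profile and lowers
   `H0`. Markers are the genes with the highest specificity `log2 N - H0`.
2. **Deconvolution (constrained least squares as an exact QP).** Each bulk
   sample's marker betas `y` are modeled as `y = X a + eps` with the marker x
   cell-type signature `X`, minimizing `sum eps_i^2` subject to `a_j >= 0`
   and `sum_j a_j <= 1`. The quadratic program is solved exactly by face
   enumeration; the slack `1 - sum a_j` is the sample's non-immune content,
   and fractions below 0.01 are reported as zero.
3. **Subtyping (consensus k-means).** Per cancer, tumors are clustered on
   their 7-dimensional fraction vectors over repeated subsampled k-means
   runs (k = 2..20, 100 resamples, subsample 0.8); the number of clusters is
   the smallest k after which the area under the consensus CDF stops growing
   by more than a stability tolerance. A seeded t-SNE embedding is provided
   for visualization.
4. **Annotation.** Every (cancer, subtype, cell type) is called increase /
   decrease / no-change against the cancer's normal samples (Welch t,
   Benjamini-Hochberg within cancer, alpha 0.05).
5. **Phenotype & transcriptome.** Kaplan-Meier curves and log-rank tests
   across subtypes; stage and tumor-size association tests;
   methylation-expression correlation against a permutation baseline;
   differential expression for "increased" subtypes vs normals; immune
   checkpoint gene testing; hypergeometric gene-set enrichment; import hooks
   for externally computed per-sample scores (ESTIMATE, TIDE).

## Worked example

```python
import methimmune as mi

cohort = mi.generate_cohort(seed=7)                  # synthetic study + truth
config = mi.RunConfig(entropy_threshold_value=350, k_max=8, seed=7)
result = mi.run_pipeline(cohort.reference, cohort.reference_sheet,
                         cohort.bulk, cohort.sheet, config)

print(result.signature.marker_counts.to_string())
print(result.fractions.fractions.iloc[0].round(3).to_string())
for cancer, res in sorted(result.consensus.items()):
    surv = result.survival[cancer]
    print(f"{cancer}: chose k={res.chosen_k}, "
          f"log-rank chi2={surv.statistic:.1f} (p={surv.p_value:.2e})")
```

Output:

```
CD14    50
CD19    50
CD4     50
CD56    50
CD8     50
Eos     50
Neu     50
CD14    0.139
CD19    0.159
CD4     0.221
CD56    0.109
CD8     0.153
Eos     0.096
Neu     0.124
CAN1: chose k=3, log-rank chi2=43.3 (p=4.05e-10)
CAN2: chose k=3, log-rank chi2=16.5 (p=2.67e-04)
```

The signature retains all 350 planted marker genes (50 per cell type); the
first tumor's reported fractions are its estimated immune composition (here
summing to ~1, i.e. little unexplained non-immune mass); both pseudo-cancers
recover the three planted subtypes, whose planted hazard differences the
log-rank test detects.

A thin CLI mirrors the stages: `methimmune simulate|deconvolve|subtype|
annotate|survival --help`.

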