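# Methods

## Model and assumptions

The pipeline treats a bulk tissue methylome as a convex-ish mixture of
cell-type methylomes. On the beta scale (fraction of methylated signal, in
[0, 1]) this mixing is linear: if cell type j occupies fraction `a_j` of a
sample and has marker-gene profile `x_.j`, the observed marker vector is
`y = X a + eps`. Three assumptions follow:

- **Conserved cell-type profiles.** A cell type's methylation profile is
  approximately the same in every sample (replicate noise aside); this is
  what makes a fixed signature matrix meaningful.
- **Partial composition.** The seven immune types do not exhaust the tissue;
  tumor cells, stroma and anything else form a non-immune remainder, so
  `sum_j a_j <= 1` rather than `= 1`. The remainder is never modeled
  explicitly — it is the constraint slack.
- **Additive noise.** Measurement and biological noise enter additively on
  the beta scale (with clipping at the boundaries).

All analysis stays on the beta scale; no M-value transform is applied because
the mixing model is linear in betas, not in logits.

## Stages and numerical choices

### Marker selection

Entropy is computed on the N = 7 cell-type mean profiles, not on the 42
individual replicates: specificity is a property of the populations, and
averaging replicates removes replicate noise first. A pseudocount
(default 1e-6) guards genes whose betas are all ~0; entropy of an all-zero
profile with zero pseudocount is undefined and raises. Genes with any missing
value across the panel are excluded — the entropy profile and the QP both
need complete vectors, and imputation inside a reference panel would
manufacture specificity.

Specificity is `log2 N - H0`: a concentrated (cell-type-specific) profile has
*low* entropy. A configuration switch (`high_entropy_specific`) inverts the
ranking for users who prefer the opposite convention, but the default follows
the mathematics of the score. Both hypo- and hyper-methylated markers
qualify; the direction is recorded. The retention rule is configurable
(`top_m` — default, `quantile`, or `absolute` cutoff in bits) because the
"right" marker count depends on the panel; on the bundled synthetic panel the
matched choice is top-350.

### Deconvolution

The constrained least-squares problem (min `||y - X a||^2`, `a >= 0`,
`sum a <= 1`) is a strictly convex QP whose optimum lies on a face of the
feasible polytope and coincides there with the least-squares minimizer over
the face's affine hull. The solver enumerates all `2^J` zero-patterns times
the two states of the sum constraint, solves each face's KKT system, and
keeps the feasible candidate with the smallest objective. This is exact (no
iterative tolerance) and costs microseconds at J = 7; a guard rejects J > 14
where enumeration would be inappropriate. Rank-deficient signatures produce a
warning and one of the minimizers (pseudo-inverse solve). The upper bounds
`a_j <= 1` are implied by nonnegativity plus the sum constraint and are not
encoded separately; the nominally strict bounds of the model statement
(`0 < a_j < 1`) are implemented as closed bounds, with the 0.01 reporting
threshold playing the role of the open lower bound.

Reported fractions below the infiltration threshold (default 0.01) are set to
zero with **no renormalization** — the remainder `1 - sum a` is interpreted
as non-immune content, and renormalizing would silently reassign it. Raw
(pre-threshold) solutions are kept in the diagnostics.

### Subtyping

Consensus k-means per cancer on raw fractions (no standardization: the seven
coordinates already share the [0, 1] scale and rescaling would inflate noise
in near-zero cell types). Per k, 100 subsampled (fraction 0.8) k-means runs
(scikit-learn, seeded k-means++, one initialization per resample) accumulate
`consensus(i, j)` = co-clustered / co-sampled; pairs never co-sampled are
excluded from the CDF and counted. The final partition at the chosen k uses
ten k-means++ restarts on the full data.

**Choosing k.** The area under the consensus CDF equals `1 - mean(consensus)`
over sample pairs, so it grows with every additional cluster; the rule takes
the smallest k after which the relative gain `(A(k+1) - A(k)) / A(k)` stays
below a stability tolerance. The tolerance default is **0.1**: for an ideal,
equal-size 3-cluster structure the relative gain at k = 3 -> 4 is already
~0.085 even with perfectly stable clustering (splitting a clean cluster
separates ~1/9 of pairs), so a 0.05 tolerance can never stop at 3; 0.1 sits
between this ideal post-elbow gain and the ~0.4+ gains observed before the
elbow. The statistic has a known blind spot: for k_true = 2 the ideal
post-elbow gain is ~0.25, above any tolerance that still accepts 3-cluster
structures — two-cluster candidates warrant inspecting the area curve (it is
returned per k). The k range is truncated to n - 1 for small cohorts, and a
decreasing area curve triggers a warning but the rule is still applied.

t-SNE (scikit-learn, seeded, random initialization) is a visualization hook
only; nothing downstream consumes the coordinates.

### Annotation

"Corrected t-test" is implemented as Welch's t (robust to unequal variances
between a subtype and the normal pool) with Benjamini-Hochberg adjustment
within each cancer across its subtype x cell-type tests; a `global` switch
adjusts across cancers jointly, and a Mann-Whitney switch replaces the t-test.
Calls use the reported (post-threshold) fractions — the annotation describes
the reported infiltration. Cancers without >= 2 normals are emitted as
all-nochange with an `untestable` flag rather than dropped, so every subtype
always carries exactly seven rows.

### Phenotype and transcriptome

Survival uses the Kaplan-Meier product-limit estimator and the standard
log-rank chi-square (lifelines), overall survival only. Stage association is
a chi-square independence test with a linear-by-linear trend option
(`M^2 = (N-1) r^2`) for ordinal stage and a Fisher-exact fallback for sparse
2x2 tables. The methylation-expression check compares the observed per-gene
Pearson r (within subtype) against a baseline in which the expression columns
are permuted across samples, with a rank-based permutation p (1000
permutations by default, seeded). Differential expression is Welch t + BH
with the "strictly selected" defaults q < 0.05 and |log2FC| >= 1; checkpoint
genes are tested by Kruskal-Wallis across subtypes with the star-tier
convention (`*` q<=0.05 ... `****` q<=1e-4). ESTIMATE and TIDE are
third-party scoring algorithms with their own reference data; this package
imports their per-sample scores and performs only the cross-subtype
comparison.

## The synthetic study

The generator emulates exactly the statistical structure the analysis
assumes, with ground truth recorded at every stage:

- **Reference panel** (defaults): 7 cell types x 6 replicates, 2000 genes,
  baseline betas U(0.2, 0.8), 50 markers per type with contrast 0.4
  (hypo-methylated where the baseline is high, hyper where low, so the
  planted contrast is not clipped), replicate noise sd 0.02.
- **Mixtures**: immune composition Dirichlet on the 7-simplex; a non-immune
  mass m ~ U(0.1, 0.3) scales the immune part to sum 1 - m and adds m of a
  background profile (gene-wise reference mean plus an independent offset,
  sd 0.05) — this creates genuine `sum <= 1` slack without modeling tumor
  methylomes; additive Gaussian beta noise sd 0.05, clipped.
- **Cohort**: two pseudo-cancers of 200 tumors + 50 normals; three planted
  tumor subtypes per cancer, each raising one cell type's mean fraction by
  0.15 (renormalized); normals follow the unshifted composition. The
  within-subtype Dirichlet concentration is 300, putting the within-subtype
  spread (~0.05 across the 7-dimensional fraction space) well below the
  planted between-subtype distance (~0.17) — the planted structure must be
  identifiable for recovery benchmarks to be informative. Expression is
  coupled to methylation at Pearson rho = -0.5 per gene (exact population
  correlation by construction); survival is exponential with hazard ratio 2
  between adjacent subtypes (base 0.002/day) and exponential censoring
  (0.0005/day); ordinal stage is loosely tied to the subtype index.

What the generator does **not** emulate: probe-level 450K structure and
normalization artifacts, copy-number or tumor-purity confounding, correlated
(non-independent) gene noise, cell types missing from the signature, and
batch effects. Passing recovery benchmarks therefore demonstrates the
correctness of the estimator under its own model, not robustness to real
tumor methylome violations of it.

## Problem sizes used in the bundled benchmarks

The test suite and `scripts/acceptance.py` run the full method at the cohort
sizes above (500 bulk samples, 2000 genes, k scanned 2-8 with 100 resamples),
plus simulation studies of 500 null cohorts for annotation error control,
100 shifted cohorts for power, and 1000/500 replicates for log-rank size and
power — sizes at which the Monte-Carlo error of each checked rate is well
below its acceptance margin.

## Known limitations

- Face enumeration is exponential in the number of cell types; it is the
  right tool at J = 7 but a primal active-set or interior-point solver would
  be needed for signatures with many more populations.
- The CDF-area rule's constant tolerance cannot be calibrated simultaneously
  for k_true = 2 and k_true >= 3 (see above).
- The deconvolution inherits a small positive bias (~m/J per cell type) when
  the non-immune background resembles the average immune profile, because
  part of the background projects onto the signature span; the noisy-recovery
  error budget in the benchmarks includes this bias.
- Fractions are compositional; the annotation's per-cell-type tests ignore
  the induced negative correlation between coordinates (a subtype that truly
  gains one cell type will show mild compensatory decreases elsewhere).
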