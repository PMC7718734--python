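# Methods

## Data model and preprocessing

The analysis unit is the inbred line: every layer is a line-level table and
all layers are joined on the sorted intersection of line identifiers (dropped
ids are recorded). Genotypes are allele dosages; in a fully inbred panel VCF
calls collapse to {0, 2} with residual heterozygous calls treated as
no-calls by default (configurable to dosage 1) — residual heterozygosity in
such panels is rare and usually reflects segregating or mis-called sites, so
no-call is the conservative default.

Preparation steps, with strict inequalities throughout:

- variants kept when MAF > 0.05 **and** call rate > 0.8 (both configurable);
  remaining missing calls are mean-imputed per variant so the kernel algebra
  operates on a complete matrix — with call rate > 0.8 imputation touches a
  small minority of cells and standard practice in genomic prediction;
- genes kept when mean log2FPKM across lines > −1.828; the threshold is the
  expressed-mode boundary of a bimodal abundance distribution and is consumed
  here as a plain configuration value, not re-derived;
- phenotypes optionally replaced by OLS residuals on an intercept plus
  nuisance covariates (infection status, inversion karyotypes, ...), with the
  grand mean added back. Residual-plus-mean preserves the trait mean exactly
  and can only reduce variance. Aliased covariate columns are dropped with a
  warning; lines with missing covariates are dropped and reported;
- variants map to a gene when their position falls in the gene body ± a
  1,000 bp window (1-based inclusive coordinates). The window is a
  configuration value recorded in outputs; annotation pipelines differ in how
  far regulatory context extends, and ±1 kb is a common default.

## Kernels

Feature matrices are column-centered and scaled to unit **population**
(divisor-n) variance; zero-variance columns are dropped and reported. The
linear kernel is `K = WW'/p` over the retained columns, which makes the mean
diagonal exactly 1 and every row sum exactly 0. The divisor-n convention is a
deliberate choice: it pins the kernel scale (the alternative divisor-(n−1)
only rescales all variance components jointly and leaves accuracies
unchanged). The interaction kernel is the Hadamard product `G#T`, PSD by the
Schur product theorem. GO partitions subset the columns of the **once**
standardized matrix, so

    |in| · K_in + |out| · K_out = p · K_full

holds exactly; this reconstruction identity is asserted in tests and
exercised by every scan.

Kernels are built once on all lines (training and test together) and variance
components are then estimated on training rows only. Building on all lines
matches how relationship matrices are used in practice on fixed panels; the
only information that crosses the fold boundary is the per-feature column
mean and scale, which does not involve test phenotypes. The leakage-sensitive
steps (TWAS gene selection, random gene draws) are re-done strictly inside
each training fold, and a test asserts that permuting test-line phenotypes
cannot change a fold's selected gene set.

## REML and BLUP

The mixed model is `y = 1μ + Σ_c u_c + e`, `u_c ~ N(0, K_c σ²_c)`,
`e ~ N(0, I σ²e)`. The restricted log-likelihood with the intercept profiled
out is

    lR = −½ [ (n−1) log 2π + log|V| + log(1'V⁻¹1) + y'Py ],
    V = Σ_c K_c σ²_c + I σ²e,   P = V⁻¹ − V⁻¹1 (1'V⁻¹1)⁻¹ 1'V⁻¹.

Estimation is constrained to σ²_c ≥ 0 (components clamped at zero are
flagged); unconstrained REML implementations permit negative components, but
a negative component does not define a valid covariance and a clamped
component contributes nothing to prediction, so accuracy is insensitive to
this choice.

- **Single-kernel models** use a one-time eigendecomposition of K and a 1-D
  profiled search over the signal fraction h = σ²g/(σ²g+σ²e) (64-point grid
  plus bounded Brent refinement) — global, exact and O(n) per evaluation,
  which keeps per-fold fits cheap inside cross-validation.
- **Multi-kernel models** use average-information (AI) REML with an
  active-set treatment of the non-negativity bounds: if a proposed step
  pushes a component negative, that component is fixed at zero and the step
  re-solved for the remaining directions (whole-step damping would stall the
  free directions). A step that fails to increase the likelihood is shrunk
  and, failing that, replaced by the guaranteed-ascent EM update. Clamped
  components are released whenever their gradient turns positive.
- Initialization: every component (including the residual) starts at
  var(y)/(C+1) for C kernels. Convergence: relative restricted-log-likelihood
  change < 1e−8 on a full undamped AI step (or with a flat gradient), max 200
  iterations; non-convergent fits are flagged and their folds excluded from
  summaries with a warning.

A numerical note: centered features make every kernel row-sum zero, so V is
singular along the ones vector with eigenvalue σ²e. The restricted likelihood
is flat in that direction (the log|V| and log(1'V⁻¹1) contributions cancel),
but evaluating it with σ²e below ~1e−9·var(y) amplifies cancellation error;
the residual variance is therefore floored at 1e−10·var(y).

Prediction of held-out lines is the conditional mean

    ŷ_test = μ̂ + Σ_c σ̂²_c K_c[test,train] V⁻¹ (y_train − μ̂1)

with μ̂ the GLS intercept under V; the residual does not enter the
cross-covariance because test and train residuals are independent. Tests
verify this equals the partitioned-multivariate-normal conditional mean
computed by dense linear algebra to 1e−8, and that the REML optimum matches a
grid-plus-Nelder–Mead search of the same likelihood to 1e−4.

## Cross-validation

Replicated k-fold (defaults k = 5, 30 replicates): per replicate a fresh
seeded shuffle split into near-equal folds; every line is tested exactly once
per replicate. Lines missing the trait are dropped before the design. One
design is shared across all models and all GO terms at a given seed so
contrasts are paired. Accuracy is Pearson r per fold; a zero-variance
prediction (e.g., an all-clamped fit or an empty gene selection) scores r = 0
with a degenerate flag, keeping aggregation total. Means and SEMs are
computed over all k·n_reps fold-level values; aggregating replicate means
first is available as an alternative through the per-fold table that every
run returns.

## TWAS-informed and GO-informed prediction

The per-gene scan is OLS of the (pre-adjusted) line-mean phenotype on an
intercept plus that gene's abundance, two-sided t test with n−2 df; constant
genes get p = 1. Covariate adjustment having already happened at the
phenotype level, intercept-only regression is the appropriate per-gene model.
Gene selection is strict (p < threshold); an empty selection degrades the
fold to an intercept-only prediction (r = 0 by the convention above). The
random-gene control draws k genes uniformly without replacement from a seed
that depends only on the design seed and fold.

GO terms with at least 5 genes inside the relevant feature universe are
eligible (variant-side universe: genes with ≥1 mapped variant; transcript
side: expressed genes; the combined model uses the intersection of the two
eligible lists). The GO hierarchy is *not* propagated — a gene belongs to
exactly the terms listed in the input map; users wanting ancestor closure can
pre-close the map upstream. Terms are ranked by mean r (ties: larger in-term
training proportion, then term id), and two scan-level diagnostics are
reported: the correlation of term accuracy with term size (near zero when
accuracy reflects term-specific signal rather than feature count) and with
the in-term training variance proportion (high when training-set variance
capture transfers to test-set accuracy).

## Random Forest

Regression forest over transcript features: 1000 trees on bootstrap
resamples, max(1, ⌊m/3⌋) features tried per split, minimum node size 5 —
the classic regression-forest defaults. The ensemble is backed by
scikit-learn's RandomForestRegressor; columns are addressed by gene id and
sorted internally, so predictions are invariant to input column order at a
fixed seed, and averaging training responses keeps predictions inside the
training range.

## Synthetic panels

The generator emulates the statistical structure the models assume, not any
particular organism's biology:

- **Genotypes**: fully homozygous dosages in {0, 2}; per-variant allele
  frequency uniform on [0.05, 0.5]; block LD from a first-order copying
  process (within a block of 20 variants, each line's allele copies the
  previous variant's allele with probability 0.9). A copying chain is a crude
  but adequate stand-in for haplotype structure at desk scale; it produces
  the LD decay the kernels care about without coalescent machinery.
- **Expression**: gene j is a linear function of its 5 randomly placed eQTLs
  plus non-genetic variation, scaled so the genetic fraction of each gene's
  variance equals the target (default 0.5) exactly. The non-genetic part is
  **not** independent across genes: half of it (default) loads on 20 latent
  line-level environmental factors shared by all genes. Real RNA-seq panels
  show strong co-expression from shared (micro-)environment, and this
  structure is load-bearing: with mutually independent transcripts the TRM's
  effective dimension equals the gene count and transcriptomic prediction at
  n ≈ 200 is capped near r ≈ 0.2 however strong the signal, which no real
  transcriptome resembles.
- **Phenotypes**: line means under four architectures — variant-additive,
  transcript-mediated, mixed, and genome×transcriptome interaction (products
  of standardized causal variant and transcript pairs). Effects are N(0,1);
  noise is orthogonalized against the signal and rescaled so the realized
  signal fraction equals h² exactly. In the mixed and interaction
  architectures the causal variants are drawn from the causal transcripts'
  eQTLs (a shared cis pathway) when expression truth is available: layer
  redundancy is a statement about traits whose genetic signal flows through
  expression, and disjoint layer signals would not be expected to show it.
- **Annotation**: random, possibly overlapping GO terms (sizes uniform on
  [5, 200]); an optional causal term contains exactly a specified gene list;
  gene spans are tiled along a toy chromosome so positional variant→gene
  mapping is exercised end to end.

Every bundle is a pure function of configuration and seed. Two sexes, when
needed, are just two independent bundles sharing genotypes, and line means
are generated directly (no within-line replicates) since all models consume
line means.

### What the simulations do and do not show

Passing tests on these panels show the estimators, the cross-validation
protocol and the scan logic behave correctly under the models' own
assumptions, with realistic sample sizes and dimensionalities. They do not
certify performance on real panels, whose allele-frequency spectra,
population structure, expression networks and trait architectures are far
richer than uniform MAF, first-order LD, a 20-factor co-expression model and
Gaussian effects.

## Problem sizes used in the checks

The end-to-end checks run at panel sizes chosen to exercise the full
pipeline while staying desk-scale: 200 lines with 5,000 variants / 2,000
genes for the layer contrasts (10 replicates of fivefold CV), 2,000 variants
/ 2,000 genes / 50 GO terms for the scan enrichment (2 replicates), 1,000
variants for heritability recovery (50 seeds), and n ≤ 60 instances for the
likelihood and conditional-mean oracles.

## Known limitations

- Single-trait, single-intercept models only; no covariates inside the mixed
  model (adjust phenotypes beforehand), no multi-trait or dominance kernels,
  no variance-component standard errors or likelihood-ratio tests.
- Allele-frequency-weighted GRMs (VanRaden-2 style) are not implemented.
- The AI-REML engine targets dense kernels at panel scale (hundreds of
  lines); it is not built for tens of thousands of individuals.
- GO scans refit every term independently; no multi-term joint model or
  unbiased in-training term selection is attempted.
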