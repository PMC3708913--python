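# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-cohort generator
does and does not emulate, and the numerical conventions that matter
for reproducing its output.

## Data model

A biallelic SNP is a `LocusSpec` (name, gene, major/minor allele); the
minor allele is the one whose copies the 0/1/2 dose counts. Cohorts are
individual-level tables of status (1 = case), optional covariates (age,
sex, smoking, drinking, COPD, family history) and one dose column per
locus; missing doses use the sentinel −1 and are excluded locus-wise
(available-case analysis), never subject-wise. Phase is never stored in
the cohort: inferred phase lives in EM posteriors, and simulated true
phase in a separate side channel.

`expand_counts_to_cohort` reconstructs an individual-level cohort from
per-locus 3×2 genotype counts. Single-locus statistics depend only on
those marginals, so every published per-locus quantity can be recomputed
exactly from printed tables; the cross-locus joint assignment is random
under the given seed and deliberately carries no information.

## Single-locus analysis

* **Hardy–Weinberg**: Pearson goodness of fit of the observed genotype
  counts against p², 2pq, q² from the sample allele frequency, 1 df, no
  continuity correction; monomorphic loci are flagged with χ² = 0, p = 1.
  Tested separately within cases and controls.
* **Association χ²**: Pearson on the 3×2 genotype table (2 df) and the
  2×2 allele table (1 df), no Yates correction. Expected cells below 1
  raise an error; the implementation warns through the precondition
  rather than silently proceeding.
* **Odds ratios**. Dominant compares carriers (het + minor-hom) to
  major-homozygotes; recessive compares minor-homozygotes to the rest.
  Both are 2×2 odds ratios with Woolf intervals
  exp(ln OR ± 1.96·√Σ1/cell) and Wald p. The additive model is the
  per-allele logistic regression coefficient on dose. The choice is
  deliberate: the two candidate additive conventions (allele-count 2×2
  vs dose logistic) differ at the second decimal at several of the
  package's reference loci, and the dose-logistic convention is the one
  that matches the reference table entries exactly, evidently being what
  the original R analysis computed. A Haldane–Anscombe +0.5 continuity
  correction is available for zero cells, off by default and flagged.
* **Adjusted ORs** refit the genetic term with covariates in a logistic
  model; the default adjustment set is age, sex, smoking, drinking.
* **Logistic regression** is implemented as IRLS with convergence at
  max |Δβ| < 1e-8 (≤ 50 iterations) and covariance from the inverse
  observed information. A coefficient exceeding 15 in absolute value is
  treated as (quasi-)separation and the fit is flagged non-converged;
  the statsmodels MLE serves as an independent oracle in the tests, not
  as the implementation. Frequency weights are supported because the
  haplotype GLM reuses this routine.
* **Power** uses the two-sided two-proportion normal approximation with
  pooled SE under the null and unpooled SE under the alternative. No
  continuity correction: dedicated power software implements several
  internal variants and one reference value (81.3%) sits one rounding
  unit from this formula's 81.2%; the other three reference values
  (94.2%, 81.6%, 99.5%) agree at printed precision.
* **Baseline comparisons**: unpaired equal-variance t-test for
  continuous variables (switchable to Welch), Pearson χ² for binary.
  No multiple-testing correction is applied anywhere in the package;
  raw p-values are reported and this is intentional.

## Haplotype inference

EM over all 2^L haplotypes of an L-locus gene (L ≤ 10 enforced;
in practice 2–3). E-step: a subject's compatible diplotypes (a,b) get
weight f_a·f_b, doubled when a ≠ b; M-step: expected haplotype
counting. Uniform initialisation, single start (the within-gene
likelihoods here are well behaved; the tests verify agreement with a
brute-force likelihood grid), convergence when the log-likelihood gains
less than 1e-8, hard assertion that the log-likelihood never decreases,
frequencies below 1e-12 pruned. Case, control and pooled frequencies
come from separate EM runs on the respective subsets.

**Score test.** For haplotype h, u_h = Σᵢ (yᵢ − ŷᵢ)·E[d_ih | genotype],
with ŷ the fitted values of a covariates-only logistic null model and
E[d_ih] the posterior-expected dose under the pooled EM. The variance is
the efficient score variance (dose information projected off the null
design); haplotypes whose variance is numerically zero are excluded and
reported. The global statistic is the quadratic form over the score
vector on its non-null eigenspace (the dose matrix has a built-in rank
deficiency because doses sum to 2). "Simulated" p-values permute the
trait and covariates jointly and use the add-one estimator
(1 + #{|z*| ≥ |z|})/(B + 1), which is never zero and mildly
conservative; the default B is 10,000, configurable.

**Haplotype GLM.** Each subject expands into its compatible diplotypes;
haplotype doses enter additively; the most frequent haplotype is the
reference; haplotypes under 1% pooled frequency are pooled into one
"rare" column (1% is the conventional pooling default and reproduces
the typical published-table structure of 7 listed RAGE haplotypes out
of 8). The fit iterates the phase posteriors jointly with the risk
model: E-step weight ∝ f_a·f_b·P(y | diplotype, β), M-step weighted
IRLS plus a frequency recount. This joint iteration is the package's
deliberate default rather than one-pass expectation substitution:
at realistic frequencies a triple heterozygote can hold only ~33%
posterior mass on its true diplotype, and the one-pass variant (kept as
`joint=False`) measurably attenuates per-copy odds ratios (a planted OR
of 2.1 shrinks to ≈1.7 on average at n ≈ 1600, while the joint fit
recovers ≈2.15). Standard errors use a cluster sandwich over each
subject's pseudo-observations. Haplotype analyses run per gene, never
across genes (the genes sit on different chromosomes and are simulated
in linkage equilibrium).

## MDR

A k-locus genotype cell is high-risk when its training case:control
ratio is ≥ the training fold's overall ratio (ties high, the canonical
convention); case-only cells are high, control-only low, empty cells
stay empty and — like cells unseen at testing time — predict "control"
(an "abstain" alternative was considered and rejected to keep the
classifier total). The attribute is scored by balanced accuracy,
(sensitivity + specificity)/2; with 819:803 near-balance the distinction
from raw accuracy is small but fixed by convention.

The exhaustive search evaluates every locus subset of each size within
stratified 10-fold cross-validation (stratification keeps class balance
in every fold; fold assignment is seeded). Per k, each fold selects the
training-BA-maximising combination; the reported model is the modal
(most often selected) combination with its cross-validation consistency
(CVC), and the reported testing accuracy is the mean over folds of each
fold winner's held-out balanced accuracy — the honest prediction
estimate, which naturally penalises larger k through selection
overfitting. The single overall best model must maximise testing
accuracy and CVC; when the two criteria disagree, parsimony (smaller k)
decides. Tie-breaks within a fold go to the lexicographically first
combination. Permutation significance re-runs the search at the model's
k on label-permuted data, p = (1 + #{BA* ≥ BA})/(B + 1).

## Synthetic cohorts

The generator emulates the package's reference study design: two genes
on different chromosomes, haplotypes drawn independently per gene under
Hardy–Weinberg within gene and linkage equilibrium between genes,
default frequencies equal to the published control-group haplotype
estimates (the one unlisted RAGE haplotype, T-A-A, receives the
remaining 4.3% of probability mass), 819 cases / 803 controls. Disease
risk follows logit p = β₀ + Σ_h β_h·copies(h) + γ·1[carrier at both
interaction loci], with β₀ = −2 (≈12% baseline risk — the intercept is
not identified by case-control data, so it only sets rejection-sampling
efficiency). Exact case/control totals come from rejection sampling,
so within-group genotype distributions are exact conditionals. Binary
covariates are drawn independently of genotype with status-specific
prevalences equal to the published baseline table (retrospective
margins); age is Gaussian with the published group means/SDs. True
diplotypes are retained in a side channel for validating phase
inference only.

What the simulator does **not** emulate: linkage-disequilibrium decay
within genes beyond what the haplotype frequencies imply, population
stratification, genotyping error and missingness, genotype–covariate
dependence, or covariate effects on risk. Passing recovery and
calibration tests therefore demonstrates correctness of the inference
machinery under the stated generative model, not robustness to those
real-data complications.

## Validation operating points

Chosen once as realistic for this design and recorded here:

* Haplotype-GLM recovery: planted C-A-A log-OR ln(2.1), 50 replicates
  at 819/803; the mean estimated OR is required to fall in [1.9, 2.3].
* Interaction recovery: planted interaction OR 2.5 on
  rs2070600 × rs1130409 carriers, no haplotype main effects, 100
  replicates at 819/803, full k = 1..5 search; the planted pair must be
  the overall best model in ≥ 80% of replicates. At this effect size
  the measured recovery is right at that boundary (~80–82%): misses are
  supersets of the true pair winning the testing-accuracy comparison by
  well under one accuracy point.
* Null calibration: 200 null cohorts for the score test (300+300,
  B = 199) and for MDR permutation (150+150, B = 100), each required to
  give a uniform p-value distribution (KS p > 0.01); 1000 null cohorts
  for Hardy–Weinberg type-I error (rejection rate in [0.03, 0.07] at
  α = 0.05). Cohort and permutation sizes here are the package's own
  test-design choices, balancing Monte-Carlo resolution against suite
  runtime.

## Known limitations

* The EM uses single-start uniform initialisation; multimodality is not
  expected at 2–3 common SNPs but is not impossible in general.
* The score test and the GLM treat EM haplotype frequencies as known
  when building the dose expectation; the sandwich variance absorbs
  within-subject weight reuse but not frequency-estimation uncertainty.
* The MDR permutation test permutes labels but reuses the stratified
  fold mechanism; fold randomness is resampled per permutation, which
  makes p-values mildly conservative relative to conditioning on folds.
* PED input supports the two-allele text dialect with `0` missing
  codes only; VCF, multi-allelic sites and X-linked dosage are out of
  scope.
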