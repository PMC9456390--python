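# Methods

`osteopgs` implements a fixed-weight polygenic-score (PGS) analysis for
case-control osteoporosis cohorts: genotype quality control, a
population-structure check, per-individual scoring against a curated
variant panel, cohort normalization, and ROC/decile/odds-ratio evaluation
of three phenotype contrasts (fracture, low bone mineral density, and the
comorbid combination). A seeded synthetic-cohort generator provides data
with the statistical structure the analysis assumes, so the whole pipeline
is testable without access to any genotype deposit.

## Scoring model

For individual *j* the raw score over a panel of *N* biallelic SNPs is

    PRS_j = Σ_i s_i · G_ij / (2 · M_j)

with `G_ij` the effect-allele dosage (0/1/2) and `s_i` the variant weight.
Weights derive from published per-allele odds ratios; the default
transform is `s_i = ln(OR_i)`, making the score additive on the log-odds
(liability) scale. The `identity` transform (`s_i = OR_i`) is retained as
a first-class option because published panel analyses sometimes sum raw
odds ratios; with no missing data the two give identical ranks whenever
weights are monotonically related, but they are not equivalent in general,
so the transform used is always recorded in the output.

Missing genotypes admit two conventions, both implemented:

* `observed` — the sum runs over called genotypes only and `M_j` is the
  per-sample count of called panel variants (the "average score over what
  was measured" convention). This is the formula as usually printed.
* `impute_freq` (default for cohort scoring) — each missing call
  contributes its cohort expectation `2·p̂_i` and the denominator stays
  `2N`. This is the default behaviour of the standard scoring tool
  (PLINK `--score`). We measured the difference on liability-model
  cohorts (n = 20,000, 140 SNPs, 5% missingness, weights equal to the
  generative effects): the `observed` convention attenuates AUC by
  ~0.015 relative to the latent-liability oracle because the *pattern*
  of missing loci (whose mean contributions differ) adds between-sample
  noise; frequency imputation reduces the gap to ~0.007, within Monte
  Carlo error. Hence the cohort-level default.

Raw scores are z-normalized over the whole analysis cohort
(mean 0, SD 1, n−1 denominator). Normalizing on controls only is possible
by fitting `PGSScorer` on a control subset and transforming the cohort.

## Quality control

Filters run in a fixed order so every removed variant has exactly one
primary reason: sample call rate (default ≥ 0.97), variant call rate
(≥ 0.97, on retained samples), minor-allele-frequency window
(0.01 ≤ MAF ≤ 0.49), Hardy-Weinberg equilibrium (exact p ≥ 0.05), and
greedy LD pruning (dosage r² ≤ 0.8). The full sequence is iterated to a
fixed point: dropping variants can push a sample's call rate on the
surviving panel below threshold, and a second pass catches this, making
QC idempotent (re-running it on its own output removes nothing).

* **HWE** uses the exact conditional test: all heterozygote counts
  compatible with the observed allele counts are enumerated and the
  probabilities no larger than the observed table's are summed. Weights
  are computed in exact integer arithmetic, so ties are decided exactly
  and the test is strictly symmetric under swapping homozygote classes.
  The standard (non-mid) p-value is reported. When a phenotype table is
  available the test runs on fracture-contrast controls only, because
  case ascertainment distorts genotype frequencies at associated loci;
  this is configurable.
* **LD** is measured as squared Pearson correlation of dosages over
  pairwise-complete samples — the phase-free composite surrogate for
  haplotype r², adequate for pruning decisions. Pruning walks each
  chromosome in map order; within a conflicting pair the higher call
  rate wins, then higher MAF, then earlier map position.
* **Cochran's Q / I²** (inverse-variance, log-OR scale, chi-square with
  k−1 df, I² = max(0,(Q−df)/Q)·100) are provided for weight-table
  curation with the conventional p < 0.1 screening level; they are not
  part of the default filtering path because published panels rarely
  document how heterogeneity screening fed the final locus list.

## Population structure

Dosages are standardized per variant to unit binomial variance
(subtract 2p̂, divide by √(2p̂(1−p̂))); missing entries are mean-imputed to
zero; the top eigenvectors of the sample covariance are extracted by SVD.
A deterministic sign convention (largest-magnitude loading positive)
makes scores reproducible across BLAS builds. Whether self-reported
ethnicity clusters in the PC1/PC2 plane is tested by permutation: the
statistic is the between-group sum of squares of group centroids, labels
are shuffled `n_perm = 999` times (seeded), and
p = (1 + #{perm ≥ obs})/(n_perm + 1). A non-significant p supports
analysing the cohort as a single population.

## Evaluation

Each contrast is evaluated on the z-scores of its cases and controls:

* **AUC** as the Mann-Whitney concordance (ties counted ½), with a
  DeLong placement-value variance and normal 95% CI (clipped to [0,1]);
  a seeded stratified bootstrap CI (2,000 resamples) is available.
* **Operating point** maximizing Youden's J = sensitivity +
  specificity − 1, ties broken toward higher sensitivity. The selection
  rule is a package choice; published sensitivity/specificity pairs
  rarely state theirs.
* **OR per SD** from univariable maximum-likelihood logistic regression
  of case status on the z-score (Wald CI and p). Under complete
  separation a Firth-penalized fit is reported with a warning. A second,
  group-based OR (top vs bottom decile, Haldane-Anscombe corrected,
  Woolf CI, chi-square p) is always emitted because published ORs are
  often of either construction.
* **Decile table**: samples ranked by score (sample-ID tie-break for a
  stable order), cut into 10 contiguous groups, remainders to the lower
  deciles; per-decile case fraction plus a Cochran-Armitage trend test
  (scores 1..10, two-sided normal p).
* **Group summaries** (medians, means, per-group score vectors) support
  density plots.

Contrasts are compared by AUC; the ranking flags overlapping CIs and no
superiority claim is attached where they overlap. The three contrasts are
reported without multiplicity adjustment, matching how such model
batteries are usually presented.

## Synthetic cohorts

The generator emulates a small postmenopausal panel study:

* **Panel**: `n_snps` = 150 biallelic SNPs, MAF uniform on [0.01, 0.49],
  effect allele minor or major with equal probability; `n_causal` = 140
  variants carry ORs drawn log-uniformly from [1.05, 1.5] (conventional
  for BMD-associated variants; config-exposed, not asserted), the rest
  OR = 1.
* **Genotypes**: Binomial(2, p) under HWE; with `fst > 0`, two equal
  subpopulations draw allele frequencies from the Balding-Nichols Beta
  around the ancestral frequency.
* **Engineered QC violations**: HWE violators are redrawn with
  heterozygote depletion (inbreeding-like distortion F = 0.5), sampled
  from loci with frequency in [0.1, 0.9] where the distortion is
  well-powered at n ≈ 700 (at MAF 0.01 the exact test cannot reliably
  detect F = 0.5). LD duplicates copy another variant's dosages with 1%
  of entries resampled and 2% of calls dropped — a redundant,
  lower-quality assay — so the pruner's call-rate preference removes the
  duplicate, not its clean source, and truth-recovery is well defined.
  Only non-causal loci are tampered with, keeping the phenotype model
  intact. Of the 10 default casualties the HWE/LD split (5/5) is a
  package choice.
* **Phenotypes**: liability-threshold model. The genetic value
  g = Σ β_i·dosage_i (β = ln OR) is standardized; each trait's liability
  is √h²·g + √(1−h²)·e with environmental deviates correlated so the
  total cross-trait liability correlation approaches 0.6. Defaults
  h² = 0.25 (fracture) and 0.35 (BMD) reflect that a small curated panel
  explains a modest fraction of liability and that BMD is the more
  heritable, better-predicted trait. Fracture cases are the top 294/701
  of fracture liability; BMD is measured in a random 496/701 subset with
  324/496 below threshold; T-scores are an affine map of BMD liability
  pinned so T = −1 sits at the case threshold, and WHO classes follow
  (> −1 normal; [−2.5, −1] osteopenia, both boundaries included;
  < −2.5 osteoporosis). Comorbid cases are, by construction, the
  intersection of fracture cases and low-BMD cases.
* **Missingness** is injected MCAR last, on top of the engineered
  violations; default 0 in the library, 0.01 in the acceptance script
  (at 2% a 97% call-rate filter would remove ~30% of individuals,
  inconsistent with a cohort that passed such a filter; at 1% it removes
  a handful).
* Everything is driven by one `numpy` Generator seeded from `SimConfig`;
  identical seeds give bit-identical cohorts.

The generator retains the generative truth (causal effects, genetic
values, latent liabilities, violation labels), so tests can compare
pipeline outputs against oracles computed directly on the latent model.

### What passing tests do and do not show

The simulated cohorts have independent loci (no realistic LD maps), MCAR
missingness, no covariate effects (age/BMI are decorative), no
genotyping batch effects, and exactly correct external weights. Passing
the validation battery therefore demonstrates that the *machinery* is
correct and calibrated — the scoring formula, the exact HWE test, the
AUC/CI/OR estimators, the QC truth recovery — not that any particular
real-world discriminative performance will be achieved, which depends on
how well published weights transfer to the target population.

## Numerical choices

* HWE: exact integer weights; ties included via exact `≤` comparison.
* Logistic ML: statsmodels Newton fit; fallback to Firth (penalized
  score with hat-matrix correction, tolerance 1e-10) on separation or
  non-convergence.
* DeLong variance ≤ 0 (degenerate placements): warning and the widest
  informative interval [0, 1].
* PCA: mean imputation before, column re-centering after, so imputation
  cannot shift the origin; eigenvalues from squared singular values over
  n−1.
* Decile remainders to lower deciles; all tie-breaks documented above.
* Problem sizes in the validation battery (e.g. 20,000-sample oracle
  cohorts, 200-replicate calibration loops, 20-seed QC truth recovery)
  were chosen so each check has the statistical resolution its tolerance
  needs while the whole suite stays comfortably interactive.

## Known limitations

* No clumping/thresholding or shrinkage re-weighting: weights are taken
  as given (fixed externally derived panel).
* Covariate-adjusted evaluation (age, BMI) is out of scope; the models
  are score-only.
* Multi-allelic VCF records are skipped with a warning; binary PLINK,
  BGEN and imputation dosages are unsupported.
* Strand is assumed consistent between weight table and genotypes; A/T
  and C/G sites are joined by allele match with a warning, so an
  unflagged strand flip at a palindromic site would silently flip the
  dosage.
* The permutation stratification test addresses the top-2 PC plane only.
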