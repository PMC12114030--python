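# Methods

## Setting and model

The package analyses the metabolic consequences of complete gene
knockouts in a biobank-style cohort: for each candidate pLoF variant, the
homozygous carriers (knockouts, typically 2–12 individuals) are compared
with a fixed panel of carrier-free controls (hundreds) across a matrix of
untargeted LC–MS metabolite peak areas.  Three statistical components
carry the analysis: an exact rank test that remains valid at extreme
group imbalance and extreme significance thresholds, a
below-the-limit-of-detection (LOD) missingness test, and a stratified
exact test for diagnosis co-occurrence from EHR events.

## Exact one-sided Wilcoxon rank-sum tail

For carrier values x₁..x_{n₁} and control values y₁..y_{n₂}, the test
statistic is the carrier rank sum T in the pooled sample.  Under the null
every size-n₁ subset of the pooled ranks is equally likely, so the null
pmf of T is obtained by a subset-counting dynamic programme: f(j, t) =
number of size-j subsets of the scores with total t, filled in O(n₁ ·
range(T)) per score.  Ties are handled with midranks; midranks are
half-integers, so the DP runs on doubled midranks (always integers) and
is exact *conditionally on the observed tie pattern*.  Counts are
accumulated in float64 — exact up to 2⁵³ and accurate to machine relative
precision beyond, far finer than any reported tail.

The reported p is the one-sided tail in the direction of the observed
shift (the side on which T falls relative to its null mean), and that
direction is reported with the record.  A fixed direction and a two-sided
(doubled) variant are available.  Two consequences are worth stating
plainly:

- The smallest attainable p for group sizes (n₁, n₂) is 1/C(n₁+n₂, n₁),
  attained iff the groups separate completely.  `minimal_p` computes this
  in exact rational arithmetic and the scan uses it to mark group sizes
  that cannot reach the study-wise threshold (e.g. a single knockout
  against 258 controls has minimal p = 1/259, hopeless at 9 × 10⁻⁷).
- Direction-adaptive testing doubles the null tail: P(p ≤ t) ≈ 2t for a
  null pair.  The study-wise threshold α/(M_eff · n_variants) therefore
  controls the family-wise error near 2α, not α.  This is a property of
  the published construction, reproduced deliberately; the end-to-end
  recovery tests quantify it (a run flags exactly the injected effects
  with probability ≈ exp(−2α · n_met/M_eff) ≈ 0.90, not > 0.95).

The asymptotic normal approximation is never used: with 3–10 carriers the
exact tail at 10⁻⁷–10⁻¹⁸ differs from the normal tail by orders of
magnitude.

## Effective number of tests

Metabolites are correlated, so Bonferroni over the raw metabolite count
is needlessly harsh.  M_eff is the smallest number of principal
components of the residual matrix explaining ≥ 90% of total variance
(SVD after column-mean centering; missing entries zero-filled, which is
the column mean after z-scoring and is used for this computation only).
The threshold is α/(M_eff · n_variants), kept unrounded internally;
reports may round to one significant digit.

## Metabolite preprocessing

Peak areas are strictly positive where detected; missingness encodes
below-LOD censoring and is never imputed.  Metabolites missing in
strictly more than 95% of samples are removed.  Remaining values are
natural-log transformed (the base only rescales residuals, which
z-scoring absorbs).  Adjustment is two-stage:

1. Stage 1 regresses each log metabolite on the always-observed base
   covariates — intercept, age, sex indicator, genotype PCs 1–10 — by OLS
   over the samples where the metabolite is present.
2. Candidate covariates (BMI, smoking, education, sampling season) are
   tested *marginally* on the stage-1 residuals, each on the samples
   where it is observed: simple linear regression for BMI, one-way ANOVA
   for categoricals; selected at p < 0.05.
3. Stage 2 refits each metabolite from the log values on base + its
   selected candidates jointly (categoricals one-hot, first level
   reference), restricted to samples with the metabolite and all its
   selected covariates observed.  Selecting per metabolite preserves
   samples: a metabolite with no BMI effect keeps the samples whose BMI
   is missing.

Final residuals are z-scored per metabolite (mean 0, SD 1, sample SD with
ddof = 1), which makes them commensurate with the N(0,1)/N(β,1) power
model.  Rank-deficient designs drop the offending column with a warning;
a metabolite with fewer usable samples than regressors + 2 is skipped.

## Below-LOD missingness test

Per (variant, metabolite) pair the 2×2 table (missing/detected) ×
(KO/other) is tested one-sided toward higher knockout missingness with
Fisher's exact test (scipy's hypergeometric tail).  The dedicated
missingness scan also covers pairs the rank test cannot touch — a
metabolite entirely absent in the knockouts yields an empty group for the
rank test but the strongest possible missingness signal.

## Power simulation

Controls are drawn N(0,1) and knockouts N(β,1); each (β, n_KO) cell
counts the fraction of 10,000 trials with one-sided exact p (direction +,
known by construction) below the study-wise threshold.  Continuous draws
are tie-free, so the exact null distribution of T depends only on the two
group sizes; it is computed once per cell and each trial reduces to a
rank-sum lookup, which is what makes 100 cells × 10,000 trials run in
seconds.  Cells whose minimal attainable p already exceeds the threshold
are reported as power 0 without simulation.  Defaults: β ∈ {0.5, 1, …, 5},
n_KO ∈ 1..10, 258 controls.  Note the boundary cell β = 3, n_KO = 5 has
true power ≈ 0.7995 at threshold 9 × 10⁻⁷ — "80% power" holds exactly at
Monte-Carlo precision of a 10,000-trial estimate (SE ≈ 0.004).

## EHR disease association

A sample is a case for an ICD-10 three-character category when ≥ 2
recorded events fall in the category (codes uppercased, dot stripped,
truncated to 3 characters before counting — recurrence is evaluated at
the category level; the stricter same-full-code rule is available behind
a flag).  Categories with < 5 cases and variants with < 2 knockouts are
excluded; the Bonferroni threshold uses the surviving counts.

Knockouts and controls are stratified by sex × age group (10-year bins
from age 18; width configurable).  Conditional on all margins of the
per-stratum 2×2 tables, the null distribution of T = Σ per-stratum
knockout-case counts is the convolution of central hypergeometric pmfs
(computed in log space; support is tiny because knockout counts are).
The two-sided p sums the probabilities of all outcomes no more probable
than the observed T (probability-mass rule, with a 1 + 10⁻⁷ relative
guard against ties in floating point) — the convention under which a
single stratum reduces exactly to Fisher's two-sided test.  Strata with
an empty margin carry no conditional information and are dropped; adding
one never changes p or ψ.

The common odds ratio ψ is estimated by conditional maximum likelihood
over the product of noncentral hypergeometric likelihoods: E_ψ[T] is
strictly increasing in ψ, so ψ̂ is the unique root of E_ψ[T] = T_obs,
found by bracketed Brent search on log ψ (xtol 10⁻⁸).  When T_obs sits on
the attainable boundary the estimate is 0 or ∞ with a boundary flag.

## Synthetic cohort generator

The generator emulates the *structure* of a biobank knockout survey, not
any real population: phenotypes (age uniform 18–90; sex Bernoulli 0.5; 10 genotype
PCs as independent standard normals — they enter only as nuisance
covariates; BMI normal 26.5 ± 4.5; smoking/education/season categorical),
per-variant carrier sets drawn without replacement, controls drawn from
carrier-free samples, and log-normal metabolites: log X = baseline +
covariate effects + β·1[knockout] + N(0,1), so β is the location shift in
units of the residual SD.  Left-censoring sets values below the
per-metabolite `lod_quantile` missing, giving a per-metabolite missing
fraction equal to the quantile.  Covariate missingness is applied after
metabolite generation (observational, not structural).  EHR case flags
are drawn per stratum with constant baseline odds and knockout odds
multiplied by the configured common odds ratio, so the conditional OR
equals the configured value by construction; cases receive two events in
the category and half-rate single events exercise the at-least-twice
rule.  Every injected effect is stored in a truth record, which is the
acceptance surface for stages with no printed numbers.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: linkage disequilibrium and relatedness,
genotype-PC population structure, batch effects and platform drift,
metabolite–metabolite correlation beyond shared covariates, informative
(non-quantile) censoring, and longitudinal EHR structure.

## Problem sizes and numerical choices

Tests and the acceptance checks run the generator at 450–981 samples with
25–300 metabolites, 10,000-trial power cells, 200 replicates for the
common-OR recovery (cohorts of 5,000), and 20 seeds for end-to-end
recovery — sizes chosen so each check's Monte-Carlo error is small
against the quantity it asserts.  Exhaustive-enumeration oracles cover
all group splits up to n = 12; the DP is additionally cross-checked
against scipy's exact Mann–Whitney on untied data and the stratified test
against Fisher's exact on single strata.  Determinism: every stochastic
component takes a single integer seed (numpy default_rng); fixed seed
means byte-identical fixtures and identical power grids.

## Known limitations

- The scan treats variants marginally; a gene with several variants
  yields several rows, and compound heterozygotes are only reported as
  candidates (phase unknown), never promoted to knockouts.
- The conditional exact test is two-sided by the probability-mass rule;
  sidedness conventions differ across software and a one-sided option is
  exposed.
- No effect-size estimation for the metabolite scan (the exact p and the
  3-SD outlier count are the reported evidence), and no confidence
  interval for ψ.
- With quantile censoring, a strong *negative* knockout effect removes
  the knockouts from the rank test entirely; the missingness channel is
  the intended detector in that regime.
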