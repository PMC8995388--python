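# Methods notes

## Synthetic cohort generator

The generator (`twinprs.simulate`) produces every input the pipeline
consumes. It is deliberately minimal: each component reproduces the one
statistical feature downstream code depends on, and nothing else.

**Genotypes.** One synthetic chromosome, evenly spaced 1-based positions
(default 20 kb apart, so a 50-variant block spans the 1 Mb clumping
window), block-diagonal LD. Haplotypes follow a copy-with-refresh Markov
chain: within a block every variant shares the block's MAF and each allele
copies its left neighbour with probability `block_ld`, otherwise draws
fresh from Bernoulli(MAF). Consequently the expected adjacent-pair dosage
correlation *equals* `block_ld`, and correlation decays geometrically with
distance — a caricature of real LD (no allele-frequency heterogeneity
within blocks, no long-range structure, a single population), but exact
and easy to reason about. Designated fractions of variants are flagged
strand-ambiguous (A/T, C/G), indel, or low-INFO to exercise QC.

**Twins.** MZ co-twins get identical genotypes. DZ co-twins draw one of
two haplotypes from each of two simulated parents, independently per twin;
without recombination this yields the textbook expected within-pair dosage
correlation of 0.5 (as a mixture over pairs sharing 0, 1 or 2 haplotypes,
not per-pair). Pairs share birth year; MZ pairs share sex.

**Discovery summary statistics.** Effect estimates are drawn around the
true per-variant liability effects with the standard logistic-GWAS
standard-error approximation `se = 1/sqrt(2p(1−p)·Nφ(1−φ))` (φ = case
fraction), defaults 19,099 cases / 34,194 controls. A configurable
`null_fraction` of variants carries exactly zero true effect; nonzero
effects are N(0, 0.03²), which at these defaults gives a realistically
mixed-power discovery scan (mean χ² ≈ 5 for causal variants).

**Phenotypes.** Binary mediators (education, tobacco, alcohol) follow
logistic models in the standardized true score with intercepts solved
numerically for their target prevalences. BMI is built from a
unit-variance Gaussian latent (slope `beta1` on the score, so `beta1` is
exactly the generative slope on the standardized model scale) and mapped
to kg/m²; the modelling column is the re-standardized value. Each outcome
follows a logistic model in score, mediators and covariates; the intercept
is solved by bracketed root-finding so the *latent* lifetime prevalence
hits its target (defaults taken from the combined prevalences of the
cohort this design emulates, e.g. hypertension 25.6%). Register and
self-report flags are drawn from the latent status with per-outcome
sensitivity/specificity, conditionally independent given the status; the
combined flag is their OR. Dementia and sleep disorder have no self-report
instrument (sensitivity 0). The sensitivity/specificity defaults are free
parameters, not estimates of any real register's operating
characteristics — with imperfect ascertainment the *observed* combined
prevalence deviates from the latent target, which is intended.

What passing tests on this generator do **not** show: robustness to real
LD maps, population structure beyond the two-cluster fixture,
ascertainment that depends on covariates or on the score, informative
follow-up, or mediator–outcome confounding. Those are assumptions of the
method, not properties the synthetic world can violate.

## Score engine

Harmonization excludes, in order: variants absent from the target panel,
indels/multi-allelic records, strand-ambiguous SNPs, INFO < 0.8 (boundary
kept), allele-set mismatches; when the summary-statistics effect allele is
the target REF the weight is negated. Re-orienting weights to the
risk-increasing allele changes every score by an additive constant only
(2·Σβ per flipped variant), which standardization removes — the package
therefore never takes absolute values of weights, which would destroy the
weighting.

Clumping is greedy on p-value (ties broken by position then id, for
determinism), claiming neighbours within the window with r² above the
threshold; r² is squared Pearson correlation of dosages in whatever panel
is supplied as LD reference. Thresholding happens after a single clumping
pass on all harmonized variants.

The PC-PRS is the first right-singular-vector combination of the
column-standardized threshold scores, re-standardized, with sign fixed by
positive correlation with the most inclusive (P_T ≤ 1) column — the sign
of a principal component is otherwise arbitrary and would flip odds-ratio
directions. Zero-SNP and zero-variance columns are dropped with a warning;
fewer than two usable columns is an error. The dominance property (PC-PRS
correlates with the true score at least as well as the best single
threshold, −0.01 tolerance) emerges reliably at ≳1,500 variants and ≳1,500
individuals; at very small panel sizes sparse strict-threshold columns are
noisy enough to drag the first component below an oracle-selected single
column, which is visible in the test suite's choice of simulation sizes.

Ancestry PCs: greedy LD pruning (r² ≤ 0.2, 1 Mb), moments and loadings
from one twin per family, all individuals projected. Requesting more
components than the unrelated set's numerical rank is an error.

## Association layer

GEE with logit link, independence working correlation (exchangeable
available), sandwich covariance clustered on twin pair; Wald tests and
exp-transformed CIs. With singleton clusters the sandwich reduces to HC0,
which the tests check to 1e-6. Perfect or quasi-separation (non-finite
estimates, or any non-intercept |coefficient| > 30) raises a named error;
scan rows whose fit fails are emitted flagged and excluded from their FDR
family. Wald p-values are clipped to the smallest positive float.

Nagelkerke ΔR² is computed from ordinary (independence) logistic
likelihoods — GEE has no likelihood — as the difference of rescaled
Cox–Snell R² between the model with and without the score term, reported
in percent. BH-FDR is applied within each (source, stratum) family for the
association scan, across the whole 64-test family for moderation, and
across indirect-effect tests for mediation. Sex-stratified models drop the
sex covariate; the cross-stratum comparison is a z-test on the two
log-ORs.

## Mediation layer

Outcome model Y ~ A + M + C (logistic), mediator model M ~ A + C
(logistic or linear), no exposure–mediator product term — the total effect
then factorizes exactly as TE = NDE × PNIE on the odds-ratio scale, an
identity the tests check to 1e-12 and the structure of the code would
admit extending with an interaction term later. The exposure contrast is
one SD of the standardized score (0 → 1). Covariate reference values for
the binary-mediator formula are full-data covariate means, held fixed
across bootstrap replicates.

The closed forms are rare-outcome approximations (OR ≈ RR). The
Monte-Carlo counterfactual-standardization path (`rare_outcome=False`)
draws the mediator under each exposure level — independent draws per arm,
so the delta-method SEs are exact — and forms standardized odds-ratio
contrasts. Agreement between the two routes within 3 Monte-Carlo SEs at
10⁶ draws holds across the coefficient ranges this design targets
(exposure ORs ≤ ~1.2, mediator ORs ≤ ~1.4) at prevalences up to ~3%; at
5% prevalence with mediator log-ORs ≥ 0.4 the non-collapsibility gap
exceeds the Monte-Carlo noise, which is the approximation's known failure
mode, not an implementation defect.

Bootstrap: twin pairs resampled with replacement (preserving the cluster
structure the GEE acknowledges), both models refit per replicate with the
full-data estimates as starting values, percentile CIs; replicates that
fail to converge are dropped and counted, with a warning above 5%.
Point estimates always come from the full-data fit. The indirect-effect
p-value feeding the FDR step is a normal approximation
|log PNIE|/bootstrap-SE. Percentile intervals at n ≈ 1,200 with ~10%
outcome prevalence show mild undercoverage (~93–95% empirical for a
nominal 95%), typical for the percentile method at this sample size; at
the 40,000-individual scale of the recovery studies coverage is nominal.

Proportion mediated is log(PNIE)/log(TE), returned untruncated with a flag
outside [0, 1] (inconsistent mediation — opposite-sign direct and indirect
paths make the ratio uninterpretable as a proportion). A total-effect OR
of exactly 1 makes it undefined (error). Classification: *full* if the
PNIE CI excludes 1 and the NDE CI includes it, *partial* if both exclude
1, *none* otherwise. BMI is not tested as a mediator of obesity — the
mediator and outcome would measure the same construct.

## Scan grids and problem sizes

The association scan covers 16 outcomes × {combined, register,
self-report} × {all, male, female}; moderation covers 16 × 4 product
terms; mediation 4 × 16 − 1 = 63 pairs. The simulation studies in the
tests and the acceptance script use: 20,000 pairs with a 500-replicate
bootstrap for effect recovery; 600 pairs × 500 replicates × 100 worlds for
coverage; 300 pairs × 200 worlds for type-I error; 1,500 variants × 800
pairs for score-dominance — sizes chosen so each study's Monte-Carlo error
is small relative to the quantity it measures while a full run stays in
the minutes range on one CPU.

## Determinism

One global seed drives everything. The generator derives fixed per-stage
substreams (so a stage rerun in isolation reproduces its output), and each
(mediator, outcome) bootstrap derives its stream from a CRC of the pair
name (so scan results do not depend on scan order). Identical configs
produce byte-identical output files, checked by checksum in the tests.
Reported percentages use decimal half-up rounding to one decimal, matching
standard prevalence-table presentation.
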