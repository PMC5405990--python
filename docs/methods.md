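# Methods

## Phenotype and cohort model

The trait is modelled as plasma FXI coagulant activity in percent of
normal, generated as

    y_i = mu + beta_age * age_i + beta_sex * sex_i + sum_j beta_j g_ij + eps_i,
    eps_i ~ Normal(0, sigma^2),

with age ~ Uniform(18, 80) years, sex ~ Bernoulli(0.5) (coded 0 = female,
1 = male), and additive per-allele effects beta_j in percent activity.
The study-shaped defaults are mu = 95%, beta_age = 0.2 %/year,
beta_sex = −5%, sigma = 28%: together with the genetic variance these put
roughly 95% of a random cohort inside the 55–185% clinical reference
range, which is the only phenotype anchor the source design states. One
strong common causal variant per locus (+19.1 and +11.5 % per allele,
echoing the magnitude of published common-variant effects on FXI) and a
physically adjacent cluster of three rare causal variants (target MAF
0.015–0.05, +45% per allele — the size of effect a splice-disrupting
coagulation-factor variant can plausibly have) are planted so both
analysis arms have something to find.

Cohort assembly follows the tail-sampling design: the generator simulates
a pool of unrelated individuals (default 935, the size of the project the
study sampled from), selects 20 subjects with phenotype in 36–80% and 20
in 158–250% as the discovery subsample, and completes the cohort to
n = 110 with a uniform draw from the remainder. A random n = 110 Gaussian
cohort would frequently not contain 20 subjects per tail; sampling from a
pool is both feasible and faithful to how such cohorts are actually
constructed. A consequence worth knowing: the assembled cohort is
tail-enriched, so its phenotype distribution is wider than the generative
Gaussian and Shapiro–Wilk can reject normality for it — as it nearly did
for the real cohort.

## Genotype generator

Haplotypes come from a latent Gaussian copula: within each LD block a
latent AR(1) chain z_j = r_j z_{j−1} + sqrt(1 − r_j²) e_j is thresholded
at the Normal quantile of each variant's target MAF; two independent
haplotypes per individual are summed to dosages, so sites are in
Hardy–Weinberg proportions and realized MAFs converge to their targets.
Because thresholding attenuates correlation, the block parameter rho is
interpreted on the genotype scale: the latent coefficient r_j is obtained
per adjacent pair by inverting the tetrachoric relationship (bivariate
normal orthant probability via 64-node Gauss–Legendre quadrature plus
Brent root-finding, cached), clipped to the maximum achievable when the
two MAFs make the requested correlation infeasible. rho = 0.9 therefore
yields adjacent genotype r² ≈ 0.8 rather than ≈ 0.45.

The study-shaped default places 504 and 258 variants uniformly at random
(positions without replacement, sorted) across the two printed GRCh37
locus spans, draws ~41% of target MAFs from Uniform(0.10, 0.50) and the
rest log-uniformly from 0.004–0.095, and partitions variants into
12-variant blocks with alternating correlation (0.9, 0.5, 0.8, 0.2, 0.7).
Synthetic annotations (43% dbSNP-style ids; panel frequencies as the
target MAF perturbed log-normally; mostly intronic feature locations with
a near-exon minority) exist so the downstream screen is exercised in both
directions; they are labelled synthetic and are not a model of any real
annotation database.

What the generator does **not** emulate: sequencing and genotyping error,
missingness informative of genotype, indel alleles in the dosage matrix,
pedigree or population structure (individuals are unrelated by
construction), recombination-map-shaped LD decay, and selection-induced
covariate imbalance. Passing tests therefore demonstrate correctness of
the statistical machinery under a clean additive model, not robustness to
real-data artefacts.

All randomness flows from one integer seed through named
`SeedSequence(seed, spawn_key)` substreams (genotypes, positions,
alleles, covariates, noise, tails), so any stage can be reproduced in
isolation.

## Variant bookkeeping

Coordinates are 1-based inclusive throughout (VCF agrees natively). MAF
is computed from non-missing allele counts; missing genotypes are
excluded, not imputed. Common means sample MAF ≥ 0.10 (boundary
inclusive). Summary percentages are rounded half-up to one decimal, the
convention of the printed tables. VCF input goes through cyvcf2;
multiallelic records are counted and skipped. The VCF writer is a minimal
in-package text serialiser (round-trip identity on dosages, positions and
missingness is tested).

## LD pruning and clumping

VIF pruning slides a 30-variant window, advancing 3 variants per step;
within a window each retained variant's VIF = 1/(1 − R²) comes from least
squares of its (mean-imputed, centred) dosages on the other retained
window members, and the max-VIF variant is removed until max VIF ≤ 2.
Ties break toward removing the lower-MAF, then the later-positioned
variant — keeping the more informative site; monomorphic columns get
VIF 1 and are never removed by this criterion. Sweeps repeat until a full
pass removes nothing. The fixed point makes pruning idempotent and
guarantees that auditing any window of the output finds max VIF ≤ 2 +
1e−8, properties a single sweep cannot promise because removals shift
later variants into already-processed windows. The final partial window
is processed like any other.

Clumping greedily takes the unassigned variant with smallest
p ≤ index threshold (default 1e−4) as an index and absorbs unassigned
variants with p ≤ 0.05, r² ≥ 0.5 to the index, within 250 kb. Nominally
significant variants that are never absorbed and never index-eligible
remain as singleton signals, so the clump list partitions all nominally
significant variants and its length is the number of independent signals.

## Single-variant association and multiple testing

Per variant: complete-case OLS on [1, dosage, age, sex]; the reported
beta is per copy of the sample minor allele (dosages are flipped when the
ALT allele is the major one, making results invariant to allele
labelling; a raw-orientation mode is available, under which recoding
d → 2 − d flips the sign of beta and leaves p unchanged). The six
corrections delegate to statsmodels' `multipletests`; an explicit test
count m (for adjusting a subset of a larger panel) is supported for the
single-step closed forms. The Shapiro–Wilk check wraps scipy and enforces
its 3 ≤ n ≤ 5000 validity range.

## Kernel set test

Windows are anchored at each successive low-frequency variant and span
[anchor, anchor + 2000] bp, both edges inclusive; windows never cross
chromosomes, and the right-edge inclusivity is a documented choice. With
null-model residuals r (OLS on intercept + covariates; sigma^2 = r'r /
(n − p)) and Z = G W, W = diag(Beta(1, 25) weights on sample MAF; flat
weights available):

    Q = || Z' r ||^2,   Q ~ sum_k lambda_k chi^2_1 under H0,
    lambda_k = sigma^2 * eig(Z' P0 Z).

Missing dosages are mean-imputed inside a set. Eigenvalues below 1e−10
(relative) are dropped; a set with no surviving eigenvalue (all members
monomorphic) gets the defined no-test result p = 1 and a `tested=False`
flag. Tail probabilities: Imhof's inversion integral, evaluated after
rescaling lambdas and Q by max(lambda) so the integrand oscillates on an
O(1) scale, with adaptive quadrature (limit 2000, epsabs 1e−9); if the
quadrature fails, returns a non-probability, or underflows, the Liu
moment-matching approximation is used instead and the result records
which method produced it.

## Permutation FWER and regions

B permutations (default 1,000) shuffle the raw phenotype across
individuals; covariates stay attached to individuals and the null model
is refit per permutation, which preserves the LD structure among variants
exactly. Every window's analytic p is recomputed per permutation and the
genome-wide minimum across all windows (both loci jointly) is recorded;
empirical_p(s) = (1 + #{b: min_b ≤ p_s}) / (B + 1), so it is never zero
and never below 1/(B+1). A Freedman–Lane variant (permute residuals, add
back fitted values) is available behind a flag. Inside the permutation
loop all p-values — observed and permuted alike — use the Liu
approximation: the Liu standardisation is scale-free, so the per-
permutation sigma^2 enters analytically and the whole B × sets grid
reduces to matrix products plus one vectorised chi-square tail call per
set; using one consistent method also makes the min-p comparison an
ordering of like with like (the empirical p is then monotone in the
analytic p by construction). Standalone single-set tests default to the
Imhof evaluation.

Merging selects windows either by analytic p < alpha (nominal tier) or by
the permutation flag (FWER tier) and unions overlapping intervals per
chromosome into maximal disjoint regions; the sweep is idempotent and
order-independent. BED exports convert to 0-based half-open coordinates.

## Mutation screen

Three rules, all evaluated for every variant so the audit trail is
complete: (a) rarity — every supplied reference-panel AF < 1%, absence
from a panel counting as rare there (this is what lets unannotated
variants pass, matching the published candidate set); (b) location —
intronic variants more than 30 bp from the nearest exon boundary are
rejected; (c) fallback — a variant absent from the primary panel needs
sample MAF < 5%, and lacking that MAF is an error rather than a silent
pass. Splice-score percent change is 100·(mutated − native)/native,
undefined for native = 0; the consensus count uses unrounded deltas with
a strict |delta| > 10% threshold and flags a variant when at least two
algorithms exceed it. Printed one-decimal deltas are reporting artefacts
(one published value differs by 0.1 from the recomputed quantity), so
reporting rounds half-up to one decimal while keeping the exact value.

## Calibration experiment sizes

The FWER calibration (also what `scripts/acceptance.py` reruns) uses 100
null cohorts of n = 110 with ~60 low-frequency variants on a 12-kb locus
in AR(1) blocks (rho 0.8), B = 500 permutations at alpha = 0.05 —
replicate counts chosen to give a two-standard-error band of about ±0.044
around the nominal level while the whole experiment stays in the
tens-of-seconds range. The test suite's power checks (a planted 2-SD rare
effect detected in ≥ 50% of replicates) use 25 replicates at B = 200 for
the same reason.

## Known limitations

* The kernel test's mixture null is asymptotic; no small-sample moment
  adjustment is implemented (n = 110 with permutation calibration makes
  this acceptable here, and the permutation arm is the one used for
  inference).
* Burden and SKAT-O style combinations, binary-trait kernels, dominance
  codings and interaction terms are out of scope.
* The pruner's mean-imputation of missing dosages inside a window is a
  documented simplification (complete-case within-window regression is
  available through the same code path only by pre-filtering).
* Clumping uses genotype r² on the sample, not reference-panel LD.
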