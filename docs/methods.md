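# Methods

`prsconv` re-implements, as a tested and reusable pipeline, an analysis
chain that runs from discovery GWAS summary statistics and target-cohort
genotypes to (i) a clumping-and-thresholding polygenic risk score (PRS),
(ii) prediction of conversion from amnestic mild cognitive impairment
(aMCI) to Alzheimer's disease, (iii) a covariate-adjusted scan of the
score against regional brain structure, and (iv) a one-sample Mendelian
randomization (MR) of the chain *score → regional surface area →
conversion*.  Because the cohorts this design targets (clinical genotype +
neuroimaging datasets) are access-restricted, the package ships a
first-class synthetic-cohort generator whose statistical structure matches
the analysis's assumptions, so every downstream stage is testable.

## Synthetic cohort model

**Genotypes.**  Haplotypes are simulated blockwise by a first-order
allele-copying Markov chain.  All variants in an LD block share one allele
frequency `f ~ U(maf_range)`; the first allele of each haplotype is
Bernoulli(f) and each subsequent allele copies its left neighbour with
probability `ld_copy_prob = c`, else is drawn fresh.  Sharing `f` within a
block makes the chain preserve marginal frequencies exactly, and gives
haplotype-allele (and therefore dosage) correlation `c^d` at index
distance `d`, i.e. r² decays as `c^(2d)` inside a block and is zero across
blocks.  Variants sit on one synthetic chromosome at a fixed 10 kb
spacing, so the 250 kb clumping window spans 25 variants.  The default
`c = 0.8` puts adjacent pairs at r² ≈ 0.64, above the 0.5 clumping cutoff,
so clumping is genuinely exercised.

A deliberately simple model: no realistic human LD map, no admixture, no
X chromosome, no imputation uncertainty (panels are treated as
post-imputation).  Tests passing on this generator demonstrate the
*algorithms* behave correctly under LD, missingness and confounding — not
that effect sizes transfer to any real cohort.

**Discovery summary statistics.**  True effects are drawn N(0,1) at
`n_causal` random variants and rescaled analytically (accounting for
within-block LD) so the genetic score has liability variance `h2`.  A
discovery cohort of `n_discovery` samples (default 5,000) is simulated
with the same LD process; the continuous trait is the genetic score plus
N(0, 1−h2) noise, and each variant's reported effect is its *marginal*
least-squares slope with its standard error and two-sided p-value.
Marginal effects at non-causal variants therefore show real LD tagging
(`E[beta_neighbour] = c^d · beta_causal` for same-frequency variants),
which is what clumping must undo.

**Target cohort.**  The standardized true score `S` drives a designated
mediator region's surface area, `M = −gamma_med·S + covariate loadings +
N(0,1)`; all other region×measure columns (130 regions × surface area /
thickness / volume) are unit noise.  One-year conversion follows
`logit(P) = logit(base_rate) + beta_med_out·M + beta_direct·S + centered
covariate terms`, with covariates mimicking an elderly clinical cohort:
age ~ N(75.02, 7.20²), ~66% male, six sites, education ~ round(N(15.7, 3²))
and APOE ε4 count in {0,1,2} with probabilities (0.43, 0.44, 0.13).
Time-to-event is exponential with the per-sample rate chosen so that
`P(T ≤ 1 yr)` equals the logistic probability, censored at 10 years; the
1- and 10-year conversion labels are `T ≤ 1` and `T ≤ 10`.  The binary
outcome is generated on the logistic scale even though the MR stage
estimates a linear-probability model — the generative truth is kept
separate from the estimator's approximation on purpose.

**Defaults and why.**  `n_target = 304`, `n_variants = 10,000` in 200
blocks, `n_causal = 50`, `h2 = 0.3`, `gamma_med = 0.7`,
`beta_med_out = −1.0`, `beta_direct = 0.5`, `base_rate = 0.12`.  Two
defaults deserve comment.  (1) The marker count: the method-of-moments
IBD estimator (below) has null standard deviation ≈ 0.07 at 2,000 LD'd
markers, which would push unrelated pairs over the 0.1875 relatedness
cutoff; 10,000 markers bring the null sd to ≈ 0.026 so the filter
separates cleanly — the same reason production tools want tens of
thousands of pruned markers for IBD.  (2) `gamma_med`: the region scan
tests the *realized* PRS, whose correlation with the true score is ≈ 0.5
at these settings, so the mediator's PRS-level partial correlation is
attenuated to about half its true-score value; `gamma_med = 0.7`
(true-score r ≈ −0.57) yields a PRS-level r ≈ −0.3, detectable at n ≈ 300
under FDR over 390 tests.  Effect sizes are chosen for detectability at
this sample size, not calibrated to any published cohort.

QC violations (sex flips, duplicated genotype rows with a 0.5% mutation
rate, constructed first-degree relatives sharing one haplotype,
heterozygosity inflation, per-sample missingness above 3%) are injected
on request with ground-truth labels for testing.

## Quality control

Variant filters (clinical preset): call rate ≥ 0.95, MAF ≥ 0.01, exact
Hardy–Weinberg p ≥ 5×10⁻⁷, non-ambiguous strand (A/T and C/G pairs
dropped).  The biobank preset relaxes MAF to 0.001.  The HWE test is the
exact conditional test: conditioning on allele counts, it sums the
probabilities of all heterozygote counts no more probable than the
observed one (a chi-square variant is deliberately not the default —
the exact test is standard practice near the MAF boundary).

Sample filters, applied sequentially so each removal carries exactly one
reason: reported-vs-genetic sex mismatch; relatedness (PI_HAT > 0.1875);
heterozygosity outside mean ± 5 SD; call rate < 0.97.  PI_HAT is the
method-of-moments estimate: per-pair IBS0/1/2 counts and allele-frequency
expectations give P(IBD=0,1,2), clamped to [0,1] and renormalized, with
PI_HAT = P(IBD=2) + P(IBD=1)/2.  Of a related pair the lower-call-rate
member is removed (ties: the lexicographically larger id).  The sex check
compares a supplied genetic-sex field rather than X-heterozygosity since
no X chromosome is modelled — a documented limitation.  Population
structure covariates are the top principal components of the standardized
(mean-imputed) dosage matrix, with the sign convention that each
component's largest-magnitude loading is positive; samples beyond 6 SD on
any of the top four components can be flagged as ancestry outliers.

## PRS construction

Effects are sign-harmonized to the panel's counted allele (negated when
the allele pair is swapped; dropped and logged when allele sets disagree
or the pair is strand-ambiguous).  Clumping is greedy: variants in
ascending discovery-p order (ties: position) become index variants and
remove unprocessed variants within ±250 kb whose dosage r² (composite LD
on unphased dosages, computed in the target panel itself — no external
reference) exceeds 0.5.  The raw score is `Σ G_ij·β_j` over index
variants with `p_j ≤ p_T` ("sum of risk-allele counts times effects", not
an average; the downstream z-transform makes the distinction immaterial),
with missing dosages imputed as twice the counted-allele frequency.

The threshold grid is 0.001…1.000 in steps of 0.001 (1,000 scores).  At
each threshold the z-scored PRS enters a logistic model of conversion
with the standard covariates (sex, age, site, education, APOE ε4 count,
four PCs); the model's Nagelkerke R² minus the covariate-only model's is
recorded, and the best threshold maximizes it (ties toward the sparser
score).  The best score is z-transformed and samples outside mean ± 2 SD
are *flagged*, not deleted, so sensitivity analyses can toggle the trim.
Selection is corrected by permuting the outcome vector only and re-running
the entire sweep per permutation: corrected p = (1 + #{permuted best R² ≥
observed}) / (1 + n_perm).  Distinct variant-count sets are cached across
thresholds, which makes the ~10⁵–10⁶ logistic refits of a permutation run
affordable; the logistic fitter is an in-package IRLS (convergence when
the largest score component < 10⁻⁸, 100-iteration cap, separation
flagged) cross-checked against statsmodels in the tests.

## Conversion models and statistics

Nagelkerke R² is `[1 − exp((2/n)(ll₀ − ll₁))]/[1 − exp((2/n) ll₀)]`.  The
odds ratio is reported per SD of the z-scored PRS with a 95% Wald
interval.  AUC is the rank statistic `P(score_case > score_control) +
½P(tie)`.  The Cox model (lifelines backend) uses time-to-conversion with
censoring at last follow-up and reports the Breslow baseline cumulative
hazard and per-profile cumulative risk `1 − exp(−Λ₀(t)·e^{xβ})`;
simulated event times are continuous so tie-handling conventions do not
bite.  Risk groups are rank-based splits with remainders assigned upward,
reproducing 139/139 and 92/93/93 at n = 278; group differences use
Pearson's chi-square *without* continuity correction and group means the
pooled-variance t — the conventions that reproduce the published
cohort-table statistics to printed precision.

## Region scan and FDR

Each of the 390 region×measure columns is tested by partial Pearson
correlation: score and measure are residualized on [1 | covariates], and
p comes from `t = r·√((n−2−k)/(1−r²))` on n−2−k df.  Benjamini–Hochberg
correction is applied over the *joint* family of all 390 tests by default
(the conservative reading; a per-measure family is a config option).  A
replication-style second scan re-tests only the discovery-significant
set with a second score at unadjusted p < 0.05.

## One-sample MR (TSLS)

Stage 1 regresses the exposure (a regional measure, standardized to unit
SD so the estimate reads per-SD) on [1 | score | covariates]; stage 2
regresses the binary outcome — as a linear-probability outcome, the plain
TSLS convention — on [1 | fitted exposure | covariates].  Standard errors
are classical homoskedastic TSLS (stage-2 residuals recomputed with the
observed exposure); robust errors are an option, and a control-function
variant is deliberately out of scope.  Stage-1 F below 10 flags a weak
instrument.  With one instrument and no covariates the estimate equals
the Wald ratio `cov(Z,Y)/cov(Z,X)` exactly, and residualizing everything
on the covariates first leaves the estimate unchanged (Frisch–Waugh);
both identities are enforced in the tests at 10⁻¹⁰/10⁻⁸.

Note that in the full generative model the score also has a *direct*
effect on conversion (`beta_direct ≠ 0`), which violates the exclusion
restriction — so the pipeline's MR estimate on default synthetic data is
a sign-and-significance demonstration, not an unbiased effect estimate.
The dedicated recovery test uses an exclusion-valid confounded design and
verifies ~95% CI coverage over 500 replicates while naive OLS is
measurably biased.

## Numerical and scale choices

Threshold-sweep fits that fail or do not converge are skipped with a log
entry; monomorphic variants define r² = 0; zero-variance score columns
are excluded from selection; residuals at numerical-noise scale raise
rather than returning spurious correlations.  The acceptance script runs
the pipeline at the generator defaults (304 samples, 10,000 variants,
5,000 discovery samples, 1,000-point grid, 200 permutations) — sizes
chosen so a complete run takes a few minutes on one CPU; the test suite
uses smaller panels with the same structure.  Determinism: every stage
derives its randomness from the run seed via independent named streams,
manifests contain no timestamps, and identical configurations produce
byte-identical reports.

## Known limitations

Block-constant allele frequencies (a consequence of making the copy chain
preserve marginals exactly); no external LD reference for clumping; sex
checks require a genetic-sex column; PI_HAT needs several thousand
near-independent markers before the 0.1875 cutoff separates relatives
from noise; the linear-probability MR ignores the logistic data-generating
link (by design, matching the estimator it implements).
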