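# Methods

`metabomr` implements a metabolome-wide two-sample Mendelian randomisation
(MR) screen of the kind used to test plasma metabolites against psychiatric
and neurodegenerative disorder GWAS, together with its follow-up analyses:
multivariable Bayesian model averaging, regional colocalisation, eQTL-based
summary MR with the HEIDI heterogeneity test, and product-of-coefficients
mediation. Everything operates on GWAS summary statistics; no individual-level
data are required. This note records the models, the defaults and why, the
numerical choices, and what the synthetic benchmark does and does not show.

## Two-sample MR model

For variant j, let (b_Xj, s_Xj) be its estimated effect on the exposure
(a metabolite, in SD units) and (b_Yj, s_Yj) its effect on the outcome (a
disorder, on the log-odds scale, so exp(beta) is an odds ratio). Under the
instrumental-variable assumptions the per-variant Wald ratio
theta_j = b_Yj / b_Xj estimates the causal effect theta, with first-order
standard error s_Yj / |b_Xj| (exposure-side noise is ignored; with the F >= 10
instrument filter the neglected term is O(theta^2/F) and immaterial for the
effect sizes this screen targets).

### Primary estimator

IVW with multiplicative random effects: weighted regression of b_Y on b_X
through the origin with weights 1/s_Y^2. The SE is the fixed-effect SE scaled
by the residual standard deviation sqrt(Q/(k-1)), floored at 1 so that
under-dispersion can never make the random-effects SE smaller than the
fixed-effect SE. We chose the floored form as the default (the unconstrained
scale is available as `model="mre_unconstrained"`): with normal reference
p-values the unconstrained form is anti-conservative at k ~ 20 (analytic
type-I error ~0.065 at nominal 0.05), while the floored form is mildly
conservative (~0.041 measured, ~0.043 analytic) and matches the convention of
the standard two-sample MR tooling.

### Sensitivity estimators

Six pleiotropy-aware estimators accompany every FDR-significant IVW result:

- **Weighted median / penalised weighted median** — consistent when >= 50% of
  the weight is on valid instruments. The estimate interpolates the ratio
  order statistics where the standardised cumulative inverse-variance weight
  crosses 0.5; the penalised variant multiplies weights by
  min(1, 20 * P(chi2_1 > q_j)) with q_j the variant's heterogeneity
  contribution about the unpenalised estimate. SEs come from a seeded
  parametric bootstrap (default 1000 draws; the seed is part of the screen
  config, so reruns are byte-identical).
- **MR-Egger** — weighted regression with an intercept after orienting all
  variants to b_X >= 0; the intercept estimates directional pleiotropy, the
  slope is consistent under InSIDE. t reference on k-2 df.
- **MR-Lasso** — per-variant direct effects alpha_j penalised by L1 and
  solved by coordinate descent (soft-thresholding). Descending a geometric
  lambda grid from the smallest lambda that zeroes every alpha, we stop at
  the first (largest) lambda whose selected valid set is homogeneous
  (Cochran's Q below the 0.95 chi-square quantile) and report IVW on that
  set.
- **Contamination mixture** — profile likelihood over a theta grid where each
  variant is assigned to a valid N(theta, se_j^2) or invalid
  N(0, se_j^2 + psi^2) component; the 95% CI is the 3.841/2 likelihood-ratio
  set. The pleiotropy scale psi defaults to
  1.5 * max(SD(ratio estimates), 2 * RMS ratio SE). The plain 1.5 * SD
  heuristic degenerates when all instruments are valid: the ratio SD then
  measures sampling noise only, the null-centred invalid component absorbs
  the tail of valid ratios lying toward zero, and the estimate is biased away
  from zero (clean-scenario CI coverage drops to ~0.82 in our simulations).
  Flooring psi at twice the measurement-error scale restores ~0.95 coverage
  while leaving genuine contamination detectable; psi remains an explicit
  argument.
- **Constrained maximum likelihood (cML)** — for each candidate count K of
  invalid instruments, alternate between flagging the K largest squared
  standardised residuals as carrying free direct effects and re-estimating
  theta on the rest; BIC(K) = RSS_valid + K log k. The default reports the
  BIC-weighted model average with between-model variance added to the SE
  (the model-averaged flavour; a data-perturbation variant is not
  implemented). cML at K = 0 reproduces fixed-effect IVW to machine
  precision, which the test suite asserts at 1e-8.

### Instrument selection

Clumping is greedy by p-value: take the smallest-p variant with
p <= threshold, remove everything with LD r^2 > 0.001 within +/-10 Mb,
repeat. Primary threshold 5e-8; if fewer than five instruments survive, the
selection relaxes once to 5e-6; still fewer than five excludes the exposure.
Instruments missing from the outcome are replaced by the best LD proxy
(r^2 > 0.8, highest r^2, nearest position on ties). Palindromic A/T / C/G
variants with MAF > 0.42 are dropped (conservatively also when the frequency
is missing), and weak instruments (F = b_X^2/s_X^2 < 10) removed. I^2_GX < 0.9
is recorded as a measurement-error flag but does not exclude: it marks
regression-dilution risk for Egger, which the screen reports rather than
gates on. Variants absent from the LD panel are treated as unlinked
singletons with a warning. Ties in clumping and proxy search break on
variant ID and position, so selection is fully deterministic.

### The screening cascade

Per outcome, Benjamini-Hochberg FDR is applied to the IVW p-values of that
outcome's tests only (families are defined by the outcome label; pooling
across outcomes would mis-state each disorder's test burden). An
FDR-significant pair passes the sensitivity verdict only if all six
sensitivity point estimates share the IVW sign and at least four are
significant at 0.05; an estimator that errors counts as discordant.
Egger-intercept and Cochran's Q flags are reported but do not gate the
verdict. Survivors are split by leave-one-out: if excluding a single variant
lifts the IVW p above 0.05 (the "influential" rule; the threshold is the
configurable `loo_alpha`, and when several variants qualify the one with the
largest leave-out p is named), the pair is classed *single instrument* and
re-estimated by a Wald ratio on that variant alone; otherwise *polygenic*.
Sensitivity passers are also tested for reverse causation by running the
full selection + IVW with the disorder as the exposure; disorders that yield
too few instruments at both thresholds are recorded as reverse-untestable,
and FDR for the reverse family is computed over the reverse tests only.

## Multivariable MR-BMA

Candidate exposures are first pruned for near-collinearity using a supplied
genetic-correlation matrix: within any pair correlated >= 0.95, the member
correlated >= 0.95 with more than one other candidate is dropped, otherwise
the one with the weaker univariable IVW p. Instruments are pooled across the
candidates and re-clumped by each variant's best exposure p.

The model works on the weighted scale y = b_Y/s_Y, X = b_X/s_Y with each
column scaled to unit norm, so the N(0, 0.25) effect prior refers to
comparably scaled effects — this is also what makes the null behaviour
honest: with unit-norm columns the Bayes factor for adding a null exposure
has expectation 1, and simulated null data return mean MIP ~= the 0.1 prior.
Every subset of up to `k_max` = 4 exposures is enumerated exactly (the
per-outcome candidate sets this screen produces have d < 15, where
enumeration is cheap and exact, unlike stochastic model search); the subset
marginal likelihood is the conjugate closed form, subsets are weighted by an
independence prior with inclusion probability 0.1, and posteriors are
normalised over the enumerated space. MIP >= 0.1 is the prioritisation call.
Outlier diagnostics (Cook's distance, per-variant q) are not implemented.

## Colocalisation

Regions are +/-250 kb around an index variant (the influential instrument
from leave-one-out). Per-variant evidence is the Wakefield approximate Bayes
factor computed from (beta, se) with prior effect variance W = (0.15 * sdY)^2
for quantitative traits (sdY defaults to 1, i.e. standardised metabolite
GWAS; a per-region `sdY` field accepts an estimate when traits are not
standardised) and W = 0.04 on the log-odds scale for binary traits. The five
hypothesis posteriors use configuration priors p1 = p2 = 1e-4, p12 = 1e-5;
H3 sums variant pairs excluding the diagonal via a log1p-protected
log-sum-exp, and the posteriors sum to 1 within 1e-9 by construction.
Labels: PP.H4 >= 0.8 colocalised, >= 0.6 suggestive, with the analogous H3
labels for distinct signals. Credible SNPs are accumulated from the per-SNP
H4 posterior in decreasing order (position, then ID, on ties) until 95% mass.

## eQTL follow-up

Genes within 10 kb of credible SNPs (supplied as a plain annotation table)
are candidate transcripts. Expression effects on metabolite and disorder are
estimated by IVW on cis-eQTL instruments clumped at 5e-8 only — no relaxed
fallback, and a single instrument falls back to the Wald ratio. SMR uses the
top cis-eQTL: beta_SMR = b_GWAS/b_eQTL with the chi-square(1) statistic
T = z_G^2 z_E^2 / (z_G^2 + z_E^2). HEIDI tests the single-shared-variant
assumption: for SNPs near the top eQTL (eQTL p < 1.57e-3, LD r^2 with the
top in [0.05, 0.9], at most 20 — the published tool's defaults, since these
parameters are rarely restated), the differences d_i between their SMR
ratios and the top SNP's ratio are centred at zero under a shared variant;
their delta-method covariance uses the LD correlations (eQTL and GWAS
samples independent), near-collinear SNPs are pruned if the correlation
matrix is numerically singular, and the sum of standardised d_i^2 is
referred to a Satterthwaite-matched scaled chi-square. The approximation is
known to be slightly liberal (we measure ~9% rejection at nominal 5% under
the shared-variant simulation), which is acceptable here because HEIDI
rejections are used to *discard* SMR hits.

Mediation uses the product of coefficients: indirect = a*b with
se = sqrt(a^2 se_b^2 + b^2 se_a^2); proportion = a*b/c with a first-order
delta SE treating (a*b) and c as independent — appropriate because the three
coefficients come from non-overlapping samples, and a documented limitation
otherwise. p-values come from the normal reference on proportion/se.

## Synthetic data

Summary statistics are simulated directly at the summary level: with R the
LD matrix (AR(1) blocks, r_ij = rho^|i-j|) and b the joint effects on a
standardised trait, marginal estimates are drawn from N(Rb, R/n) with
se = 1/sqrt(n). Binary outcomes are simulated on the log-odds scale with an
effective sample size — a deliberate simplification that sidesteps
liability-scale conversion and case-control ascertainment. Defaults emulate
the screen's data scale: metabolite GWAS n = 50,000, disorder effective
n = 100,000, 20 instruments jointly explaining 5% of metabolite variance
(per-instrument F ~ 125). The single-locus regime plants one dominant
instrument (b = 0.2, F ~ 2000, matching the upper range of single-instrument
F statistics such screens report) whose outcome association implies a ratio
of 0.2, plus four satellites (b = 0.03) with no outcome effect, so the
entire signal rides on the driver. Pleiotropy regimes add balanced or
directional direct effects to a configurable fraction of instruments. The
eQTL triplet chains expression -> metabolite -> disorder with an optional
direct expression -> disorder path across two unlinked blocks: a cis block
instrumenting expression and a trans block instrumenting the metabolite
alone — without the trans block the mediator -> outcome path b is not
identifiable separately from the direct path. Colocalisation regions use
100 SNPs at rho = 0.9 with 1% variance explained (n = 10k) for the
coloc studies and 4% (eQTL) / 0.2% (GWAS) at n = 30k for the HEIDI studies.

What the generators do *not* emulate: realistic allele-frequency spectra,
imputation error, sample overlap between exposure and outcome GWAS,
liability-scale binary effects, and trans-ancestry LD heterogeneity. Passing
benchmarks therefore demonstrates the statistical machinery's correctness
and calibration under its own assumptions, not robustness to those
real-data complications.

## Benchmark sizes and numerical choices

The seeded studies in `metabomr.benchmarks` use 2000 replicates for
calibration/leave-one-out rates, 1000 for estimator coverage and 150 per arm
elsewhere — sizes chosen so Monte-Carlo error is small relative to the
property being measured while the whole battery runs in a couple of minutes
on one CPU. Other numerical choices: the contamination-mixture grid spans
the ratio range +/- 3 widths at 1e-3 resolution capped at 20,001 points; cML
iterates to |delta theta| < 1e-10 with a 200-iteration cap and falls back to
converged models only; MR-Lasso uses a 50-point geometric lambda grid over
three decades; degenerate inputs (zero exposure effect in a Wald ratio,
fewer variants than a method needs, singular HEIDI covariance after pruning)
raise or return missing values rather than guessing.

## Known limitations

- The multiplicative random-effects floor makes IVW mildly conservative
  (measured type-I ~0.041 at nominal 0.05); the unconstrained switch trades
  that for anti-conservatism.
- The leave-one-out "influential" rule is a significance-attenuation rule;
  it is not a formal influence statistic and inherits the arbitrariness of
  the 0.05 threshold (configurable).
- Contamination-mixture inference ignores classification uncertainty; its
  CI is a profile-likelihood set and can undercover when theta is within
  ~2 ratio-SEs of zero.
- HEIDI's scaled chi-square reference is approximate and slightly liberal.
- The mediation delta method assumes independent inputs and a non-null
  total effect; proportions are unstable when c is near zero, which is why
  wide intervals (as in weak-total-effect applications) must be reported
  alongside the point estimate.
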