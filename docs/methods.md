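# Methods

This note records the models behind `poolgwas`, the defaults and why they
were chosen, the numerical decisions, and what the simulation studies do
and do not demonstrate.

## Cohort simulator

**Pedigrees.** Families are generated independently. Each family draws a
target size 3 + Poisson(mean_size − 3) (default mean_size = 4) and is
nuclear (founder couple + children) or, with probability `p_extended`
(default 0.3) when size permits, three-generational: the eldest child
receives a married-in founder spouse and grandchildren. Construction order
puts parents before children, so truncating a cohort to an exact size
never orphans anyone. Default cohort size 1,402.

**Genotypes.** Biallelic autosomal variants (chromosomes 1–22, 1-based
positions, strictly increasing per chromosome). Minor-allele frequencies
follow Beta(1, 3) truncated to [0.01, 0.5] by inverse-CDF — an array-like
spectrum skewed toward lower frequencies that respects the 1% inclusion
floor. Founders are drawn Hardy–Weinberg at the panel MAF; non-founders
receive one uniformly chosen allele from each parent (gene dropping,
vectorized per generation), so Mendelian consistency holds by
construction. Default desk-scale panel 5,000 variants; genome-scale
(~6 × 10⁵) runs work but are not the default.

**Traits.** Four binary traits — T2D, central obesity (CO), hypertension
(HTN), dyslipidemia (DL) — from a liability-threshold model:

    L_t = λ·F + √v_fam·A_{fam,t} + G·1[t = T2D] + √v_resid·ε,

with F ~ N(0,1) a latent metabolic-syndrome factor shared across the four
traits within a person (loading λ = 0.4, i.e. 16% of liability variance;
gives modest positive cross-trait correlation ≈ λ² = 0.16 on the liability
scale), A a per-family, per-trait polygenic deviate (v_fam = 0.2, chosen
to echo the sizeable familial component of T2D in family cohorts without
full infinitesimal machinery), G the standardized causal-variant score
(panel `effect` column; acts on T2D only; default all zero), and the
residual filling the variance to 1. Thresholds are standard-normal
quantiles of the target prevalences (defaults 29.82 / 71.98 / 52.93 /
31.03%), so marginal prevalences are matched in expectation; a single
realization at n = 1,402 fluctuates with sd ≈ 0.015 because families are
clustered. An optional ascertainment flag redraws each family until it
contains at least one T2D case (enrollment-style conditioning; off by
default, since conditioning changes the marginal prevalences in ways the
targets already encode).

Clinical thresholds (glucose, blood pressure, lipids) are deliberately not
modeled: traits are generated directly as indicators.

**What the generator does not emulate.** Linkage disequilibrium between
variants (variants are dropped independently), assortative mating,
genotyping batch chemistry, array-calling quality scores, and
ascertainment beyond the optional per-family case requirement. Passing
tests therefore demonstrate the statistical machinery under a clean
family-based measurement model, not robustness to LD structure or array
artifacts.

## Kinship

Pairwise kinship φ(i,j) by the standard pedigree recursion (parents before
children; founders unrelated and non-inbred unless stated):
φ(i,i) = ½(1 + φ(f,m)), φ(i,j) = ½(φ(f,j) + φ(m,j)). A gene-drop
Monte-Carlo estimator with uniquely labeled founder alleles is shipped as
an independent validation oracle and agrees within ±0.01 at 10⁵ replicates
on small pedigrees.

The pool covariate PHI is the **mean** pairwise kinship over distinct
member pairs (the natural pool-level scalar; the median is available as an
option — which summary the design intends is genuinely open, so it is
configurable rather than guessed). Singleton pools get PHI = 0 with a
warning.

`pool_af_covariance` aggregates the kinship matrix to pool level: under
Hardy–Weinberg founders the genotype covariance is 4p(1−p)K, so pool mean
allele frequencies satisfy Cov(q_g, q_h) = p(1−p)(MᵀKM)_{gh}/(n_g n_h).
The diagonal reduces to the familiar (1 + 2(n_g−1)·PHI_g)/(2n_g)
inflation; the off-diagonal captures relatives split across pools, which
matters because T2D clusters within families and therefore case pools
co-vary.

## Pools and measurement

**Construction.** The 16 trait combinations are tabulated in
lexicographic order (T2D, CO, HTN, DL; No < Yes). Combinations under the
1% share threshold merge into the nearest **preceding** retained
combination with the same T2D status — this keeps the pool outcome
constant and reproduces the two reference merges (the n = 7 and n = 11
combinations absorbed upward) — iterating until all pools clear the
threshold; if no preceding same-outcome pool exists the merge goes forward
with a warning. Empty combinations are dropped. Covariates of merged pools
are member-weighted trait proportions (fractional), preserving the mixed
DL composition rather than forcing a majority label. Two replicates per
pool by default; chips are assigned round-robin with a per-pool offset,
chip = (pool index + replicate) mod n_chips, so chip and replicate effects
are never aliased.

**BAF measurement model.** Per (pool, replicate), member contribution
weights are drawn Dirichlet(c·1) over the pool (c = 50 by default — the
pipetting inequality of ~100 µL aliquots; c → ∞ gives exact equal
contributions); the replicate's true pooled allele frequency is
Σ w_i g_i / 2, shared across variants because the physical pipetting is.
Observed BAF adds N(0, σ²) array noise per variant (σ = 0.01 default, the
scale of array allele-frequency read noise) and truncates to [0, 1].
Truncation rather than resampling: simpler, and testable at the
boundaries. Near 0 or 1 the truncation shrinks noise, so
noise-recovery oracles are evaluated at interior frequencies.

**Pooling error.** From duplicate measurements, d = BAF_rep1 − BAF_rep2
per pool and variant: the report gives mean(d) with mean ± 1.96·sd(d)
(the spread of per-variant error estimates — a distributional interval,
not a standard error of the mean), and the variance component Var(d)/2
attributable to pooling + array noise per measurement. The sign convention
is fixed as rep1 − rep2 and documented because it is otherwise arbitrary.

## Association scan

**The model.** Per variant, a logistic regression of the pool outcome on
BAF with the comorbidity proportions, chip, replicate and PHI as fixed
effects, a pool random intercept u ~ N(0, τ²), and frequency weights equal
to pool member counts (each unit's log-likelihood multiplied by n, not
normalized).

**Why the likelihood alone cannot calibrate a scan.** Two structural
facts. (1) The outcome is constant within pools and the weights are large,
so each pool's weighted Bernoulli likelihood is all-or-nothing: the
Laplace marginal likelihood is monotone increasing in τ² and its maximizer
diverges. (2) Across variants the outcome vector never changes — the only
randomness is in the measured BAF — so an outcome-likelihood-based
standard error answers the wrong sampling question; empirically it is off
by factors of 3–5 either way depending on τ².

**The scan statistic (method="score", default).** The null (no-BAF) model
is fitted by weighted logistic regression with a weakly-informative ridge
(prior sd 1 per standardized covariate, intercept unpenalized) — without
it, ~8 fixed effects can quasi-separate ~14 pool outcomes and the
coefficient on PHI explodes. The contrast is r = w(y − μ̂); the score for
β_s is U = Σ_u r_u·BAF_u; and its variance comes from the measurement
model:

    Var(U) = p̂(1−p̂) · RᵀCR  +  v_rep(p̂) · Σ_u r_u²,

with R the pool-summed contrast, C the kinship-derived pool
allele-frequency covariance coefficients above, and v_rep(p) = a + b·p(1−p)
the replicate-level variance fitted by least squares to the per-variant
squared replicate differences (intercept: array noise; slope: pipetting,
which scales with allele-frequency variance; both floored at zero).
T = U/√Var(U) is referred to the standard normal (a Student-t option with
pools-minus-pool-level-effects degrees of freedom is provided). The
reported slope is the one-step estimate β̂ = U/I with I the model
information from the null fit, and SE = √Var(U)/I, so β̂/SE = T exactly.
This is a sandwich construction — model bread, measurement-model meat —
and it is validated two ways: genome-wide null calibration (sd(T) ≈ 1.00,
fraction p < 0.05 within 0.05 ± 0.01, λ within [0.91, 1.05] across seeds)
and a direct oracle (for individual variants, Var(U) over repeated
gene-drops of the same variant through the same pedigree and pools matches
the model value within ~5%).

**Full-ML fits (method="wald").** For small data, oracle checks and data
with within-pool outcome variation: Newton–Raphson on the joint penalized
log-likelihood for fixed τ² (batched across variants via a Schur
complement on the diagonal random-effect block; step halving; gradient
tolerance 1e-8; max 50 iterations; non-convergence flags the record and
blanks its p-value rather than aborting the scan). τ² = 0 reduces exactly
to plain weighted logistic regression — the test-suite verifies agreement
with two independent implementations (statsmodels GLM and a textbook
Newton–Raphson) to 1e-6 relative. τ² may also be profiled over the Laplace
marginal likelihood on a log grid with parabolic refinement; as noted,
for pool-constant outcomes this profile runs to the grid edge, which is
reported, not hidden. A pool-level overdispersion moment estimate of τ²
(excess of squared latent pool residuals over their binomial sampling
term, with a degrees-of-freedom correction) accompanies score scans as a
diagnostic.

**Design hygiene.** Shared design columns are pruned by a greedy weighted
rank check (tolerance 1e-8) and reported; per-variant BAF columns that are
constant after projection on the shared design (weighted residual sd
< 1e-8) are flagged aliased with missing estimates. Scans require at
least two pools in each outcome class. m for the Bonferroni threshold is
the number of scanned variants; records with missing p cannot be
significant. Ranking ties break by variant id so top-k lists are
reproducible.

**Panel filter.** Autosomes 1–22 only (a leading "chr" is tolerated);
MAF < 1% excluded — the boundary 1% is retained because the exclusion is
strictly "below 1%". Exclusions are tallied per criterion.

## Reporting and annotation

QQ data uses order-statistic expectations i/(m+1) and pointwise
Beta(i, m−i+1) 95% bands; note a single sample's band-coverage fraction
fluctuates widely because order statistics are correlated — the ~95%
coverage statement is an expectation over scans. Manhattan tables carry
cumulative positions; rendering is optional and side-effect-free.

Coordinates: variants are 1-based (VCF), gene intervals 0-based half-open
(BED); the conversion lives in one function. Distance is the interval gap
— the count of bases strictly between variant and gene, 0 for overlap
**or direct adjacency** — and the within-gene flag is defined as
distance == 0, which keeps "distance 0 iff within" exact at the adjacency
edge case. Ties go to the gene with the smaller start. Strand is carried
but ignored for distances. Variants on chromosomes absent from the
interval file are labeled unannotated (warning); beyond `max_distance`
(default 1 Mb), intergenic.

## Operating characteristics and their limits

Problem sizes used by the test-suite and the reproducibility script:
null calibration at 10,000 variants; family-wise error over 20–40
independent 2,000-variant scans; power over 50 replicates per effect size
with a 40-variant context panel; kinship oracle at 10⁵ gene drops;
pooling-error recovery at 10,000 interior-frequency variants.

Two findings are worth stating plainly:

* **Power ceiling at common MAF.** With 14 pools of 22–230 members, the
  binomial sampling noise of pool allele frequencies (sd ≈ 0.02–0.05)
  bounds what any test can detect. A +0.10 case-pool BAF shift at
  α = 10⁻⁵ is detected in ~94% of runs at MAF 0.10 but only ~72% near the
  panel's median MAF (~0.18) — and an optimal-linear-contrast calculation
  shows the latter is within a few percent of the information-theoretic
  ceiling, so the shortfall is a property of the design, not the
  estimator.
* **Bonferroni is near-exact here, not conservative.** Because the scan's
  p-values are calibrated (not deflated), the family-wise error rate sits
  at its nominal ~0.05; small batches of null scans will occasionally show
  2+ of 20 seeds with a hit by chance.

Known limitations: no LD (each variant is tested and simulated
independently, so the multiplicity behavior of correlated panels is not
exercised); low-MAF variants near the truncation boundary are tested
slightly conservatively; the score method needs a scan (many variants) to
estimate the replicate variance law, so single-variant fits default to the
full-ML Wald path; and the cross-pool covariance requires the pedigree —
plans built without a kinship matrix fall back to the within-pool diagonal
(PHI-based) variance.
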