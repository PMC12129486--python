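# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions a user should know before
interpreting output.

## Case-control association on read counts (`assoc`)

**Model.** At each biallelic site, alternate/reference read counts are
pooled within phenotype class. Under H0 both classes share one allele
frequency; under H1 each class has its own maximum-likelihood frequency.
The statistic is the binomial likelihood ratio
`G = 2 [ ℓ(p̂_case) + ℓ(p̂_ctrl) − ℓ(p̂_pooled) ]`,
referred to χ²(1). `site_lrt` exposes this closed form on raw counts.

**Effective read counts.** Reads from one individual share a genotype, so
pooled raw counts are overdispersed relative to binomial sampling. For an
individual with `t` reads at a site, the alternate-read count has variance
`p(1−p)·t(t+1)/2` under HWE — the same as `2t/(t+1)` independent allele
draws (one read is one draw; infinitely many reads resolve exactly the two
chromosomes). `run_gwas` therefore weights each cell's counts by
`2/(t+1)` before pooling, which matches the first two moments of the
pooled count to a binomial exactly, and then applies Williams' correction
for the residual small-sample bias of the G statistic. Without these the
test is measurably anticonservative at ~0.35× coverage (≈7.6% of null
sites below p = 0.05); with them the null p-value distribution is
indistinguishable from uniform in our calibration tests. Both corrections
can be disabled (`effective_counts=False`, `williams=False`) to recover
the plain pooled-read LRT.

**Genome-wide significance.** Phenotype labels are shuffled uniformly
without replacement; the GWAS is re-run and the minimum p-value recorded;
the threshold is the inverse-ECDF lower-`fwer` quantile of the minima
(the `⌈n_perm·fwer⌉`-th smallest — conservative and reproducible). A
true-data p-value *equal* to the threshold counts as significant. With
`n_perm` permutations the expected family-wise error rate is
`⌈n_perm·fwer⌉ / (n_perm + 1)` by exchangeability; the calibration test
verifies it lands in [0.02, 0.08] at nominal 0.05. No FDR layer is
applied; control is FWER-only by design.

**Structure correction.** Pseudo-haploid calls sample one read uniformly
per covered cell (a Bernoulli(alt/total) call), which removes the
depth-dependent bias of genotype calls at low coverage at the price of
noise. Filtering removes sites with minor-allele frequency < 0.02
(computed over non-missing calls; a site at exactly 0.02 is retained) or
missing in ≥ 75% of individuals. PCA runs once on the per-site
mean-imputed, centered call matrix; per-site logistic regressions
(phenotype ~ call + PC1..PC4 by default) give Wald p-values. Sites with
complete separation — e.g. a fully penetrant dominant locus with
error-free reads, where an alternate call implies case status — are
flagged NaN rather than assigned a fabricated p-value.

**LD.** `pairwise_r2` is composite LD: squared Pearson correlation of
dosage/call vectors over individuals non-missing at both sites.
Monomorphic partners are NaN, not 0.

## Balancing-selection scan (`balscan`)

π uses the ratio-of-sums convention: per site, `k(m−k)` differing pairs
over `C(m,2)` comparable pairs among `m` non-missing alleles; invariant
covered sites contribute zero differences and full pair counts to the
denominator. This keeps π unbiased under missingness and makes the
denominator explicit rather than dividing by window length (a per-bp
variant is available). Tajima's D uses only sites genotyped in all
haplotypes, with the 1989 normalizing constants, and is undefined (NaN,
never 0) when no site segregates. NCD1 is the root-mean-square deviation
of SNP minor-allele frequencies from the target frequency, default
`tf = 0.3`; it uses within-window SNPs only (no outgroup — this is NCD1,
not NCD2). Because results should not hinge on the target, report a small
tf sweep (e.g. 0.2–0.5) alongside any single-window claim.

Windows tile the chromosome from coordinate 1, half-open, non-overlapping
(stride = width; the simplest reproducible choice where a stride is not
otherwise dictated). Diploid GTs are split into two pseudo-haplotypes
ignoring phase — all three statistics are phase-free. Empirical quantiles
count the focal value in its own tail, so "top X%" statements are
conservative under ties. The recombination-matched filter keeps windows
at or below the inverse-ECDF `quantile_cut` (default 0.08) quantile of
per-window ρ/bp, ties included. Whether positions without VCF records are
covered invariant sites or unknown is the caller's declaration
(`assume_invariant_covered`, default true), since VCFs rarely carry
invariant records.

## Wright–Fisher retention (`driftsim`)

The schedule is piecewise-constant (generation-before-present, Ne),
oldest segment first; Ne is rounded to the nearest integer ≥ 1 per
segment because binomial sampling needs integer chromosome counts.
Simulation starts at the oldest boundary, draws
`count ~ Binomial(2N, p_prev)` each generation with no recurrent
mutation, and stops early on absorption. "Retained" means both alleles
present at the final simulated generation. `truncate_recent` drops the
most recent segments (demographic inference is typically unreliable
there) and ends the run at the oldest removed segment's start, so the
simulated span shortens by exactly the removed generations.
`dominant_freq` converts a dominant phenotype frequency to its HWE allele
frequency, `d = 1 − sqrt(1 − f)`. `mutation_rate` (default 3.5 × 10⁻⁹)
and `generation_time_years` (default 0.5) ride along for scaling
helpers only.

`wf_run` simulates one trajectory from its own seed; `retention_probability`
advances all replicates as a single vectorized batch from one seeded
generator (one binomial draw per generation across unabsorbed replicates),
which is what makes 10⁴ replicates over 10⁴–10⁵ generations practical.
Results are bit-reproducible given (schedule, p0, n_reps, seed). The
simulator is validated against an exact Markov-chain oracle (the
(2N+1)-state binomial transition matrix raised to the t-th power) for
small populations, against the neutral fixation probability `u(p0) = p0`,
and against the heterozygosity decay rate `(1 − 1/2N)^t`.

## Haplotype association (`hapassoc`)

Fisher's exact test follows the dominant software convention for the
two-sided p (sum of point probabilities ≤ observed, relative tolerance
1 + 10⁻⁷) and is cross-checked against full hypergeometric enumeration in
the tests. The all-heterozygote probability for `n` sampled
phenotype-positive individuals is `(2d(1−d)/f)^n`; the simulation route
rejection-samples carrier genotypes from HWE dosage draws and must agree
with the closed form within Monte Carlo error — it exists so that the
sampling claim can be verified rather than asserted. Diagnostic-SNP
filtering returns 1-based alignment positions where each group is fixed
for a different base, no gap or N intrudes, and every indel is more than
`indel_buffer_bp` (default 5) away; mapping to genome coordinates is the
caller's concern.

## Choice-trial power (`choicepower`)

The test is the classical one-sample two-sided Wilcoxon signed-rank:
zeros dropped, average ranks for ties, exact p by the generating-
polynomial null distribution of W⁺ for n ≤ 25 without ties
(`2·min(P(W ≤ w), P(W ≥ w))`, capped at 1), otherwise the normal
approximation with continuity and tie correction (delegated to scipy).
Power simulation draws `n_reps` datasets of size `n` from Normal(effect,
sd) — plain normal draws, no truncation, matching how such power analyses
are specified; the truncating generator in `synthgen.simulate_trials`
exists separately for emulating observed data, where a difference of
proportions cannot leave [−1, 1]. Detection is strict `p < alpha`.
Because continuous draws are tie-free almost surely, the batch computes
W⁺ from row-wise ranks and looks p-values up in the exact table, making a
17-point × 10⁴-replicate curve essentially instant. The generator is
re-seeded identically at each grid point, so all effect sizes see the
same noise (coupled, monotone-in-practice curves comparable across
groups). At effect 0 the power equals the attainable size of the discrete
exact test — slightly below alpha at small n; that is a property of the
test, not an error.

## Synthetic data (`synthgen`)

The generators reproduce the statistical structure each analysis assumes,
at the study's stated conditions: a fully dominant, fully penetrant
causal locus at phenotype frequency defaults like 0.39 (allele frequency
`1 − sqrt(1 − f)` ≈ 0.219), HWE genotypes, Poisson(0.35) read depth with
optional base error, and normally distributed preference differences.
Non-causal allele frequencies default to Uniform(0.05, 0.5) — a
post-filter site-frequency range typical of a GWAS panel.

Neutral windows come from a standard single-population Kingman coalescent
with infinite-sites mutation (Poisson(θ/2 × branch length) per branch),
positions drawn uniform-without-replacement on the window. Balanced
windows are a *structural* emulation of an old balanced polymorphism: the
haplotypes are split into two allelic classes (Binomial(n, tf), empty
classes resampled), each class gets an independent within-class coalescent
with θ scaled by its class share, and Poisson(θ·t_split) class-diagnostic
mutations accumulate on the internal branch. Defaults θ_within = 5,
t_split = 5 (coalescent units) encode a deep, pre-speciation-age split.
With `t_split = 0` the generator returns the neutral coalescent exactly.
This emulation produces the targeted signatures — elevated π, positive
Tajima's D shift, intermediate-frequency variants, low NCD1 — without
simulating selection dynamically; it does not model recombination within
windows, mutation-rate heterogeneity, linked sweeps, or migration, so
passing scan tests demonstrates statistical behavior of the estimators,
not robustness to every feature of real data. The same caveat applies to
the read model (no mapping bias, no duplicate reads, symmetric base
error) and to the trial model (no side bias, no between-female variance
heterogeneity — group variances are acknowledged to differ in real
datasets but are modeled as a single sd per group here).

All generators are bit-reproducible given their parameters and a single
integer seed; one `numpy` Generator is created per call.

## Problem sizes used in the checked examples

Calibration and acceptance tests run at desk scale, chosen to keep Monte
Carlo error well inside the asserted tolerances: 10⁴ replicates for
binomial probabilities (SE ≈ 0.005), 2000 coalescent windows for the
neutral Tajima's D mean (SE ≈ 0.01), 200 outer replicates × 100
permutations for family-wise error calibration (SE ≈ 0.015), 50 paired
seeds × 200 replicates for the bottleneck comparison, and 20–30 planted-
window chromosomes of 30 × 8.8 kb windows for outlier detection.

## Known limitations

* The association LRT treats sequencing error as noise (it is available
  in the generator but not modeled in the statistic); a genotype-
  likelihood EM refinement is out of scope.
* The balanced-window generator is a two-class heuristic, not a
  structured coalescent with selection; use msprime for a full coalescent
  cross-check if needed.
* The drift simulator consumes an already-scaled schedule; it does not
  infer demography, and raw PSMC output must be converted by the caller.
* `covariate_association` loops per site through statsmodels logistic
  fits; it is meant for thousands, not millions, of sites.
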