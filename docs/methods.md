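# Methods

## The weighted variable-threshold test

For a gene with $m$ variants, the test statistic at a candidate MAF
threshold $T$ is

$$z(T) = \frac{\sum_i \delta_i(T)\, S_i \sum_j C_{ij}(\pi_j - \bar\pi)}
              {\sqrt{\sum_i \delta_i(T)\, S_i^2 \sum_j C_{ij}^2}},$$

with $C_{ij}$ the minor-allele count of variant $i$ in subject $j$,
$\pi_j \in \{0,1\}$ the phenotype, $S_i \in [0,1]$ the functional weight,
and $\delta_i(T) = \mathbf{1}[\mathrm{MAF}_i < T]$. $z_{\max}$ maximizes
$z(T)$ over the gene's candidate thresholds. The test is one-sided: large
$z_{\max}$ means an excess of weighted rare minor alleles in cases.
Assumptions: unrelated subjects, no covariates, binary phenotype,
genotypes complete (missing genotypes are rejected, not imputed).

**Allele orientation.** Inputs may encode either allele; on load every
variant is recoded so the counted allele is the minor one (count
$\mapsto 2 - \mathrm{count}$ when the counted-allele frequency exceeds
0.5). This makes the MAF used by $\delta_i(T)$ the frequency of the
counted allele and keeps the collapsed burden a rare-allele count.

**Threshold grid.** With the strict inclusion rule $\mathrm{MAF}_i < T$,
the candidates are the midpoints between consecutive distinct observed
MAFs plus one value half a gap above the maximum (a single distinct MAF
gets one candidate just above it). This realizes exactly one nested
variant configuration per distinct MAF, always including the all-variants
configuration. The MAF is computed once from the full sample
(cases + controls) and held fixed across permutations. A configuration
with no positively weighted variant gets $z = -\infty$ and can never be
selected; a gene where every configuration is degenerate (e.g. all
monomorphic, or no nonsynonymous variant under a score-based scheme) is
reported with p = NA and a warning. Ties in the maximization go to the
smallest threshold, for determinism.

**Permutation inference.** Phenotype labels are permuted; the full
threshold maximization re-runs in every permutation. Because neither the
per-threshold weighted burden matrix $B_{Tj} = \sum_i \delta_i(T) S_i
C_{ij}$ nor the denominator depends on the phenotype, each permutation
costs one matrix product; permutations are processed in blocks of 2,000
to bound memory. The reported p-value is the add-one estimator
$p = (1 + \#\{z^{(b)}_{\max} \ge z^{\mathrm{obs}}_{\max}\})/(1+B)$, which
is never zero and valid for any $B$. Alongside it the test reports a
**mid-p** that gives half weight to permutations exactly tying the
observed statistic. For genes with very few carriers $z_{\max}$ takes few
distinct values, ties are massive, and the plain estimator is noticeably
conservative while mid-p is close to uniform under the null; mid-p is
therefore the recommended input for downstream p-value combination
(atoms of p = 1 would otherwise destabilize the mixture fit — see below).
Per-gene, per-scheme RNG substreams are derived from
(master seed, CRC32 of gene and scheme), so results are independent of
gene processing order.

**Weights.** `unweighted`: $S_i = 1$ everywhere. `binary`: indicator of
nonsynonymous. `sift`: $1 - \mathrm{SIFT}$ on nonsynonymous variants
(SIFT is a tolerance probability, small = damaging), 0 on synonymous.
`polyphen`: the PolyPhen-2 posterior probability of damage, 0 on
synonymous. Nonsynonymous variants missing a score are imputed with the
median raw score — 0.1 for SIFT, 0.2 for PolyPhen-2 — *before* the
transform (so imputed SIFT weight is 0.9, imputed PolyPhen weight 0.2);
the constants are overridable for datasets with different medians.
Qualitative calls use the standard cutoffs: SIFT damaging iff score
< 0.05 (0.05 itself is tolerated); PolyPhen-2 benign on [0, 0.2],
possibly damaging on (0.2, 0.85), probably damaging on [0.85, 1].

## Combining two tests: the mixture model

P-values from two weighted tests are transformed per gene to
$x_{gk} = \Phi^{-1}(1 - p_{gk})$, $k = 1, 2$, so small p-values become
large z-values, and clamped to a finite range first (by default half the
smallest observed p-value, capped at $10^{-4}$). The pairs are modelled
as a two-component bivariate normal mixture
$f(x) = \pi_0 f_0(x) + \pi_1 f_1(x)$ whose components factorize across
the two dimensions given association status (diagonal covariances). The
univariate case (K = 1) is supported for single-test FDR estimation.

EM details (all tunable): initialization assigns the associated component
to genes above the 90th percentile of the first dimension, with 5
restarts at random split quantiles in [0.75, 0.95], best final
log-likelihood wins; relative log-likelihood tolerance $10^{-8}$; max
1,000 iterations (non-convergence warns and returns the best iterate);
variance floor $10^{-6}$ against collapse. The associated component is
identified as the one with the larger mean in dimension 1 (dimension 2
breaks ties). The observed-data log-likelihood trace is retained and is
non-decreasing, as EM guarantees.

The posterior probability of association
$\pi_1 f_1(x_g) / (\pi_0 f_0(x_g) + \pi_1 f_1(x_g))$ is computed in log
space (no NaN under joint underflow). Genes are ranked by descending
posterior with ties sharing the best rank. The FDR of a declared set
$\{$posterior $\ge c\}$ is the mean of $1 - $posterior over the set
(local-fdr averaging), non-increasing in $c$. Because the conditional
independence model can misfit real z-values, posteriors are primarily a
ranking device; FDR estimates carry an explicit caveat field.

## Concordance analytics

The SIFT/PolyPhen agreement table dichotomizes jointly scored variants
(SIFT damaging iff raw < 0.05 — the familiar 0.95 cutoff on the
$1-\mathrm{SIFT}$ axis — PolyPhen damaging iff score > 0.2); variants
missing either score are excluded. The odds ratio is $ad/bc$ with the
Haldane–Anscombe $+0.5$ correction (and a warning) when a cell is zero;
the chi-square test is Pearson's without continuity correction (at the
table sizes of interest the correction is immaterial, but the choice is
fixed for reproducibility). Spearman correlation uses average ranks for
ties. Top-k overlaps report exclusive Venn region counts for 2 or 3
ranked lists; p-value ties at the k boundary are broken lexicographically
by gene id.

## The synthetic mini-exome

The simulator emulates the structure of a small case-control mini-exome
study: 697 unrelated subjects with exactly 209 cases by default; gene
sizes $2 + \lfloor\mathrm{LogNormal}(\ln 4,\ 1.1)\rceil$ clipped to
[2, 231], giving min 2, median ≈ 6 and a long right tail; per-variant
MAFs $\mathrm{Beta}(0.25, 5)$ capped at 0.5 (median below 1%, most mass
below 5%); genotypes $\mathrm{Binomial}(2, \mathrm{MAF})$ per subject
(HWE); 55% of variants nonsynonymous.

**Scores.** Each nonsynonymous variant gets a latent damaging status
(fraction 0.5). The two algorithms' dichotomous calls are drawn
conditionally independently given that status, with damaging-conditional
call rates found by a one-dimensional root search so the realized
dichotomized odds ratio hits the configured target (default 5) while
marginal call rates match the observed 0.418 (SIFT) and 0.507
(PolyPhen). Targets ≤ 1 are infeasible for this concordant construction
and raise. Continuous scores are then drawn uniformly within the call's
interval; the default missing-score fractions are 939/13,572 (SIFT) and
1,241/13,572 (PolyPhen), missing completely at random.

**Phenotype.** Causal genes (default 10% of genes) are sampled among
genes possessing at least one rare (MAF < 0.05), nonsynonymous, latently
damaging variant; those variants are causal with a common per-allele
liability effect (default 0.8). Liability is the causal burden plus
standard normal noise; the top 30% of liabilities are cases, so the case
count is exact. A causal fraction of zero yields a phenotype independent
of genotype (the null configuration used for calibration checks).

**What the simulator does not model:** linkage disequilibrium (genotypes
are independent across variants), population structure, relatedness,
genotyping error, covariates, and any realistic relation between a
variant's score and its effect size beyond the latent damaging flag.
Passing tests on this generator show the statistics behave as designed
under their own assumptions — exchangeable subjects, independent
variants — not that the pipeline is robust to the correlation structure
of real exomes.

## Problem sizes used in the checks

The automated checks run at these sizes, chosen to keep Monte-Carlo error
well below the asserted tolerances: 200 random small genes (≤ 30
subjects, ≤ 12 variants) for exact brute-force agreement of $z_{\max}$;
$n = 6$ subjects for exhaustive-permutation agreement (all 20 case
placements); 500 null genes at 2,000 permutations for type-I error and
p-value uniformity (KS on mid-p); G = 2,000 genes over 10 seeds for
mixture parameter recovery; 20 bundles of 400 genes (5% causal, 1,000
permutations) for the combiner non-inferiority comparison (partial AUC at
FPR ≤ 0.2, margin 0.02); 17 all-causal bundles of 25 genes (≥ 200 causal
genes, 1,000 permutations) for the weighting power comparison; and the
default 100-gene benchmark for end-to-end causal-gene recovery.

## Known limitations

- One-sided testing only (protective rare-allele burdens are not sought),
  and qualitative (binary) traits only.
- The permutation p-value floor $1/(B+1)$ bounds attainable significance;
  genome-wide use needs large $B$ or adaptive permutation (not
  implemented).
- The mixture's FDR estimates inherit the conditional-independence
  assumption; with correlated tests they can be optimistic. Ranking is
  the supported use.
- VCF input is limited to complete-GT biallelic SNVs; multi-allelics and
  missing genotypes are rejected rather than handled.
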