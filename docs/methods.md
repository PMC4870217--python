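# Methods

`msatabc` implements a complete desk-scale pipeline for inferring the
demographic history of a grove-structured, long-lived conifer from diploid
microsatellite genotypes: data model and GENEPOP I/O, diversity and
relatedness statistics, kin pruning, differentiation and isolation-by-distance
testing, a coalescent simulator with generalized stepwise mutation, and
approximate Bayesian computation (ABC) over four competing divergence
scenarios with full validation machinery. This note records the models, the
defaults and why, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Data model

Allele calls are stored in base pairs. Stepwise-mutation arithmetic needs
repeat units, obtained as `(size - offset) / motif_length` with a per-locus
offset defaulting to 0 (raw data rarely document the flanking length; the
offset is configurable for datasets scored in bp with known flanks).
Missing genotypes use pairwise deletion: an individual drops out of a locus'
statistics but contributes everywhere it is typed, matching GENEPOP/FSTAT
behavior. Simulated datasets encode repeat counts as `motif_length x repeat`
bp so the repeat-unit view is exact.

## Diversity statistics

* Observed heterozygosity: fraction of heterozygous individuals per locus.
* Gene diversity: Nei's unbiased estimator `H_E = 2n/(2n-1) (1 - sum p_i^2)`.
* Allelic richness: hypergeometric rarefaction to `g` diploid individuals
  (2g genes, FSTAT convention), `A_R(g) = sum_i [1 - C(2N-N_i, 2g)/C(2N, 2g)]`.
  `g = 5` is the default, the smallest usable grove sample.
* Hardy-Weinberg exact test: a Markov chain over pairings of the observed
  gene copies into diploids. Each step swaps one allele between two random
  individuals; the proposal is symmetric and every pairing is equally likely
  under the null, so the chain needs no accept/reject step and its stationary
  distribution over genotype tables is exactly the conditional
  (allele-counts-fixed) null. The p-value uses probability ordering, with a
  Monte-Carlo standard error from batch means. Complete enumeration on
  two-allele tables is used as the test oracle.
* Linkage disequilibrium: a genotypic permutation test using the
  log-likelihood-ratio (G) statistic on the two-locus genotype table, with
  one locus' genotypes shuffled across individuals. This is a deliberate
  substitution: the composite-disequilibrium statistic of the legacy LinkDos
  program is under-documented, and LD here is only a data-quality screen.
* Multiple testing: Holm's sequential Bonferroni.
* Partial correlations: Pearson residual method (regress both variables on
  the controls, correlate residuals), two-sided p from t with
  `df = n - k - 2`. Rank-based variants are out of scope.

## Relatedness and kin pruning

Seed-orchard collections contain maternal sibships, which bias
population-level statistics. Pairwise relatedness uses the Lynch-Ritland
estimator with reference individual `x` (alleles a, b) and proband `y`:

    r = [p_a(d_bc + d_bd) + p_b(d_ac + d_ad) - 4 p_a p_b]
        / [(1 + d_ab)(p_a + p_b) - 4 p_a p_b]

Loci are combined by the Lynch-Ritland inverse-variance weights, allele
frequencies come from the full sample, and the two directed estimates are
averaged (the common GenAlEx convention). Pruning iteratively removes the
individual involved in the most pairs with r above the half-sib threshold
(0.25, strict inequality by default), recomputing ranks after each removal;
ties break by higher mean offending relatedness, then lexicographic id, so
the procedure is deterministic. Populations can be exempted wholesale — the
small-isolate case where every within-grove pair exceeds the threshold and
pruning would empty the sample.

## Differentiation

F_ST is the Weir-Cockerham variance-component estimator; R_ST applies the
same one-way ANOVA logic to allele size in repeat units. Loci combine by
summing components, never by averaging ratios, and negative component
estimates stay in the sums. The phylogeographic test permutes allele *sizes*
among the distinct allelic states within each locus (a bijection, preserving
all frequency structure) and compares observed R_ST to the permutation
distribution: a significant excess means divergence carries stepwise-mutation
memory beyond drift, and the mean permuted R_ST serves as an F_ST-like
reference value. One-tailed p with the +1 permutation correction.

Supporting distances: Rousset's `F_ST/(1-F_ST)`, Goldstein's delta-mu^2
(squared difference of mean repeat counts), Garza-Williamson
`M = k/(range+1)` (depressed by bottlenecks), and the shared-allele distance
D_AS (1 minus the mean proportion of alleles shared by cross-population
individual pairs).

## Isolation by distance

Geographic distances are haversine great-circle distances (sphere radius
6371 km) between grove centroids, optionally log-transformed (the
two-dimensional-habitat convention). Discrete grouping is encoded as a 0/1
indicator matrix (like/unlike group). Mantel tests correlate off-diagonal
upper triangles with significance from simultaneous row/column permutation;
partial Mantel tests use the residual-permutation method of Legendre &
Legendre. Tails are directional by default because the working hypotheses
are directional. Populations under 10 samples are dropped before IBD by a
mechanical filter that logs its removals.

## Coalescent simulator

The continuous-time n-coalescent with piecewise-constant diploid deme sizes
and no post-divergence migration: a deme holding k lineages coalesces at
rate `k(k-1)/(4N)` per generation. Backward-time events are deme mergers
(forward-time colonizations) and size changes; a colonization bottleneck is
a size change to `founder_N` for `duration` generations immediately after
founding. Scenario builders produce the four competing histories for five
analysis demes (pooled southern groves plus four northern demes):

1. **stepping_stone** — northward serial founding, each with a bottleneck,
   colonization times strictly ordered;
2. **mass_colonization** — all northern demes founded simultaneously from
   the south, with bottlenecks;
3. **simultaneous_divergence** — all five demes split at `t_div1` from a
   restricted population of size `N_div` (late-Pleistocene contraction);
4. **ancient_divergence** — the same split in the deep past (`t_div2`).

All scenarios change the root deme to `N_anc` at `t_anc`, constrained to
predate every other event. Time is in generations throughout; conversion to
years happens only at reporting, via Lande's generation time
`T = alpha + s/(lambda - s)` (maturity age 60-150 y and survival ~0.995
give T ~ 260-350 y; 305 y is the conventional midpoint).

Mutation follows the generalized stepwise model: Poisson mutations on
branches change the repeat count by a geometric(P) number of motif units in
a random direction, reflecting at the boundary of a 40-state allele window
(P = 0 recovers the strict SMM). The per-dataset hyperprior is
DIYABC-style: mean rate uniform on [1e-4, 1e-3], per-locus rates Gamma
(shape 2) around the mean, P uniform on [0.1, 0.3]; ten dinucleotide loci
and one trinucleotide locus by default. Priors on demographic parameters are
independent uniforms with inequality conditions enforced by rejection
sampling; defaults are wide enough to contain plausible grove-scale sizes
and late-Quaternary times and are fully overridable.

The simulation kernel is numba-compiled; all randomness flows through a
single seeded stream, so identical seeds give identical datasets. Checked
invariants: mean pairwise TMRCA 2N, total tree length `4N sum 1/i`,
strict-SMM equilibrium heterozygosity `1 - 1/sqrt(1 + 8 N mu)`, reflection
bounds, and exact seed reproducibility.

## ABC

Each simulated or observed dataset reduces to a fixed summary vector (per
deme: mean allele count, mean genic diversity, mean allele-size variance;
per deme pair: Weir-Cockerham F_ST and delta-mu^2, lexicographic order).
Summaries are standardized by reference-table median/MAD (robust to the
heavy tails prior-predictive simulation produces).

* **Model choice**: the `tolerance` fraction (default 1%, at least 50
  simulations) closest to the observed vector in Euclidean distance is
  retained; a multinomial logistic regression of scenario identity on
  summary deviations is evaluated at the observed point, with 95% CIs by
  the delta method on the asymptotic covariance. When a scenario is absent
  from the retained set or the fit degenerates, the result falls back to
  rejection counts with a binomial CI and says so.
* **Parameter estimation**: Beaumont local-linear adjustment with
  Epanechnikov weights. Each parameter is logit-transformed to its prior
  bounds before the weighted regression and back-transformed after, which
  both linearizes boundary effects and guarantees adjusted draws stay in
  the prior support. Reported: weighted posterior median and 2.5/97.5%
  quantiles.
* **Validation**: pseudo-observed datasets (parameters drawn from the
  priors by default) give type I error (focal scenario true but not
  selected), type II error (focal selected when false), RMAE
  (median |estimate - truth|/truth per parameter), and credible-interval
  coverage. Posterior-predictive model checking simulates from the adjusted
  posterior and reports lower-tail probabilities of the observed values for
  holdout statistics never used in training (Garza-Williamson M per deme;
  pooled two-sample allele counts and size variances and shared-allele
  distance per deme pair).

## Synthetic data

The orchard generator emulates open-pollinated single-cone collections:
mother trees drawn from grove allele frequencies, each seedling a Mendelian
maternal gamete plus a pollen-pool gamete (pollen pool = grove frequencies,
selfing rate default 0), with the true pedigree returned for calibration.
It reproduces the feature that matters for pruning — maternal half-sib
families nested in groves — but not spatial sub-structure within groves,
genotyping error, or null alleles; passing tests therefore validate the
estimator and the pruning algorithm, not robustness to scoring artifacts.
Pseudo-observed datasets wrap the coalescent simulator with recorded truth;
the default truth vector is the published posterior-median fit of the
simultaneous-divergence scenario, and default per-deme sample sizes mirror
the pooled grove sampling (200/19/44/16/50).

## Problem sizes and numerical choices

The validation suite runs at desk scale by design: reference tables of
2 x 10^4 simulations per scenario (the production-scale analysis this
mirrors used 4 x 10^6), 50 pseudo-observed datasets for selection-rate and
coverage checks, 500 replicates for permutation-test calibration, and
10^3-10^4 replicates for coalescent expectations. Permutation p-values use
the +1 correction and are therefore slightly conservative; calibration tests
assert the nominal rate within a binomial band rather than exact uniformity.
Ties in the HWE probability ordering are resolved with a 1e-9 log-domain
slack. Degenerate cases return NaN and are flagged rather than silently
dropped: monomorphic loci in the HWE/LD tests, R_ST of datasets with no
size variance, populations below two individuals for H_E.

## Known limitations

* No migration after divergence, no admixture events; the scenario space is
  exactly the four histories above.
* The DIYABC single-nucleotide-indel mutation component is not modeled.
* Logistic model-choice CIs use the asymptotic covariance, which understates
  uncertainty when the retained set is small or nearly separable (the
  fallback rejection CI is then wider and more honest).
* Allelic richness requires `2g` genes after missing-data removal; loci
  below that are excluded from the mean, which can bias comparisons across
  populations with very different missingness.
* The orchard generator's panmictic pollen pool understates relatedness when
  pollen dispersal is spatially limited.
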