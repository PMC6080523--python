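# Methods

## Model

The package analyzes one trait at a time under the repeatability animal
model `y = Xb + Za + Wp + e`. Fixed effects are a single
contemporary-group factor (in the motivating application the cross of
AI station x year x month of collection) plus two record-level
covariates (collection interval in days, boar age in months), with the
first factor level dropped and an intercept retained; covariates are
centered at build time. Random effects are the additive genetic effect
`a ~ N(0, K s2a)` — `K` being either the pedigree matrix `A` or the
single-step matrix `H` — a permanent-environment effect per recorded
animal `p ~ N(0, I s2p)`, and an iid residual. Traits that are strongly
right-skewed (e.g. sperm-cell counts) are expected to arrive
log-transformed; the model makes no transformation itself.

`A` is built by the tabular method with inbreeding accumulated on the
diagonal; its inverse uses Henderson's rules with Mendelian-sampling
variances `0.5 - 0.25 (F_s + F_d)` (an unknown parent contributes as an
unrelated, non-inbred base animal). Pedigree pruning is ancestor
closure of the phenotyped-or-genotyped set — the only definition used
anywhere in the package. All matrices are dense and carry explicit id
orderings; the intended scale is desk-sized (10^3–10^4 animals), not
national evaluations.

## Genomic matrices and the centering subtlety

`G = Z D Z' * lambda` with `lambda = 1 / sum_i 2 p_i (1 - p_i)`. After
QC every SNP is recoded so the counted allele is the minor one, making
the centering frequency the minor allele frequency. When `p` is
estimated from exactly the animals that enter `G`, the columns of `Z`
sum to zero and `G` is *exactly* singular (`G 1 = 0`); this is a
property of the construction, not an implementation accident. Two
remedies are exposed:

- `blend_alpha` (default 0.05): replace `G` by
  `(1 - alpha) G + alpha A22`, the standard single-step safeguard;
- `freq_source="base"`: center on base-population allele frequencies
  when they are available (the simulator records its founder-pool
  frequencies on the panel). Sample frequencies then differ from the
  centering frequencies almost surely, `G` is invertible unblended, and
  the decomposition identity `Z u = a_g` holds to machine precision —
  the configuration used by the identity checks.

Matrix inverses are dense Cholesky factorizations with an explicit
pivot-ratio guard; a singular matrix raises (never a silent
pseudo-inverse). LAPACK's `potrf` can return a tiny positive pivot on
an exactly singular matrix, so the guard is load-bearing.

## REML

Variance components `(s2a, s2p, s2e)` are estimated by EM-REML with
average-information acceleration: three EM warm-up steps, then AI
Newton steps accepted only if they stay in the parameter space and do
not decrease the restricted likelihood, with EM as fallback. EM updates
can never go negative, which keeps the maximizer stable near
boundaries. Convergence is a relative parameter change below 1e-8; a
component collapsing toward zero is pinned at the floor, flagged
(`at_boundary`), and excluded from the convergence test — otherwise its
geometric decay would stall the loop. Standard errors come from the
inverse AI matrix (delta method for h2). The restricted likelihood is
evaluated through the mixed-model equations
(`-2l = log|R| + log|G_u| + log|C| + y'Py`), so no `V` matrix is ever
formed. Components are estimated once at `D = I` and held fixed across
the weighting iterations; the reported window percentages therefore use
the unweighted s2a, matching a single variance-component estimation per
trait.

## The weighting loop

Each iteration rebuilds `G` from the current weights, re-solves the
mixed-model equations, back-solves SNP effects, then squares and
renormalizes the weights (`trace(D) = M` after every update, conserving
total genetic variance). The back-solve uses the same (possibly
blended) `G` whose inverse entered `H^-1` — using a different matrix
would break the decomposition identity even unblended. The loop runs a
fixed three iterations; weight collapse onto a single SNP (> 99.9% of
the trace) warns but continues. All per-iteration states are retained.

Windows are a greedy non-overlapping partition per chromosome: a window
opens at the first unassigned SNP and absorbs consecutive SNPs strictly
within 0.4 Mb of its start; the midpoint is the mean of the first and
last member positions. Window variance is the population variance
(denominator n, `ddof=0` by default) of the window genetic value across
genotyped animals. Selection takes windows at >= 1% of genetic
variance; merging is single linkage on the strict `< 0.4 Mb` midpoint
rule (chains merge transitively), so results are independent of input
order. Top-3 regions are flanked 0.4 Mb either side of the midpoint and
clipped at 1 bp. Internal coordinates are 0-based half-open; all
reports are 1-based inclusive, stated in their headers.

## The synthetic-data generator

The generator emulates a commercial boar line at desk scale and is the
basis of every test:

- **Pedigree**: founders plus discrete cohorts mated at random from all
  earlier generations; both sexes forced present in every cohort.
  Defaults put a broad base (~200 founders behind ~500 recorded boars
  in the power studies), reflecting that breeding-program pedigrees are
  wide rather than deep; a narrow founder base makes family structure,
  not QTL, dominate the Manhattan profile.
- **Genotypes**: per 0.4 Mb block, founder haplotypes are drawn from a
  pool of 8 ancestral haplotypes (every SNP polymorphic in the pool);
  meioses place one crossover per chromosome uniformly over block
  boundaries. This yields within-block LD clearly above cross-block LD
  at chip-like SNP density (~1 SNP / 60 kb, ~7 SNPs per window). An
  optional `haplotype_diversity` rate adds per-SNP deviations from the
  pool haplotype to weaken within-block LD; default 0.
- **Phenotypes**: total random variance is scaled to 1 with
  `s2a = h2`, `s2p = rep - h2`, `s2e = 1 - rep`. True breeding values
  are QTL effects at designated SNPs plus a *marker-mediated* polygenic
  background (small effects at every non-QTL SNP), so the genetic
  signal is in principle recoverable from the chip — the configuration
  a null-calibration of window percentages presupposes. Planted QTL
  are drawn from common SNPs (MAF >= 0.2): chip markers are ascertained
  for common variation, and a fixed variance fraction at a rare variant
  would concentrate in a handful of carriers the surrounding block tags
  poorly. Ejaculate counts per boar follow a clipped negative binomial
  (dispersion 3, default range 10–50, mean 25) — the distribution is a
  package decision since only means/SDs are typically published.
  Realized TBV, permanent-environment and residual samples are
  rescaled to their exact target variances (the TBV target is
  `s2a * (tr(A)/n - 1'A1/n^2)` over the phenotyped set, the
  A-consistent expectation of a sample variance among relatives), so
  recovery tests measure estimator behaviour rather than Monte-Carlo
  luck. One seed drives all stages through fixed SeedSequence streams.

What the generator does *not* emulate: realistic recombination maps and
mutation, selection across generations, sex chromosomes, genotyping
batch structure, or cross-chip imputation. Passing tests therefore show
the machinery is correct under the stated statistical structure, not
that field data meet that structure.

## Numerical and design choices

- Mixed-model equations are assembled dense (`C` of order
  p + animals + recorded animals) and solved by Cholesky; MME residuals
  above 1e-8 relative are flagged on the solutions object.
- QC filter order is fixed and logged: unmapped/sex-chromosome SNPs,
  SNP call rate < 0.95, MAF < 0.01, Hardy-Weinberg chi2 > 600 (1-df
  goodness-of-fit; an unbounded statistic is the only reading
  compatible with a threshold of 600), then animals > 5% missing.
  Surviving missing genotypes are mean-imputed (2p). Re-applying QC to
  its own output removes nothing.
- The HWE chi2 of a monomorphic SNP is 0 by convention; the MAF filter
  is the one that removes it. Note chi2 at full disequilibrium is ~n,
  so the 600 threshold only bites at chip-scale sample sizes.
- Tie-breaks: top-k windows rank by (-percentage, chromosome, start).
- `run_wssgwas` rebuilds `G`, then GEBV, then SNP effects within each
  iteration; every state is kept so the alternative reading (effects
  from the previous `G`) can be inspected post hoc.

## Known limitations

- The weighting iteration concentrates window variance by construction.
  Under a pure polygene the largest window's percentage typically
  reaches 5–15x the equal-contribution expectation by iteration 3 even
  though the largest *true* window share is 3–5x (unequal SNP counts
  per window plus LD covariance); window percentages after weighting
  are a localization signal, not an unbiased variance decomposition,
  and no formal significance test exists for them.
- Localization power is honest but finite: a QTL at 10% of the genetic
  variance on ~500 genotyped-and-recorded animals lands in the top
  three windows in roughly 9 of 10 replicates; rarer or smaller QTL
  degrade quickly.
- Dense algebra bounds practical size at roughly 10^4 animals / 10^5
  SNPs; no APY-style approximations are provided.
- Single-trait only: no multi-trait models, genetic correlations,
  dominance, or maternal effects.
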