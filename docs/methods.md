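# Methods

This note records the models, algorithmic conventions, numerical
choices and known limitations behind `epifilter`. Everything stated
here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from elsewhere.

## ReliefF on categorical genotypes

Genotypes are categorical codes {0, 1, 2} (minor-allele count). The
per-SNP difference between two samples is the 0/1 equality test, and
the distance between samples is the Hamming distance over the current
SNP set — an integer in [0, N]. For each target sample, taken
exhaustively in presentation order, the K nearest same-class samples
("hits") and K nearest opposite-class samples ("misses") are selected,
the target itself excluded; every (target, neighbour) pair updates each
SNP's weight by −diff/(M·K) for hits and +diff/(M·K) for misses.

Conventions that matter:

- **Normalization.** Dividing each of the K updates by M·K (rather
  than M alone) keeps every weight in [−1, 1] for any K. The rescaling
  is uniform across SNPs, so rankings — the only thing consumed
  downstream — are unchanged.
- **Tie rule.** Neighbour candidates are ordered by (distance, current
  position) and the first K kept. Integer distances tie frequently, so
  this selection depends on presentation order — deliberately: this is
  the documented behaviour of the classical implementations that the
  ensemble exists to repair. A target is flagged *tie-causing* when
  more than K candidates (on either side) lie at or within the K-th
  neighbour distance.
- **Exact arithmetic.** Weights are accumulated as integers and divided
  once at the end. Two runs that select identical neighbour sets
  therefore produce bit-identical weights regardless of summation
  order; order invariance can be asserted exactly, not approximately.
  Pairwise distances come from per-genotype indicator Gram matrices
  (float32 BLAS; counts < 2²⁴, hence exact).

SURF replaces rank-based selection with a distance threshold (default:
the mean off-diagonal pairwise distance), making neighbour sets
order-invariant by construction. Each target contributes (mean miss
difference − mean hit difference)/M, averaging within each side over
its own neighbour count; an empty side contributes nothing. This
per-side averaging matches the classical ReliefF update in the
balanced case (the 4-sample worked toy gives W = (+1, −1) under both
K = 1 ReliefF and threshold-1.5 SURF) and keeps weights in [−1, 1].
SURF weights are summed in canonical sample-id order so they too are
bit-identical across presentation orders.

## TuRF

TuRF runs R = 10 scoring passes, discarding the floor(N/R)
lowest-weighted surviving SNPs after each of the first R−1 passes and
any remainder (N mod R) after the last; for N = 1000 this removes 100
per iteration and scores 100 survivors in the final pass. Distances
are recomputed on the surviving SNPs each iteration (implemented by
downdating the Gram matrices, which costs proportional to the SNPs
*removed* rather than those kept). Removal ties in weight discard the
higher SNP index first, mirroring the ranking tie rule.

The algorithm only scores survivors, but percentile-based evaluation
needs a rank for every SNP. The composite ranking places survivors
first (by final weights), then removed SNPs in blocks by removal
iteration — later removal ranks better — ordered within a block by
weight at removal. Rationale: a SNP discarded early was judged least
discriminative while the most noise was present; this matches how
iterative-filter output is consumed for dimensionality reduction.

## Ensemble filters (ReliefF-E, TuRF-E)

L = 50 copies of the dataset are produced by uniformly permuting the
sample order (seed per member derived from a master seed via a seed
sequence and recorded in the result); the base filter runs once per
copy and the per-SNP *ranks* are averaged; the final ranking sorts by
ascending mean rank, ties by SNP index. Ranks, not weights, are the
aggregation currency: TuRF weights from different runs live on
different surviving subsets and are not comparable. Member runs are
independent and the mean is order-insensitive, so concurrent execution
cannot change the result.

For TuRF-E the default aggregates each member run's composite final
ranking. An alternative reading — averaging all R·L per-iteration
rankings, removed SNPs carrying their block rank — is implemented as
`per_iteration=True`; both are exposed rather than guessing a single
intent, and the default was chosen because the final composite is the
ranking a practitioner would otherwise have used from one run.

## Univariate comparators

The χ² filter ranks by the Pearson statistic of the 2×3 genotype-class
table (zero-margin genotype columns dropped; statistic, not p-value, to
avoid underflow at large effects and because the two are monotone at
fixed df). The odds-ratio filter uses the allelic 2×2 table (each
sample contributes two alleles), Haldane–Anscombe 0.5 correction when
any cell is zero, and ranks by |ln OR| so risk and protective deviations
count equally. Both depend on counts only and are exactly
order-invariant.

## Synthetic benchmark data

Each dataset has one functional pair ("X0", "X1") governed by a 3×3
penetrance table f(a,b) = P(case | genotypes a, b), plus independent
HWE noise SNPs distributed identically in cases and controls. Tables
are constructed by rejection: draw a random 3×3 deviation, project onto
the zero-marginal-effect subspace by HWE-weighted double centering
(every row and column of penetrances, HWE-averaged, then equals the
prevalence exactly), rescale deviations to the target heritability
h² = Σ π_a π_b (f_ab − K)² / (K(1−K)), and accept when all entries lie
in [0, 1]. Emitted models satisfy the prevalence, marginality and
heritability constraints to 1e−6. Case/control rows are filled by
rejection sampling on the functional genotypes (case with probability
f_ab), giving exact balanced quotas as in a retrospective design.

Defaults: MAF 0.4 and prevalence 0.25 for all loci. The achievable
heritability of a marginal-effect-free two-locus model is bounded by
(MAF, prevalence); numerical maximization shows the ceiling is ≈ 0.12
at (0.2, 0.1) but ≈ 0.39 at (0.4, 0.25), so the chosen defaults admit
the full benchmark range h² ∈ {0.05, 0.1, 0.2, 0.3} with headroom.
Both parameters are config-exposed and recorded in simulation sidecars.

What the generator does *not* emulate: linkage disequilibrium,
per-SNP MAF variation, genotyping error, missingness, covariates, or
main-effect loci. Passing tests therefore demonstrate behaviour on
idealized panels with a single clean epistatic signal; real GWAS data
add confounders the benchmark deliberately excludes.

## Evaluation protocol

- **Stability**: Pearson r between the rank vectors of two runs under
  different sample orders, by default on log₁₀-transformed ranks
  (weights agreement at the top of the ranking); raw-rank r is also
  reported. Identical rank vectors short-circuit to exactly 1.0.
- **Success rate**: percent of datasets in a collection where *both*
  functional SNPs rank within the top round(N·q/100) at percentile q
  (retaining one member of an interacting pair is useless downstream).
  ACSR is the mean over percentiles 1–50.
- **Tie removal**: removal of tie-causing samples iterates to a fixed
  point because removal reshapes candidate sets. On 1000-SNP panels the
  integer distance lattice is coarse (≈ 90 distinct values for ≈ 200
  candidates), so most samples are tie-causing and removing every
  flagged sample at once empties a class; instead flagged samples are
  removed a few at a time
  in seeded random order, never taking a class below K+1, with
  restarts at dead ends. A 400-sample dataset typically keeps ≈ 11
  samples per class — removal is aggressive, which is precisely the
  cost that motivates the ensemble approach instead.

## Known limitations

- **Exact TuRF invariance after tie removal.** ReliefF on a
  tie-removed dataset is exactly order-invariant (asserted
  bit-identically). TuRF is not guaranteed to be: it recomputes
  distances on shrinking SNP subsets (down to N/R SNPs), where the
  distance lattice is coarser and new ties appear. A search over
  feasible 11+11-sample subsets (simulated annealing, 60k moves) could
  not eliminate ties across all ten TuRF iterations at N = 1000;
  measured permuted-run TuRF correlation after removal is ≈ 0.99, not
  exactly 1. Exact TuRF invariance is expected only when the distance
  lattice stays fine at every iteration, i.e. for panels with far more
  SNPs (e.g. 10⁵-scale real GWAS data, where even the last iteration
  keeps 10⁴ SNPs).
- **Problem sizes.** The test suite and acceptance script run at desk
  scale by design: stability targets use one dataset per sample size
  with L = 50 (400 samples) and L = 30 (800 samples); the near-ceiling
  retention check uses 10 datasets × L = 10 at h² = 0.3; the
  method-ordering check uses 20 datasets × L = 10 per heritability.
  Larger collections tighten the stochastic estimates but do not change
  the orderings.
- Odds-ratio details (allelic table, |ln OR|) are one reasonable
  convention among several; absolute univariate ACSR values depend
  mildly on it, the ordering against ReliefF-family filters does not.
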