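# epifilter

Ensemble SNP–SNP interaction filtering for case-control GWAS data.

## The problem

Two-step analyses of genome-wide association studies first *filter* the
SNP panel down to a tractable subset, then search that subset for
gene-gene interactions with combinatorial methods (MDR, random forests,
…). The filter is the weak link: univariate statistics (χ²-test, odds
ratio) are blind to SNP pairs that act purely epistatically — strong
joint effect, no marginal effect — and will happily discard exactly the
pairs the downstream search is looking for.

ReliefF-family filters keep such pairs because they score each SNP by
contrasting k-nearest-neighbour structure between cases and controls.
For a target sample *s_i* with *k*-th nearest hit *h_k* (same class) and
miss *m_k* (opposite class), each SNP *g_j* is updated

    W(g_j) ← W(g_j) − D(g_j, s_i, h_k)/(MK) + D(g_j, s_i, m_k)/(MK)

where *D* is the 0/1 genotype difference and distance is the Hamming
distance over genotype codes {0,1,2}. TuRF iterates ReliefF *R* times,
discarding the *N/R* lowest-weighted SNPs per iteration to sharpen the
signal-to-noise ratio.

But on categorical genotypes the integer-valued distances tie
constantly: whenever more than *K* candidates sit at or within the
*K*-th neighbour distance, the forced choice of exactly *K* of them
depends on the order in which samples appear in the file. ReliefF and
(much more severely) TuRF therefore return *different SNP rankings when
the rows of the dataset are shuffled*.

## The method

The ensemble filters ReliefF-E and TuRF-E turn that instability into
signal. They run the base filter on *L* copies of the dataset with
independently permuted sample order and average the per-run **ranks**:

    W_ensemble(g_j) = (1/L) · Σ_l rank(h_l(g_j), D_l)

Each permuted run samples a different resolution of the neighbour ties,
so the aggregate uses the full neighbourhood information. The final
ranking (ascending mean rank) is far more stable between runs, and
retains functional epistatic pairs better than any single run.

The package provides:

- `data`: the MDR flat-file format (tab-delimited genotypes 0/1/2 with a
  trailing `Class` column), sample-order permutation, rank construction;
- `relieff`: ReliefF with the order-dependent first-K tie rule it
  deliberately reproduces, and SURF (distance-threshold neighbours);
- `turf`: TuRF and SURFTuRF with per-iteration traces;
- `ensemble`: rank aggregation, ReliefF-E, TuRF-E;
- `univariate`: χ²-test and allelic odds-ratio comparators;
- `simulate`: two-locus penetrance-model benchmarks — balanced
  case/control panels, 1000 SNPs, one purely epistatic pair "X0"/"X1"
  at heritabilities 0.05–0.3 (models `Epistatic_{400,800}_{0.05..0.3}`);
- `evaluate`: stability correlations, tie-causing-sample removal,
  percentile success rates and the average cumulative success rate
  (ACSR, mean success over percentiles 1–50).

## Worked example

```python
from epifilter import (
    ensemble_filter, make_penetrance_model, model_config, permute_samples,
    rank_correlation, simulate_dataset, turf_ranking,
)

cfg = model_config("Epistatic_400_0.3", seed=1)          # 200 cases / 200 controls
model = make_penetrance_model(cfg.h2, cfg.maf, cfg.prevalence, seed=2)
data = simulate_dataset(cfg, model, seed=3)              # 1000 SNPs, pair X0/X1

t1, _ = turf_ranking(permute_samples(data, 11))          # single TuRF, order A
t2, _ = turf_ranking(permute_samples(data, 22))          # single TuRF, order B
print("single TuRF r:", round(rank_correlation(t1, t2), 3))

e1 = ensemble_filter(data, "turf", L=50, master_seed=100)
e2 = ensemble_filter(data, "turf", L=50, master_seed=200)
print("TuRF-E    r:", round(rank_correlation(
    e1.final_ranking, e2.final_ranking), 3))
print("pair ranks:", e1.final_ranking.rank_of("X0"),
      e1.final_ranking.rank_of("X1"))
```

prints

```
single TuRF r: 0.593
TuRF-E    r: 0.985
pair ranks: 2 1
```

Two single TuRF runs disagree badly once the sample order changes
(Pearson r ≈ 0.59 between their log₁₀-rank vectors), while two fully
independent 50-member ensembles agree at r ≈ 0.99 — and place the
functional pair at the very top of 1000 SNPs.

The same workflow is available from the shell:

```sh
epifilter simulate --model Epistatic_400_0.1 --n 1 --seed 1 --out sim/
epifilter filter sim/Epistatic_400_0.1_0.txt --method turf-e --l 50 --seed 1
epifilter evaluate sim/Epistatic_400_0.1_0.txt --mode stability \
    --method turf-e --seed 1 --out stability.json
```

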