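"""Ensemble ReliefF / TuRF: rank aggregation over permuted sample orders.

A single ReliefF or TuRF run uses only one arbitrary resolution of the
k-NN distance ties, so its ranking reflects a partial sample of the
neighbourhood information in the data. The ensemble filters (ReliefF-E,
TuRF-E) run the base filter on L copies of the dataset whose sample
order has been independently permuted, and average the per-run *ranks*
of each SNP:

    W_ensemble(g_j) = (1/L) * sum_l rank(h_l(g_j), D_l)

Ranks — not weights — are the aggregation currency: TuRF weights from
different runs live on different surviving SNP subsets and are not
comparable, whereas ranks always are. The final ranking sorts SNPs by
ascending mean rank (lower = better), ties broken by SNP index.

Member runs are mutually independent; each permutation seed is derived
deterministically from the master seed and recorded, so any single
member is re-derivable and the whole ensemble is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeDataset, SnpRanking, permute_samples, weights_to_ranking
from .relieff import relieff_weights
from .turf import iteration_rankings, turf_ranking

__all__ = ["EnsembleResult", "aggregate_ranks", "ensemble_filter", "member_seeds"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleResult:
    """Aggregated outcome of L permuted base-filter runs."""

    mean_ranks: np.ndarray
    per_run_rankings: tuple[SnpRanking, ...]
    final_ranking: SnpRanking
    meta: dict = field(default_factory=dict)


def aggregate_ranks(rankings: list[SnpRanking], meta: dict | None = None) -> EnsembleResult:
    """Average per-SNP ranks over runs and rank by ascending mean.

    All rankings must cover the same SNP set; each SNP's mean rank lies
    in [1, N] and the mean ranks sum to N(N+1)/2 exactly, since every
    member ranking is a permutation of 1..N.
    """
    if not rankings:
        raise ValueError("need at least one ranking to aggregate")
    ref = rankings[0].snp_names
    n = len(ref)
    total = np.zeros(n, dtype=np.int64)
    for rk in rankings:
        if rk.snp_names == ref:
            total += rk.ranks
        elif set(rk.snp_names) == set(ref):
            pos = {s: j for j, s in enumerate(rk.snp_names)}
            total += rk.ranks[[pos[s] for s in ref]]
        else:
            raise ValueError("rankings cover different SNP sets")
    mean_ranks = total / len(rankings)
    order = np.lexsort((np.arange(n), mean_ranks))
    final = np.empty(n, dtype=np.int64)
    final[order] = np.arange(1, n + 1)
    meta = dict(meta or {})
    meta.setdefault("L", len(rankings))
    return EnsembleResult(
        mean_ranks=mean_ranks,
        per_run_rankings=tuple(rankings),
        final_ranking=SnpRanking(ranks=final, snp_names=ref, meta=meta),
        meta=meta,
    )


def member_seeds(master_seed: int, L: int) -> np.ndarray:
    """L permutation seeds derived deterministically from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(L, dtype=np.uint32) & 0x7FFFFFFF


def ensemble_filter(
    dataset: GenotypeDataset,
    base: str = "turf",
    L: int = 50,
    K: int = 10,
    R: int = 10,
    master_seed: int = 0,
    *,
    per_iteration: bool = False,
) -> EnsembleResult:
    """ReliefF-E (``base="relieff"``) or TuRF-E (``base="turf"``).

    Runs the base filter once per sample-order-permuted copy and
    aggregates with :func:`aggregate_ranks`. For TuRF-E the default
    aggregates each run's composite final ranking; ``per_iteration=True``
    instead averages over all R*L per-iteration rankings (removed SNPs
    carrying their removal-block rank).
    """
    if L < 1:
        raise ValueError("ensemble size L must be >= 1")
    if base not in ("relieff", "turf"):
        raise ValueError(f"unknown base filter {base!r}")
    seeds = member_seeds(master_seed, L)
    log.debug("ensemble %s-e: member permutation seeds %s",
              base, [int(x) for x in seeds])
    rankings: list[SnpRanking] = []
    for seed in seeds:
        permuted = permute_samples(dataset, int(seed))
        if base == "relieff":
            wv = relieff_weights(permuted, K)
            rk = weights_to_ranking(wv)
            rk = SnpRanking(
                ranks=rk.ranks, snp_names=rk.snp_names,
                meta={**rk.meta, "permutation_seed": int(seed)},
            )
            rankings.append(rk)
        else:
            ranking, trace = turf_ranking(permuted, R=R, K=K)
            if per_iteration:
                rankings.extend(iteration_rankings(permuted, trace))
            else:
                rankings.append(
                    SnpRanking(
                        ranks=ranking.ranks,
                        snp_names=ranking.snp_names,
                        removal_iteration=ranking.removal_iteration,
                        meta={**ranking.meta, "permutation_seed": int(seed)},
                    )
                )
    meta = {
        "filter": f"{base}-e",
        "base": base,
        "L": L,
        "K": K,
        "R": R if base == "turf" else None,
        "master_seed": master_seed,
        "member_seeds": [int(s) for s in seeds],
        "per_iteration": per_iteration,
    }
    return aggregate_ranks(rankings, meta=meta)
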