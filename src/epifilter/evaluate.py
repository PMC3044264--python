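"""Evaluation protocol: ranking stability, tie removal, success rates.

Two complementary questions are asked of a SNP filter. *Stability*: does
it return the same ranking when the samples are presented in a different
order? Measured as the Pearson correlation r between the rank vectors of
two permuted runs (ranks are log10-transformed by default, which weights
agreement at the top of the ranking where filtering decisions happen).
*Power*: does it retain the functional SNP pair when the dataset is cut
to its top percentile? Summarised by the success rate per percentile and
the average cumulative success rate (ACSR) over percentiles 1-50.

The module also locates and removes *tie-causing samples* — targets for
which more than K candidates sit at or within the K-th neighbour
distance, making the k-NN hit/miss choice order-dependent. Removing all
of them (iterated to a fixed point, since each removal reshapes the
candidate sets) makes ReliefF and TuRF exactly order-invariant, at the
price of discarding data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeDataset, SnpRanking
from .ensemble import ensemble_filter
from .relieff import relieff_scan

__all__ = [
    "StabilityReport",
    "SuccessCurve",
    "rank_correlation",
    "stability_report",
    "find_tie_causing_samples",
    "remove_tie_samples",
    "percentile_cutoff",
    "success_rate",
    "success_curve",
    "avg_cumulative_success",
    "ensemble_size_sweep",
]


@dataclass(frozen=True)
class StabilityReport:
    """Rank agreement between two runs of the same filter."""

    pearson_r_raw: float
    pearson_r_log10: float
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SuccessCurve:
    """Success rate (percent) per percentile 1..50 plus its mean (ACSR)."""

    percentiles: tuple[int, ...]
    rates: tuple[float, ...]
    acsr: float
    meta: dict = field(default_factory=dict)


def rank_correlation(
    r1: SnpRanking, r2: SnpRanking, log10_transform: bool = True
) -> float:
    """Pearson r between two rank vectors over the same SNP set."""
    if set(r1.snp_names) != set(r2.snp_names):
        raise ValueError("rankings cover different SNP sets")
    a = r1.ranks.astype(np.float64)
    if r2.snp_names == r1.snp_names:
        b = r2.ranks.astype(np.float64)
    else:
        pos = {s: j for j, s in enumerate(r2.snp_names)}
        b = r2.ranks[[pos[s] for s in r1.snp_names]].astype(np.float64)
    if np.array_equal(a, b):
        return 1.0  # exact: identical rank vectors correlate perfectly
    if log10_transform:
        a = np.log10(a)
        b = np.log10(b)
    return float(np.corrcoef(a, b)[0, 1])


def stability_report(
    r1: SnpRanking, r2: SnpRanking, meta: dict | None = None
) -> StabilityReport:
    return StabilityReport(
        pearson_r_raw=rank_correlation(r1, r2, log10_transform=False),
        pearson_r_log10=rank_correlation(r1, r2, log10_transform=True),
        meta=dict(meta or {}),
    )


def find_tie_causing_samples(
    dataset: GenotypeDataset, K: int = 10
) -> set[str]:
    """Sample ids whose hit or miss k-NN selection is order-dependent."""
    _, tie_flags = relieff_scan(dataset, K)
    return {dataset.sample_ids[i] for i in np.flatnonzero(tie_flags)}


def remove_tie_samples(
    dataset: GenotypeDataset,
    K: int = 10,
    seed: int = 0,
    max_restarts: int = 50,
) -> GenotypeDataset:
    """Iteratively remove tie-causing samples until none remain.

    A removal pass can create new ties (the candidate sets shrink), so
    removal repeats to a fixed point. On datasets with few SNPs the
    integer Hamming lattice is coarse and most samples are tie-causing,
    so removing every flagged sample at once would empty a class;
    instead flagged samples are removed a few at a time, in seeded
    random order, never taking a class below K+1 members (the ReliefF
    minimum), with restarts if a dead end is reached. The result is
    tie-free at this K for the full SNP set — ReliefF on it is exactly
    order-invariant. Removal is typically aggressive (a 400-sample,
    1000-SNP dataset keeps roughly K+1 samples per class).

    Note: TuRF recomputes distances on shrinking SNP subsets, where new
    ties can appear even on output of this function; exact TuRF
    invariance additionally needs a fine distance lattice (many SNPs).
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        result = _try_remove_ties(dataset, K, rng)
        if result is not None:
            return result
    raise ValueError(
        f"could not reach a tie-free sample subset at K={K}; "
        "dataset too tie-ridden"
    )


def _try_remove_ties(
    dataset: GenotypeDataset, K: int, rng: np.random.Generator
) -> GenotypeDataset | None:
    current = dataset
    while True:
        _, tie_flags = relieff_scan(current, K)
        flagged = np.flatnonzero(tie_flags)
        if flagged.size == 0:
            return current
        y = current.labels
        counts = {cls: int((y == cls).sum()) for cls in (0, 1)}
        removable = [i for i in flagged if counts[int(y[i])] > K + 1]
        if not removable:
            return None  # dead end: flagged samples all at the class floor
        # slack above the floor governs how boldly we may remove
        slack = sum(c - (K + 1) for c in counts.values())
        batch = max(1, min(len(removable) // 3, slack // 3)) if slack > 4 * K else 1
        rng.shuffle(removable)
        drop: set[int] = set()
        for i in removable:
            if len(drop) >= batch:
                break
            if counts[int(y[i])] > K + 1:
                drop.add(i)
                counts[int(y[i])] -= 1
        keep = [i for i in range(current.n_samples) if i not in drop]
        current = current.take_samples(keep)


def percentile_cutoff(n_snps: int, percentile: int) -> int:
    """Top-list size at a percentile: round(n_snps * percentile / 100)."""
    if not 1 <= percentile <= 100:
        raise ValueError("percentile must be in 1..100")
    return int(np.floor(n_snps * percentile / 100 + 0.5))


def success_rate(
    rankings: list[SnpRanking],
    functional_pair: tuple[str, str],
    percentile: int,
) -> float:
    """Percent of datasets whose rankings keep BOTH pair members.

    A dataset counts as a success only when both functional SNPs rank
    within the percentile cutoff — retaining one of an interacting pair
    is useless for downstream pairwise search.
    """
    a, b = functional_pair
    hits = 0
    for rk in rankings:
        if a not in rk.snp_names or b not in rk.snp_names:
            raise ValueError(f"ranking lacks functional pair {functional_pair}")
        cut = percentile_cutoff(len(rk.snp_names), percentile)
        if rk.rank_of(a) <= cut and rk.rank_of(b) <= cut:
            hits += 1
    return 100.0 * hits / len(rankings)


def success_curve(
    rankings: list[SnpRanking],
    functional_pair: tuple[str, str] = ("X0", "X1"),
    percentiles: range = range(1, 51),
    meta: dict | None = None,
) -> SuccessCurve:
    rates = tuple(
        success_rate(rankings, functional_pair, p) for p in percentiles
    )
    return SuccessCurve(
        percentiles=tuple(percentiles),
        rates=rates,
        acsr=float(np.mean(rates)),
        meta=dict(meta or {}),
    )


def avg_cumulative_success(curve: SuccessCurve) -> float:
    """Mean success rate over percentiles 1..50."""
    if tuple(curve.percentiles) != tuple(range(1, 51)):
        raise ValueError("ACSR is defined over percentiles 1..50")
    return float(np.mean(curve.rates))


def ensemble_size_sweep(
    dataset: GenotypeDataset,
    base: str = "turf",
    sizes: tuple[int, ...] = (10, 20, 30, 40, 50),
    seeds: tuple[int, int] = (0, 1),
    K: int = 10,
    R: int = 10,
) -> list[tuple[int, float]]:
    """Inter-run rank correlation of the ensemble filter per ensemble size.

    For each size L the ensemble is run twice with the two master seeds
    and the Pearson r of the final (log10) rankings is recorded; the
    curve shows where extra members stop improving stability.
    """
    out = []
    for L in sizes:
        r1 = ensemble_filter(dataset, base, L=L, K=K, R=R,
                             master_seed=seeds[0]).final_ranking
        r2 = ensemble_filter(dataset, base, L=L, K=K, R=R,
                             master_seed=seeds[1]).final_ranking
        out.append((L, rank_correlation(r1, r2)))
    return out
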