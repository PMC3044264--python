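"""TuRF: tuned ReliefF by iterative removal of low-ranked SNPs.

TuRF re-scores the surviving SNPs for R iterations, discarding the
floor(N/R) lowest-weighted SNPs after each scoring pass (any remainder
goes in the final iteration). Because pairwise distances are recomputed
on the surviving subset each iteration, removing noise SNPs sharpens the
neighbourhood structure and with it the weights of interacting SNPs —
that signal-to-noise gain is the point of the procedure.

The final output must rank *every* SNP (downstream filtering is
percentile-based), but the algorithm itself only scores survivors. The
composite ranking used here places the survivors of the last scoring
pass first, ordered by their final weights, followed by the removed SNPs
in blocks by removal iteration — later removal outranks earlier removal,
and within a block SNPs are ordered by their weight at the time of
removal. Weight ties are broken by SNP index when ranking and by
*reverse* index when removing, so the two rules agree on which SNP is
"worse".

SURFTuRF is the same schedule with the SURF core; its distance threshold
is recomputed each iteration on the surviving SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeDataset, SnpRanking, WeightVector
from .relieff import downdate_gram, match_gram, relieff_scan, surf_weights

__all__ = ["TurfTrace", "turf_ranking", "surfturf_ranking", "iteration_rankings"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TurfTrace:
    """Per-iteration record of a TuRF run.

    ``weights[i]`` scores the SNPs alive at iteration i (1-based);
    ``removed_snps[i]`` lists the names discarded right after that
    scoring, worst first.
    """

    weights: tuple[WeightVector, ...]
    removed_snps: tuple[tuple[str, ...], ...]
    R: int
    meta: dict = field(default_factory=dict)


def _removal_schedule(n: int, R: int) -> list[int]:
    """SNPs to discard after each of the R scoring passes.

    floor(N/R) per iteration; the remainder is removed in the final
    iteration, so N - (R-1)*floor(N/R) - remainder survive.
    """
    per = n // R
    return [per] * (R - 1) + [n - R * per]


def turf_ranking(
    dataset: GenotypeDataset,
    R: int = 10,
    K: int = 10,
    *,
    core: str = "relieff",
) -> tuple[SnpRanking, TurfTrace]:
    """Run TuRF and return the composite ranking plus the full trace.

    ``core`` selects the scoring pass: ``"relieff"`` (order-dependent
    first-K neighbour rule) or ``"surf"`` (order-invariant threshold
    rule, i.e. SURFTuRF).
    """
    if R < 2:
        raise ValueError("R must be at least 2")
    n = dataset.n_snps
    if n < R:
        raise ValueError(f"need at least R={R} SNPs, got {n}")
    if core not in ("relieff", "surf"):
        raise ValueError(f"unknown TuRF core {core!r}")

    X = dataset.genotypes
    alive = np.arange(n)
    gram = match_gram(X)
    schedule = _removal_schedule(n, R)

    iter_weights: list[WeightVector] = []
    removed_blocks: list[tuple[str, ...]] = []
    removed_weight: dict[int, float] = {}
    removed_iter = np.zeros(n, dtype=np.int64)

    for it, n_remove in enumerate(schedule, start=1):
        sub = dataset.select_snps(alive)
        dist = (alive.size - gram).astype(np.int32)
        if core == "relieff":
            int_w, _ = relieff_scan(sub, K, dist=dist)
            w = int_w / (sub.n_samples * K)
            wv = WeightVector(
                weights=w,
                snp_names=sub.snp_names,
                meta={"filter": "relieff", "K": K, "iteration": it},
            )
        else:
            wv = surf_weights(sub, dist=dist)
            w = wv.weights
        iter_weights.append(wv)

        if n_remove > 0:
            # worst first: lowest weight, ties -> higher original index
            order = np.lexsort((-alive, w))
            drop_local = order[:n_remove]
        else:
            drop_local = np.array([], dtype=np.intp)
        drop_global = alive[drop_local]
        if drop_global.size and log.isEnabledFor(logging.DEBUG):
            log.debug(
                "iteration %d: removed %d SNPs: %s", it, drop_global.size,
                ", ".join(dataset.snp_names[g] for g in drop_global[:10])
                + ("..." if drop_global.size > 10 else ""),
            )
        removed_blocks.append(tuple(dataset.snp_names[g] for g in drop_global))
        for lo, gl in zip(drop_local, drop_global):
            removed_weight[int(gl)] = float(w[lo])
            removed_iter[gl] = it
        keep = np.ones(alive.size, dtype=bool)
        keep[drop_local] = False
        if it < R:
            gram = downdate_gram(gram, X[:, alive[drop_local]])
        alive = alive[keep]
        final_weights = w[keep]

    # composite ranking: survivors by final weight, then removal blocks
    # (later iteration = better), within a block by weight at removal.
    # sort key: (block, -weight, index) with block 0 = survivors.
    n_alive = alive.size
    block = np.where(removed_iter == 0, 0, R + 1 - removed_iter)
    weight_key = np.empty(n, dtype=np.float64)
    weight_key[alive] = final_weights
    for g, w_at in removed_weight.items():
        weight_key[g] = w_at
    order = np.lexsort((np.arange(n), -weight_key, block))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)

    ranking = SnpRanking(
        ranks=ranks,
        snp_names=dataset.snp_names,
        removal_iteration=removed_iter,
        meta={"filter": "turf" if core == "relieff" else "surfturf",
              "R": R, "K": K, "n_survivors": int(n_alive)},
    )
    trace = TurfTrace(
        weights=tuple(iter_weights),
        removed_snps=tuple(removed_blocks),
        R=R,
        meta=dict(ranking.meta),
    )
    return ranking, trace


def surfturf_ranking(
    dataset: GenotypeDataset, R: int = 10
) -> tuple[SnpRanking, TurfTrace]:
    """TuRF with the SURF threshold core (sample-order invariant)."""
    return turf_ranking(dataset, R=R, core="surf")


def iteration_rankings(
    dataset: GenotypeDataset, trace: TurfTrace
) -> list[SnpRanking]:
    """One full-length ranking per TuRF iteration.

    At iteration i the SNPs alive at that scoring are ranked by their
    iteration-i weights; SNPs already removed keep their block position
    (later removal = better, within block by weight at removal). Used by
    the per-iteration aggregation mode of the TuRF ensemble.
    """
    n = dataset.n_snps
    name_to_idx = {s: j for j, s in enumerate(dataset.snp_names)}
    out: list[SnpRanking] = []
    block = np.zeros(n, dtype=np.int64)
    weight_key = np.zeros(n, dtype=np.float64)
    for it, wv in enumerate(trace.weights, start=1):
        for s, w in zip(wv.snp_names, wv.weights):
            weight_key[name_to_idx[s]] = w
        order = np.lexsort((np.arange(n), -weight_key, block))
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(1, n + 1)
        out.append(
            SnpRanking(
                ranks=ranks,
                snp_names=dataset.snp_names,
                meta={**trace.meta, "iteration": it},
            )
        )
        # removal after this iteration shifts existing blocks down
        removed_now = trace.removed_snps[it - 1]
        block[block > 0] += 1
        for s in removed_now:
            block[name_to_idx[s]] = 1
    return out
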