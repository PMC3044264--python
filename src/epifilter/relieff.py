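"""ReliefF-family SNP weighting on categorical genotype data.

ReliefF scores each SNP by contrasting, for every target sample, its K
nearest neighbours of the same class ("hits") against its K nearest
neighbours of the opposite class ("misses"): a SNP gains weight when it
separates the target from its misses and loses weight when it separates
the target from its hits. Distance between samples is the Hamming
distance over genotype codes, so distances are small integers and k-NN
ties are common. The baseline deliberately resolves those ties by taking
the first K candidates in the current presentation order — this is the
order-dependent behaviour the ensemble filters exist to repair, and the
per-neighbour ``tie_flag`` records exactly when it bites: a tie occurs
when more than K candidates lie at or within the K-th neighbour
distance.

SURF replaces the rank-based k-NN rule with a fixed distance threshold
(default: the mean pairwise distance), which makes the neighbour sets —
and hence the weights — independent of sample order by construction.

Implementation notes: pairwise Hamming distances are computed from
per-genotype indicator Gram matrices (three rank-M updates via BLAS);
counts stay below 2**24 so float32 arithmetic is exact. ReliefF weights
are accumulated as integers and divided once at the end, so two runs
that select identical neighbour sets produce bit-identical weights
regardless of summation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenotypeDataset, WeightVector

__all__ = [
    "NeighborSets",
    "genotype_diff",
    "sample_distance",
    "distance_matrix",
    "find_neighbors",
    "relieff_weights",
    "relieff_scan",
    "surf_threshold",
    "surf_neighbors",
    "surf_weights",
]


@dataclass(frozen=True)
class NeighborSets:
    """Hit/miss neighbour index lists for one target sample.

    ``tie_flag`` is true when, on either side, more candidates sat at or
    within the K-th neighbour distance than could be kept — i.e. the
    selection depended on presentation order.
    """

    hits: tuple[int, ...]
    misses: tuple[int, ...]
    tie_flag: bool


# ----------------------------------------------------------------------
# Distances
# ----------------------------------------------------------------------

def genotype_diff(g: int, a: np.ndarray, b: np.ndarray) -> int:
    """0/1 difference between two samples at SNP index ``g``.

    Genotypes are categorical here: any mismatch counts 1, regardless of
    allele-count distance.
    """
    return int(a[g] != b[g])


def sample_distance(a: np.ndarray, b: np.ndarray, snp_subset=None) -> int:
    """Hamming distance between two genotype vectors over ``snp_subset``."""
    a = np.asarray(a)
    b = np.asarray(b)
    if snp_subset is not None:
        idx = np.asarray(snp_subset, dtype=np.intp)
        if idx.size == 0:
            raise ValueError("snp_subset must be non-empty")
        a = a[idx]
        b = b[idx]
    elif a.size == 0:
        raise ValueError("samples must cover at least one SNP")
    return int((a != b).sum())


def match_gram(genotypes: np.ndarray) -> np.ndarray:
    """M x M matrix of per-pair genotype *match* counts (float32, exact).

    ``hamming = n_snps - match_gram``. Kept separate from the distance
    matrix because TuRF can downdate it cheaply when SNPs are removed
    (see :func:`downdate_gram`).
    """
    g = np.asarray(genotypes)
    m = g.shape[0]
    gram = np.zeros((m, m), dtype=np.float32)
    for code in (0, 1, 2):
        ind = (g == code).astype(np.float32)
        gram += ind @ ind.T
    return gram


def downdate_gram(gram: np.ndarray, removed: np.ndarray) -> np.ndarray:
    """Subtract removed SNP columns' match contributions from ``gram``."""
    r = np.asarray(removed)
    for code in (0, 1, 2):
        ind = (r == code).astype(np.float32)
        gram -= ind @ ind.T
    return gram


def distance_matrix(dataset: GenotypeDataset, snp_subset=None) -> np.ndarray:
    """Symmetric integer Hamming distance matrix over the given SNP subset."""
    g = dataset.genotypes
    if snp_subset is not None:
        g = g[:, np.asarray(snp_subset, dtype=np.intp)]
    n = g.shape[1]
    return (n - match_gram(g)).astype(np.int32)


# ----------------------------------------------------------------------
# Neighbour selection
# ----------------------------------------------------------------------

def find_neighbors(
    dist_row: np.ndarray,
    labels: np.ndarray,
    target: int,
    K: int,
) -> NeighborSets:
    """K hits and K misses of one target under the first-K tie rule.

    Candidates on each side are ordered by (distance, current sample
    position) and the first K are kept. This reproduces the presentation
    -order dependency of the classical implementation; ``tie_flag``
    reports whether order actually mattered for this target.
    """
    dist_row = np.asarray(dist_row)
    labels = np.asarray(labels)
    same = np.flatnonzero(labels == labels[target])
    same = same[same != target]
    other = np.flatnonzero(labels != labels[target])
    if same.size < K:
        raise ValueError(
            f"class of sample {target} has {same.size + 1} members; "
            f"needs > {K} for K={K} hit neighbours"
        )
    if other.size < K:
        raise ValueError(
            f"opposite class has {other.size} members; needs >= {K}"
        )
    hits, hit_tie = _first_k(dist_row, same, K)
    misses, miss_tie = _first_k(dist_row, other, K)
    return NeighborSets(
        hits=tuple(int(i) for i in hits),
        misses=tuple(int(i) for i in misses),
        tie_flag=bool(hit_tie or miss_tie),
    )


def _first_k(dist_row: np.ndarray, candidates: np.ndarray, K: int):
    d = dist_row[candidates]
    order = np.argsort(d, kind="stable")  # ties resolved by position
    chosen = candidates[order[:K]]
    kth = d[order[K - 1]]
    tie = candidates.size > K and d[order[K]] == kth
    return chosen, tie


# ----------------------------------------------------------------------
# ReliefF
# ----------------------------------------------------------------------

def relieff_scan(
    dataset: GenotypeDataset,
    K: int = 10,
    *,
    dist: np.ndarray | None = None,
    targets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One exhaustive ReliefF pass; returns integer weights and tie flags.

    ``int_weights[j]`` is the raw count ``sum_i sum_k D(j, s_i, m_k) -
    D(j, s_i, h_k)``; divide by (#targets * K) for the normalised weight.
    ``tie_flags[i]`` is true when target i's hit or miss selection was
    order-dependent. Targets are evaluated in presentation order; a
    subset may be supplied (random sample selection).
    """
    X = dataset.genotypes
    y = dataset.labels
    m, n = X.shape
    if dist is None:
        dist = distance_matrix(dataset)
    if targets is None:
        targets = np.arange(m)
    targets = np.asarray(targets, dtype=np.intp)

    for label in (0, 1):
        cls = int((y == label).sum())
        opp = m - cls
        if cls <= K or opp < K:
            raise ValueError(
                f"class {label} has {cls} samples (opposite {opp}); "
                f"both classes must exceed K={K}"
            )

    int_weights = np.zeros(n, dtype=np.int64)
    tie_flags = np.zeros(m, dtype=bool)
    target_set = np.zeros(m, dtype=bool)
    target_set[targets] = True

    idx = {label: np.flatnonzero(y == label) for label in (0, 1)}
    for label in (0, 1):
        members = idx[label]
        sel = members[target_set[members]]
        if sel.size == 0:
            continue
        others = idx[1 - label]
        # hits: same-class block, self pushed to front with sentinel -1
        block = dist[np.ix_(sel, members)].astype(np.int64)
        self_pos = np.searchsorted(members, sel)
        block[np.arange(sel.size), self_pos] = -1
        order = np.argsort(block, axis=1, kind="stable")
        sorted_d = np.take_along_axis(block, order, axis=1)
        hit_idx = members[order[:, 1 : K + 1]]
        hit_tie = (
            sorted_d[:, K + 1] == sorted_d[:, K]
            if members.size > K + 1
            else np.zeros(sel.size, dtype=bool)
        )
        # misses: opposite-class block
        mblock = dist[np.ix_(sel, others)].astype(np.int64)
        morder = np.argsort(mblock, axis=1, kind="stable")
        msorted = np.take_along_axis(mblock, morder, axis=1)
        miss_idx = others[morder[:, :K]]
        miss_tie = (
            msorted[:, K] == msorted[:, K - 1]
            if others.size > K
            else np.zeros(sel.size, dtype=bool)
        )
        tie_flags[sel] = hit_tie | miss_tie

        tgt = X[sel][:, None, :]  # (t, 1, n)
        hit_diff = (X[hit_idx] != tgt).sum(axis=1, dtype=np.int64)
        miss_diff = (X[miss_idx] != tgt).sum(axis=1, dtype=np.int64)
        int_weights += (miss_diff - hit_diff).sum(axis=0, dtype=np.int64)

    return int_weights, tie_flags


def relieff_weights(
    dataset: GenotypeDataset,
    K: int = 10,
    *,
    dist: np.ndarray | None = None,
    n_samples: int | None = None,
    seed: int | None = None,
) -> WeightVector:
    """ReliefF weights in [-1, 1], evaluated in presentation order.

    By default every sample is a target (exhaustive selection). Passing
    ``n_samples`` draws that many targets at random using ``seed``. Each
    of the K neighbour updates is divided by (#targets * K), which keeps
    the weights inside [-1, 1] for any K while preserving the ranking.
    """
    if n_samples is None:
        targets = None
        n_targets = dataset.n_samples
    else:
        if seed is None:
            raise ValueError("random sample selection requires a seed")
        rng = np.random.default_rng(seed)
        targets = np.sort(
            rng.choice(dataset.n_samples, size=n_samples, replace=False)
        )
        n_targets = n_samples
    int_weights, _ = relieff_scan(dataset, K, dist=dist, targets=targets)
    weights = int_weights / (n_targets * K)
    return WeightVector(
        weights=weights,
        snp_names=dataset.snp_names,
        meta={"filter": "relieff", "K": K, "n_targets": n_targets},
    )


# ----------------------------------------------------------------------
# SURF: threshold-based neighbours (order-invariant)
# ----------------------------------------------------------------------

def surf_threshold(dist: np.ndarray) -> float:
    """Mean off-diagonal pairwise distance — SURF's default threshold."""
    m = dist.shape[0]
    total = float(np.asarray(dist, dtype=np.float64).sum())
    return total / (m * (m - 1))


def surf_neighbors(
    dist: np.ndarray,
    labels: np.ndarray,
    target: int,
    threshold: float,
) -> NeighborSets:
    """All samples strictly within ``threshold`` of the target, split by class.

    Sizes vary per target and may be zero; no tie-breaking exists, so
    the result is invariant to sample order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels = np.asarray(labels)
    row = np.asarray(dist[target])
    near = np.flatnonzero(row < threshold)
    near = near[near != target]
    hits = near[labels[near] == labels[target]]
    misses = near[labels[near] != labels[target]]
    return NeighborSets(
        hits=tuple(int(i) for i in hits),
        misses=tuple(int(i) for i in misses),
        tie_flag=False,
    )


def surf_weights(
    dataset: GenotypeDataset,
    *,
    threshold: float | None = None,
    dist: np.ndarray | None = None,
) -> WeightVector:
    """SURF weights: ReliefF-style updates over all threshold neighbours.

    Each target contributes (mean miss difference - mean hit difference)
    / M, averaging within each side over that target's neighbour counts;
    an empty side contributes nothing. The per-target contribution lies
    in [-1/M, 1/M], bounding the total weight in [-1, 1]. Per-sample
    contributions are summed in canonical sample-id order so the result
    is bit-identical across presentation orders.
    """
    X = dataset.genotypes
    y = dataset.labels
    m, n = X.shape
    if dist is None:
        dist = distance_matrix(dataset)
    if threshold is None:
        threshold = surf_threshold(dist)

    contrib = np.zeros((m, n), dtype=np.float64)
    for i in range(m):
        ns = surf_neighbors(dist, y, i, threshold)
        net = np.zeros(n, dtype=np.float64)
        if ns.misses:
            net += (X[list(ns.misses)] != X[i]).sum(axis=0) / len(ns.misses)
        if ns.hits:
            net -= (X[list(ns.hits)] != X[i]).sum(axis=0) / len(ns.hits)
        contrib[i] = net / m

    canonical = np.argsort(np.asarray(dataset.sample_ids))
    weights = np.add.reduce(contrib[canonical], axis=0)
    return WeightVector(
        weights=weights,
        snp_names=dataset.snp_names,
        meta={"filter": "surf", "threshold": float(threshold)},
    )
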