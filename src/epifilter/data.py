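"""Core data containers and I/O for case-control SNP genotype datasets.

The central object is :class:`GenotypeDataset`: an ``M x N`` matrix of
genotype codes (0/1/2 = minor-allele count) for ``M`` samples over ``N``
SNPs, plus a binary phenotype label per sample (0 = control, 1 = case).
Sample *order* is an explicit part of the container because the ReliefF
family of filters is, by construction, sensitive to it.

Datasets are read and written in the MDR flat-file convention: a
tab-delimited text file whose header lists the SNP names followed by a
final ``Class`` column, with one genotype row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GenotypeDataset",
    "WeightVector",
    "SnpRanking",
    "MdrParseError",
    "read_mdr",
    "write_mdr",
    "permute_samples",
    "weights_to_ranking",
]

GENOTYPE_CODES = (0, 1, 2)
CLASS_COLUMN = "Class"


class MdrParseError(ValueError):
    """Raised when an MDR flat file violates the expected layout."""


@dataclass(frozen=True)
class GenotypeDataset:
    """Case-control genotype matrix with explicit sample order.

    Parameters
    ----------
    genotypes
        ``(M, N)`` integer array with entries in ``{0, 1, 2}``.
    labels
        ``(M,)`` integer array with entries in ``{0, 1}`` (0 = control,
        1 = case).
    snp_names
        ``N`` unique SNP identifiers, aligned with the columns.
    sample_ids
        ``M`` sample identifiers preserving the current presentation
        order. Generated as ``s0..s{M-1}`` when omitted.
    """

    genotypes: np.ndarray
    labels: np.ndarray
    snp_names: tuple[str, ...]
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        y = np.asarray(self.labels, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        m, n = g.shape
        if n < 1:
            raise ValueError("dataset must contain at least one SNP")
        if m < 2:
            raise ValueError("dataset must contain at least two samples")
        if y.shape != (m,):
            raise ValueError(f"labels shape {y.shape} does not match {m} samples")
        if not np.isin(g, GENOTYPE_CODES).all():
            raise ValueError("genotype codes must be 0, 1 or 2")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("class labels must be 0 (control) or 1 (case)")
        if (y == 0).sum() == 0 or (y == 1).sum() == 0:
            raise ValueError("dataset needs at least one case and one control")
        names = tuple(str(s) for s in self.snp_names)
        if len(names) != n:
            raise ValueError(f"{len(names)} SNP names for {n} SNP columns")
        if len(set(names)) != n:
            raise ValueError("SNP names must be unique")
        ids = tuple(str(s) for s in self.sample_ids) or tuple(
            f"s{i}" for i in range(m)
        )
        if len(ids) != m or len(set(ids)) != m:
            raise ValueError("sample_ids must be unique and match sample count")
        g.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "genotypes", g)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "snp_names", names)
        object.__setattr__(self, "sample_ids", ids)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == 0).sum())

    def class_indices(self, label: int) -> np.ndarray:
        """Positions (in current order) of samples with the given label."""
        return np.flatnonzero(self.labels == label)

    def take_samples(self, order: Sequence[int]) -> "GenotypeDataset":
        """Return a dataset with rows re-indexed by ``order``.

        The sample <-> label pairing travels with each row, so this only
        changes presentation order (or drops samples when ``order`` is a
        strict subset).
        """
        idx = np.asarray(order, dtype=np.intp)
        return GenotypeDataset(
            genotypes=self.genotypes[idx],
            labels=self.labels[idx],
            snp_names=self.snp_names,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
        )

    def select_snps(self, cols: Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(cols, dtype=np.intp)
        return GenotypeDataset(
            genotypes=self.genotypes[:, idx],
            labels=self.labels,
            snp_names=tuple(self.snp_names[i] for i in idx),
            sample_ids=self.sample_ids,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snp_names == other.snp_names
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.labels, other.labels)
        )


@dataclass(frozen=True)
class WeightVector:
    """Per-SNP discrimination weights produced by a filter.

    ReliefF-family weights live in ``[-1, 1]``; univariate scores
    (chi-square statistic, |log odds ratio|) are non-negative and
    unbounded. ``meta`` records the filter name and its parameters so a
    ranking is reproducible from its provenance.
    """

    weights: np.ndarray
    snp_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        names = tuple(str(s) for s in self.snp_names)
        if w.ndim != 1 or len(names) != w.shape[0]:
            raise ValueError("weights and snp_names must align 1-D")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "snp_names", names)


@dataclass(frozen=True)
class SnpRanking:
    """A total order over SNPs; rank 1 = most discriminative.

    ``ranks[j]`` is the rank of ``snp_names[j]`` and the rank vector is a
    permutation of ``1..N``. ``removal_iteration`` is TuRF bookkeeping:
    the 1-based iteration at which a SNP was discarded, 0 for SNPs that
    survived every iteration.
    """

    ranks: np.ndarray
    snp_names: tuple[str, ...]
    removal_iteration: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = np.asarray(self.ranks, dtype=np.int64)
        names = tuple(str(s) for s in self.snp_names)
        n = r.shape[0]
        if r.ndim != 1 or len(names) != n:
            raise ValueError("ranks and snp_names must align 1-D")
        if not np.array_equal(np.sort(r), np.arange(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..N")
        r.setflags(write=False)
        object.__setattr__(self, "ranks", r)
        object.__setattr__(self, "snp_names", names)
        if self.removal_iteration is not None:
            ri = np.asarray(self.removal_iteration, dtype=np.int64)
            if ri.shape != (n,):
                raise ValueError("removal_iteration must align with snp_names")
            ri.setflags(write=False)
            object.__setattr__(self, "removal_iteration", ri)

    def rank_of(self, name: str) -> int:
        return int(self.ranks[self.snp_names.index(name)])

    def top(self, k: int) -> tuple[str, ...]:
        """Names of the ``k`` best-ranked SNPs, in rank order."""
        order = np.argsort(self.ranks, kind="stable")[:k]
        return tuple(self.snp_names[i] for i in order)


# ----------------------------------------------------------------------
# MDR flat-file I/O
# ----------------------------------------------------------------------

def read_mdr(path: str | Path, sep: str = "\t") -> GenotypeDataset:
    """Read an MDR flat file (tab-delimited, trailing ``Class`` column).

    The sample order of the returned dataset equals the file's row
    order. Genotype codes are validated against {0,1,2} and class codes
    against {0,1}; violations raise :class:`MdrParseError` naming the
    offending line.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n")
        if not header:
            raise MdrParseError(f"{path}: empty file")
        cols = header.split(sep)
        if cols[-1].strip().lower() != CLASS_COLUMN.lower():
            raise MdrParseError(
                f"{path}: line 1: last header column must be "
                f"'{CLASS_COLUMN}', got {cols[-1]!r}"
            )
        snp_names = [c.strip() for c in cols[:-1]]
        if not snp_names:
            raise MdrParseError(f"{path}: line 1: no SNP columns before Class")
        n = len(snp_names)
        rows: list[list[int]] = []
        labels: list[int] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split(sep)
            if len(fields) != n + 1:
                raise MdrParseError(
                    f"{path}: line {lineno}: expected {n + 1} fields, "
                    f"got {len(fields)}"
                )
            try:
                values = [int(v) for v in fields]
            except ValueError as exc:
                raise MdrParseError(f"{path}: line {lineno}: {exc}") from exc
            if any(v not in GENOTYPE_CODES for v in values[:-1]):
                raise MdrParseError(
                    f"{path}: line {lineno}: genotype codes must be 0/1/2"
                )
            if values[-1] not in (0, 1):
                raise MdrParseError(
                    f"{path}: line {lineno}: class must be 0 or 1"
                )
            rows.append(values[:-1])
            labels.append(values[-1])
    if not rows:
        raise MdrParseError(f"{path}: no sample rows")
    return GenotypeDataset(
        genotypes=np.array(rows, dtype=np.int8),
        labels=np.array(labels, dtype=np.int8),
        snp_names=tuple(snp_names),
    )


def write_mdr(dataset: GenotypeDataset, path: str | Path, sep: str = "\t") -> None:
    """Write a dataset as an MDR flat file readable by :func:`read_mdr`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(sep.join((*dataset.snp_names, CLASS_COLUMN)) + "\n")
        for row, label in zip(dataset.genotypes, dataset.labels):
            fh.write(sep.join(map(str, row)) + sep + str(int(label)) + "\n")


# ----------------------------------------------------------------------
# Sample-order permutation and rank construction
# ----------------------------------------------------------------------

def permute_samples(dataset: GenotypeDataset, seed: int) -> GenotypeDataset:
    """Return a copy with rows in a uniformly random order drawn from ``seed``.

    The sample <-> label pairing is preserved row-wise; only presentation
    order changes. Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(dataset.n_samples)
    return dataset.take_samples(order)


def weights_to_ranking(w: WeightVector) -> SnpRanking:
    """Convert weights into ranks (1 = largest weight).

    Ties in weight are broken by ascending SNP index so the ranking is a
    deterministic function of the weight vector alone.
    """
    weights = w.weights
    if not np.isfinite(weights).all():
        raise ValueError("weights contain NaN or infinite values")
    # sort by (-weight, index); stable sort on -weight gives index tie-break
    order = np.argsort(-weights, kind="stable")
    ranks = np.empty(weights.shape[0], dtype=np.int64)
    ranks[order] = np.arange(1, weights.shape[0] + 1)
    return SnpRanking(ranks=ranks, snp_names=w.snp_names, meta=dict(w.meta))
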