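"""Traditional univariate SNP filters: chi-square test and odds ratio.

Both score each SNP against the phenotype on marginal counts alone, so
they are exactly invariant to sample order — the structural contrast
with the ReliefF family — and blind, by construction, to purely
epistatic pairs with no marginal effect.

Ranking uses the chi-square *statistic* (not the p-value; monotone
equivalent at fixed df, no underflow at large effects) and the absolute
log allelic odds ratio (deviation from the null in either direction is
evidence).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import chi2_contingency

from .data import GenotypeDataset, WeightVector

__all__ = [
    "genotype_table",
    "allele_table",
    "chi2_score",
    "odds_ratio_score",
    "chi2_weights",
    "odds_ratio_weights",
]


def genotype_table(snp_column: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """2 x 3 counts: rows (control, case), columns genotypes (0, 1, 2)."""
    snp = np.asarray(snp_column)
    y = np.asarray(labels)
    table = np.zeros((2, 3), dtype=np.int64)
    for cls in (0, 1):
        col = snp[y == cls]
        for g in (0, 1, 2):
            table[cls, g] = int((col == g).sum())
    return table


def allele_table(snp_column: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """2 x 2 allele counts: rows (control, case), columns (minor, major).

    Each sample contributes two alleles; the genotype code is the minor
    allele count.
    """
    snp = np.asarray(snp_column, dtype=np.int64)
    y = np.asarray(labels)
    out = np.zeros((2, 2), dtype=np.int64)
    for cls in (0, 1):
        col = snp[y == cls]
        minor = int(col.sum())
        out[cls] = (minor, 2 * col.size - minor)
    return out


def chi2_score(snp_column: np.ndarray, labels: np.ndarray) -> float:
    """Pearson chi-square statistic of the genotype x class table.

    Genotype columns with zero margin are dropped (df shrinks with
    them). Returns 0.0 when the table degenerates to a single column.
    """
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("chi2_score needs both classes present")
    table = genotype_table(snp_column, y)
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 0.0
    stat, _, _, _ = chi2_contingency(table, correction=False)
    return float(stat)


def odds_ratio_score(snp_column: np.ndarray, labels: np.ndarray) -> float:
    """|ln OR| of the allelic 2x2 table, Haldane-Anscombe corrected.

    OR = (case minor * control major) / (case major * control minor);
    0.5 is added to every cell when any cell is zero. The absolute log
    makes the score direction-agnostic (risk and protective alleles
    count equally).
    """
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("odds_ratio_score needs both classes present")
    table = allele_table(snp_column, y).astype(np.float64)
    if (table == 0).any():
        table = table + 0.5
    (c_minor, c_major), (a_minor, a_major) = table
    odds_ratio = (a_minor * c_major) / (a_major * c_minor)
    return abs(math.log(odds_ratio))


def _column_weights(dataset: GenotypeDataset, score, name: str) -> WeightVector:
    w = np.array(
        [score(dataset.genotypes[:, j], dataset.labels)
         for j in range(dataset.n_snps)]
    )
    return WeightVector(weights=w, snp_names=dataset.snp_names,
                        meta={"filter": name})


def chi2_weights(dataset: GenotypeDataset) -> WeightVector:
    """Per-SNP chi-square statistics as ranking weights."""
    return _column_weights(dataset, chi2_score, "chi2")


def odds_ratio_weights(dataset: GenotypeDataset) -> WeightVector:
    """Per-SNP |ln allelic OR| as ranking weights."""
    return _column_weights(dataset, odds_ratio_score, "oddsratio")
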