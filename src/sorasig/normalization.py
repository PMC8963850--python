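"""Platform-specific expression normalization.

Three platforms, three conventions:

* microarray intensities -> quantile normalization: every sample is
  forced onto the common reference distribution (row means of the
  column-sorted matrix), preserving within-sample ranks;
* RNA-seq raw counts -> median-of-ratios size factors: each sample is
  divided by the median, over genes expressed in every sample, of its
  count-to-geometric-mean ratio;
* qRT-PCR threshold cycles -> ΔCt against a housekeeping set:
  ΔCt(g, s) = geometric mean of housekeeping Ct in sample s minus
  Ct(g, s), so higher ΔCt means higher expression.

No cross-platform calibration is attempted; scores are only ever
compared within one platform cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .cohort import Platform
from .errors import DataError, DegenerateDataError

__all__ = [
    "ExpressionMatrix",
    "HousekeepingSet",
    "DeltaCtTable",
    "load_expression_matrix",
    "quantile_normalize",
    "size_factor_normalize",
    "delta_ct",
    "normalize",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric table with platform and normalization state.

    ``data`` is indexed by HGNC symbol with sample ids as columns.
    """

    data: pd.DataFrame
    platform: Platform
    normalized: bool = False

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        if self.data.index.has_duplicates:
            raise DataError("duplicate gene ids in expression matrix")
        if self.data.columns.has_duplicates:
            raise DataError("duplicate sample ids in expression matrix")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("expression matrix must be numeric")
        if self.platform is Platform.RNASEQ_COUNTS and not self.normalized:
            if (values < 0).any():
                raise DataError("RNA-seq counts must be non-negative")
        if self.platform is Platform.PCR_CT and (values <= 0).any():
            raise DataError("Ct values must be positive cycle numbers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise DataError(f"genes absent from matrix: {missing}")
        return replace(self, data=self.data.loc[genes])


@dataclass(frozen=True)
class HousekeepingSet:
    """Reference genes for ΔCt normalization."""

    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise DataError("housekeeping set must be non-empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("housekeeping set contains duplicates")


@dataclass
class DeltaCtTable:
    """Target genes x samples grid of ΔCt values (cycles; log2 scale)."""

    data: pd.DataFrame
    housekeeping: HousekeepingSet

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def load_expression_matrix(
    source: Union[str, Path],
    platform: Platform | str,
    normalized: bool = False,
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix (first column = HGNC
    symbol, header = sample ids).  TSV by default, comma auto-detected.
    The platform is declared, never inferred."""
    path = Path(source)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, platform=Platform(platform), normalized=normalized)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize a microarray intensity matrix.

    Every output column shares one sorted value multiset: the row means
    of the column-sorted input.  Within-column rank order is preserved;
    tied values receive the mean of the reference values their ranks span.
    """
    if matrix.platform is not Platform.MICROARRAY:
        raise DataError(f"quantile normalization expects microarray data, got {matrix.platform.value}")
    if matrix.normalized:
        raise DataError("matrix is already normalized (refusing double normalization)")
    X = matrix.data.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_genes < 2 or n_samples < 2:
        raise DataError("quantile normalization needs >=2 genes and >=2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        # within tied groups, assign the mean of the spanned reference values
        _, inverse, counts = np.unique(col[order], return_inverse=True, return_counts=True)
        group_means = np.bincount(inverse, weights=reference) / counts
        out[order, j] = group_means[inverse]
    data = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(data, platform=matrix.platform, normalized=True)


def size_factor_normalize(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios normalization of an RNA-seq count matrix.

    The per-gene geometric mean is computed over genes with strictly
    positive counts in every sample; a sample's size factor is the
    median over those genes of count / geometric mean.  Returns the
    scaled matrix and the size factors.
    """
    if matrix.platform is not Platform.RNASEQ_COUNTS:
        raise DataError(f"size-factor normalization expects RNA-seq counts, got {matrix.platform.value}")
    if matrix.normalized:
        raise DataError("matrix is already normalized (refusing double normalization)")
    counts = matrix.data.to_numpy(dtype=float)
    if not np.allclose(counts, np.round(counts)):
        raise DataError("RNA-seq matrix must contain integer-valued counts")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise DataError(
            "no gene has positive counts in every sample; add a pseudocount "
            "or filter samples before size-factor estimation"
        )
    log_counts = np.log(counts[all_positive, :])
    log_geo_means = log_counts.mean(axis=1)
    log_factors = np.median(log_counts - log_geo_means[:, None], axis=0)
    factors = np.exp(log_factors)
    data = pd.DataFrame(
        counts / factors[None, :], index=matrix.data.index, columns=matrix.data.columns
    )
    size_factors = pd.Series(factors, index=matrix.data.columns, name="size_factor")
    return ExpressionMatrix(data, platform=matrix.platform, normalized=True), size_factors


def delta_ct(
    ct: ExpressionMatrix,
    housekeeping: HousekeepingSet | Iterable[str],
    targets: Iterable[str] | None = None,
) -> DeltaCtTable:
    """Housekeeping-referenced qPCR expression.

    ΔCt(g, s) = geometric mean over housekeeping genes of Ct(h, s)
    minus Ct(g, s).  The geometric mean is computed as the exponential
    of the mean log Ct for numerical stability.  Replicate wells must
    already be aggregated to one Ct per gene per sample.
    """
    if ct.platform is not Platform.PCR_CT:
        raise DataError(f"ΔCt normalization expects Ct data, got {ct.platform.value}")
    if not isinstance(housekeeping, HousekeepingSet):
        housekeeping = HousekeepingSet(tuple(housekeeping))
    missing = [g for g in housekeeping.gene_ids if g not in ct.data.index]
    if missing:
        raise DataError(f"housekeeping genes absent from Ct matrix: {missing}")
    if targets is None:
        targets = [g for g in ct.gene_ids if g not in set(housekeeping.gene_ids)]
    else:
        targets = list(targets)
        absent = [g for g in targets if g not in ct.data.index]
        if absent:
            raise DataError(f"target genes absent from Ct matrix: {absent}")
        overlap = set(targets) & set(housekeeping.gene_ids)
        if overlap:
            raise DataError(f"genes cannot be both target and housekeeping: {sorted(overlap)}")
    if not targets:
        raise DegenerateDataError("no target genes left after removing housekeeping set")
    hk = ct.data.loc[list(housekeeping.gene_ids)].to_numpy(dtype=float)
    hk_geo_mean = np.exp(np.log(hk).mean(axis=0))  # per sample
    table = hk_geo_mean[None, :] - ct.data.loc[targets].to_numpy(dtype=float)
    data = pd.DataFrame(table, index=targets, columns=ct.data.columns)
    return DeltaCtTable(data, housekeeping=housekeeping)


def normalize(
    matrix: ExpressionMatrix,
    housekeeping: HousekeepingSet | Iterable[str] | None = None,
) -> Union[ExpressionMatrix, DeltaCtTable]:
    """Dispatch to the platform-appropriate normalization."""
    if matrix.platform is Platform.MICROARRAY:
        return quantile_normalize(matrix)
    if matrix.platform is Platform.RNASEQ_COUNTS:
        return size_factor_normalize(matrix)[0]
    if housekeeping is None:
        raise DataError("ΔCt normalization requires a housekeeping set")
    return delta_ct(matrix, housekeeping)
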