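"""Expression-level utilities: FPKM, per-gene Z-scores, sample correlation,
and qPCR/RNA-seq fold-change concordance."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionMatrix, ModelSpecError

__all__ = [
    "compute_fpkm",
    "zscore_rows",
    "sample_correlation",
    "platform_concordance",
    "ConcordanceResult",
]


@dataclass(frozen=True)
class ConcordanceResult:
    """OLS fit of qPCR log2 fold changes on RNA-seq log2 fold changes."""

    pearson_r: float
    slope: float
    intercept: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ModelSpecError("concordance needs n >= 3 genes")
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ModelSpecError("pearson_r outside [-1, 1]")


def compute_fpkm(counts: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Fragments per kilobase per million mapped reads.

    FPKM = 1e9 * C / (N * L) with C the read count of a transcript, L its
    length in bp and N the per-library total (column sum of the count
    matrix).  Effective-length correction is not applied.
    """
    if counts.value_kind != "counts":
        raise ModelSpecError(f"compute_fpkm expects counts, got {counts.value_kind}")
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise ModelSpecError(f"missing transcript length for gene {missing[0]!r} "
                             f"({len(missing)} missing in total)")
    L = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    if (L < 1).any():
        bad = counts.gene_ids[int(np.argmax(L < 1))]
        raise ModelSpecError(f"non-positive length for gene {bad!r}")
    K = counts.values.to_numpy(dtype=float)
    N = K.sum(axis=0)
    if (N <= 0).any():
        bad = counts.sample_ids[int(np.argmax(N <= 0))]
        raise ModelSpecError(f"zero column sum for sample {bad!r}")
    fpkm = 1e9 * K / (N[np.newaxis, :] * L[:, np.newaxis])
    out = pd.DataFrame(fpkm, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(values=out, value_kind="fpkm", condition=counts.condition)


def zscore_rows(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, frozenset[str]]:
    """Standardize each gene row to mean 0, sd 1 (n-1 denominator).

    Constant rows cannot be standardized; they become all zeros and their
    gene ids are returned (and warned about) so callers can drop or flag
    them before plotting.
    """
    df = matrix.values
    if df.shape[1] < 2:
        raise ModelSpecError("zscore_rows needs >= 2 samples")
    vals = df.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0.0
    sd_safe = np.where(constant[:, None], 1.0, sd)
    z = (vals - mean) / sd_safe
    z[constant, :] = 0.0
    constant_genes = frozenset(df.index[constant])
    if constant_genes:
        warnings.warn(f"{len(constant_genes)} constant row(s) set to zero: "
                      f"{sorted(constant_genes)[:5]}...", stacklevel=2)
    out = pd.DataFrame(z, index=df.index, columns=df.columns)
    return (ExpressionMatrix(values=out, value_kind="zscore",
                             condition=matrix.condition), constant_genes)


def sample_correlation(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation between sample columns.

    Zero-variance columns yield NaN off-diagonal entries (undefined); the
    diagonal is 1 by convention.
    """
    if matrix.values.shape[0] < 2:
        raise ModelSpecError("sample_correlation needs >= 2 genes")
    corr = matrix.values.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def platform_concordance(log2fc_rnaseq: pd.Series, log2fc_qpcr: pd.Series) -> ConcordanceResult:
    """Concordance of qPCR vs RNA-seq log2 fold changes for the same genes.

    Fits ordinary least squares of the qPCR values on the RNA-seq values and
    reports Pearson r, slope and intercept.
    """
    x = pd.Series(log2fc_rnaseq).astype(float)
    y = pd.Series(log2fc_qpcr).astype(float)
    if set(x.index) != set(y.index):
        only_x = sorted(set(x.index) - set(y.index))
        only_y = sorted(set(y.index) - set(x.index))
        raise ModelSpecError(f"mismatched gene sets (rnaseq-only: {only_x[:3]}, "
                             f"qpcr-only: {only_y[:3]})")
    y = y.reindex(x.index)
    if len(x) < 3:
        raise ModelSpecError("concordance needs n >= 3 genes")
    res = stats.linregress(x.to_numpy(), y.to_numpy())
    return ConcordanceResult(pearson_r=float(res.rvalue), slope=float(res.slope),
                             intercept=float(res.intercept), n=len(x))
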