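"""Differential expression between two conditions on count matrices.

This stage is a documented, self-contained negative-binomial Wald pipeline:
median-of-ratios size factors, a per-gene method-of-moments dispersion, a
delta-method Wald z on the log2 fold change, and Benjamini-Hochberg FDR.
It deliberately omits dispersion shrinkage, outlier filtering and
independent filtering; the contract is the stated formulas, not agreement
with any particular external tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ExpressionMatrix, ModelSpecError

__all__ = [
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "classify_degs",
    "DeResult",
]

_LN2 = np.log(2.0)


@dataclass
class DeResult:
    """Per-gene differential-expression table.

    Columns: ``base_mean`` (mean normalized count), ``log2_fold_change``
    (second group vs first; positive = higher in the second group),
    ``wald_z``, ``p_value``, ``fdr`` and ``status`` in {up, down, ns}.
    """

    table: pd.DataFrame
    group_levels: tuple[str, str]
    fdr_threshold: float = 0.01


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios library size factors.

    For each gene with all-positive counts, form the ratio of each sample's
    count to the gene's geometric mean across samples; the size factor of a
    sample is the median of these ratios.
    """
    K = counts.values.to_numpy(dtype=float)
    positive = (K > 0).all(axis=1)
    if not positive.any():
        raise ModelSpecError("no gene with all-positive counts; cannot compute size factors")
    Kp = K[positive]
    log_geomean = np.log(Kp).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(Kp) - log_geomean)
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.values.columns, name="size_factor")


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        bad = p[(p < 0) | (p > 1) | np.isnan(p)][0]
        raise ModelSpecError(f"p-value outside [0, 1]: {bad}")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(counts: ExpressionMatrix,
                 groups: Mapping[str, str] | None = None,
                 sf: pd.Series | None = None,
                 levels: tuple[str, str] | None = None,
                 fdr_threshold: float = 0.01) -> DeResult:
    """Two-group negative-binomial Wald test on a count matrix.

    Per gene, with normalized counts k = K / s:

    * group means ``mu1``, ``mu2``; log2FC = log2(mu2 + 0.5) - log2(mu1 + 0.5)
      (a 0.5 pseudocount per group mean keeps fold changes finite);
    * dispersion ``alpha = max(0, (v - m) / m^2)`` with ``m`` the overall mean
      and ``v`` the pooled within-group variance of the normalized counts
      (floored at 0, the Poisson limit; no sharing across genes);
    * delta-method SE^2 = (1/ln2)^2 * [(1/mu1 + alpha)/n1 + (1/mu2 + alpha)/n2],
      Wald z = log2FC / SE, two-sided p from the standard normal.

    Genes where either group mean is zero get an infinite SE, hence z = 0 and
    p = 1; counts are accepted as given (integers not required).
    """
    groups = groups if groups is not None else counts.condition
    if groups is None:
        raise ModelSpecError("no group labels supplied")
    samples = counts.sample_ids
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ModelSpecError(f"no group label for sample {missing[0]!r}")
    if levels is None:
        seen: list[str] = []
        for s in samples:
            if groups[s] not in seen:
                seen.append(groups[s])
        levels = tuple(seen)  # type: ignore[assignment]
    if len(levels) != 2:
        raise ModelSpecError(f"need exactly two group levels, got {levels}")
    unknown = {groups[s] for s in samples} - set(levels)
    if unknown:
        raise ModelSpecError(f"unknown group label(s): {sorted(unknown)}")
    idx1 = [i for i, s in enumerate(samples) if groups[s] == levels[0]]
    idx2 = [i for i, s in enumerate(samples) if groups[s] == levels[1]]
    n1, n2 = len(idx1), len(idx2)
    if n1 < 2 or n2 < 2:
        small = levels[0] if n1 < 2 else levels[1]
        raise ModelSpecError(f"group {small!r} has fewer than 2 samples")

    if sf is None:
        sf = size_factors(counts)
    s = sf.reindex(samples).to_numpy(dtype=float)
    if (s <= 0).any() or np.isnan(s).any():
        raise ModelSpecError("size factors must be positive for every sample")
    k = counts.values.to_numpy(dtype=float) / s[np.newaxis, :]

    k1, k2 = k[:, idx1], k[:, idx2]
    mu1, mu2 = k1.mean(axis=1), k2.mean(axis=1)
    lfc = np.log2(mu2 + 0.5) - np.log2(mu1 + 0.5)

    v1 = k1.var(axis=1, ddof=1)
    v2 = k2.var(axis=1, ddof=1)
    v = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    m = k.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(m > 0, np.maximum(0.0, (v - m) / np.where(m > 0, m, 1.0) ** 2), 0.0)
        se2 = (1.0 / _LN2) ** 2 * ((1.0 / mu1 + alpha) / n1 + (1.0 / mu2 + alpha) / n2)
        z = np.where(np.isfinite(se2) & (se2 > 0), lfc / np.sqrt(se2), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)

    table = pd.DataFrame({
        "base_mean": m,
        "log2_fold_change": lfc,
        "wald_z": z,
        "p_value": p,
        "fdr": bh_adjust(p),
    }, index=counts.values.index)
    result = DeResult(table=table, group_levels=levels, fdr_threshold=fdr_threshold)
    up, down = classify_degs(result, fdr_threshold)
    status = np.full(len(table), "ns", dtype=object)
    status[table.index.isin(up)] = "up"
    status[table.index.isin(down)] = "down"
    table["status"] = status
    return result


def classify_degs(result: DeResult, fdr_threshold: float = 0.01) -> tuple[frozenset[str], frozenset[str]]:
    """Split genes into up- and down-regulated sets at the given FDR.

    ``up`` = fdr <= threshold and log2FC > 0; ``down`` = fdr <= threshold and
    log2FC < 0 (a gene at exactly the threshold is included).
    """
    if not 0 < fdr_threshold < 1:
        raise ModelSpecError(f"fdr_threshold must be in (0, 1), got {fdr_threshold}")
    t = result.table
    sig = t["fdr"] <= fdr_threshold
    up = frozenset(t.index[sig & (t["log2_fold_change"] > 0)])
    down = frozenset(t.index[sig & (t["log2_fold_change"] < 0)])
    return up, down
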