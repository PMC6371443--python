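"""GO-term over-representation by the one-sided hypergeometric test.

The universe is the set of annotated genes; for a query of n annotated genes
and a term annotating M of the N universe genes, the p-value is
P(X >= k) for X ~ Hypergeometric(N, M, n) where k is the observed overlap.
Raw p-values are reported by default; an optional BH column can be added.
The GO graph itself is not modeled (no term-term decorrelation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelSpecError
from .de import bh_adjust

__all__ = ["Annotation", "EnrichmentResult", "hypergeom_upper_tail", "enrich_terms"]


@dataclass
class Annotation:
    """Gene -> GO-term mapping with an optional term-name table."""

    gene_to_terms: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_to_terms = {g: frozenset(ts) for g, ts in self.gene_to_terms.items()
                              if len(ts) > 0}
        if not self.gene_to_terms:
            raise ModelSpecError("annotation is empty (no gene with a term)")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.gene_to_terms)

    def term_to_genes(self) -> dict[str, frozenset[str]]:
        index: dict[str, set[str]] = {}
        for g, terms in self.gene_to_terms.items():
            for t in terms:
                index.setdefault(t, set()).add(g)
        return {t: frozenset(gs) for t, gs in index.items()}

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "Annotation":
        """Build from a (gene_id, term_id[, term_name]) long table."""
        mapping: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for row in table.itertuples(index=False):
            mapping.setdefault(str(row.gene_id), set()).add(str(row.term_id))
            if hasattr(row, "term_name") and isinstance(row.term_name, str):
                names[str(row.term_id)] = row.term_name
        return cls(gene_to_terms={g: frozenset(ts) for g, ts in mapping.items()},
                   term_names=names)


@dataclass
class EnrichmentResult:
    """Per-term over-representation table sorted by p (term id tie-break)."""

    table: pd.DataFrame
    universe_size: int
    query_size: int


def hypergeom_upper_tail(N: int, M: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, M, n).

    N: universe size; M: genes annotated to the term; n: query size;
    k: observed overlap.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ModelSpecError(f"invalid hypergeometric parameters N={N}, M={M}, n={n}")
    if not 0 <= k <= min(n, M):
        raise ModelSpecError(f"overlap k={k} outside [0, min(n={n}, M={M})]")
    # survival function at k-1 gives P(X >= k); scipy evaluates it stably
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def enrich_terms(query: Iterable[str], annotation: Annotation,
                 min_overlap: int = 2, with_bh: bool = False) -> EnrichmentResult:
    """Test every annotated term for over-representation in a gene set.

    Query genes absent from the annotation universe are dropped with a
    warning and excluded from n.  Terms overlapping the query by fewer than
    ``min_overlap`` genes are not reported.  ``frequency`` is 100*k/n over
    the annotated query.
    """
    universe = annotation.universe
    N = len(universe)
    if N == 0:
        raise ModelSpecError("empty annotation universe")
    query_set = set(query)
    annotated = query_set & universe
    dropped = query_set - universe
    if dropped:
        warnings.warn(f"{len(dropped)} query gene(s) not in the annotation universe "
                      f"were dropped: {sorted(dropped)[:5]}...", stacklevel=2)
    n = len(annotated)
    rows = []
    for term, genes in annotation.term_to_genes().items():
        M = len(genes)
        k = len(genes & annotated)
        if k < min_overlap:
            continue
        rows.append({
            "term_id": term,
            "term_name": annotation.term_names.get(term, ""),
            "k": k, "n": n, "M": M, "N": N,
            "frequency": 100.0 * k / n if n else np.nan,
            "p_value": hypergeom_upper_tail(N, M, n, k),
        })
    table = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "n", "M", "N",
                                        "frequency", "p_value"])
    if len(table):
        table = table.sort_values(["p_value", "term_id"], kind="mergesort",
                                  ignore_index=True)
        if with_bh:
            table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    elif with_bh:
        table["fdr"] = pd.Series(dtype=float)
    return EnrichmentResult(table=table, universe_size=N, query_size=n)
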