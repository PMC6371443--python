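"""Core data structures shared across the pipeline.

The containers here are deliberately thin wrappers around pandas/numpy
objects: an :class:`ExpressionMatrix` is a genes x samples DataFrame with a
declared value kind, a :class:`BlockSpec` ties a latent variable to its
indicator columns, and an :class:`InnerModel` is a directed acyclic graph
over latent variables.  Validation happens at construction so that every
downstream stage can assume its invariants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BlockSpec",
    "InnerModel",
    "RunConfig",
    "SyntheticTruth",
    "ModelSpecError",
]


class ModelSpecError(ValueError):
    """Raised when a model specification violates its invariants."""


VALUE_KINDS = ("counts", "fpkm", "zscore")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with optional condition labels.

    Parameters
    ----------
    values:
        DataFrame indexed by gene id with sample ids as columns.
    value_kind:
        One of ``counts``, ``fpkm`` or ``zscore``.  Negative entries are
        rejected for counts and FPKM.
    condition:
        Optional map from sample id to group label (e.g. ``DP`` / ``SP``).
    """

    values: pd.DataFrame
    value_kind: str = "counts"
    condition: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ModelSpecError(
                f"unknown value_kind {self.value_kind!r}; expected one of {VALUE_KINDS}"
            )
        df = self.values
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ModelSpecError(
                f"expression matrix needs >=1 gene and >=2 samples, got shape {df.shape}"
            )
        dup_genes = df.index[df.index.duplicated()].unique()
        if len(dup_genes):
            raise ModelSpecError(f"duplicated gene id(s): {list(dup_genes)}")
        dup_samples = df.columns[df.columns.duplicated()].unique()
        if len(dup_samples):
            raise ModelSpecError(f"duplicated sample id(s): {list(dup_samples)}")
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ModelSpecError(f"non-numeric column(s): {bad}")
        if df.isna().any().any():
            gene = df.index[df.isna().any(axis=1)][0]
            raise ModelSpecError(f"missing value in row for gene {gene!r}")
        if self.value_kind in ("counts", "fpkm") and (df.to_numpy() < 0).any():
            gene = df.index[(df < 0).any(axis=1)][0]
            raise ModelSpecError(
                f"negative value for gene {gene!r} in a {self.value_kind} matrix"
            )
        if self.condition is not None:
            unknown = set(self.condition) - set(df.columns)
            if unknown:
                raise ModelSpecError(f"condition labels for unknown sample(s): {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BlockSpec:
    """A reflective (Mode A) measurement block: one latent variable and its
    indicator columns."""

    lv_name: str
    indicators: tuple[str, ...]
    mode: str = "A"

    def __post_init__(self) -> None:
        if self.mode != "A":
            raise ModelSpecError(
                f"block {self.lv_name!r}: unknown mode {self.mode!r} (only Mode A supported)"
            )
        if len(self.indicators) == 0:
            raise ModelSpecError(f"block {self.lv_name!r} has an empty indicator list")
        if len(set(self.indicators)) != len(self.indicators):
            raise ModelSpecError(f"block {self.lv_name!r} repeats an indicator")
        object.__setattr__(self, "indicators", tuple(self.indicators))


def validate_blocks(blocks: Sequence[BlockSpec]) -> None:
    """Cross-block invariants: unique lv names, no indicator in two blocks."""
    seen_lv: set[str] = set()
    owner: dict[str, str] = {}
    for b in blocks:
        if b.lv_name in seen_lv:
            raise ModelSpecError(f"latent variable {b.lv_name!r} defined twice")
        seen_lv.add(b.lv_name)
        for ind in b.indicators:
            if ind in owner:
                raise ModelSpecError(
                    f"indicator {ind!r} assigned to both {owner[ind]!r} and {b.lv_name!r}"
                )
            owner[ind] = b.lv_name


@dataclass(frozen=True)
class InnerModel:
    """Acyclic directed structural model over latent variables."""

    lv_names: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lv_names", tuple(self.lv_names))
        object.__setattr__(self, "edges", tuple((s, t) for s, t in self.edges))
        if len(set(self.lv_names)) != len(self.lv_names):
            raise ModelSpecError("duplicate latent-variable names")
        names = set(self.lv_names)
        seen: set[tuple[str, str]] = set()
        for s, t in self.edges:
            if s not in names or t not in names:
                missing = s if s not in names else t
                raise ModelSpecError(f"edge ({s!r}, {t!r}) references unknown lv {missing!r}")
            if s == t:
                raise ModelSpecError(f"self-loop on {s!r}")
            if (s, t) in seen:
                raise ModelSpecError(f"duplicate edge ({s!r}, {t!r})")
            seen.add((s, t))
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            pretty = " -> ".join([e[0] for e in cycle] + [cycle[0][0]])
            raise ModelSpecError(f"inner model contains a cycle: {pretty}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.lv_names)
        g.add_edges_from(self.edges)
        return g

    def predecessors(self, lv: str) -> list[str]:
        return [s for s, t in self.edges if t == lv]

    def successors(self, lv: str) -> list[str]:
        return [t for s, t in self.edges if s == lv]

    def topological_order(self) -> list[str]:
        # stable within each generation: preserve lv_names order
        order = list(nx.lexicographical_topological_sort(
            self.graph(), key=lambda v: self.lv_names.index(v)))
        return order

    @property
    def endogenous(self) -> list[str]:
        return [lv for lv in self.lv_names if self.predecessors(lv)]

    @property
    def exogenous(self) -> list[str]:
        return [lv for lv in self.lv_names if not self.predecessors(lv)]


@dataclass
class RunConfig:
    """Estimation and inference settings.

    ``bootstrap_samples`` defaults to 5000 resamples and ``critical_t`` to the
    two-sided 5% normal critical value 1.96; both follow common PLS-SEM
    practice for reflective gene-block models.
    """

    tolerance: float = 1e-7
    max_iterations: int = 300
    bootstrap_samples: int = 5000
    alpha: float = 0.05
    critical_t: float = 1.96
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ModelSpecError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ModelSpecError("max_iterations must be >= 1")
        if self.bootstrap_samples < 1:
            raise ModelSpecError("bootstrap_samples must be >= 1")
        if not 0 < self.alpha < 1:
            raise ModelSpecError("alpha must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators so recovery can be scored.

    Only the fields relevant to the generator that produced the object are
    populated; the rest stay ``None``.
    """

    # structural-equation generator
    inner_paths: pd.DataFrame | None = None   # lv x lv, B_true[source, target]
    loadings: dict[str, tuple[float, ...]] | None = None
    # count generator
    de_genes: frozenset[str] | None = None
    de_log2fc: dict[str, float] | None = None
    dispersion: float | None = None
    size_factors: dict[str, float] | None = None
    # annotation generator
    enriched_terms: frozenset[str] | None = None
    # qPCR generator
    fold_changes: pd.DataFrame | None = None  # genes x samples
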