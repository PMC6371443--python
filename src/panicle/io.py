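"""Readers and writers for the package's plain-text dialects.

All tabular files are UTF-8 TSV with a mandatory header row and "." as the
decimal separator.  The block file is the one exception: a GMT-like dialect
with one block per line (``lv_name <TAB> mode <TAB> indicator ...``) and no
header.  JSON reports serialize floats at full precision so that a
read-after-write round-trip reproduces every numeric field exactly.
"""

from __future__ import annotations

import json
import os
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .model import (
    BlockSpec,
    ExpressionMatrix,
    InnerModel,
    ModelSpecError,
    validate_blocks,
)

__all__ = [
    "read_expression_matrix",
    "write_matrix",
    "read_block_spec",
    "write_block_spec",
    "read_inner_model",
    "write_inner_model",
    "read_groups",
    "read_lengths",
    "read_annotation_table",
    "read_ct_table",
    "write_report",
    "read_report",
]


def read_expression_matrix(path: str | os.PathLike, value_kind: str = "counts",
                           condition: dict[str, str] | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ModelSpecError(
                f"non-numeric cell in column {col!r}"
                + (f" (gene {bad.index[0]!r}: {bad.iloc[0]!r})" if len(bad) else "")
            )
    return ExpressionMatrix(values=df, value_kind=value_kind, condition=condition)


def write_matrix(matrix: ExpressionMatrix, path: str | os.PathLike,
                 index_label: str = "gene_id") -> None:
    matrix.values.to_csv(path, sep="\t", index_label=index_label)


def read_block_spec(path: str | os.PathLike) -> list[BlockSpec]:
    """Read the GMT-like block file: ``lv_name\\tmode\\tindicator...`` per line."""
    blocks: list[BlockSpec] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ModelSpecError(
                    f"{path}:{lineno}: block line needs lv_name, mode and >=1 indicator"
                )
            blocks.append(BlockSpec(lv_name=parts[0], mode=parts[1],
                                    indicators=tuple(parts[2:])))
    if not blocks:
        raise ModelSpecError(f"{path}: no blocks found")
    validate_blocks(blocks)
    return blocks


def write_block_spec(blocks: Iterable[BlockSpec], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for b in blocks:
            fh.write("\t".join([b.lv_name, b.mode, *b.indicators]) + "\n")


def read_inner_model(path: str | os.PathLike,
                     lv_names: Iterable[str] | None = None) -> InnerModel:
    """Read an edge-list TSV with header ``source_lv\\ttarget_lv``.

    If ``lv_names`` is given (e.g. from a companion block file) the node set
    and its order are taken from it; otherwise nodes are collected from the
    edges in order of first appearance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["source_lv", "target_lv"]:
        raise ModelSpecError(
            f"{path}: expected header 'source_lv\\ttarget_lv', got {list(df.columns)}"
        )
    edges = [(s, t) for s, t in zip(df["source_lv"], df["target_lv"])]
    if lv_names is None:
        names: list[str] = []
        for s, t in edges:
            for v in (s, t):
                if v not in names:
                    names.append(v)
    else:
        names = list(lv_names)
    return InnerModel(lv_names=tuple(names), edges=tuple(edges))


def write_inner_model(inner: InnerModel, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source_lv\ttarget_lv\n")
        for s, t in inner.edges:
            fh.write(f"{s}\t{t}\n")


def read_groups(path: str | os.PathLike) -> dict[str, str]:
    """Read a sample->group TSV with header ``sample_id\\tgroup``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ModelSpecError(f"{path}: expected header 'sample_id\\tgroup'")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ModelSpecError(f"{path}: duplicated sample id {dup.iloc[0]!r}")
    return dict(zip(df["sample_id"], df["group"]))


def read_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Read a transcript-length TSV with header ``gene_id\\tlength_bp``."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "length_bp"]:
        raise ModelSpecError(f"{path}: expected header 'gene_id\\tlength_bp'")
    lengths = dict(zip(df["gene_id"].astype(str), df["length_bp"].astype(int)))
    bad = [g for g, L in lengths.items() if L < 1]
    if bad:
        raise ModelSpecError(f"{path}: non-positive length for gene {bad[0]!r}")
    return lengths


def read_annotation_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene->term TSV with header ``gene_id\\tterm_id[\\tterm_name]``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "term_id"]:
        raise ModelSpecError(f"{path}: expected header starting 'gene_id\\tterm_id'")
    return df


def read_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a qPCR Ct table with header ``sample_id\\tgene_id\\tct\\trole``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str,
                                            "ct": float, "role": str})
    expected = ["sample_id", "gene_id", "ct", "role"]
    if list(df.columns[:4]) != expected:
        raise ModelSpecError(f"{path}: expected header {expected}")
    bad = set(df["role"]) - {"target", "reference"}
    if bad:
        raise ModelSpecError(f"{path}: unknown role(s) {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {str(c): {str(i): _jsonable(v) for i, v in obj[c].items()}
                for c in obj.columns}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, frozenset, set)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(result: Any, path: str | os.PathLike) -> list[str]:
    """Write a JSON report (machine-readable) plus flat TSV tables.

    ``path`` is the JSON destination; companion TSVs are written next to it
    with the same stem.  Returns the list of paths written.  The result may
    be a :class:`~panicle.plssem.PlsSemFit`,
    :class:`~panicle.inference.BootstrapResult`,
    :class:`~panicle.de.DeResult` or
    :class:`~panicle.enrichment.EnrichmentResult`.
    """
    # local imports avoid an import cycle with the result-owning modules
    from .de import DeResult
    from .enrichment import EnrichmentResult
    from .inference import BootstrapResult
    from .plssem import PlsSemFit

    path = os.fspath(path)
    stem = path[:-5] if path.endswith(".json") else path
    written = [path]

    if isinstance(result, PlsSemFit):
        doc = {
            "kind": "plssem_fit",
            "outer_weights": _jsonable(result.outer_weights),
            "loadings": _jsonable(result.loadings),
            "paths": _jsonable(result.paths),
            "r2": _jsonable(result.r2),
            "ave": _jsonable(result.ave),
            "cr": _jsonable(result.cr),
            "communality": _jsonable(result.communality),
            "total_effects": _jsonable(result.total_effects),
            "iterations": int(result.iterations),
            "converged": bool(result.converged),
        }
        outer = pd.DataFrame({
            "indicator": result.outer_weights.index,
            "lv": [result.block_of[i] for i in result.outer_weights.index],
            "weight": result.outer_weights.to_numpy(),
            "loading": result.loadings.to_numpy(),
        })
        outer.to_csv(stem + "_outer.tsv", sep="\t", index=False)
        rows = [(s, t, result.paths.loc[s, t]) for s, t in result.inner.edges]
        pd.DataFrame(rows, columns=["source", "target", "path"]).to_csv(
            stem + "_paths.tsv", sep="\t", index=False)
        written += [stem + "_outer.tsv", stem + "_paths.tsv"]
    elif isinstance(result, BootstrapResult):
        doc = {
            "kind": "bootstrap",
            "requested_draws": int(result.requested_draws),
            "valid_draws": int(result.valid_draws),
            "discarded_draws": int(result.discarded_draws),
            "seed": int(result.seed),
            "table": _jsonable(result.table),
        }
        tsv = result.table.rename(columns={"boot_se": "se"})[
            ["parameter", "original", "se", "t", "significant"]]
        tsv.to_csv(stem + ".tsv", sep="\t", index=False)
        written.append(stem + ".tsv")
    elif isinstance(result, DeResult):
        doc = {
            "kind": "de",
            "fdr_threshold": float(result.fdr_threshold),
            "n_up": int((result.table["status"] == "up").sum()),
            "n_down": int((result.table["status"] == "down").sum()),
            "table": _jsonable(result.table.drop(columns=["status"])),
            "status": _jsonable(result.table["status"]),
        }
        result.table.to_csv(stem + ".tsv", sep="\t", index_label="gene_id")
        written.append(stem + ".tsv")
    elif isinstance(result, EnrichmentResult):
        doc = {
            "kind": "enrichment",
            "universe_size": int(result.universe_size),
            "query_size": int(result.query_size),
            "table": _jsonable(result.table),
        }
        result.table.to_csv(stem + ".tsv", sep="\t", index=False)
        written.append(stem + ".tsv")
    else:
        raise TypeError(f"cannot write a report for {type(result).__name__}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
    return written


def read_report(path: str | os.PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
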