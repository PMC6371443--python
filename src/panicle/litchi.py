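"""Built-in registry of the six hormone-specific litchi path-model structures.

Each model relates one hormone-related gene block (ABA, BR, IAA, CTK, JA or
SA) to a flowering-related gene block through three transcription-factor
blocks (NACs, MYBs, WRKYs): first-order edges run hormone -> TF, second-order
edges TF -> flowering, and all hormones except IAA additionally carry a
direct hormone -> flowering edge.  The registry also records the reported
number of cases per hormone model and, for the CTK model, the reported
standardized path coefficients, which the synthetic-data generator can use
as ground truth for recovery studies.

How a cases x indicators matrix is constructed from expression data (what a
"case" is, which genes form each block) is left to the user: the case counts
are advisory metadata only, and any matrix with the right block structure is
accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import BlockSpec, InnerModel, ModelSpecError, validate_blocks
from .plssem import PlsSemData

__all__ = ["HormoneModelSpec", "HORMONES", "REPORTED_CASES", "CTK_REPORTED_PATHS",
           "builtin_model", "assemble_model"]

HORMONES = ("ABA", "BR", "IAA", "CTK", "JA", "SA")

REPORTED_CASES = {"ABA": 88, "BR": 41, "IAA": 38, "CTK": 52, "JA": 56, "SA": 59}

TF_BLOCKS = ("NACs", "MYBs", "WRKYs")
FLOWERING = "flowering"

#: Reported standardized inner path coefficients of the CTK model
#: (first order hormone->TF, second order TF->flowering).  The direct
#: CTK->flowering coefficient was not printed and is not listed.
CTK_REPORTED_PATHS: dict[tuple[str, str], float] = {
    ("CTK", "NACs"): 0.945,
    ("CTK", "MYBs"): 0.993,
    ("CTK", "WRKYs"): 0.917,
    ("NACs", FLOWERING): 0.130,
    ("MYBs", FLOWERING): -0.359,
    ("WRKYs", FLOWERING): -0.208,
}


@dataclass(frozen=True)
class HormoneModelSpec:
    """Structure of one hormone model: latent variables, edges, case count."""

    hormone: str
    lv_names: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    reported_cases: int
    reported_paths: dict[tuple[str, str], float] | None = None

    def inner_model(self) -> InnerModel:
        return InnerModel(lv_names=self.lv_names, edges=self.edges)


def builtin_model(hormone: str, direct_edge: bool | None = None) -> HormoneModelSpec:
    """Return the built-in structure for one hormone model.

    ``direct_edge`` overrides whether the hormone -> flowering edge is
    included; by default it is present for every hormone except IAA.
    """
    if hormone not in HORMONES:
        raise ModelSpecError(f"unknown hormone {hormone!r}; expected one of {HORMONES}")
    if direct_edge is None:
        direct_edge = hormone != "IAA"
    edges = [(hormone, tf) for tf in TF_BLOCKS]
    edges += [(tf, FLOWERING) for tf in TF_BLOCKS]
    if direct_edge:
        edges.append((hormone, FLOWERING))
    return HormoneModelSpec(
        hormone=hormone,
        lv_names=(hormone, *TF_BLOCKS, FLOWERING),
        edges=tuple(edges),
        reported_cases=REPORTED_CASES[hormone],
        reported_paths=dict(CTK_REPORTED_PATHS) if hormone == "CTK" else None,
    )


def assemble_model(spec: HormoneModelSpec,
                   block_members: Mapping[str, Sequence[str]],
                   data: PlsSemData) -> tuple[list[BlockSpec], InnerModel]:
    """Turn a structure plus block membership into a runnable model.

    ``block_members`` maps each latent variable to its indicator gene ids,
    which must exist in ``data``.  A case count differing from the reported
    one only triggers an informational warning.
    """
    missing_lv = [lv for lv in spec.lv_names if lv not in block_members]
    if missing_lv:
        raise ModelSpecError(f"block_members missing latent variable {missing_lv[0]!r}")
    available = set(data.indicator_ids)
    blocks = []
    for lv in spec.lv_names:
        members = tuple(block_members[lv])
        unknown = [m for m in members if m not in available]
        if unknown:
            raise ModelSpecError(
                f"block {lv!r}: indicator {unknown[0]!r} not in the data")
        blocks.append(BlockSpec(lv_name=lv, indicators=members))
    validate_blocks(blocks)
    n = data.X.shape[0]
    if n != spec.reported_cases:
        warnings.warn(
            f"{spec.hormone} model: data has {n} cases; the reported case count "
            f"is {spec.reported_cases}", stacklevel=2)
    return blocks, spec.inner_model()
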