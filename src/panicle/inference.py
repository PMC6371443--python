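"""Bootstrap inference for PLS path models.

Cases are resampled with replacement, the model is refit on each resample
(re-standardizing within the resample), and every parameter — outer weights,
loadings, path coefficients and total effects — is sign-aligned to the
original-sample estimate before accumulating ("individual sign changes":
a resampled estimate whose sign differs from the original's is multiplied
by -1).  The bootstrap standard error is the n-1 standard deviation of the
sign-corrected draws; t = |original| / SE is compared with a fixed critical
value (1.96 by default) for the significance flag.

Resamples in which an indicator column has zero variance, or the PLS
iteration fails to converge, are discarded and redrawn; more than 10% of
the requested draws discarded is treated as an error (pathological data).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import BlockSpec, InnerModel, ModelSpecError, RunConfig
from .plssem import PlsSemData, PlsSemFit, _compile_model, _estimate, fit_plssem

__all__ = ["BootstrapResult", "bootstrap_plssem", "summarize_effects", "sign_align"]


@dataclass
class BootstrapResult:
    """Per-parameter bootstrap summary.

    ``table`` columns: parameter, original, boot_mean, boot_se, t,
    significant.  ``t`` is infinite when the bootstrap SE is zero and the
    original estimate is nonzero (a degenerate, noise-free parameter).
    """

    table: pd.DataFrame
    requested_draws: int
    valid_draws: int
    discarded_draws: int
    seed: int
    critical_t: float
    edges: tuple[tuple[str, str], ...]


def _reachable_pairs(inner: InnerModel) -> list[tuple[str, str]]:
    """Ordered (source, target) pairs connected by at least one directed path."""
    g = inner.graph()
    pairs = []
    for s in inner.lv_names:
        reach = nx.descendants(g, s)
        for t in inner.lv_names:
            if t in reach:
                pairs.append((s, t))
    return pairs


def _param_layout(blocks: list[BlockSpec], inner: InnerModel,
                  lvs: list[str]) -> tuple[list[str], list[tuple[int, int]],
                                           list[tuple[int, int]]]:
    """Names plus (row, col) index pairs into B and T for path/total params."""
    order = {lv: i for i, lv in enumerate(lvs)}
    names = [f"weight:{b.lv_name}:{ind}" for b in blocks for ind in b.indicators]
    names += [f"loading:{b.lv_name}:{ind}" for b in blocks for ind in b.indicators]
    edge_ix = [(order[s], order[t]) for s, t in inner.edges]
    names += [f"path:{s}->{t}" for s, t in inner.edges]
    total_pairs = _reachable_pairs(inner)
    total_ix = [(order[s], order[t]) for s, t in total_pairs]
    names += [f"total:{s}->{t}" for s, t in total_pairs]
    return names, edge_ix, total_ix


def sign_align(original: np.ndarray, draw: np.ndarray) -> np.ndarray:
    """Individual sign change: flip every draw entry whose sign disagrees
    with the original estimate.  Idempotent."""
    return np.where(original * draw < 0, -draw, draw)


def _vector(est: dict, edge_ix, total_ix) -> np.ndarray:
    B, T = est["B"], est["T"]
    return np.concatenate([
        np.concatenate(est["w"]),
        np.concatenate(est["lam"]),
        np.array([B[i, j] for i, j in edge_ix]),
        np.array([T[i, j] for i, j in total_ix]),
    ])


def bootstrap_plssem(data: PlsSemData, blocks: list[BlockSpec], inner: InnerModel,
                     config: RunConfig | None = None) -> BootstrapResult:
    """Bootstrap a PLS path model with individual sign changes."""
    config = config or RunConfig()
    cm = _compile_model(data.indicator_ids, blocks, inner)
    est0 = _estimate(data.X, cm, config)
    if not est0["converged"]:
        raise ModelSpecError("full-data fit did not converge; cannot bootstrap")
    names, edge_ix, total_ix = _param_layout(cm.blocks, inner, cm.lvs)
    original = _vector(est0, edge_ix, total_ix)

    B = config.bootstrap_samples
    n = data.X.shape[0]
    rng = np.random.default_rng(config.seed)
    max_discard = int(np.floor(0.1 * B))

    draws = np.empty((B, original.size))
    valid = 0
    discarded = 0
    while valid < B:
        rows = rng.integers(0, n, size=n)
        Xb = data.X[rows]
        ok = not (Xb.std(axis=0, ddof=1) == 0).any()
        estb = None
        if ok:
            try:
                estb = _estimate(Xb, cm, config)
            except ModelSpecError:
                estb = None
        if estb is None or not estb["converged"]:
            discarded += 1
            if discarded > max_discard:
                raise ModelSpecError(
                    f"more than 10% of bootstrap resamples discarded "
                    f"({discarded} of {B} requested)")
            continue
        # individual sign changes: align each draw's sign to the original
        draws[valid] = sign_align(original, _vector(estb, edge_ix, total_ix))
        valid += 1

    boot_mean = draws.mean(axis=0)
    boot_se = draws.std(axis=0, ddof=1) if B > 1 else np.zeros_like(boot_mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(boot_se > 0, np.abs(original) / boot_se,
                     np.where(original != 0, np.inf, 0.0))
    significant = t > config.critical_t
    table = pd.DataFrame({
        "parameter": names,
        "original": original,
        "boot_mean": boot_mean,
        "boot_se": boot_se,
        "t": t,
        "significant": significant,
    })
    return BootstrapResult(table=table, requested_draws=B, valid_draws=valid,
                           discarded_draws=discarded, seed=config.seed,
                           critical_t=config.critical_t, edges=inner.edges)


def _edge_order_label(inner: InnerModel, s: str, t: str) -> str:
    """Structural role of a direct edge in a hormone-TF-flowering style DAG:
    exogenous -> intermediate is "first order", intermediate -> sink is
    "second order", exogenous -> sink is "direct"."""
    s_exog = not inner.predecessors(s)
    t_sink = not inner.successors(t)
    if s_exog and not t_sink:
        return "first order"
    if not s_exog and t_sink:
        return "second order"
    if s_exog and t_sink:
        return "direct"
    return "other"


def summarize_effects(boot: BootstrapResult, fit: PlsSemFit) -> pd.DataFrame:
    """Table of all direct paths and nonzero total effects with bootstrap
    statistics and structural order labels."""
    if tuple(boot.edges) != tuple(fit.inner.edges):
        raise ModelSpecError("bootstrap result and fit come from different models")
    inner = fit.inner
    by_param = boot.table.set_index("parameter")
    rows = []
    for s, t in inner.edges:
        rec = by_param.loc[f"path:{s}->{t}"]
        rows.append({"kind": "path", "source": s, "target": t,
                     "order": _edge_order_label(inner, s, t),
                     "original": rec["original"], "boot_se": rec["boot_se"],
                     "t": rec["t"], "significant": rec["significant"]})
    for s, t in _reachable_pairs(inner):
        rec = by_param.loc[f"total:{s}->{t}"]
        rows.append({"kind": "total", "source": s, "target": t, "order": "total",
                     "original": rec["original"], "boot_se": rec["boot_se"],
                     "t": rec["t"], "significant": rec["significant"]})
    return pd.DataFrame(rows)
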