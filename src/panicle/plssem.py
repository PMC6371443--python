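"""Partial least squares path modeling (PLS-SEM).

The estimator is the classical Lohmöller alternating algorithm with the
path weighting scheme for the inner approximation and Mode A (reflective)
outer estimation:

1. standardize every indicator column (mean 0, sd 1, n-1 denominator);
2. latent scores ``Y_j = standardize(X_j w_j)`` from the current outer
   weights (initialized to 1);
3. inner weights: a predecessor of latent variable j is weighted by its
   coefficient in the multiple OLS regression of Y_j on all of j's
   predecessors; a successor is weighted by its correlation with Y_j;
4. inner proxies ``Z_j = standardize(sum_i e_ji Y_i)``;
5. Mode A update ``w_jk = cor(x_jk, Z_j)``;
6. stop when the largest change of any outer weight (expressed on the
   unit-variance score scale) falls below the tolerance.

After convergence the sign of each latent variable is fixed so that the sum
of its loadings is non-negative (ties broken by the first indicator), path
coefficients come from per-target OLS of each endogenous score on its
predecessors' scores, and total effects are the finite matrix series
``T = sum_p B^p`` (B is nilpotent on a DAG).

The numeric core (:func:`_estimate`) works on plain arrays against a
pre-compiled model so that bootstrap resampling can refit thousands of
times without re-validating or re-wrapping results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import BlockSpec, InnerModel, ModelSpecError, RunConfig, validate_blocks

__all__ = ["PlsSemData", "PlsSemFit", "fit_plssem", "total_effects",
           "quality_criteria", "ave_cr_from_loadings"]


def ave_cr_from_loadings(loadings: Sequence[float]) -> tuple[float, float]:
    """Average variance extracted and composite reliability of one block.

    AVE is the mean squared loading; CR = (sum lam)^2 / ((sum lam)^2 +
    sum(1 - lam^2)).  A single-indicator block has AVE = CR = 1.
    """
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ModelSpecError("a block needs at least one loading")
    ave = float(np.mean(lam ** 2))
    sum_l = float(lam.sum())
    cr = sum_l ** 2 / (sum_l ** 2 + float(np.sum(1.0 - lam ** 2)))
    return ave, cr


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class PlsSemData:
    """Cases x indicators data for a PLS path model."""

    case_ids: list[str]
    indicator_ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if n < 3:
            raise ModelSpecError(f"need at least 3 cases, got {n}")
        if len(self.case_ids) != n or len(self.indicator_ids) != p:
            raise ModelSpecError("id lists do not match the matrix shape")
        if len(set(self.indicator_ids)) != p:
            raise ModelSpecError("indicator ids are not unique")
        if np.isnan(self.X).any():
            raise ModelSpecError("missing values in the data matrix")
        sd = self.X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = self.indicator_ids[int(np.argmax(sd == 0))]
            raise ModelSpecError(f"zero-variance indicator column {bad!r}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PlsSemData":
        return cls(case_ids=[str(i) for i in df.index],
                   indicator_ids=[str(c) for c in df.columns],
                   X=df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.case_ids, columns=self.indicator_ids)


@dataclass
class PlsSemFit:
    """Everything the estimator produces for one model on one dataset."""

    blocks: list[BlockSpec]
    inner: InnerModel
    outer_weights: pd.Series        # per indicator, unit-variance score scale
    loadings: pd.Series             # cor(indicator, own lv score)
    scores: pd.DataFrame            # cases x lvs, standardized
    paths: pd.DataFrame             # lvs x lvs, B[source, target]
    r2: pd.Series                   # per endogenous lv
    ave: pd.Series
    cr: pd.Series
    communality: pd.Series
    total_effects: pd.DataFrame     # lvs x lvs
    iterations: int
    converged: bool
    block_of: dict[str, str] = field(default_factory=dict)  # indicator -> lv


@dataclass
class _CompiledModel:
    """Validated, array-indexed form of (blocks, inner) for one data layout."""

    lvs: list[str]
    blocks: list[BlockSpec]
    idx: list[np.ndarray]           # per block: column indices into X
    preds_pos: list[np.ndarray]     # per lv: positions of predecessor lvs
    succs_pos: list[np.ndarray]


def _compile_model(indicator_ids: Sequence[str], blocks: Sequence[BlockSpec],
                   inner: InnerModel) -> _CompiledModel:
    blocks = list(blocks)
    validate_blocks(blocks)
    block_lvs = [b.lv_name for b in blocks]
    if set(block_lvs) != set(inner.lv_names):
        raise ModelSpecError(
            f"blocks define lvs {sorted(block_lvs)} but inner model names "
            f"{sorted(inner.lv_names)}")
    col_of = {ind: i for i, ind in enumerate(indicator_ids)}
    for b in blocks:
        missing = [i for i in b.indicators if i not in col_of]
        if missing:
            raise ModelSpecError(
                f"block {b.lv_name!r}: indicator {missing[0]!r} not in the data")
    for lv in block_lvs:
        if not inner.predecessors(lv) and not inner.successors(lv):
            raise ModelSpecError(f"latent variable {lv!r} has no inner-model edge")
    lvs = list(inner.lv_names)
    order = {lv: i for i, lv in enumerate(lvs)}
    blocks = sorted(blocks, key=lambda b: order[b.lv_name])
    return _CompiledModel(
        lvs=lvs,
        blocks=blocks,
        idx=[np.array([col_of[i] for i in b.indicators]) for b in blocks],
        preds_pos=[np.array([order[p] for p in inner.predecessors(lv)], dtype=int)
                   for lv in lvs],
        succs_pos=[np.array([order[s] for s in inner.successors(lv)], dtype=int)
                   for lv in lvs],
    )


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def _solve_ols(R: np.ndarray, r: np.ndarray, target: str, preds: Sequence[str]) -> np.ndarray:
    """OLS coefficients on standardized variables from the correlation system."""
    if R.shape[0] == 1:
        return r / R[0, 0]
    if np.linalg.cond(R) > 1e12:
        raise ModelSpecError(
            f"collinear predecessor scores for {target!r}: {list(preds)}")
    return np.linalg.solve(R, r)


def _estimate(X_raw: np.ndarray, cm: _CompiledModel, config: RunConfig) -> dict:
    """Run the Lohmöller iteration on raw data; returns plain arrays."""
    n = X_raw.shape[0]
    L = len(cm.lvs)
    nm1 = n - 1
    X = _standardize_columns(X_raw)

    # outer weights on the unit-variance score scale
    w = []
    for j in range(L):
        wj = np.ones(len(cm.idx[j]))
        score = X[:, cm.idx[j]] @ wj
        sd = score.std(ddof=1)
        if sd == 0:
            raise ModelSpecError(
                f"initial score of block {cm.lvs[j]!r} has zero variance")
        w.append(wj / sd)

    converged = False
    iterations = 0
    delta = np.inf
    Y = np.empty((n, L))
    for iteration in range(1, config.max_iterations + 1):
        iterations = iteration
        for j in range(L):
            Y[:, j] = X[:, cm.idx[j]] @ w[j]
        Y = _standardize_columns(Y)

        # inner proxies (path weighting scheme)
        Ryy = Y.T @ Y / nm1
        Z = np.empty_like(Y)
        for j in range(L):
            e = np.zeros(L)
            p = cm.preds_pos[j]
            if p.size:
                e[p] = _solve_ols(Ryy[np.ix_(p, p)], Ryy[p, j],
                                  cm.lvs[j], [cm.lvs[q] for q in p])
            s = cm.succs_pos[j]
            if s.size:
                e[s] = Ryy[s, j]
            z = Y @ e
            zsd = z.std(ddof=1)
            if zsd == 0:
                raise ModelSpecError(f"degenerate inner proxy for {cm.lvs[j]!r}")
            Z[:, j] = (z - z.mean()) / zsd

        # Mode A outer update
        delta = 0.0
        w_new = []
        for j in range(L):
            wj = X[:, cm.idx[j]].T @ Z[:, j] / nm1
            score = X[:, cm.idx[j]] @ wj
            sd = score.std(ddof=1)
            if sd == 0:
                raise ModelSpecError(
                    f"outer weights of block {cm.lvs[j]!r} collapsed to zero")
            wj = wj / sd
            delta = max(delta, float(np.abs(wj - w[j]).max()))
            w_new.append(wj)
        w = w_new
        if delta < config.tolerance:
            converged = True
            break

    for j in range(L):
        Y[:, j] = X[:, cm.idx[j]] @ w[j]
    Y = _standardize_columns(Y)

    # loadings and the sign convention (sum of loadings >= 0 per lv)
    lam = []
    for j in range(L):
        lj = X[:, cm.idx[j]].T @ Y[:, j] / nm1
        s = lj.sum()
        if s < 0 or (s == 0 and lj[0] < 0):
            Y[:, j] = -Y[:, j]
            w[j] = -w[j]
            lj = -lj
        lam.append(lj)

    # inner path coefficients by per-target OLS on the final scores
    Ryy = Y.T @ Y / nm1
    B = np.zeros((L, L))
    r2 = np.full(L, np.nan)
    for j in range(L):
        p = cm.preds_pos[j]
        if not p.size:
            continue
        coef = _solve_ols(Ryy[np.ix_(p, p)], Ryy[p, j],
                          cm.lvs[j], [cm.lvs[q] for q in p])
        B[p, j] = coef
        r2[j] = float(coef @ Ryy[p, j])

    # total effects: finite series of the nilpotent path matrix
    T = np.zeros_like(B)
    P = np.eye(L)
    for _ in range(L):
        P = P @ B
        T += P

    return {"w": w, "lam": lam, "Y": Y, "B": B, "T": T, "r2": r2,
            "iterations": iterations, "converged": converged, "delta": delta}


def fit_plssem(data: PlsSemData, blocks: Sequence[BlockSpec], inner: InnerModel,
               config: RunConfig | None = None) -> PlsSemFit:
    """Estimate a PLS path model (path weighting scheme, Mode A)."""
    config = config or RunConfig()
    cm = _compile_model(data.indicator_ids, blocks, inner)
    est = _estimate(data.X, cm, config)
    if not est["converged"]:
        warnings.warn(f"PLS algorithm did not converge in {config.max_iterations} "
                      f"iterations (last max weight change {est['delta']:.3g})",
                      ConvergenceWarning, stacklevel=2)

    lvs = cm.lvs
    ave, cr, comm = {}, {}, {}
    for j, b in enumerate(cm.blocks):
        ave[b.lv_name], cr[b.lv_name] = ave_cr_from_loadings(est["lam"][j])
        comm[b.lv_name] = ave[b.lv_name]

    ind_index = [i for b in cm.blocks for i in b.indicators]
    r2 = {lv: est["r2"][j] for j, lv in enumerate(lvs) if not np.isnan(est["r2"][j])}
    return PlsSemFit(
        blocks=cm.blocks,
        inner=inner,
        outer_weights=pd.Series(np.concatenate(est["w"]), index=ind_index, name="weight"),
        loadings=pd.Series(np.concatenate(est["lam"]), index=ind_index, name="loading"),
        scores=pd.DataFrame(est["Y"], index=data.case_ids, columns=lvs),
        paths=pd.DataFrame(est["B"], index=lvs, columns=lvs),
        r2=pd.Series(r2, name="r2", dtype=float),
        ave=pd.Series(ave, name="ave", dtype=float),
        cr=pd.Series(cr, name="cr", dtype=float),
        communality=pd.Series(comm, name="communality", dtype=float),
        total_effects=pd.DataFrame(est["T"], index=lvs, columns=lvs),
        iterations=est["iterations"],
        converged=est["converged"],
        block_of={i: b.lv_name for b in cm.blocks for i in b.indicators},
    )


def total_effects(B: pd.DataFrame, inner: InnerModel) -> pd.DataFrame:
    """Total effects T[s, t] = sum over all directed paths s..t of the product
    of edge coefficients, computed as the finite series sum_{p=1..L} B^p."""
    lvs = list(inner.lv_names)
    Bm = B.loc[lvs, lvs].to_numpy(dtype=float)
    support = np.zeros_like(Bm, dtype=bool)
    for s, t in inner.edges:
        support[lvs.index(s), lvs.index(t)] = True
    if (Bm[~support] != 0).any():
        raise ModelSpecError("path matrix has a nonzero entry off the inner-model edges")
    T = np.zeros_like(Bm)
    P = np.eye(len(lvs))
    for _ in range(len(lvs)):
        P = P @ Bm
        T += P
    return pd.DataFrame(T, index=lvs, columns=lvs)


def quality_criteria(fit: PlsSemFit) -> pd.DataFrame:
    """Per-latent-variable AVE, composite reliability and communality.

    ``meets_thresholds`` applies the conventional convergent-validity and
    internal-consistency cutoffs AVE >= 0.5 and CR >= 0.7.
    """
    lvs = list(fit.inner.lv_names)
    table = pd.DataFrame({
        "ave": fit.ave.reindex(lvs),
        "cr": fit.cr.reindex(lvs),
        "communality": fit.communality.reindex(lvs),
    })
    table["meets_thresholds"] = (table["ave"] >= 0.5) & (table["cr"] >= 0.7)
    return table
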