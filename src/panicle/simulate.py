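"""Seeded generators for every input the pipeline consumes, with recorded
ground truth, plus the 2^-ddCt relative quantification that pairs with the
Ct generator.

Every generator owns one `numpy.random.Generator` seeded explicitly, so a
rerun with the same parameters and seed is bit-identical.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import Annotation
from .model import ExpressionMatrix, InnerModel, ModelSpecError, SyntheticTruth
from .plssem import PlsSemData

__all__ = [
    "simulate_sem_dataset",
    "simulate_counts",
    "simulate_annotation",
    "simulate_ct",
    "relative_quantification",
]


def implied_lv_covariance(inner: InnerModel, B: pd.DataFrame) -> pd.DataFrame:
    """Latent covariance implied by unit-variance recursive structural
    equations with independent exogenous variables and residuals."""
    order = inner.topological_order()
    lvs = list(inner.lv_names)
    S = pd.DataFrame(np.zeros((len(lvs), len(lvs))), index=lvs, columns=lvs)
    for lv in order:
        preds = inner.predecessors(lv)
        S.loc[lv, lv] = 1.0
        if not preds:
            continue
        b = np.array([B.loc[p, lv] for p in preds])
        for other in order:
            if other == lv:
                continue
            cov = float(b @ np.array([S.loc[p, other] for p in preds]))
            # covariance with later variables is filled when they are visited
            if S.loc[other, other] != 0.0:
                S.loc[lv, other] = cov
                S.loc[other, lv] = cov
    return S


def simulate_sem_dataset(inner: InnerModel,
                         b_true: Mapping[tuple[str, str], float] | pd.DataFrame,
                         loadings: Mapping[str, Sequence[float]],
                         n: int, seed: int = 0) -> tuple[PlsSemData, SyntheticTruth]:
    """Generate cases x indicators data from a known recursive path model.

    Exogenous latent variables are standard normal; every endogenous one is
    the coefficient-weighted sum of its predecessors plus a residual scaled
    so the latent variance is 1 (requires b' S b <= 1 where S is the implied
    predecessor covariance).  Each indicator is lam * lv + sqrt(1 - lam^2) *
    independent noise, so loadings of 1 give noise-free indicators.
    """
    if n < 3:
        raise ModelSpecError(f"need n >= 3 cases, got {n}")
    lvs = list(inner.lv_names)
    B = pd.DataFrame(np.zeros((len(lvs), len(lvs))), index=lvs, columns=lvs)
    if isinstance(b_true, pd.DataFrame):
        B.loc[b_true.index, b_true.columns] = b_true
    else:
        for (s, t), v in b_true.items():
            B.loc[s, t] = float(v)
    edge_set = set(inner.edges)
    nz = [(s, t) for s in lvs for t in lvs if B.loc[s, t] != 0.0]
    off = [e for e in nz if e not in edge_set]
    if off:
        raise ModelSpecError(f"coefficient on a non-edge {off[0]}")
    missing = [lv for lv in lvs if lv not in loadings]
    if missing:
        raise ModelSpecError(f"no loadings given for block {missing[0]!r}")
    for lv in lvs:
        lam = np.asarray(loadings[lv], dtype=float)
        if lam.size == 0 or (np.abs(lam) > 1).any():
            raise ModelSpecError(f"block {lv!r}: loadings must be nonempty with |lam| <= 1")

    S = implied_lv_covariance(inner, B)
    rng = np.random.default_rng(seed)
    scores = {}
    for lv in inner.topological_order():
        preds = inner.predecessors(lv)
        if not preds:
            scores[lv] = rng.standard_normal(n)
            continue
        b = np.array([B.loc[p, lv] for p in preds])
        Spp = S.loc[preds, preds].to_numpy()
        explained = float(b @ Spp @ b)
        if explained > 1.0 + 1e-12:
            raise ModelSpecError(
                f"infeasible coefficients: implied variance of {lv!r} is "
                f"{explained:.4f} > 1 before adding the residual")
        resid_sd = np.sqrt(max(0.0, 1.0 - explained))
        scores[lv] = sum(B.loc[p, lv] * scores[p] for p in preds) \
            + resid_sd * rng.standard_normal(n)

    cols = []
    names = []
    lam_truth = {}
    for lv in lvs:
        lam = np.asarray(loadings[lv], dtype=float)
        lam_truth[lv] = tuple(float(v) for v in lam)
        for k, l in enumerate(lam, 1):
            noise_sd = np.sqrt(max(0.0, 1.0 - l * l))
            x = l * scores[lv] + noise_sd * rng.standard_normal(n)
            cols.append(x)
            names.append(f"{lv}_x{k}")
    X = np.column_stack(cols)
    data = PlsSemData(case_ids=[f"case{i+1}" for i in range(n)],
                      indicator_ids=names, X=X)
    truth = SyntheticTruth(inner_paths=B, loadings=lam_truth)
    return data, truth


def simulate_counts(n_genes: int, group_sizes: tuple[int, int] = (3, 3),
                    base_mean: float = 100.0, dispersion: float = 0.1,
                    de_fraction: float = 0.0, de_log2fc: float = 2.0,
                    size_factors: Sequence[float] | None = None,
                    group_labels: tuple[str, str] = ("DP", "SP"),
                    seed: int = 0) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Negative-binomial count matrix for a two-condition replicated design.

    Counts for gene g in sample j are NB with mean s_j * mu_g * 2^(lfc_g)
    in the second condition (lfc_g = de_log2fc for planted DE genes, else 0)
    and dispersion alpha; alpha = 0 is the Poisson limit.  The default 3 + 3
    layout mirrors a triplicated two-treatment RNA-seq design.
    """
    if dispersion < 0:
        raise ModelSpecError("dispersion must be >= 0")
    if not 0 <= de_fraction < 1:
        raise ModelSpecError("de_fraction must be in [0, 1)")
    if base_mean <= 0 or n_genes < 1:
        raise ModelSpecError("need base_mean > 0 and n_genes >= 1")
    n1, n2 = group_sizes
    samples = [f"{group_labels[0]}{i+1}" for i in range(n1)] + \
              [f"{group_labels[1]}{i+1}" for i in range(n2)]
    if size_factors is None:
        sf = np.ones(n1 + n2)
    else:
        sf = np.asarray(size_factors, dtype=float)
        if sf.shape != (n1 + n2,) or (sf <= 0).any():
            raise ModelSpecError("size_factors must be positive, one per sample")
    rng = np.random.default_rng(seed)
    genes = [f"g{i+1:05d}" for i in range(n_genes)]
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    lfc = np.zeros(n_genes)
    lfc[de_idx] = de_log2fc
    group2 = np.array([0] * n1 + [1] * n2)
    mean = sf[np.newaxis, :] * base_mean * np.power(2.0, np.outer(lfc, group2))
    if dispersion == 0:
        counts = rng.poisson(mean)
    else:
        shape = 1.0 / dispersion
        p = shape / (shape + mean)
        counts = rng.negative_binomial(shape, p)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    condition = {s: (group_labels[0] if g == 0 else group_labels[1])
                 for s, g in zip(samples, group2)}
    em = ExpressionMatrix(values=df, value_kind="counts", condition=condition)
    truth = SyntheticTruth(
        de_genes=frozenset(genes[i] for i in de_idx),
        de_log2fc={genes[i]: float(de_log2fc) for i in de_idx},
        dispersion=float(dispersion),
        size_factors=dict(zip(samples, sf.astype(float))),
    )
    return em, truth


def simulate_annotation(universe_size: int = 1000, n_terms: int = 50,
                        term_size: int = 20, enriched_terms: int = 3,
                        query_size: int = 100, enrichment_factor: float = 5.0,
                        seed: int = 0) -> tuple[Annotation, frozenset[str], SyntheticTruth]:
    """Annotation universe with planted enriched terms and a matching query.

    Terms are random gene subsets of the universe; the query is drawn
    without replacement with sampling weight ``enrichment_factor`` for genes
    belonging to any planted term (factor 1 gives a null query).
    """
    if term_size > universe_size:
        raise ModelSpecError("term_size cannot exceed universe_size")
    if enriched_terms > n_terms:
        raise ModelSpecError("enriched_terms cannot exceed n_terms")
    if query_size > universe_size:
        raise ModelSpecError("query_size cannot exceed universe_size")
    if enrichment_factor <= 0:
        raise ModelSpecError("enrichment_factor must be > 0")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i+1:05d}" for i in range(universe_size)])
    terms = [f"T{i+1:03d}" for i in range(n_terms)]
    term_genes = {t: frozenset(genes[rng.choice(universe_size, term_size, replace=False)])
                  for t in terms}
    planted = frozenset(rng.choice(terms, size=enriched_terms, replace=False)) \
        if enriched_terms else frozenset()
    favored = set().union(*(term_genes[t] for t in planted)) if planted else set()
    weights = np.array([enrichment_factor if g in favored else 1.0 for g in genes])
    weights = weights / weights.sum()
    query = frozenset(genes[rng.choice(universe_size, query_size, replace=False,
                                       p=weights)])
    gene_to_terms: dict[str, set[str]] = {}
    for t, gs in term_genes.items():
        for g in gs:
            gene_to_terms.setdefault(g, set()).add(t)
    # genes hit by no term stay unannotated (outside the universe)
    ann = Annotation(gene_to_terms={g: frozenset(ts) for g, ts in gene_to_terms.items()})
    truth = SyntheticTruth(enriched_terms=planted)
    return ann, query, truth


def simulate_ct(genes: Sequence[str], samples: Sequence[str],
                true_fold_changes: Mapping[str, float] | pd.DataFrame,
                reference_ct: float = 20.0, noise_sd: float = 0.0,
                calibrator: str | None = None, reference_gene: str = "actin",
                baseline_dct: float = 4.0, replicates: int = 1,
                seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Ct table for 2^-ddCt quantification with known fold changes.

    ``true_fold_changes`` is either gene -> fold change (applied to every
    non-calibrator sample; the calibrator is fixed at 1) or a genes x
    samples DataFrame.  The target Ct of gene g in sample s is
    ``reference_ct + baseline_dct - log2(fc[g, s]) + noise``; with
    ``noise_sd = 0`` the downstream quantification recovers the fold
    changes exactly.
    """
    if noise_sd < 0:
        raise ModelSpecError("noise_sd must be >= 0")
    samples = list(samples)
    genes = list(genes)
    calibrator = calibrator or samples[0]
    if calibrator not in samples:
        raise ModelSpecError(f"calibrator {calibrator!r} not among the samples")
    if isinstance(true_fold_changes, pd.DataFrame):
        fc = true_fold_changes.reindex(index=genes, columns=samples).astype(float)
    else:
        fc = pd.DataFrame(1.0, index=genes, columns=samples)
        for g, v in true_fold_changes.items():
            for s in samples:
                if s != calibrator:
                    fc.loc[g, s] = float(v)
    if fc.isna().any().any() or (fc.to_numpy() <= 0).any():
        raise ModelSpecError("fold changes must be positive and cover every gene/sample")
    rng = np.random.default_rng(seed)
    rows = []
    for s in samples:
        for _ in range(replicates):
            rows.append((s, reference_gene, reference_ct + noise_sd * rng.standard_normal(),
                         "reference"))
        for g in genes:
            for _ in range(replicates):
                ct = reference_ct + baseline_dct - np.log2(fc.loc[g, s]) \
                    + noise_sd * rng.standard_normal()
                rows.append((s, g, float(ct), "target"))
    table = pd.DataFrame(rows, columns=["sample_id", "gene_id", "ct", "role"])
    truth = SyntheticTruth(fold_changes=fc)
    return table, truth


def relative_quantification(ct_table: pd.DataFrame,
                            calibrator: str | None = None) -> pd.DataFrame:
    """Relative quantification by the 2^-ddCt method.

    Technical-replicate Cts are averaged per (sample, gene, role); per gene
    and sample, dCt = Ct_target - Ct_reference; ddCt subtracts the
    calibrator sample's dCt; RQ = 2^(-ddCt), so the calibrator's RQ is 1
    exactly.  Returns a genes x samples DataFrame of RQ values.
    """
    required = {"sample_id", "gene_id", "ct", "role"}
    if not required <= set(ct_table.columns):
        raise ModelSpecError(f"Ct table must have columns {sorted(required)}")
    samples = list(dict.fromkeys(ct_table["sample_id"]))
    calibrator = calibrator or samples[0]
    if calibrator not in samples:
        raise ModelSpecError(f"no calibrator sample {calibrator!r} in the table")
    ref = ct_table[ct_table["role"] == "reference"].groupby("sample_id")["ct"].mean()
    missing_ref = [s for s in samples if s not in ref.index]
    if missing_ref:
        raise ModelSpecError(f"sample {missing_ref[0]!r} has no reference Ct")
    tgt = (ct_table[ct_table["role"] == "target"]
           .groupby(["gene_id", "sample_id"])["ct"].mean().unstack("sample_id"))
    if tgt.isna().any().any():
        g = tgt.index[tgt.isna().any(axis=1)][0]
        raise ModelSpecError(f"gene {g!r} is missing a target Ct in some sample")
    dct = tgt - ref.reindex(tgt.columns)
    ddct = dct.sub(dct[calibrator], axis=0)
    rq = np.power(2.0, -ddct)
    return rq[samples]
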