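import numpy as np
import pandas as pd
import pytest

import panicle as pn
from panicle.model import ModelSpecError


class TestSemGenerator:
    def test_single_edge_correlation_converges_to_beta(self):
        inner = pn.InnerModel(("a", "b"), (("a", "b"),))
        data, truth = pn.simulate_sem_dataset(
            inner, {("a", "b"): 0.5}, {"a": (1.0,), "b": (1.0,)}, n=50_000, seed=1)
        r = np.corrcoef(data.X[:, 0], data.X[:, 1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.01)
        assert truth.inner_paths.loc["a", "b"] == 0.5

    def test_null_model_uncorrelated(self):
        spec = pn.builtin_model("CTK")
        inner = spec.inner_model()
        n = 10_000
        data, _ = pn.simulate_sem_dataset(
            inner, {e: 0.0 for e in spec.edges},
            {lv: (1.0,) for lv in inner.lv_names}, n=n, seed=2)
        corr = np.corrcoef(data.X, rowvar=False)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(n)

    def test_latent_variances_near_unity(self):
        spec = pn.builtin_model("CTK")
        inner = spec.inner_model()
        b = dict(pn.CTK_REPORTED_PATHS)
        b[("CTK", "flowering")] = 0.0
        n = 5000
        data, _ = pn.simulate_sem_dataset(inner, b,
                                          {lv: (1.0,) for lv in inner.lv_names},
                                          n=n, seed=3)
        sd = data.X.std(axis=0, ddof=1)
        assert np.abs(sd - 1.0).max() < 3 / np.sqrt(n) * 2

    def test_deterministic_and_infeasible(self):
        inner = pn.InnerModel(("a", "b", "c"), (("a", "c"), ("b", "c")))
        loadings = {lv: (1.0,) for lv in inner.lv_names}
        d1, _ = pn.simulate_sem_dataset(inner, {("a", "c"): 0.5, ("b", "c"): 0.5},
                                        loadings, n=100, seed=9)
        d2, _ = pn.simulate_sem_dataset(inner, {("a", "c"): 0.5, ("b", "c"): 0.5},
                                        loadings, n=100, seed=9)
        assert (d1.X == d2.X).all()
        with pytest.raises(ModelSpecError, match="infeasible"):
            pn.simulate_sem_dataset(inner, {("a", "c"): 0.9, ("b", "c"): 0.9},
                                    loadings, n=100, seed=9)

    def test_noisy_loadings_attenuate_indicator_correlation(self):
        inner = pn.InnerModel(("a", "b"), (("a", "b"),))
        data, _ = pn.simulate_sem_dataset(inner, {("a", "b"): 0.8},
                                          {"a": (0.7,), "b": (0.7,)}, n=50_000, seed=4)
        r = np.corrcoef(data.X[:, 0], data.X[:, 1])[0, 1]
        assert r == pytest.approx(0.8 * 0.7 * 0.7, abs=0.02)


class TestCountGenerator:
    def test_poisson_limit_moments(self):
        em, _ = pn.simulate_counts(n_genes=5000, dispersion=0.0, base_mean=100.0,
                                   seed=5)
        vals = em.values.to_numpy(dtype=float)
        mean = vals.mean()
        var = vals.var(axis=1, ddof=1).mean()
        assert mean == pytest.approx(100.0, rel=0.02)
        assert var == pytest.approx(mean, rel=0.1)

    def test_overdispersion_above_poisson(self):
        em, _ = pn.simulate_counts(n_genes=5000, dispersion=0.2, base_mean=100.0,
                                   seed=6)
        vals = em.values.to_numpy(dtype=float)
        # NB variance mu + alpha*mu^2 = 100 + 2000
        assert vals.var(axis=1, ddof=1).mean() == pytest.approx(2100, rel=0.2)

    def test_no_de_truth_empty_and_deterministic(self):
        em1, truth = pn.simulate_counts(n_genes=100, de_fraction=0.0, seed=7)
        assert truth.de_genes == frozenset()
        em2, _ = pn.simulate_counts(n_genes=100, de_fraction=0.0, seed=7)
        assert em1.values.equals(em2.values)

    def test_planted_fold_change_visible(self):
        em, truth = pn.simulate_counts(n_genes=200, de_fraction=0.1, de_log2fc=2.0,
                                       dispersion=0.01, base_mean=500.0, seed=8)
        de = sorted(truth.de_genes)
        sp = em.values.loc[de, ["SP1", "SP2", "SP3"]].mean(axis=1)
        dp = em.values.loc[de, ["DP1", "DP2", "DP3"]].mean(axis=1)
        assert np.log2(sp / dp).mean() == pytest.approx(2.0, abs=0.2)

    def test_invalid_parameters(self):
        with pytest.raises(ModelSpecError):
            pn.simulate_counts(n_genes=10, dispersion=-1.0)
        with pytest.raises(ModelSpecError):
            pn.simulate_counts(n_genes=10, de_fraction=1.0)


class TestAnnotationGenerator:
    def test_null_factor_rarely_tops_planted_terms(self):
        import warnings
        hits = 0
        for seed in range(50):
            ann, query, truth = pn.simulate_annotation(
                universe_size=300, n_terms=50, term_size=10, enriched_terms=3,
                query_size=50, enrichment_factor=1.0, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # unannotated drops
                res = pn.enrich_terms(query, ann, min_overlap=1)
            if len(res.table) and res.table.iloc[0]["term_id"] in truth.enriched_terms:
                hits += 1
        # chance level is 3/50 per run; allow binomial noise above it
        assert hits <= 8

    def test_planted_factor_ranks_first(self):
        import warnings
        hits = 0
        for seed in range(50):
            ann, query, truth = pn.simulate_annotation(
                universe_size=1000, n_terms=50, term_size=20, enriched_terms=3,
                query_size=100, enrichment_factor=5.0, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                res = pn.enrich_terms(query, ann, min_overlap=1)
            if res.table.iloc[0]["term_id"] in truth.enriched_terms:
                hits += 1
        assert hits >= 45

    def test_deterministic(self):
        a1, q1, _ = pn.simulate_annotation(seed=3)
        a2, q2, _ = pn.simulate_annotation(seed=3)
        assert q1 == q2 and a1.gene_to_terms == a2.gene_to_terms


class TestCtAndQuantification:
    def test_unit_fold_change_noise_free(self):
        table, _ = pn.simulate_ct(["g1"], ["cal", "s2"], {"g1": 1.0}, noise_sd=0.0)
        rq = pn.relative_quantification(table)
        assert rq.loc["g1", "cal"] == pytest.approx(1.0, abs=1e-12)
        assert rq.loc["g1", "s2"] == pytest.approx(1.0, abs=1e-12)

    def test_fourfold_recovered_exactly(self):
        table, truth = pn.simulate_ct(["g1"], ["cal", "s2"], {"g1": 4.0}, noise_sd=0.0)
        # ddCt = -2 for the treated sample
        rq = pn.relative_quantification(table)
        assert rq.loc["g1", "s2"] == pytest.approx(4.0, abs=1e-12)
        assert truth.fold_changes.loc["g1", "s2"] == 4.0

    def test_hand_computed_ddct(self):
        table = pd.DataFrame({
            "sample_id": ["cal", "cal", "s2", "s2"],
            "gene_id": ["actin", "g1", "actin", "g1"],
            "ct": [20.0, 26.0, 20.0, 24.0],
            "role": ["reference", "target", "reference", "target"],
        })
        rq = pn.relative_quantification(table, calibrator="cal")
        assert rq.loc["g1", "s2"] == pytest.approx(4.0, abs=1e-12)
        assert rq.loc["g1", "cal"] == 1.0

    def test_technical_replicates_average(self):
        single, _ = pn.simulate_ct(["g1"], ["cal", "s2"], {"g1": 2.0},
                                   noise_sd=0.0, replicates=1)
        triple, _ = pn.simulate_ct(["g1"], ["cal", "s2"], {"g1": 2.0},
                                   noise_sd=0.0, replicates=3)
        rq1 = pn.relative_quantification(single)
        rq3 = pn.relative_quantification(triple)
        assert rq3.loc["g1", "s2"] == pytest.approx(rq1.loc["g1", "s2"], abs=1e-12)

    def test_deterministic_with_noise(self):
        t1, _ = pn.simulate_ct(["g1"], ["cal", "s2"], {"g1": 2.0}, noise_sd=0.5, seed=4)
        t2, _ = pn.simulate_ct(["g1"], ["cal", "s2"], {"g1": 2.0}, noise_sd=0.5, seed=4)
        assert t1.equals(t2)

    def test_errors(self):
        with pytest.raises(ModelSpecError, match="positive"):
            pn.simulate_ct(["g1"], ["cal", "s2"], {"g1": -2.0})
        table, _ = pn.simulate_ct(["g1"], ["cal", "s2"], {"g1": 2.0})
        with pytest.raises(ModelSpecError, match="reference"):
            pn.relative_quantification(table[table["role"] == "target"])
        with pytest.raises(ModelSpecError, match="calibrator"):
            pn.relative_quantification(table, calibrator="nope")
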