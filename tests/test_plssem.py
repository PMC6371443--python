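import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import panicle as pn
from panicle.model import ModelSpecError
from panicle.plssem import ConvergenceWarning

from .conftest import two_lv_data


def path_enumeration_oracle(B, inner):
    """Total effects by explicit enumeration of all directed paths."""
    g = inner.graph()
    lvs = list(inner.lv_names)
    T = pd.DataFrame(0.0, index=lvs, columns=lvs)
    for s in lvs:
        for t in lvs:
            if s == t:
                continue
            for path in nx.all_simple_paths(g, s, t):
                T.loc[s, t] += np.prod([B.loc[a, b] for a, b in zip(path, path[1:])])
    return T


class TestFit:
    def test_identical_columns_give_unit_path(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        data = pn.PlsSemData([f"c{i}" for i in range(30)], ["a1", "b1"],
                             np.column_stack([x, x.copy()]))
        blocks = [pn.BlockSpec("A", ("a1",)), pn.BlockSpec("B", ("b1",))]
        inner = pn.InnerModel(("A", "B"), (("A", "B"),))
        fit = pn.fit_plssem(data, blocks, inner)
        assert fit.paths.loc["A", "B"] == pytest.approx(1.0, abs=1e-12)
        assert fit.loadings["a1"] == pytest.approx(1.0, abs=1e-12)
        assert fit.r2["B"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_two_lv_path_equals_pearson(self, seed):
        data, blocks, inner = two_lv_data(n=80, beta=0.4, seed=seed)
        fit = pn.fit_plssem(data, blocks, inner)
        r = np.corrcoef(data.X[:, 0], data.X[:, 1])[0, 1]
        assert fit.paths.loc["A", "B"] == pytest.approx(r, abs=1e-10)

    def test_scores_standardized_and_B_on_edges_only(self):
        data, blocks, inner = two_lv_data(n=50, beta=0.6, seed=5)
        fit = pn.fit_plssem(data, blocks, inner)
        Y = fit.scores.to_numpy()
        np.testing.assert_allclose(Y.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(Y.std(axis=0, ddof=1), 1.0, atol=1e-8)
        assert fit.paths.loc["B", "A"] == 0.0

    def test_scale_invariance(self):
        """Multiplying a raw indicator by a positive constant changes nothing."""
        spec = pn.builtin_model("CTK")
        inner = spec.inner_model()
        loadings = {lv: (0.9, 0.8) for lv in inner.lv_names}
        b = {e: 0.4 if e[1] != "flowering" else 0.2 for e in spec.edges}
        data, _ = pn.simulate_sem_dataset(inner, b, loadings, n=100, seed=6)
        blocks = [pn.BlockSpec(lv, (f"{lv}_x1", f"{lv}_x2")) for lv in inner.lv_names]
        fit1 = pn.fit_plssem(data, blocks, inner)
        X2 = data.X.copy()
        X2[:, 3] *= 1000.0
        data2 = pn.PlsSemData(data.case_ids, data.indicator_ids, X2)
        fit2 = pn.fit_plssem(data2, blocks, inner)
        np.testing.assert_allclose(fit1.paths.to_numpy(), fit2.paths.to_numpy(),
                                   atol=1e-10)
        np.testing.assert_allclose(fit1.loadings.to_numpy(), fit2.loadings.to_numpy(),
                                   atol=1e-10)

    def test_sign_determinism_and_repeatability(self):
        data, blocks, inner = two_lv_data(n=60, beta=0.5, seed=7)
        fit1 = pn.fit_plssem(data, blocks, inner)
        fit2 = pn.fit_plssem(data, blocks, inner)
        assert (fit1.paths.to_numpy() == fit2.paths.to_numpy()).all()  # bit-identical
        # negating a whole column: the sign convention restores the loading sign
        X2 = data.X.copy()
        X2[:, 1] *= -1.0
        fit3 = pn.fit_plssem(pn.PlsSemData(data.case_ids, data.indicator_ids, X2),
                             blocks, inner)
        assert fit3.loadings["b1"] == pytest.approx(fit1.loadings["b1"], abs=1e-12)
        assert abs(fit3.paths.loc["A", "B"]) == pytest.approx(
            abs(fit1.paths.loc["A", "B"]), abs=1e-12)

    def test_single_indicator_reduction_to_ols(self):
        """All-single-indicator models reduce to OLS among standardized columns."""
        rng = np.random.default_rng(10)
        n = 300
        a = rng.standard_normal(n)
        b = 0.5 * a + rng.standard_normal(n)
        c = 0.3 * a - 0.4 * b + rng.standard_normal(n)
        X = np.column_stack([a, b, c])
        data = pn.PlsSemData([f"c{i}" for i in range(n)], ["a1", "b1", "c1"], X)
        blocks = [pn.BlockSpec(lv, (ind,)) for lv, ind in
                  zip("ABC", ["a1", "b1", "c1"])]
        inner = pn.InnerModel(("A", "B", "C"), (("A", "B"), ("A", "C"), ("B", "C")))
        fit = pn.fit_plssem(data, blocks, inner)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        coef_b = np.linalg.lstsq(Z[:, [0]], Z[:, 1], rcond=None)[0]
        coef_c = np.linalg.lstsq(Z[:, [0, 1]], Z[:, 2], rcond=None)[0]
        assert fit.paths.loc["A", "B"] == pytest.approx(coef_b[0], abs=1e-10)
        assert fit.paths.loc["A", "C"] == pytest.approx(coef_c[0], abs=1e-10)
        assert fit.paths.loc["B", "C"] == pytest.approx(coef_c[1], abs=1e-10)

    def test_parameter_recovery_at_large_n(self):
        """Known single-indicator model, n=20000: every path within 0.02 of
        truth on average over 10 seeds."""
        inner = pn.InnerModel(("A", "B", "C", "D"),
                              (("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")))
        b_true = {("A", "B"): 0.6, ("A", "C"): -0.5, ("B", "D"): 0.4, ("C", "D"): -0.3}
        loadings = {lv: (1.0,) for lv in inner.lv_names}
        blocks = [pn.BlockSpec(lv, (f"{lv}_x1",)) for lv in inner.lv_names]
        acc = {e: [] for e in b_true}
        for seed in range(10):
            data, _ = pn.simulate_sem_dataset(inner, b_true, loadings, n=20_000,
                                              seed=seed)
            fit = pn.fit_plssem(data, blocks, inner)
            for (s, t), v in b_true.items():
                acc[(s, t)].append(fit.paths.loc[s, t])
        for e, v in b_true.items():
            assert np.mean(acc[e]) == pytest.approx(v, abs=0.02)

    def test_collinear_predecessors_reported(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal(40)
        X = np.column_stack([a, a.copy(), rng.standard_normal(40)])
        data = pn.PlsSemData([f"c{i}" for i in range(40)], ["a1", "b1", "c1"], X)
        blocks = [pn.BlockSpec(lv, (ind,)) for lv, ind in
                  zip("ABC", ["a1", "b1", "c1"])]
        inner = pn.InnerModel(("A", "B", "C"), (("A", "C"), ("B", "C")))
        with pytest.raises(ModelSpecError, match="collinear"):
            pn.fit_plssem(data, blocks, inner)

    def test_nonconvergence_warns_and_flags(self):
        spec = pn.builtin_model("CTK")
        inner = spec.inner_model()
        loadings = {lv: (0.8, 0.7, 0.6) for lv in inner.lv_names}
        b = {e: 0.3 for e in spec.edges}
        data, _ = pn.simulate_sem_dataset(inner, b, loadings, n=60, seed=12)
        blocks = [pn.BlockSpec(lv, tuple(f"{lv}_x{k}" for k in (1, 2, 3)))
                  for lv in inner.lv_names]
        cfg = pn.RunConfig(max_iterations=1, tolerance=1e-12)
        with pytest.warns(ConvergenceWarning):
            fit = pn.fit_plssem(data, blocks, inner, cfg)
        assert not fit.converged
        assert fit.iterations == 1

    def test_validation_errors(self):
        data, blocks, inner = two_lv_data()
        with pytest.raises(ModelSpecError, match="not in the data"):
            pn.fit_plssem(data, [pn.BlockSpec("A", ("zz",)),
                                 pn.BlockSpec("B", ("b1",))], inner)
        lonely = pn.InnerModel(("A", "B", "C"), (("A", "B"),))
        blocks3 = blocks + [pn.BlockSpec("C", ("b1",))]
        with pytest.raises(ModelSpecError):
            pn.fit_plssem(data, blocks3, lonely)


class TestTotalEffects:
    def test_hand_example(self):
        inner = pn.InnerModel(("a", "b", "c"), (("a", "b"), ("b", "c"), ("a", "c")))
        B = pd.DataFrame(0.0, index=list("abc"), columns=list("abc"))
        B.loc["a", "b"] = 0.5
        B.loc["b", "c"] = 0.4
        B.loc["a", "c"] = 0.2
        T = pn.total_effects(B, inner)
        assert T.loc["a", "c"] == pytest.approx(0.4, abs=1e-12)
        assert T.loc["a", "b"] == pytest.approx(0.5, abs=1e-12)

    def test_edgeless_model_is_zero(self):
        inner = pn.InnerModel(("a", "b"), ())
        B = pd.DataFrame(0.0, index=list("ab"), columns=list("ab"))
        assert (pn.total_effects(B, inner).to_numpy() == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_enumeration_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(3, 7))
        lvs = [f"v{i}" for i in range(L)]
        edges = [(lvs[i], lvs[j]) for i in range(L) for j in range(i + 1, L)
                 if rng.random() < 0.5]
        inner = pn.InnerModel(tuple(lvs), tuple(edges))
        B = pd.DataFrame(0.0, index=lvs, columns=lvs)
        for s, t in edges:
            B.loc[s, t] = rng.uniform(-1, 1)
        T = pn.total_effects(B, inner)
        np.testing.assert_allclose(T.to_numpy(),
                                   path_enumeration_oracle(B, inner).to_numpy(),
                                   atol=1e-12)

    def test_nilpotent_on_dag(self):
        spec = pn.builtin_model("CTK")
        inner = spec.inner_model()
        B = pd.DataFrame(0.0, index=inner.lv_names, columns=inner.lv_names)
        for s, t in inner.edges:
            B.loc[s, t] = 0.5
        P = np.linalg.matrix_power(B.to_numpy(), len(inner.lv_names) + 1)
        assert (P == 0).all()

    def test_off_edge_entry_rejected(self):
        inner = pn.InnerModel(("a", "b"), (("a", "b"),))
        B = pd.DataFrame(0.0, index=list("ab"), columns=list("ab"))
        B.loc["b", "a"] = 0.3
        with pytest.raises(ModelSpecError, match="off the inner-model edges"):
            pn.total_effects(B, inner)


class TestQuality:
    def test_hand_examples(self):
        assert pn.ave_cr_from_loadings([1.0]) == pytest.approx((1.0, 1.0))
        ave, _ = pn.ave_cr_from_loadings([0.8, 0.6])
        assert ave == pytest.approx(0.5, abs=1e-12)
        _, cr = pn.ave_cr_from_loadings([0.9, 0.9, 0.9])
        assert cr == pytest.approx(7.29 / (7.29 + 3 * 0.19), abs=1e-12)

    def test_quality_table_thresholds(self):
        data, blocks, inner = two_lv_data(n=60, beta=0.6, seed=8)
        fit = pn.fit_plssem(data, blocks, inner)
        q = pn.quality_criteria(fit)
        assert q.loc["A", "ave"] == pytest.approx(1.0)
        assert q.loc["A", "cr"] == pytest.approx(1.0)
        assert bool(q.loc["A", "meets_thresholds"])
        assert ((q["ave"] >= 0) & (q["ave"] <= 1)).all()
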