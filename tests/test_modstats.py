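import numpy as np
import pandas as pd
import pytest

from pathmod import (
    SampleMetadata,
    combine_factor_weights,
    correlate_continuous,
    filter_factors,
    integrate_factors,
    integrate_weights,
    make_planted_pseudobulk,
    sample_metadata_from_truth,
    test_category,
    top_weight_pairs,
    train_factor_model,
)
from pathmod.factors import FactorMatrix, WeightMatrix


def _factor_matrix(values, samples=None, labels=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"S{i}" for i in range(values.shape[0])]
    labels = labels or [f"factor_{k+1}" for k in range(values.shape[1])]
    table = pd.DataFrame(values, index=samples, columns=labels)
    return FactorMatrix(table=table, group=pd.Series("g", index=table.index))


def _weight_matrix(df):
    return WeightMatrix(table=df)


class TestCategoryTests:
    def test_exact_mwu_p(self):
        fm = _factor_matrix(np.array([[1.0], [2], [3], [4], [5], [6]]))
        sm = SampleMetadata(
            pd.DataFrame({"status": ["a"] * 3 + ["b"] * 3}, index=fm.table.index)
        )
        res = test_category(fm, sm, "status", mode="nonparametric")
        assert res.loc["factor_1", "test"] == "mwu"
        # exact two-sided enumeration over all 20 rank splits
        assert res.loc["factor_1", "p_value"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_parametric_null(self):
        fm = _factor_matrix(np.array([[1.0], [2], [3], [1], [2], [3]]))
        sm = SampleMetadata(
            pd.DataFrame({"status": ["a"] * 3 + ["b"] * 3}, index=fm.table.index)
        )
        res = test_category(fm, sm, "status", mode="parametric")
        assert res.loc["factor_1", "test"] == "t"
        assert res.loc["factor_1", "statistic"] == pytest.approx(0.0)
        assert res.loc["factor_1", "p_value"] == pytest.approx(1.0)

    def test_constant_factor_parametric(self):
        fm = _factor_matrix(np.full((6, 1), 2.0))
        sm = SampleMetadata(
            pd.DataFrame({"status": ["a"] * 3 + ["b"] * 3}, index=fm.table.index)
        )
        res = test_category(fm, sm, "status", mode="parametric")
        assert res.loc["factor_1", "statistic"] == 0.0
        assert res.loc["factor_1", "p_value"] == 1.0

    def test_bh_across_factors(self):
        from pathmod.modstats import _bh

        # step-up by hand: p_(i) * m / i = [.04, .04, .04, .04] -> cummin .04
        adj = _bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)
        # adjusted p-values follow the step-up cummin on real test output
        rng = np.random.default_rng(5)
        fm = _factor_matrix(rng.normal(size=(12, 4)))
        sm = SampleMetadata(
            pd.DataFrame({"status": ["a"] * 6 + ["b"] * 6}, index=fm.table.index)
        )
        res = test_category(fm, sm, "status")
        p = res["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        stepup = (p[order] * m / np.arange(1, m + 1))[::-1]
        expect = np.minimum.accumulate(stepup)[::-1]
        expect = np.minimum(expect, 1.0)
        assert np.allclose(res["adj_p_value"].to_numpy()[order], expect)

    def test_dispatch_three_levels(self):
        rng = np.random.default_rng(0)
        fm = _factor_matrix(rng.normal(size=(9, 2)))
        sm = SampleMetadata(
            pd.DataFrame(
                {"status": ["a"] * 3 + ["b"] * 3 + ["c"] * 3}, index=fm.table.index
            )
        )
        nonpar = test_category(fm, sm, "status", mode="nonparametric")
        par = test_category(fm, sm, "status", mode="parametric")
        assert set(nonpar["test"]) == {"kw"}
        assert set(par["test"]) == {"anova"}
        assert (nonpar["adj_p_value"] >= nonpar["p_value"] - 1e-15).all()

    def test_small_level_rejected(self):
        fm = _factor_matrix(np.arange(5.0).reshape(-1, 1))
        sm = SampleMetadata(
            pd.DataFrame({"status": ["a"] * 4 + ["b"]}, index=fm.table.index)
        )
        with pytest.raises(ValueError, match="'b'"):
            test_category(fm, sm, "status")


class TestContinuousTraits:
    def test_self_and_anti_correlation(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(10, 2))
        fm = _factor_matrix(vals)
        sm = SampleMetadata(
            pd.DataFrame(
                {"t_self": vals[:, 0], "t_anti": -vals[:, 1]}, index=fm.table.index
            )
        )
        for method in ("spearman", "pearson"):
            res = correlate_continuous(fm, sm, "t_self", method=method)
            assert res.loc["factor_1", "coefficient"] == pytest.approx(1.0)
            res2 = correlate_continuous(fm, sm, "t_anti", method=method)
            assert res2.loc["factor_2", "coefficient"] == pytest.approx(-1.0)

    def test_null_trait_rarely_significant(self):
        """Independent noise traits: significance rate stays near nominal."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fm = _factor_matrix(rng.normal(size=(50, 5)))
            sm = SampleMetadata(
                pd.DataFrame({"noise": rng.normal(size=50)}, index=fm.table.index)
            )
            res = correlate_continuous(fm, sm, "noise")
            hits += int((res["adj_p_value"] < 0.05).any())
        assert hits / 100 <= 0.10

    def test_zero_variance_trait_rejected(self):
        fm = _factor_matrix(np.random.default_rng(1).normal(size=(6, 1)))
        sm = SampleMetadata(pd.DataFrame({"t": [1.0] * 6}, index=fm.table.index))
        with pytest.raises(ValueError, match="variance"):
            correlate_continuous(fm, sm, "t")


class TestTopWeights:
    def _wm(self):
        idx = pd.MultiIndex.from_tuples(
            [("P1", "T"), ("P2", "T"), ("P1", "B"), ("P2", "B")],
            names=["feature", "view"],
        )
        return _weight_matrix(
            pd.DataFrame(
                {"factor_1": [0.5, -0.9, 0.2, 0.7]}, index=idx
            )
        )

    def test_directions(self):
        wm = self._wm()
        pos = top_weight_pairs(wm, "factor_1", k=1, direction="positive")
        assert pos.iloc[0].tolist() == ["P2", "B", 0.7]
        neg = top_weight_pairs(wm, "factor_1", k=1, direction="negative")
        assert neg.iloc[0].tolist() == ["P2", "T", -0.9]
        ab = top_weight_pairs(wm, "factor_1", k=2, direction="absolute")
        assert ab.iloc[0].tolist() == ["P2", "T", -0.9]  # magnitude rule

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(6)
        idx = pd.MultiIndex.from_tuples(
            [(f"P{i}", v) for i in range(10) for v in ("T", "B")],
            names=["feature", "view"],
        )
        wm = _weight_matrix(pd.DataFrame({"factor_1": rng.normal(size=20)}, index=idx))
        got = top_weight_pairs(wm, "factor_1", k=20, direction="absolute")
        expect = sorted(
            ((f, v, w) for (f, v), w in wm.table["factor_1"].items()),
            key=lambda t: (-abs(t[2]), t[0], t[1]),
        )
        assert [tuple(r) for r in got.to_numpy()] == expect

    def test_oversized_k_warns(self):
        wm = self._wm()
        with pytest.warns(UserWarning, match="exceeds"):
            out = top_weight_pairs(wm, "factor_1", k=99)
        assert len(out) == 4


class TestCombinedWeights:
    def test_single_factor_is_elementwise_abs(self):
        wm = TestTopWeights()._wm()
        cw = combine_factor_weights(wm, ["factor_1"], top_n=2)
        stacked = cw.table.stack()
        for (v, f), val in stacked.items():
            assert val == abs(wm.table.loc[(f, v), "factor_1"])

    def test_abs_max_across_factors(self):
        idx = pd.MultiIndex.from_tuples([("P1", "T")], names=["feature", "view"])
        wm = _weight_matrix(
            pd.DataFrame({"fa": [0.5], "fb": [-0.9]}, index=idx)
        )
        cw = combine_factor_weights(wm, ["fa", "fb"], top_n=1)
        assert cw.table.loc["T", "P1"] == pytest.approx(0.9)

    def test_engineered_enumeration(self):
        # 4 views x 12 pathways, one factor, weights designed so that:
        #   top-3 of view Vi are P(3i)..P(3i+2), with mean-descending order
        #   P0 > P1 > ... > P11 across columns of the union
        # home weight 1 - 0.05*pi dominates the 0.001-scale background, so
        # view Vi's top-3 are P(3i)..P(3i+2) and column means decrease in pi
        views = [f"V{i}" for i in range(4)]
        paths = [f"P{i:02d}" for i in range(12)]
        rows = []
        for vi, v in enumerate(views):
            for pi, p in enumerate(paths):
                base = 0.001 * (12 - pi)
                if pi // 3 == vi:
                    base = 1.0 - 0.05 * pi
                rows.append((p, v, base))
        idx = pd.MultiIndex.from_tuples(
            [(p, v) for p, v, _ in rows], names=["feature", "view"]
        )
        wm = _weight_matrix(
            pd.DataFrame({"f1": [w for *_, w in rows]}, index=idx)
        )
        cw = combine_factor_weights(wm, ["f1"], top_n=3)
        assert cw.table.shape == (4, 12)  # union covers all 12 pathways
        assert list(cw.table.columns) == paths  # mean-descending == P00..P11
        means = cw.table.mean(axis=0)
        assert (means.diff().dropna() < 0).all()


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_planted_module_flagged_and_interpreted(self, seed):
        table, truth = make_planted_pseudobulk(seed=seed)
        result = filter_factors(train_factor_model(table, K=10), 1.0)
        fm = integrate_factors(result)
        wm = integrate_weights(result)
        sm = sample_metadata_from_truth(truth)
        res = test_category(fm, sm, "condition", mode="nonparametric")
        z = pd.Series(
            truth.extras["Z"][:, truth.extras["condition_factor_index"]],
            index=truth.condition.index,
        ).loc[fm.table.index]
        corr = fm.table.apply(lambda c: abs(np.corrcoef(c, z)[0, 1]))
        cond_factor = corr.idxmax()
        assert res.loc[cond_factor, "significant"]
        top = top_weight_pairs(
            wm, cond_factor, k=len(truth.planted_pairs), direction="absolute"
        )
        hits = set(map(tuple, top[["feature", "view"]].to_numpy())) & set(
            truth.planted_pairs
        )
        assert len(hits) / len(truth.planted_pairs) >= 0.8
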