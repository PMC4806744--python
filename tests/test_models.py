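"""Transforms, screening, OLS/AICc machinery, and non-parametric tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bearsalmon import models as m


class TestTransforms:
    def test_arcsine_sqrt_closed_form(self):
        df = pd.DataFrame({"p": [1.0, 0.5]})
        out, meta = m.transform_variables(
            df, {"p": m.TransformSpec("arcsine_sqrt", standardize=False)})
        assert out["p"].iloc[0] == pytest.approx(np.pi / 2)
        assert out["p"].iloc[1] == pytest.approx(np.pi / 4)

    def test_negative_reciprocal_closed_form(self):
        df = pd.DataFrame({"x": [2.0, 0.5]})
        out, _ = m.transform_variables(
            df, {"x": m.TransformSpec("negative_reciprocal", standardize=False)})
        assert list(out["x"]) == [-0.5, -2.0]

    def test_standardization_exact(self, rng):
        df = pd.DataFrame({"x": rng.lognormal(1, 0.5, 200)})
        out, meta = m.transform_variables(df, {"x": m.TransformSpec("ln", True)})
        assert abs(out["x"].mean()) < 1e-12
        assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert meta["x"]["transform"] == "ln"

    @pytest.mark.parametrize("transform,bad", [
        ("ln", [1.0, 0.0]), ("negative_reciprocal", [1.0, -2.0]),
        ("arcsine_sqrt", [0.5, 1.2])])
    def test_domain_violations_name_variable_and_row(self, transform, bad):
        df = pd.DataFrame({"v": bad})
        with pytest.raises(ValueError, match="'v' row 1"):
            m.transform_variables(df, {"v": m.TransformSpec(transform, False)})

    def test_zero_variance_standardization_rejected(self):
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="zero variance"):
            m.transform_variables(df, {"x": m.TransformSpec("identity", True)})


class TestOutlierScreen:
    def test_hand_computed_example(self):
        # mean 2.5, sd ~3.674: z(10) ~ 2.04 > 2 excludes only the 10
        keep = m.flag_outliers([1, 1, 1, 1, 1, 10])
        assert list(keep) == [True] * 5 + [False]

    def test_constant_vector_keeps_everything(self):
        assert m.flag_outliers([3.0, 3.0, 3.0]).all()

    @pytest.mark.parametrize("a", [0.1, 1.0, 57.0])
    def test_symmetric_triple_never_excluded(self, a):
        # (-a, 0, a): sample sd = a, so max |z| = 1 for every a
        assert m.flag_outliers([-a, 0.0, a]).all()

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            m.flag_outliers([1.0, 2.0])


class TestCollinearity:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        rep = m.collinearity_screen(pd.DataFrame({"a": x1, "b": x2}), ["a", "b"])
        assert rep.vif["a"] == pytest.approx(1.0, abs=1e-10)
        assert rep.vif["b"] == pytest.approx(1.0, abs=1e-10)

    def test_perfect_collinearity_flagged_not_raised(self, rng):
        x = rng.normal(size=50)
        rep = m.collinearity_screen(pd.DataFrame({"a": x, "b": 2 * x}), ["a", "b"])
        assert np.isinf(rep.vif["a"])
        assert rep.flagged_vif == ["a", "b"]
        assert rep.correlations.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(80, 3))
        X[:, 2] += 0.8 * X[:, 0]
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        rep = m.collinearity_screen(df, ["a", "b", "c"])
        for j, name in enumerate(["a", "b", "c"]):
            others = np.delete(X, j, axis=1)
            D = np.column_stack([np.ones(len(X)), others])
            beta = np.linalg.solve(D.T @ D, D.T @ X[:, j])
            resid = X[:, j] - D @ beta
            r2 = 1 - resid @ resid / np.sum((X[:, j] - X[:, j].mean()) ** 2)
            assert rep.vif[name] == pytest.approx(1 / (1 - r2), abs=1e-8)


class TestOls:
    def test_exact_fit_flagged_degenerate(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 * df["x"]
        fit = m.fit_ols(["x"], df, "y")
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.degenerate
        assert fit.llf == np.inf

    def test_matches_normal_equations_oracle(self, rng):
        df = pd.DataFrame({"x1": rng.normal(size=10), "x2": rng.normal(size=10)})
        df["y"] = 1.0 + 0.5 * df.x1 - 0.7 * df.x2 + rng.normal(0, 0.3, 10)
        fit = m.fit_ols(["x1", "x2"], df, "y")
        X = np.column_stack([np.ones(10), df.x1, df.x2])
        beta = np.linalg.solve(X.T @ X, X.T @ df.y.to_numpy())
        resid = df.y.to_numpy() - X @ beta
        sigma2 = resid @ resid / (10 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-10)
        assert fit.bse.to_numpy() == pytest.approx(se, abs=1e-10)
        assert fit.k == 4  # 3 coefficients + residual variance

    def test_intercept_only_is_the_mean(self, rng):
        df = pd.DataFrame({"y": rng.normal(3.0, 1.0, 25)})
        fit = m.fit_ols([], df, "y")
        assert fit.params["Intercept"] == pytest.approx(df["y"].mean())

    def test_rank_deficiency_names_alias(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20)})
        df["b"] = 2 * df["a"]
        df["y"] = df["a"] + rng.normal(size=20)
        with pytest.raises(ValueError, match="aliased"):
            m.fit_ols(["a", "b"], df, "y")

    def test_standardized_fit_invariant_to_predictor_rescaling(self, rng):
        raw = pd.DataFrame({"x": rng.lognormal(0, 1, 60)})
        raw["y"] = 0.6 * raw["x"] + rng.normal(0, 0.5, 60)

        def standardized_beta(x):
            df = pd.DataFrame({
                "x": (x - x.mean()) / x.std(ddof=1),
                "y": (raw.y - raw.y.mean()) / raw.y.std(ddof=1)})
            return m.fit_ols(["x"], df, "y").params["x"]

        assert standardized_beta(raw.x) == pytest.approx(
            standardized_beta(3.0 * raw.x + 5.0), abs=1e-12)


def _fit_with_aicc(aicc_target, n, k, name="f"):
    """ModelFit whose AIC part (-2logL + 2k) equals the given value."""
    llf = -(aicc_target - 2 * k) / 2
    return m.ModelFit(name=name, terms=(), params=pd.Series(dtype=float),
                      bse=pd.Series(dtype=float), n=n, k=k, llf=llf, adj_r2=0.0)


class TestAiccRanking:
    def test_small_sample_correction_arithmetic(self):
        fit = _fit_with_aicc(100.0, n=54, k=3)
        assert m.aicc_of(fit) == pytest.approx(100.48)

    def test_two_model_weights_closed_form(self):
        ranked = m.aicc_rank([_fit_with_aicc(100.0, 200, 2, "a"),
                              _fit_with_aicc(102.0, 200, 2, "b")])
        w = ranked.table.set_index("name")["weight"]
        assert w["a"] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-9)
        assert w["b"] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)), abs=1e-9)
        assert list(ranked.table["delta"]) == pytest.approx([0.0, 2.0])

    def test_single_model(self):
        ranked = m.aicc_rank([_fit_with_aicc(50.0, 30, 2)])
        assert ranked.table["weight"].iloc[0] == 1.0
        assert ranked.table["delta"].iloc[0] == 0.0

    def test_weights_sum_to_one_single_zero_delta(self, rng):
        fits = [_fit_with_aicc(100 + d, 100, 3, f"m{i}")
                for i, d in enumerate(rng.uniform(0, 20, 12))]
        ranked = m.aicc_rank(fits)
        assert ranked.table["weight"].sum() == pytest.approx(1.0)
        assert (ranked.table["delta"] == 0).sum() == 1
        assert (ranked.table["delta"] >= 0).all()

    def test_saturated_model_dropped_with_warning(self, caplog):
        fits = [_fit_with_aicc(10.0, 5, 2, "ok"), _fit_with_aicc(5.0, 5, 4, "sat")]
        with caplog.at_level("WARNING"):
            ranked = m.aicc_rank(fits)
        assert list(ranked.table["name"]) == ["ok"]
        assert "sat" in caplog.text


class TestGroupWeights:
    def _rankings(self, weights):
        out = {}
        for i, w in enumerate(weights):
            tab = pd.DataFrame([{"name": f"top{i}", "category": f"c{i}", "k": 3,
                                 "n": 50, "aicc": 10.0, "adj_r2": 0.1,
                                 "delta": 0.0, "weight": w}])
            out[f"c{i}"] = m.RankedModels(table=tab, fits={})
        return out

    def test_proportional_to_top_weights(self):
        gw = m.group_relative_weights(self._rankings([0.4, 0.3, 0.2, 0.1]))
        assert list(gw["omega_pct"]) == pytest.approx([40, 30, 20, 10])

    def test_single_category_is_everything(self):
        gw = m.group_relative_weights(self._rankings([0.55]))
        assert gw["omega_pct"].iloc[0] == pytest.approx(100.0)

    def test_equal_weights_split_evenly(self):
        gw = m.group_relative_weights(self._rankings([0.2, 0.2, 0.2]))
        assert list(gw["omega_pct"]) == pytest.approx([100 / 3] * 3)


def exact_rank_sum_p(x, y):
    """Enumeration oracle: null distribution of U over all assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return min(1.0, 2 * min(cdf, sf))


class TestRankSum:
    def test_tiny_example_full_enumeration(self):
        r = m.rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == 0.0
        assert r.p_raw == pytest.approx(2 / 6)
        assert r.method == "exact"

    def test_swap_identity(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=7)
        w_xy = m.rank_sum_test(x, y).statistic
        w_yx = m.rank_sum_test(y, x).statistic
        assert w_xy + w_yx == 5 * 7

    def test_exact_p_matches_enumeration_for_all_small_sizes(self, rng):
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                x, y = rng.normal(size=n1), rng.normal(size=n2)
                r = m.rank_sum_test(x, y)
                assert r.method == "exact"
                assert r.p_raw == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_ties_fall_back_to_corrected_normal(self):
        r = m.rank_sum_test([1, 2, 2, 3], [2, 4, 5, 6])
        assert r.method == "asymptotic"
        assert 0 <= r.p_raw <= 1

    def test_degenerate_all_tied(self):
        r = m.rank_sum_test([2, 2, 2], [2, 2])
        assert r.p_raw == 1.0
        assert r.flag == "all values tied"


class TestHolm:
    def test_step_down_hand_computation(self):
        adj = m.holm_adjust([0.01, 0.02, 0.03])
        assert list(adj) == pytest.approx([0.03, 0.04, 0.04])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=9)
        ours = m.holm_adjust(p)
        theirs = multipletests(p, method="holm")[1]
        assert ours == pytest.approx(theirs, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_dominates_raw_and_bounded_by_bonferroni(self, p):
        adj = m.holm_adjust(p)
        p = np.asarray(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= np.minimum(1.0, len(p) * p) + 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_larger_family_size(self):
        adj = m.holm_adjust([0.01], m=4)
        assert adj[0] == pytest.approx(0.04)

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            m.holm_adjust([0.1, 0.2], m=1)


class TestWilcoxonHolmFamily:
    def test_family_bookkeeping(self, rng):
        groups = {f"c{i}": (rng.normal(size=8), rng.normal(0.5, 1, 8))
                  for i in range(4)}
        results = m.wilcoxon_holm(groups)
        assert all(r.family_size == 4 for r in results)
        assert all(r.p_adjusted >= r.p_raw - 1e-15 for r in results)


class TestVarianceRatio:
    def test_identical_samples_unit_f(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = m.variance_ratio_test(x, x)
        assert r.statistic == 1.0
        assert r.p_raw == pytest.approx(1.0)

    def test_df_convention(self, rng):
        r = m.variance_ratio_test(rng.normal(size=12), rng.normal(size=10))
        assert r.df == (11, 9)

    def test_constructed_variance_ratio(self):
        x = [0.0, 4.0]   # variance 8
        y = [0.0, 2.0]   # variance 2
        r = m.variance_ratio_test(x, y)
        assert r.statistic == pytest.approx(4.0)

    def test_zero_denominator_flagged(self):
        r = m.variance_ratio_test([1.0, 2.0], [5.0, 5.0])
        assert np.isinf(r.statistic)
        assert r.flag is not None


class TestDefaultModelSets:
    def test_no_candidate_is_strict_superset_of_additive_full(self):
        sets = m.default_model_sets(["productivity", "availability",
                                     "consumption", "other_hormone", "density"])
        full = set(sets["combined"]["additive_full"])
        for cat, ms in sets.items():
            for name, terms in ms.items():
                if name == "additive_full":
                    continue
                assert not full < set(terms)

    def test_intercept_only_in_every_category(self):
        sets = m.default_model_sets(["productivity", "availability",
                                     "consumption", "other_hormone"])
        for cat, ms in sets.items():
            assert any(len(t) == 0 for t in ms.values()), cat

    def test_year_and_density_category_appears_when_available(self):
        sets = m.default_model_sets(["productivity", "availability",
                                     "consumption", "other_hormone",
                                     "density", "year_2010", "year_2011"])
        assert "environment2" in sets
        assert sets["environment2"]["year"] == ["year_2010", "year_2011"]
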