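"""Per-patient layer: kappa, screening, logistic/ordinal models, VIF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perishell.cohort import (SeparationError, fit_logistic, fit_ordinal, kappa,
                              screen_univariable, vif)
from perishell.phantom import PhantomConfig, cohort_frame, generate_cohort


class TestKappa:
    def test_perfect_agreement(self):
        r = kappa(np.diag([5, 7, 3]))
        assert r.kappa == pytest.approx(1.0)
        assert r.ci95 == (1.0, 1.0)

    def test_hand_computed_2x2(self):
        """[[4,1],[1,4]]: p_o = 0.8, p_e = 0.5 -> kappa = 0.6."""
        r = kappa([[4, 1], [1, 4]])
        assert r.kappa == pytest.approx(0.6, abs=1e-12)
        assert r.ci95[0] <= 0.6 <= r.ci95[1]

    def test_quadratic_equals_unweighted_on_2x2(self):
        t = [[12, 3], [5, 20]]
        assert kappa(t, "quadratic").kappa == pytest.approx(kappa(t, "none").kappa)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 30))
    def test_bounded_and_matches_sklearn(self, seed):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(seed)
        r = int(rng.integers(2, 5))
        t = rng.integers(0, 12, size=(r, r))
        t[0, 0] += 1  # nonzero total
        # expand the table into paired label vectors
        a, b = [], []
        for i in range(r):
            for j in range(r):
                a.extend([i] * t[i, j])
                b.extend([j] * t[i, j])
        for weighting, sk_weights in (("none", None), ("quadratic", "quadratic")):
            mine = kappa(t, weighting)
            assert -1.0 - 1e-9 <= mine.kappa <= 1.0 + 1e-9
            if len(set(a)) > 1 and len(set(b)) > 1:
                ref = cohen_kappa_score(a, b, weights=sk_weights,
                                        labels=list(range(r)))
                assert mine.kappa == pytest.approx(ref, abs=1e-10)

    def test_invariant_to_simultaneous_category_permutation(self):
        rng = np.random.default_rng(1)
        t = rng.integers(0, 10, size=(4, 4))
        perm = rng.permutation(4)
        assert kappa(t).kappa == pytest.approx(kappa(t[np.ix_(perm, perm)]).kappa)

    def test_ci_shrinks_with_sample_size(self):
        t = np.array([[4, 1], [1, 4]])
        small, big = kappa(t), kappa(t * 20)
        assert big.se < small.se

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            kappa([[1, 2, 3], [4, 5, 6]])


class TestScreening:
    def _frame(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        return pd.DataFrame({
            "has_cluster": y,
            "flat": np.ones(n),
            "separator": y.astype(float),
            "noise": rng.normal(size=n),
            "count_cov": rng.poisson(3, size=n),
        })

    def test_constant_covariate_not_flagged(self):
        out = screen_univariable(self._frame())
        row = out[out["term"] == "flat"].iloc[0]
        assert row["p_value"] == pytest.approx(1.0) and not row["flagged"]

    def test_perfect_separator_flagged(self):
        out = screen_univariable(self._frame())
        assert out[out["term"] == "separator"]["flagged"].iloc[0]

    def test_flags_invariant_to_record_order(self):
        df = self._frame()
        a = screen_univariable(df)
        b = screen_univariable(df.sample(frac=1.0, random_state=3))
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_outcome_rejected(self):
        df = self._frame()
        df["has_cluster"] = 1
        with pytest.raises(ValueError, match="2 classes"):
            screen_univariable(df)

    def test_test_menu_by_covariate_type(self):
        out = screen_univariable(self._frame()).set_index("term")
        assert out.loc["noise", "test"] == "t"
        assert out.loc["count_cov", "test"] == "mannwhitneyu"
        assert out.loc["separator", "test"] in ("chi2", "fisher_exact")


class TestVif:
    def test_orthogonal_covariates_give_unit_vif(self):
        n = 16
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert all(c.vif == pytest.approx(1.0, abs=1e-10) for c in out)

    def test_closed_form_at_correlation_0p8(self):
        """Exact r = 0.8 pair: VIF = 1/(1 - 0.64) = 2.777..."""
        n = 50
        rng = np.random.default_rng(0)
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        # orthonormalise so the sample correlation is exactly 0.8
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= (z @ x) / (x @ x) * x
        z /= z.std()
        y = 0.8 * x + np.sqrt(1 - 0.64) * z
        out = vif(pd.DataFrame({"x": x, "y": y}))
        assert out[0].vif == pytest.approx(1.0 / 0.36, abs=1e-9)
        assert out[1].vif == pytest.approx(1.0 / 0.36, abs=1e-9)

    def test_duplicated_covariate_is_unbounded_or_raises(self):
        x = np.random.default_rng(2).normal(size=30)
        df = pd.DataFrame({"a": x, "b": x})
        assert all(np.isinf(c.vif) for c in vif(df))
        with pytest.raises(np.linalg.LinAlgError):
            vif(df, on_singular="raise")

    def test_needs_two_covariates_and_enough_rows(self):
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"a": [1.0, 2.0]}))


class TestLogistic:
    def test_null_effect_or_near_one(self):
        cases = generate_cohort(PhantomConfig(seed=11), 3000, with_volumes=False)
        df = cohort_frame(cases).reset_index()
        e = fit_logistic(df, "has_cluster", ["smoking"]).effect("smoking")
        assert e.ci95[0] < 1.0 < e.ci95[1]
        assert 0.8 < e.odds_ratio < 1.25

    def test_fit_is_a_likelihood_maximum(self):
        """The log-likelihood at the fit beats a grid of nearby
        coefficient perturbations."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(size=(n, 2))
        eta = 0.4 * x[:, 0] - 0.7 * x[:, 1]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        df = pd.DataFrame({"y": y.astype(int), "a": x[:, 0], "b": x[:, 1]})
        res = fit_logistic(df, "y", ["a", "b"])
        beta_hat = np.array([0.0, res.effect("a").coef, res.effect("b").coef])
        beta_hat[0] = sm.Logit(df["y"], sm.add_constant(df[["a", "b"]])).fit(disp=0).params.iloc[0]
        model = sm.Logit(df["y"], sm.add_constant(df[["a", "b"]]))
        ll_hat = model.loglike(beta_hat)
        eps = 0.05
        for da in (-eps, 0, eps):
            for db in (-eps, 0, eps):
                for dc in (-eps, 0, eps):
                    assert ll_hat >= model.loglike(beta_hat + [dc, da, db]) - 1e-9

    def test_perfect_separation_raises(self):
        y = np.repeat([0, 1], 20)
        df = pd.DataFrame({"y": y, "x": y.astype(float) + 0.0})
        with pytest.raises(SeparationError):
            fit_logistic(df, "y", ["x"])

    def test_vif_report_and_collinear_policy(self):
        rng = np.random.default_rng(7)
        n = 500
        a = rng.normal(size=n)
        b = a + rng.normal(0, 0.25, size=n)  # heavily collinear pair
        c = rng.normal(size=n)
        eta = 0.8 * a + 0.5 * c
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"y": y, "a": a, "b": b, "c": c})
        res = fit_logistic(df, "y", ["a", "b", "c"], vif_threshold=5.0)
        vifs = {r.term: r.vif for r in res.collinearity}
        assert vifs["a"] > 5.0 and vifs["b"] > 5.0 and vifs["c"] < 2.0
        assert res.effect("a").source_model.startswith("reduced")
        assert res.effect("c").source_model == "full"
        assert res.notices


class TestOrdinal:
    def test_two_categories_fall_back_to_logistic(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        df = pd.DataFrame({"count": y, "x": x})
        with pytest.warns(UserWarning, match="falling back"):
            res = fit_ordinal(df, "count", ["x"], collapse_at=4)
        ref = fit_logistic(df.assign(_b=(df["count"] >= 1).astype(int)), "_b", ["x"])
        assert res.effect("x").odds_ratio == pytest.approx(
            ref.effect("x").odds_ratio, rel=1e-6)

    def test_null_covariate_ci_covers_one(self):
        cases = generate_cohort(PhantomConfig(seed=13), 3000, with_volumes=False)
        df = cohort_frame(cases).reset_index()
        e = fit_ordinal(df, "n_vessel_clusters", ["hypertension"]).effect("hypertension")
        assert e.ci95[0] < 1.0 < e.ci95[1]

    def test_recovers_generating_odds_ratio(self):
        beta = np.log(1.8)
        cases = generate_cohort(PhantomConfig(seed=17), 4000,
                                effect_spec={"wmh_norm_log10": beta},
                                with_volumes=False)
        df = cohort_frame(cases).reset_index()
        e = fit_ordinal(df, "n_vessel_clusters", ["wmh_norm_log10"]).effect("wmh_norm_log10")
        assert e.ci95[0] <= 1.8 <= e.ci95[1]

    def test_collapse_limits_categories(self):
        cases = generate_cohort(PhantomConfig(seed=19), 1500,
                                effect_spec={"intercept": 1.0}, with_volumes=False)
        df = cohort_frame(cases).reset_index()
        res = fit_ordinal(df, "n_vessel_clusters", ["age"], collapse_at=3)
        assert res.model_kind == "proportional-odds"
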