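"""The mixed-model engine: likelihood accuracy, AIC tooling, selection, averaging."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import expit

from roadecol.glmm import (
    BinomialRandomInterceptGLMM,
    ModelFit,
    aic_table,
    correlogram,
    fit_binomial_glmm,
    forward_select,
    model_average,
    predict_probability,
)


def _simulate(seed, n_groups, n_per, beta, sigma=1.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), n_per)
    X = rng.normal(size=(n_groups * n_per, len(beta)))
    u = rng.normal(0, sigma, n_groups)
    eta = 0.3 + X @ np.asarray(beta) + u[g]
    y = rng.binomial(1, expit(eta))
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(len(beta))])
    df["response"] = y
    df["individual"] = g
    return df


class TestLikelihoodAccuracy:
    def test_zero_variance_matches_plain_logistic(self):
        """With a balanced 2x2 table the slope is the closed-form log-odds ratio."""
        x = np.array([0] * 50 + [1] * 50)
        y = np.array([0] * 30 + [1] * 20 + [0] * 10 + [1] * 40)
        df = pd.DataFrame({"individual": np.tile([0, 1], 50), "response": y, "x": x})
        f = fit_binomial_glmm(df, ["x"])
        assert f.sigma == pytest.approx(0.0, abs=1e-4)
        assert f.beta[1] == pytest.approx(np.log(40 * 30 / (10 * 20)), abs=1e-5)

    def test_zero_variance_matches_statsmodels_glm(self):
        """Independent cross-check against statsmodels plain logistic."""
        import statsmodels.api as sm

        df = _simulate(5, 4, 50, [0.7, -0.5], sigma=0.0)
        mine = fit_binomial_glmm(df, ["x0", "x1"], fix_sigma=0.0)
        ref = sm.GLM(
            df["response"], sm.add_constant(df[["x0", "x1"]]), family=sm.families.Binomial()
        ).fit()
        assert mine.sigma == 0.0
        np.testing.assert_allclose(mine.beta, ref.params.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(mine.se, ref.bse.to_numpy(), rtol=1e-3)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-5)

    def test_quadrature_matches_direct_integration(self, tiny_glmm_data):
        """AGQ marginal logLik equals brute-force 1-D integration on tiny data."""
        f = fit_binomial_glmm(tiny_glmm_data, ["x"], method="agq", n_quad=25)
        g = tiny_glmm_data["individual"].to_numpy()
        x = tiny_glmm_data["x"].to_numpy()
        y = tiny_glmm_data["response"].to_numpy()

        total = 0.0
        for gi in np.unique(g):
            m = g == gi

            def integrand(u):
                p = expit(f.beta[0] + f.beta[1] * x[m] + f.sigma * u)
                lik = np.prod(np.where(y[m] == 1, p, 1 - p))
                return lik * np.exp(-(u**2) / 2) / np.sqrt(2 * np.pi)

            val, _ = quad(integrand, -12, 12, limit=200)
            total += np.log(val)
        assert f.loglik == pytest.approx(total, abs=1e-3)

    def test_laplace_close_to_quadrature_on_tiny_data(self, tiny_glmm_data):
        fl = fit_binomial_glmm(tiny_glmm_data, ["x"], method="laplace")
        fa = fit_binomial_glmm(tiny_glmm_data, ["x"], method="agq", n_quad=25)
        assert fl.loglik == pytest.approx(fa.loglik, abs=0.05)

    def test_laplace_agrees_with_quadrature_on_design(self, usage_design):
        """On the bundled study-scale design the two modes agree within 1e-2."""
        for terms in ([], ["d_highway_x_traffic"], ["d_streams", "habitat_area"]):
            fl = fit_binomial_glmm(usage_design, terms, method="laplace")
            fa = fit_binomial_glmm(usage_design, terms, method="agq", n_quad=15)
            assert fl.loglik == pytest.approx(fa.loglik, abs=1e-2)

    def test_wald_ci_coverage(self):
        """95% Wald CIs on beta=(-0.4, +0.8) cover the truth in >=90/100 replicates."""
        cover = np.zeros(2, dtype=int)
        for seed in range(100):
            df = _simulate(seed, 30, 100, [-0.4, 0.8], sigma=1.0)
            f = fit_binomial_glmm(df, ["x0", "x1"])
            for j, truth in enumerate([-0.4, 0.8]):
                lo = f.beta[j + 1] - 1.96 * f.se[j + 1]
                hi = f.beta[j + 1] + 1.96 * f.se[j + 1]
                cover[j] += lo <= truth <= hi
        assert (cover >= 90).all()

    def test_agreement_with_lme4(self, tmp_path):
        """Cross-validate the fitter against R lme4::glmer on one simulated set."""
        df = _simulate(11, 8, 60, [0.6], sigma=0.8)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(response ~ x0 + (1|individual), data=d, family=binomial, nAGQ=25)
            cat(fixef(m)[1], fixef(m)[2], as.numeric(logLik(m)), "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, ll = map(float, out.stdout.split())
        mine = fit_binomial_glmm(df, ["x0"], method="agq", n_quad=25)
        assert mine.beta[0] == pytest.approx(b0, abs=5e-3)
        assert mine.beta[1] == pytest.approx(b1, abs=5e-3)
        assert mine.loglik == pytest.approx(ll, abs=1e-2)

    def test_input_validation(self):
        df = _simulate(0, 4, 20, [0.5])
        with pytest.raises(ValueError, match="binary"):
            fit_binomial_glmm(df.assign(response=df["response"] * 2.5), ["x0"])
        with pytest.raises(ValueError, match="zero variance"):
            fit_binomial_glmm(df.assign(x0=1.0), ["x0"])
        with pytest.raises(ValueError, match="groups"):
            fit_binomial_glmm(df.assign(individual=0), ["x0"])


class TestAicTable:
    def test_printed_habitat_competition_delta(self):
        """Null-vs-best AIC gap of 719.3 - 662.0 gives delta AIC 57.3."""
        tab = aic_table([("best", 662.0), ("null", 719.3)])
        assert tab["delta_aic"].tolist() == pytest.approx([0.0, 57.3])

    def test_equal_aics_split_weight(self):
        tab = aic_table([("a", 100.0), ("b", 100.0), ("c", 100.0)])
        assert tab["weight"].tolist() == pytest.approx([1 / 3] * 3)

    def test_two_unit_gap_weights(self):
        tab = aic_table([("a", 0.0), ("b", 2.0)])
        assert tab["weight"].tolist() == pytest.approx([0.7311, 0.2689], abs=1e-4)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 500), min_size=1, max_size=12))
    def test_weights_sum_to_one_and_order(self, aics):
        tab = aic_table(list(enumerate(aics)))
        assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert tab["delta_aic"].iloc[0] == 0.0
        assert (np.diff(tab["weight"]) <= 1e-12).all()


class TestModelAverage:
    def _fit(self, terms, beta, se, aic):
        k = len(terms)
        return ModelFit(
            terms=terms, beta=np.asarray(beta, float), se=np.asarray(se, float),
            p_values=np.full(k, 0.5), sigma=0.5, loglik=-aic / 2, aic=aic,
            n_obs=100, n_groups=5, method="laplace",
        )

    def test_single_model_identity(self):
        f = self._fit(["(intercept)", "a"], [0.2, 1.0], [0.1, 0.2], 100.0)
        avg = model_average([f])
        assert avg["beta"].tolist() == pytest.approx([0.2, 1.0])

    def test_zero_substitution(self):
        """A term absent from one of two supported models shrinks by its weight."""
        f1 = self._fit(["(intercept)", "a"], [0.0, 1.0], [0.1, 0.2], 100.0)
        f2 = self._fit(["(intercept)"], [0.0], [0.1], 100.0 + 2 * np.log(0.6 / 0.4))
        avg = model_average([f1, f2])
        w1 = 1 / (1 + np.exp(-np.log(0.6 / 0.4)))
        row = avg.set_index("term").loc["a"]
        assert row["beta"] == pytest.approx(w1 * 1.0)

    def test_three_model_hand_computation(self):
        fits = [
            self._fit(["(intercept)", "a"], [0.0, 2.0], [0.1, 0.5], 10.0),
            self._fit(["(intercept)", "a"], [0.0, 1.0], [0.1, 0.4], 11.0),
            self._fit(["(intercept)", "b"], [0.0, 3.0], [0.1, 0.6], 12.0),
        ]
        d = np.array([0.0, 1.0, 2.0])
        w = np.exp(-d / 2) / np.exp(-d / 2).sum()
        avg = model_average(fits).set_index("term")
        assert avg.loc["a", "beta"] == pytest.approx(w[0] * 2 + w[1] * 1)
        assert avg.loc["b", "beta"] == pytest.approx(w[2] * 3)
        ba = w[0] * 2 + w[1] * 1
        se_a = (
            w[0] * np.sqrt(0.5**2 + (2 - ba) ** 2)
            + w[1] * np.sqrt(0.4**2 + (1 - ba) ** 2)
            + w[2] * np.sqrt(0.0 + (0 - ba) ** 2)
        )
        assert avg.loc["a", "se"] == pytest.approx(se_a)


class TestForwardSelect:
    def test_useless_variable_rarely_enters(self):
        """With a permuted response, selection usually stops at the null model.

        AIC admits a pure-noise variable whenever its deviance drop exceeds
        2, which happens with probability P(chi2_1 > 2) ~ 0.157, so the
        theoretical stop-at-null rate is ~84%; the check allows binomial
        noise around that.
        """
        stopped = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = _simulate(seed, 4, 100, [0.8])
            df["response"] = rng.permutation(df["response"].to_numpy())
            path, best = forward_select(df, ["x0"])
            stopped += best.spec == "null"
        assert stopped >= 73  # ~3 SD below the theoretical 84.3%

    def test_duplicate_predictor_enters_once(self):
        df = _simulate(3, 6, 80, [1.2])
        df["x0_copy"] = df["x0"]
        path, best = forward_select(df, ["x0", "x0_copy"])
        chosen = [t for t in best.terms if t != "(intercept)"]
        assert len(chosen) == 1

    def test_planted_two_variable_truth_recovered(self):
        df = _simulate(9, 8, 250, [0.8, -0.8, 0.0])
        path, best = forward_select(df, ["x0", "x1", "x2"])
        chosen = set(best.terms)
        assert {"x0", "x1"} <= chosen
        assert "x2" not in chosen

    def test_correlation_screen_drops_weaker_variable(self):
        rng = np.random.default_rng(12)
        df = _simulate(12, 6, 100, [1.0])
        df["x_noisy"] = df["x0"] + rng.normal(0, 0.3, len(df))  # r ~ 0.96
        path, best = forward_select(df, ["x_noisy", "x0"])
        chosen = [t for t in best.terms if t != "(intercept)"]
        # the screen lets exactly one of the collinear pair into the model
        assert len(chosen) == 1 and chosen[0] in {"x0", "x_noisy"}


class TestCorrelogram:
    def test_iid_residuals_stay_inside_envelope(self):
        inside = 0
        rng = np.random.default_rng(0)
        for rep in range(100):
            z = rng.normal(size=100)
            xy = rng.uniform(0, 1_000, size=(100, 2))
            tab = correlogram(z, xy, n_bins=6, n_perm=199, seed=rep)
            ok = ((tab["moran"] >= tab["lower"]) & (tab["moran"] <= tab["upper"])).all()
            inside += ok
        assert inside >= 90

    def test_smooth_field_flagged_in_first_bin(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 1_000, size=(80, 2))
        z = np.sin(xy[:, 0] / 150.0) + rng.normal(0, 0.1, 80)
        tab = correlogram(z, xy, n_bins=6, n_perm=199, seed=2)
        assert tab["moran"].iloc[0] > tab["upper"].iloc[0]

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlogram(np.ones(40), np.random.default_rng(0).uniform(0, 1, (40, 2)))


class TestPredictProbability:
    def _fit(self, terms, beta):
        k = len(terms)
        return ModelFit(
            terms=terms, beta=np.asarray(beta, float), se=np.ones(k),
            p_values=np.full(k, 0.5), sigma=0.0, loglik=0.0, aic=0.0,
            n_obs=10, n_groups=2, method="laplace",
        )

    def test_zero_linear_predictor(self):
        f = self._fit(["(intercept)", "d"], [0.0, 0.0])
        assert predict_probability(f, {"d": 123.0}) == 0.5

    def test_owl_directionality_threshold_point(self):
        """The printed owl movement model is indifferent at ~1203 m."""
        f = self._fit(["(intercept)", "d_start"], [-0.361, 0.0003])
        assert predict_probability(f, {"d_start": 1203.33}) == pytest.approx(0.5, abs=1e-4)

    def test_monotone_in_positive_coefficient(self):
        f = self._fit(["(intercept)", "d"], [0.1, 0.5])
        ps = [predict_probability(f, {"d": v}) for v in (-2, 0, 2)]
        assert ps[0] < ps[1] < ps[2]

    def test_missing_covariate(self):
        f = self._fit(["(intercept)", "d"], [0.0, 1.0])
        with pytest.raises(ValueError, match="missing"):
            predict_probability(f, {})
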