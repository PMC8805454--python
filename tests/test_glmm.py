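"""Negative binomial mixed model: design, likelihood, inference, predictions."""

import datetime as dt
import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from newsaffect import simulate
from newsaffect.glmm import (
    ModelSpec,
    _design_matrix,
    _laplace_negloglik,
    _laplace_nll_grad,
    build_design,
    compare_time_transforms,
    efron_pseudo_r2,
    fit_nb_glmm,
    percent_change,
    predict_marginal,
)


def _synthetic(seed=3, n_states=8, days=120, theta=8.0, cluster="Depression"):
    cfg = simulate.GeneratorConfig(
        seed=seed,
        n_states=n_states,
        start_date=dt.date(2020, 3, 24),
        end_date=dt.date(2020, 3, 24) + dt.timedelta(days=days - 1),
        theta=theta,
    )
    feats = simulate.simulate_features(cfg)
    _, truth = simulate.generate_trends(cfg, feats)
    spec = ModelSpec(cluster, "VA", "linear")
    design = build_design(feats, truth.cluster_counts, spec)
    return design, spec, truth


class TestBuildDesign:
    def _features(self, states, dates):
        rows = []
        for s in states:
            for d in dates:
                row = {"state": s, "date": d, "n_mapped": 10}
                for dim in "VAD":
                    row[f"mean_{dim}"] = 0.1
                    row[f"Flux_{dim}"] = 0.8
                for plane in ("VA", "VD", "AD"):
                    row[f"Pulse_{plane}"] = 0.5
                    row[f"Spin_{plane}"] = 25.0
                rows.append(row)
        return pd.DataFrame(rows)

    def _counts(self, states, dates):
        return pd.DataFrame(
            [
                {"state": s, "date": d, "cluster": "All", "count": 5}
                for s in states
                for d in dates
            ]
        )

    def test_cardinality_of_inner_join(self):
        dates = pd.date_range("2020-04-01", periods=3)
        feats = self._features(["AA", "BB"], dates)
        counts = self._counts(["AA", "BB"], dates)
        design = build_design(feats, counts, ModelSpec("All", "VA"))
        assert len(design) == 6

    def test_time_origin_and_study_span(self):
        dates = [pd.Timestamp("2020-03-24"), pd.Timestamp("2020-10-22")]
        feats = self._features(["AA", "BB"], dates)
        counts = self._counts(["AA", "BB"], dates)
        design = build_design(feats, counts, ModelSpec("All", "VA"))
        assert design["t"].min() == 0
        assert design["t"].max() == 212
        # inclusive day count of the modeling window
        assert (dt.date(2020, 10, 22) - dt.date(2020, 3, 24)).days + 1 == 213

    def test_row_with_missing_feature_dropped(self):
        dates = pd.date_range("2020-04-01", periods=3)
        feats = self._features(["AA", "BB"], dates)
        feats.loc[0, "Spin_VA"] = np.nan
        counts = self._counts(["AA", "BB"], dates)
        design = build_design(feats, counts, ModelSpec("All", "VA"))
        assert len(design) == 5

    def test_empty_join_raises(self):
        feats = self._features(["AA"], [pd.Timestamp("2020-04-01")])
        counts = self._counts(["BB"], [pd.Timestamp("2020-04-01")])
        with pytest.raises(ValueError):
            build_design(feats, counts, ModelSpec("All", "VA"))


class TestEfronPseudoR2:
    def test_perfect_fit(self):
        assert efron_pseudo_r2([1, 5, 9], [1, 5, 9]) == pytest.approx(1.0)

    def test_null_model(self):
        y = np.array([1.0, 2.0, 3.0])
        assert efron_pseudo_r2(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_worked_example(self):
        assert efron_pseudo_r2([1, 2, 3], [1, 2, 2]) == pytest.approx(0.5)

    def test_constant_outcome_undefined(self):
        with pytest.raises(ValueError):
            efron_pseudo_r2([2, 2, 2], [1, 2, 3])


class TestPercentChange:
    @pytest.mark.parametrize(
        "beta, expected",
        [(0.0, 0.0), (0.221, 24.7), (-0.207, -18.7), (math.log(2), 100.0)],
    )
    def test_examples(self, beta, expected):
        assert round(percent_change(beta), 1) == expected


class TestLaplaceGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        design, spec, _ = _synthetic(seed=9, n_states=5, days=40)
        X, _ = _design_matrix(design, spec)
        y = design["y"].to_numpy(float)
        _, gidx = np.unique(design["state"], return_inverse=True)
        G = gidx.max() + 1
        rng = np.random.default_rng(1)
        p = np.concatenate([[5.0], rng.normal(0, 0.02, X.shape[1] - 1), [0.3, -0.5]])
        _, grad = _laplace_nll_grad(p, X, y, gidx, G)
        for i in range(len(p)):
            e = np.zeros_like(p)
            e[i] = 1e-6
            fd = (
                _laplace_negloglik(p + e, X, y, gidx, G)
                - _laplace_negloglik(p - e, X, y, gidx, G)
            ) / 2e-6
            assert grad[i] == pytest.approx(fd, rel=2e-3, abs=0.05)


class TestFit:
    def test_constant_counts_recover_log_mean(self):
        """With a flat outcome the intercept approaches log(c) and slopes 0."""
        dates = pd.date_range("2020-04-01", periods=30)
        rng = np.random.default_rng(0)
        rows = []
        for s in ("AA", "BB", "CC"):
            for d in dates:
                rows.append(
                    {
                        "state": s, "date": d, "y": 7, "t": (d - dates[0]).days,
                        "mean_V": rng.normal(), "mean_A": rng.normal(),
                        "Spin_VA": rng.normal(25, 3), "Pulse_VA": rng.normal(0.5, 0.1),
                        "Flux_V": rng.normal(0.9, 0.1), "Flux_A": rng.normal(0.9, 0.1),
                    }
                )
        design = pd.DataFrame(rows)
        fit = fit_nb_glmm(design, ModelSpec("All", "VA"))
        predicted_flat = fit.beta["(Intercept)"] + (
            fit.beta.drop("(Intercept)") * fit.feature_means
        ).sum()
        assert predicted_flat == pytest.approx(math.log(7), abs=1e-3)
        assert math.isnan(fit.pseudo_r2)

    def test_single_fit_recovers_truth_within_three_se(self):
        design, spec, truth = _synthetic(seed=17, n_states=15, days=150)
        fit = fit_nb_glmm(design, spec)
        for term, true_val in truth.beta.items():
            est = fit.table.loc[term]
            assert abs(est["beta"] - true_val) < 3 * est["se"], term
        icept = fit.table.loc["(Intercept)"]
        true_icept = truth.cluster_intercepts["Depression"]
        assert abs(icept["beta"] - true_icept) < 4 * icept["se"] + 0.05
        assert fit.theta == pytest.approx(truth.theta, rel=0.25)
        assert all(np.isfinite(fit.table["se"]))
        assert ((fit.table["ci_low"] < fit.table["beta"])
                & (fit.table["beta"] < fit.table["ci_high"])).all()

    def test_deterministic_given_data(self):
        design, spec, _ = _synthetic(seed=5, n_states=5, days=60)
        f1 = fit_nb_glmm(design, spec)
        f2 = fit_nb_glmm(design, spec)
        pd.testing.assert_frame_equal(f1.table, f2.table)
        assert f1.theta == f2.theta and f1.sigma_b == f2.sigma_b

    def test_random_modes_track_true_intercepts(self):
        design, spec, truth = _synthetic(seed=23, n_states=12, days=120)
        fit = fit_nb_glmm(design, spec)
        states = sorted(fit.random_modes)
        est = np.array([fit.random_modes[s] for s in states])
        true = np.array([truth.random_modes[s] for s in states])
        assert np.corrcoef(est, true)[0, 1] > 0.9


class TestAgainstReferenceImplementations:
    """Independent oracles: glmmTMB (nbinom2) and lme4 (Poisson limit) via R."""

    def _run_r(self, tmp_path, script):
        path = tmp_path / "check.R"
        path.write_text(textwrap.dedent(script))
        result = subprocess.run(
            ["Rscript", "--vanilla", str(path)],
            capture_output=True, text=True, timeout=600,
        )
        assert result.returncode == 0, result.stderr
        return result.stdout

    def test_matches_glmmtmb_estimates(self, tmp_path):
        design, spec, _ = _synthetic(seed=3, n_states=8, days=120)
        csv = tmp_path / "design.csv"
        design.to_csv(csv, index=False)
        fit = fit_nb_glmm(design, spec)
        out = self._run_r(
            tmp_path,
            f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}")
            m <- glmmTMB(y ~ t + mean_V + mean_A + Spin_VA + Pulse_VA +
                             Flux_V + Flux_A + (1|state),
                         family = nbinom2, data = d)
            co <- summary(m)$coefficients$cond
            cat(co[, "Estimate"], "\n")
            cat(co[, "Std. Error"], "\n")
            cat(sigma(m), sqrt(VarCorr(m)$cond$state[1]), "\n")
            """,
        )
        lines = [np.array(l.split(), dtype=float) for l in out.strip().splitlines()]
        ref_beta, ref_se, (ref_theta, ref_sigma) = lines[0], lines[1], lines[2]
        np.testing.assert_allclose(fit.table["beta"], ref_beta, atol=2e-3, rtol=1e-2)
        np.testing.assert_allclose(fit.table["se"], ref_se, rtol=0.05, atol=1e-4)
        assert fit.theta == pytest.approx(ref_theta, rel=0.02)
        assert fit.sigma_b == pytest.approx(ref_sigma, rel=0.05)

    def test_poisson_limit_matches_glmer(self, tmp_path):
        """Data with huge theta are effectively Poisson; the NB fit's betas
        should match a Poisson mixed fit closely."""
        design, spec, _ = _synthetic(seed=29, n_states=6, days=80, theta=1e6)
        csv = tmp_path / "design.csv"
        design.to_csv(csv, index=False)
        fit = fit_nb_glmm(design, spec)
        out = self._run_r(
            tmp_path,
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ t + mean_V + mean_A + Spin_VA + Pulse_VA +
                           Flux_V + Flux_A + (1|state),
                       family = poisson, data = d,
                       control = glmerControl(optimizer = "bobyqa"))
            cat(fixef(m), "\n")
            """,
        )
        ref_beta = np.array(out.strip().split(), dtype=float)
        np.testing.assert_allclose(fit.table["beta"], ref_beta, atol=1e-2)


@pytest.fixture(scope="module")
def marginal_fit():
    design, spec, _ = _synthetic(seed=41, n_states=8, days=100)
    return fit_nb_glmm(design, spec)


class TestPredictMarginal:
    @pytest.fixture
    def fit(self, marginal_fit):
        return marginal_fit

    def test_single_point_at_means_is_exp_linear_predictor(self, fit):
        point = fit.feature_means["Flux_A"]
        pred = predict_marginal(fit, "Flux_A", [point])["predicted"].iloc[0]
        expected = math.exp(
            fit.beta["(Intercept)"]
            + float((fit.beta.drop("(Intercept)") * fit.feature_means).sum())
        )
        assert pred == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_coefficient_sign(self, fit):
        grid = np.linspace(10, 40, 7)
        pred = predict_marginal(fit, "Spin_VA", grid)["predicted"].to_numpy()
        if fit.beta["Spin_VA"] < 0:
            assert np.all(np.diff(pred) < 0)
        else:
            assert np.all(np.diff(pred) > 0)

    def test_unknown_variable_rejected(self, fit):
        with pytest.raises(ValueError):
            predict_marginal(fit, "Flux_Q", [0.0])

    def test_interaction_grid_shape_and_margins(self, fit):
        g1, g2 = [15.0, 25.0, 35.0], [0.5, 1.0]
        surface = predict_marginal(fit, "Spin_VA", g1, "Flux_A", g2)
        assert len(surface) == 6
        single = predict_marginal(fit, "Spin_VA", g1)
        # at Flux_A fixed to its mean the surface reduces to the 1D curve
        at_mean = predict_marginal(
            fit, "Spin_VA", g1, "Flux_A", [fit.feature_means["Flux_A"]]
        )
        np.testing.assert_allclose(
            at_mean["predicted"], single["predicted"], rtol=1e-12
        )


class TestCompareTimeTransforms:
    def test_reports_both_transforms_rounded(self):
        design, spec, _ = _synthetic(seed=7, n_states=5, days=80)
        report = compare_time_transforms(design, spec)
        assert list(report["time_transform"]) == ["linear", "log"]
        assert len(report) == 2
        assert (report["pseudo_r2_2dp"] == report["pseudo_r2"].round(2)).all()
        assert report["pseudo_r2"].between(-1, 1).all()
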