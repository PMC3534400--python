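"""Spline bases, penalized IRLS submodels, dispersion profiling, and the
composite hurdle estimator."""

import json
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from hurdlecall import flow_model as fm
from hurdlecall.gam import (
    HurdleBaseCaller,
    LogisticGAM,
    SmoothTerm,
    TruncatedWeightedPoissonGAM,
    estimate_theta,
    fit_binomial_gam,
    spline_basis,
    ztwp_loglik,
)
from hurdlecall.simulator import simulate_from_model


def cox_de_boor(x, t, i, k):
    """Textbook B-spline recursion, independent of scipy."""
    if k == 0:
        # right-closed last interval so the boundary point is covered
        if t[i] <= x < t[i + 1] or (x == t[-1] and t[i] < t[i + 1] == t[-1]):
            return 1.0
        return 0.0
    out = 0.0
    if t[i + k] > t[i]:
        out += (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, t, i, k - 1)
    if t[i + k + 1] > t[i + 1]:
        out += (
            (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * cox_de_boor(x, t, i + 1, k - 1)
        )
    return out


class TestSplineBasis:
    def test_partition_of_unity(self):
        x = np.linspace(0, 1, 200)
        term = SmoothTerm("x").fit(x)
        raw = term._raw(x)
        np.testing.assert_allclose(raw.sum(axis=1), 1.0, atol=1e-10)

    def test_penalty_psd_with_nullity_two(self):
        x = np.linspace(0, 1, 100)
        term = SmoothTerm("x").fit(x)
        S = term.penalty()
        eig = np.linalg.eigvalsh(S)
        assert (eig > -1e-10).all()
        assert (np.abs(eig) < 1e-10).sum() == term.penalty_order

    def test_matches_de_boor_recursion(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 80)
        term = SmoothTerm("x").fit(x)
        t = term.knots_
        mids = 0.5 * (np.unique(t)[:-1] + np.unique(t)[1:])
        raw = term._raw(mids)
        for xi, row in zip(mids, raw):
            ref = [cox_de_boor(xi, t, i, term.degree) for i in range(term.n_cols_)]
            np.testing.assert_allclose(row, ref, atol=1e-10)

    def test_linear_extension_outside_range(self):
        x = np.linspace(0, 1, 50)
        term = SmoothTerm("x").fit(x)
        coef = np.arange(term.n_cols_, dtype=float)
        inside = term.transform(np.array([0.999999, 1.0]))
        slope = (inside[1] - inside[0]) @ coef / 1e-6
        outside = term.transform(np.array([1.0, 1.5, 2.0]))
        vals = outside @ coef
        np.testing.assert_allclose(np.diff(vals), [0.5 * slope, 0.5 * slope], rtol=1e-3)

    def test_constant_covariate_degrades_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            B, S = spline_basis(np.full(20, 3.0), SmoothTerm("c"))
        assert B.shape == (20, 1)
        np.testing.assert_allclose(S, 0.0)


class TestLogisticGAM:
    def test_intercept_only_recovery(self):
        rng = np.random.default_rng(10)
        z = (rng.random(10_000) < 0.75).astype(float)
        m = LogisticGAM().fit(np.empty((10_000, 0)), z)
        assert 1 / (1 + math.exp(-m.intercept_)) == pytest.approx(0.75, abs=0.02)

    def test_linear_logit_slope_recovery(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20_000)
        z = (rng.random(20_000) < 1 / (1 + np.exp(-2.0 * x))).astype(float)
        m = LogisticGAM().fit(pd.DataFrame({"x": x}), z)
        grid = np.linspace(-1, 1, 41)
        slope = np.polyfit(grid, m.predict_linear(pd.DataFrame({"x": grid})), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_balanced_classes_give_zero_intercept(self):
        z = np.array([0.0, 1.0] * 50)
        m = LogisticGAM().fit(np.empty((100, 0)), z)
        assert m.intercept_ == pytest.approx(0.0, abs=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            fit_binomial_gam(np.empty((50, 0)), np.ones(50))

    def test_penalized_deviance_monotone(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=3000)
        z = (rng.random(3000) < 1 / (1 + np.exp(-np.sin(2 * x)))).astype(float)
        m = LogisticGAM(penalty=1.0).fit(pd.DataFrame({"x": x}), z)
        diffs = np.diff(m.deviance_path_)
        assert (diffs <= 1e-10).all()

    def test_infinite_smoothing_collapses_to_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        x = rng.normal(size=2000)
        z = (rng.random(2000) < 1 / (1 + np.exp(-(0.3 + 1.2 * x)))).astype(float)
        m = LogisticGAM(penalty=1e9, tol=1e-12).fit(pd.DataFrame({"x": x}), z)
        glm = sm.GLM(z, sm.add_constant(x), family=sm.families.Binomial()).fit()
        ours = 1 / (1 + np.exp(-m.predict_linear(pd.DataFrame({"x": x}))))
        np.testing.assert_allclose(ours, glm.fittedvalues, atol=1e-4)


class TestZtwpLoglik:
    def test_theta_zero_matches_closed_form(self):
        from scipy.stats import poisson

        counts = np.array([1, 2, 3, 5, 2])
        lam = 2.2
        expected = sum(
            poisson.logpmf(c, lam) - math.log1p(-math.exp(-lam)) for c in counts
        )
        assert ztwp_loglik(counts, lam, 0.0) == pytest.approx(expected, abs=1e-10)

    def test_single_observation_composition(self):
        p = fm.WeightedPoissonParams(2.0, 0.3)
        assert ztwp_loglik(np.array([2]), 2.0, 0.3) == pytest.approx(
            math.log(fm.zt_weighted_poisson_pmf(2, p)), abs=1e-12
        )

    def test_likelihood_peaks_near_data(self):
        counts = np.full(50, 3)
        assert ztwp_loglik(counts, 3.0, 0.0) > ztwp_loglik(counts, 6.0, 0.0)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ztwp_loglik(np.array([0, 1]), 1.0, 0.0)


class TestZtwpGAM:
    def test_intercept_only_rate_recovery(self):
        rng = np.random.default_rng(14)
        c = rng.poisson(3.0, 30_000)
        c = c[c >= 1][:10_000]
        m = TruncatedWeightedPoissonGAM(theta=0.0, penalty=1.0).fit(np.empty((len(c), 0)), c)
        assert math.exp(m.intercept_) == pytest.approx(3.0, abs=0.1)

    def test_degenerate_all_ones(self):
        c = np.ones(400, dtype=int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = TruncatedWeightedPoissonGAM(theta=0.0, penalty=1.0).fit(np.empty((400, 0)), c)
        lam = math.exp(m.intercept_)
        zt_mean = lam / (1 - math.exp(-lam))
        assert zt_mean == pytest.approx(1.0, abs=1e-3)

    def test_smooth_log_rate_recovery(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(-2, 2, 20_000)
        lam_fn = lambda v: np.exp(1.0 + np.sin(v))
        c = simulate_from_model(lambda v: np.ones_like(v), lam_fn, 0.3, x, seed=16)
        pos = c >= 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = TruncatedWeightedPoissonGAM(theta=0.3, penalty=1.0).fit(
                pd.DataFrame({"x": x[pos]}), c[pos]
            )
        q = np.quantile(x, [0.25, 0.75])
        grid = np.linspace(q[0], q[1], 60)
        fitted = m.predict_linear(pd.DataFrame({"x": grid}))
        rmse = np.sqrt(np.mean((fitted - (1.0 + np.sin(grid))) ** 2))
        assert rmse < 0.1

    def test_monotone_penalized_deviance(self):
        rng = np.random.default_rng(17)
        c = rng.poisson(2.5, 8000)
        c = c[c >= 1][:3000]
        x = rng.normal(size=len(c))
        m = TruncatedWeightedPoissonGAM(theta=0.1, penalty=10.0).fit(pd.DataFrame({"x": x}), c)
        assert (np.diff(m.deviance_path_) <= 1e-10).all()

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            TruncatedWeightedPoissonGAM(theta=0.0, penalty=1.0).fit(
                np.empty((3, 0)), np.array([0, 1, 2])
            )


class TestEstimateTheta:
    def test_recovers_positive_theta(self):
        rng = np.random.default_rng(18)
        x = rng.uniform(-2, 2, 20_000)
        lam_fn = lambda v: np.exp(1.0 + 0.4 * np.sin(v) + 0.3 * v)
        c = simulate_from_model(lambda v: np.ones_like(v), lam_fn, 0.4, x, seed=19)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theta, profile, _ = estimate_theta(pd.DataFrame({"x": x}), c, penalty=1.0)
        assert 0.3 <= theta <= 0.5
        assert len(profile) >= 7

    def test_poisson_limit_selects_smallest(self):
        rng = np.random.default_rng(20)
        c = rng.poisson(3.0, 15_000)
        c = c[c >= 1][:6000]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theta, _, _ = estimate_theta(
                np.empty((len(c), 0)), c, penalty=1.0, grid=(0.0, 0.4, 0.8)
            )
        assert theta == 0.0

    def test_single_value_grid_passthrough(self):
        c = np.array([1, 2, 3, 2, 1, 2] * 20)
        theta, profile, _ = estimate_theta(np.empty((len(c), 0)), c, penalty=1.0, grid=(0.25,))
        assert theta == 0.25
        assert len(profile) == 1


class TestHurdleBaseCaller:
    def test_requires_reference_hpls(self, small_sim):
        _, flows, _ = small_sim
        with pytest.raises(ValueError, match="ref_hpl"):
            HurdleBaseCaller().fit(flows.drop(columns=["ref_hpl"]))

    def test_no_zero_flows_names_hurdle(self, small_sim):
        _, flows, _ = small_sim
        pos = flows[flows.ref_hpl > 0]
        with pytest.raises(ValueError, match="hurdle"):
            HurdleBaseCaller().fit(pos)

    def test_too_few_positive_flows_refused(self, small_sim):
        _, flows, _ = small_sim
        sub = pd.concat(
            [flows[flows.ref_hpl == 0].head(100), flows[flows.ref_hpl > 0].head(20)]
        ).sort_index()
        with pytest.raises(ValueError, match="positive flows"):
            HurdleBaseCaller().fit(sub)

    def test_refit_is_deterministic(self, small_sim, trained_model):
        _, flows, _ = small_sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = HurdleBaseCaller(
                theta_grid=(0.0, 0.2, 0.8), penalty_grid=(1e-2, 1.0, 1e2)
            ).fit(flows)
        np.testing.assert_array_equal(again.binomial_.coef_, trained_model.binomial_.coef_)
        np.testing.assert_array_equal(again.poisson_.coef_, trained_model.poisson_.coef_)
        assert again.theta_ == trained_model.theta_

    def test_feature_config_mismatch_refused(self, trained_model, small_sim):
        from hurdlecall.features import FeatureConfig

        _, flows, _ = small_sim
        other = FeatureConfig(normalize_raw=False)
        with pytest.raises(ValueError, match="configuration"):
            trained_model.predict_proba(flows, feature_config=other)

    def test_serialization_round_trip_bit_exact(self, trained_model, small_sim):
        _, flows, _ = small_sim
        text = trained_model.to_json()
        clone = HurdleBaseCaller.from_json(text)
        assert clone.to_json() == text
        np.testing.assert_array_equal(
            clone.predict_proba(flows.head(200)), trained_model.predict_proba(flows.head(200))
        )

    def test_extrapolation_flags(self, trained_model, small_sim):
        _, flows, _ = small_sim
        sub = flows.head(40).copy()
        assert not trained_model.extrapolation_flags(sub).any()
        sub.loc[sub.index[5], "flowgram"] = 1e5
        flags = trained_model.extrapolation_flags(sub)
        assert flags.any()
        # probabilities are still returned for flagged flows
        probs = trained_model.predict_proba(sub)
        assert np.isfinite(probs).all()

    def test_sklearn_params_round_trip(self):
        m = HurdleBaseCaller(n_basis=8)
        params = m.get_params()
        assert params["n_basis"] == 8
        m.set_params(n_basis=12)
        assert m.n_basis == 12
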