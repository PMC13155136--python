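import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from cooplda import (
    AssayGroup,
    ConvergenceWarning,
    DilutionObservation,
    EstimationRefusedError,
    InputError,
    LimitingDilutionModel,
    SimulationConfig,
    compare_models,
    fit_loglog_glm,
    simulate_lda,
)


def brute_force_mle(model, alpha_range=(-8, 4), b_range=(0.05, 8), grid=40):
    """Independent likelihood maximization: dense grid then Nelder-Mead."""
    best = None
    for a0 in np.linspace(*alpha_range, grid):
        for b0 in np.linspace(*b_range, grid):
            ll = model.loglike(np.array([a0, b0]))
            if best is None or ll > best[0]:
                best = (ll, a0, b0)
    res = minimize(
        lambda p: -model.loglike(p),
        [best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    return res.x


def _informative_group(seed, n_wells=24, p=None, b=None):
    rng = np.random.default_rng(seed)
    p = p if p is not None else rng.uniform(0.05, 0.4)
    b = b if b is not None else rng.uniform(0.6, 2.0)
    exp = simulate_lda(
        SimulationConfig(p=p, b=b, n_wells=n_wells, seed=int(rng.integers(2**31)))
    )
    return exp.groups[0]


class TestSaturatedAndClosedForms:
    def test_two_point_fit_interpolates_link_scale(self, two_point_group):
        res = fit_loglog_glm(two_point_group)
        # mu = 0.5 at S=1 and 0.25 at S=4 are hit exactly
        assert res.alpha == pytest.approx(np.log(np.log(2)), abs=1e-8)
        assert res.b == pytest.approx(0.5, abs=1e-8)
        assert res.deviance == pytest.approx(0.0, abs=1e-9)
        assert res.converged

    def test_single_point_fixed_slope_closed_form(self):
        g = AssayGroup("t", "r", (DilutionObservation(2, 4, 2),))
        res = fit_loglog_glm(g, slope_fixed=True)
        assert res.alpha == pytest.approx(np.log(-np.log(0.5)) - np.log(2), abs=1e-8)
        assert res.b == 1.0
        assert res.n_params == 1

    def test_aic_identity(self, two_point_group):
        res = fit_loglog_glm(two_point_group)
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.n_params)


class TestPrediction:
    def test_unit_rate_failure_fraction(self, two_point_group):
        res = fit_loglog_glm(two_point_group)
        # alpha=0, b=1 would give mu(1) = 1/e; emulate via direct formula
        assert np.exp(-np.exp(0.0)) == pytest.approx(1 / np.e)
        # inverse of the fitting example: mu(4) = 0.25
        assert res.predict(4.0) == pytest.approx(0.25, abs=1e-8)

    def test_mu_at_activity_is_one_over_e(self, two_point_group):
        res = fit_loglog_glm(two_point_group)
        a = np.exp(-res.alpha / res.b)
        assert res.predict(a) == pytest.approx(1 / np.e, abs=1e-10)

    def test_band_contains_point_and_stays_in_unit_interval(self):
        res = fit_loglog_glm(_informative_group(1))
        for S in (0.5, 1, 5, 50):
            mu, (lo, hi) = res.predict(S, level=0.95)
            assert 0.0 <= lo <= mu <= hi <= 1.0

    def test_predicted_mu_monotone_decreasing_in_S(self):
        res = fit_loglog_glm(_informative_group(2))
        assert res.b > 0
        S = np.logspace(-2, 4, 100)
        mu = res.predict(S)
        assert np.all(np.diff(mu) <= 0)
        # strictly decreasing wherever mu has not underflowed to 0
        alive = mu > 1e-12
        assert np.all(np.diff(mu[alive]) < 0)

    def test_nonpositive_S_rejected(self, two_point_group):
        res = fit_loglog_glm(two_point_group)
        with pytest.raises(InputError):
            res.predict(-1.0)


class TestOracles:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_mle(self, seed):
        g = _informative_group(seed + 100, n_wells=24)
        if g.all_negative or g.all_positive:
            pytest.skip("degenerate draw")
        res = fit_loglog_glm(g)
        if not res.converged:
            pytest.skip("boundary draw")
        ref = brute_force_mle(res.model)
        assert res.alpha == pytest.approx(ref[0], abs=1e-4)
        assert res.b == pytest.approx(ref[1], abs=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels_cloglog_on_successes(self, seed):
        """Fitting failures with log-log link equals fitting successes with
        complementary log-log link: same alpha, b, covariance and deviance."""
        sm = pytest.importorskip("statsmodels.api")
        g = _informative_group(seed + 300, n_wells=24)
        if g.all_negative or g.all_positive:
            pytest.skip("degenerate draw")
        res = fit_loglog_glm(g)
        if not res.converged:
            pytest.skip("boundary draw")
        glm = sm.GLM(
            np.column_stack([g.n_wells - g.n_negative, g.n_negative]),
            sm.add_constant(np.log(g.cells_per_well)),
            family=sm.families.Binomial(sm.families.links.CLogLog()),
        )
        ref = glm.fit(tol=1e-12, maxiter=300)
        np.testing.assert_allclose(ref.params, res.params, atol=1e-6)
        np.testing.assert_allclose(ref.cov_params(), res.cov_params, atol=1e-5)
        assert res.llf == pytest.approx(ref.llf, abs=1e-6)
        assert res.deviance == pytest.approx(ref.deviance, abs=1e-6)


class TestInvariances:
    @pytest.mark.parametrize("c", [0.1, 2.0, 1000.0])
    def test_dilution_rescaling_shifts_intercept_only(self, c):
        g = _informative_group(7)
        res = fit_loglog_glm(g)
        scaled = AssayGroup(
            g.treatment,
            g.replicate,
            tuple(
                DilutionObservation(o.cells_per_well * c, o.n_wells, o.n_negative)
                for o in g.observations
            ),
        )
        res_c = fit_loglog_glm(scaled)
        assert res_c.b == pytest.approx(res.b, abs=1e-6)
        assert res_c.alpha == pytest.approx(res.alpha - res.b * np.log(c), abs=1e-5)

    def test_estimator_consistent_at_high_replication(self):
        """Mean b over 200 simulated assays at 8 dilutions x 96 wells is within
        0.05 of the generating value; bias shrinks relative to n=12."""
        def mean_b(n_wells, n_runs=200):
            bs = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for seed in range(n_runs):
                    exp = simulate_lda(
                        SimulationConfig(p=0.1, b=1.5, n_wells=n_wells, seed=seed)
                    )
                    try:
                        r = fit_loglog_glm(exp.groups[0])
                    except EstimationRefusedError:
                        continue
                    if r.converged:
                        bs.append(r.b)
            return float(np.mean(bs))

        b96 = mean_b(96)
        b12 = mean_b(12)
        assert abs(b96 - 1.5) < 0.05
        assert abs(b96 - 1.5) < abs(b12 - 1.5)


class TestDegenerateInputs:
    def test_all_negative_refused(self, all_negative_group):
        with pytest.raises(EstimationRefusedError, match="not estimable"):
            fit_loglog_glm(all_negative_group)

    def test_all_positive_flagged_not_converged(self):
        obs = tuple(DilutionObservation(2.0**k, 12, 0) for k in range(4))
        g = AssayGroup("t", "r", obs)
        with pytest.warns(ConvergenceWarning):
            res = fit_loglog_glm(g)
        assert not res.converged

    def test_too_few_distinct_dilutions(self):
        g = AssayGroup("t", "r", (DilutionObservation(4, 12, 3),))
        with pytest.raises(InputError, match="distinct dilutions"):
            fit_loglog_glm(g)

    def test_quasi_separated_data_flagged(self):
        # all-negative below a threshold dilution, all-positive above it:
        # the likelihood increases toward the parameter-space boundary
        obs = (
            DilutionObservation(1, 12, 12),
            DilutionObservation(4, 12, 12),
            DilutionObservation(16, 12, 0),
            DilutionObservation(64, 12, 0),
        )
        with pytest.warns(ConvergenceWarning):
            res = fit_loglog_glm(AssayGroup("t", "r", obs))
        assert not res.converged


class TestModelComparison:
    def test_nesting_gives_nonnegative_delta_deviance(self, two_point_group):
        free = fit_loglog_glm(two_point_group)
        fixed = fit_loglog_glm(two_point_group, slope_fixed=True)
        cmp = compare_models(free, fixed)
        assert cmp.delta_deviance >= 0
        assert cmp.delta_deviance == pytest.approx(fixed.deviance, abs=1e-9)
        assert 0 <= cmp.lrt_p <= 1
        assert cmp.delta_aic == pytest.approx(fixed.aic - free.aic)

    def test_mismatched_data_rejected(self, two_point_group):
        free = fit_loglog_glm(two_point_group)
        other = AssayGroup(
            "t", "r", (DilutionObservation(1, 8, 4), DilutionObservation(4, 8, 2))
        )
        fixed = fit_loglog_glm(other, slope_fixed=True)
        with pytest.raises(InputError, match="identical"):
            compare_models(free, fixed)

    def test_argument_order_enforced(self, two_point_group):
        free = fit_loglog_glm(two_point_group)
        fixed = fit_loglog_glm(two_point_group, slope_fixed=True)
        with pytest.raises(InputError):
            compare_models(fixed, free)

    def test_summary_mentions_key_quantities(self, two_point_group):
        res = fit_loglog_glm(two_point_group)
        text = res.summary()
        assert "alpha" in text and "clonogenic activity" in text and "AIC" in text
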