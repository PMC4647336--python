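import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from physdens import synth, ztnb
from physdens.errors import ConfigError, DegenerateInputError, DomainError


# ---------------------------------------------------------------------------
# standardization and design
# ---------------------------------------------------------------------------


class TestTwoSdStandardize:
    def test_known_values(self):
        values = np.array([8.0, 10.0, 12.0])  # mean 10, sd 2
        scaled, (mean, sd) = ztnb.two_sd_standardize(values)
        assert mean == pytest.approx(10.0)
        assert sd == pytest.approx(2.0)
        assert scaled[2] == pytest.approx(0.5)  # (12-10)/4
        # an input of 14 maps to (14-10)/4 = 1.0
        assert (14.0 - mean) / (2 * sd) == pytest.approx(1.0)

    def test_mean_maps_to_zero(self):
        scaled, _ = ztnb.two_sd_standardize([1.0, 2.0, 3.0])
        assert scaled.mean() == pytest.approx(0.0, abs=1e-12)

    def test_output_sd_is_half(self):
        rng = np.random.default_rng(0)
        scaled, _ = ztnb.two_sd_standardize(rng.normal(5, 3, 1000))
        assert scaled.std(ddof=1) == pytest.approx(0.5, abs=1e-10)

    def test_constant_column(self):
        with pytest.raises(DegenerateInputError):
            ztnb.two_sd_standardize([2.0, 2.0, 2.0])


def tiny_table(n=60, seed=0, regions=("A", "B", "C")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "region": rng.choice(regions, size=n),
            "inhabitants": rng.uniform(5e4, 2e5, size=n),
            "metric1": rng.normal(10, 2, size=n),
            "binary1": rng.integers(0, 2, size=n),
            "gp_count": rng.integers(1, 50, size=n),
            "sp_count": rng.integers(1, 30, size=n),
        }
    )


class TestBuildDesign:
    def test_column_layout(self):
        table = tiny_table()
        spec = ztnb.ModelSpec(
            response="gp_count",
            metric=("metric1",),
            binary=("binary1",),
            interactions=(("metric1", "binary1"),),
        )
        design, y, offset = ztnb.build_design(table, spec)
        assert design.columns[:4] == ["intercept", "metric1", "binary1", "metric1:binary1"]
        assert len(design.columns) == 4 + 2  # two region dummies
        assert len(y) == len(offset) == len(table)

    def test_reference_region_rows_all_zero(self):
        table = tiny_table()
        spec = ztnb.ModelSpec(response="gp_count", metric=("metric1",),
                              reference_region="B")
        design, _, _ = ztnb.build_design(table, spec)
        dummies = design.X[[c for c in design.columns if c.startswith("region[")]]
        ref_rows = dummies[table["region"].to_numpy() == "B"]
        assert (ref_rows.to_numpy() == 0).all()
        assert "region[B]" not in design.columns

    def test_interaction_is_product(self):
        table = tiny_table()
        spec = ztnb.ModelSpec(
            response="gp_count",
            metric=("metric1",),
            binary=("binary1",),
            interactions=(("metric1", "binary1"),),
        )
        design, _, _ = ztnb.build_design(table, spec)
        np.testing.assert_allclose(
            design.X["metric1:binary1"],
            design.X["metric1"] * design.X["binary1"],
        )

    def test_scaled_columns_centered(self):
        table = tiny_table()
        spec = ztnb.ModelSpec(response="gp_count", metric=("metric1",))
        design, _, _ = ztnb.build_design(table, spec)
        col = design.X["metric1"]
        assert col.mean() == pytest.approx(0.0, abs=1e-10)
        assert col.std(ddof=1) == pytest.approx(0.5, abs=1e-10)

    def test_offset_population(self):
        table = tiny_table()
        spec = ztnb.ModelSpec(response="gp_count", metric=("metric1",))
        _, _, offset = ztnb.build_design(table, spec)
        np.testing.assert_allclose(offset, np.log(table["inhabitants"] / 1e4))

    def test_offset_sp_count(self):
        table = tiny_table()
        spec = ztnb.ModelSpec(response="gp_count", offset=ztnb.OFFSET_SP_COUNT,
                              metric=("metric1",))
        _, _, offset = ztnb.build_design(table, spec)
        np.testing.assert_allclose(offset, np.log(table["sp_count"]))

    def test_missing_column(self):
        with pytest.raises(ConfigError, match="missing"):
            ztnb.build_design(tiny_table(), ztnb.ModelSpec(response="gp_count",
                                                           metric=("nope",)))

    def test_rank_deficiency_names_columns(self):
        table = tiny_table()
        table["metric2"] = 2.0 * table["metric1"] + 1.0
        spec = ztnb.ModelSpec(response="gp_count", metric=("metric1", "metric2"))
        with pytest.raises(ConfigError, match="metric2"):
            ztnb.build_design(table, spec)

    def test_response_among_terms_rejected(self):
        with pytest.raises(ConfigError):
            ztnb.ModelSpec(response="gp_count", metric=("gp_count",))

    def test_interaction_needs_parents(self):
        with pytest.raises(ConfigError):
            ztnb.ModelSpec(response="gp_count", metric=("metric1",),
                           interactions=(("metric1", "binary1"),))


# ---------------------------------------------------------------------------
# probability law
# ---------------------------------------------------------------------------


class TestProbabilityLaw:
    def test_geometric_case(self):
        assert ztnb.nb_pmf(0, 1.0, 1.0) == pytest.approx(0.5)
        assert ztnb.nb_pmf(1, 1.0, 1.0) == pytest.approx(0.25)

    def test_pmf_normalizes(self):
        ys = np.arange(0, 2001)
        assert ztnb.nb_pmf(ys, 5.0, 0.3).sum() == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("mu,sigma", [(0.5, 0.1), (2.0, 1.0), (10.0, 0.05), (20.0, 2.0)])
    def test_truncated_pmf_normalizes(self, mu, sigma):
        ys = np.arange(1, 4001)
        total = np.exp(ztnb.ztnb_logpmf(ys, mu, sigma)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_truncated_geometric_case(self):
        assert ztnb.ztnb_logpmf(1, 1.0, 1.0) == pytest.approx(np.log(0.5))

    def test_poisson_limit(self):
        mu, y = 2.0, 3
        pois = stats.poisson.logpmf(y, mu) - np.log1p(-np.exp(-mu))
        assert ztnb.ztnb_logpmf(y, mu, 1e-10) == pytest.approx(pois, abs=1e-6)

    def test_mean_variance_relation(self):
        mu, sigma = 7.0, 0.25
        ys = np.arange(0, 5000)
        pmf = ztnb.nb_pmf(ys, mu, sigma)
        assert (pmf * ys).sum() == pytest.approx(mu, rel=1e-10)
        assert (pmf * ys**2).sum() - mu**2 == pytest.approx(mu + sigma * mu**2, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            ztnb.nb_pmf(-1, 1.0, 1.0)
        with pytest.raises(DomainError):
            ztnb.nb_pmf(1, -1.0, 1.0)
        with pytest.raises(DomainError):
            ztnb.ztnb_logpmf(0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class TestNegLoglik:
    def test_matches_rowwise_sum(self):
        table = tiny_table()
        spec = ztnb.ModelSpec(response="gp_count", metric=("metric1",))
        design, y, offset = ztnb.build_design(table, spec)
        params = np.concatenate([np.full(len(design.columns), 0.1), [np.log(0.5)]])
        mu = np.exp(design.to_numpy() @ params[:-1] + offset)
        direct = -np.sum(ztnb.ztnb_logpmf(y, mu, 0.5))
        assert ztnb.neg_loglik(params, design.to_numpy(), y, offset) == pytest.approx(direct)

    def test_single_row_mle_property(self):
        X = np.ones((1, 1))
        y = np.array([7.0])
        offset = np.zeros(1)
        ls = np.log(1e-6)
        at_opt = ztnb.neg_loglik(np.array([np.log(7.0), ls]), X, y, offset)
        for delta in (-0.5, 0.5):
            away = ztnb.neg_loglik(np.array([np.log(7.0) + delta, ls]), X, y, offset)
            assert at_opt <= away

    def test_analytic_gradient_matches_numeric(self):
        table = tiny_table(n=80, seed=3)
        spec = ztnb.ModelSpec(response="gp_count", metric=("metric1",), binary=("binary1",))
        design, y, offset = ztnb.build_design(table, spec)
        params = np.concatenate([np.full(len(design.columns), 0.05), [0.2]])
        params[0] = 1.0
        args = (design.to_numpy(), y, offset)
        numeric = optimize.approx_fprime(params, ztnb.neg_loglik, 1e-7, *args)
        analytic = ztnb._neg_loglik_grad(params, *args)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-4, atol=1e-4)

    def test_overflow_guard(self):
        X = np.ones((2, 1))
        y = np.array([1.0, 2.0])
        offset = np.zeros(2)
        assert ztnb.neg_loglik(np.array([1e4, 0.0]), X, y, offset) == np.inf


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFit:
    def test_parameter_recovery_full_design(self, default_table_5000):
        table, truth = default_table_5000
        spec = ztnb.ModelSpec(
            response="gp_count",
            metric=tuple(
                s.name for s in synth.default_covariate_specs() if s.kind == "metric"
            ),
            binary=tuple(
                s.name for s in synth.default_covariate_specs() if s.kind == "binary"
            ),
            interactions=(("population_density", "city"),),
            reference_region="R01",
        )
        fit = ztnb.fit_table(table, spec)
        for name, value in truth["coefficients"]["gp"].items():
            assert abs(fit.coef(name) - value) <= 3 * fit.se_of(name), name
        # dispersion recovered on the log scale
        assert abs(fit.log_sigma - np.log(truth["sigma"]["gp"])) <= 3 * fit.se[-1]
        # region offsets against the R01 reference
        for label, value in truth["region_intercepts"].items():
            if label == "R01":
                continue
            name = f"region[{label}]"
            assert abs(fit.coef(name) - value) <= 3 * fit.se_of(name), name

    def test_refit_deterministic(self, small_table):
        table, _ = small_table
        spec = ztnb.ModelSpec(response="gp_count", metric=("population_density",),
                              binary=("city",))
        fit1 = ztnb.fit_table(table, spec)
        fit2 = ztnb.fit_table(table, spec)
        np.testing.assert_allclose(fit1.coefficients, fit2.coefficients, atol=1e-8)
        assert fit1.log_sigma == pytest.approx(fit2.log_sigma, abs=1e-8)

    def test_grid_oracle_brackets_optimum(self):
        # intercept-only data: brute-force grid over (intercept, log_sigma)
        rng = np.random.default_rng(5)
        n = 400
        table = pd.DataFrame(
            {
                "region": "R01",
                "inhabitants": np.full(n, 1e4),
                "gp_count": 0,
                "sp_count": 1,
            }
        )
        table["gp_count"] = synth.simulate_counts(
            table, {"intercept": np.log(6.0)}, sigma=0.3, seed=13
        )
        spec = ztnb.ModelSpec(response="gp_count")
        design, y, offset = ztnb.build_design(table, spec)
        fit = ztnb.fit(design, y, offset)
        args = (design.to_numpy(), y, offset)

        b_grid = np.linspace(fit.coef("intercept") - 0.5, fit.coef("intercept") + 0.5, 41)
        s_grid = np.linspace(fit.log_sigma - 1.0, fit.log_sigma + 1.0, 41)
        nll = np.array(
            [[ztnb.neg_loglik(np.array([b, s]), *args) for s in s_grid] for b in b_grid]
        )
        i, j = np.unravel_index(np.argmin(nll), nll.shape)
        # grid minimum sits at the interior cell containing the fitted optimum
        assert abs(b_grid[i] - fit.coef("intercept")) <= (b_grid[1] - b_grid[0])
        assert abs(s_grid[j] - fit.log_sigma) <= (s_grid[1] - s_grid[0])
        # polish from the grid minimum reaches the same optimum
        polished = optimize.minimize(
            ztnb.neg_loglik, np.array([b_grid[i], s_grid[j]]), args=args,
            method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12},
        )
        assert polished.fun == pytest.approx(-fit.loglik, abs=1e-6)

    def test_covariance_psd_and_bic(self, small_fit):
        fit = small_fit
        eigvals = np.linalg.eigvalsh(fit.cov)
        assert (eigvals > -1e-10).all()
        np.testing.assert_allclose(fit.cov, fit.cov.T)
        assert fit.bic == pytest.approx(-2 * fit.loglik + fit.k * np.log(fit.n))
        assert ((fit.pvalues >= 0) & (fit.pvalues <= 1)).all()

    def test_gradient_small_at_optimum(self, small_table, small_fit):
        table, _ = small_table
        assert small_fit.convergence["converged"]
        assert small_fit.convergence["grad_max"] <= 1e-6

    def test_scale_equivariance(self, small_table):
        # multiplying a metric covariate by a constant changes nothing
        table, _ = small_table
        spec = ztnb.ModelSpec(response="gp_count", metric=("population_density",),
                              binary=("city",))
        fit1 = ztnb.fit_table(table, spec)
        scaled = table.copy()
        scaled["population_density"] = scaled["population_density"] * 37.0
        scaled["area"] = scaled["inhabitants"] / scaled["population_density"]
        fit2 = ztnb.fit_table(scaled, spec)
        np.testing.assert_allclose(fit1.coefficients, fit2.coefficients, atol=1e-7)

    def test_offset_correctness(self, small_table):
        # scaling all inhabitants by 10 shifts only the offset
        table, _ = small_table
        spec = ztnb.ModelSpec(response="gp_count", metric=("population_density",),
                              binary=("city",))
        fit1 = ztnb.fit_table(table, spec)
        bigger = table.copy()
        bigger["inhabitants"] = bigger["inhabitants"] * 10.0
        bigger["area"] = bigger["area"] * 10.0
        fit2 = ztnb.fit_table(bigger, spec)
        np.testing.assert_allclose(
            fit1.coefficients[1:], fit2.coefficients[1:], atol=1e-6
        )
        assert fit2.coef("intercept") == pytest.approx(
            fit1.coef("intercept") - np.log(10.0), abs=1e-6
        )

    def test_poisson_limit_fit(self):
        # data simulated at sigma ~ 0 is matched by a truncated-Poisson MLE
        n = 2000
        rng = np.random.default_rng(17)
        table = pd.DataFrame({"region": "R01", "inhabitants": np.full(n, 1e4)})
        table["gp_count"] = synth.simulate_counts(
            table, {"intercept": np.log(4.0)}, sigma=1e-8, seed=18
        )
        spec = ztnb.ModelSpec(response="gp_count")
        fit = ztnb.fit_table(table, spec)

        y = table["gp_count"].to_numpy(dtype=float)

        def trunc_pois_nll(log_mu):
            mu = np.exp(log_mu[0])
            return -np.sum(stats.poisson.logpmf(y, mu) - np.log1p(-np.exp(-mu)))

        res = optimize.minimize(trunc_pois_nll, [np.log(4.0)], method="Nelder-Mead",
                                options={"xatol": 1e-12})
        assert fit.coef("intercept") == pytest.approx(res.x[0], abs=3 * fit.se[0])
        assert fit.sigma < 0.01

    def test_too_few_rows(self):
        table = tiny_table(n=3)
        spec = ztnb.ModelSpec(response="gp_count", metric=("metric1",))
        with pytest.raises(DegenerateInputError):
            ztnb.fit_table(table, spec)

    def test_wald_coverage(self):
        # 200 seeded replicates at n=2000: 95% CIs cover each coefficient
        specs = [
            s for s in synth.default_covariate_specs()
            if s.name in ("population_density", "hospital_beds", "city")
        ]
        coefs = {"intercept": 1.7, "population_density": -0.15,
                 "hospital_beds": 0.1, "city": 0.1}
        names = list(coefs)
        z95 = stats.norm.isf(0.025)
        cover = np.zeros(len(names))
        n_reps = 200
        spec = ztnb.ModelSpec(
            response="gp_count",
            metric=("population_density", "hospital_beds"),
            binary=("city",),
        )
        for rep in range(n_reps):
            rng = np.random.default_rng(90_000 + rep)
            table = synth.draw_covariates(specs, 2000, rng)
            table["region"] = "R01"
            table["inhabitants"] = 1e4
            table["gp_count"] = synth.simulate_counts(table, coefs, 0.3, rng)
            fit = ztnb.fit_table(table, spec)
            for i, name in enumerate(names):
                cover[i] += abs(fit.coef(name) - coefs[name]) <= z95 * fit.se_of(name)
        rates = cover / n_reps
        assert (rates >= 0.93).all() and (rates <= 0.97).all(), rates


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


class TestPredictedDensity:
    def make_fit(self, eta):
        spec = ztnb.ModelSpec(response="gp_count")
        return ztnb.ZTNBFit(
            spec=spec, columns=("intercept",), coefficients=np.array([eta]),
            log_sigma=np.log(0.05), cov=np.eye(2), loglik=-1.0, n=100,
            convergence={"converged": True},
        )

    def test_baseline_specialist_density(self):
        assert ztnb.predicted_density(self.make_fit(1.919)) == pytest.approx(6.81, abs=5e-3)

    def test_zero_eta(self):
        assert ztnb.predicted_density(self.make_fit(0.0)) == pytest.approx(1.0)

    def test_ratio_back_transform(self):
        assert ztnb.predicted_density(self.make_fit(-0.178)) == pytest.approx(0.837, abs=5e-4)

    def test_row_contributions(self):
        spec = ztnb.ModelSpec(response="gp_count", metric=("x",))
        fit = ztnb.ZTNBFit(
            spec=spec, columns=("intercept", "x"), coefficients=np.array([1.0, 0.5]),
            log_sigma=0.0, cov=np.eye(3), loglik=-1.0, n=100,
            convergence={"converged": True}, scaling={"x": (0.0, 1.0)},
        )
        assert ztnb.predicted_density(fit, {"x": 1.0}) == pytest.approx(np.exp(1.5))

    def test_truncated_mean_exceeds_untruncated(self):
        fit = self.make_fit(0.5)
        plain = ztnb.predicted_density(fit)
        trunc = ztnb.predicted_density(fit, truncated=True)
        assert trunc > plain


@given(st.floats(-3.0, 5.0))
@settings(max_examples=50, deadline=None)
def test_two_sd_standardize_then_fit_invariance_eta(eta):
    # exp/log round trip at the prediction layer
    assert np.log(np.exp(eta)) == pytest.approx(eta, abs=1e-12)
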