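"""Continuous twin variance-component models."""
import math

import numpy as np
import pytest

import biometwin as bt
from biometwin.continuous import pair_loglik, singleton_loglik

LOG2PI = math.log(2 * math.pi)


# ---------------------------------------------------------------------------
# implied correlations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("comp,expected", [
    (dict(a2=0.47, d2=0.17, e2=0.36), (0.64, 0.2775)),
    (dict(a2=0.64, e2=0.36), (0.64, 0.32)),
    (dict(c2=0.42, e2=0.58), (0.42, 0.42)),
    (dict(e2=1.0), (0.0, 0.0)),
])
def test_implied_correlations(comp, expected):
    vc = bt.VarianceComponents(**comp)
    r_mz, r_dz = bt.implied_correlations(vc)
    assert r_mz == pytest.approx(expected[0], abs=1e-12)
    assert r_dz == pytest.approx(expected[1], abs=1e-12)


def test_variance_components_validation():
    with pytest.raises(ValueError):
        bt.VarianceComponents(a2=0.5, e2=0.4)      # does not sum to 1
    with pytest.raises(ValueError):
        bt.VarianceComponents(a2=0.3, d2=0.2, c2=0.2, e2=0.3)  # C and D
    with pytest.raises(ValueError):
        bt.VarianceComponents(e2=1.0, total_sd=0.0)


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------

class TestPairLoglik:
    def test_independent_standard_normals_at_mode(self):
        assert pair_loglik([0.0, 0.0], [0.0, 0.0], 1.0, 0.0) == \
            pytest.approx(2 * math.log(1 / math.sqrt(2 * math.pi)))

    def test_symmetric_under_member_swap(self):
        a = pair_loglik([1.3, -0.4], [0.2, 0.1], 0.8, 0.6)
        b = pair_loglik([-0.4, 1.3], [0.1, 0.2], 0.8, 0.6)
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_independent_closed_form(self):
        """Direct evaluation of the bivariate normal density formula."""
        x1, x2, rho, s = 1.0, -1.0, 0.5, 1.0
        det = s ** 4 * (1 - rho ** 2)
        quad = (x1 ** 2 - 2 * rho * x1 * x2 + x2 ** 2) / (s ** 2 * (1 - rho ** 2))
        expected = -LOG2PI - 0.5 * math.log(det) - 0.5 * quad
        assert pair_loglik([x1, x2], [0, 0], s, rho) == \
            pytest.approx(expected, abs=1e-12)

    def test_density_normalizes_by_quadrature(self):
        """Numerical 2-D integration of exp(loglik) equals 1."""
        from scipy.integrate import dblquad
        val, err = dblquad(
            lambda y2, y1: math.exp(pair_loglik([y1, y2], [0, 0], 1.0, 0.5)),
            -8, 8, -8, 8, epsabs=1e-9)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_sigma_or_rho(self):
        with pytest.raises(ValueError):
            pair_loglik([0, 0], [0, 0], 0.0, 0.3)
        with pytest.raises(ValueError):
            pair_loglik([0, 0], [0, 0], 1.0, 1.0)

    def test_singleton_term_is_univariate_normal(self):
        assert singleton_loglik(0.7, 0.2, 2.0) == pytest.approx(
            -0.5 * LOG2PI - math.log(2.0) - 0.5 * (0.25 ** 2))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class TestFitContinuous:
    def test_recovers_generating_fraction(self, ae_pairs, ae_cohort):
        fit = bt.fit_continuous(ae_pairs, model_label="AE", seed=0,
                                ci_method=None)
        assert fit.converged
        assert fit.components.a2 == pytest.approx(0.6, abs=0.1)
        assert fit.components.total_sd == pytest.approx(0.5, abs=0.05)
        assert fit.mean.beta_sex == pytest.approx(0.3, abs=0.1)
        assert fit.mean.beta_height == pytest.approx(0.04, abs=0.01)

    def test_zero_resemblance_hits_boundary(self):
        cfg = bt.SimulationConfig(
            n_mz_pairs=500, n_dz_pairs=500,
            continuous_traits=[bt.ContinuousTraitSpec(
                "y", bt.VarianceComponents(e2=1.0, total_sd=1.0))], seed=2)
        cohort, _ = bt.simulate_cohort(cfg, seed=2)
        pairs, _ = bt.assemble_pairs(cohort, "y")
        fit = bt.fit_continuous(pairs, model_label="AE", seed=2,
                                ci_method=None)
        assert fit.components.a2 == pytest.approx(0.0, abs=0.05)

    def test_likelihood_nesting_monotonicity(self, continuous_model_fits):
        f = continuous_model_fits
        assert f["SAT"].loglik >= f["ACE"].loglik - 1e-6
        assert f["SAT"].loglik >= f["ADE"].loglik - 1e-6
        assert f["ACE"].loglik >= f["AE"].loglik - 1e-6
        assert f["ADE"].loglik >= f["AE"].loglik - 1e-6
        assert f["AE"].loglik >= f["E"].loglik - 1e-6
        assert f["CE"].loglik >= f["E"].loglik - 1e-6

    def test_aic_consistent_with_definition(self, continuous_model_fits):
        for fit in continuous_model_fits.values():
            assert fit.aic == pytest.approx(
                2 * fit.n_params - 2 * fit.loglik, abs=1e-9)

    def test_scale_equivariance(self, ae_pairs):
        fit1 = bt.fit_continuous(ae_pairs, model_label="AE", seed=0,
                                 ci_method=None)
        scaled = ae_pairs.subset(np.arange(len(ae_pairs)))
        scaled.y = ae_pairs.y * 3.0
        fit3 = bt.fit_continuous(scaled, model_label="AE", seed=0,
                                 ci_method=None)
        assert fit3.components.a2 == pytest.approx(fit1.components.a2,
                                                   abs=1e-4)
        assert fit3.components.total_sd == pytest.approx(
            3 * fit1.components.total_sd, rel=1e-3)
        assert fit3.implied_r_mz == pytest.approx(fit1.implied_r_mz, abs=1e-4)

    def test_known_sex_shift_moves_beta_not_a2(self, ae_pairs):
        base = bt.fit_continuous(ae_pairs, model_label="AE", seed=0,
                                 ci_method=None)
        shifted = ae_pairs.subset(np.arange(len(ae_pairs)))
        sex = ae_pairs.x[:, :, 0]
        shifted.y = ae_pairs.y + 1.5 * sex
        fit = bt.fit_continuous(shifted, model_label="AE", seed=0,
                                ci_method=None)
        assert fit.mean.beta_sex == pytest.approx(base.mean.beta_sex + 1.5,
                                                  abs=0.02)
        assert fit.components.a2 == pytest.approx(base.components.a2,
                                                  abs=0.02)

    def test_tiny_dataset_matches_grid_oracle(self):
        """On a 6-pair instance the optimizer must find the same maximum as
        an exhaustive (refined) grid search over (a2, sigma, intercept)."""
        y = np.array([[0.5, 0.9], [-0.3, 0.1], [1.2, 0.8],
                      [0.2, -0.4], [-0.9, -0.2], [0.4, 0.6]])
        zyg = np.array(["MZ", "MZ", "MZ", "DZ_same_sex", "DZ_same_sex",
                        "DZ_same_sex"])
        pairs = bt.PairData(y, np.zeros((6, 2, 0)), zyg,
                            np.array([f"p{i}" for i in range(6)]), ())
        fit = bt.fit_continuous(pairs, model_label="AE", seed=0,
                                ci_method=None)
        from oracles import continuous_ae_grid_oracle
        oracle_ll, a_hat, s_hat, m_hat = continuous_ae_grid_oracle(y, zyg)
        assert fit.loglik == pytest.approx(oracle_ll, abs=1e-4)
        assert fit.components.a2 == pytest.approx(a_hat, abs=2e-3)
        assert fit.components.total_sd == pytest.approx(s_hat, abs=2e-3)
        assert fit.mean.intercept == pytest.approx(m_hat, abs=5e-3)

    def test_unknown_model_and_empty_data_errors(self, ae_pairs):
        with pytest.raises(ValueError, match="unknown model"):
            bt.fit_continuous(ae_pairs, model_label="XYZ")
        empty = ae_pairs.subset(np.zeros(len(ae_pairs), dtype=bool))
        with pytest.raises(ValueError, match="no complete pairs"):
            bt.fit_continuous(empty)

    def test_singletons_change_mean_precision_not_structure(self, ae_cohort):
        cohort, _ = ae_cohort
        df = cohort.df.copy()
        df.loc[df.index[:200:2], "y"] = np.nan   # break one member of 100 pairs
        c2 = bt.Cohort(df)
        pairs, singles = bt.assemble_pairs(c2, "y")
        s_arr = bt.singleton_arrays(singles, "y")
        f_no = bt.fit_continuous(pairs, s_arr, model_label="AE",
                                 include_singletons=False, ci_method=None)
        f_yes = bt.fit_continuous(pairs, s_arr, model_label="AE",
                                  include_singletons=True, ci_method=None)
        assert f_yes.n_singletons == len(s_arr[0]) > 0
        assert f_yes.loglik < f_no.loglik      # more data terms
        assert f_yes.components.a2 == pytest.approx(f_no.components.a2,
                                                    abs=0.05)


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

class TestComponentCI:
    def test_delta_e2_reflects_a2_in_ae_model(self, ae_pairs):
        fit = bt.fit_continuous(ae_pairs, model_label="AE", seed=0)
        lo_a, hi_a = fit.ci95["a2"]
        lo_e, hi_e = fit.ci95["e2"]
        assert lo_e == pytest.approx(1 - hi_a, abs=1e-6)
        assert hi_e == pytest.approx(1 - lo_a, abs=1e-6)

    def test_profile_interval_brackets_estimate(self, ae_pairs):
        fit = bt.fit_continuous(ae_pairs, model_label="AE", seed=0,
                                ci_method=None)
        ci = bt.component_ci(fit, method="profile")
        lo, hi = ci["a2"]
        assert lo < fit.components.a2 < hi
        assert hi - lo < 0.4

    def test_bootstrap_degenerate_data_zero_width(self):
        y = np.tile([0.0, 1.0], (8, 1))
        zyg = np.array(["MZ"] * 4 + ["DZ_same_sex"] * 4)
        pairs = bt.PairData(y, np.zeros((8, 2, 0)), zyg,
                            np.array([f"p{i}" for i in range(8)]), ())
        fit = bt.fit_continuous(pairs, model_label="AE", seed=0,
                                ci_method=None)
        ci = bt.component_ci(fit, method="bootstrap", n_boot=20, seed=0)
        lo, hi = ci["a2"]
        assert hi - lo == pytest.approx(0.0, abs=1e-6)
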