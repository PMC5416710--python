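"""Standardization, age-group coding, OLS fits and APOE stratification."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from telomr.cohort_models import (CohortTooSmallError, assign_age_group,
                                  cohort_associations, fit_linear,
                                  stratify_apoe, z_transform)
from telomr.grs import add_grs_column
from telomr.synthetic_data import (Cohort, default_true_params,
                                   simulate_cohort)


def normal_equations(y, X):
    """Independent OLS oracle: explicit (X'X)^-1 X'y with textbook SEs."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se


class TestZTransform:
    def test_three_point_example(self):
        np.testing.assert_allclose(z_transform([1, 2, 3]), [-1, 0, 1],
                                   atol=1e-12)

    def test_output_is_standardized(self):
        rng = np.random.default_rng(0)
        x = 0.68 + 0.15 * rng.normal(size=400)  # raw T/S-like scale
        z = z_transform(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotence(self):
        x = np.random.default_rng(1).normal(2.0, 3.0, 50)
        np.testing.assert_allclose(z_transform(z_transform(x)),
                                   z_transform(x), atol=1e-12)

    def test_missing_passes_through(self):
        z = z_transform([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(z[1]) and not np.isnan(z[[0, 2, 3]]).any()

    def test_constant_vector_errors_with_name(self):
        with pytest.raises(ValueError, match="tl_raw"):
            z_transform([2.0, 2.0, 2.0], name="tl_raw")


class TestAgeGroups:
    @pytest.mark.parametrize("age,code", [
        (0, 1), (14.1, 1), (29.9, 1), (30, 2), (59, 2), (59.9, 2),
        (60, 3), (79.9, 3), (80, 4), (93.3, 4),
    ])
    def test_boundaries(self, age, code):
        assert assign_age_group([age])[0] == code

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            assign_age_group([-1.0])


class TestFitLinear:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        X = sm.add_constant(pd.DataFrame({"x": x}))
        est, _ = fit_linear(x, X)
        assert est.beta == pytest.approx(1.0, abs=1e-12)
        assert est.se <= 1e-12

    def test_hand_computed_three_points(self):
        X = sm.add_constant(pd.DataFrame({"x": [0.0, 1.0, 2.0]}))
        est, _ = fit_linear([0.0, 2.0, 1.0], X)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n, p = int(rng.integers(8, 20)), int(rng.integers(1, 4))
            X = pd.DataFrame(rng.normal(size=(n, p)),
                             columns=[f"x{j}" for j in range(p)])
            X = sm.add_constant(X)
            y = rng.normal(size=n)
            est, table = fit_linear(y, X)
            beta_o, se_o = normal_equations(y, X)
            np.testing.assert_allclose(table["beta"], beta_o, atol=1e-8)
            np.testing.assert_allclose(table["se"], se_o, atol=1e-8)

    def test_listwise_deletion(self):
        X = sm.add_constant(pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, np.nan]}))
        y = [0.0, 1.0, 2.0, np.nan, 4.0]
        est, _ = fit_linear(y, X)
        assert est.n == 3

    def test_constant_adjuster_dropped_not_fatal(self):
        rng = np.random.default_rng(3)
        X = sm.add_constant(pd.DataFrame({"x": rng.normal(size=30),
                                          "female": np.ones(30)}))
        est, table = fit_linear(rng.normal(size=30), X)
        assert "female" not in table.index

    def test_constant_exposure_is_an_error(self):
        X = sm.add_constant(pd.DataFrame({"x": np.ones(10)}))
        with pytest.raises(ValueError, match="x"):
            fit_linear(np.random.default_rng(4).normal(size=10), X)


@pytest.fixture
def apoe_cohort():
    frame = pd.DataFrame({
        "apoe": ["e4/e4", "e3/e4", "e3/e3", "e2/e3", "e2/e2", "e2/e4",
                 np.nan, "e3/e4"],
        "tl_raw": np.linspace(0.8, 1.5, 8),
        "age": np.linspace(40, 75, 8),
        "sex": ["female", "male"] * 4,
    })
    return Cohort("TEST", frame)


class TestStratifyApoe:
    def test_partition(self, apoe_cohort):
        carrier, noncarrier, excluded = stratify_apoe(apoe_cohort)
        assert set(carrier.data["apoe"]) == {"e4/e4", "e3/e4"}
        assert set(noncarrier.data["apoe"]) == {"e3/e3", "e2/e3", "e2/e2"}
        assert excluded == 2  # one e2/e4 + one missing
        assert len(carrier) + len(noncarrier) + excluded == len(apoe_cohort)

    def test_unknown_genotype_rejected(self, apoe_cohort):
        apoe_cohort.data.loc[0, "apoe"] = "e1/e3"
        with pytest.raises(ValueError, match="e1/e3"):
            stratify_apoe(apoe_cohort)


def _scored_cohort(config, snps, truth, seed):
    c = simulate_cohort(config, snps, truth, seed)
    return Cohort(c.name, add_grs_column(c.data, snps), c.covariates)


class TestCohortAssociations:
    def test_null_grs_tl_effect_recovered(self, snps, small_config):
        # zero per-allele effects: the first-stage slope is null
        null_snps = [type(s)(s.rsid, s.gene_label, s.effect_allele,
                             s.other_allele, s.eaf, 0.0) for s in snps]
        truth = default_true_params()
        c = _scored_cohort(small_config(n=3000), null_snps, truth, seed=21)
        est = cohort_associations(c, "GENERAL")["GRS_TL"]
        assert abs(est.beta) < 3 * est.se

    def test_first_stage_recovers_simulation_truth(self, snps, null_truth,
                                                   small_config):
        # calibrate residual noise so Var(TL_std) = 1: the standardized
        # slope then equals beta_tl = -0.05 per allele
        g_var = sum(0.05**2 * 2 * s.eaf * (1 - s.eaf) for s in snps)
        cfg = small_config(n=20000, tl_noise_sd=np.sqrt(1 - g_var))
        c = _scored_cohort(cfg, snps, null_truth, seed=23)
        est = cohort_associations(c, "GENERAL")["GRS_TL"]
        assert abs(est.beta - (-0.05)) < 3 * est.se

    def test_affine_tl_rescaling_leaves_estimates_unchanged(
            self, snps, confounded_null_truth, small_config):
        c = _scored_cohort(small_config(n=800), snps, confounded_null_truth,
                           seed=25)
        base = cohort_associations(c, "GENERAL")
        scaled = Cohort(c.name, c.data.assign(tl_raw=3.1 * c.data["tl_raw"]
                                              + 0.4), c.covariates)
        rescaled = cohort_associations(scaled, "GENERAL")
        for label in base:
            assert rescaled[label].beta == pytest.approx(base[label].beta,
                                                         abs=1e-9)
            assert rescaled[label].se == pytest.approx(base[label].se,
                                                       abs=1e-9)

    def test_stratification_requires_apoe(self, snps, confounded_null_truth,
                                          small_config):
        c = _scored_cohort(small_config(n=200, has_apoe=False), snps,
                           confounded_null_truth, seed=27)
        with pytest.raises(ValueError, match="APOE"):
            cohort_associations(c, "GENERAL", stratum="e4_carrier")

    def test_small_stratum_refused(self, snps, confounded_null_truth,
                                   small_config):
        c = _scored_cohort(small_config(n=40, has_apoe=True), snps,
                           confounded_null_truth, seed=29)
        with pytest.raises(CohortTooSmallError, match="cohort|minimum"):
            cohort_associations(c, "GENERAL", stratum="e4_carrier")

    def test_unavailable_trait_rejected(self, snps, confounded_null_truth,
                                        small_config):
        c = _scored_cohort(small_config(n=100), snps, confounded_null_truth,
                           seed=31)
        with pytest.raises(ValueError, match="MMSE"):
            cohort_associations(c, "MMSE")
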