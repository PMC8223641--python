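"""Per-cohort OLS models: correctness, calibration, degenerate designs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietmeta import association, pipeline, simulate


def _design(rng, n, k):
    X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, k - 1))])
    return X


class TestFitOLS:
    def test_noiseless_fit_recovers_coefficients_exactly(self):
        x = np.arange(5, dtype=float)
        y = 3.0 + 2.0 * x
        fit = association.fit_ols(y, np.column_stack([np.ones(5), x]),
                                  names=["intercept", "x"])
        assert fit.beta == pytest.approx([3.0, 2.0], abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_orthogonal_covariate_leaves_exposure_beta_unchanged(self):
        # x and z orthogonal, z orthogonal to y's x-part
        x = np.array([-1.0, -1.0, 1.0, 1.0, -1.0, 1.0])
        z = np.array([-1.0, 1.0, -1.0, 1.0, 0.0, 0.0])
        y = 1.0 + 0.7 * x
        base = association.fit_ols(
            y, np.column_stack([np.ones(6), x]), ["intercept", "x"])
        extended = association.fit_ols(
            y, np.column_stack([np.ones(6), x, z]), ["intercept", "x", "z"])
        assert extended.coef("x")["beta"] == pytest.approx(
            base.coef("x")["beta"], abs=1e-12)

    def test_matches_normal_equations_oracle_on_random_designs(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 50))
            k = int(rng.integers(2, 7))
            X = _design(rng, n, k)
            y = rng.normal(0, 1, n)
            fit = association.fit_ols(y, X)
            # independent closed-form oracle
            beta = np.linalg.pinv(X.T @ X) @ X.T @ y
            resid = y - X @ beta
            sigma2 = resid @ resid / (n - k)
            se = np.sqrt(np.diag(sigma2 * np.linalg.pinv(X.T @ X)))
            assert np.allclose(fit.beta, beta, rtol=1e-8, atol=1e-10)
            assert np.allclose(fit.se, se, rtol=1e-8, atol=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = _design(rng, 40, 4)
        y = rng.normal(0, 1, 40)
        fit = association.fit_ols(y, X)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(fit.beta, ref.params, rtol=1e-10)
        assert np.allclose(fit.se, ref.bse, rtol=1e-10)
        assert np.allclose(fit.p, ref.pvalues, rtol=1e-8)

    def test_rank_deficiency_names_columns(self):
        x = np.arange(6, dtype=float)
        X = np.column_stack([np.ones(6), x, 2 * x])
        with pytest.raises(association.RankDeficientError, match="collinear"):
            association.fit_ols(np.ones(6), X, ["intercept", "x", "2x"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(association.AssociationError, match="n = 2"):
            association.fit_ols(np.ones(2), np.ones((2, 3)))

    def test_null_p_values_uniform(self, rng):
        pvals = []
        for _ in range(400):
            X = _design(rng, 30, 3)
            y = rng.normal(0, 1, 30)
            pvals.append(association.fit_ols(y, X).p[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.statistic < stats.ksone.ppf(0.99, 400)


def _cohort_data(rng, n=80, cohort="HC", beta=0.0):
    x = rng.normal(0, 1, n)
    covs = pd.DataFrame({"age": rng.normal(45, 10, n),
                         "sex": rng.integers(0, 2, n).astype(float)},
                        index=[f"s{i}" for i in range(n)])
    y = beta * x + 0.1 * (covs["age"] - 45) / 10 + rng.normal(0, 1, n)
    return association.CohortData(
        cohort=cohort,
        exposures=pd.DataFrame({"food": x}, index=covs.index),
        features={"taxa": pd.DataFrame({"bug": y}, index=covs.index)},
        covariates=covs)


class TestAssociate:
    def test_subject_order_invariance(self, rng):
        data = _cohort_data(rng, beta=0.4)
        rec = association.associate(
            data.exposures["food"], data.features["taxa"]["bug"],
            data.covariates, "HC", "taxa")
        perm = rng.permutation(data.covariates.index)
        rec2 = association.associate(
            data.exposures["food"].loc[perm],
            data.features["taxa"]["bug"].loc[perm],
            data.covariates.loc[perm], "HC", "taxa")
        assert rec["beta"] == pytest.approx(rec2["beta"], abs=1e-12)
        assert rec["p"] == pytest.approx(rec2["p"], abs=1e-12)

    def test_constant_exposure_flagged_unusable(self, rng):
        data = _cohort_data(rng)
        data.exposures["food"] = 1.0
        rec = association.associate(
            data.exposures["food"], data.features["taxa"]["bug"],
            data.covariates, "HC", "taxa")
        assert not rec["usable"]
        assert "constant" in rec["reason"]

    def test_min_complete_cases_enforced(self, rng):
        data = _cohort_data(rng, n=10)
        rec = association.associate(
            data.exposures["food"], data.features["taxa"]["bug"],
            data.covariates, "HC", "taxa", min_n=20)
        assert not rec["usable"]
        assert "complete cases" in rec["reason"]

    def test_batched_path_equals_single_fits(self, rng):
        n = 60
        covs = pd.DataFrame({"age": rng.normal(0, 1, n)},
                            index=[f"s{i}" for i in range(n)])
        exposures = pd.DataFrame(rng.normal(0, 1, (n, 3)),
                                 index=covs.index, columns=list("abc"))
        features = pd.DataFrame(rng.normal(0, 1, (n, 4)),
                                index=covs.index, columns=list("wxyz"))
        features.iloc[3, 2] = np.nan  # force one feature down the slow path
        data = association.CohortData(cohort="CD", exposures=exposures,
                                      features={"taxa": features},
                                      covariates=covs)
        table = association.associate_cohort(data, "taxa", ("age",))
        for _, row in table.iterrows():
            single = association.associate(
                exposures[row["exposure"]], features[row["response"]],
                covs, "CD", "taxa")
            assert row["beta"] == pytest.approx(single["beta"], abs=1e-10)
            assert row["p"] == pytest.approx(single["p"], abs=1e-10)

    def test_planted_effect_recovered_within_3_se(self):
        config = simulate.SimulationConfig(
            n_per_cohort=(400, 200, 200, 120), n_foods=6, n_food_blocks=3,
            n_taxa=8, n_pathways=12,
            planted_effects=(simulate.PlantedEffect(
                food=2, feature=4, kind="pathway", beta=0.5),),
            seed=77)
        result = pipeline.run_pipeline(
            pipeline.PipelineConfig(simulation=config, seed=77))
        planted = result.dataset.truth.iloc[0]
        row = result.meta[
            (result.meta["exposure"] == planted["exposure_name"])
            & (result.meta["response"] == planted["feature_name"])].iloc[0]
        assert abs(row["beta_meta"] - 0.5) < 3 * row["se_meta"]
        # every cohort estimate should individually bracket the truth too
        per_cohort = result.associations[
            (result.associations["exposure"] == planted["exposure_name"])
            & (result.associations["response"] == planted["feature_name"])]
        assert (abs(per_cohort["beta"] - 0.5) < 4 * per_cohort["se"]).all()


class TestSensitivityRefit:
    def _cohorts(self, rng, confounded=False):
        cohorts = {}
        for c, n in [("HC", 150), ("IBS", 90), ("CD", 90), ("UC", 70)]:
            bmi = rng.normal(25, 4, n)
            x = rng.normal(0, 1, n) + (0.9 * (bmi - 25) / 4 if confounded
                                       else 0.0)
            covs = pd.DataFrame(
                {"age": rng.normal(45, 12, n),
                 "sex": rng.integers(0, 2, n).astype(float),
                 "bmi": bmi,
                 "smoking": rng.integers(0, 2, n).astype(float),
                 "antihypertensives": rng.integers(0, 2, n).astype(float),
                 "antidiabetics": rng.integers(0, 2, n).astype(float),
                 "statins": rng.integers(0, 2, n).astype(float)},
                index=[f"{c}{i}" for i in range(n)])
            y = (0.6 * (bmi - 25) / 4 if confounded else 0.6 * x) \
                + rng.normal(0, 1, n)
            cohorts[c] = association.CohortData(
                cohort=c,
                exposures=pd.DataFrame({"food": x}, index=covs.index),
                features={"taxa": pd.DataFrame({"bug": y}, index=covs.index)},
                covariates=covs)
        return cohorts

    def _significant(self, cohorts):
        from dietmeta import meta as meta_mod

        assoc = association.associate_all(cohorts, [("taxa", ("age", "sex"))])
        pooled = meta_mod.meta_analyze(assoc)
        return pooled[pooled["fdr"] < 0.05]

    def test_independent_extra_covariates_replicate(self, rng):
        cohorts = self._cohorts(rng, confounded=False)
        sig = self._significant(cohorts)
        assert len(sig) == 1
        table = association.sensitivity_refit(
            sig, cohorts, {"taxa": ("age", "sex")})
        assert table.attrs["replication_fraction"] == 1.0

    def test_bmi_confounded_effect_drops_out(self, rng):
        cohorts = self._cohorts(rng, confounded=True)
        sig = self._significant(cohorts)
        assert len(sig) == 1  # confounding makes it "significant" at first
        table = association.sensitivity_refit(
            sig, cohorts, {"taxa": ("age", "sex")})
        assert table.attrs["replication_fraction"] == 0.0

    def test_empty_significant_set(self, rng):
        cohorts = self._cohorts(rng)
        empty = self._significant(cohorts).iloc[0:0]
        table = association.sensitivity_refit(
            empty, cohorts, {"taxa": ("age", "sex")})
        assert len(table) == 0
        assert np.isnan(table.attrs["replication_fraction"])

    def test_missing_covariates_rejected(self, rng):
        cohorts = self._cohorts(rng)
        for c in cohorts.values():
            c.covariates.drop(columns=["statins"], inplace=True)
        with pytest.raises(association.AssociationError, match="statins"):
            association.sensitivity_refit(
                self._significant(cohorts), cohorts, {"taxa": ("age", "sex")})
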