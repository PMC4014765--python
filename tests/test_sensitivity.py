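import numpy as np
import pandas as pd
import pytest

from mixshrink.cohort import covariate_design, generate_cohort
from mixshrink.preprocess import preprocess_panel
from mixshrink.sensitivity import (
    ipw_weights,
    run_sensitivity_suite,
    sex_interaction,
    single_pollutant_fits,
)
from mixshrink.first_stage import fit_repeated_model

from conftest import small_config


def two_visit_outcomes(lp, rng, sigma=2.0, rho=0.5):
    n = len(lp)
    b = rng.normal(0, sigma * np.sqrt(rho), n)
    rows = []
    for age in (4, 5):
        rows.append(
            pd.DataFrame(
                {"subject_id": np.arange(n), "age": age,
                 "score": lp + b + rng.normal(0, sigma * np.sqrt(1 - rho), n)}
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestIpwWeights:
    def test_independent_completion_weights_near_one(self, rng):
        n = 4000
        baseline = pd.DataFrame({"z": rng.normal(size=n)}, index=pd.RangeIndex(n, name="subject_id"))
        completed = pd.Series(rng.random(n) < 0.6, index=baseline.index)
        w = ipw_weights(baseline, completed)
        assert w.mean() == pytest.approx(1.0, abs=0.01)
        assert np.abs(w - 1.0).max() < 0.15

    def test_all_complete_weights_exactly_one(self, rng):
        n = 50
        baseline = pd.DataFrame({"z": rng.normal(size=n)}, index=pd.RangeIndex(n))
        completed = pd.Series(True, index=baseline.index)
        w = ipw_weights(baseline, completed)
        assert (w == 1.0).all()

    def test_reweighting_restores_covariate_mean(self, rng):
        n = 6000
        z = rng.normal(size=n)
        p = 1.0 / (1.0 + np.exp(-(0.3 + 1.2 * z)))
        completed = pd.Series(rng.random(n) < p, index=pd.RangeIndex(n))
        baseline = pd.DataFrame({"z": z}, index=completed.index)
        w = ipw_weights(baseline, completed)
        naive = z[completed.to_numpy()].mean()
        weighted = np.average(z[completed.to_numpy()], weights=w.to_numpy())
        assert abs(naive) > 0.15  # attrition shifts the mean
        assert abs(weighted) < 0.05  # reweighting restores it

    def test_probability_floor_triggers(self, rng):
        n = 2000
        z = rng.normal(size=n)
        p = 1.0 / (1.0 + np.exp(-(0.5 + 2.0 * z)))
        completed = pd.Series(rng.random(n) < p, index=pd.RangeIndex(n))
        baseline = pd.DataFrame({"z": z}, index=completed.index)
        with pytest.raises(ValueError, match="floor"):
            ipw_weights(baseline, completed, probability_floor=0.5)

    def test_no_completers_fails(self, rng):
        baseline = pd.DataFrame({"z": rng.normal(size=20)}, index=pd.RangeIndex(20))
        with pytest.raises(ValueError):
            ipw_weights(baseline, pd.Series(False, index=baseline.index))


class TestIpwBiasRemoval:
    def test_collider_selection_bias_reduced(self):
        # outcome depends on u (omitted from analysis); completion depends on
        # both u and exposure, inducing complete-case bias that IPW removes
        reps, n, true_beta = 60, 500, 2.0
        bias_naive, bias_ipw = [], []
        for r in range(reps):
            rng = np.random.default_rng(9000 + r)
            x = rng.normal(size=n)
            u = rng.normal(size=n)
            lp = 50 + true_beta * x + 4.0 * u
            out = two_visit_outcomes(lp, rng)
            logit = 0.5 + 1.5 * u + 1.5 * x
            completed = pd.Series(
                rng.random(n) < 1 / (1 + np.exp(-logit)), index=pd.RangeIndex(n)
            )
            keep = out["subject_id"].map(completed).to_numpy(dtype=bool)
            out_cc = out[keep]
            xdf = pd.DataFrame({"x": x}, index=pd.RangeIndex(n, name="subject_id"))
            baseline = pd.DataFrame({"u": u, "x": x}, index=xdf.index)
            w = ipw_weights(baseline, completed)
            naive = fit_repeated_model(out_cc, xdf)
            weighted = fit_repeated_model(out_cc, xdf, weights=w)
            bias_naive.append(naive.beta["x"] - true_beta)
            bias_ipw.append(weighted.beta["x"] - true_beta)
        assert abs(np.mean(bias_naive)) > 0.15  # selection really biases
        assert abs(np.mean(bias_ipw)) < abs(np.mean(bias_naive)) / 2


@pytest.fixture(scope="module")
def suite():
    cohort = generate_cohort(small_config(seed=55, n=300, true_betas={"S0": 3.0}))
    processed = preprocess_panel(cohort.panel)
    return run_sensitivity_suite(
        cohort.outcomes, processed, cohort.covariates, completed=cohort.completed
    )


class TestSensitivitySuite:

    def test_all_scenarios_present(self, suite):
        assert set(suite.table["scenario"]) == {
            "main", "tau2_small", "empirical_bayes", "ipw", "single_pollutant",
        }

    def test_identical_chemical_lists(self, suite):
        lists = suite.table.groupby("scenario")["chemical"].apply(lambda s: sorted(s))
        first = lists.iloc[0]
        assert all(l == first for l in lists)

    def test_smaller_tau2_shrinks_harder(self, suite):
        main = suite.scenario("main")
        small = suite.scenario("tau2_small")
        assert small["tau2"].iloc[0] < main["tau2"].iloc[0]
        # stronger shrinkage compresses the coefficient spread
        assert small["beta"].std() <= main["beta"].std() + 1e-12
        assert (small["se"] <= main["se"] + 1e-12).all()

    def test_no_dropout_ipw_equals_main_first_stage(self):
        cohort = generate_cohort(small_config(seed=56, n=250))
        assert cohort.completed.all()
        processed = preprocess_panel(cohort.panel)
        report = run_sensitivity_suite(
            cohort.outcomes, processed, cohort.covariates,
            completed=cohort.completed, scenarios=("main", "ipw"),
        )
        main = report.scenario("main").sort_index()
        ipw = report.scenario("ipw").sort_index()
        assert np.allclose(main["beta"], ipw["beta"])
        assert np.allclose(main["se"], ipw["se"])

    def test_null_cohort_scenarios_centered(self):
        reps = 25
        means = {s: [] for s in ("main", "tau2_small", "single_pollutant")}
        for r in range(reps):
            cohort = generate_cohort(small_config(seed=700 + r, n=150))
            processed = preprocess_panel(cohort.panel)
            rep = run_sensitivity_suite(
                cohort.outcomes, processed, cohort.covariates,
                scenarios=("main", "tau2_small", "single_pollutant"),
            )
            for s in means:
                means[s].append(rep.scenario(s)["beta"].mean())
        for s, vals in means.items():
            mc_se = np.std(vals, ddof=1) / np.sqrt(reps)
            assert abs(np.mean(vals)) < 4 * mc_se + 0.05, s


class TestSinglePollutant:
    def test_masked_chemical_uses_maximal_sample(self, rng):
        cohort = generate_cohort(small_config(seed=58, n=200))
        processed = preprocess_panel(cohort.panel)
        coded = processed.data.copy()
        coded.loc[coded.index[:50], "S0"] = np.nan
        sp = single_pollutant_fits(cohort.outcomes, coded, cohort.covariates)
        sp = sp.set_index("chemical")
        assert sp.loc["S0", "n_obs"] < sp.loc["S1", "n_obs"]

    def test_copollutant_confounding_demonstrated(self):
        # high within-class correlation: the single-pollutant model attributes
        # S0's effect to its correlated neighbour; the mixture model does not
        mix_s1, single_s1 = [], []
        for r in range(12):
            cfg = small_config(
                seed=5900 + r, n=1000, true_betas={"S0": 3.0},
                within_class_correlation=0.9, cross_class_correlation=0.0,
            )
            cohort = generate_cohort(cfg)
            processed = preprocess_panel(cohort.panel)
            mixture = fit_repeated_model(cohort.outcomes, processed.data, cohort.covariates)
            sp = single_pollutant_fits(
                cohort.outcomes, processed.data, cohort.covariates
            ).set_index("chemical")
            mix_s1.append(float(mixture.beta["S1"]))
            single_s1.append(float(sp.loc["S1", "beta"]))
        assert abs(np.mean(mix_s1)) < 1.0  # mixture model: no S1 effect
        assert np.mean(single_s1) > 1.5  # single-pollutant: confounded upward
        assert np.mean(single_s1) > np.mean(mix_s1) + 1.0

    def test_independent_exposures_single_matches_mixture(self):
        cfg = small_config(
            seed=60, n=2500, true_betas={"S0": 3.0},
            within_class_correlation=0.0, cross_class_correlation=0.0,
        )
        cohort = generate_cohort(cfg)
        processed = preprocess_panel(cohort.panel)
        mixture = fit_repeated_model(cohort.outcomes, processed.data, cohort.covariates)
        sp = single_pollutant_fits(cohort.outcomes, processed.data, cohort.covariates).set_index("chemical")
        for chem in processed.data.columns:
            assert sp.loc[chem, "beta"] == pytest.approx(mixture.beta[chem], abs=0.35)


class TestSexInteraction:
    def _sexed_cohort(self, seed, n, girl_effect, boy_effect):
        cfg = small_config(seed=seed, n=n)
        cohort = generate_cohort(cfg)
        processed = preprocess_panel(cohort.panel)
        coded = processed.data
        rng = np.random.default_rng(seed + 1)
        girl = (cohort.covariates["child_sex"] == "girl").to_numpy(dtype=float)
        slope = np.where(girl == 1.0, girl_effect, boy_effect)
        lp = 50.0 + slope * coded["S0"].to_numpy()
        outcomes = two_visit_outcomes(lp, rng, sigma=4.0)
        return outcomes, coded, cohort.covariates

    def test_recovers_sex_specific_effects(self):
        outcomes, coded, cov = self._sexed_cohort(61, 4000, girl_effect=5.6, boy_effect=0.3)
        res = sex_interaction(outcomes, coded, cov, "S0")
        assert res.beta_girls == pytest.approx(5.6, abs=0.5)
        assert res.beta_boys == pytest.approx(0.3, abs=0.5)
        assert res.interaction_p < 0.01
        assert res.display

    def test_label_swap_symmetry(self):
        outcomes, coded, cov = self._sexed_cohort(62, 800, girl_effect=3.0, boy_effect=-1.0)
        a = sex_interaction(outcomes, coded, cov, "S0", girl_level="girl")
        b = sex_interaction(outcomes, coded, cov, "S0", girl_level="boy")
        assert a.beta_girls == pytest.approx(b.beta_boys, rel=1e-9)
        assert a.beta_boys == pytest.approx(b.beta_girls, rel=1e-9)
        assert a.interaction_p == pytest.approx(b.interaction_p, rel=1e-6)

    def test_single_sex_fails(self):
        outcomes, coded, cov = self._sexed_cohort(63, 200, 1.0, 1.0)
        cov = cov.copy()
        cov["child_sex"] = pd.Categorical(["girl"] * len(cov), categories=["boy", "girl"])
        with pytest.raises(ValueError, match="both sexes"):
            sex_interaction(outcomes, coded, cov, "S0")

    def test_null_interaction_type1_error(self):
        reps = 120
        pvals = []
        for r in range(reps):
            outcomes, coded, cov = self._sexed_cohort(8000 + r, 150, 2.0, 2.0)
            pvals.append(sex_interaction(outcomes, coded, cov, "S0").interaction_p)
        pvals = np.asarray(pvals)
        frac = (pvals < 0.10).mean()
        # binomial 99.7% band around 0.10 at 120 replicates
        assert abs(frac - 0.10) < 3 * np.sqrt(0.1 * 0.9 / reps) + 0.01
        assert pvals.min() >= 0 and pvals.max() <= 1
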