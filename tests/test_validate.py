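"""Cox comparison, association regressions, subtype contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from substage import (ConfigurationError, cox_compare, default_study_config,
                      generate_cohort, logistic_association, nested_linear,
                      subtype_contrasts)
from substage.cohort import HazardSpec


def _survival(seed=0, n_mci=2000, **hazard_kwargs):
    hz = HazardSpec(**hazard_kwargs) if hazard_kwargs else HazardSpec()
    cfg = default_study_config().replace(
        seed=seed, n_cn=10, n_ad=10, n_mci=n_mci, hazard=hz)
    return generate_cohort(cfg)[2]


def _null_frame(rng, n):
    return pd.DataFrame({
        "age": rng.normal(73, 7, n),
        "gender": rng.integers(0, 2, n),
        "education": rng.normal(16, 2.5, n),
        "apoe4": rng.integers(0, 3, n),
    })


class TestCoxCompare:
    def test_full_model_beats_base_on_planted_hazards(self):
        for seed in range(1, 6):
            comp = cox_compare(_survival(seed=seed))
            assert comp.full.concordance_index > comp.base.concordance_index
            assert comp.full.aic < comp.base.aic

    def test_planted_stage_hazard_recovered_within_ci(self):
        comp = cox_compare(_survival(seed=11))
        row = comp.full.hazard_ratios.set_index("term").loc["stage"]
        assert row["ci_low"] < 1.77 < row["ci_high"]
        assert comp.logrank_stage_p < 1e-6

    def test_permuted_stage_gives_no_concordance_gain(self):
        surv = _survival(seed=12)
        rng = np.random.default_rng(0)
        surv["stage"] = rng.permutation(surv["stage"].to_numpy())
        surv["subtype"] = rng.permutation(surv["subtype"].to_numpy())
        comp = cox_compare(surv)
        gain = comp.full.concordance_index - comp.base.concordance_index
        assert abs(gain) < 0.02

    def test_covariate_independent_hazard_has_chance_concordance(self):
        surv = _survival(seed=13, baseline_rate=0.006, stage_log_hr=0.0,
                         subtype_log_hr=(0.0,) * 4, age_log_hr=0.0,
                         gender_log_hr=0.0, education_log_hr=0.0,
                         apoe4_log_hr=0.0)
        comp = cox_compare(surv)
        assert abs(comp.base.concordance_index - 0.5) < 0.03

    def test_one_hot_reference_is_most_prevalent_subtype(self):
        comp = cox_compare(_survival(seed=14))
        terms = set(comp.full.hazard_ratios["term"])
        assert "subtype_1" not in terms           # subtype 1 is most prevalent
        assert {"subtype_2", "subtype_3", "subtype_4"} <= terms
        hr = comp.full.hazard_ratios
        assert ((hr["ci_low"] <= hr["hr"]) & (hr["hr"] <= hr["ci_high"])).all()

    def test_too_few_events_rejected(self):
        surv = _survival(seed=15, n_mci=200)
        surv["event"] = 0
        with pytest.raises(ConfigurationError, match="events"):
            cox_compare(surv)


class TestNestedLinear:
    def test_exact_linear_outcome_gives_unit_r2(self):
        rng = np.random.default_rng(1)
        n = 300
        cov = _null_frame(rng, n)
        stage = pd.Series(rng.integers(0, 6, n))
        subtype = pd.Series(rng.integers(1, 5, n))
        rep = nested_linear(2.0 * stage, cov, stage, subtype)
        assert rep.r2_ladder["base+stage"] == pytest.approx(1.0)
        assert rep.beta_stage == pytest.approx(2.0)

    def test_planted_negative_slope_recovered(self):
        """A stage effect on the scale of delayed-recall decline is
        recovered within its 95% confidence interval."""
        rng = np.random.default_rng(2)
        n = 600
        cov = _null_frame(rng, n)
        stage = pd.Series(rng.integers(0, 6, n))
        subtype = pd.Series(rng.integers(1, 5, n))
        y = 10 - 0.8 * stage + 0.1 * cov["education"] + rng.normal(0, 1, n)
        rep = nested_linear(y, cov, stage, subtype)
        assert abs(rep.beta_stage + 0.8) < 1.96 * rep.beta_stage_se
        assert rep.overall_p < 1e-6
        ladder = list(rep.r2_ladder.values())
        assert ladder[1] > ladder[0]

    def test_null_stage_pvalues_are_uniform(self):
        """Type-I calibration: with no stage effect the stage p-value is
        Uniform(0, 1) across simulations."""
        rng = np.random.default_rng(3)
        pvals = []
        n = 150
        for _ in range(200):
            cov = _null_frame(rng, n)
            stage = pd.Series(rng.integers(0, 6, n))
            subtype = pd.Series(rng.integers(1, 5, n))
            y = pd.Series(rng.normal(size=n))
            pvals.append(nested_linear(y, cov, stage, subtype).beta_stage_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_r2_ladder_nondecreasing_with_planted_effects(self):
        rng = np.random.default_rng(4)
        ladders = []
        for _ in range(50):
            n = 240
            cov = _null_frame(rng, n)
            stage = pd.Series(rng.integers(0, 6, n))
            subtype = pd.Series(rng.integers(1, 5, n))
            y = (-0.5 * stage + 0.8 * (subtype == 2) - 0.4 * (subtype == 4)
                 + rng.normal(0, 1.5, n))
            ladders.append(list(nested_linear(y, cov, stage, subtype)
                                .r2_ladder.values()))
        mean = np.mean(ladders, axis=0)
        assert mean[0] <= mean[1] <= mean[2]

    def test_collinear_design_rejected_with_names(self):
        rng = np.random.default_rng(5)
        n = 100
        cov = _null_frame(rng, n)
        cov["education"] = 2 * cov["age"]  # exactly collinear pair
        stage = pd.Series(rng.integers(0, 6, n))
        subtype = pd.Series(rng.integers(1, 5, n))
        with pytest.raises(ConfigurationError, match="education"):
            nested_linear(pd.Series(rng.normal(size=n)), cov, stage, subtype)


class TestLogisticAssociation:
    def test_planted_logistic_slope_recovered(self):
        """A per-stage log-odds decline on the pentagon-copy scale is
        recovered within its 95% confidence interval."""
        rng = np.random.default_rng(6)
        n = 1000
        cov = _null_frame(rng, n)
        stage = pd.Series(rng.integers(0, 6, n))
        subtype = pd.Series(rng.integers(1, 5, n))
        eta = 1.5 - 0.33 * stage
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-eta))))
        rep = logistic_association(y, cov, stage, subtype)
        assert abs(rep.beta_stage + 0.33) < 1.96 * rep.beta_stage_se
        assert rep.overall_p < 0.01

    def test_null_likelihood_ratio_calibrated(self):
        rng = np.random.default_rng(7)
        n = 200
        nonsig = 0
        for _ in range(100):
            cov = _null_frame(rng, n)
            stage = pd.Series(rng.integers(0, 6, n))
            subtype = pd.Series(rng.integers(1, 5, n))
            y = pd.Series(rng.binomial(1, 0.4, n))
            rep = logistic_association(y, cov, stage, subtype)
            nonsig += rep.overall_p > 0.05
        assert nonsig >= 90

    def test_single_class_outcome_rejected(self):
        rng = np.random.default_rng(8)
        n = 50
        cov = _null_frame(rng, n)
        with pytest.raises(ConfigurationError, match="both classes"):
            logistic_association(pd.Series(np.ones(n)), cov,
                                 pd.Series(rng.integers(0, 6, n)),
                                 pd.Series(rng.integers(1, 5, n)))

    def test_perfect_separation_flagged_not_raised(self):
        rng = np.random.default_rng(9)
        n = 120
        cov = _null_frame(rng, n)
        stage = pd.Series(rng.integers(0, 6, n))
        subtype = pd.Series(rng.integers(1, 5, n))
        y = (stage >= 3).astype(float)  # outcome determined by stage
        rep = logistic_association(y, cov, stage, subtype)
        assert rep.notes and "non-estimable" in rep.notes[0]
        assert np.isnan(rep.beta_stage)


class TestSubtypeContrasts:
    def _data(self, rng, n_per=100, shift=None):
        n = 4 * n_per
        cov = _null_frame(rng, n)
        stage = pd.Series(rng.integers(0, 6, n))
        subtype = pd.Series(np.repeat([1, 2, 3, 4], n_per))
        y = pd.Series(0.3 * stage.to_numpy() + rng.normal(size=n))
        if shift:
            y = y + shift * (subtype == 1).to_numpy()
        return y, subtype, cov, stage

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(10)
        clean = 0
        for _ in range(200):
            y, subtype, cov, stage = self._data(rng, n_per=40)
            table = subtype_contrasts(y, subtype, cov, stage)
            clean += (table["p_adjusted"] > 0.05).all()
        assert clean >= 0.95 * 200 - 2 * np.sqrt(200 * 0.05 * 0.95)

    def test_shifted_subtype_detected(self):
        rng = np.random.default_rng(11)
        y, subtype, cov, stage = self._data(rng, n_per=100, shift=3.0)
        table = subtype_contrasts(y, subtype, cov, stage).set_index("pair")
        for pair in ("1-2", "1-3", "1-4"):
            assert table.loc[pair, "p_adjusted"] < 1e-4
        assert len(table) == 6

    def test_single_pair_adjustment_is_identity(self):
        rng = np.random.default_rng(12)
        n = 120
        cov = _null_frame(rng, n)
        stage = pd.Series(rng.integers(0, 6, n))
        subtype = pd.Series(np.repeat([1, 2], 60))
        y = pd.Series(rng.normal(size=n))
        table = subtype_contrasts(y, subtype, cov, stage)
        assert len(table) == 1
        assert table["p_adjusted"].iloc[0] == pytest.approx(
            table["p_raw"].iloc[0])

    def test_adjusted_p_monotone_in_raw_p(self):
        rng = np.random.default_rng(13)
        y, subtype, cov, stage = self._data(rng, n_per=50, shift=0.5)
        table = subtype_contrasts(y, subtype, cov, stage)
        ordered = table.sort_values("p_raw")
        assert (ordered["p_adjusted"].diff().dropna() >= -1e-12).all()
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-12).all()

    def test_undersized_group_skipped_with_log(self):
        rng = np.random.default_rng(14)
        n = 91
        cov = _null_frame(rng, n)
        stage = pd.Series(rng.integers(0, 6, n))
        subtype = pd.Series(np.concatenate([np.repeat([1, 2, 3], 30), [4]]))
        y = pd.Series(rng.normal(size=n))
        table = subtype_contrasts(y, subtype, cov, stage)
        assert len(table) == 3
        assert set(table.attrs["skipped"]) == {(1, 4), (2, 4), (3, 4)}
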