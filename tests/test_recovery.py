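"""Hemoglobin recovery model: predictor, threshold probability, interval solver, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import donorsim as ds
from donorsim.config import ConfigurationError
from donorsim.population import generate_two_visit_dataset
from donorsim.recovery import linear_predictor_frame

from conftest import make_donor, random_donor


class TestLinearPredictor:
    def test_matches_hand_dot_product(self, female_model, example_donor):
        # independent arithmetic: intercept + 0.6*134 + 0.05*40 + eth + bg + slope*t
        expected = (
            female_model.intercept
            + female_model.coef_index_hb * 134.0
            + female_model.coef_age * 40.0
            + female_model.ethnicity_effects["White"]
            + female_model.blood_group_effects["O+"]
            + female_model.slope * 10.0
        )
        assert ds.linear_predictor(female_model, example_donor, 10.0) == pytest.approx(expected, abs=1e-12)

    def test_zero_slope_constant_in_time(self, female_model, example_donor):
        model = female_model.replace(slope=0.0)
        vals = {ds.linear_predictor(model, example_donor, t) for t in (0, 5, 30, 52)}
        assert len(vals) == 1

    def test_linearity_in_time(self, female_model, example_donor):
        model = female_model.replace(slope=0.4)
        d = ds.linear_predictor(model, example_donor, 10.0) - ds.linear_predictor(model, example_donor, 0.0)
        assert d == pytest.approx(4.0, abs=1e-12)

    def test_unknown_category_rejected(self, female_model):
        donor = make_donor(ethnicity="Martian")
        with pytest.raises(ConfigurationError):
            ds.linear_predictor(female_model, donor, 0.0)

    def test_negative_time_rejected(self, female_model, example_donor):
        with pytest.raises(ValueError):
            ds.linear_predictor(female_model, example_donor, -1.0)

    def test_frame_version_agrees_scalar(self, female_model, female_pop_small):
        mu = linear_predictor_frame(female_model, female_pop_small, 12.0)
        for i in (0, 7, 123):
            donor = female_pop_small.iloc[i]
            assert mu[i] == pytest.approx(ds.linear_predictor(female_model, donor, 12.0))


class TestProbOverThreshold:
    def test_half_at_threshold(self, female_model, example_donor):
        mu = ds.linear_predictor(female_model, example_donor, 16.0)
        assert ds.prob_over_threshold(female_model, example_donor, 16.0, mu) == pytest.approx(0.5)

    def test_normal_cdf_oracle_one_sigma(self, female_model, example_donor):
        mu = ds.linear_predictor(female_model, example_donor, 16.0)
        thr = mu - female_model.predictive_sd  # mu = threshold + sigma
        p = ds.prob_over_threshold(female_model, example_donor, 16.0, thr)
        assert p == pytest.approx(norm.cdf(1.0), abs=1e-12)
        assert p == pytest.approx(0.8413, abs=5e-5)

    def test_far_tail(self, female_model, example_donor):
        mu = ds.linear_predictor(female_model, example_donor, 16.0)
        thr = mu - 5 * female_model.predictive_sd
        assert ds.prob_over_threshold(female_model, example_donor, 16.0, thr) > 0.999

    def test_degenerate_sigma_step_function(self, female_model, example_donor):
        model = female_model.replace(latent_sd=0.0, residual_sd=0.0)
        mu = ds.linear_predictor(model, example_donor, 0.0)
        assert ds.prob_over_threshold(model, example_donor, 0.0, mu) == 1.0
        assert ds.prob_over_threshold(model, example_donor, 0.0, mu + 1e-9) == 0.0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        t1=st.floats(0, 40), dt=st.floats(0, 20),
        hb=st.floats(100, 170), dhb=st.floats(0, 30),
        thr=st.floats(110, 150), dthr=st.floats(0, 20),
    )
    def test_monotonicity_properties(self, female_model, t1, dt, hb, dhb, thr, dthr):
        """Non-decreasing in time (slope>=0) and last Hb; non-increasing in threshold."""
        donor = make_donor(index_hb=hb)
        p = ds.prob_over_threshold(female_model, donor, t1, thr)
        assert ds.prob_over_threshold(female_model, donor, t1 + dt, thr) >= p - 1e-12
        assert ds.prob_over_threshold(female_model, donor, t1, thr, last_hb=hb + dhb) >= p - 1e-12
        assert ds.prob_over_threshold(female_model, donor, t1, thr + dthr) <= p + 1e-12
        assert 0.0 <= p <= 1.0


class TestPersonalizedInterval:
    def test_floor_when_already_certain(self, female_model):
        # a high-Hb woman meets either certainty level at the 16-week floor
        donor = make_donor(index_hb=165.0)
        for p_min in (0.7, 0.9):
            assert ds.prob_over_threshold(female_model, donor, 16, 125.0) >= p_min
            res = ds.personalized_interval(female_model, donor, 125.0, p_min, 16, 52)
            assert res == (16, False)

    def test_zero_slope_never_crossing_capped(self, female_model):
        model = female_model.replace(slope=0.0)
        donor = make_donor(index_hb=110.0)
        res = ds.personalized_interval(model, donor, 125.0, 0.9, 16, 52)
        assert res.weeks == 52 and res.capped

    def test_certainty_ordering(self, female_model):
        # higher required certainty never shortens the interval
        rng = np.random.default_rng(2)
        for _ in range(100):
            donor = random_donor(rng)
            w07 = ds.personalized_interval(female_model, donor, 125.0, 0.7, 16, 52).weeks
            w09 = ds.personalized_interval(female_model, donor, 125.0, 0.9, 16, 52).weeks
            assert w09 >= w07

    def test_non_increasing_in_last_hb(self, female_model):
        donor = make_donor()
        weeks = [
            ds.personalized_interval(female_model, donor, 125.0, 0.9, 12, 52, last_hb=h).weeks
            for h in (110, 120, 130, 140, 150)
        ]
        assert weeks == sorted(weeks, reverse=True)

    def test_closed_form_equals_brute_force_scan(self, female_model, male_model):
        """Closed-form inversion agrees exactly with a week-by-week scan."""
        rng = np.random.default_rng(77)
        for i in range(1000):
            sex = "female" if i % 2 == 0 else "male"
            model = female_model if sex == "female" else male_model
            thr = 125.0 if sex == "female" else 135.0
            donor = random_donor(rng, sex)
            p_min = float(rng.uniform(0.55, 0.99))
            t_min = int(rng.choice([8, 12, 16]))
            res = ds.personalized_interval(model, donor, thr, p_min, t_min, 52)
            scan = next(
                (t for t in range(t_min, 53)
                 if ds.prob_over_threshold(model, donor, t, thr) >= p_min),
                None,
            )
            assert res.weeks == (scan if scan is not None else 52)
            assert res.capped == (scan is None)

    def test_invalid_inputs(self, female_model, example_donor):
        with pytest.raises(ValueError):
            ds.personalized_interval(female_model, example_donor, 125.0, 1.0, 16, 52)
        with pytest.raises(ValueError):
            ds.personalized_interval(female_model, example_donor, 125.0, 0.9, 20, 10)


class TestSimulateTrueHb:
    def test_noiseless_equals_predictor(self, female_model, example_donor):
        model = female_model.replace(residual_sd=0.0)
        rng = np.random.default_rng(0)
        hb = ds.simulate_true_hb(model, example_donor, 12.0, rng)
        assert hb == pytest.approx(ds.linear_predictor(model, example_donor, 12.0))

    def test_latent_offset_persists_across_visits(self, female_model):
        model = female_model.replace(residual_sd=0.0)
        donor = make_donor(latent_offset=5.5)
        rng = np.random.default_rng(0)
        first = ds.simulate_true_hb(model, donor, 12.0, rng)
        second = ds.simulate_true_hb(model, donor, 30.0, rng)
        mu1 = ds.linear_predictor(model, donor, 12.0)
        mu2 = ds.linear_predictor(model, donor, 30.0)
        assert first - mu1 == pytest.approx(5.5)
        assert second - mu2 == pytest.approx(5.5)

    def test_variance_decomposition(self, female_model, female_pop_5k):
        """Across donors, sd of (true - predictor) matches sqrt(latent^2+residual^2)."""
        rng = np.random.default_rng(3)
        pop = female_pop_5k.head(10_000)
        devs = [
            ds.simulate_true_hb(female_model, donor, 16.0, rng) -
            ds.linear_predictor(female_model, donor, 16.0)
            for donor in pop.itertuples(index=False)
        ]
        assert np.std(devs) == pytest.approx(female_model.predictive_sd, rel=0.03)


class TestFitRecoveryModel:
    def test_noiseless_exact_recovery(self, female_model, female_pop_small):
        model = female_model.replace(latent_sd=0.0, residual_sd=0.0)
        pop = female_pop_small.assign(latent_offset=0.0)
        rng = np.random.default_rng(5)
        data = generate_two_visit_dataset(model, pop, rng.uniform(8, 30, len(pop)), seed=0)
        est = ds.fit_recovery_model(data)
        # the fit's intercept absorbs the reference-category effects
        ref_eth = sorted(pop["ethnicity"].unique())[0]
        ref_bg = sorted(pop["blood_group"].unique())[0]
        expected_intercept = (
            model.intercept + model.ethnicity_effects[ref_eth] + model.blood_group_effects[ref_bg]
        )
        assert est.intercept == pytest.approx(expected_intercept, abs=1e-8)
        assert est.coef_index_hb == pytest.approx(model.coef_index_hb, abs=1e-8)
        assert est.slope == pytest.approx(model.slope, abs=1e-8)
        assert est.coef_age == pytest.approx(model.coef_age, abs=1e-8)
        eth = sorted(pop["ethnicity"].unique())
        for lv in eth[1:]:
            assert est.ethnicity_effects[lv] == pytest.approx(
                model.ethnicity_effects[lv] - model.ethnicity_effects[ref_eth], abs=1e-8
            )

    def test_slope_recovery_with_noise(self, female_model, female_pop_5k):
        model = female_model.replace(slope=0.5)
        rng = np.random.default_rng(6)
        times = rng.uniform(8, 30, size=len(female_pop_5k))
        data = generate_two_visit_dataset(model, female_pop_5k, times, seed=10)
        est = ds.fit_recovery_model(data)
        assert est.slope == pytest.approx(0.5, abs=0.05)

    def test_parameter_recovery_within_3se(self, female_model, female_pop_5k):
        rng = np.random.default_rng(15)
        times = rng.uniform(8, 30, size=len(female_pop_5k))
        data = generate_two_visit_dataset(female_model, female_pop_5k, times, seed=16)
        res = ds.HbRecoveryModel.from_dataframe(data).fit()
        truth = {
            "const": female_model.intercept,
            "index_hb": female_model.coef_index_hb,
            "age": female_model.coef_age,
            "t_weeks": female_model.slope,
        }
        # category contrasts are identified relative to the fit's reference level
        eth_levels = sorted(female_pop_5k["ethnicity"].unique())
        for lv in eth_levels[1:]:
            truth[f"ethnicity[{lv}]"] = (
                female_model.ethnicity_effects[lv] - female_model.ethnicity_effects[eth_levels[0]]
            )
        bg_levels = sorted(female_pop_5k["blood_group"].unique())
        for lv in bg_levels[1:]:
            truth[f"blood_group[{lv}]"] = (
                female_model.blood_group_effects[lv] - female_model.blood_group_effects[bg_levels[0]]
            )
        for name, true_val in truth.items():
            assert abs(res.params[name] - true_val) < 3 * res.bse[name], name
        # total predictive sd (latent and residual are confounded in a
        # single-return design); oracle SE for a normal sd is sd/sqrt(2n)
        se_sd = female_model.predictive_sd / math.sqrt(2 * len(data))
        assert abs(res.predictive_sd - female_model.predictive_sd) < 3 * se_sd

    def test_intercept_only_null_slope(self, female_model, female_pop_5k):
        model = female_model.replace(slope=0.0)
        rng = np.random.default_rng(8)
        times = rng.uniform(8, 30, size=len(female_pop_5k))
        data = generate_two_visit_dataset(model, female_pop_5k, times, seed=9)
        res = ds.HbRecoveryModel.from_dataframe(data).fit()
        assert abs(res.params["t_weeks"]) < 2 * res.bse["t_weeks"]

    def test_mixed_model_separates_variance_components(self, female_model, female_pop_small):
        # repeated returns per donor let the random intercept be estimated
        import pandas as pd

        pop = female_pop_small
        rng = np.random.default_rng(21)
        frames = [
            generate_two_visit_dataset(female_model, pop, rng.uniform(8, 30, len(pop)), seed=s)
            for s in (100, 101, 102)
        ]
        data = pd.concat(frames, ignore_index=True)
        res = ds.HbRecoveryModel.from_dataframe(data).fit()
        assert res.latent_sd == pytest.approx(female_model.latent_sd, rel=0.35)
        assert res.residual_sd == pytest.approx(female_model.residual_sd, rel=0.15)

    def test_rank_deficient_design_names_terms(self, female_model, female_pop_small):
        data = generate_two_visit_dataset(female_model, female_pop_small, 16.0, seed=0)
        data["ethnicity"] = "White"
        data["blood_group"] = "O+"
        data["age"] = 40.0
        # t constant and collinear with the intercept once age is constant too
        with pytest.raises(np.linalg.LinAlgError, match="t_weeks|age"):
            ds.fit_recovery_model(data)
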