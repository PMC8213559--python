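import io

import numpy as np
import pytest
from scipy import stats

import magest
from magest import PopulationSpec, apply_anchoring_bias, draw_participants, simulate_ratings
from magest.preprocessing import to_standard_scale

from conftest import make_dataset


class TestDrawParticipants:
    def test_zero_spread_gives_population_means(self):
        pop = PopulationSpec(mean_k=2.0, sd_k=0.0, mean_a=0.7, sd_a=0.0, n_participants=5)
        fns = draw_participants(pop)
        assert all(f.k == 2.0 and f.a == 0.7 for f in fns)

    def test_same_seed_identical_draws(self):
        pop = PopulationSpec(seed=123, n_participants=20)
        a = draw_participants(pop)
        b = draw_participants(pop)
        assert a == b

    def test_truncated_normal_moments(self):
        # Monte-Carlo mean against the closed-form truncated-normal mean
        mean_a, sd_a, n = 0.5, 0.1, 10_000
        pop = PopulationSpec(mean_a=mean_a, sd_a=sd_a, n_participants=n, seed=7)
        draws = np.array([f.a for f in draw_participants(pop)])
        lo = (0.0 - mean_a) / sd_a
        expected = stats.truncnorm.mean(lo, np.inf, loc=mean_a, scale=sd_a)
        expected_sd = stats.truncnorm.std(lo, np.inf, loc=mean_a, scale=sd_a)
        assert abs(draws.mean() - expected) < 3 * expected_sd / np.sqrt(n)

    def test_all_draws_positive(self):
        pop = PopulationSpec(mean_a=0.05, sd_a=0.5, mean_k=0.05, sd_k=0.5,
                             n_participants=2000, seed=11)
        fns = draw_participants(pop)
        assert all(f.a > 0 and f.k > 0 for f in fns)


class TestSimulateRatings:
    def test_reversal_is_reciprocal_of_standard_noiseless(self, lum):
        ds_std, pop, parts = make_dataset(lum, "standard", noise_sd=0.0, seed=5)
        ds_rev = simulate_ratings(parts, lum, "reversal", pop)
        std = ds_std.trials.sort_values(["participant_id", "stimulus_id", "trial_index"])
        rev = ds_rev.trials.sort_values(["participant_id", "stimulus_id", "trial_index"])
        np.testing.assert_allclose(
            rev["response"].to_numpy(),
            100.0 / std["response"].to_numpy(),
            rtol=1e-12,
        )

    def test_linear_observer_rates_brightest_at_hundred(self, lum):
        # a = 1: the 100 cd/m2 stimulus is 10x the reference -> rating 100
        pop = PopulationSpec(mean_a=1.0, sd_a=0.0, noise_sd=0.0, n_participants=2, seed=0)
        ds = simulate_ratings(draw_participants(pop), lum, "standard", pop)
        top = ds.trials[ds.trials["stimulus_id"] == 9]["response"]
        np.testing.assert_allclose(top, 100.0, rtol=1e-12)

    def test_loglog_slope_recovers_exponent_noiselessly(self, lum):
        ds, pop, parts = make_dataset(lum, "standard", noise_sd=0.0, sd_a=0.0,
                                      mean_a=0.62, n_participants=1, seed=3)
        t = ds.trials
        slope = np.polyfit(np.log(t["intensity"]), np.log(t["response"]), 1)[0]
        assert slope == pytest.approx(0.62, abs=1e-10)

    def test_unidirectional_at_least_modulus(self, lum):
        ds, _, _ = make_dataset(lum, "unidirectional", noise_sd=0.08, seed=9)
        assert (ds.trials["response"] >= 10.0).all()
        assert ds.trials["direction"].notna().all()

    def test_unidirectional_backtransform_matches_standard_noiseless(self, lum):
        ds_std, pop, parts = make_dataset(lum, "standard", noise_sd=0.0, seed=13)
        ds_uni = simulate_ratings(parts, lum, "unidirectional", pop)
        back = to_standard_scale(ds_uni)
        key = ["participant_id", "stimulus_id", "trial_index"]
        merged = back.trials.merge(ds_std.trials, on=key, suffixes=("_uni", "_std"))
        np.testing.assert_allclose(
            merged["response_uni"], merged["response_std"], rtol=1e-12
        )

    def test_reference_never_a_test_stimulus(self, lum):
        ds, _, _ = make_dataset(lum, seed=1)
        assert lum.reference_id not in set(ds.trials["stimulus_id"])

    def test_trial_count_is_eight_times_reps(self, lum):
        ds, _, _ = make_dataset(lum, n_participants=4, n_reps=5, seed=2)
        counts = ds.trials.groupby("participant_id").size()
        assert (counts == 40).all()

    def test_unknown_method_rejected(self, lum):
        ds, pop, parts = make_dataset(lum, seed=0)
        with pytest.raises(ValueError):
            simulate_ratings(parts, lum, "sideways", pop)

    def test_csv_round_trip_and_byte_identical_reproduction(self, lum, tmp_path):
        ds1, pop, _ = make_dataset(lum, seed=77, noise_sd=0.05)
        ds2 = simulate_ratings(draw_participants(pop), lum, "standard", pop)
        buf1, buf2 = io.StringIO(), io.StringIO()
        ds1.to_csv(buf1)
        ds2.to_csv(buf2)
        assert buf1.getvalue() == buf2.getvalue()
        path = tmp_path / "trials.csv"
        ds1.to_csv(path)
        back = magest.RatingDataset.from_csv(path, lum)
        np.testing.assert_allclose(
            back.trials["response"], ds1.trials["response"], rtol=1e-12
        )


class TestAnchoringBias:
    def test_identity_at_lambda_one(self, lum):
        ds, _, _ = make_dataset(lum, seed=4)
        out = apply_anchoring_bias(ds, 1.0)
        np.testing.assert_array_equal(out.trials["response"], ds.trials["response"])

    def test_pure_difference_thinker_worked_value(self, lum):
        # f = 1/2, c = 1: 10 - (1/f - 1) = 9
        pop = PopulationSpec(mean_a=1.0, sd_a=0.0, noise_sd=0.0, n_participants=1, seed=0)
        ds = simulate_ratings(draw_participants(pop), lum, "standard", pop)
        df = ds.trials
        # a=1 and x_ref=0.1: stimulus 4 (5.7 cd/m2) has f = 0.57
        out = apply_anchoring_bias(ds, 0.0, bias_c=1.0)
        f = df["latent_f"].to_numpy()
        expect = np.where(f < 1, np.maximum(0.0, 10.0 - (1.0 / f - 1.0)), df["response"])
        np.testing.assert_allclose(out.trials["response"], expect, rtol=1e-12)

    def test_above_reference_untouched_any_lambda(self, lum):
        ds, _, _ = make_dataset(lum, seed=6)
        out = apply_anchoring_bias(ds, 0.3)
        above = ds.trials["latent_f"] >= 1.0
        np.testing.assert_array_equal(
            out.trials.loc[above, "response"], ds.trials.loc[above, "response"]
        )

    def test_lambda_out_of_range_rejected(self, lum):
        ds, _, _ = make_dataset(lum, seed=6)
        with pytest.raises(ValueError):
            apply_anchoring_bias(ds, 1.5)

    def test_wrong_format_rejected(self, lum):
        ds, _, _ = make_dataset(lum, "reversal", seed=6)
        with pytest.raises(ValueError):
            apply_anchoring_bias(ds, 0.5)


class TestStudyPresets:
    def test_designs_match_experiments(self):
        assert magest.study_population(2, "standard").n_participants == 16
        assert magest.study_population(2, "unidirectional").n_participants == 18
        assert magest.study_population(1, "reversal").n_participants == 20
        assert magest.study_population(3, "standard").mean_a == pytest.approx(1.99)
        assert magest.study_stimuli(3).dimension_label == "red_saturation"

    def test_unknown_study_or_arm_rejected(self):
        with pytest.raises(ValueError):
            magest.study_population(4, "standard")
        with pytest.raises(ValueError):
            magest.study_population(1, "unidirectional")
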