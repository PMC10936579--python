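import math

import numpy as np
import pytest

from binlat.metrics import (
    METRIC_NAMES,
    compute_metric_vector,
    extreme_and_monaural,
    fit_side_line,
    location_metrics,
    mirror_metric_vector,
    range_metrics,
    retain_trials,
    slope_ratio,
    variability_metrics,
)
from binlat.schema import LateralizationSession, StimulusDescriptor, Trial

from _helpers import assert_metrics_equal, full_session_from_retained, make_session
from _oracle import oracle_metrics, session_to_tuples


class TestRetainTrials:
    def test_complete_session_counts(self, ideal_session):
        retained = retain_trials(ideal_session)
        groups = retained.stimulus_groups()
        for key, trials in groups.items():
            expected = 7 if key[0] == "diotic" else 5
            assert len(trials) == expected, key

    def test_two_presentations_keeps_one(self):
        s = make_session({("diotic", None): [3, 7]})
        retained = retain_trials(s)
        assert [t.response_key for t in retained.trials] == [7]

    def test_single_presentation_errors(self):
        s = make_session({("diotic", None): [3]})
        with pytest.raises(ValueError, match="single presentation"):
            retain_trials(s)

    def test_shuffled_order_same_retained_set(self, noisy_session_factory, rng):
        s = noisy_session_factory(11)
        shuffled = LateralizationSession(
            s.participant_id,
            s.group,
            s.phase,
            [s.trials[i] for i in rng.permutation(len(s.trials))],
        )
        kept_a = {(t.stimulus.key, t.presentation_index) for t in retain_trials(s).trials}
        kept_b = {
            (t.stimulus.key, t.presentation_index)
            for t in retain_trials(shuffled).trials
        }
        assert kept_a == kept_b


class TestSideFit:
    @staticmethod
    def _trials(family, cue_responses):
        out = []
        for cv, resp in cue_responses.items():
            for i, r in enumerate(resp, start=1):
                out.append(Trial(StimulusDescriptor(family, cv), i, r))
        return out

    def test_collinear_means(self):
        # mean responses 2, 3, 4 at ILD -12, -8, -4 force r = 5 + 0.25*ILD
        trials = self._trials("ild", {-12.0: [2] * 5, -8.0: [3] * 5, -4.0: [4] * 5})
        fit = fit_side_line(trials, "left", "ild")
        assert fit.slope == pytest.approx(0.25)
        assert fit.fitted_mean == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(5.0)

    def test_flat_responses(self):
        trials = self._trials("ild", {4.0: [5] * 5, 8.0: [5] * 5, 12.0: [5] * 5})
        fit = fit_side_line(trials, "right", "ild")
        assert fit.slope == pytest.approx(0.0)
        assert fit.fitted_mean == pytest.approx(5.0)

    def test_matches_closed_form_ols(self, rng):
        for _ in range(20):
            cue_responses = {
                c: list(rng.integers(1, 10, size=5)) for c in (-600.0, -400.0, -200.0)
            }
            trials = self._trials("itd", cue_responses)
            fit = fit_side_line(trials, "left", "itd")
            # independent closed form on the same trial list
            xs = [t.stimulus.cue_value for t in trials]
            ys = [t.response_key for t in trials]
            xbar, ybar = sum(xs) / len(xs), sum(ys) / len(ys)
            sxx = sum((x - xbar) ** 2 for x in xs)
            sxy = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
            assert fit.slope == pytest.approx(sxy / sxx, abs=1e-12)
            assert fit.fitted_mean == pytest.approx(
                ybar - (sxy / sxx) * xbar + (sxy / sxx) * (-400.0), abs=1e-12
            )

    def test_missing_stimulus_named(self):
        trials = self._trials("ild", {-12.0: [2] * 5, -8.0: [3] * 5})
        with pytest.raises(ValueError, match="-4"):
            fit_side_line(trials, "left", "ild")

    def test_trial_level_equals_mean_level_fit_when_balanced(self, rng):
        # design decision: OLS on trials == OLS on per-stimulus means for
        # balanced repetition counts
        cue_responses = {
            c: list(rng.integers(1, 10, size=5)) for c in (200.0, 400.0, 600.0)
        }
        trials = self._trials("itd", cue_responses)
        fit = fit_side_line(trials, "right", "itd")
        xs = sorted(cue_responses)
        ys = [np.mean(cue_responses[c]) for c in xs]
        slope_means = np.polyfit(xs, ys, 1)[0]
        assert fit.slope == pytest.approx(slope_means, abs=1e-12)


class TestSlopeRatio:
    def test_symmetric_zero(self):
        assert slope_ratio(0.25, 0.25) == pytest.approx(0.0)

    def test_ln2(self):
        assert slope_ratio(0.5, 0.25) == pytest.approx(math.log(2))

    def test_nonpositive_quotient_is_na(self):
        assert math.isnan(slope_ratio(-0.1, 0.25))
        assert math.isnan(slope_ratio(0.25, 0.0))


class TestLocationMetrics:
    def test_symmetric_listener(self):
        # mirror-symmetric retained responses: response 10-k at mirrored cue
        retained = {
            ("itd", -600.0): [1] * 5,
            ("itd", -400.0): [2] * 5,
            ("itd", -200.0): [4] * 5,
            ("itd", 200.0): [6] * 5,
            ("itd", 400.0): [8] * 5,
            ("itd", 600.0): [9] * 5,
            ("ild", -12.0): [1] * 5,
            ("ild", -8.0): [2] * 5,
            ("ild", -4.0): [4] * 5,
            ("ild", 4.0): [6] * 5,
            ("ild", 8.0): [8] * 5,
            ("ild", 12.0): [9] * 5,
            ("diotic", None): [5] * 7,
        }
        s = retain_trials(full_session_from_retained(retained))
        loc = location_metrics(s)
        assert loc["itd_mean"] == pytest.approx(5.0)
        assert loc["ild_mean"] == pytest.approx(5.0)
        assert loc["itd_center"] == pytest.approx(0.0)
        assert loc["ild_center"] == pytest.approx(0.0)
        assert loc["diotic_percept"] == pytest.approx(5.0)

    def test_itd_center_weighted_mean(self):
        # key 5 on ITD trials at -200 (x2), 0 (x7), +200 (x3): center 200/12
        retained = {
            ("itd", -200.0): [5, 5, 4, 4, 4],
            ("itd", 200.0): [5, 5, 5, 6, 6],
            ("itd", -600.0): [1] * 5,
            ("itd", -400.0): [2] * 5,
            ("itd", 400.0): [8] * 5,
            ("itd", 600.0): [9] * 5,
            ("diotic", None): [5] * 7,
        }
        s = retain_trials(full_session_from_retained(retained, filler_first=4))
        loc = location_metrics(s)
        assert loc["itd_center"] == pytest.approx(200.0 / 12.0)

    def test_center_na_without_key5(self):
        retained = {("diotic", None): [6] * 7}
        s = retain_trials(full_session_from_retained(retained, filler_first=6))
        loc = location_metrics(s)
        assert math.isnan(loc["itd_center"])
        assert math.isnan(loc["ild_center"])

    def test_diotic_percept(self):
        retained = {("diotic", None): [7] * 7}
        s = retain_trials(full_session_from_retained(retained))
        assert location_metrics(s)["diotic_percept"] == pytest.approx(7.0)


class TestVariabilityMetrics:
    def test_deterministic_listener_zero_stds_and_ratios(self):
        s = retain_trials(full_session_from_retained({}))
        var = variability_metrics(s)
        for name in ("diotic_std", "itd_std", "ild_std", "itd_l_std", "ild_r_std"):
            assert var[name] == pytest.approx(0.0)
        # both side stds floored at 0.1 -> log ratio 0
        assert var["itd_std_ratio"] == pytest.approx(0.0)
        assert var["ild_std_ratio"] == pytest.approx(0.0)

    def test_hand_computed_sample_sd(self):
        # responses {4,4,6,6,5}: sample sd exactly 1.0
        retained = {("itd", -600.0): [4, 4, 6, 6, 5]}
        s = retain_trials(full_session_from_retained(retained))
        var = variability_metrics(s)
        assert var["itd_std"] == pytest.approx(1.0 / 7.0)
        assert var["itd_l_std"] == pytest.approx(1.0 / 3.0)
        assert var["itd_r_std"] == pytest.approx(0.0)

    def test_mirrored_noise_pattern_zero_ratio(self):
        retained = {
            ("itd", -600.0): [1, 2, 1, 2, 1],
            ("itd", 600.0): [9, 8, 9, 8, 9],
        }
        s = retain_trials(full_session_from_retained(retained))
        assert variability_metrics(s)["itd_std_ratio"] == pytest.approx(0.0)

    def test_single_retained_trial_errors(self):
        s = full_session_from_retained({})
        # drop all but one diotic trial, then bypass retain_trials
        trials = [t for t in s.trials if t.stimulus.cue_type != "diotic"]
        trials.append(Trial(StimulusDescriptor("diotic"), 1, 5))
        broken = LateralizationSession("T", "patient", "acute", trials)
        with pytest.raises(ValueError, match="diotic"):
            variability_metrics(broken)


class TestRangeMetrics:
    def test_hand_computed_itd_range(self):
        # per-stimulus ITD means {2, 2.6, 3.4, 5, 6.2, 7, 7.8} -> range 5.8
        retained = {
            ("itd", -600.0): [2] * 5,
            ("itd", -400.0): [2, 2, 3, 3, 3],
            ("itd", -200.0): [3, 3, 3, 4, 4],
            ("itd", 200.0): [6, 6, 6, 6, 7],
            ("itd", 400.0): [7] * 5,
            ("itd", 600.0): [8, 8, 8, 8, 7],
            ("diotic", None): [5] * 7,
        }
        s = retain_trials(full_session_from_retained(retained))
        assert range_metrics(s)["itd_range"] == pytest.approx(5.8)

    def test_constant_responses_floor(self):
        s = retain_trials(full_session_from_retained({}))
        r = range_metrics(s)
        assert r["itd_range"] == pytest.approx(0.0)
        assert r["ild_range"] == pytest.approx(0.0)
        assert r["range_ratio"] == pytest.approx(0.0)  # ln(0.5/0.5)

    def test_equal_ranges_zero_ratio(self, ideal_session):
        r = range_metrics(retain_trials(ideal_session))
        assert r["itd_range"] == pytest.approx(r["ild_range"])
        assert r["range_ratio"] == pytest.approx(0.0)


class TestExtremeAndMonaural:
    def test_control_like(self):
        retained = {
            ("mono_left", None): [1] * 5,
            ("mono_right", None): [9] * 5,
        }
        s = retain_trials(full_session_from_retained(retained))
        em = extreme_and_monaural(s)
        assert em["mon_left"] == pytest.approx(1.0)
        assert em["mon_right"] == pytest.approx(9.0)

    def test_confused_extreme_mean(self):
        # +1500 µs heard left on 3 of 5 trials: {2,2,2,8,8} -> mean 4.4
        retained = {("itd", 1500.0): [2, 2, 2, 8, 8]}
        s = retain_trials(full_session_from_retained(retained))
        assert extreme_and_monaural(s)["pos_1500"] == pytest.approx(4.4)

    def test_mirrored_extremes_sum_to_ten(self, noisy_session_factory):
        s = noisy_session_factory(3)
        em = extreme_and_monaural(retain_trials(s))
        em_m = extreme_and_monaural(retain_trials(s.mirrored()))
        assert em_m["neg_1500"] + em["pos_1500"] == pytest.approx(10.0)


class TestMetricVector:
    def test_ideal_listener_forced_values(self, ideal_session):
        mv = compute_metric_vector(ideal_session)
        # symmetric listener: every symmetry-forced entry is exact
        for name in ("ild_slope_ratio", "itd_slope_ratio", "itd_std_ratio",
                     "ild_std_ratio", "range_ratio", "itd_center", "ild_center"):
            assert mv[name] == pytest.approx(0.0), name
        assert mv["itd_mean"] == pytest.approx(5.0)
        assert mv["ild_mean"] == pytest.approx(5.0)
        assert mv["diotic_percept"] == pytest.approx(5.0)
        assert mv["itd_range"] == pytest.approx(8.0)
        assert mv["ild_range"] == pytest.approx(8.0)
        assert mv["mon_left"] == pytest.approx(1.0)
        assert mv["mon_right"] == pytest.approx(9.0)
        assert mv["neg_1500"] == pytest.approx(1.0)
        assert mv["pos_1500"] == pytest.approx(9.0)
        for name in METRIC_NAMES:
            if "std" in name and "ratio" not in name:
                assert mv[name] == pytest.approx(0.0), name
        # integer-key readout of the linear percept: slopes are the OLS of
        # the rounded responses (1, 2, 4) on the side cues
        assert mv["ild_l_slope"] == pytest.approx(0.375)
        assert mv["ild_r_slope"] == pytest.approx(0.375)
        assert mv["itd_l_slope"] == pytest.approx(0.0075)
        assert mv["itd_r_slope"] == pytest.approx(0.0075)

    @pytest.mark.parametrize("seed", range(50))
    def test_equals_bruteforce_oracle(self, noisy_session_factory, seed):
        s = noisy_session_factory(seed)
        mv = compute_metric_vector(s)
        expected = oracle_metrics(session_to_tuples(s))
        assert_metrics_equal(mv.as_dict(), expected)

    @pytest.mark.parametrize("seed", range(25))
    def test_mirror_symmetry(self, noisy_session_factory, seed):
        s = noisy_session_factory(seed)
        direct = compute_metric_vector(s.mirrored()).as_dict()
        mapped = mirror_metric_vector(compute_metric_vector(s)).as_dict()
        assert_metrics_equal(direct, mapped, tol=1e-9)

    def test_permutation_invariance(self, noisy_session_factory, rng):
        s = noisy_session_factory(7)
        shuffled = LateralizationSession(
            s.participant_id,
            s.group,
            s.phase,
            [s.trials[i] for i in rng.permutation(len(s.trials))],
        )
        assert_metrics_equal(
            compute_metric_vector(s).as_dict(),
            compute_metric_vector(shuffled).as_dict(),
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_bounds(self, noisy_session_factory, seed):
        mv = compute_metric_vector(noisy_session_factory(seed))
        key_scale = (
            "itd_mean", "ild_mean", "itd_l_fit", "itd_r_fit", "ild_l_fit",
            "ild_r_fit", "diotic_percept", "mon_left", "mon_right",
            "neg_1500", "pos_1500",
        )
        for name in key_scale:
            if not math.isnan(mv[name]):
                assert 1.0 <= mv[name] <= 9.0, name
        for name in METRIC_NAMES:
            if name.endswith("_std"):
                assert 0.0 <= mv[name] <= 4.0, name
        for name in ("itd_range", "ild_range"):
            assert 0.0 <= mv[name] <= 8.0, name
        if not math.isnan(mv["itd_center"]):
            assert -600.0 <= mv["itd_center"] <= 600.0
        if not math.isnan(mv["ild_center"]):
            assert -12.0 <= mv["ild_center"] <= 12.0

    def test_exactly_31_metrics_stable_order(self, ideal_session):
        assert len(METRIC_NAMES) == 31
        mv = compute_metric_vector(ideal_session)
        assert tuple(mv.as_dict()) == METRIC_NAMES
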