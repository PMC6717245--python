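"""Detection-probability machinery: localization Monte Carlo, effort
rule, count corrections, effective range, day/night test, visibility."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cuerate import detection as det


def make_field(sl, tl, nl, threshold=0.5):
    n_cells = np.atleast_2d(tl).shape[0]
    grid = np.column_stack([np.arange(n_cells), np.zeros(n_cells)])
    return det.LocalizationField(
        grid_xy=grid,
        sl_samples_db=np.asarray(sl, dtype=float),
        tl_db=np.asarray(tl, dtype=float),
        nl_db=np.atleast_2d(np.asarray(nl, dtype=float)),
        snr_threshold_db=threshold,
    )


def brute_force_pl(sl, tl, nl, threshold=0.5):
    """Exhaustive enumeration over SL samples x cells x hydrophones."""
    sl, tl, nl = np.asarray(sl), np.atleast_2d(tl), np.asarray(nl)
    cell_probs = []
    for cell in range(tl.shape[0]):
        hits = 0
        for s in sl:
            min_snr = min(s - tl[cell, i] - nl[i] for i in range(tl.shape[1]))
            if min_snr > threshold:
                hits += 1
        cell_probs.append(hits / len(sl))
    return float(np.mean(cell_probs))


class TestProbabilityOfLocalization:
    def test_saturated_field_gives_one(self):
        f = make_field(sl=[200] * 5, tl=[[60] * 4, [70] * 4], nl=[80, 80, 80, 80])
        assert det.probability_of_localization(f, 0) == 1.0

    def test_hopeless_field_gives_zero(self):
        f = make_field(sl=[100] * 5, tl=[[60] * 4], nl=[80, 80, 80, 80])
        assert det.probability_of_localization(f, 0) == 0.0

    def test_matches_exhaustive_enumeration_on_hand_instance(self):
        sl = [150.0, 155.0, 160.0, 165.0]
        tl = [[60.0, 65.0, 70.0, 62.0], [80.0, 75.0, 78.0, 81.0]]
        nl = [85.0, 84.0, 83.0, 86.0]
        f = make_field(sl, tl, nl)
        assert det.probability_of_localization(f, 0) == pytest.approx(
            brute_force_pl(sl, tl, nl)
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_enumeration_on_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_cells = rng.integers(1, 11)
        n_sl = rng.integers(1, 11)
        sl = rng.uniform(140, 170, n_sl)
        tl = rng.uniform(50, 90, (n_cells, 4))
        nl = rng.uniform(70, 95, 4)
        f = make_field(sl, tl, nl)
        assert det.probability_of_localization(f, 0) == pytest.approx(
            brute_force_pl(sl, tl, nl)
        )

    def test_monotone_in_sl_tl_nl(self):
        rng = np.random.default_rng(7)
        sl = rng.uniform(150, 160, 20)
        tl = rng.uniform(60, 80, (5, 4))
        nl = rng.uniform(75, 90, 4)
        base = det.probability_of_localization(make_field(sl, tl, nl), 0)
        up = det.probability_of_localization(make_field(sl + 3, tl, nl), 0)
        louder_noise = det.probability_of_localization(make_field(sl, tl, nl + 3), 0)
        lossier = det.probability_of_localization(make_field(sl, tl + 3, nl), 0)
        assert up >= base >= louder_noise
        assert base >= lossier

    def test_missing_noise_minute_signals_no_effort(self):
        f = make_field([150] * 3, [[60] * 4], [np.nan, 80, 80, 80])
        assert np.isnan(det.probability_of_localization(f, 0))


class TestEffortRule:
    def detections(self, minutes):
        return [
            det.DetectionRecord(sensor="acoustic", time_s=m * 60.0, range_m=1000.0, minute=m)
            for m in minutes
        ]

    def test_all_minutes_good_keeps_everything(self):
        p_l = np.full(10, 0.9)
        kept, log = det.apply_effort_rule(p_l, self.detections(range(10)))
        assert len(kept) == 10
        assert log.p_ne == 0.0

    def test_low_probability_minutes_dropped(self):
        p_l = np.array([0.4, 0.9] * 5)
        kept, log = det.apply_effort_rule(p_l, self.detections(range(10)))
        assert len(kept) == 5
        assert all(k.minute % 2 == 1 for k in kept)
        assert log.p_ne == pytest.approx(0.5)

    def test_p_ne_is_flagged_fraction(self):
        p_l = np.ones(1440)
        p_l[:36] = 0.2
        _, log = det.apply_effort_rule(p_l, [])
        assert log.p_ne == pytest.approx(0.025)


class TestCountCorrections:
    def test_call_correction_arithmetic(self):
        assert det.correct_call_count(100, 0.2, 0.8, 0.0).corrected == pytest.approx(100.0)
        assert det.correct_call_count(50, 0.0, 0.5, 0.5).corrected == pytest.approx(200.0)

    def test_identity_when_all_factors_unity(self):
        assert det.correct_call_count(37, 0.0, 1.0, 0.0).corrected == 37
        assert det.correct_blow_count(1427, 0.0, 1.0, 0.0).corrected == 1427

    def test_blow_correction_scales_for_video_gaps(self):
        c = det.correct_blow_count(290, 0.0, 1.0, 0.025)
        assert c.corrected == pytest.approx(297.4, abs=0.05)

    def test_corrected_scales_inverse_in_effort(self):
        base = det.correct_call_count(80, 0.1, 0.7, 0.0).corrected
        halved = det.correct_call_count(80, 0.1, 0.7, 0.5).corrected
        assert halved == pytest.approx(2 * base)

    @pytest.mark.parametrize("p_l,p_ne", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_probabilities_rejected(self, p_l, p_ne):
        with pytest.raises(det.UndefinedCorrectionError):
            det.correct_call_count(10, 0.0, p_l, p_ne)


class TestEffectiveDetectionRange:
    def test_identical_curves_return_max_range(self, rng):
        ranges = rng.uniform(400, 3000, 500)
        res = det.effective_detection_range(ranges, ranges)
        assert res.degenerate
        assert res.effective_max_range_m == pytest.approx(ranges.max())

    def test_truncation_radius_recovered_within_10pct(self, rng):
        sightings = rng.uniform(200, 3000, 3000)
        detections = sightings[sightings <= 2100.0]
        res = det.effective_detection_range(detections, sightings)
        assert not res.degenerate
        assert res.effective_max_range_m == pytest.approx(2100.0, rel=0.10)
        assert res.near_cutoff_m == 500.0

    def test_cumulative_curves_nondecreasing(self, rng):
        sightings = rng.uniform(200, 3000, 400)
        detections = sightings[sightings <= 2000.0]
        res = det.effective_detection_range(detections, sightings)
        assert np.all(np.diff(res.cumulative_detections) >= 0)
        assert np.all(np.diff(res.cumulative_sightings) >= 0)

    def test_single_range_is_degenerate(self):
        res = det.effective_detection_range([1000.0] * 50, np.linspace(500, 3000, 50))
        assert res.degenerate

    def test_too_few_points_rejected(self):
        with pytest.raises(det.InsufficientDataError):
            det.effective_detection_range([1000.0, 1200.0], [900.0, 1100.0])


def brute_force_ranksum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of group labels."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    observed = ranks[:nx].sum()
    sums = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), nx)
    ]
    sums = np.array(sums)
    mean = sums.mean()
    p = np.mean(np.abs(sums - mean) >= abs(observed - mean) - 1e-12)
    return float(p)


class TestDayNightComparison:
    def test_identical_hours_are_symmetric(self):
        counts = np.full(24, 5.0)
        share, p = det.day_night_comparison(counts)
        assert share == pytest.approx(9.0 / 24.0)
        assert p == 1.0

    def test_uniform_cues_give_window_share(self, rng):
        # many days of Poisson-uniform hourly counts: share ~ 9/24
        counts = rng.poisson(30, 24 * 30)
        share, p = det.day_night_comparison(counts)
        se = np.sqrt((9 / 24) * (15 / 24) / counts.sum())
        assert share == pytest.approx(9.0 / 24.0, abs=4 * se)
        assert p > 0.05

    def test_exact_p_matches_enumeration_oracle(self):
        # half a day of distinct counts: hours 8-11 fall in the watch
        # window, so the exact method must equal the 12-choose-4
        # enumeration of rank sums
        counts = np.array([3, 1, 4, 1.5, 5, 9, 2, 6, 5.5, 3.5, 8, 9.5])
        share, p = det.day_night_comparison(counts)
        hours = np.arange(12)
        in_day = (hours >= 7.5) & (hours < 16.5)
        day, night = counts[in_day], counts[~in_day]
        assert p == pytest.approx(brute_force_ranksum_p(day, night), abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            det.day_night_comparison(np.arange(8), day_window=(0.0, 7.0))


class TestVisibilityMetric:
    def test_constant_frame_scores_zero(self):
        assert det.visibility_metric(np.full((10, 8), 42.0)) == 0.0

    def test_two_band_frame_population_variance(self):
        frame = np.vstack([np.full((5, 6), 10.0), np.full((5, 6), 30.0)])
        assert det.visibility_metric(frame) == pytest.approx(100.0)

    def test_translation_invariance(self, rng):
        frame = rng.uniform(0, 255, (48, 64))
        assert det.visibility_metric(frame + 17.0) == pytest.approx(
            det.visibility_metric(frame)
        )

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            det.visibility_metric(np.empty((0, 0)))
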