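"""Simulated tracks, cue processes, and sensor thinning."""

import numpy as np
import pytest

from cuerate import synthetic_data as sd
from cuerate.detection import EffortLog


def config(**kw):
    defaults = dict(random_seed=42, n_whales_per_day=(100,) * 5)
    defaults.update(kw)
    return sd.SimulationConfig(**defaults)


class TestSimulateTracks:
    def test_zero_whales_everywhere_gives_empty(self):
        assert sd.simulate_tracks(config(n_whales_per_day=(0, 0, 0))) == []

    def test_counts_match_configuration(self):
        cfg = config(n_whales_per_day=(3, 0, 7))
        tracks = sd.simulate_tracks(cfg)
        per_day = {d: sum(t.day == d for t in tracks) for d in range(3)}
        assert per_day == {0: 3, 1: 0, 2: 7}

    def test_deterministic_under_seed(self):
        t1 = sd.simulate_tracks(config())
        t2 = sd.simulate_tracks(config())
        assert t1 == t2

    def test_seed_changes_output(self):
        assert sd.simulate_tracks(config()) != sd.simulate_tracks(config(random_seed=43))

    def test_uniform_offshore_fraction_binomial_oracle(self):
        cfg = config(
            n_whales_per_day=(10_000,),
            offshore_distribution=sd.OffshoreModel(name="uniform", params=(500.0, 3000.0)),
        )
        tracks = sd.simulate_tracks(cfg)
        x = np.array([t.offshore_m for t in tracks])
        frac = np.mean((x > 500.0) & (x <= 2100.0))
        p = (2100.0 - 500.0) / (3000.0 - 500.0)  # 0.64
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(frac - p) < 3 * se

    def test_southbound_fraction_respected(self):
        cfg = config(n_whales_per_day=(10_000,), southbound_fraction=0.9)
        tracks = sd.simulate_tracks(cfg)
        south = np.mean([t.direction == "south" for t in tracks])
        assert abs(south - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 10_000)

    def test_invalid_distribution_name_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.OffshoreModel(name="lognormal", params=(500.0, 3000.0))


class TestSimulateCalls:
    def test_zero_rate_produces_no_calls(self):
        tracks = sd.simulate_tracks(config())
        assert sd.simulate_calls(tracks, lambda d: 0.0, seed=1) == []

    def test_negative_rate_rejected(self):
        tracks = sd.simulate_tracks(config(n_whales_per_day=(1,)))
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_calls(tracks, lambda d: -1.0, seed=1)

    def test_total_count_poisson_oracle(self):
        # N whales at constant rate r over fixed residence t: the total
        # is Poisson with mean N*r*t, so it must land within 3 sqrt(Nrt)
        cfg = config(n_whales_per_day=(2000,), corridor_length_m=13824.0)
        tracks = sd.simulate_tracks(cfg)
        rate = 10.0  # calls/whale/day
        res_days = (13824.0 / 1.6) / 86400.0  # = 0.1 day per whale
        mean = 2000 * rate * res_days
        calls = sd.simulate_calls(tracks, lambda d: rate, seed=9, corridor_length_m=13824.0)
        assert abs(len(calls) - mean) < 3 * np.sqrt(mean)

    def test_default_rate_curve_near_floor_on_day_one(self):
        # a*x^b + c at x = 1 is dominated by the constant term
        assert sd.default_call_rate(1) == pytest.approx(3.39, abs=1e-5)

    def test_call_positions_lie_on_track(self):
        cfg = config(n_whales_per_day=(50,))
        tracks = sd.simulate_tracks(cfg)
        calls = sd.simulate_calls(tracks, lambda d: 50.0, seed=3)
        by_id = {t.whale_id: t for t in tracks}
        for c in calls[:200]:
            tr = by_id[c.whale_id]
            assert c.x_m == tr.offshore_m
            assert 0.0 <= c.y_m <= cfg.corridor_length_m + 1e-6


class TestSimulateBlows:
    def test_deterministic_cycle_matches_renewal_closed_form(self):
        # 3 blows 25 s apart + 210 s dive repeats every 260 s: the
        # long-run rate is 3/260 blows/s ~ 41.5 blows/hour
        cycle = sd.BlowCycle(
            blows_per_bout=(3, 3), inter_blow_s=(25.0, 25.0), long_dive_s=(210.0, 210.0)
        )
        corridor = 1.6 * 86400.0 * 2  # two days in corridor
        cfg = config(n_whales_per_day=(20,), corridor_length_m=corridor)
        tracks = sd.simulate_tracks(cfg)
        blows = sd.simulate_blows(tracks, cycle, seed=5, corridor_length_m=corridor)
        hours = 20 * corridor / 1.6 / 3600.0
        assert len(blows) / hours == pytest.approx(3.0 / 260.0 * 3600.0, rel=0.02)

    def test_zero_length_track_has_no_blows(self):
        tracks = sd.simulate_tracks(config(n_whales_per_day=(5,)))
        blows = sd.simulate_blows(tracks, sd.BlowCycle(), seed=1, corridor_length_m=1e-9)
        assert blows == []

    def test_midpoint_rate_within_observed_blow_rate_range(self):
        # observed migrating blow rates span 27-67.2 blows/whale/hour
        corridor = 1.6 * 3600.0 * 100  # 100 whale-hours per whale
        cfg = config(n_whales_per_day=(20,), corridor_length_m=corridor)
        tracks = sd.simulate_tracks(cfg)
        blows = sd.simulate_blows(tracks, sd.BlowCycle(), seed=11, corridor_length_m=corridor)
        hourly = len(blows) / (20 * 100.0)
        assert 27.0 <= hourly <= 67.2

    def test_times_strictly_increasing_per_whale(self):
        tracks = sd.simulate_tracks(config(n_whales_per_day=(30,)))
        blows = sd.simulate_blows(tracks, sd.BlowCycle(), seed=2)
        per_whale: dict[int, list[float]] = {}
        for b in blows:
            per_whale.setdefault(b.whale_id, []).append(b.time_s)
        for times in per_whale.values():
            assert all(a < b for a, b in zip(times, times[1:]))


class TestSimulateDetections:
    def cues(self, n_days=1, rate=200.0):
        cfg = config(n_whales_per_day=(100,) * n_days)
        tracks = sd.simulate_tracks(cfg)
        return sd.simulate_calls(tracks, lambda d: rate, seed=21)

    def full_effort(self, n_days=1):
        return EffortLog.from_flags(np.ones(n_days * 1440, dtype=bool))

    def test_perfect_sensor_detects_every_cue_in_domain(self):
        cues = self.cues()
        dets = sd.simulate_detections(
            cues, sd.SensorModel(kind="acoustic"), self.full_effort(), seed=1
        )
        assert len(dets) == len(cues)

    def test_detections_never_exceed_cues(self):
        cues = self.cues()
        dets = sd.simulate_detections(
            cues,
            sd.SensorModel(kind="acoustic", detection_prob=0.7),
            self.full_effort(),
            seed=1,
        )
        assert 0 < len(dets) < len(cues)

    def test_effort_window_share_of_uniform_cues(self):
        cues = self.cues(n_days=4)
        flags = sd.EffortSchedule().visual_flags(4)  # 9 of 24 hours
        dets = sd.simulate_detections(
            cues, sd.SensorModel(kind="visual"), EffortLog.from_flags(flags), seed=1
        )
        frac = len(dets) / len(cues)
        se = np.sqrt((9 / 24) * (15 / 24) / len(cues))
        assert abs(frac - 9.0 / 24.0) < 4 * se

    def test_camera_range_window_clips_domain(self):
        cues = self.cues()
        dets = sd.simulate_detections(
            cues,
            sd.SensorModel(kind="camera", range_window=(500.0, 2100.0)),
            self.full_effort(),
            seed=1,
        )
        assert dets and all(500.0 < d.range_m <= 2100.0 for d in dets)
        assert all(d.pixel is not None for d in dets)

    def test_unknown_sensor_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SensorModel(kind="sonar")

    def test_detection_stream_deterministic(self):
        cues = self.cues()
        m = sd.SensorModel(kind="acoustic", detection_prob=0.5)
        d1 = sd.simulate_detections(cues, m, self.full_effort(), seed=4)
        d2 = sd.simulate_detections(cues, m, self.full_effort(), seed=4)
        assert d1 == d2
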