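"""Operant/gustometer metrics against hand counts and brute-force recounts."""

import numpy as np
import pandas as pd
import pytest

from conftest import oracle_operant_recount
from dopsig.errors import InvalidParameterError, ScheduleMismatchError
from dopsig.operant import (
    LickLog,
    OperantSession,
    crf_metrics,
    fi_metrics,
    lick_metrics,
    scallop_curve,
    trough_training_metrics,
)
from dopsig.synth import (
    LatencyModel,
    ScheduleSpec,
    simulate_event_schedule,
    simulate_lick_session,
)


def build_session(trial_specs, schedule="CRF", interval=None):
    """trial_specs: list of dicts with keys ext, presses, dipper, head."""
    rows = []
    for ti, spec in enumerate(trial_specs):
        rows.append(("lever_extension", spec["ext"], ti))
        for p in spec.get("presses", []):
            rows.append(("lever_press", p, ti))
        if "dipper" in spec:
            up, down = spec["dipper"]
            rows.append(("dipper_up", up, ti))
            rows.append(("dipper_down", down, ti))
        for h in spec.get("head", []):
            rows.append(("head_entry", h, ti))
    ev = pd.DataFrame(rows, columns=["event_type", "time_s", "trial_index"])
    ev = ev.sort_values("time_s", kind="stable").reset_index(drop=True)
    return OperantSession(events=ev, schedule=schedule, fixed_interval_s=interval)


class TestCrfMetrics:
    def test_all_pressed_and_consumed(self):
        trials = [
            dict(ext=60.0 * i, presses=[60.0 * i + 2.0],
                 dipper=(60.0 * i + 2.1, 60.0 * i + 7.1), head=[60.0 * i + 3.0])
            for i in range(10)
        ]
        m = crf_metrics(build_session(trials))
        assert m.pct_lever_press == 100.0
        assert m.pct_rewarded_trials == 100.0

    def test_hand_count_nine_pressed_six_consumed(self):
        trials = []
        for i in range(10):
            t0 = 60.0 * i
            spec = dict(ext=t0)
            if i < 9:
                spec["presses"] = [t0 + 2.0]
                spec["dipper"] = (t0 + 2.1, t0 + 7.1)
                if i < 6:
                    spec["head"] = [t0 + 3.0]
            trials.append(spec)
        m = crf_metrics(build_session(trials))
        assert m.pct_lever_press == pytest.approx(90.0)
        assert m.pct_rewarded_trials == pytest.approx(60.0)

    def test_first_press_latency_42s(self):
        trials = [dict(ext=0.0, presses=[42.0], dipper=(42.1, 47.1), head=[43.0])]
        m = crf_metrics(build_session(trials))
        assert m.latency_first_press_s == pytest.approx(42.0)

    def test_schedule_mismatch(self):
        s = simulate_event_schedule(ScheduleSpec("CRF", n_trials=2), seed=0)
        with pytest.raises(ScheduleMismatchError):
            fi_metrics(s)


class TestFiMetrics:
    def test_rule_application_interval_two(self):
        t0 = 0.0
        trials = [dict(ext=t0, presses=[0.5, 1.0, 2.5],
                       dipper=(2.51, 12.51), head=[3.0])]
        m = fi_metrics(build_session(trials, schedule="FI", interval=2.0))
        assert m.total_presses == 3
        assert m.latency_first_press_s == pytest.approx(0.5)
        # rewarded press is the first after the interval -> dipper at 2.51
        assert m.pct_rewarded_trials == 100.0

    def test_unpressed_trial_counts_in_denominator(self):
        trials = [
            dict(ext=0.0, presses=[3.0], dipper=(3.01, 13.01), head=[4.0]),
            dict(ext=30.0),  # lever out, never pressed before session end
        ]
        m = fi_metrics(build_session(trials, schedule="FI", interval=2.0))
        assert m.n_presentations == 2
        assert m.pct_lever_press == pytest.approx(50.0)
        assert m.n_missing_press == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_bruteforce_recount_oracle(self, seed):
        rng = np.random.default_rng(seed)
        interval = float(rng.choice([2.0, 4.0, 8.0, 12.0, 24.0]))
        spec = ScheduleSpec("FI", n_trials=int(rng.integers(3, 15)),
                            fixed_interval_s=interval,
                            press_rate_profile=float(rng.uniform(0.05, 0.8)))
        lm = LatencyModel(jitter="exponential", p_retrieve=0.8)
        s = simulate_event_schedule(spec, lm, seed=seed)
        m = fi_metrics(s)
        oracle = oracle_operant_recount(s.events)
        assert m.total_presses == oracle["total_presses"]
        assert m.pct_lever_press == pytest.approx(oracle["pct_lever_press"])
        assert m.pct_rewarded_trials == pytest.approx(oracle["pct_rewarded_trials"])
        assert m.latency_first_press_s == pytest.approx(
            oracle["latency_first_press_s"], nan_ok=True
        )
        assert m.latency_mean_press_s == pytest.approx(
            oracle["latency_mean_press_s"], nan_ok=True
        )
        assert m.latency_reward_s == pytest.approx(
            oracle["latency_reward_s"], nan_ok=True
        )

    def test_rewarded_never_exceeds_pressed(self):
        for seed in range(10):
            lm = LatencyModel(jitter="exponential", p_press=0.7, p_retrieve=0.6)
            s = simulate_event_schedule(ScheduleSpec("CRF", n_trials=20), lm,
                                        seed=seed)
            m = crf_metrics(s)
            assert m.pct_rewarded_trials <= m.pct_lever_press

    def test_first_press_latency_grows_with_interval(self):
        # interval-scaled press rates; latency to first press should grow in
        # expectation as the interval does (mirrors the task's latency trend)
        def mean_first(interval):
            lat = []
            for seed in range(8):
                spec = ScheduleSpec("FI", n_trials=20, fixed_interval_s=interval,
                                    press_rate_profile=lambda t: 2.0 * t / interval)
                s = simulate_event_schedule(spec, LatencyModel(jitter="exponential"),
                                            seed=seed)
                lat.append(fi_metrics(s).latency_first_press_s)
            return np.mean(lat)

        assert mean_first(24.0) > mean_first(2.0)


class TestScallopCurve:
    def test_uniform_rate_flat(self):
        spec = ScheduleSpec("FI", n_trials=60, fixed_interval_s=24.0,
                            press_rate_profile=0.5)
        s = simulate_event_schedule(spec, seed=1)
        c = scallop_curve(s, 6)
        total = c.total_in_interval_presses
        se = np.sqrt(total / 6) / (c.n_trials * 4.0)
        assert np.abs(c.rate_hz - 0.5).max() < 5 * se + 0.05

    def test_increasing_rate_positive_slope(self):
        spec = ScheduleSpec("FI", n_trials=60, fixed_interval_s=24.0,
                            press_rate_profile=lambda t: 0.05 + 0.04 * np.asarray(t))
        s = simulate_event_schedule(spec, seed=2)
        c = scallop_curve(s, 6)
        centers = (c.bin_edges_s[:-1] + c.bin_edges_s[1:]) / 2
        slope = np.polyfit(centers, c.rate_hz, 1)[0]
        assert slope > 0

    def test_single_bin_overall_rate(self):
        spec = ScheduleSpec("FI", n_trials=10, fixed_interval_s=8.0,
                            press_rate_profile=0.3)
        s = simulate_event_schedule(spec, seed=3)
        c = scallop_curve(s, 1)
        expected = c.total_in_interval_presses / (c.n_trials * 8.0)
        assert c.rate_hz[0] == pytest.approx(expected)

    def test_press_count_conserved(self):
        spec = ScheduleSpec("FI", n_trials=30, fixed_interval_s=12.0,
                            press_rate_profile=0.4)
        s = simulate_event_schedule(spec, seed=4)
        for n_bins in (2, 5, 10):
            c = scallop_curve(s, n_bins)
            bin_dur = 12.0 / n_bins
            assert c.rate_hz.sum() * c.n_trials * bin_dur == pytest.approx(
                c.total_in_interval_presses
            )

    def test_zero_presses_flagged(self):
        s = build_session([dict(ext=0.0), dict(ext=60.0)], schedule="FI",
                          interval=8.0)
        c = scallop_curve(s, 4)
        assert c.all_zero
        np.testing.assert_array_equal(c.rate_hz, 0.0)
        np.testing.assert_array_equal(c.normalized(), 0.0)


class TestLickMetrics:
    CONCS = [0.0, 6.25, 12.5, 25.0, 50.0, 100.0]

    def test_hand_count_completed(self):
        log = simulate_lick_session(30, self.CONCS, p_engage=1.0, seed=0)
        # disengage 6 trials manually
        drop = log.licks["trial_index"].isin([0, 5, 10, 15, 20, 25])
        log.licks = log.licks[~drop]
        m = lick_metrics(log)
        assert m.n_trials_presented == 30
        assert m.n_completed == 24
        assert m.n_incomplete == 6
        assert m.n_completed + m.n_incomplete == m.n_trials_presented

    def test_first_lick_at_onset(self):
        log = simulate_lick_session(12, self.CONCS, p_engage=1.0, seed=1,
                                    first_lick_latency_s=0.0)
        assert lick_metrics(log).latency_first_lick_s == pytest.approx(0.0)

    def test_empty_session(self):
        log = simulate_lick_session(10, self.CONCS, p_engage=0.0, seed=2)
        m = lick_metrics(log)
        assert m.total_licks == 0
        assert np.isnan(m.latency_first_lick_s)

    def test_unlicked_concentration_is_nan_not_zero(self):
        log = simulate_lick_session(30, self.CONCS, p_engage=1.0, seed=3)
        water = log.trials[log.trials.concentration_pct == 0.0]["trial_index"]
        log.licks = log.licks[~log.licks["trial_index"].isin(water)]
        m = lick_metrics(log)
        assert np.isnan(m.licks_by_concentration[0.0])
        assert m.licks_by_concentration[100.0] > 0

    def test_per_concentration_mean_over_completed_only(self):
        log = simulate_lick_session(12, [10.0, 20.0], p_engage=1.0, seed=4)
        m = lick_metrics(log)
        counts = log.licks.groupby("trial_index").size()
        for conc in (10.0, 20.0):
            idx = log.trials[log.trials.concentration_pct == conc]["trial_index"]
            assert m.licks_by_concentration[conc] == pytest.approx(
                counts.loc[idx].mean()
            )


class TestTroughMetrics:
    def test_all_retrieved(self):
        spec = ScheduleSpec("trough", n_trials=30, reward_duration_s=10.0)
        s = simulate_event_schedule(spec, LatencyModel(retrieval_latency_s=1.0),
                                    seed=0)
        assert trough_training_metrics(s) == pytest.approx(100.0)

    def test_late_head_entry_not_counted(self):
        rows = [
            ("dipper_up", 0.0, 0),
            ("dipper_down", 10.0, 0),
            ("head_entry", 11.0, 0),  # dipper already down
        ]
        ev = pd.DataFrame(rows, columns=["event_type", "time_s", "trial_index"])
        s = OperantSession(events=ev, schedule="trough")
        assert trough_training_metrics(s) == pytest.approx(0.0)

    def test_sixty_presentations_supported(self):
        spec = ScheduleSpec("trough", n_trials=60, reward_duration_s=10.0)
        s = simulate_event_schedule(spec, LatencyModel(p_retrieve=0.5), seed=1)
        pct = trough_training_metrics(s)
        assert 0.0 <= pct <= 100.0

    def test_schedule_mismatch(self):
        s = simulate_event_schedule(ScheduleSpec("CRF", n_trials=2), seed=0)
        with pytest.raises(ScheduleMismatchError):
            trough_training_metrics(s)


class TestValidation:
    def test_press_before_extension_rejected(self):
        rows = [
            ("lever_press", 0.5, 0),
            ("lever_extension", 1.0, 0),
        ]
        ev = pd.DataFrame(rows, columns=["event_type", "time_s", "trial_index"])
        with pytest.raises(InvalidParameterError):
            OperantSession(events=ev, schedule="CRF")

    def test_dipper_before_press_rejected(self):
        rows = [
            ("lever_extension", 0.0, 0),
            ("dipper_up", 1.0, 0),
            ("lever_press", 2.0, 0),
        ]
        ev = pd.DataFrame(rows, columns=["event_type", "time_s", "trial_index"])
        with pytest.raises(InvalidParameterError):
            OperantSession(events=ev, schedule="CRF")
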