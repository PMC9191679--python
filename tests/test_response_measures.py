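"""Individual/collective response extraction and time-course aggregates."""

import numpy as np
import pandas as pd
import pytest

from antquorum import response_measures as rm


def traj(times, dists, angle=0.0, nest=(50.0, 50.0)):
    """Straight-ray trajectory at given distances from the nest."""
    times = np.asarray(times, float)
    dists = np.asarray(dists, float)
    return pd.DataFrame(
        {
            "time_s": times,
            "x_mm": nest[0] + dists * np.cos(angle),
            "y_mm": nest[1] + dists * np.sin(angle),
        }
    )


NEST = (50.0, 50.0)
ARENA_C = (50.0, 50.0)


class TestIndividualResponse:
    def test_outside_at_onset_is_missing(self):
        t = np.arange(0, 1000.0)
        tr = traj(t, np.full(t.size, 20.0))
        r = rm.individual_response(tr, NEST, 100.0, 900.0, ARENA_C)
        assert r.b is None and r.latency_s is None

    def test_first_sustained_exit_defines_latency(self):
        # exits at 120 s but returns at 145 s; real response at 200-400 s
        t = np.arange(0.0, 1500.0)
        d = np.full(t.size, 5.0)
        d[(t >= 120) & (t < 145)] = 20.0
        d[(t >= 200) & (t < 400)] = 25.0
        r = rm.individual_response(traj(t, d), NEST, 0.0, 900.0, ARENA_C)
        assert r.b == 1
        assert r.latency_s == pytest.approx(200.0)

    def test_never_leaving_scores_zero(self):
        t = np.arange(0.0, 1000.0)
        r = rm.individual_response(
            traj(t, np.full(t.size, 10.0)), NEST, 0.0, 900.0, ARENA_C
        )
        assert r.b == 0 and r.latency_s is None and r.direction_rad is None

    def test_exit_after_event_end_does_not_count(self):
        t = np.arange(0.0, 2000.0)
        d = np.full(t.size, 5.0)
        d[t >= 1000] = 25.0  # leaves only after the 900 s event
        r = rm.individual_response(traj(t, d), NEST, 0.0, 900.0, ARENA_C)
        assert r.b == 0

    def test_run_shorter_than_30s_not_sustained(self):
        t = np.arange(0.0, 1000.0)
        d = np.full(t.size, 5.0)
        d[(t >= 100) & (t < 125)] = 20.0
        r = rm.individual_response(traj(t, d), NEST, 0.0, 900.0, ARENA_C)
        assert r.b == 0

    def test_direction_relative_to_arena_ray(self):
        # nest left of arena center; exit straight up -> alpha = +pi/2
        nest = (30.0, 50.0)
        t = np.arange(0.0, 600.0)
        d = np.concatenate([np.full(50, 5.0), np.full(550, 25.0)])
        tr = traj(t, d, angle=np.pi / 2, nest=nest)
        r = rm.individual_response(tr, nest, 0.0, 500.0, (50.0, 50.0))
        assert r.b == 1
        assert r.direction_rad == pytest.approx(np.pi / 2, abs=1e-6)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            rm.individual_response(
                traj([], []), NEST, 0.0, 900.0, ARENA_C
            )


def trace(times, f):
    return pd.DataFrame({"time_s": np.asarray(times, float),
                         "f_out": np.asarray(f, float)})


class TestCollectiveResponse:
    def test_sustained_quorum(self):
        t = np.arange(0.0, 900.0)
        r = rm.collective_response(trace(t, np.full(t.size, 0.95)), 0.0, 900.0)
        assert r.B == 1

    def test_short_burst_rejected(self):
        t = np.arange(0.0, 900.0)
        f = np.full(t.size, 0.5)
        f[100:120] = 0.95  # only 20 s above quorum
        r = rm.collective_response(trace(t, f), 0.0, 900.0)
        assert r.B == 0

    def test_boundary_31s_just_above_quorum(self):
        t = np.arange(0.0, 900.0)
        f = np.full(t.size, 0.5)
        f[100:131] = 0.91  # 31 consecutive seconds above 0.9
        r = rm.collective_response(trace(t, f), 0.0, 900.0)
        assert r.B == 1

    def test_quorum_comparison_is_strict(self):
        t = np.arange(0.0, 900.0)
        r = rm.collective_response(trace(t, np.full(t.size, 0.9)), 0.0, 900.0)
        assert r.B == 0

    def test_gap_flagging(self):
        t = np.concatenate([np.arange(0.0, 100.0), np.arange(200.0, 900.0)])
        r = rm.collective_response(trace(t, np.full(t.size, 0.1)), 0.0, 900.0)
        assert r.gap_flagged

    def test_raising_parameters_never_creates_response(self, rng):
        """Monotonicity: a stricter quorum or duration cannot turn B=0
        into B=1 (robustness-sweep property)."""
        t = np.arange(0.0, 900.0)
        for _ in range(20):
            f = np.clip(rng.normal(0.85, 0.15, t.size), 0, 1)
            base = rm.collective_response(trace(t, f), 0.0, 900.0,
                                          quorum=0.85, min_dur_s=20.0).B
            stricter_q = rm.collective_response(trace(t, f), 0.0, 900.0,
                                                quorum=0.95, min_dur_s=20.0).B
            stricter_d = rm.collective_response(trace(t, f), 0.0, 900.0,
                                                quorum=0.85, min_dur_s=60.0).B
            assert stricter_q <= base
            assert stricter_d <= base


def _activity_for_events(events, curves):
    parts = []
    for ev, f in zip(events.itertuples(), curves):
        t = np.arange(0.0, ev.duration_s + 1.0)
        parts.append(pd.DataFrame(
            {"event_id": ev.event_id, "time_s": ev.onset_s + t, "f_out": f(t)}
        ))
    return pd.concat(parts, ignore_index=True)


def _events(temps, B, duration=900.0, spacing=2000.0):
    return pd.DataFrame(
        {
            "event_id": np.arange(len(temps)),
            "onset_s": spacing * (1 + np.arange(len(temps))),
            "duration_s": duration,
            "set_temp_C": temps,
            "B": B,
        }
    )


class TestTimecourseAggregate:
    def test_class_bookkeeping(self):
        temps = [30.0, 34.0, 34.0, 40.0]
        events = _events(temps, B=[0, 1, 0, 1])
        prob = pd.DataFrame({"temperature": [30.0, 34.0, 40.0],
                             "p_hat": [0.05, 0.5, 0.95]})
        act = _activity_for_events(
            events, [lambda t: t * 0 + 0.1] * 4
        )
        curves = rm.timecourse_aggregate(act, events, prob)
        assert set(curves) == {"weak", "intermediate_responded",
                               "intermediate_no_response", "strong"}
        for c in curves.values():
            assert c["n_events"].iloc[0] == 1

    def test_exclusion_rules(self):
        # strong events keep only B=1; weak events keep only B=0
        events = _events([40.0, 40.0, 30.0, 30.0], B=[1, 0, 1, 0])
        prob = pd.DataFrame({"temperature": [30.0, 40.0], "p_hat": [0.01, 0.99]})
        act = _activity_for_events(events, [lambda t: t * 0 + 0.5] * 4)
        with pytest.warns(UserWarning):
            curves = rm.timecourse_aggregate(act, events, prob)
        assert curves["strong"]["n_events"].iloc[0] == 1
        assert curves["weak"]["n_events"].iloc[0] == 1

    def test_empty_class_warns_and_is_omitted(self):
        events = _events([40.0], B=[1])
        prob = pd.DataFrame({"temperature": [40.0], "p_hat": [0.99]})
        act = _activity_for_events(events, [lambda t: t * 0 + 1.0])
        with pytest.warns(UserWarning):
            curves = rm.timecourse_aggregate(act, events, prob)
        assert list(curves) == ["strong"]


class TestStateHistograms:
    def test_constant_trace_equal_medians(self):
        events = _events([34.0, 34.0], B=[1, 0])
        act = _activity_for_events(events, [lambda t: t * 0 + 0.4] * 2)
        sh = rm.state_histograms(act, events)
        assert np.allclose(sh.early, sh.late)

    def test_window_at_event_end_is_valid(self):
        events = _events([34.0], B=[1], duration=900.0)
        act = _activity_for_events(events, [lambda t: t / 900.0])
        sh = rm.state_histograms(act, events, late_window=(840.0, 900.0))
        assert sh.late[0] == pytest.approx(np.median(np.arange(840, 901) / 900))

    def test_window_beyond_event_rejected(self):
        events = _events([34.0], B=[1], duration=600.0)
        act = _activity_for_events(events, [lambda t: t * 0 + 0.5])
        with pytest.raises(ValueError):
            rm.state_histograms(act, events, late_window=(840.0, 900.0))
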