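"""Generator contracts: protocol, determinism, conservation, ground truth."""

import numpy as np
import pandas as pd
import pytest

from antquorum import synthetic_data as sd
from antquorum.pipeline import extract_event_features
from antquorum.response_measures import (
    collective_responses_table,
    individual_responses_table,
)
from antquorum.tracking_features import nest_trace


class TestMakeProtocol:
    def test_full_sweep_spans_thirty_hours(self, rng):
        temps = np.arange(29.0, 44.0)  # 15 perturbations
        sched = sd.make_protocol(temps, rng)
        assert len(sched.events) == 15
        assert sched.events[0].onset_s == 7200.0
        # the perturbation sequence itself spans 15 x 2 h = 30 h
        assert sched.total_duration_s - sched.events[0].onset_s == pytest.approx(
            30 * 3600.0
        )
        assert sorted(ev.set_temp_C for ev in sched.events) == sorted(temps)
        assert all(ev.duration_s == 900.0 for ev in sched.events)

    def test_identical_perturbation_protocol(self, rng):
        sched = sd.make_protocol(np.full(24, 40.0), rng)
        assert len(sched.events) == 24
        assert {ev.set_temp_C for ev in sched.events} == {40.0}

    def test_fixed_seed_reproduces_permutation(self):
        temps = np.arange(29.0, 44.0)
        s1 = sd.make_protocol(temps, np.random.default_rng(7))
        s2 = sd.make_protocol(temps, np.random.default_rng(7))
        assert [e.set_temp_C for e in s1.events] == [e.set_temp_C for e in s2.events]

    def test_empty_temperature_list_rejected(self, rng):
        with pytest.raises(ValueError):
            sd.make_protocol([], rng)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError):
            sd.PerturbationSchedule(
                events=(
                    sd.PerturbationEvent(0, 1000.0, 900.0, 40.0),
                    sd.PerturbationEvent(1, 1500.0, 900.0, 40.0),
                )
            )


def tiny_colony(**kw):
    kw.setdefault("n_ants", 12)
    return sd.ColonyParams(**kw)


class TestGenerateRecording:
    def test_null_protocol_keeps_colony_home(self, rng):
        arena = sd.ArenaSpec(frame_rate=1.0)
        sched = sd.PerturbationSchedule(events=(), interval_s=1800.0)
        colony = tiny_colony(scout_fraction=0.0)
        blobs, ants, gt = sd.generate_recording(arena, sched, colony, rng)
        d = np.hypot(ants["x_mm"] - 30.0, ants["y_mm"] - 30.0)
        # stays within the response circle up to placement tail probability
        assert (d < 15.0).mean() > 0.995

    def test_forced_regime_marks_all_nest_ants_responders(self, rng):
        arena = sd.ArenaSpec(frame_rate=1.0)
        sched = sd.make_protocol([50.0, 50.0], rng, interval_s=1800.0)
        colony = tiny_colony(beta1=5.0, j_p=1.0, j_r=0.01)
        _blobs, _ants, gt = sd.generate_recording(arena, sched, colony, rng)
        for _eid, g in gt.individual.groupby("event_id"):
            in_nest = g[~g["missing"]]
            assert in_nest["responded"].eq(1.0).all()
        assert gt.collective["evacuated"].all()

    def test_ant_conservation_per_frame(self, small_recording):
        ants = small_recording["ants"]
        counts = ants.groupby("time_s")["ant_id"].nunique()
        assert (counts == small_recording["colony"].n_ants).all()
        blobs = small_recording["blobs"]
        per_frame = blobs[blobs["blob_id"] > 0].groupby("time_s")["blob_id"].nunique()
        assert (per_frame == small_recording["colony"].n_ants).all()

    def test_blob_table_invariants(self, small_recording):
        blobs = small_recording["blobs"]
        arena = small_recording["arena"]
        assert (blobs["area_mm2"] > 0).all()
        assert blobs["x_mm"].between(0, arena.width_mm).all()
        assert blobs["y_mm"].between(0, arena.height_mm).all()
        t = blobs["time_s"].to_numpy()
        assert np.all(t[:-1] <= t[1:])

    def test_identical_seed_identical_tables(self):
        arena = sd.ArenaSpec(frame_rate=1.0)
        colony = tiny_colony()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            sched = sd.make_protocol([36.0], rng, interval_s=1800.0)
            blobs, ants, _gt = sd.generate_recording(arena, sched, colony, rng)
            out.append((blobs, ants))
        pd.testing.assert_frame_equal(out[0][0], out[1][0])
        pd.testing.assert_frame_equal(out[0][1], out[1][1])

    def test_ground_truth_threshold_reflects_interactions(self, rng):
        """Stronger inhibition raises the colony's exact threshold."""
        colony_sym = tiny_colony(n_ants=24, scout_fraction=0.0)
        colony_inh = tiny_colony(n_ants=24, scout_fraction=0.0, j_r=0.2)
        th = np.full(24, 34.0) + np.linspace(-2, 2, 24)
        t_sym = sd.true_collective_threshold(th, colony_sym)
        t_inh = sd.true_collective_threshold(th, colony_inh)
        assert t_inh > t_sym


class TestGroundTruthConsistency:
    def test_individual_binary_agreement(self, small_recording):
        """The measurement pipeline recovers the generator's individual
        responses almost exactly (>= 99%)."""
        ants = small_recording["ants"]
        blobs = small_recording["blobs"]
        sched = small_recording["schedule"]
        arena = small_recording["arena"]
        nest = nest_trace(blobs)
        est = individual_responses_table(ants, nest, sched.to_frame(), arena.center)
        m = est.merge(
            small_recording["gt"].individual,
            on=["event_id", "ant_id"],
            suffixes=("_est", "_gt"),
        )
        both_missing = m["b"].isna() & m["responded"].isna()
        agree = (both_missing | (m["b"] == m["responded"])).mean()
        assert agree >= 0.99

    def test_latency_and_direction_agreement(self, small_recording):
        ants = small_recording["ants"]
        blobs = small_recording["blobs"]
        sched = small_recording["schedule"]
        arena = small_recording["arena"]
        nest = nest_trace(blobs)
        est = individual_responses_table(ants, nest, sched.to_frame(), arena.center)
        m = est.merge(
            small_recording["gt"].individual,
            on=["event_id", "ant_id"],
            suffixes=("_est", "_gt"),
        )
        lat = m.dropna(subset=["latency_s_est", "latency_s_gt"])
        assert len(lat) > 50
        assert np.abs(lat["latency_s_est"] - lat["latency_s_gt"]).median() <= 2.0
        dirn = m.dropna(subset=["direction_rad_est", "direction_rad_gt"])
        derr = np.abs(
            np.mod(
                dirn["direction_rad_est"] - dirn["direction_rad_gt"] + np.pi,
                2 * np.pi,
            )
            - np.pi
        )
        assert derr.median() < 0.15

    def test_collective_outcome_agreement(self, small_recording):
        blobs = small_recording["blobs"]
        sched = small_recording["schedule"]
        feats = extract_event_features(blobs, sched.to_frame())
        resp = collective_responses_table(feats.activity, feats.events)
        m = resp.merge(small_recording["gt"].collective, on="event_id")
        assert (m["B"] == m["evacuated"].astype(int)).mean() >= 0.9

    def test_strong_perturbations_always_recovered(self, rng):
        """Identical strong perturbations: pipeline scores a collective
        response for >= 90% of events."""
        arena = sd.ArenaSpec(frame_rate=0.4)
        sched = sd.make_protocol(np.full(24, 40.0), rng, interval_s=2400.0)
        colony = sd.ColonyParams()
        blobs, _, gt = sd.generate_recording(arena, sched, colony, rng, tagged=False)
        feats = extract_event_features(blobs, sched.to_frame())
        resp = collective_responses_table(feats.activity, feats.events)
        assert resp["B"].mean() >= 0.9
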