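"""Individual and collective responses per perturbation event.

An individual ant responds (b=1) to a perturbation when it first exits a
circle of radius 15 mm around the nest (fixed at the event onset) during the
perturbation and stays outside for at least 30 consecutive seconds; its
latency tau is the time from onset to that crossing and its direction alpha
the angle of the crossing point relative to the ray from the nest center to
the arena center. Ants outside the circle at onset are missing values.

The colony responds (B=1) when the activity fraction f_out exceeds a quorum
of 0.9 for at least 30 consecutive seconds during the perturbation; the nest
circle used for f_out is the (smaller) nest radius, not the 15 mm response
circle.

Also provides the event-aligned time-course aggregates by perturbation
strength and the early/late colony-state histograms whose late-time
bimodality is the signature of the slow social feedback stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dip import DipResult, dip_test

__all__ = [
    "IndividualResponse",
    "CollectiveResponse",
    "individual_response",
    "individual_responses_table",
    "collective_response",
    "collective_responses_table",
    "quorum_duration_sweep",
    "timecourse_aggregate",
    "state_histograms",
    "StateHistograms",
]

RESPONSE_RADIUS_MM = 15.0
MIN_OUT_S = 30.0


@dataclass(frozen=True)
class IndividualResponse:
    """b in {0, 1, None}; None marks a missing value (ant outside the
    response circle at onset). latency/direction defined only when b=1."""

    ant_id: int
    event_id: int
    b: int | None
    latency_s: float | None = None
    direction_rad: float | None = None


@dataclass(frozen=True)
class CollectiveResponse:
    event_id: int
    B: int
    quorum_used: float
    min_duration_used: float
    trace: pd.DataFrame | None = None
    gap_flagged: bool = False


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs (stop exclusive)."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts, stops))


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + np.pi) % (2 * np.pi) - np.pi
    if a == -np.pi:
        a = np.pi
    return float(a)


def individual_response(
    trajectory: pd.DataFrame,
    nest_center: tuple[float, float],
    onset_s: float,
    duration_s: float,
    arena_center: tuple[float, float],
    ant_id: int = -1,
    event_id: int = -1,
    radius_mm: float = RESPONSE_RADIUS_MM,
    min_out_s: float = MIN_OUT_S,
) -> IndividualResponse:
    """Individual response of one ant to one perturbation event.

    ``trajectory`` must cover the event window (columns time_s, x_mm, y_mm)
    and should extend at least ``min_out_s`` beyond the event end so that a
    late exit can still be scored as sustained. Sampling is assumed regular;
    a run of k consecutive outside samples at spacing dt counts as k*dt
    seconds outside, and a single-frame re-entry breaks the run.
    """
    t = trajectory["time_s"].to_numpy(dtype=float)
    if t.size == 0:
        raise ValueError("empty trajectory in event window")
    x = trajectory["x_mm"].to_numpy(dtype=float)
    y = trajectory["y_mm"].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    t, x, y = t[order], x[order], y[order]
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0

    dist = np.hypot(x - nest_center[0], y - nest_center[1])
    i0 = int(np.searchsorted(t, onset_s, side="right")) - 1
    if i0 < 0:
        i0 = 0
    if dist[i0] > radius_mm:
        return IndividualResponse(ant_id=ant_id, event_id=event_id, b=None)

    outside = dist > radius_mm
    for start, stop in _runs(outside):
        t_start = t[start]
        if t_start <= onset_s or t_start > onset_s + duration_s:
            continue
        if (stop - start) * dt >= min_out_s:
            vx = x[start] - nest_center[0]
            vy = y[start] - nest_center[1]
            ref = np.arctan2(
                arena_center[1] - nest_center[1], arena_center[0] - nest_center[0]
            )
            alpha = _wrap_angle(np.arctan2(vy, vx) - ref)
            return IndividualResponse(
                ant_id=ant_id,
                event_id=event_id,
                b=1,
                latency_s=float(t_start - onset_s),
                direction_rad=alpha,
            )
    return IndividualResponse(ant_id=ant_id, event_id=event_id, b=0)


def individual_responses_table(
    ants: pd.DataFrame,
    nest: pd.DataFrame,
    events: pd.DataFrame,
    arena_center: tuple[float, float],
    radius_mm: float = RESPONSE_RADIUS_MM,
    min_out_s: float = MIN_OUT_S,
) -> pd.DataFrame:
    """Individual responses for every (ant, event).

    ``ants`` is the tagged trajectory table (time_s, ant_id, x_mm, y_mm),
    ``nest`` the nest-trace table (the estimate at each event's onset is
    used), ``events`` the schedule (event_id, onset_s, duration_s).
    Returns a tidy frame with b as a nullable integer.
    """
    from .tracking_features import nest_at

    t_all = ants["time_s"].to_numpy(dtype=float)
    records = []
    for ev in events.itertuples():
        est = nest_at(nest, ev.onset_s)
        lo = ev.onset_s - 1.0
        hi = ev.onset_s + ev.duration_s + min_out_s + 1.0
        window = ants[(t_all >= lo) & (t_all <= hi)]
        for ant_id, traj in window.groupby("ant_id"):
            r = individual_response(
                traj,
                est.center,
                ev.onset_s,
                ev.duration_s,
                arena_center,
                ant_id=int(ant_id),
                event_id=int(ev.event_id),
                radius_mm=radius_mm,
                min_out_s=min_out_s,
            )
            records.append(
                {
                    "ant_id": r.ant_id,
                    "event_id": r.event_id,
                    "b": np.nan if r.b is None else r.b,
                    "latency_s": np.nan if r.latency_s is None else r.latency_s,
                    "direction_rad": np.nan
                    if r.direction_rad is None
                    else r.direction_rad,
                }
            )
    return pd.DataFrame.from_records(records)


def collective_response(
    trace: pd.DataFrame,
    onset_s: float,
    duration_s: float,
    event_id: int = -1,
    quorum: float = 0.9,
    min_dur_s: float = MIN_OUT_S,
    keep_trace: bool = False,
) -> CollectiveResponse:
    """Binary collective response from the activity trace of one event.

    B=1 iff f_out stays strictly above ``quorum`` for at least ``min_dur_s``
    consecutive seconds within the perturbation window. Sampling gaps longer
    than ``min_dur_s`` inside the window are flagged.
    """
    t = trace["time_s"].to_numpy(dtype=float)
    f = trace["f_out"].to_numpy(dtype=float)
    sel = (t >= onset_s) & (t <= onset_s + duration_s)
    t, f = t[sel], f[sel]
    if t.size == 0:
        raise ValueError("activity trace does not cover the event window")
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    gap_flagged = bool(t.size > 1 and np.max(np.diff(t)) > min_dur_s)
    above = f > quorum
    B = 0
    for start, stop in _runs(above):
        if (stop - start) * dt >= min_dur_s:
            B = 1
            break
    return CollectiveResponse(
        event_id=event_id,
        B=B,
        quorum_used=quorum,
        min_duration_used=min_dur_s,
        trace=trace.loc[sel].reset_index(drop=True) if keep_trace else None,
        gap_flagged=gap_flagged,
    )


def collective_responses_table(
    activity: pd.DataFrame,
    events: pd.DataFrame,
    quorum: float = 0.9,
    min_dur_s: float = MIN_OUT_S,
) -> pd.DataFrame:
    """Collective response per event from a per-event activity table.

    ``activity`` has columns event_id, time_s, f_out (nest circle fixed at
    each event's own onset).
    """
    rows = []
    for ev in events.itertuples():
        tr = activity[activity["event_id"] == ev.event_id]
        cr = collective_response(
            tr, ev.onset_s, ev.duration_s, event_id=int(ev.event_id),
            quorum=quorum, min_dur_s=min_dur_s,
        )
        rows.append(
            {"event_id": cr.event_id, "B": cr.B, "gap_flagged": cr.gap_flagged}
        )
    return pd.DataFrame(rows)


def quorum_duration_sweep(
    activity: pd.DataFrame,
    events: pd.DataFrame,
    quorums=(0.7, 0.8, 0.9, 0.95),
    durations_s=(10.0, 30.0, 60.0),
) -> pd.DataFrame:
    """Robustness grid: collective responses across (quorum, duration)."""
    rows = []
    for q in quorums:
        for d in durations_s:
            tab = collective_responses_table(activity, events, quorum=q, min_dur_s=d)
            rows.append(
                {"quorum": q, "min_dur_s": d, "n_responses": int(tab["B"].sum()),
                 "n_events": len(tab)}
            )
    return pd.DataFrame(rows)


def _aligned(activity: pd.DataFrame, ev) -> pd.DataFrame:
    tr = activity[activity["event_id"] == ev.event_id]
    out = tr.copy()
    out["t_aligned"] = out["time_s"] - ev.onset_s
    return out


def timecourse_aggregate(
    activity: pd.DataFrame,
    events: pd.DataFrame,
    response_prob: pd.DataFrame,
    strong_cut: float = 0.9,
    weak_cut: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """Event-aligned mean activity curves by perturbation-strength class.

    ``events`` must carry event_id, onset_s, duration_s, set_temp_C and B;
    ``response_prob`` maps temperature -> empirical response probability
    (columns temperature, p_hat). Classes: 'strong' (p > strong_cut, only
    B=1 events), 'weak' (p < weak_cut, only B=0 events), and intermediate
    events split into 'intermediate_responded' / 'intermediate_no_response'.
    Empty classes are omitted with a warning.
    """
    pmap = dict(
        zip(response_prob["temperature"].to_numpy(), response_prob["p_hat"].to_numpy())
    )
    groups: dict[str, list[pd.DataFrame]] = {
        "strong": [],
        "intermediate_responded": [],
        "intermediate_no_response": [],
        "weak": [],
    }
    for ev in events.itertuples():
        p = pmap.get(ev.set_temp_C)
        if p is None:
            continue
        if p > strong_cut:
            if ev.B == 1:
                groups["strong"].append(_aligned(activity, ev))
        elif p < weak_cut:
            if ev.B == 0:
                groups["weak"].append(_aligned(activity, ev))
        else:
            key = (
                "intermediate_responded" if ev.B == 1 else "intermediate_no_response"
            )
            groups[key].append(_aligned(activity, ev))
    out: dict[str, pd.DataFrame] = {}
    for name, traces in groups.items():
        if not traces:
            warnings.warn(f"time-course class {name!r} has no events", stacklevel=2)
            continue
        cat = pd.concat(traces)
        g = (
            cat.groupby("t_aligned")["f_out"]
            .agg(["mean", "count"])
            .reset_index()
            .rename(columns={"mean": "f_out_mean", "count": "n_events"})
        )
        out[name] = g
    return out


@dataclass(frozen=True)
class StateHistograms:
    """Per-event medians of the colony state in an early and a late window
    after onset, with dip tests of unimodality for both samples."""

    early: np.ndarray
    late: np.ndarray
    early_dip: DipResult | None
    late_dip: DipResult | None
    early_window: tuple[float, float]
    late_window: tuple[float, float]


def state_histograms(
    activity: pd.DataFrame,
    events: pd.DataFrame,
    early_window: tuple[float, float] = (180.0, 240.0),
    late_window: tuple[float, float] = (840.0, 900.0),
    rng: np.random.Generator | None = None,
    n_boot: int = 1000,
) -> StateHistograms:
    """Distributions of per-event median colony state in two windows.

    Intended for intermediate-strength events (response probability between
    the weak and strong cutoffs): early (3-4 min) the state is continuously
    spread by independent individual responses; late (14-15 min) the social
    feedback has driven it toward 0 or 1 and the distribution turns bimodal.
    Windows are event-relative seconds, right-closed at the event end.
    """
    early_vals, late_vals = [], []
    for ev in events.itertuples():
        tr = _aligned(activity, ev)
        for (w0, w1), acc in ((early_window, early_vals), (late_window, late_vals)):
            if w1 > ev.duration_s:
                raise ValueError(
                    f"window ({w0}, {w1}) extends past event duration {ev.duration_s}"
                )
            m = tr[(tr["t_aligned"] >= w0) & (tr["t_aligned"] <= w1)]["f_out"]
            if len(m):
                acc.append(float(m.median()))
    early = np.asarray(early_vals)
    late = np.asarray(late_vals)
    early_dip = late_dip = None
    if rng is not None:
        early_dip = dip_test(early, rng, n_boot=n_boot)
        late_dip = dip_test(late, rng, n_boot=n_boot)
    return StateHistograms(
        early=early,
        late=late,
        early_dip=early_dip,
        late_dip=late_dip,
        early_window=early_window,
        late_window=late_window,
    )
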