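"""End-to-end measurement pipeline over a blob-table recording.

Chains the feature stage (nest trace, per-event activity with the nest
circle frozen at each onset) with the response stage (collective quorum
response, settling filter) and the psychometric threshold fit. Operates on
the same tabular structure for synthetic and real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .response_measures import collective_responses_table
from .threshold_estimation import (
    ThresholdFit,
    fit_threshold,
    fit_with_ci,
    settling_filter,
)
from .tracking_features import onset_nest_estimate

__all__ = ["EventFeatures", "extract_event_features", "collective_threshold_pipeline"]


@dataclass
class EventFeatures:
    """Per-event activity traces plus the nest estimates used for them."""

    nest_onsets: pd.DataFrame  # event_id, x_mm, y_mm, radius_mm at onset
    activity: pd.DataFrame  # event_id, time_s, f_out
    events: pd.DataFrame  # schedule + pre_activity


def extract_event_features(
    blobs: pd.DataFrame,
    events: pd.DataFrame,
    window_s: float = 600.0,
    pre_window_s: float = 900.0,
) -> EventFeatures:
    """Nest trace and per-event activity fraction.

    For each event the nest center and radius are the trailing-median
    estimates at the perturbation onset; f_out is computed from
    ``pre_window_s`` before onset to the event end, and ``pre_activity`` is
    its mean over the pre-onset window (the settling-filter covariate).
    """
    from .tracking_features import _sorted_frames

    order, _ts, times, starts = _sorted_frames(blobs)
    x = blobs["x_mm"].to_numpy(dtype=float)[order]
    y = blobs["y_mm"].to_numpy(dtype=float)[order]
    a = blobs["area_mm2"].to_numpy(dtype=float)[order]
    starts_ext = np.append(starts, x.size)

    act_parts = []
    pre_vals = []
    nest_rows = []
    for ev in events.itertuples():
        est = onset_nest_estimate(blobs, ev.onset_s, window_s=window_s)
        nest_rows.append(
            {
                "event_id": ev.event_id,
                "x_mm": est.x_mm,
                "y_mm": est.y_mm,
                "radius_mm": est.radius_mm,
            }
        )
        f0 = int(np.searchsorted(times, ev.onset_s - pre_window_s, side="left"))
        f1 = int(np.searchsorted(times, ev.onset_s + ev.duration_s, side="right"))
        lo, hi = starts_ext[f0], starts_ext[f1]
        seg_starts = starts[f0:f1] - lo
        out = (
            np.hypot(x[lo:hi] - est.x_mm, y[lo:hi] - est.y_mm) > est.radius_mm
        )
        aa = a[lo:hi]
        total = np.add.reduceat(aa, seg_starts)
        outside = np.add.reduceat(np.where(out, aa, 0.0), seg_starts)
        tr = pd.DataFrame(
            {
                "event_id": ev.event_id,
                "time_s": times[f0:f1],
                "f_out": outside / total,
            }
        )
        act_parts.append(tr)
        pre = tr["f_out"].to_numpy()[times[f0:f1] < ev.onset_s]
        pre_vals.append(float(pre.mean()) if pre.size else np.nan)
    activity = pd.concat(act_parts, ignore_index=True)
    ev_out = events.copy()
    ev_out["pre_activity"] = pre_vals
    return EventFeatures(
        nest_onsets=pd.DataFrame(nest_rows), activity=activity, events=ev_out
    )


def collective_threshold_pipeline(
    blobs: pd.DataFrame,
    events: pd.DataFrame,
    rng: np.random.Generator | None = None,
    n_bootstrap: int = 1000,
    quorum: float = 0.9,
    min_dur_s: float = 30.0,
    window_s: float = 600.0,
) -> tuple[ThresholdFit, pd.DataFrame, EventFeatures]:
    """Recording -> collective threshold estimate.

    Returns the threshold fit (with a case-resample bootstrap CI when an
    ``rng`` is given), the per-event table (B, pre_activity, included) and
    the intermediate features.
    """
    feats = extract_event_features(blobs, events, window_s=window_s)
    resp = collective_responses_table(
        feats.activity, feats.events, quorum=quorum, min_dur_s=min_dur_s
    )
    ev = feats.events.merge(resp, on="event_id")
    ev = settling_filter(ev)
    kept = ev[ev["included"]]
    t = kept["set_temp_C"].to_numpy()
    B = kept["B"].to_numpy()
    if rng is None:
        fit = fit_threshold(t, B)
    else:
        fit = fit_with_ci(t, B, rng, n_reps=n_bootstrap)
    return fit, ev, feats
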