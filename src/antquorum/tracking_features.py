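"""Nest location, nest radius and colony activity from tracked blob tables.

The tracker output is a per-frame list of blobs (centroid + area), where a
blob may contain one or many ants; blob area is used as a proxy for the
number of ants it contains. The nest center is the per-axis area-weighted
median of blob centroids, smoothed with a trailing 10-min median filter.
The nest radius comes from the "nest blob" -- the large blob representing
the tight aggregation of ants at the nest -- and the activity fraction
f_out(t) is the area fraction of blobs lying outside the nest circle.

Coordinates are millimetres, origin at the arena's lower-left corner,
y upward; distances are Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NestEstimate",
    "weighted_median",
    "weighted_median_location",
    "nest_location_trace",
    "nest_radius",
    "nest_trace",
    "nest_at",
    "activity_fraction",
    "activity_trace",
]


@dataclass(frozen=True)
class NestEstimate:
    """Nest state at one instant: center (mm) and effective radius (mm)."""

    time_s: float
    x_mm: float
    y_mm: float
    radius_mm: float

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_mm, self.y_mm)


def weighted_median(values, weights) -> float:
    """Lower weighted median: the first sorted point whose cumulative weight
    reaches half the total; an exact tie at half is resolved to the midpoint
    with the next point."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    half = 0.5 * cw[-1]
    i = int(np.searchsorted(cw, half, side="left"))
    if cw[i] == half and i + 1 < v.size:
        return float(0.5 * (v[i] + v[i + 1]))
    return float(v[i])


def weighted_median_location(frame: pd.DataFrame) -> tuple[float, float]:
    """Area-weighted median of blob centroids, per axis independently."""
    if len(frame) == 0:
        raise ValueError("frame contains no blobs")
    a = frame["area_mm2"].to_numpy(dtype=float)
    return (
        weighted_median(frame["x_mm"].to_numpy(), a),
        weighted_median(frame["y_mm"].to_numpy(), a),
    )


def _sorted_frames(blobs: pd.DataFrame):
    """Sort the blob table by time and return segment bookkeeping.

    Tables that are already time-sorted (the common case) skip the argsort.
    """
    t = blobs["time_s"].to_numpy(dtype=float)
    if t.size and np.all(t[:-1] <= t[1:]):
        order = slice(None)
    else:
        order = np.argsort(t, kind="stable")
        t = t[order]
    times, starts = np.unique(t, return_index=True)
    return order, t, times, starts


def _segment_weighted_median(val, w, starts) -> np.ndarray:
    """Vectorized per-segment lower weighted median (segments = frames).

    ``val``/``w`` are frame-sorted; within each segment entries are re-sorted
    by value and the cumulative-weight rule applied, entirely with reduceat
    arithmetic (no Python loop over frames).
    """
    n = val.size
    seg_id = np.zeros(n, dtype=np.int64)
    seg_id[starts[1:]] = 1
    seg_id = np.cumsum(seg_id)
    # sort by (segment, value)
    order = np.lexsort((val, seg_id))
    v, wv = val[order], w[order]
    cw = np.cumsum(wv)
    offs = np.concatenate([[0.0], cw[starts[1:] - 1]])
    cw_local = cw - np.repeat(offs, np.diff(np.append(starts, n)))
    totals = np.add.reduceat(wv, starts)
    half = np.repeat(0.5 * totals, np.diff(np.append(starts, n)))
    pos = np.arange(n)
    cand = np.where(cw_local >= half, pos, n)
    first = np.minimum.reduceat(cand, starts)
    res = v[first]
    # exact tie at half the total weight -> midpoint with the next point
    seg_end = np.append(starts[1:], n)
    tie = (cw_local[first] == half[first]) & (first + 1 < seg_end)
    res = np.where(tie, 0.5 * (v[first] + v[np.minimum(first + 1, n - 1)]), res)
    return res


def _trailing_median(times: np.ndarray, values: np.ndarray, window_s: float):
    """Median over the trailing window [t - k, t] (inclusive); shorter
    prefixes use whatever is available."""
    s = pd.Series(values, index=pd.to_timedelta(times, unit="s"))
    out = s.rolling(pd.Timedelta(seconds=window_s), min_periods=1).median()
    return out.to_numpy()


def nest_location_trace(blobs: pd.DataFrame, window_s: float = 600.0) -> pd.DataFrame:
    """Per-frame nest center: area-weighted median location smoothed by a
    trailing median filter of duration ``window_s`` (default 10 min)."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    order, _t, times, starts = _sorted_frames(blobs)
    x = blobs["x_mm"].to_numpy(dtype=float)[order]
    y = blobs["y_mm"].to_numpy(dtype=float)[order]
    a = blobs["area_mm2"].to_numpy(dtype=float)[order]
    wx = _segment_weighted_median(x, a, starts)
    wy = _segment_weighted_median(y, a, starts)
    return pd.DataFrame(
        {
            "time_s": times,
            "x_mm": _trailing_median(times, wx, window_s),
            "y_mm": _trailing_median(times, wy, window_s),
        }
    )


def nest_radius(
    frame: pd.DataFrame, center: tuple[float, float], aspect: float = 1.0
) -> float:
    """Effective nest radius from the nest blob at one frame.

    The nest blob is the blob maximizing an area-over-distance score
    (largest blob nearest the nest center; the score makes ties
    deterministic). With centroid+area data only, the radius is the
    circular-equivalent radius sqrt(area/pi) scaled by ``aspect``; adapters
    with pixel moments may supply the semimajor axis directly instead.
    """
    if len(frame) == 0:
        raise ValueError("frame contains no blobs")
    x = frame["x_mm"].to_numpy(dtype=float)
    y = frame["y_mm"].to_numpy(dtype=float)
    a = frame["area_mm2"].to_numpy(dtype=float)
    d = np.hypot(x - center[0], y - center[1])
    score = a / (d + 1.0)
    i = int(np.argmax(score))
    return float(np.sqrt(a[i] / np.pi) * aspect)


def nest_trace(
    blobs: pd.DataFrame, window_s: float = 600.0, aspect: float = 1.0
) -> pd.DataFrame:
    """Nest center and radius per frame, both median-filtered over the same
    trailing window."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    order, _t, times, starts = _sorted_frames(blobs)
    x = blobs["x_mm"].to_numpy(dtype=float)[order]
    y = blobs["y_mm"].to_numpy(dtype=float)[order]
    a = blobs["area_mm2"].to_numpy(dtype=float)[order]
    wx = _segment_weighted_median(x, a, starts)
    wy = _segment_weighted_median(y, a, starts)
    loc = pd.DataFrame(
        {
            "time_s": times,
            "x_mm": _trailing_median(times, wx, window_s),
            "y_mm": _trailing_median(times, wy, window_s),
        }
    )
    cx = np.repeat(loc["x_mm"].to_numpy(), np.diff(np.append(starts, x.size)))
    cy = np.repeat(loc["y_mm"].to_numpy(), np.diff(np.append(starts, x.size)))
    d = np.hypot(x - cx, y - cy)
    score = a / (d + 1.0)
    # per-frame argmax of the score via a (frame, score) sort
    order2 = np.lexsort((score, np.repeat(np.arange(times.size), np.diff(np.append(starts, x.size)))))
    seg_end = np.append(starts[1:], x.size)
    seg_best = order2[seg_end - 1]
    raw_r = np.sqrt(a[seg_best] / np.pi) * aspect
    loc["radius_mm"] = _trailing_median(times, raw_r, window_s)
    return loc


def onset_nest_estimate(
    blobs: pd.DataFrame, t: float, window_s: float = 600.0, aspect: float = 1.0
) -> NestEstimate:
    """Nest estimate at one instant (e.g. a perturbation onset).

    Same definition as :func:`nest_trace` evaluated at a single time point:
    the median over the trailing window [t - k, t] of the per-frame
    area-weighted median locations and nest-blob radii, but computed only
    on the frames inside that window.
    """
    tt = blobs["time_s"].to_numpy(dtype=float)
    if tt.size and np.all(tt[:-1] <= tt[1:]):
        lo = int(np.searchsorted(tt, t - window_s, side="left"))
        hi = int(np.searchsorted(tt, t, side="right"))
        win = blobs.iloc[lo:hi]
    else:
        win = blobs.loc[(tt >= t - window_s) & (tt <= t)]
    if not len(win):
        raise ValueError(f"no frames in [{t - window_s}, {t}]")
    order, _t, times, starts = _sorted_frames(win)
    x = win["x_mm"].to_numpy(dtype=float)[order]
    y = win["y_mm"].to_numpy(dtype=float)[order]
    a = win["area_mm2"].to_numpy(dtype=float)[order]
    wx = _segment_weighted_median(x, a, starts)
    wy = _segment_weighted_median(y, a, starts)
    cx, cy = float(np.median(wx)), float(np.median(wy))
    counts = np.diff(np.append(starts, x.size))
    d = np.hypot(x - np.repeat(wx, counts), y - np.repeat(wy, counts))
    score = a / (d + 1.0)
    order2 = np.lexsort((score, np.repeat(np.arange(times.size), counts)))
    seg_best = order2[np.append(starts[1:], x.size) - 1]
    radius = float(np.median(np.sqrt(a[seg_best] / np.pi) * aspect))
    return NestEstimate(time_s=t, x_mm=cx, y_mm=cy, radius_mm=radius)


def nest_at(nest: pd.DataFrame, t: float) -> NestEstimate:
    """Nest estimate at (the last frame not after) time t."""
    times = nest["time_s"].to_numpy(dtype=float)
    i = int(np.searchsorted(times, t, side="right")) - 1
    if i < 0:
        raise ValueError(f"no nest estimate at or before t={t}")
    row = nest.iloc[i]
    return NestEstimate(
        time_s=float(row["time_s"]),
        x_mm=float(row["x_mm"]),
        y_mm=float(row["y_mm"]),
        radius_mm=float(row.get("radius_mm", np.nan)),
    )


def activity_fraction(
    frame: pd.DataFrame, center: tuple[float, float], radius: float
) -> float:
    """f_out: area fraction of blobs strictly farther than ``radius`` from
    the nest center (nest center/radius fixed at perturbation onset)."""
    a = frame["area_mm2"].to_numpy(dtype=float)
    total = a.sum()
    if total <= 0:
        raise ValueError("zero total blob area")
    d = np.hypot(
        frame["x_mm"].to_numpy(dtype=float) - center[0],
        frame["y_mm"].to_numpy(dtype=float) - center[1],
    )
    return float(a[d > radius].sum() / total)


def activity_trace(
    blobs: pd.DataFrame,
    center: tuple[float, float],
    radius: float,
    t_start: float | None = None,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Per-frame f_out over [t_start, t_end] with a fixed nest circle."""
    df = blobs
    if t_start is not None or t_end is not None:
        t = df["time_s"].to_numpy(dtype=float)
        lo = -np.inf if t_start is None else t_start
        hi = np.inf if t_end is None else t_end
        df = df[(t >= lo) & (t <= hi)]
    order, _t, times, starts = _sorted_frames(df)
    x = df["x_mm"].to_numpy(dtype=float)[order]
    y = df["y_mm"].to_numpy(dtype=float)[order]
    a = df["area_mm2"].to_numpy(dtype=float)[order]
    out = np.hypot(x - center[0], y - center[1]) > radius
    total = np.add.reduceat(a, starts)
    outside = np.add.reduceat(np.where(out, a, 0.0), starts)
    with np.errstate(invalid="ignore"):
        f = outside / total
    return pd.DataFrame({"time_s": times, "f_out": f})
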