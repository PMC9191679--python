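"""Synthetic colony recordings with known ground truth.

Emulates the tabular output of a video tracker watching an ant colony in a
100 x 100 mm temperature-controlled arena: per-frame blob tables (centroid +
area; one blob per ant plus one merged "nest blob" for the central
aggregation) and tagged per-ant trajectories, driven by a perturbation
schedule of 15-min step-temperature events.

Behavior is generated by the two-stage spin model: at each event the
colony's (fixed) individual thresholds set the stage-1 activation, the
social dynamics then settle to a collective outcome, and the activated ants
physically evacuate along a shared per-event direction (von Mises spread)
with latencies on the fast individual (1-3 min) and slow social (5-10 min)
timescales, returning exponentially to the nest after the event.

Because the generator knows the colony's thresholds, it can compute the
recording's *exact* collective threshold: the temperature at which the
probability of full evacuation (Poisson-binomial stage-1 activation pushed
through the exact stage-2 birth-death absorption) equals 0.5. Every
downstream pipeline stage is validated against this ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from ._logistic import sigmoid
from .spin_model import (
    SpinColony,
    ThresholdDistribution,
    _birth_death_matrix,
    sample_thresholds,
)

__all__ = [
    "ArenaSpec",
    "PerturbationEvent",
    "PerturbationSchedule",
    "ColonyParams",
    "GroundTruth",
    "make_protocol",
    "generate_recording",
]


@dataclass(frozen=True)
class ArenaSpec:
    """Arena geometry and recording parameters."""

    width_mm: float = 100.0
    height_mm: float = 100.0
    frame_rate: float = 1.0  # tracker ran at 10 Hz; rules are in seconds
    baseline_temp_C: float = 26.0

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0 or self.frame_rate <= 0:
            raise ValueError("arena dimensions and frame rate must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_mm / 2.0, self.height_mm / 2.0)


@dataclass(frozen=True)
class PerturbationEvent:
    event_id: int
    onset_s: float
    duration_s: float
    set_temp_C: float


@dataclass(frozen=True)
class PerturbationSchedule:
    """Ordered, non-overlapping step-temperature events."""

    events: tuple[PerturbationEvent, ...]
    interval_s: float = 7200.0
    baseline_temp_C: float = 26.0

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for ev in self.events:
            if ev.duration_s <= 0:
                raise ValueError("event duration must be positive")
            if ev.onset_s < prev_end:
                raise ValueError("events overlap")
            prev_end = ev.onset_s + ev.duration_s

    @property
    def total_duration_s(self) -> float:
        if not self.events:
            return self.interval_s
        return self.events[-1].onset_s + self.interval_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "event_id": ev.event_id,
                    "onset_s": ev.onset_s,
                    "duration_s": ev.duration_s,
                    "set_temp_C": ev.set_temp_C,
                }
                for ev in self.events
            ]
        )


def make_protocol(
    temps,
    rng: np.random.Generator,
    duration_s: float = 900.0,
    interval_s: float = 7200.0,
    permute: bool = True,
    baseline_temp_C: float = 26.0,
) -> PerturbationSchedule:
    """Perturbation schedule: one event per temperature, in randomly
    permuted order, 15-min duration and 2-h spacing by default; the first
    onset falls one interval into the recording."""
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("need at least one perturbation temperature")
    if permute:
        temps = rng.permutation(temps)
    events = tuple(
        PerturbationEvent(
            event_id=i,
            onset_s=interval_s * (i + 1),
            duration_s=duration_s,
            set_temp_C=float(T),
        )
        for i, T in enumerate(temps)
    )
    return PerturbationSchedule(
        events=events, interval_s=interval_s, baseline_temp_C=baseline_temp_C
    )


@dataclass(frozen=True)
class ColonyParams:
    """Colony composition, spin-model parameters, and movement model.

    The defaults are the study conditions: 36 workers nesting as a tight
    Gaussian cluster (SD 5 mm), ~5% scouts roaming the arena, individual
    thresholds Normal(34, 2) degC, symmetric global interactions, fast-stage
    latencies ~Gamma(shape 2, mean 90 s) and slow-stage latencies delayed by
    240 s plus Gamma(shape 2, mean 180 s) (total mean 420 s, mass in the
    4-10 min band so the slow process is not yet visible at 3-4 min),
    shared evacuation direction with von Mises kappa=8 individual spread,
    and exponential return (mean delay 300 s).
    """

    n_ants: int = 36
    theta_m: float = 34.0
    theta_sd: float = 2.0
    beta1: float = 2.0
    beta2: float = 10.0
    j_p: float = 0.1
    j_r: float = 0.1
    alpha_p: float = 1.0
    alpha_r: float = 1.0
    inhibition_mode: str = "state_dependent"
    n_cycles: int = 20
    nest_center: tuple[float, float] = (30.0, 30.0)
    scatter_sd_mm: float = 5.0
    scout_fraction: float = 0.05
    speed_mm_s: float = 5.0
    stage1_latency_mean_s: float = 90.0
    stage2_latency_offset_s: float = 240.0
    stage2_latency_mean_s: float = 180.0  # post-offset; total mean 420 s
    latency_shape: float = 2.0
    # event-level log-normal spread of response timing, shared by all ants
    # in an event; the source of within-event latency coherence
    latency_event_sigma: float = 0.9
    direction_kappa: float = 8.0
    return_delay_mean_s: float = 300.0
    exit_distance_mm: float = 35.0
    ant_area_mm2: float = 2.0
    area_jitter_sd: float = 0.2
    pos_jitter_mm: float = 0.3
    scout_step_mm: float = 3.0

    def spin_colony(self, thresholds: np.ndarray) -> SpinColony:
        return SpinColony(
            thresholds=thresholds,
            beta1=self.beta1,
            beta2=self.beta2,
            j_p=self.j_p,
            j_r=self.j_r,
            alpha_p=self.alpha_p,
            alpha_r=self.alpha_r,
            inhibition_mode=self.inhibition_mode,
        )


@dataclass
class GroundTruth:
    """Generator-side truth for every pipeline quantity."""

    thresholds: np.ndarray
    nest_center: tuple[float, float]
    scout_ids: np.ndarray
    individual: pd.DataFrame  # event_id, ant_id, missing, responded, latency_s, direction_rad
    collective: pd.DataFrame  # event_id, set_temp_C, m_final, n_responders, evacuated
    theta_c_true: float
    params: dict = field(default_factory=dict)


def _truncated_gamma(
    rng: np.random.Generator, shape: float, mean: float, cap: float, size: int
) -> np.ndarray:
    """Gamma(shape, scale=mean/shape) draws conditioned on being < cap."""
    scale = mean / shape
    fcap = gamma_dist.cdf(cap, shape, scale=scale)
    u = rng.random(size) * fcap
    return gamma_dist.ppf(u, shape, scale=scale)


def _poisson_binomial_pmf(p: np.ndarray) -> np.ndarray:
    """PMF of a sum of independent Bernoulli(p_i), by convolution."""
    pmf = np.array([1.0])
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    return pmf


def true_collective_threshold(
    thresholds: np.ndarray, params: ColonyParams
) -> float:
    """Exact collective threshold of a colony with fixed thresholds.

    Temperature at which P(full evacuation) = 0.5, with P computed as the
    Poisson-binomial stage-1 activation distribution pushed through the
    exact stage-2 birth-death absorption into the all-active state.
    """
    theta = np.asarray(thresholds, dtype=float)
    n = theta.size
    colony = params.spin_colony(theta)
    T_mat = _birth_death_matrix(colony)
    M = np.linalg.matrix_power(T_mat, params.n_cycles * n)
    a_full = M[:, n]  # P(all active at the end | k0)

    def p_resp(temp: float) -> float:
        p1 = sigmoid(params.beta1 * (temp - theta))
        return float(_poisson_binomial_pmf(p1) @ a_full) - 0.5

    lo = float(theta.min() - 10.0)
    hi = float(theta.max() + 10.0)
    if p_resp(lo) > 0:  # spontaneous cascade: responds at any temperature
        return float("-inf")
    if p_resp(hi) < 0:  # inhibition dominates: never fully evacuates
        return float("inf")
    return float(brentq(p_resp, lo, hi, xtol=1e-6))


def _scout_walk(
    rng: np.random.Generator,
    n_frames: int,
    n_scouts: int,
    arena: ArenaSpec,
    step_mm: float,
) -> np.ndarray:
    """Reflected Gaussian random walks across the arena, (frames, scouts, 2)."""
    steps = rng.normal(0.0, step_mm, size=(n_frames, n_scouts, 2))
    start = rng.uniform(
        [10.0, 10.0],
        [arena.width_mm - 10.0, arena.height_mm - 10.0],
        size=(n_scouts, 2),
    )
    path = start[None, :, :] + np.cumsum(steps, axis=0)
    lo, hix, hiy = 2.0, arena.width_mm - 2.0, arena.height_mm - 2.0
    for dim, hi in ((0, hix), (1, hiy)):
        span = hi - lo
        x = np.abs(np.mod(path[..., dim] - lo, 2 * span) - span)
        path[..., dim] = lo + np.minimum(x, span)
    return path


def _first_sustained_exit(
    dist: np.ndarray, times: np.ndarray, onset: float, duration: float,
    radius: float, min_out_s: float, dt: float,
) -> tuple[bool, float]:
    """Geometric response rule applied to one generated path (used for
    scouts, whose behavior is not scripted by the spin model)."""
    outside = dist > radius
    padded = np.concatenate([[False], outside, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    for s, e in zip(starts, stops):
        ts = times[s]
        if ts <= onset or ts > onset + duration:
            continue
        if (e - s) * dt >= min_out_s:
            return True, float(ts - onset)
    return False, np.nan


def generate_recording(
    arena: ArenaSpec,
    schedule: PerturbationSchedule,
    colony: ColonyParams,
    rng: np.random.Generator,
    tagged: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None, GroundTruth]:
    """Generate one synthetic recording.

    Returns ``(blobs, ants, ground_truth)``: the untagged blob table
    (time_s, blob_id, x_mm, y_mm, area_mm2; blob_id 0 is the merged nest
    blob, present whenever any ant sits within 2 scatter-SD of the nest),
    the tagged trajectory table (time_s, ant_id, x_mm, y_mm; None when
    ``tagged`` is False), and the generator's ground truth.
    """
    rng_theta, rng_spin, rng_beh, rng_noise = rng.spawn(4)
    n = colony.n_ants
    dt = 1.0 / arena.frame_rate
    n_frames = int(round(schedule.total_duration_s * arena.frame_rate))
    times = np.arange(n_frames) * dt
    nest = np.asarray(colony.nest_center, dtype=float)

    dist_params = ThresholdDistribution(colony.theta_m, colony.theta_sd)
    thresholds = sample_thresholds(dist_params, n, rng_theta)

    n_scouts = int(round(colony.scout_fraction * n))
    scout_ids = rng_beh.choice(n, size=n_scouts, replace=False)
    is_scout = np.zeros(n, dtype=bool)
    is_scout[scout_ids] = True

    offsets = rng_beh.normal(0.0, colony.scatter_sd_mm, size=(n, 2))
    base = nest[None, :] + offsets
    base_dist = np.hypot(offsets[:, 0], offsets[:, 1])
    # spin-model participants: the nest cluster (non-scouts inside the
    # 15 mm response circle)
    participant = (~is_scout) & (base_dist <= 15.0)
    part_idx = np.nonzero(participant)[0]
    n_part = part_idx.size
    spin = colony.spin_colony(thresholds[part_idx])

    # positions: start everyone at their base spot
    pos = np.broadcast_to(base[None, :, :], (n_frames, n, 2)).copy()
    if n_scouts:
        pos[:, scout_ids, :] = _scout_walk(
            rng_beh, n_frames, n_scouts, arena, colony.scout_step_mm
        )

    arena_c = np.asarray(arena.center)
    indiv_rows = []
    coll_rows = []
    for ev in schedule.events:
        T = ev.set_temp_C
        # stage 1: independent thermal activation of the nest cluster
        p1 = sigmoid(colony.beta1 * (T - spin.thresholds))
        active0 = rng_spin.random(n_part) < p1
        # stage 2: social dynamics with per-ant state capture
        final_active, ever_active = _final_states(
            active0, spin, colony.n_cycles, rng_spin
        )
        m_final = final_active.mean() if n_part else 0.0

        ev_end = ev.onset_s + ev.duration_s
        responders_local = np.nonzero(final_active)[0]
        resp_idx = part_idx[responders_local]
        was_stage1 = active0[responders_local]
        n_resp = resp_idx.size
        # transients: excited thermally (stage 1) or recruited briefly
        # during stage 2, but suppressed in the end; they make a
        # sub-response excursion near the nest before relaxing back
        trans_local = np.nonzero((active0 | ever_active) & ~final_active)[0]
        trans_idx = part_idx[trans_local]
        trans_stage1 = active0[trans_local]
        n_trans = trans_idx.size

        # departure latencies: fast individual stage vs slow social stage
        cap = ev.duration_s - 150.0
        lat = np.empty(n_resp)
        lat[was_stage1] = _truncated_gamma(
            rng_beh, colony.latency_shape, colony.stage1_latency_mean_s, cap,
            int(was_stage1.sum()),
        )
        off2 = colony.stage2_latency_offset_s
        lat[~was_stage1] = off2 + _truncated_gamma(
            rng_beh, colony.latency_shape, colony.stage2_latency_mean_s,
            cap - off2, int((~was_stage1).sum()),
        )
        # shared event tempo: slow and fast events, coherent across ants
        sig = colony.latency_event_sigma
        tempo = float(np.exp(rng_beh.normal(-0.5 * sig * sig, sig)))
        lat = np.clip(lat * tempo, 1.0, cap)
        t_dep = ev.onset_s + lat

        # shared evacuation direction with individual von Mises spread
        mu = rng_beh.uniform(-np.pi, np.pi)
        phi = rng_beh.vonmises(mu, colony.direction_kappa, size=n_resp)
        exit_pos = nest[None, :] + colony.exit_distance_mm * np.column_stack(
            [np.cos(phi), np.sin(phi)]
        )
        exit_pos[:, 0] = np.clip(exit_pos[:, 0], 2.0, arena.width_mm - 2.0)
        exit_pos[:, 1] = np.clip(exit_pos[:, 1], 2.0, arena.height_mm - 2.0)

        b0 = base[resp_idx]
        seg = exit_pos - b0
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        seg_len = np.where(seg_len == 0, 1e-9, seg_len)
        u = seg / seg_len[:, None]
        # distance along the path at which the 15 mm circle is crossed
        rel = b0 - nest[None, :]
        bq = np.einsum("ij,ij->i", rel, u)
        cq = np.einsum("ij,ij->i", rel, rel) - 15.0**2
        s_cross = -bq + np.sqrt(np.maximum(bq**2 - cq, 0.0))
        t_cross = t_dep + s_cross / colony.speed_mm_s
        cross_pos = b0 + u * s_cross[:, None]

        # responders return after the event end, with exponential delay
        t_arr = t_dep + seg_len / colony.speed_mm_s
        delay_cap = max(
            schedule.interval_s - ev.duration_s - 900.0 - 60.0, 60.0
        )
        delay = -colony.return_delay_mean_s * np.log1p(
            -rng_beh.random(n_resp)
            * (1.0 - np.exp(-delay_cap / colony.return_delay_mean_s))
        )
        t_ret = np.maximum(ev_end + delay, t_arr)
        t_home = t_ret + seg_len / colony.speed_mm_s

        # transient excursions: departure onto an excited ring between the
        # nest radius and the response circle, relaxing back well before
        # the late-response window (they never cross the 15 mm circle).
        # Thermally excited ants leave on the fast timescale, briefly
        # recruited ones on the slow one.
        r_nest2 = 2.0 * colony.scatter_sd_mm
        tr_lat = np.empty(n_trans)
        tr_lat[trans_stage1] = _truncated_gamma(
            rng_beh, colony.latency_shape, colony.stage1_latency_mean_s, cap,
            int(trans_stage1.sum()),
        )
        tr_lat[~trans_stage1] = colony.stage2_latency_offset_s + _truncated_gamma(
            rng_beh, colony.latency_shape, colony.stage2_latency_mean_s,
            cap - colony.stage2_latency_offset_s, int((~trans_stage1).sum()),
        )
        tr_lat = np.clip(tr_lat * tempo, 1.0, cap)
        tr_dep = ev.onset_s + tr_lat
        tr_phi = rng_beh.uniform(-np.pi, np.pi, size=n_trans)
        tr_r = rng_beh.uniform(r_nest2 + 1.0, 13.5, size=n_trans)
        tr_target = nest[None, :] + tr_r[:, None] * np.column_stack(
            [np.cos(tr_phi), np.sin(tr_phi)]
        )
        tr_b0 = base[trans_idx]
        tr_seg = tr_target - tr_b0
        tr_len = np.maximum(np.hypot(tr_seg[:, 0], tr_seg[:, 1]), 1e-9)
        tr_arr = tr_dep + tr_len / colony.speed_mm_s
        # excitement persists through the fast stage and relaxes on the slow
        # (social-suppression) timescale ...
        excite_s = 180.0 + _truncated_gamma(rng_beh, 2.0, 150.0, 540.0, n_trans)
        # ... but everyone is back before the late-response window and the
        # next settling check
        tr_ret = np.minimum(tr_dep + excite_s, ev.onset_s + 780.0)
        tr_ret = np.maximum(tr_ret, tr_arr)
        tr_home = tr_ret + tr_len / colony.speed_mm_s

        # write the excursions into the position array
        w0 = int(np.searchsorted(times, ev.onset_s))
        w1 = int(np.searchsorted(times, ev.onset_s + schedule.interval_s))
        tw = times[w0:w1]
        with np.errstate(invalid="ignore"):
            p_out = np.clip(
                (tw[:, None] - t_dep[None, :])
                / np.maximum(t_arr - t_dep, 1e-9)[None, :],
                0.0, 1.0,
            )
            p_back = np.clip(
                (tw[:, None] - t_ret[None, :])
                / np.maximum(t_home - t_ret, 1e-9)[None, :],
                0.0, 1.0,
            )
        frac = p_out * (1.0 - p_back)
        pos[w0:w1, resp_idx, :] = b0[None, :, :] + seg[None, :, :] * frac[:, :, None]
        if n_trans:
            with np.errstate(invalid="ignore"):
                q_out = np.clip(
                    (tw[:, None] - tr_dep[None, :])
                    / np.maximum(tr_arr - tr_dep, 1e-9)[None, :],
                    0.0, 1.0,
                )
                q_back = np.clip(
                    (tw[:, None] - tr_ret[None, :])
                    / np.maximum(tr_home - tr_ret, 1e-9)[None, :],
                    0.0, 1.0,
                )
            tr_frac = q_out * (1.0 - q_back)
            pos[w0:w1, trans_idx, :] = (
                tr_b0[None, :, :] + tr_seg[None, :, :] * tr_frac[:, :, None]
            )

        # ground truth bookkeeping
        onset_frame = min(int(np.searchsorted(times, ev.onset_s)), n_frames - 1)
        d_onset = np.hypot(
            pos[onset_frame, :, 0] - nest[0], pos[onset_frame, :, 1] - nest[1]
        )
        missing = d_onset > 15.0
        responded = np.zeros(n, dtype=bool)
        responded[resp_idx] = True
        latency = np.full(n, np.nan)
        latency[resp_idx] = t_cross - ev.onset_s
        ref_angle = np.arctan2(arena_c[1] - nest[1], arena_c[0] - nest[0])
        direction = np.full(n, np.nan)
        raw = np.arctan2(cross_pos[:, 1] - nest[1], cross_pos[:, 0] - nest[0])
        direction[resp_idx] = np.mod(raw - ref_angle + np.pi, 2 * np.pi) - np.pi
        # scouts: score their actual walk with the geometric rule
        for sid in scout_ids:
            if missing[sid]:
                continue
            dwin = np.hypot(
                pos[w0:w1, sid, 0] - nest[0], pos[w0:w1, sid, 1] - nest[1]
            )
            b, tau = _first_sustained_exit(
                dwin, tw, ev.onset_s, ev.duration_s, 15.0, 30.0, dt
            )
            responded[sid] = b
            latency[sid] = tau if b else np.nan

        for i in range(n):
            indiv_rows.append(
                {
                    "event_id": ev.event_id,
                    "ant_id": i,
                    "missing": bool(missing[i]),
                    "responded": (np.nan if missing[i] else float(responded[i])),
                    "latency_s": (np.nan if missing[i] else latency[i]),
                    "direction_rad": (np.nan if missing[i] else direction[i]),
                }
            )
        coll_rows.append(
            {
                "event_id": ev.event_id,
                "set_temp_C": T,
                "m_final": float(m_final),
                "n_responders": int(n_resp),
                "evacuated": bool(n_part > 0 and final_active.all()),
            }
        )

    # measurement noise and blob areas
    pos += rng_noise.normal(0.0, colony.pos_jitter_mm, size=pos.shape)
    pos[..., 0] = np.clip(pos[..., 0], 0.5, arena.width_mm - 0.5)
    pos[..., 1] = np.clip(pos[..., 1], 0.5, arena.height_mm - 0.5)
    sd = colony.area_jitter_sd
    areas = colony.ant_area_mm2 * np.exp(
        rng_noise.normal(-0.5 * sd * sd, sd, size=(n_frames, n))
    )

    # merged nest blob: area proportional to the count of ants within
    # 2 * scatter SD of the nest center, calibrated so that its
    # circular-equivalent radius ~ 2 * scatter SD at full occupancy
    r_nest = 2.0 * colony.scatter_sd_mm
    d_all = np.hypot(pos[..., 0] - nest[0], pos[..., 1] - nest[1])
    n_in = (d_all < r_nest).sum(axis=1)
    a_unit = np.pi * r_nest**2 / n
    nest_area = a_unit * n_in
    nest_xy = nest[None, :] + rng_noise.normal(0.0, 0.3, size=(n_frames, 2))

    # assemble tables, pre-sorted by (time, blob_id): slot 0 of each frame
    # is the nest blob (dropped where empty), slots 1..N the ants
    blob_time = np.repeat(times, n + 1)
    ids = np.tile(np.arange(n + 1), n_frames)
    bx = np.column_stack([nest_xy[:, 0], pos[..., 0]]).ravel()
    by = np.column_stack([nest_xy[:, 1], pos[..., 1]]).ravel()
    ba = np.column_stack([nest_area, areas]).ravel()
    keep = np.ones((n_frames, n + 1), dtype=bool)
    keep[:, 0] = n_in > 0
    keep = keep.ravel()
    blobs = pd.DataFrame(
        {
            "time_s": blob_time[keep],
            "blob_id": ids[keep],
            "x_mm": bx[keep],
            "y_mm": by[keep],
            "area_mm2": ba[keep],
        }
    )
    ants = None
    if tagged:
        ants = pd.DataFrame(
            {
                "time_s": np.repeat(times, n),
                "ant_id": np.tile(np.arange(n), n_frames),
                "x_mm": pos[..., 0].ravel(),
                "y_mm": pos[..., 1].ravel(),
            }
        )

    theta_c = (
        true_collective_threshold(thresholds[part_idx], colony)
        if n_part
        else np.nan
    )
    gt = GroundTruth(
        thresholds=thresholds,
        nest_center=tuple(nest),
        scout_ids=np.sort(scout_ids),
        individual=pd.DataFrame(indiv_rows),
        collective=pd.DataFrame(coll_rows),
        theta_c_true=theta_c,
        params=asdict(colony),
    )
    return blobs, ants, gt


def _final_states(
    active0: np.ndarray,
    spin: SpinColony,
    n_cycles: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-2 dynamics for one chain, with per-ant state capture.

    Returns (final_active, ever_active): the states after the last cycle
    and the set of ants that were active at any point during the run.
    """
    n = active0.size
    if n == 0:
        return active0.copy(), active0.copy()
    active = active0.copy()
    count = int(active.sum())
    from .spin_model import _input_coefficients

    cp, cr = _input_coefficients(spin)
    state_dep = spin.inhibition_mode == "state_dependent"
    mk = np.arange(n + 1) / n
    hk = cp * mk - (cr * (1.0 - mk) if state_dep else cr)
    p_act = sigmoid(spin.beta2 * hk)
    n_steps = n_cycles * n
    picks = rng.integers(0, n, size=n_steps)
    unif = rng.random(n_steps)
    ever = active.copy()
    for s in range(n_steps):
        i = picks[s]
        new = unif[s] < p_act[count]
        count += int(new) - int(active[i])
        active[i] = new
        if new:
            ever[i] = True
    return active, ever
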