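"""Simulation studies of the model and pipeline at their study conditions.

Each function runs one self-contained computational experiment -- the same
experiments the analysis drivers report and the acceptance checks assert on:

* separatrix location of the exact stage-2 chain vs. the analytic formula,
* consistency of the simulated collective threshold with the closed form
  theta_c = theta_m + theta_sd * Phi^-1(m_c),
* group-size scaling of the threshold for asymmetric vs. symmetric
  interaction exponents,
* type-I-error calibration of the permutation collectivity test,
* bootstrap-CI coverage of the end-to-end pipeline on synthetic colonies,
* the early/late bimodality signature of the two-timescale response.
"""

from __future__ import annotations

import numpy as np

from . import spin_model as sm
from . import synthetic_data as sd
from .collectivity_stats import permutation_null
from .pipeline import collective_threshold_pipeline, extract_event_features
from .response_measures import state_histograms
from .threshold_estimation import bootstrap_ci

__all__ = [
    "separatrix_oracle_study",
    "threshold_consistency_study",
    "size_scaling_study",
    "permutation_calibration_study",
    "recovery_coverage_study",
    "timescale_bimodality_study",
]


def separatrix_oracle_study(n_cycles: int = 20) -> dict:
    """Exact absorption analysis of the stage-2 chain for small colonies.

    For every N <= 8 configuration the exact response probability (birth-
    death chain powered over 20 cycles) is scanned over the initial active
    fraction; its 0.5-crossing is compared with the analytic separatrix
    m_c. Deterministic (no sampling).
    """
    configs = [
        (8, 1.0, 1.0),
        (8, 1.0, 2.0),
        (8, 2.0, 1.0),
        (6, 0.5, 1.5),
        (5, 1.0, 1.0),
    ]
    rows = []
    for n, j_p, j_r in configs:
        col = sm.SpinColony(thresholds=np.zeros(n), beta2=50.0, j_p=j_p, j_r=j_r)
        m_c = sm.separatrix(col).m_c
        crossing = sm.exact_separatrix_crossing(col, n_cycles=n_cycles)
        rows.append(
            {
                "n_ants": n,
                "j_p": j_p,
                "j_r": j_r,
                "m_c": m_c,
                "crossing": crossing,
                "abs_error": abs(crossing - m_c),
                "tolerance": 1.0 / n,
            }
        )
    return {
        "configs": rows,
        "max_error_over_tolerance": max(r["abs_error"] / r["tolerance"] for r in rows),
    }


def threshold_consistency_study(
    seed: int,
    n_runs: int = 500,
    n_ants: int = 100,
    n_bootstrap: int = 200,
) -> dict:
    """Simulated collective threshold vs. the analytic prediction.

    Symmetric interactions (m_c = 1/2, threshold = theta_m) and an
    inhibition-dominated case (J_r = 2 J_p, m_c = 2/3). Both betas are
    large: the closed form assumes individual noise small against the
    threshold spread (beta1) and a sharp separatrix (beta2; at moderate
    beta2 the stochastic separatrix solves sigmoid(beta2*h(m)) = m, which
    sits slightly above the h(m)=0 root). The Monte-Carlo SE of the fitted
    threshold comes from a case bootstrap over runs.
    """
    dist = sm.ThresholdDistribution(34.0, 2.0)
    grid = np.arange(29.0, 39.5, 0.5)
    out = {}
    rng = np.random.default_rng(seed)
    for name, j_p, j_r in (("symmetric", 0.1, 0.1), ("asymmetric", 0.1, 0.2)):
        col = sm.SpinColony(thresholds=np.zeros(n_ants), j_p=j_p, j_r=j_r)
        predicted = sm.predict_threshold(sm.separatrix(col).m_c, dist)
        rc = sm.simulate_response_curve(
            dist, n_ants, grid, rng, n_runs=n_runs,
            beta1=10.0, beta2=50.0, j_p=j_p, j_r=j_r, keep_runs=True,
        )
        lo, hi, _deg, _unrel = bootstrap_ci(
            rc.runs["temperature"].to_numpy(),
            rc.runs["responded"].to_numpy(),
            rng,
            n_reps=n_bootstrap,
        )
        se = (hi - lo) / (2 * 1.96)
        out[name] = {
            "simulated": float(rc.fit.theta_c),
            "predicted": float(predicted),
            "mc_se": float(se),
            "abs_error": float(abs(rc.fit.theta_c - predicted)),
        }
    return out


def size_scaling_study(
    seed: int,
    sizes=(10, 20, 50, 100, 200),
    n_runs: int = 200,
    n_bootstrap: int = 100,
) -> dict:
    """Fitted collective threshold across colony sizes.

    Asymmetric exponents (alpha_p=0, alpha_r=1: local excitation, global
    inhibition) produce a rising threshold; equal exponents a flat one.
    beta2 = 50 keeps small colonies in the bistable regime even though the
    saturating excitatory coupling no longer grows with N.
    """
    dist = sm.ThresholdDistribution(34.0, 2.0)
    grid = np.arange(28.0, 42.5, 0.5)
    rng = np.random.default_rng(seed)
    out = {}
    for name, kw in (
        ("asymmetric", dict(alpha_p=0.0, alpha_r=1.0, j_p=1.0, j_r=0.02)),
        ("symmetric", dict(alpha_p=1.0, alpha_r=1.0, j_p=0.1, j_r=0.1)),
    ):
        rows = []
        for n in sizes:
            col = sm.SpinColony(thresholds=np.zeros(n), beta2=50.0, **kw)
            rc = sm.simulate_response_curve(
                dist, n, grid, rng, n_runs=n_runs,
                beta1=10.0, beta2=50.0, keep_runs=True, **kw,
            )
            lo, hi, _d, _u = bootstrap_ci(
                rc.runs["temperature"].to_numpy(),
                rc.runs["responded"].to_numpy(),
                rng,
                n_reps=n_bootstrap,
            )
            rows.append(
                {
                    "n_ants": int(n),
                    "theta_c": float(rc.fit.theta_c),
                    "se": float((hi - lo) / (2 * 1.96)),
                    "predicted": float(
                        sm.predict_threshold(sm.separatrix(col).m_c, dist)
                    ),
                }
            )
        out[name] = rows
    return out


def permutation_calibration_study(
    seed: int,
    n_datasets: int = 1000,
    n_shuffles: int = 999,
    n_ants: int = 36,
    n_events: int = 24,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the collectivity permutation test.

    Independent Bernoulli(1/2) response matrices (no true correlation);
    the rejection rate at nominal ``alpha`` should match ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_datasets):
        M = (rng.random((n_ants, n_events)) < 0.5).astype(float)
        res = permutation_null(M, rng, n_shuffles=n_shuffles)
        if res.exceedances / n_shuffles <= alpha:
            rejections += 1
    return {
        "type_i_rate": rejections / n_datasets,
        "n_datasets": n_datasets,
        "n_shuffles": n_shuffles,
        "alpha": alpha,
    }


def recovery_coverage_study(
    seed: int,
    n_replicates: int = 500,
    n_bootstrap: int = 200,
) -> dict:
    """End-to-end parameter recovery: generate -> features -> measure -> fit.

    Each replicate simulates a fresh 36-ant colony through a 30-event
    variable-amplitude protocol (29-43 degC twice each), runs the full
    measurement pipeline and checks whether the bootstrap CI covers the
    colony's exact generator threshold. Recordings are subsampled to 0.4 Hz
    and events compressed to 40-min spacing (all rules are in seconds).
    """
    root = np.random.default_rng(seed)
    arena = sd.ArenaSpec(frame_rate=0.4)
    colony = sd.ColonyParams()
    temps = np.repeat(np.arange(29.0, 44.0), 2)
    covered = 0
    n_valid = 0
    errors = []
    for child in root.spawn(n_replicates):
        sched = sd.make_protocol(temps, child, interval_s=2400.0)
        blobs, _ants, gt = sd.generate_recording(
            arena, sched, colony, child, tagged=False
        )
        fit, _ev, _feats = collective_threshold_pipeline(
            blobs, sched.to_frame(), child, n_bootstrap=n_bootstrap
        )
        n_valid += 1
        errors.append(abs(fit.theta_c - gt.theta_c_true))
        if (
            np.isfinite(fit.ci_low)
            and fit.ci_low <= gt.theta_c_true <= fit.ci_high
        ):
            covered += 1
    return {
        "coverage": covered / n_valid,
        "n_replicates": n_valid,
        "n_bootstrap": n_bootstrap,
        "mean_abs_error": float(np.mean(errors)),
    }


def timescale_bimodality_study(
    seed: int,
    n_colonies: int = 10,
    n_boot: int = 1000,
) -> dict:
    """Early vs. late colony-state distributions at intermediate strength.

    Replicate colonies (10, as in the pooled threshold experiment) each run
    the standard variable-amplitude protocol (29-43 degC, two events per
    temperature). The pooled events give a logistic response curve; events
    at temperatures whose fitted response probability lies in (0.1, 0.9)
    form the intermediate class, mirroring the experimental selection. For
    those events the early-window (3-4 min) per-event medians form a
    continuum while the late-window (14-15 min) medians split toward the
    collective fixed points.
    """
    import pandas as pd

    from .response_measures import collective_responses_table
    from .threshold_estimation import fit_threshold

    root = np.random.default_rng(seed)
    arena = sd.ArenaSpec(frame_rate=0.4)
    colony = sd.ColonyParams()
    temps = np.repeat(np.arange(29.0, 44.0), 2)
    acts, evs = [], []
    offset = 0
    for child in root.spawn(n_colonies):
        sched = sd.make_protocol(temps, child, interval_s=2400.0)
        blobs, _ants, _gt = sd.generate_recording(
            arena, sched, colony, child, tagged=False
        )
        feats = extract_event_features(blobs, sched.to_frame())
        resp = collective_responses_table(feats.activity, feats.events)
        ev = feats.events.merge(resp, on="event_id")
        act = feats.activity.copy()
        # re-key event ids so pooled colonies stay distinct
        ev = ev.copy()
        ev["event_id"] += offset
        act["event_id"] += offset
        offset += len(ev)
        acts.append(act)
        evs.append(ev)
    activity = pd.concat(acts, ignore_index=True)
    events = pd.concat(evs, ignore_index=True)
    fit = fit_threshold(events["set_temp_C"].to_numpy(), events["B"].to_numpy())
    p_fit = fit.predict(events["set_temp_C"].to_numpy())
    inter = events[(p_fit > 0.1) & (p_fit < 0.9)]
    rng = np.random.default_rng(seed + 1)
    sh = state_histograms(
        activity[activity["event_id"].isin(inter["event_id"])], inter,
        rng=rng, n_boot=n_boot,
    )
    return {
        "early_dip": sh.early_dip.dip,
        "early_p": sh.early_dip.p_value,
        "late_dip": sh.late_dip.dip,
        "late_p": sh.late_dip.p_value,
        "n_events": int(len(inter)),
        "n_responded": int(inter["B"].sum()),
    }
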