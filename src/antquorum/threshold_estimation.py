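"""Psychometric estimation of the collective response threshold.

The colony's binary collective responses B over a set of step-temperature
perturbation events trace out a sigmoidal response curve. The collective
threshold theta_c is the temperature at which the fitted logistic response
probability equals 0.5 (theta_c = -b0/b1 for logit P = b0 + b1*T).

Includes the settling filter (exclude events whose pre-onset activity
exceeds twice the across-event median), the case-resample bootstrap CI for
theta_c, and the group-size covariate model (logistic regression with
temperature and group size as independent variables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._logistic import logit_irls, sigmoid

__all__ = [
    "ThresholdFit",
    "GroupSizeResult",
    "settling_filter",
    "fit_threshold",
    "response_curve_table",
    "bootstrap_ci",
    "fit_with_ci",
    "group_size_model",
]


@dataclass(frozen=True)
class ThresholdFit:
    """Logistic threshold fit: logit P(B=1) = intercept + slope * T."""

    intercept: float
    slope: float
    theta_c: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_events: int = 0
    n_bootstrap: int = 0
    separated: bool = False
    converged: bool = True
    ci_unreliable: bool = False

    def predict(self, temperature) -> np.ndarray:
        return sigmoid(self.intercept + self.slope * np.asarray(temperature, float))


def settling_filter(
    events: pd.DataFrame, pre_activity_col: str = "pre_activity"
) -> pd.DataFrame:
    """Mark events where the colony had not settled before onset.

    An event is retained when its mean pre-onset activity is strictly lower
    than twice the median of that quantity across *all* events of the
    experiment (median computed once, over the unfiltered set). Returns a
    copy with a boolean ``included`` column.
    """
    out = events.copy()
    pre = out[pre_activity_col].to_numpy(dtype=float)
    med = float(np.median(pre))
    if med == 0.0:
        warnings.warn(
            "median pre-onset activity is zero; settling filter keeps nothing "
            "under the strict inequality -- retaining all events",
            stacklevel=2,
        )
        out["included"] = True
        return out
    out["included"] = pre < 2.0 * med
    return out


def _check_fittable(temps: np.ndarray, resp: np.ndarray) -> None:
    if temps.size != resp.size:
        raise ValueError("temperature and response vectors differ in length")
    if temps.size < 2:
        raise ValueError("need at least two events")
    if np.unique(temps).size < 2:
        raise ValueError("need at least two distinct temperatures")
    if resp.min() == resp.max():
        raise ValueError("both response classes must be present")


def _separated(temps: np.ndarray, resp: np.ndarray) -> bool:
    return float(temps[resp == 1].min()) > float(temps[resp == 0].max())


def fit_threshold(temperatures, responses) -> ThresholdFit:
    """Maximum-likelihood logistic fit of B on temperature.

    Under complete separation the MLE does not exist; the fit is flagged and
    theta_c falls back to the midpoint between the highest all-0 and lowest
    all-1 temperatures, with an infinite-slope marker.
    """
    temps = np.asarray(temperatures, dtype=float)
    resp = np.asarray(responses, dtype=float)
    _check_fittable(temps, resp)
    if _separated(temps, resp):
        lo = temps[resp == 0].max()
        hi = temps[resp == 1].min()
        theta = 0.5 * (lo + hi)
        return ThresholdFit(
            intercept=-np.inf,
            slope=np.inf,
            theta_c=float(theta),
            n_events=temps.size,
            separated=True,
        )
    X = np.column_stack([np.ones_like(temps), temps])
    beta, _cov, converged = logit_irls(X, resp)
    theta = -beta[0] / beta[1] if beta[1] != 0 else np.nan
    return ThresholdFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        theta_c=float(theta),
        n_events=temps.size,
        converged=bool(converged),
    )


def response_curve_table(temperatures, responses) -> pd.DataFrame:
    """Per-temperature empirical response probability with its 95% band.

    The band is the asymptotic normal approximation for a binomial
    proportion, p_hat +/- 1.96*sqrt(p_hat*(1-p_hat)/n), clipped to [0, 1].
    """
    df = pd.DataFrame(
        {"temperature": np.asarray(temperatures, float), "B": np.asarray(responses, float)}
    )
    g = df.groupby("temperature")["B"].agg(["mean", "count"]).reset_index()
    p, n = g["mean"].to_numpy(), g["count"].to_numpy()
    se = np.sqrt(p * (1 - p) / n)
    g = g.rename(columns={"mean": "p_hat", "count": "n"})
    g["band_low"] = np.clip(p - 1.96 * se, 0, 1)
    g["band_high"] = np.clip(p + 1.96 * se, 0, 1)
    return g


def bootstrap_ci(
    temperatures,
    responses,
    rng: np.random.Generator,
    n_reps: int = 1000,
    ci_level: float = 0.95,
) -> tuple[float, float, int, bool]:
    """Case-resample bootstrap percentile CI for theta_c.

    Events (cases) are resampled with replacement and the threshold refit on
    each replicate; replicates where only one response class (or a single
    temperature) is drawn are dropped and counted. Returns
    (ci_low, ci_high, n_degenerate, unreliable).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    temps = np.asarray(temperatures, dtype=float)
    resp = np.asarray(responses, dtype=float)
    _check_fittable(temps, resp)
    n = temps.size
    estimates = []
    n_degenerate = 0
    idx_matrix = rng.integers(0, n, size=(n_reps, n))
    for idx in idx_matrix:
        t, r = temps[idx], resp[idx]
        if r.min() == r.max() or np.unique(t).size < 2:
            n_degenerate += 1
            continue
        estimates.append(fit_threshold(t, r).theta_c)
    unreliable = n_degenerate > n_reps // 2
    if not estimates:
        return np.nan, np.nan, n_degenerate, True
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(estimates, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi), n_degenerate, unreliable


def fit_with_ci(
    temperatures,
    responses,
    rng: np.random.Generator,
    n_reps: int = 1000,
) -> ThresholdFit:
    """Threshold fit plus case-resample bootstrap CI in one call."""
    fit = fit_threshold(temperatures, responses)
    lo, hi, _n_deg, unreliable = bootstrap_ci(
        temperatures, responses, rng, n_reps=n_reps
    )
    return ThresholdFit(
        intercept=fit.intercept,
        slope=fit.slope,
        theta_c=fit.theta_c,
        ci_low=lo,
        ci_high=hi,
        n_events=fit.n_events,
        n_bootstrap=n_reps,
        separated=fit.separated,
        converged=fit.converged,
        ci_unreliable=unreliable,
    )


@dataclass(frozen=True)
class GroupSizeResult:
    """Per-size threshold fits plus the pooled temperature+size model."""

    per_size: dict  # group size -> ThresholdFit or None (one response class)
    size_coefficient: float
    size_ci_low: float
    size_ci_high: float
    temperature_coefficient: float
    intercept: float


def group_size_model(events: pd.DataFrame) -> GroupSizeResult:
    """Group-size dependence of the collective threshold.

    ``events`` needs columns ``group_size``, ``set_temp_C`` and ``B``.
    Fits a per-size logistic threshold (None where only one response class
    was observed) and a pooled logistic regression with temperature and
    group size as the independent variables; the size coefficient's 95% CI
    is the Wald interval.
    """
    sizes = np.sort(events["group_size"].unique())
    if sizes.size < 2:
        raise ValueError("need at least two group sizes")
    per_size: dict = {}
    for s in sizes:
        sub = events[events["group_size"] == s]
        try:
            per_size[int(s)] = fit_threshold(
                sub["set_temp_C"].to_numpy(), sub["B"].to_numpy()
            )
        except ValueError:
            per_size[int(s)] = None
    t = events["set_temp_C"].to_numpy(dtype=float)
    gsz = events["group_size"].to_numpy(dtype=float)
    y = events["B"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(t), t, gsz])
    beta, cov, _converged = logit_irls(X, y)
    se = float(np.sqrt(cov[2, 2]))
    return GroupSizeResult(
        per_size=per_size,
        size_coefficient=float(beta[2]),
        size_ci_low=float(beta[2] - 1.96 * se),
        size_ci_high=float(beta[2] + 1.96 * se),
        temperature_coefficient=float(beta[1]),
        intercept=float(beta[0]),
    )
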