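"""Two-stage binary network model of the colony response.

Each ant i is a spin sigma_i in {-1, +1} (+1 = "perturbed"/active, -1 =
"relaxed"). Activation is probabilistic through a logistic function
P(sigma_i=+1) = 1/(1+exp(-beta*h_i)). The dynamics are split into two stages
separated by timescale:

* stage 1 -- each ant responds independently to the external temperature,
  h_i = T - theta_i, with theta_i drawn from Normal(theta_m, theta_sd);
* stage 2 -- temperature is ignored and the ants interact through a
  mean-field input common to all ants,

      h(m) = N**alpha_p * J_p * m  -  N**alpha_r * J_r * (1 - m)

  (state-dependent inhibition) or, with a state-independent nest-attraction
  term, h(m) = N**alpha_p * J_p * m - N**alpha_r * J_r.  m is the order
  parameter, the fraction of active ants.

For sufficiently deterministic ants (large beta) the stage-2 dynamics are
bistable with stable fixed points at m=0 and m=1 and a separatrix at a
critical initial fraction m_c; the collective temperature threshold is then
the temperature at which stage 1 activates a fraction m_c of the colony,
i.e. theta_c = theta_m + theta_sd * Phi^-1(m_c).  Unequal size-scaling
exponents (alpha_r > alpha_p) make m_c, and hence the collective threshold,
grow with colony size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from ._logistic import sigmoid

__all__ = [
    "ThresholdDistribution",
    "SpinColony",
    "SimulationRun",
    "Separatrix",
    "ResponseCurve",
    "sample_thresholds",
    "activation_probability",
    "stage1_response",
    "social_input",
    "stage2_dynamics",
    "separatrix",
    "predict_threshold",
    "simulate_response_curve",
    "exact_response_probabilities",
    "exact_separatrix_crossing",
]

STATE_DEPENDENT = "state_dependent"
STATE_INDEPENDENT = "state_independent"


@dataclass(frozen=True)
class ThresholdDistribution:
    """Normal distribution of individual thermal thresholds (deg C)."""

    theta_m: float = 34.0
    theta_sd: float = 2.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta_m):
            raise ValueError("theta_m must be finite")
        if not (self.theta_sd >= 0.0):
            raise ValueError("theta_sd must be >= 0")


@dataclass
class SpinColony:
    """Model state: per-ant thresholds, interaction parameters, spin vector.

    ``beta1`` is the stage-1 determinism (1/degC); ``beta2`` the stage-2
    determinism (1/input-unit). ``states`` holds sigma_i in {-1, +1} and is
    initialized to the all-relaxed state.
    """

    thresholds: np.ndarray
    beta1: float = 2.0
    beta2: float = 10.0
    j_p: float = 0.1
    j_r: float = 0.1
    alpha_p: float = 1.0
    alpha_r: float = 1.0
    inhibition_mode: str = STATE_DEPENDENT
    states: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim != 1 or self.thresholds.size < 1:
            raise ValueError("thresholds must be a nonempty 1-d vector")
        for name in ("beta1", "beta2", "j_p", "j_r"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.inhibition_mode not in (STATE_DEPENDENT, STATE_INDEPENDENT):
            raise ValueError(f"unknown inhibition_mode {self.inhibition_mode!r}")
        if self.states is None:
            self.states = np.full(self.thresholds.size, -1, dtype=np.int8)
        else:
            self.states = np.asarray(self.states, dtype=np.int8)
            if self.states.shape != self.thresholds.shape:
                raise ValueError("states and thresholds must have equal length")
            if not np.all(np.abs(self.states) == 1):
                raise ValueError("states must be -1 or +1")

    @property
    def n_ants(self) -> int:
        return int(self.thresholds.size)

    @property
    def order_parameter(self) -> float:
        """m = (1/2N) * sum(sigma_i + 1): the fraction of active ants."""
        return float(np.sum(self.states + 1) / (2 * self.n_ants))


@dataclass(frozen=True)
class SimulationRun:
    """Outcome of one stage-2 run: m recorded once per update cycle.

    ``m_trajectory[0]`` is the post-stage-1 state (cycle 0); ``responded``
    scores the run by whether the final order parameter reached 0.5.
    """

    m_trajectory: np.ndarray
    m0: float
    final_m: float
    responded: bool


@dataclass(frozen=True)
class Separatrix:
    """Critical initial active fraction m_c; ``valid`` is False when no
    active fixed point exists (state-independent inhibition too strong)."""

    m_c: float
    valid: bool = True


def sample_thresholds(
    dist: ThresholdDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n individual thresholds from Normal(theta_m, theta_sd).

    No truncation or clipping is applied; at realistic parameters negative
    draws have negligible probability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.normal(dist.theta_m, dist.theta_sd, size=int(n))


def activation_probability(h, beta: float):
    """Logistic activation P(sigma=+1) = 1/(1+exp(-beta*h)).

    Evaluated in a numerically stable form; saturates to 0/1 for large
    |beta*h| instead of overflowing.
    """
    return sigmoid(beta * np.asarray(h, dtype=float))


def stage1_response(
    colony: SpinColony, temperature: float, rng: np.random.Generator
) -> tuple[SpinColony, float]:
    """Independent individual responses to temperature (h_i = T - theta_i).

    Returns a new colony with updated states and the resulting order
    parameter m0. The input colony is expected in the all-relaxed state.
    """
    p = activation_probability(temperature - colony.thresholds, colony.beta1)
    active = rng.random(colony.n_ants) < p
    states = np.where(active, 1, -1).astype(np.int8)
    out = replace(colony, states=states)
    return out, out.order_parameter


def _input_coefficients(colony: SpinColony) -> tuple[float, float]:
    n = colony.n_ants
    return n**colony.alpha_p * colony.j_p, n**colony.alpha_r * colony.j_r


def social_input(m, colony: SpinColony):
    """Mean-field stage-2 input h(m) for the colony's interaction mode."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("order parameter m must lie in [0, 1]")
    cp, cr = _input_coefficients(colony)
    if colony.inhibition_mode == STATE_DEPENDENT:
        h = cp * m - cr * (1.0 - m)
    else:
        h = cp * m - cr
    if h.ndim == 0:
        return float(h)
    return h


def _batch_stage2(
    active0: np.ndarray,
    colony: SpinColony,
    n_cycles: int,
    rng: np.random.Generator,
    update: str = "random",
) -> np.ndarray:
    """Asynchronous stage-2 dynamics for many chains at once.

    ``active0`` is a (chains, N) boolean matrix of post-stage-1 states.
    Returns the (chains, n_cycles+1) matrix of order parameters recorded
    after every full update cycle (N single-ant updates).
    """
    active = np.ascontiguousarray(active0, dtype=bool).copy()
    n_chains, n = active.shape
    counts = active.sum(axis=1).astype(np.int64)
    cp, cr = _input_coefficients(colony)
    state_dep = colony.inhibition_mode == STATE_DEPENDENT
    beta2 = colony.beta2
    m_traj = np.empty((n_chains, n_cycles + 1))
    m_traj[:, 0] = counts / n
    rows = np.arange(n_chains)
    for cycle in range(n_cycles):
        if update == "permutation":
            order = np.argsort(rng.random((n_chains, n)), axis=1)
        for step in range(n):
            if update == "permutation":
                idx = order[:, step]
            else:
                idx = rng.integers(0, n, size=n_chains)
            m = counts / n
            h = cp * m - (cr * (1.0 - m) if state_dep else cr)
            p = sigmoid(beta2 * h)
            new = rng.random(n_chains) < p
            old = active[rows, idx]
            counts += new.astype(np.int64) - old.astype(np.int64)
            active[rows, idx] = new
        m_traj[:, cycle + 1] = counts / n
    return m_traj


def stage2_dynamics(
    colony: SpinColony,
    n_cycles: int = 20,
    rng: np.random.Generator | None = None,
    update: str = "random",
) -> SimulationRun:
    """Run the asynchronous social dynamics for ``n_cycles`` update cycles.

    One cycle = N single-ant updates; with ``update='random'`` the updating
    ant is drawn uniformly with replacement (Glauber-style), with
    ``update='permutation'`` each cycle updates every ant once in random
    order. m is recorded after each cycle; the run counts as a collective
    response when the final m reaches 0.5.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    active0 = (colony.states == 1)[None, :]
    m_traj = _batch_stage2(active0, colony, n_cycles, rng, update=update)[0]
    return SimulationRun(
        m_trajectory=m_traj,
        m0=float(m_traj[0]),
        final_m=float(m_traj[-1]),
        responded=bool(m_traj[-1] >= 0.5),
    )


def separatrix(colony: SpinColony) -> Separatrix:
    """Critical initial fraction m_c separating the basins of m=0 and m=1.

    State-dependent: m_c = N^ar*Jr / (N^ap*Jp + N^ar*Jr).
    State-independent: the unstable fixed point sits at
    m_c = N^(ar-ap)*Jr/Jp; when that exceeds 1 no active fixed point
    exists and the colony cannot respond (``valid`` is False).
    """
    cp, cr = _input_coefficients(colony)
    if cp + cr == 0:
        raise ValueError("separatrix undefined when j_p = j_r = 0")
    if colony.inhibition_mode == STATE_DEPENDENT:
        return Separatrix(m_c=cr / (cp + cr), valid=True)
    if cp == 0:
        return Separatrix(m_c=np.inf, valid=False)
    m_c = cr / cp
    return Separatrix(m_c=float(m_c), valid=bool(m_c < 1.0))


def predict_threshold(m_c: float, dist: ThresholdDistribution) -> float:
    """Collective threshold from the condition P(theta_i < theta_c) = m_c.

    theta_c = theta_m + theta_sd * Phi^-1(m_c); valid in the regime where
    individual noise is small relative to the threshold spread.
    """
    if not (0.0 < m_c < 1.0):
        raise ValueError("m_c must lie strictly in (0, 1)")
    return float(dist.theta_m + dist.theta_sd * norm.ppf(m_c))


@dataclass(frozen=True)
class ResponseCurve:
    """Simulated psychometric curve and its logistic threshold fit."""

    temperatures: np.ndarray
    response_prob: np.ndarray
    n_runs: int
    fit: object | None  # ThresholdFit; None when degenerate
    degenerate: bool
    runs: "object" = None  # tidy per-run DataFrame (optional)


def simulate_response_curve(
    dist: ThresholdDistribution,
    n_ants: int,
    temperatures: np.ndarray,
    rng: np.random.Generator,
    n_runs: int = 100,
    n_cycles: int = 20,
    keep_runs: bool = False,
    **colony_kwargs,
) -> ResponseCurve:
    """Collective response probability vs. temperature, plus threshold fit.

    For every temperature, ``n_runs`` independent runs are simulated; each
    run samples a fresh set of individual thresholds, applies stage 1 at
    that temperature, and relaxes through stage 2. The collective threshold
    is extracted with the same logistic fit used on experimental event data.
    """
    from .threshold_estimation import fit_threshold  # local: avoid cycle

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    temperatures = np.asarray(temperatures, dtype=float)
    rng_theta, rng_s1, rng_s2 = rng.spawn(3)
    n_temp = temperatures.size
    chains = n_temp * n_runs
    temp_per_chain = np.repeat(temperatures, n_runs)
    thresholds = rng_theta.normal(dist.theta_m, dist.theta_sd, size=(chains, n_ants))
    colony = SpinColony(thresholds=np.zeros(n_ants), **colony_kwargs)
    p1 = sigmoid(colony.beta1 * (temp_per_chain[:, None] - thresholds))
    active0 = rng_s1.random((chains, n_ants)) < p1
    m_traj = _batch_stage2(active0, colony, n_cycles, rng_s2)
    responded = m_traj[:, -1] >= 0.5
    prob = responded.reshape(n_temp, n_runs).mean(axis=1)

    degenerate = bool(np.all(responded) or not np.any(responded))
    fit = None
    if not degenerate:
        fit = fit_threshold(temp_per_chain, responded.astype(int))
    runs = None
    if keep_runs:
        import pandas as pd

        runs = pd.DataFrame(
            {
                "temperature": temp_per_chain,
                "n_ants": n_ants,
                "run_id": np.tile(np.arange(n_runs), n_temp),
                "m0": m_traj[:, 0],
                "final_m": m_traj[:, -1],
                "responded": responded.astype(int),
            }
        )
    return ResponseCurve(
        temperatures=temperatures,
        response_prob=prob,
        n_runs=n_runs,
        fit=fit,
        degenerate=degenerate,
        runs=runs,
    )


# -- exact (matrix) analysis of the stage-2 chain ---------------------------
#
# Stage 2 is threshold-free: the input h depends on the states only through
# the active count k, so the asynchronous dynamics reduce to a birth-death
# chain on k in {0..N}. This gives exact finite-time response probabilities
# used as the oracle for the separatrix analysis.


def _birth_death_matrix(colony: SpinColony) -> np.ndarray:
    n = colony.n_ants
    k = np.arange(n + 1)
    m = k / n
    cp, cr = _input_coefficients(colony)
    if colony.inhibition_mode == STATE_DEPENDENT:
        h = cp * m - cr * (1.0 - m)
    else:
        h = cp * m - cr
    p_act = sigmoid(colony.beta2 * h)
    up = (1.0 - m) * p_act
    down = m * (1.0 - p_act)
    T = np.zeros((n + 1, n + 1))
    T[k[:-1], k[:-1] + 1] = up[:-1]
    T[k[1:], k[1:] - 1] = down[1:]
    T[k, k] = 1.0 - up - down
    return T


def exact_response_probabilities(
    colony: SpinColony, n_cycles: int = 20
) -> np.ndarray:
    """P(final m >= 0.5 | k0 active after stage 1), for k0 = 0..N, exactly.

    Computed by powering the (N+1)-state birth-death transition matrix over
    n_cycles*N single-ant updates.
    """
    n = colony.n_ants
    T = _birth_death_matrix(colony)
    M = np.linalg.matrix_power(T, n_cycles * n)
    k_resp = int(np.ceil(n / 2))  # final_m >= 0.5
    return M[:, k_resp:].sum(axis=1)


def exact_separatrix_crossing(colony: SpinColony, n_cycles: int = 20) -> float:
    """Smallest initial fraction k0/N whose exact response probability
    reaches 0.5; compare with the analytic separatrix m_c."""
    probs = exact_response_probabilities(colony, n_cycles)
    idx = np.nonzero(probs >= 0.5)[0]
    if idx.size == 0:
        return float("nan")
    return float(idx[0] / colony.n_ants)
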