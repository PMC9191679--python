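"""Coordination statistics: pairwise response correlations + permutation null.

A colony's responses to a sequence of identical perturbations form an
ants x events matrix for each measure (binary response b, latency tau,
direction alpha), with missing entries where an ant was already outside the
nest circle at onset. Coordination is quantified by the Pearson correlation
between every pair of ants across events (pairwise-complete over the
non-missing events; the direction measure is treated linearly, which is
adequate because per-event directions are narrowly dispersed around the
event mean). The null hypothesis of independent individual decisions is
simulated by shuffling each ant's row across events independently of the
other ants, which destroys between-ant correlation while preserving every
ant's marginal response set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "pairwise_correlations",
    "mean_pairwise_correlation",
    "permutation_null",
    "PermutationResult",
]


def _corr_matrix(M: np.ndarray, min_events: int = 3) -> np.ndarray:
    """All-pairs Pearson correlation over pairwise-complete events.

    Entries are NaN for pairs with fewer than ``min_events`` complete events
    or zero variance in either row. Vectorized with masked cross-products.
    """
    M = np.asarray(M, dtype=float)
    valid = np.isfinite(M)
    X = np.where(valid, M, 0.0)
    W = valid.astype(float)
    n = W @ W.T
    Sx = X @ W.T
    Sy = Sx.T
    Sxy = X @ X.T
    X2 = X * X
    Sxx = X2 @ W.T
    Syy = Sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * Sxy - Sx * Sy
        vx = n * Sxx - Sx * Sx
        vy = n * Syy - Sy * Sy
        r = cov / np.sqrt(vx * vy)
    r[(n < min_events) | (vx <= 0) | (vy <= 0)] = np.nan
    return r


def pairwise_correlations(M, min_events: int = 3) -> np.ndarray:
    """Per-pair correlation coefficients (upper triangle, row-major).

    ``M`` is an ants x events matrix with NaN marking missing responses.
    Requires at least 2 ants and 3 events; pairs that cannot be evaluated
    (too few complete events, zero variance) come back NaN.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need an ants x events matrix with >= 2 ants")
    if M.shape[1] < 3:
        raise ValueError("need at least 3 events")
    r = _corr_matrix(M, min_events=min_events)
    iu = np.triu_indices(M.shape[0], k=1)
    return r[iu]


def mean_pairwise_correlation(M, min_events: int = 3) -> float:
    """Mean of the defined pairwise correlations (NaN pairs dropped)."""
    vals = pairwise_correlations(M, min_events=min_events)
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    p_string: str
    n_shuffles: int
    exceedances: int


def _shuffle_rows(M: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each row independently across events (missing entries move
    with their positions, preserving each ant's missingness count)."""
    keys = rng.random(M.shape)
    idx = np.argsort(keys, axis=1)
    return np.take_along_axis(M, idx, axis=1)


def _null_distribution_complete(
    mats, rng: np.random.Generator, n_shuffles: int
) -> np.ndarray:
    """Vectorized null distribution for matrices without missing entries.

    Row-standardizes each shuffled matrix and evaluates all pairwise
    correlations for all shuffles with one batched matrix product per
    colony. Zero-variance rows are excluded from pair formation (their
    pairs are undefined both observed and under the null).
    """
    per_colony_sums = np.zeros(n_shuffles)
    n_pairs_total = 0
    for M in mats:
        M = np.asarray(M, dtype=float)
        sd = M.std(axis=1)
        M = M[sd > 0]
        a, e = M.shape
        if a < 2:
            continue
        keys = rng.random((n_shuffles, a, e))
        idx = np.argsort(keys, axis=2)
        Z = np.take_along_axis(np.broadcast_to(M, (n_shuffles, a, e)), idx, axis=2)
        Z = Z - Z.mean(axis=2, keepdims=True)
        Z /= Z.std(axis=2, keepdims=True)
        R = np.einsum("sae,sbe->sab", Z, Z) / e
        iu = np.triu_indices(a, k=1)
        per_colony_sums += R[:, iu[0], iu[1]].sum(axis=1)
        n_pairs_total += iu[0].size
    if n_pairs_total == 0:
        raise ValueError("no pairs with nonzero variance")
    return per_colony_sums / n_pairs_total


def permutation_null(
    matrices,
    rng: np.random.Generator,
    n_shuffles: int = 100_000,
    min_events: int = 3,
    convention: str = "add_zero",
) -> PermutationResult:
    """Permutation test of the pooled mean pairwise correlation.

    ``matrices`` is one ants x events matrix or a list of them (one per
    colony). The statistic is the mean pairwise correlation pooled over all
    colonies' pairs; each shuffle independently permutes every ant's row
    within its colony. The one-sided p-value counts null statistics >= the
    observed one; with the default "add_zero" convention zero exceedances
    are reported as "< 1/n" (``p_value`` is then set to 1/n as an upper
    bound), while "add_one" uses (1 + exceedances)/(1 + n).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if convention not in ("add_zero", "add_one"):
        raise ValueError("convention must be 'add_zero' or 'add_one'")
    if isinstance(matrices, np.ndarray) and matrices.ndim == 2:
        matrices = [matrices]
    mats = [np.asarray(M, dtype=float) for M in matrices]

    def pooled_mean(ms) -> float:
        vals = np.concatenate(
            [pairwise_correlations(M, min_events=min_events) for M in ms]
        )
        return float(np.nanmean(vals))

    observed = pooled_mean(mats)
    if all(np.all(np.isfinite(M)) for M in mats):
        null = _null_distribution_complete(mats, rng, n_shuffles)
    else:
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            null[s] = pooled_mean([_shuffle_rows(M, rng) for M in mats])
    exceed = int(np.sum(null >= observed))
    if convention == "add_one":
        p = (1 + exceed) / (1 + n_shuffles)
        p_str = f"{p:.3g}"
    else:
        if exceed == 0:
            p = 1.0 / n_shuffles
            p_str = f"< {1.0 / n_shuffles:.3g}"
        else:
            p = exceed / n_shuffles
            p_str = f"{p:.3g}"
    return PermutationResult(
        observed=observed,
        null=null,
        p_value=float(p),
        p_string=p_str,
        n_shuffles=n_shuffles,
        exceedances=exceed,
    )
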