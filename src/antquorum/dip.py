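"""Hartigan's dip statistic for unimodality, with a bootstrap p-value.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and the set of unimodal CDFs (convex below the mode, concave above).
It is used here to quantify the bimodality of colony-state histograms: a
colony state distribution that has split toward "fully evacuated" vs.
"stayed in" late in a perturbation has a larger dip than the continuous
spread seen early on.

The computation follows Hartigan's iterative algorithm: alternately fit the
greatest convex minorant (GCM) and least concave majorant (LCM) of the
empirical CDF on a shrinking interval, track the largest discrepancy, and
stop when it no longer grows. The p-value is calibrated by bootstrap from
the uniform distribution, the asymptotically least favorable unimodal null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["dip_statistic", "dip_test", "DipResult"]


def _gcm_touchpoints(x: np.ndarray) -> np.ndarray:
    """mn[j]: previous touching point of the greatest convex minorant of the
    points (x_j, j)."""
    n = x.size
    mn = np.zeros(n, dtype=np.int64)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (
                j - mnj
            ):
                break
            mn[j] = mnmnj
    return mn


def _lcm_touchpoints(x: np.ndarray) -> np.ndarray:
    """mj[k]: next touching point of the least concave majorant."""
    n = x.size
    mj = np.zeros(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (
                x[mjk] - x[mjmjk]
            ) * (k - mjk):
                break
            mj[k] = mjmjk
    return mj


def dip_statistic(samples) -> float:
    """Dip statistic of a 1-d sample (0 for constant or n < 2 samples)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    mn = _gcm_touchpoints(x)
    mj = _lcm_touchpoints(x)
    low, high = 0, n - 1
    dip = 1.0  # in count units; final statistic is dip / (2n)

    while True:
        # change points of the GCM, from high down to low, and of the LCM,
        # from low up to high, restricted to [low, high]
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_gcm, l_lcm = len(gcm), len(lcm)

        if l_gcm == 1 and l_lcm == 1:
            d = 1.0
            ig, ih = 0, 0
        else:
            # largest distance between the GCM and the LCM on [low, high]
            d = 0.0
            ig, ih = l_gcm - 1, l_lcm - 1
            ix, iv = l_gcm - 2, 1
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # next break point comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    if x[gcmix] == x[gcmi1]:  # vertical chord (ties)
                        dx = -np.inf
                    else:
                        dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                            gcmix - gcmi1
                        ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv - 1
                else:
                    # next break point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    if x[lcmiv] == x[lcmiv1]:  # vertical chord (ties)
                        dx = -np.inf
                    else:
                        dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                            x[lcmiv] - x[lcmiv1]
                        ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig, ih = ix + 1, iv
                if ix < 0:
                    ix = 0
                if iv >= l_lcm:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break

        if d < dip:
            break

        # max deviation of the empirical CDF from the GCM on [low, gcm[ig]]
        dl = 0.0
        for i in range(ig, l_gcm - 1):
            jb, je = gcm[i + 1], gcm[i]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for j in range(jb, je + 1):
                    t = (j - jb + 1) - (x[j] - x[jb]) * c
                    if t > dl:
                        dl = t
        # max deviation of the empirical CDF from the LCM on [lcm[ih], high]
        du = 0.0
        for i in range(ih, l_lcm - 1):
            jb, je = lcm[i], lcm[i + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for j in range(jb, je + 1):
                    t = (x[j] - x[jb]) * c - (j - jb - 1)
                    if t > du:
                        du = t

        dx = max(dl, du)
        if dip < dx:
            dip = dx
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return float(dip / (2.0 * n))


@dataclass(frozen=True)
class DipResult:
    dip: float
    p_value: float
    n: int
    n_boot: int


def dip_test(
    samples, rng: np.random.Generator, n_boot: int = 2000
) -> DipResult:
    """Bootstrap dip test of unimodality.

    The null distribution of the dip is simulated from uniform samples of
    the same size; p = (1 + #{dip_boot >= dip_obs}) / (1 + n_boot).
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    d_obs = dip_statistic(x)
    boots = np.empty(n_boot)
    u = rng.random((n_boot, n))
    for b in range(n_boot):
        boots[b] = dip_statistic(u[b])
    p = (1.0 + np.sum(boots >= d_obs)) / (1.0 + n_boot)
    return DipResult(dip=d_obs, p_value=float(p), n=n, n_boot=n_boot)
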