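"""Hartigan's dip statistic for departure from unimodality.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and the class of unimodal distribution functions,
computed here with the classic iterative algorithm: repeatedly fit the
greatest convex minorant (GCM) and least concave majorant (LCM) of the
ECDF on the current modal interval, record the largest deviation, and
shrink the interval until the candidate dip stops growing.

p-values are calibrated by bootstrap from the uniform distribution, the
stochastically largest unimodal null, so the test is conservative for any
other unimodal data-generating law.
"""

from __future__ import annotations

import functools

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def dip_statistic(x: np.ndarray) -> float:
    """Return the dip statistic of a one-dimensional sample.

    Parameters
    ----------
    x
        Sample values; must contain at least one point.  Ties are allowed.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("dip_statistic needs at least one observation")
    if n <= 3 or x[0] == x[n - 1]:
        # degenerate: the ECDF of <=3 points (or a point mass) is itself
        # within 1/(2n) of a unimodal CDF
        return 0.5 / n if x[0] != x[n - 1] else 0.0

    # mn[j]: index of the previous GCM touch point when the minorant is
    # grown left-to-right; mj[k]: same for the LCM grown right-to-left.
    mn = np.zeros(n, dtype=np.int64)
    mj = np.zeros(n, dtype=np.int64)
    mn[0] = 0
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 0, n - 1
    dip = 1.0  # in count units; rescaled by 1/(2n) on return

    while True:
        # change points of the GCM from high down to low
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm)
        ig = l_gcm
        ix = l_gcm - 2  # 0-based counter into gcm

        # change points of the LCM from low up to high
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm)
        ih = l_lcm
        iv = 1  # 0-based counter into lcm

        # largest vertical distance between the GCM and LCM fits
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # supporting point comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        x[gcmix] - x[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 2
                        ih = iv
                else:
                    # supporting point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (x[lcmiv] - x[lcmiv1]) - (
                        gcmix - lcmiv1 - 1
                    )
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 2
                        ih = iv + 1
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # dip within the convex-minorant side: largest amount the ECDF
        # rises above the GCM chord on [gcm[ig..l_gcm-1]]
        dip_l = 0.0
        for j in range(ig - 1, l_gcm - 1):
            jb = gcm[j + 1]
            je = gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                    if t > max_t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # dip within the concave-majorant side
        dip_u = 0.0
        for j in range(ih - 1, l_lcm - 1):
            jb = lcm[j]
            je = lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * C - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig - 1] and high == lcm[ih - 1]:
            break
        low = gcm[ig - 1]
        high = lcm[ih - 1]

    return dip / (2.0 * n)


@functools.lru_cache(maxsize=64)
def _uniform_null(n: int, n_boot: int, seed: int) -> tuple[float, ...]:
    """Bootstrap null dip distribution for sample size n (cached)."""
    rng = np.random.default_rng(seed)
    return tuple(dip_statistic(rng.uniform(size=n)) for _ in range(n_boot))


def dip_test(x: np.ndarray, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against a uniform null.

    Returns ``(dip, p)`` where ``p = (1 + #{null >= dip}) / (n_boot + 1)``.
    The null distribution is simulated once per sample size and cached, so
    testing many same-sized samples costs one bootstrap.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    d = dip_statistic(x)
    null = np.array(_uniform_null(int(np.asarray(x).size), n_boot, seed))
    p = (1.0 + np.sum(null >= d)) / (n_boot + 1.0)
    return d, float(p)
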