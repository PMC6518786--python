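"""Exact dip statistic of an empirical distribution function.

The dip of a CDF ``F`` is the smallest sup-norm distance between ``F`` and
any unimodal CDF (convex up to some mode, concave after it).  For a sample
it is computed by the classical iterative greatest-convex-minorant /
least-concave-majorant (GCM/LCM) algorithm: the candidate modal interval
``[low, high]`` is shrunk step by step; at each step the largest gap between
the GCM and LCM fits inside the interval is located, and the one-sided
deviations of the empirical CDF from the fits over the settled tails are
accumulated.  All internal gaps are measured in count units and over-count
the dip by a factor of two (an optimal unimodal CDF passes midway between
the two envelopes), hence the final division by ``2 n``.

Twice the dip equals the excess-mass difference between the best two-interval
and best one-interval representations of the sample, which is how the
statistic is used by :mod:`circmort.multimode`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dip_statistic"]


@njit(cache=False)
def _dip_sorted(x):  # pragma: no cover - exercised through dip_statistic
    n = x.size
    if n < 2 or x[n - 1] == x[0]:
        return 0.0

    low = 0
    high = n - 1
    # dip in units of 2n; the smallest attainable dip is 1/(2n)
    dip = 1.0

    mn = np.empty(n, np.int64)
    mj = np.empty(n, np.int64)
    gcm = np.empty(n + 1, np.int64)
    lcm = np.empty(n + 1, np.int64)

    while True:
        # GCM touch-point pointers on [low, high]: mn[j] is the previous
        # support index of the convex minorant of (x_i, i) restricted there.
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                if mnj == low:
                    break
                mnmnj = mn[mnj]
                if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                    break
                mn[j] = mnmnj

        # LCM pointers on [low, high], built right to left.
        mj[high] = high
        for k in range(high - 1, low - 1, -1):
            mj[k] = k + 1
            while True:
                mjk = mj[k]
                if mjk == high:
                    break
                mjmjk = mj[mjk]
                if (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                    break
                mj[k] = mjmjk

        # Collect GCM change points from high down to low ...
        gcm[0] = high
        i = 0
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i + 1  # gcm[0] = high, ..., gcm[l_gcm - 1] = low

        # ... and LCM change points from low up to high.
        lcm[0] = low
        i = 0
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i + 1  # lcm[0] = low, ..., lcm[l_lcm - 1] = high

        ig = l_gcm - 1  # index (into gcm) of the modal-interval lower end
        ih = l_lcm - 1  # index (into lcm) of the modal-interval upper end

        # Walk both envelopes from low to high and find the largest
        # GCM-to-LCM gap, in count units (= 2n * sup-deviation).
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            ix = l_gcm - 2
            iv = 1
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next change point comes from the LCM: gap at lcm[iv]
                    gcmi1 = gcm[ix + 1]
                    dx = x[gcmix] - x[gcmi1]
                    if dx > 0.0:
                        d_ = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / dx
                    else:
                        d_ = float(lcmiv - gcmi1 + 1)
                    iv += 1
                    if d_ >= d:
                        d = d_
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next change point comes from the GCM: gap at gcm[ix]
                    lcmiv1 = lcm[iv - 1]
                    dx = x[lcmiv] - x[lcmiv1]
                    if dx > 0.0:
                        d_ = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / dx - (gcmix - lcmiv1 - 1)
                    else:
                        d_ = float(lcmiv - lcmiv1 - (gcmix - lcmiv1 - 1))
                    ix -= 1
                    if d_ >= d:
                        d = d_
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            # both envelopes are single chords: the restricted ECDF is
            # already compatible with unimodality
            d = 1.0

        if d < dip:
            break

        # One-sided deviations of the ECDF from the envelopes over the
        # newly settled tails [low, gcm[ig]] and [lcm[ih], high].
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for j_ in range(jb, je + 1):
                    t = (j_ - jb + 1) - (x[j_] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for j_ in range(jb, je + 1):
                    t = (x[j_] - x[jb]) * c - (j_ - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew

        new_low = gcm[ig]
        new_high = lcm[ih]
        if new_low == low and new_high == high:
            break
        low = new_low
        high = new_high

    return dip / (2.0 * n)


def dip_statistic(x: np.ndarray) -> float:
    """Hartigan's dip of the sample ``x``.

    Parameters
    ----------
    x : array-like
        One-dimensional sample; need not be sorted.  Ties are allowed.

    Returns
    -------
    float
        The dip, in ``[0, 0.25]``.  A sample of fewer than two distinct
        values has dip 0 by convention; otherwise the dip is at least
        ``1 / (2 n)``.
    """
    x = np.sort(np.asarray(x, dtype=np.float64).ravel())
    return float(_dip_sorted(x))
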