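"""Independent brute-force oracles used by the test-suite.

These deliberately re-derive quantities from their definitions, without
touching the production code paths they validate.
"""

from __future__ import annotations

import numpy as np


def _upper_envelope_vertices(masses: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Breakpoint positions (lambda values) of max_i [masses_i - lam*lengths_i].

    Each candidate interval set contributes a line ``v(lam) = mass - lam * len``;
    the envelope is their pointwise maximum over ``lam >= 0``.  Returns the
    lambda coordinates of the envelope's vertices (may be empty).
    """
    # keep, per slope, only the dominating intercept
    order = np.lexsort((-masses, lengths))  # ascending length, descending mass
    m = masses[order]
    ln = lengths[order]
    keep_m: list[float] = []
    keep_l: list[float] = []
    for mi, li in zip(m, ln):
        if keep_l and li == keep_l[-1]:
            continue  # same slope, smaller intercept
        keep_m.append(mi)
        keep_l.append(li)
    # upper hull over lines y = m - lam*l, slopes -l increasing as l decreases;
    # process in order of decreasing length (increasing slope)
    hull_m: list[float] = []
    hull_l: list[float] = []
    for mi, li in zip(keep_m[::-1], keep_l[::-1]):
        while hull_m:
            if len(hull_m) == 1:
                # new line has strictly larger slope; crossing exists unless
                # it dominates everywhere on lam >= 0
                if mi >= hull_m[-1]:
                    hull_m.pop()
                    hull_l.pop()
                else:
                    break
            else:
                # crossing of new line with hull top, vs top with its predecessor
                lam_new = (hull_m[-1] - mi) / (hull_l[-1] - li)
                lam_old = (hull_m[-2] - hull_m[-1]) / (hull_l[-2] - hull_l[-1])
                if lam_new <= lam_old:
                    hull_m.pop()
                    hull_l.pop()
                else:
                    break
        hull_m.append(mi)
        hull_l.append(li)
    verts = []
    for a in range(len(hull_m) - 1):
        verts.append((hull_m[a] - hull_m[a + 1]) / (hull_l[a] - hull_l[a + 1]))
    return np.asarray(verts, dtype=float)


def excess_mass_bruteforce(x: np.ndarray) -> float:
    """Excess-mass difference Delta = max_lam [E2(lam) - E1(lam)] by enumeration.

    E_k(lam) is the supremum over k disjoint closed intervals (endpoints at
    data points; degenerate single-point intervals included) of
    sum_j [F_n(C_j) - lam * |C_j|].  Both E1 and E2 are upper envelopes of
    finitely many lines in lam, so the maximum of their difference is
    attained at an envelope vertex (or in the flat limits lam -> 0+, inf),
    all of which are evaluated exactly.
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    vals = np.unique(x)
    k = vals.size
    # single intervals [vals[i], vals[j]], i <= j
    ii, jj = np.triu_indices(k)
    mass1 = (np.searchsorted(x, vals[jj], side="right") - np.searchsorted(x, vals[ii], side="left")) / n
    len1 = vals[jj] - vals[ii]
    # disjoint ordered pairs: right end of first < left end of second
    pair_m: list[float] = []
    pair_l: list[float] = []
    m_grid = mass1
    for a in range(ii.size):
        ja = jj[a]
        sel = ii > ja
        if np.any(sel):
            pair_m.extend(m_grid[a] + m_grid[sel])
            pair_l.extend(len1[a] + len1[sel])
    mass2 = np.concatenate([mass1, np.asarray(pair_m, dtype=float)]) if pair_m else mass1
    len2 = np.concatenate([len1, np.asarray(pair_l, dtype=float)]) if pair_m else len1

    cands = np.concatenate(
        [
            _upper_envelope_vertices(mass1, len1),
            _upper_envelope_vertices(mass2, len2),
        ]
    )
    lam_max = cands.max() * 2.0 + 1.0 if cands.size else 1.0
    cands = np.concatenate([cands, [0.0, lam_max]])
    cands = np.unique(cands[cands >= 0.0])

    e1 = np.max(mass1[:, None] - np.outer(len1, cands), axis=0)
    e2 = np.max(mass2[:, None] - np.outer(len2, cands), axis=0)
    return float(np.max(e2 - e1))
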