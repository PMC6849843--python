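"""Hartigan's dip statistic for unimodality.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal distribution function (convex
increasing up to a mode, concave beyond it; an atom at the mode is
allowed).  It is computed with the classic iterative algorithm of
Hartigan & Hartigan (1985): maintain a candidate modal interval
[x_low, x_high], build the greatest convex minorant (GCM) of the ECDF
below it and the least concave majorant (LCM) above it, measure the
largest gap between the two hulls, harvest the dip contributed by the
stretches outside the gap, shrink the interval and repeat until the hull
gap can no longer improve the estimate.

Internally everything is in "count" units (ECDF scaled by n); the
statistic is the final count value divided by 2n, giving the usual floor
of 1/(2n) for samples of distinct values.

P-values come from a seeded bootstrap of the uniform null — the
asymptotically least-favourable unimodal distribution — with the null
table cached per sample size.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def _hull_chains(x: np.ndarray) -> tuple[list[int], list[int]]:
    """Predecessor/successor chains of the convex minorant and concave majorant.

    ``mn[j]`` is the previous touchpoint of the GCM of the points
    (x[i], i); ``mj[k]`` the next touchpoint of the LCM.  Computed once for
    the full sample; restrictions to sub-intervals reuse the chains.
    """
    n = len(x)
    mn = [0] * n
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 0:
                break
            mnmnj = mn[mnj]
            if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj = [n - 1] * n
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n - 1:
                break
            mjmjk = mj[mjk]
            if (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk
    return mn, mj


def dip_statistic(values) -> float:
    """Hartigan's dip statistic of a 1-D sample.

    Returns 0.0 for a sample of identical values (a point mass is
    unimodal) and 1/(2n) for any n <= 3.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(x)
    if n < 1:
        raise ValueError("empty sample")
    if not np.isfinite(x).all():
        raise ValueError("sample contains non-finite values")
    if x[0] == x[-1]:
        return 0.0
    if n <= 3:
        return 1.0 / (2.0 * n)

    mn, mj = _hull_chains(x)
    low, high = 0, n - 1
    dip_count = 1.0  # counts; final statistic = dip_count / (2n)

    for _ in range(n + 2):  # provably terminates; guard against stalls
        # GCM touchpoints high -> low, LCM touchpoints low -> high
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_gcm, l_lcm = len(gcm), len(lcm)

        if l_gcm <= 2 and l_lcm <= 2:
            break  # both hulls are straight lines: gap is minimal

        # largest gap between the hulls, walking both touchpoint sequences
        # in ascending data order
        d = 0.0
        new_low_pos, new_high_pos = l_gcm - 1, l_lcm - 1
        g_ix, l_iv = l_gcm - 2, 1
        while True:
            gcmix, lcmiv = gcm[g_ix], lcm[l_iv]
            if gcmix > lcmiv:
                # LCM touchpoint inside a GCM segment
                gcmi1 = gcm[g_ix + 1]
                den = x[gcmix] - x[gcmi1]
                interp = gcmi1 + (
                    (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / den if den > 0 else 0.0
                )
                dx = (lcmiv + 1) - interp
                l_iv += 1
                if dx >= d:
                    d = dx
                    new_low_pos, new_high_pos = g_ix + 1, l_iv - 1
            else:
                # GCM touchpoint inside an LCM segment
                lcmiv1 = lcm[l_iv - 1]
                den = x[lcmiv] - x[lcmiv1]
                interp = lcmiv1 + (
                    (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / den if den > 0 else 0.0
                )
                dx = interp - (gcmix - 1)
                g_ix -= 1
                if dx >= d:
                    d = dx
                    new_low_pos, new_high_pos = g_ix + 1, l_iv
            g_ix = max(g_ix, 0)
            l_iv = min(l_iv, l_lcm - 1)
            if gcm[g_ix] == lcm[l_iv]:
                break

        if d <= dip_count:
            break

        # dip of the ECDF against the GCM over the discarded low stretch
        dip_l = 0.0
        for j in range(new_low_pos, l_gcm - 1):
            jb, je = gcm[j + 1], gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                slope = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * slope
                    if t > max_t:
                        max_t = t
            dip_l = max(dip_l, max_t)
        # and against the LCM over the discarded high stretch
        dip_u = 0.0
        for j in range(new_high_pos, l_lcm - 1):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                slope = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * slope - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            dip_u = max(dip_u, max_t)

        dip_count = max(dip_count, dip_l, dip_u)
        low, high = gcm[new_low_pos], lcm[new_high_pos]

    return dip_count / (2.0 * n)


# cached bootstrap null tables: (n, n_boot, seed) -> sorted dip values
_NULL_TABLES: dict[tuple[int, int, int], np.ndarray] = {}


def _uniform_null_table(n: int, n_boot: int, seed: int) -> np.ndarray:
    key = (n, n_boot, seed)
    table = _NULL_TABLES.get(key)
    if table is None:
        rng = np.random.default_rng(seed)
        table = np.sort(
            [dip_statistic(rng.random(n)) for _ in range(n_boot)]
        )
        _NULL_TABLES[key] = table
    return table


def dip_test(values, n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against the unimodal null.

    The null distribution is the dip of ``n_boot`` uniform samples of the
    same size (seeded, cached per size).  Small p-values reject
    unimodality.  Requires at least 4 finite values; a constant sample is
    degenerate and returns (0.0, 1.0).
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(x) < 4:
        raise ValueError("dip test needs at least 4 finite values")
    d = dip_statistic(x)
    if d == 0.0:
        return 0.0, 1.0
    table = _uniform_null_table(len(x), n_boot, seed)
    n_ge = len(table) - np.searchsorted(table, d, side="left")
    p = (1.0 + n_ge) / (n_boot + 1.0)
    return float(d), float(p)
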