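"""JIT-compiled inner loops of the sifting process.

A single CEEMDAN run sifts tens of thousands of envelope pairs, so the
extrema scan, the not-a-knot cubic spline through the extrema and the
envelope-mean subtraction are compiled with numba.  The spline follows
the classic second-derivative (moment) formulation: interior continuity
equations form a tridiagonal system, the two not-a-knot end rows are
folded into it by eliminating their third coefficient against the first
interior row, and the result is solved with the Thomas algorithm.
Agreement with scipy's not-a-knot CubicSpline is exercised in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["find_extrema_nb", "envelope_mean_nb", "sift_nb"]


@njit(cache=True)
def find_extrema_nb(x):
    """Interior local maxima/minima indices; plateaus yield the (lower)
    midpoint index."""
    n = x.size
    maxima = np.empty(n, dtype=np.int64)
    minima = np.empty(n, dtype=np.int64)
    n_max = 0
    n_min = 0
    prev_slope = 0  # sign of last nonzero difference
    plateau_start = 0
    i = 0
    while i < n - 1:
        d = x[i + 1] - x[i]
        if d == 0.0:
            i += 1
            continue
        s = 1 if d > 0 else -1
        if prev_slope != 0 and s != prev_slope:
            # extremum spans plateau_start..i (equal values)
            mid = (plateau_start + i) // 2
            if prev_slope > 0:
                maxima[n_max] = mid
                n_max += 1
            else:
                minima[n_min] = mid
                n_min += 1
        prev_slope = s
        # next plateau begins where the value last changed
        j = i + 1
        plateau_start = j
        i = j
    return maxima[:n_max], minima[:n_min]


@njit(cache=True)
def _solve_spline_moments(xi, yi):
    """Second derivatives of the not-a-knot cubic through (xi, yi).

    Requires at least 4 strictly increasing knots.  The not-a-knot end
    conditions (continuous third derivative at the second and
    second-to-last knots) express M0 and M_{n-1} in terms of their
    neighbours; substituting them into the adjacent continuity rows
    leaves a diagonally dominant tridiagonal system in M1..M_{n-2}.
    """
    n = xi.size
    h = xi[1:] - xi[:-1]
    a = np.zeros(n)  # sub-diagonal
    b = np.zeros(n)  # diagonal
    c = np.zeros(n)  # super-diagonal
    d = np.zeros(n)
    for i in range(1, n - 1):
        a[i] = h[i - 1] / 6.0
        b[i] = (h[i - 1] + h[i]) / 3.0
        c[i] = h[i] / 6.0
        d[i] = (yi[i + 1] - yi[i]) / h[i] - (yi[i] - yi[i - 1]) / h[i - 1]
    # left not-a-knot: M0 = (1 + h0/h1) M1 - (h0/h1) M2
    rl = h[0] / h[1]
    b[1] = b[1] + a[1] * (1.0 + rl)
    c[1] = c[1] - a[1] * rl
    # right not-a-knot: M_{n-1} = (1 + h_{n-2}/h_{n-3}) M_{n-2}
    #                             - (h_{n-2}/h_{n-3}) M_{n-3}
    rr = h[n - 2] / h[n - 3]
    b[n - 2] = b[n - 2] + c[n - 2] * (1.0 + rr)
    a[n - 2] = a[n - 2] - c[n - 2] * rr
    # Thomas on rows 1..n-2
    for i in range(2, n - 1):
        w = a[i] / b[i - 1]
        b[i] -= w * c[i - 1]
        d[i] -= w * d[i - 1]
    m = np.zeros(n)
    m[n - 2] = d[n - 2] / b[n - 2]
    for i in range(n - 3, 0, -1):
        m[i] = (d[i] - c[i] * m[i + 1]) / b[i]
    m[0] = (1.0 + rl) * m[1] - rl * m[2]
    m[n - 1] = (1.0 + rr) * m[n - 2] - rr * m[n - 3]
    return m


@njit(cache=True)
def spline_envelope_nb(xi, yi, n_out):
    """Evaluate the envelope on samples 0..n_out-1.

    Cubic not-a-knot through >= 4 knots; linear interpolation as the
    degenerate fallback for 2-3 knots (short residues).
    """
    n = xi.size
    out = np.empty(n_out)
    if n < 4:
        # linear interpolation with flat extrapolation
        for t in range(n_out):
            ft = float(t)
            if ft <= xi[0]:
                out[t] = yi[0]
            elif ft >= xi[n - 1]:
                out[t] = yi[n - 1]
            else:
                j = np.searchsorted(xi, ft) - 1
                if j < 0:
                    j = 0
                w = (ft - xi[j]) / (xi[j + 1] - xi[j])
                out[t] = yi[j] * (1 - w) + yi[j + 1] * w
        return out
    m = _solve_spline_moments(xi, yi)
    j = 0
    for t in range(n_out):
        ft = float(t)
        while j < n - 2 and ft > xi[j + 1]:
            j += 1
        hj = xi[j + 1] - xi[j]
        u = xi[j + 1] - ft
        v = ft - xi[j]
        out[t] = (m[j] * u ** 3 + m[j + 1] * v ** 3) / (6.0 * hj) \
            + (yi[j] / hj - m[j] * hj / 6.0) * u \
            + (yi[j + 1] / hj - m[j + 1] * hj / 6.0) * v
    return out


@njit(cache=True)
def _mirror_knots(idx, vals, n):
    """Mirror up to two extrema across each boundary; deduplicate."""
    k = idx.size
    n_ext = 2 if k >= 2 else 1
    total = k + 2 * n_ext
    xi = np.empty(total)
    yi = np.empty(total)
    for e in range(n_ext):
        xi[e] = -float(idx[n_ext - 1 - e])
        yi[e] = vals[n_ext - 1 - e]
    for i in range(k):
        xi[n_ext + i] = float(idx[i])
        yi[n_ext + i] = vals[i]
    for e in range(n_ext):
        xi[n_ext + k + e] = 2.0 * (n - 1) - float(idx[k - 1 - e])
        yi[n_ext + k + e] = vals[k - 1 - e]
    # drop duplicate abscissae (keep first), assuming sorted
    keep_x = np.empty(total)
    keep_y = np.empty(total)
    m = 0
    for i in range(total):
        if m == 0 or xi[i] > keep_x[m - 1]:
            keep_x[m] = xi[i]
            keep_y[m] = yi[i]
            m += 1
    return keep_x[:m], keep_y[:m]


@njit(cache=True)
def envelope_mean_nb(x):
    """Mean of the upper/lower spline envelopes; ok=False when either
    side has no extremum."""
    n = x.size
    maxima, minima = find_extrema_nb(x)
    if maxima.size < 1 or minima.size < 1:
        return np.zeros(n), False
    xu, yu = _mirror_knots(maxima, x[maxima], n)
    xl, yl = _mirror_knots(minima, x[minima], n)
    if xu.size < 2 or xl.size < 2:
        return np.zeros(n), False
    upper = spline_envelope_nb(xu, yu, n)
    lower = spline_envelope_nb(xl, yl, n)
    return 0.5 * (upper + lower), True


@njit(cache=True)
def sift_nb(x, n_sifts):
    """n_sifts envelope-mean subtractions; returns (h, sifts_used)."""
    h = x.copy()
    used = 0
    for _ in range(n_sifts):
        m, ok = envelope_mean_nb(h)
        if not ok:
            break
        h = h - m
        used += 1
    return h, used
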