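"""Compiled inner loops for EMD sifting.

These kernels are the hot path of ensemble decomposition (a cohort run
performs tens of thousands of sifts), so they are written as numba
``njit`` functions operating on plain float64 arrays.  The public,
documented API lives in :mod:`emghht.decomposition`; the semantics here
(plateau-midpoint extrema, natural cubic splines through mirror-extended
extrema, fixed-count sifting) are exactly what that module promises.
"""

from __future__ import annotations

import numba as nb
import numpy as np

__all__ = ["extrema_indices", "spline_envelope", "sift_once_array", "emd_array"]


@nb.njit(cache=True)
def extrema_indices(x):  # pragma: no cover - exercised through wrappers
    """Local maxima/minima by sign change of the first difference.

    Flat plateaus contribute a single extremum at the floor of their
    midpoint.  Endpoints are never extrema.
    """
    n = x.shape[0]
    maxima = np.empty(n, np.int64)
    minima = np.empty(n, np.int64)
    nmax = 0
    nmin = 0
    prev_sign = 0
    prev_i = 0  # sample index that ended the last nonzero step
    for i in range(1, n):
        d = x[i] - x[i - 1]
        if d > 0.0:
            s = 1
        elif d < 0.0:
            s = -1
        else:
            continue
        if prev_sign == 1 and s == -1:
            maxima[nmax] = (prev_i + (i - 1)) // 2
            nmax += 1
        elif prev_sign == -1 and s == 1:
            minima[nmin] = (prev_i + (i - 1)) // 2
            nmin += 1
        prev_sign = s
        prev_i = i
    return maxima[:nmax], minima[:nmin]


@nb.njit(cache=True)
def _natural_spline_eval(t, y, n):
    """Natural cubic spline through (t, y), evaluated at 0..n-1."""
    m = t.shape[0]
    out = np.empty(n)
    if m == 1:
        for i in range(n):
            out[i] = y[0]
        return out
    if m == 2:
        slope = (y[1] - y[0]) / (t[1] - t[0])
        for i in range(n):
            out[i] = y[0] + slope * (i - t[0])
        return out
    h = np.empty(m - 1)
    for k in range(m - 1):
        h[k] = t[k + 1] - t[k]
    # Thomas algorithm for interior second derivatives (natural ends = 0)
    p = m - 2
    diag = np.empty(p)
    sup = np.empty(p)
    rhs = np.empty(p)
    for k in range(1, m - 1):
        diag[k - 1] = 2.0 * (h[k - 1] + h[k])
        sup[k - 1] = h[k]
        rhs[k - 1] = 6.0 * ((y[k + 1] - y[k]) / h[k] - (y[k] - y[k - 1]) / h[k - 1])
    for k in range(1, p):
        w = h[k] / diag[k - 1]  # sub-diagonal entry for row k is h[k]
        diag[k] -= w * sup[k - 1]
        rhs[k] -= w * rhs[k - 1]
    M = np.zeros(m)
    M[p] = rhs[p - 1] / diag[p - 1]
    for k in range(p - 2, -1, -1):
        M[k + 1] = (rhs[k] - sup[k] * M[k + 2]) / diag[k]
    j = 0
    for i in range(n):
        xq = float(i)
        while j < m - 2 and xq > t[j + 1]:
            j += 1
        hk = h[j]
        A = (t[j + 1] - xq) / hk
        B = (xq - t[j]) / hk
        out[i] = (
            A * y[j]
            + B * y[j + 1]
            + ((A * A * A - A) * M[j] + (B * B * B - B) * M[j + 1]) * hk * hk / 6.0
        )
    return out


@nb.njit(cache=True)
def spline_envelope(x, idx, n):
    """Envelope through the extrema ``idx`` of ``x``.

    The two extrema nearest each end are mirrored about the trace
    endpoints (positions 0 and n-1) before fitting, which tames the
    end swings of the cubic spline.
    """
    k = idx.shape[0]
    last = float(n - 1)
    # worst case: k knots plus two reflections per side
    t = np.empty(k + 4)
    y = np.empty(k + 4)
    m = 0
    r = 2 if k >= 2 else k
    # left reflections, farthest first so knots stay sorted
    for q in range(r - 1, -1, -1):
        cand = -float(idx[q])
        if m == 0 or cand > t[m - 1]:
            t[m] = cand
            y[m] = x[idx[q]]
            m += 1
    for q in range(k):
        cand = float(idx[q])
        if m == 0 or cand > t[m - 1]:
            t[m] = cand
            y[m] = x[idx[q]]
            m += 1
    for q in range(k - 1, k - 1 - r, -1):
        cand = 2.0 * last - float(idx[q])
        if m == 0 or cand > t[m - 1]:
            t[m] = cand
            y[m] = x[idx[q]]
            m += 1
    return _natural_spline_eval(t[:m], y[:m], n)


@nb.njit(cache=True)
def sift_once_array(x, n_iters):
    """Run ``n_iters`` envelope-mean subtractions on a copy of ``x``.

    Returns (candidate IMF, completed flag).  The flag is False when the
    working signal ran out of extrema before the iteration budget.
    """
    cur = x.copy()
    n = cur.shape[0]
    completed = True
    for _ in range(n_iters):
        mx, mn = extrema_indices(cur)
        if mx.shape[0] < 1 or mn.shape[0] < 1:
            completed = False
            break
        eu = spline_envelope(cur, mx, n)
        el = spline_envelope(cur, mn, n)
        for i in range(n):
            cur[i] -= 0.5 * (eu[i] + el[i])
    return cur, completed


@nb.njit(cache=True)
def emd_array(x, sift_iters, max_imfs):
    """Full EMD of ``x``: (imfs matrix, count, residual).

    Extraction stops when the residual has at most one extremum (covers
    constants and monotone slopes) or ``max_imfs`` is reached.
    """
    n = x.shape[0]
    imfs = np.zeros((max_imfs, n))
    res = x.copy()
    count = 0
    for _ in range(max_imfs):
        mx, mn = extrema_indices(res)
        if mx.shape[0] + mn.shape[0] <= 1 or mx.shape[0] < 1 or mn.shape[0] < 1:
            break
        c, completed = sift_once_array(res, sift_iters)
        for i in range(n):
            imfs[count, i] = c[i]
            res[i] -= c[i]
        count += 1
        if not completed:
            break
    return imfs[:count], count, res
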