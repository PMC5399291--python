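"""Numba kernels for the marginalized N-mixture likelihood.

The latent abundance N of each site-year is summed over a per-row window
[n0_s, n0_s + w_s): the lower end is the row's maximum observed count (the
binomial pmf vanishes below it), the upper end a generous Poisson upper
quantile at the data-implied abundance scale (see the truncation-rule
check in :mod:`flywaytrends.likelihood`). Windows are stored flat: row s
occupies slots ptr[s]..ptr[s+1] of every flat array.

Layouts
-------
``nvals[a:b]``   the latent N values of row s's window
``lgfact[a:b]``  log N! on the window
``logcoef``      (total, J) log binomial coefficients log C(N, c_sj)
``Lb``           (total, J) binomial log-pmf terms per replicate
``B``            (total,) sum of Lb over observed replicates
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def marg_rows(loglam, lam, B, ptr, nvals, lgfact, rows, scratch, out):
    """log sum_N exp(N log lam - lam - log N! + B[N]) for selected rows.

    ``loglam``/``lam`` are full-length (indexed by row id); ``out`` is
    compact, aligned with ``rows``; ``scratch`` holds one window's terms.
    """
    for r in range(rows.size):
        s = rows[r]
        a, b = ptr[s], ptr[s + 1]
        m = -1e300
        am = 0
        for i in range(a, b):
            t = nvals[i] * loglam[s] - lam[s] - lgfact[i] + B[i]
            scratch[i - a] = t
            if t > m:
                m = t
                am = i - a
        # the summand is log-concave in N: only terms within ~37 nats of
        # the mode contribute above double precision
        lo = m - 37.0
        acc = 0.0
        i = am
        while i >= 0 and scratch[i] > lo:
            acc += np.exp(scratch[i] - m)
            i -= 1
        i = am + 1
        w = b - a
        while i < w and scratch[i] > lo:
            acc += np.exp(scratch[i] - m)
            i += 1
        out[r] = m + np.log(acc)


@njit(cache=True, fastmath=True)
def binom_table(p, C, mask, logcoef, nvals, ptr, Lb, B):
    """Fill Lb and B for every row from detection probabilities p (S, J)."""
    S, J = p.shape
    for s in range(S):
        a, b = ptr[s], ptr[s + 1]
        for i in range(a, b):
            B[i] = 0.0
        for j in range(J):
            if not mask[s, j]:
                continue
            pj = min(max(p[s, j], 1e-12), 1.0 - 1e-12)
            lp = np.log(pj)
            l1p = np.log1p(-pj)
            c = C[s, j]
            for i in range(a, b):
                val = logcoef[i, j] + c * lp + (nvals[i] - c) * l1p
                Lb[i, j] = val
                B[i] += val


@njit(cache=True, fastmath=True)
def binom_col(p_col, rows, j, C, logcoef, nvals, ptr, Lb, B, Lb_new, B_new):
    """Proposed replicate-j update: new Lb column and B for selected rows.

    ``p_col`` has one entry per selected row; ``Lb_new``/``B_new`` are flat
    scratch arrays (only the selected rows' slots are written).
    """
    for r in range(rows.size):
        s = rows[r]
        a, b = ptr[s], ptr[s + 1]
        pj = min(max(p_col[r], 1e-12), 1.0 - 1e-12)
        lp = np.log(pj)
        l1p = np.log1p(-pj)
        c = C[s, j]
        for i in range(a, b):
            val = logcoef[i, j] + c * lp + (nvals[i] - c) * l1p
            Lb_new[i] = val
            B_new[i] = B[i] - Lb[i, j] + val


@njit(cache=True)
def commit_col(rows, j, Lb_new, B_new, ptr, Lb, B):
    for r in range(rows.size):
        s = rows[r]
        a, b = ptr[s], ptr[s + 1]
        for i in range(a, b):
            Lb[i, j] = Lb_new[i]
            B[i] = B_new[i]


@njit(cache=True)
def commit_rows(rows, src_Lb, src_B, ptr, Lb, B):
    J = Lb.shape[1]
    for r in range(rows.size):
        s = rows[r]
        a, b = ptr[s], ptr[s + 1]
        for i in range(a, b):
            for j in range(J):
                Lb[i, j] = src_Lb[i, j]
            B[i] = src_B[i]


@njit(cache=True, fastmath=True)
def sample_latent(loglam, lam, B, ptr, nvals, lgfact, u, scratch, out):
    """Draw latent N from its conditional on each row's window (inverse CDF)."""
    S = loglam.size
    for s in range(S):
        a, b = ptr[s], ptr[s + 1]
        m = -1e300
        am = 0
        for i in range(a, b):
            t = nvals[i] * loglam[s] - lam[s] - lgfact[i] + B[i]
            scratch[i - a] = t
            if t > m:
                m = t
                am = i - a
        w = b - a
        lo_cut = m - 37.0
        lo = am
        while lo > 0 and scratch[lo - 1] > lo_cut:
            lo -= 1
        hi = am + 1
        while hi < w and scratch[hi] > lo_cut:
            hi += 1
        total = 0.0
        for i in range(lo, hi):
            scratch[i] = np.exp(scratch[i] - m)
            total += scratch[i]
        target = u[s] * total
        acc = 0.0
        pick = a + hi - 1
        for i in range(lo, hi):
            acc += scratch[i]
            if acc >= target:
                pick = a + i
                break
        out[s] = nvals[pick]
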