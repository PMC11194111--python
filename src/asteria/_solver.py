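"""Compiled proximal solver for the strong-hierarchy interaction lasso.

Solves the convex relaxation of the hierarchy-constrained problem in split
form: the main-effect vector is written as ``beta = bp - bm`` with
``bp, bm >= 0`` and the (not-necessarily-symmetric) interaction matrix
``Th`` obeys a per-row l1 cap ``sum_k |Th[j, k]| <= bp[j] + bm[j]``.  The
smooth part is

    f = 0.5 * || yc - Xc (bp - bm) - Zc w ||^2,
    w[p] = (Th[j_p, k_p] + Th[k_p, j_p]) / 2,

with column-centered mains ``Xc`` and centered pair-product columns ``Zc``
(one per unordered pair), plus the penalty
``lam * sum(bp + bm) + (lam / 2) * sum |Th|``.

The algorithm is FISTA with an objective-monotone restart: if the
accelerated candidate increases the objective, a plain proximal-gradient
step is taken instead (guaranteed descent for step <= 1/L).  The proximal
operator separates across rows of ``Th``; each row prox is solved exactly
up to a bisection on the Lagrange multiplier of the l1-cap constraint.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------- objective


@njit(cache=True)
def _pair_weights(Th, pj, pk):
    P = pj.shape[0]
    w = np.empty(P)
    for p in range(P):
        w[p] = 0.5 * (Th[pj[p], pk[p]] + Th[pk[p], pj[p]])
    return w


@njit(cache=True)
def _objective(Xc, Zc, pj, pk, yc, lam, bp, bm, Th):
    w = _pair_weights(Th, pj, pk)
    r = Xc @ (bp - bm) + Zc @ w - yc
    pen = lam * (bp.sum() + bm.sum()) + 0.5 * lam * np.abs(Th).sum()
    return 0.5 * (r @ r) + pen


@njit(cache=True)
def _residual(Xc, Zc, pj, pk, yc, bp, bm, Th):
    w = _pair_weights(Th, pj, pk)
    return Xc @ (bp - bm) + Zc @ w - yc


@njit(cache=True)
def _gradients(Xc, Zc, pj, pk, r, gbp, gbm, gTh):
    q = Xc.shape[1]
    gx = Xc.T @ r
    for j in range(q):
        gbp[j] = gx[j]
        gbm[j] = -gx[j]
    gz = Zc.T @ r
    gTh[:, :] = 0.0
    for p in range(pj.shape[0]):
        gTh[pj[p], pk[p]] = 0.5 * gz[p]
        gTh[pk[p], pj[p]] = 0.5 * gz[p]


# --------------------------------------------------------------- row prox


@njit(cache=True)
def _row_gap(mu, c, j, q, s, tl, a, b):
    """g(mu): cap slack as a function of the constraint multiplier."""
    tot = 0.0
    for k in range(q):
        if k == j:
            continue
        t = abs(c[k]) - s - mu
        if t > 0.0:
            tot += t
    p_ = a - tl + mu
    if p_ > 0.0:
        tot -= p_
    m_ = b - tl + mu
    if m_ > 0.0:
        tot -= m_
    return tot


@njit(cache=True)
def _prox_row(a, b, c, j, q, tl, s, out_bp, out_bm, out_row):
    """Exact prox of row j: min 0.5||.-(a,b,c)||^2 + tl*(p+m) + s*sum|th|
    s.t. p, m >= 0, sum|th| <= p + m.  Writes p, m into out_bp/out_bm[j]
    and the theta row into out_row (diagonal forced to 0)."""
    if _row_gap(0.0, c, j, q, s, tl, a, b) <= 0.0:
        mu = 0.0
    else:
        hi = 0.0
        for k in range(q):
            if k != j and abs(c[k]) > hi:
                hi = abs(c[k])
        lo = 0.0
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if _row_gap(mid, c, j, q, s, tl, a, b) > 0.0:
                lo = mid
            else:
                hi = mid
        mu = 0.5 * (lo + hi)
    p_ = a - tl + mu
    out_bp[j] = p_ if p_ > 0.0 else 0.0
    m_ = b - tl + mu
    out_bm[j] = m_ if m_ > 0.0 else 0.0
    lev = s + mu
    for k in range(q):
        if k == j:
            out_row[k] = 0.0
        else:
            ck = c[k]
            if ck > lev:
                out_row[k] = ck - lev
            elif ck < -lev:
                out_row[k] = ck + lev
            else:
                out_row[k] = 0.0


@njit(cache=True)
def _prox_step(bp, bm, Th, gbp, gbm, gTh, step, lam, nbp, nbm, nTh):
    q = bp.shape[0]
    tl = step * lam
    s = 0.5 * step * lam
    for j in range(q):
        a = bp[j] - step * gbp[j]
        b = bm[j] - step * gbm[j]
        c = Th[j] - step * gTh[j]
        _prox_row(a, b, c, j, q, tl, s, nbp, nbm, nTh[j])


# ------------------------------------------------------------------ driver


@njit(cache=True)
def solve_hier(Xc, Zc, pj, pk, yc, lam, step, bp0, bm0, Th0, tol, max_iter):
    """Monotone FISTA on the relaxation.  Returns
    (bp, bm, Th, n_iter, converged, objective, trace[:n_iter])."""
    q = Xc.shape[1]
    bp = bp0.copy()
    bm = bm0.copy()
    Th = Th0.copy()
    fx = _objective(Xc, Zc, pj, pk, yc, lam, bp, bm, Th)

    vbp = bp.copy()
    vbm = bm.copy()
    vTh = Th.copy()
    tk = 1.0

    gbp = np.empty(q)
    gbm = np.empty(q)
    gTh = np.empty((q, q))
    nbp = np.empty(q)
    nbm = np.empty(q)
    nTh = np.empty((q, q))
    trace = np.empty(max_iter)

    n_iter = 0
    converged = False
    for it in range(max_iter):
        r = _residual(Xc, Zc, pj, pk, yc, vbp, vbm, vTh)
        _gradients(Xc, Zc, pj, pk, r, gbp, gbm, gTh)
        _prox_step(vbp, vbm, vTh, gbp, gbm, gTh, step, lam, nbp, nbm, nTh)
        fc = _objective(Xc, Zc, pj, pk, yc, lam, nbp, nbm, nTh)
        if fc > fx:
            # accelerated candidate not monotone: plain descent step instead
            r = _residual(Xc, Zc, pj, pk, yc, bp, bm, Th)
            _gradients(Xc, Zc, pj, pk, r, gbp, gbm, gTh)
            _prox_step(bp, bm, Th, gbp, gbm, gTh, step, lam, nbp, nbm, nTh)
            fc = _objective(Xc, Zc, pj, pk, yc, lam, nbp, nbm, nTh)
            tk = 1.0
        tk_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        mom = (tk - 1.0) / tk_new
        for j in range(q):
            vbp[j] = nbp[j] + mom * (nbp[j] - bp[j])
            vbm[j] = nbm[j] + mom * (nbm[j] - bm[j])
            for k in range(q):
                vTh[j, k] = nTh[j, k] + mom * (nTh[j, k] - Th[j, k])
        tk = tk_new
        delta = abs(fx - fc)
        bp[:] = nbp
        bm[:] = nbm
        Th[:, :] = nTh
        fx = fc
        trace[it] = fx
        n_iter = it + 1
        if delta <= tol * max(1.0, abs(fx)):
            converged = True
            break
    return bp, bm, Th, n_iter, converged, fx, trace[:n_iter]
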