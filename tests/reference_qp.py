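"""Independent convex-programming oracle for the hierarchy relaxation.

Solves the identical split-variable problem (beta+/beta-, theta+/theta-,
per-row l1-cap constraints) with scipy's trust-region constrained
optimiser.  Used only to cross-check the package solver's objective value;
it shares no code path with the implementation.
"""

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize


def reference_objective(Xc, Zc, pairs, yc, lam):
    """Minimum objective of the relaxation, from a generic QP solver."""
    n, q = Xc.shape
    P = len(pairs)
    nv = 2 * q + 2 * q * q

    def unpack(v):
        bp = v[:q]
        bm = v[q : 2 * q]
        Tp = v[2 * q : 2 * q + q * q].reshape(q, q)
        Tm = v[2 * q + q * q :].reshape(q, q)
        return bp, bm, Tp, Tm

    def fobj(v):
        bp, bm, Tp, Tm = unpack(v)
        Th = Tp - Tm
        w = np.array([0.5 * (Th[j, k] + Th[k, j]) for j, k in pairs])
        r = Xc @ (bp - bm) + (Zc @ w if P else 0.0) - yc
        return 0.5 * r @ r + lam * (bp.sum() + bm.sum()) + 0.5 * lam * (Tp.sum() + Tm.sum())

    A = np.zeros((q, nv))
    for j in range(q):
        A[j, j] = -1.0
        A[j, q + j] = -1.0
        for k in range(q):
            if k != j:
                A[j, 2 * q + j * q + k] = 1.0
                A[j, 2 * q + q * q + j * q + k] = 1.0
    lb = np.zeros(nv)
    ub = np.full(nv, np.inf)
    for j in range(q):  # diagonal of theta fixed at zero
        ub[2 * q + j * q + j] = 0.0
        ub[2 * q + q * q + j * q + j] = 0.0
    res = minimize(
        fobj,
        np.zeros(nv),
        method="trust-constr",
        bounds=Bounds(lb, ub),
        constraints=[LinearConstraint(A, -np.inf, 0.0)],
        options=dict(gtol=1e-12, xtol=1e-14, maxiter=3000),
    )
    return float(res.fun)
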