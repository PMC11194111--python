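"""Strong-hierarchy interaction lasso (model / results / regularization path).

The model predicts a protein-binding profile ``y`` from a binary
modification design with all pairwise products,

    y = beta0 + sum_j beta_j L_j + sum_{j<k} theta_jk L_j L_k + eps,

where ``theta_jk`` is the single-count interaction effect of the unordered
pair (j, k): its total contribution to a fitted value is
``theta_jk * L_j * L_k``.  Both coefficient blocks carry an l1 penalty and
the strong-hierarchy (heredity) constraint ``theta_jk != 0 => beta_j != 0
and beta_k != 0`` is imposed through the standard convex relaxation (split
``beta = beta+ - beta-`` with a per-row l1 cap on theta).  Predictors are
column-centered but not scaled — all features are binary and on a common
scale — so coefficients stay in response units; the intercept absorbs the
centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._solver import solve_hier
from .design import InteractionDesign

__all__ = [
    "HierarchicalLasso",
    "HierarchicalLassoResults",
    "RegularizationPath",
    "ConvergenceError",
    "ZERO_THRESHOLD",
]

#: magnitude below which a coefficient is reported as exactly zero
ZERO_THRESHOLD = 1e-8


class ConvergenceError(RuntimeError):
    """Solver failed to reach the requested tolerance."""

    def __init__(self, msg: str, objective: float, achieved: float):
        super().__init__(msg)
        self.objective = objective
        self.achieved = achieved


class HierarchicalLasso:
    """Hierarchical interaction lasso for one response profile.

    Parameters
    ----------
    endog : array-like of shape (n,)
        Response (e.g. SILAC log-ratio binding profile); must be finite.
    idesign : InteractionDesign
        Expanded (and screened) binary design.
    zero_threshold : float
        Reporting threshold below which coefficients are set to exact zero.
    """

    def __init__(self, endog, idesign: InteractionDesign, *, zero_threshold: float = ZERO_THRESHOLD):
        y = np.asarray(endog, dtype=float).ravel()
        if y.shape[0] != idesign.design.n:
            raise ValueError("endog length does not match design rows")
        if not np.isfinite(y).all():
            raise ValueError("endog must be finite (handle missing values upstream)")
        if idesign.design.n < 4:
            raise ValueError("need at least 4 rows to fit")
        self.idesign = idesign
        self.endog = y
        self.zero_threshold = float(zero_threshold)

        X = idesign.main_cols.astype(float)
        Z = idesign.pair_cols.astype(float)
        self._xmean = X.mean(axis=0)
        self._zmean = Z.mean(axis=0) if Z.shape[1] else np.zeros(0)
        self._ymean = float(y.mean())
        self.Xc = X - self._xmean
        self.Zc = Z - self._zmean
        self.yc = y - self._ymean
        self.pair_j = np.array([j for j, _ in idesign.pair_index], dtype=np.int64)
        self.pair_k = np.array([k for _, k in idesign.pair_index], dtype=np.int64)

        A = np.hstack([self.Xc, -self.Xc, 0.5 * self.Zc, 0.5 * self.Zc])
        s = np.linalg.svd(A, compute_uv=False)
        self._lipschitz = float(s[0] ** 2) if s.size else 1.0

    # ------------------------------------------------------------- lambdas

    def lambda_max(self) -> float:
        """Smallest penalty at which the all-zero solution is optimal."""
        vals = [abs(float(self.Xc[:, j] @ self.yc)) for j in range(self.Xc.shape[1])]
        vals += [abs(float(self.Zc[:, p] @ self.yc)) for p in range(self.Zc.shape[1])]
        return max(vals) if vals else 0.0

    def lambda_path(self, n_lambda: int = 20, ratio: float = 0.01) -> np.ndarray:
        """Log-spaced decreasing penalty grid from lambda_max down to
        ``ratio * lambda_max``."""
        if n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0.0 < ratio < 1.0:
            raise ValueError("ratio must be in (0, 1)")
        lmax = self.lambda_max()
        if lmax <= 0.0:
            raise ValueError("response has no variance (lambda_max = 0)")
        return np.exp(np.linspace(np.log(lmax), np.log(ratio * lmax), n_lambda))

    # ----------------------------------------------------------------- fit

    def fit(
        self,
        lam: float,
        *,
        start=None,
        tol: float = 1e-7,
        max_iter: int = 5000,
        debug: bool = False,
    ) -> "HierarchicalLassoResults":
        """Fit at a single penalty.  ``start`` is a raw (bp, bm, Th) warm
        start; ``debug=True`` retains the per-iteration objective trace."""
        if lam <= 0:
            raise ValueError("lam must be positive")
        q = self.Xc.shape[1]
        if start is None:
            bp0 = np.zeros(q)
            bm0 = np.zeros(q)
            Th0 = np.zeros((q, q))
        else:
            bp0, bm0, Th0 = (np.array(a, dtype=float) for a in start)
        step = 1.0 / max(self._lipschitz, 1e-12)
        bp, bm, Th, n_iter, ok, obj, trace = solve_hier(
            self.Xc,
            self.Zc,
            self.pair_j,
            self.pair_k,
            self.yc,
            float(lam),
            step,
            bp0,
            bm0,
            Th0,
            float(tol),
            int(max_iter),
        )
        if not ok:
            achieved = abs(trace[-1] - trace[-2]) if len(trace) > 1 else np.inf
            raise ConvergenceError(
                f"hierarchical lasso did not converge in {max_iter} iterations "
                f"(objective {obj:.6g}, last change {achieved:.3g})",
                objective=float(obj),
                achieved=float(achieved),
            )
        return self._package(lam, bp, bm, Th, obj, n_iter, trace if debug else None)

    def _package(self, lam, bp, bm, Th, obj, n_iter, trace) -> "HierarchicalLassoResults":
        thr = self.zero_threshold
        beta = bp - bm
        beta[np.abs(beta) < thr] = 0.0
        theta = 0.5 * (Th + Th.T)  # exact symmetrization; objective unchanged
        theta[np.abs(theta) < thr] = 0.0
        np.fill_diagonal(theta, 0.0)
        # intercept on the original (uncentered) feature scale
        w = np.array([theta[j, k] for j, k in self.idesign.pair_index])
        beta0 = self._ymean - float(self._xmean @ beta) - float(self._zmean @ w if w.size else 0.0)
        return HierarchicalLassoResults(
            model=self,
            lam=float(lam),
            beta0=beta0,
            beta=beta,
            theta=theta,
            objective=float(obj),
            n_iter=int(n_iter),
            raw=(bp, bm, Th),
            objective_trace=trace,
        )

    def fit_path(
        self,
        lambdas=None,
        *,
        n_lambda: int = 20,
        ratio: float = 0.01,
        tol: float = 1e-7,
        max_iter: int = 5000,
        stop_after_entered: int | None = None,
    ) -> "RegularizationPath":
        """Fit a decreasing penalty sequence with warm starts.

        ``stop_after_entered`` truncates the walk at the first grid point
        where at least that many distinct features have entered (used by
        the first-k stability selector; the returned path is partial).
        """
        if lambdas is None:
            lambdas = self.lambda_path(n_lambda=n_lambda, ratio=ratio)
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.size < 1 or np.any(np.diff(lambdas) >= 0):
            raise ValueError("lambdas must be strictly decreasing")
        results = []
        entry_order: list[tuple[str, int]] = []
        entered: set[str] = set()
        start = None
        for i, lam in enumerate(lambdas):
            try:
                res = self.fit(lam, start=start, tol=tol, max_iter=max_iter)
            except ConvergenceError as err:
                raise ConvergenceError(
                    f"path fit failed at lambda index {i} ({lam:.4g}): {err}",
                    objective=err.objective,
                    achieved=err.achieved,
                ) from err
            res = res.enforce_hierarchy()
            start = res.raw
            for lab in res.active_set:
                if lab not in entered:
                    entered.add(lab)
                    entry_order.append((lab, i))
            results.append(res)
            if stop_after_entered is not None and len(entered) >= stop_after_entered:
                break
        return RegularizationPath(
            lambdas=lambdas[: len(results)], results=results, entry_order=entry_order
        )


@dataclass
class HierarchicalLassoResults:
    """Fitted coefficients at one penalty level.

    ``theta`` is the symmetric single-count interaction matrix (zero
    diagonal); ``active_set`` lists feature labels whose reported
    coefficient magnitude exceeds the model's zero threshold.
    """

    model: HierarchicalLasso
    lam: float
    beta0: float
    beta: np.ndarray
    theta: np.ndarray
    objective: float
    n_iter: int
    raw: tuple
    objective_trace: np.ndarray | None = None
    hierarchy_clean: bool = False

    @property
    def active_set(self) -> list[str]:
        labs = self.model.idesign.design.col_labels
        out = [labs[j] for j in range(len(labs)) if self.beta[j] != 0.0]
        for (j, k), plab in zip(
            self.model.idesign.pair_index, self.model.idesign.pair_labels
        ):
            if self.theta[j, k] != 0.0:
                out.append(plab)
        return out

    def pair_coefficients(self) -> np.ndarray:
        """theta values in the pair-column order of the design."""
        return np.array([self.theta[j, k] for j, k in self.model.idesign.pair_index])

    def predict(self, idesign: InteractionDesign | None = None) -> np.ndarray:
        idx = idesign if idesign is not None else self.model.idesign
        w = np.array([self.theta[j, k] for j, k in idx.pair_index])
        return (
            self.beta0
            + idx.main_cols.astype(float) @ self.beta
            + (idx.pair_cols.astype(float) @ w if w.size else 0.0)
        )

    def enforce_hierarchy(self) -> "HierarchicalLassoResults":
        """Zero every interaction with a zeroed parent main effect.

        Strong heredity requires both parents active; after reporting-level
        thresholding the relaxed solution can carry a tiny interaction whose
        parent main effect was rounded to zero — those entries are cleared.
        """
        theta = self.theta.copy()
        active = self.beta != 0.0
        for j in range(theta.shape[0]):
            for k in range(theta.shape[1]):
                if theta[j, k] != 0.0 and not (active[j] and active[k]):
                    theta[j, k] = 0.0
        out = HierarchicalLassoResults(
            model=self.model,
            lam=self.lam,
            beta0=self.beta0,
            beta=self.beta.copy(),
            theta=theta,
            objective=self.objective,
            n_iter=self.n_iter,
            raw=self.raw,
            objective_trace=self.objective_trace,
            hierarchy_clean=True,
        )
        return out

    def summary(self) -> str:
        lines = [
            "Hierarchical interaction lasso",
            f"  lambda = {self.lam:.6g}   objective = {self.objective:.6g}   iters = {self.n_iter}",
            f"  intercept = {self.beta0:.4f}",
            "  active features:",
        ]
        labs = self.model.idesign.design.col_labels
        for j, lab in enumerate(labs):
            if self.beta[j] != 0.0:
                lines.append(f"    {lab:<20s} {self.beta[j]: .4f}")
        for (j, k), plab in zip(
            self.model.idesign.pair_index, self.model.idesign.pair_labels
        ):
            if self.theta[j, k] != 0.0:
                lines.append(f"    {plab:<20s} {self.theta[j, k]: .4f}")
        return "\n".join(lines)


@dataclass
class RegularizationPath:
    """Warm-started fits along a decreasing penalty grid.

    ``entry_order`` records, per feature label, the first grid index at
    which its coefficient magnitude exceeded the zero threshold.
    """

    lambdas: np.ndarray
    results: list[HierarchicalLassoResults]
    entry_order: list[tuple[str, int]]

    def entered_first_k(self, k: int) -> list[str]:
        """Labels of features entered up to the first grid point at which the
        cumulative entered count reaches k (all entered features if the path
        enters fewer than k; ties at a grid point are all kept)."""
        entered: list[str] = []
        by_index: dict[int, list[str]] = {}
        for lab, i in self.entry_order:
            by_index.setdefault(i, []).append(lab)
        for i in sorted(by_index):
            entered.extend(by_index[i])
            if len(entered) >= k:
                break
        return entered

    def to_frame(self):
        import pandas as pd

        rows = []
        for lam, res in zip(self.lambdas, self.results):
            labs = res.model.idesign.design.col_labels
            for j, lab in enumerate(labs):
                rows.append((lam, lab, res.beta[j]))
            for (j, k), plab in zip(
                res.model.idesign.pair_index, res.model.idesign.pair_labels
            ):
                rows.append((lam, plab, res.theta[j, k]))
        return pd.DataFrame(rows, columns=["lambda", "feature", "coefficient"])
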