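"""Complementary-pairs stability selection (CPSS) over the hierarchy path.

CPSS draws ``B`` complementary pairs of disjoint half-samples
``{(A_{2h-1}, A_{2h}) : h = 1..B}`` of size ``floor(n/2)`` and, on each of
the ``2B`` half-samples, runs the hierarchical-lasso path recording the
first ``k`` features to enter.  A feature's selection probability is its
inclusion frequency

    pi_hat(j) = (1 / 2B) * sum_h  1{ j in S_hat(A_h) },

and the stable set is ``{j : pi_hat(j) >= pi_thr}``.  Selection operates on
hierarchy-enforced active sets, so an interaction can never be stable in a
half-sample without both parent main effects being active in that same fit.

Defaults (``B=50``, ``k=12``, ``pi_thr=0.5``) target the nucleosome-library
regime of roughly 33 experiments and 78 candidate coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import InteractionDesign
from .hierlasso import ConvergenceError, HierarchicalLasso

__all__ = [
    "CpssConfig",
    "StabilityProfile",
    "StabilitySelection",
    "draw_complementary_pairs",
    "first_k_selector",
    "estimate_selection_probabilities",
    "threshold_select",
]


@dataclass(frozen=True)
class CpssConfig:
    """Hyper-parameters of complementary-pairs stability selection."""

    B: int = 50
    k: int = 12
    pi_thr: float = 0.5
    seed: int = 0
    n_lambda: int = 20
    ratio: float = 0.01
    tol: float = 1e-7
    max_iter: int = 5000
    max_failure_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.pi_thr <= 1.0:
            raise ValueError("pi_thr must be in (0, 1]")


def draw_complementary_pairs(n: int, B: int, seed) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``B`` complementary pairs of disjoint index sets of size n//2.

    For odd ``n`` one index per pair is left out (uniformly at random, freshly
    per pair).  ``seed`` may be an int or a numpy Generator.
    """
    if n < 4:
        raise ValueError("too few samples for subsampling (need n >= 4)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = n // 2
    pairs = []
    for _ in range(B):
        perm = rng.permutation(n)
        pairs.append((np.sort(perm[:half]), np.sort(perm[half : 2 * half])))
    return pairs


def first_k_selector(
    endog,
    idesign: InteractionDesign,
    indices: np.ndarray,
    k: int,
    *,
    n_lambda: int = 20,
    ratio: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> set[str]:
    """First-k feature selector on one half-sample.

    Walks the penalty path from large to small, accumulating feature entry
    order (on hierarchy-enforced active sets), and returns every feature
    entered up to the first grid point at which the cumulative entered count
    reaches ``k`` — ties at a grid point are all kept, so the set can exceed
    ``k``.  If the whole path enters fewer than ``k`` features, all entered
    features are returned.
    """
    y = np.asarray(endog, dtype=float)[indices]
    sub = idesign.subset_rows(indices)
    model = HierarchicalLasso(y, sub)
    path = model.fit_path(
        n_lambda=n_lambda, ratio=ratio, tol=tol, max_iter=max_iter, stop_after_entered=k
    )
    return set(path.entered_first_k(k))


@dataclass
class StabilityProfile:
    """Per-feature selection probabilities from one CPSS run."""

    pi_hat: pd.Series
    subsample_sets: list[np.ndarray]
    config: CpssConfig
    n_failed: int = 0
    failed_ids: list[int] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return threshold_select(self, self.config.pi_thr)

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "feature": self.pi_hat.index,
                "pi_hat": self.pi_hat.values,
                "selected": [f in sel for f in self.pi_hat.index],
            }
        )

    def plot(self, ax=None, pi_thr: float | None = None):
        """Stability 'lollipop' plot: features vs selection probability."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, max(3, 0.18 * len(self.pi_hat))))
        thr = self.config.pi_thr if pi_thr is None else pi_thr
        order = np.argsort(self.pi_hat.values)
        vals = self.pi_hat.values[order]
        labs = self.pi_hat.index[order]
        ax.hlines(range(len(vals)), 0, vals, color="0.6", lw=1)
        ax.plot(vals, range(len(vals)), "o", ms=3, color="C0")
        ax.axvline(thr, color="C3", ls="--", lw=1)
        ax.set_yticks(range(len(vals)))
        ax.set_yticklabels(labs, fontsize=6)
        ax.set_xlabel(r"selection probability $\hat{\pi}$")
        ax.set_xlim(0, 1)
        return ax


def threshold_select(profile: StabilityProfile, pi_thr: float) -> list[str]:
    """Stable set at a (possibly re-chosen) threshold; no refitting needed."""
    if not 0.0 < pi_thr <= 1.0:
        raise ValueError("pi_thr must be in (0, 1]")
    return [f for f, p in profile.pi_hat.items() if p >= pi_thr]


class StabilitySelection:
    """CPSS estimator for one response profile over an expanded design."""

    def __init__(self, endog, idesign: InteractionDesign, config: CpssConfig | None = None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.idesign = idesign
        self.config = config or CpssConfig()
        if self.config.k > idesign.n_features:
            raise ValueError("k exceeds the number of candidate features")

    def fit(self, pairs: list[tuple[np.ndarray, np.ndarray]] | None = None) -> StabilityProfile:
        cfg = self.config
        n = self.endog.shape[0]
        if pairs is None:
            pairs = draw_complementary_pairs(n, cfg.B, cfg.seed)
        sets: list[np.ndarray] = [s for pair in pairs for s in pair]
        counts: dict[str, int] = {f: 0 for f in self.idesign.feature_labels}
        failed: list[int] = []
        for h, idx in enumerate(sets):
            try:
                sel = first_k_selector(
                    self.endog,
                    self.idesign,
                    idx,
                    cfg.k,
                    n_lambda=cfg.n_lambda,
                    ratio=cfg.ratio,
                    tol=cfg.tol,
                    max_iter=cfg.max_iter,
                )
            except (ValueError, ConvergenceError) as err:
                # degenerate half-sample: counted as selecting nothing
                failed.append(h)
                warnings.warn(f"subsample {h} failed and selected nothing: {err}", stacklevel=2)
                continue
            for f in sel:
                counts[f] += 1
        denom = 2 * cfg.B
        if len(failed) > cfg.max_failure_rate * denom:
            raise RuntimeError(
                f"{len(failed)} of {denom} subsample fits failed "
                f"(> {cfg.max_failure_rate:.0%}); first failures: {failed[:5]}"
            )
        pi = pd.Series(
            {f: counts[f] / denom for f in self.idesign.feature_labels}, name="pi_hat"
        )
        return StabilityProfile(
            pi_hat=pi,
            subsample_sets=sets,
            config=cfg,
            n_failed=len(failed),
            failed_ids=failed,
        )


def estimate_selection_probabilities(
    endog, idesign: InteractionDesign, config: CpssConfig | None = None, *, pairs=None
) -> StabilityProfile:
    """Functional wrapper around :class:`StabilitySelection`."""
    return StabilitySelection(endog, idesign, config).fit(pairs=pairs)
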