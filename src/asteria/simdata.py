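"""Synthetic nucleosome designs and replicate binding profiles.

The generator emulates the statistical structure of a designed di-nucleosome
modification library probed by label-swap affinity-purification replicates:
a small, imbalanced binary design (default 33 experiments x 12
modifications) with co-occurring modification blocks, a sparse
hierarchy-respecting truth (interactions only between true main effects),
independent Gaussian replicate noise, optional sign-discordant corruption of
the reverse replicate, and optional missing entries.  Ground truth is
attached to every dataset so recovery can be scored exactly.

Default truth: two positive main effects (+1.5 and +1.0 response units) and
one positive interaction (+1.0) between them, with noise sd 0.25 — a
recovery problem that is neither trivial nor hopeless at the default design
size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpss import CpssConfig, StabilitySelection
from .design import DesignMatrix, expand_interactions, pair_name
from .hierlasso import HierarchicalLasso
from .pipeline import ReplicateProfiles

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_design",
    "simulate_profiles",
    "simulate_dataset",
    "compare_cpss_vs_cv",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings (defaults are the package's study conditions)."""

    n: int = 33
    q: int = 12
    design_mode: str = "blocky"  # bernoulli | blocky | user
    bernoulli_p: float = 0.3
    co_occur_blocks: tuple[tuple[int, ...], ...] = ((0, 1, 2), (3, 4, 5))
    block_on_p: float = 0.4
    block_coupling: float = 0.6
    block_background_p: float = 0.15
    max_column_corr: float = 0.95
    user_design: pd.DataFrame | None = None
    main_effects: tuple[float, ...] | None = (1.5, 1.0)
    interaction_effects: tuple[float, ...] | None = (1.0,)
    s_main: int = 2
    s_int: int = 1
    effect_range: tuple[float, float] = (0.5, 1.5)
    beta0: float = 0.0
    sigma: float = 0.25
    rho_signflip: float = 0.0
    miss_rate: float = 0.0
    n_proteins: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        s_main = len(self.main_effects) if self.main_effects is not None else self.s_main
        s_int = (
            len(self.interaction_effects)
            if self.interaction_effects is not None
            else self.s_int
        )
        if s_int > s_main * (s_main - 1) // 2:
            raise ValueError("more interactions than pairs of true main effects")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for name in (
            "rho_signflip",
            "miss_rate",
            "bernoulli_p",
            "block_on_p",
            "block_coupling",
            "block_background_p",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")


@dataclass
class SimTruth:
    """Planted coefficients; always strong-hierarchy by construction."""

    beta0: float
    beta: np.ndarray
    theta: np.ndarray
    col_labels: list[str]

    @property
    def main_features(self) -> list[str]:
        return [lab for lab, b in zip(self.col_labels, self.beta) if b != 0]

    @property
    def pair_features(self) -> list[str]:
        out = []
        q = len(self.col_labels)
        for j in range(q):
            for k in range(j + 1, q):
                if self.theta[j, k] != 0:
                    out.append(pair_name(self.col_labels[j], self.col_labels[k]))
        return out

    @property
    def feature_set(self) -> set[str]:
        return set(self.main_features) | set(self.pair_features)

    def signal(self, design: DesignMatrix) -> np.ndarray:
        L = design.values.astype(float)
        s = self.beta0 + L @ self.beta
        q = L.shape[1]
        for j in range(q):
            for k in range(j + 1, q):
                if self.theta[j, k] != 0:
                    s = s + self.theta[j, k] * L[:, j] * L[:, k]
        return s

    def assert_hierarchy(self) -> None:
        nz = self.beta != 0
        bad = [
            (j, k)
            for j in range(len(nz))
            for k in range(len(nz))
            if self.theta[j, k] != 0 and not (nz[j] and nz[k])
        ]
        if bad:  # pragma: no cover - generator contract
            raise AssertionError(f"planted interactions violate hierarchy: {bad}")


@dataclass
class SimDataset:
    design: DesignMatrix
    truth: SimTruth
    profiles: list[ReplicateProfiles]
    config: SimConfig
    seed: int

    def write(self, outdir) -> None:
        """Write design/forward/reverse/truth as CSV files."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.design.to_frame().to_csv(out / "design.csv")
        fw = pd.DataFrame(
            {p.protein_id: p.forward for p in self.profiles}, index=self.design.row_labels
        )
        rv = pd.DataFrame(
            {p.protein_id: p.reverse for p in self.profiles}, index=self.design.row_labels
        )
        fw.to_csv(out / "forward.csv")
        rv.to_csv(out / "reverse.csv")
        rows = [("(intercept)", "", self.truth.beta0)]
        for lab, b in zip(self.truth.col_labels, self.truth.beta):
            if b != 0:
                rows.append((lab, "main", b))
        q = len(self.truth.col_labels)
        for j in range(q):
            for k in range(j + 1, q):
                if self.truth.theta[j, k] != 0:
                    rows.append(
                        (
                            pair_name(self.truth.col_labels[j], self.truth.col_labels[k]),
                            "interaction",
                            self.truth.theta[j, k],
                        )
                    )
        pd.DataFrame(rows, columns=["feature", "kind", "value"]).to_csv(
            out / "truth.csv", index=False
        )


# ----------------------------------------------------------------- design


def _draw_design_once(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n, q = config.n, config.q
    L = (rng.random((n, q)) < config.bernoulli_p).astype(np.int8)
    if config.design_mode == "blocky":
        # block columns share a latent per-experiment block state: the state
        # raises joint occurrence without making columns near-identical
        # (near-identical columns belong to the unscreened library and are
        # rejected below, as the collinearity screen would remove them)
        for block in config.co_occur_blocks:
            cols = [c for c in block if c < q]
            if len(cols) < 2:
                continue
            on = rng.random(n) < config.block_on_p
            for c in cols:
                with_block = on & (rng.random(n) < config.block_coupling)
                background = rng.random(n) < config.block_background_p
                L[:, c] = (with_block | background).astype(np.int8)
    return L


def _design_valid(L: np.ndarray, max_corr: float) -> bool:
    q = L.shape[1]
    sums = L.sum(axis=0)
    if (sums == 0).any() or (sums == L.shape[0]).any():
        return False
    if len({L[:, j].tobytes() for j in range(q)}) < q:
        return False
    C = np.corrcoef(L.astype(float), rowvar=False)
    off = np.abs(C[~np.eye(q, dtype=bool)])
    return bool(np.nanmax(off) < max_corr)


def simulate_design(config: SimConfig, rng: np.random.Generator | None = None) -> DesignMatrix:
    """Draw a valid binary design (no all-zero and no duplicate columns).

    ``user`` mode passes ``config.user_design`` through unchanged.
    Invalid draws are rejected and redrawn (up to 1000 times).
    """
    if config.design_mode == "user":
        if config.user_design is None:
            raise ValueError("design_mode='user' requires user_design")
        df = config.user_design
        return DesignMatrix(
            df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns]
        )
    if config.design_mode not in ("bernoulli", "blocky"):
        raise ValueError(f"unknown design_mode {config.design_mode!r}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    row_labels = [f"N{i+1:02d}" for i in range(config.n)]
    col_labels = [f"M{j+1:02d}" for j in range(config.q)]
    for _ in range(1000):
        L = _draw_design_once(config, rng)
        if not _design_valid(L, config.max_column_corr):
            continue
        return DesignMatrix(L, row_labels, col_labels)
    raise RuntimeError("could not draw a valid design in 1000 attempts (config infeasible)")


# ------------------------------------------------------------------ truth


def _draw_truth(config: SimConfig, design: DesignMatrix, rng: np.random.Generator) -> SimTruth:
    q = design.q
    if config.main_effects is not None:
        main_vals = list(config.main_effects)
    else:
        lo, hi = config.effect_range
        main_vals = [
            float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
            for _ in range(config.s_main)
        ]
    s_main = len(main_vals)
    mains = rng.choice(q, size=s_main, replace=False)
    beta = np.zeros(q)
    for j, v in zip(mains, main_vals):
        beta[j] = v
    if config.interaction_effects is not None:
        int_vals = list(config.interaction_effects)
    else:
        lo, hi = config.effect_range
        int_vals = [
            float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
            for _ in range(config.s_int)
        ]
    pairs = list(itertools.combinations(sorted(mains), 2))
    theta = np.zeros((q, q))
    if int_vals:
        chosen = rng.choice(len(pairs), size=len(int_vals), replace=False)
        for idx, v in zip(chosen, int_vals):
            j, k = pairs[idx]
            theta[j, k] = theta[k, j] = v
    truth = SimTruth(config.beta0, beta, theta, list(design.col_labels))
    truth.assert_hierarchy()
    return truth


# ---------------------------------------------------------------- profiles


def simulate_profiles(
    design: DesignMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    truth: SimTruth | None = None,
) -> SimDataset:
    """Generate forward/reverse replicate profiles with attached truth.

    Both replicates share the model signal and carry independent
    Gaussian(0, sigma^2) noise; with probability ``rho_signflip`` a reverse
    entry has its sign flipped, and entries go missing (NaN) independently
    at ``miss_rate`` in each replicate.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if truth is None:
        truth = _draw_truth(config, design, rng)
    signal = truth.signal(design)
    n = design.n
    profiles = []
    for i in range(config.n_proteins):
        fwd = signal + config.sigma * rng.standard_normal(n)
        rev = signal + config.sigma * rng.standard_normal(n)
        if config.rho_signflip > 0:
            flip = rng.random(n) < config.rho_signflip
            rev = np.where(flip, -rev, rev)
        for vec in (fwd, rev):
            if config.miss_rate > 0:
                vec[rng.random(n) < config.miss_rate] = np.nan
        profiles.append(ReplicateProfiles(f"P{i+1:03d}", fwd, rev))
    return SimDataset(design, truth, profiles, config, config.seed)


def simulate_dataset(config: SimConfig, seed: int | None = None) -> SimDataset:
    """Design + truth + profiles in one call (seed overrides config.seed)."""
    use_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    design = simulate_design(config, rng)
    ds = simulate_profiles(design, config, rng)
    ds.seed = use_seed
    return ds


# --------------------------------------------------- CPSS vs cross-validation


def _cv_select(
    y: np.ndarray,
    idesign,
    *,
    n_folds: int = 10,
    n_lambda: int = 20,
    ratio: float = 0.01,
    rng: np.random.Generator | None = None,
) -> set[str]:
    """Select features by k-fold cross-validated penalty choice.

    The penalty grid comes from the full-data path; each fold refits the
    path on the training rows and scores validation MSE; the active
    (hierarchy-enforced) set of the full-data fit at the CV-optimal penalty
    is returned.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n = y.shape[0]
    model = HierarchicalLasso(y, idesign)
    lambdas = model.lambda_path(n_lambda=n_lambda, ratio=ratio)
    folds = np.array_split(rng.permutation(n), n_folds)
    errs = np.zeros((n_folds, len(lambdas)))
    for f, val in enumerate(folds):
        train = np.setdiff1d(np.arange(n), val)
        sub = idesign.subset_rows(train)
        path = HierarchicalLasso(y[train], sub).fit_path(lambdas=lambdas, max_iter=20000)
        val_design = idesign.subset_rows(val)
        for i, res in enumerate(path.results):
            pred = res.predict(val_design)
            errs[f, i] = float(np.mean((y[val] - pred) ** 2))
    best = int(np.argmin(errs.mean(axis=0)))
    full = model.fit_path(lambdas=lambdas, max_iter=20000)
    return set(full.results[best].active_set)


def compare_cpss_vs_cv(
    config: SimConfig,
    n_seeds: int = 50,
    *,
    seed0: int = 0,
    cv_folds: int = 10,
    cpss_config: CpssConfig | None = None,
) -> pd.DataFrame:
    """Paired per-seed comparison of CPSS and cross-validated selection.

    For each seed one dataset is generated; both selectors run on the same
    forward-replicate response and are scored against the planted truth on
    interaction features only: false-positive count and true-positive rate
    (NaN when no interaction is planted).  Deterministic given
    ``(config, n_seeds, seed0)``.
    """
    rows = []
    for s in range(n_seeds):
        ds = simulate_dataset(config, seed=seed0 + s)
        idesign = expand_interactions(ds.design)
        y = ds.profiles[0].forward
        truth_pairs = set(ds.truth.pair_features)

        cfg = cpss_config or CpssConfig(seed=seed0 + s)
        cpss_sel = {
            f for f in StabilitySelection(y, idesign, cfg).fit().selected if ":" in f
        }
        cv_sel = {
            f
            for f in _cv_select(
                y,
                idesign,
                n_folds=cv_folds,
                n_lambda=cfg.n_lambda,
                ratio=cfg.ratio,
                rng=np.random.default_rng(seed0 + s),
            )
            if ":" in f
        }

        def _score(sel: set[str]) -> tuple[int, float]:
            fp = len(sel - truth_pairs)
            tpr = (
                len(sel & truth_pairs) / len(truth_pairs) if truth_pairs else float("nan")
            )
            return fp, tpr

        cpss_fp, cpss_tpr = _score(cpss_sel)
        cv_fp, cv_tpr = _score(cv_sel)
        rows.append(
            {
                "seed": seed0 + s,
                "cpss_fp": cpss_fp,
                "cpss_tpr": cpss_tpr,
                "cv_fp": cv_fp,
                "cv_tpr": cv_tpr,
            }
        )
    return pd.DataFrame(rows)
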