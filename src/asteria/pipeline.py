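"""Replicate-consistency workflow: sign filter, per-replicate CPSS, refit.

For every protein the workflow runs three steps on its forward/reverse
label-swap replicate pair:

1. **Sign consistency** — drop experiments (nucleosomes) where the two
   replicate measurements disagree in sign (exact zeros agree with
   anything; rows with a missing value in either replicate are dropped).
2. **Per-replicate selection** — complementary-pairs stability selection
   over the strong-hierarchy interaction lasso, run independently on each
   replicate; the two stable sets must be identical (*fully consistent*)
   or one nested in the other (*nested*), otherwise the protein is
   *inconsistent* and no model is reported.
3. **Refit** — unpenalised least squares of the averaged replicate response
   on the intersection of the two stable sets, yielding unbiased effect
   sizes, an adjusted R^2 (gate: >= 0.2 by default) and a mains-only
   adjusted R^2 for the variance decomposition.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cpss import CpssConfig, StabilityProfile, StabilitySelection
from .design import DesignMatrix, InteractionDesign, expand_interactions
from .modes import ModeLabel, classify_mode

__all__ = [
    "ReplicateProfiles",
    "ConsistencyVerdict",
    "FinalModel",
    "PipelineConfig",
    "ConsistencyPipeline",
    "PipelineResults",
    "sign_filter",
    "nested_consistency",
    "refit_ols",
    "run_pipeline",
]


@dataclass
class ReplicateProfiles:
    """Forward/reverse binding profile of one protein (NaN = missing)."""

    protein_id: str
    forward: np.ndarray
    reverse: np.ndarray

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float).ravel()
        self.reverse = np.asarray(self.reverse, dtype=float).ravel()
        if self.forward.shape != self.reverse.shape:
            raise ValueError("forward and reverse replicates differ in length")


@dataclass
class ConsistencyVerdict:
    status: str  # fully_consistent | nested | inconsistent | no_model
    retained_rows: list[str]
    set_forward: list[str]
    set_reverse: list[str]
    intersection: list[str]
    note: str = ""


@dataclass
class FinalModel:
    """Refit model for one protein (coefficients in response units)."""

    protein_id: str
    intercept: float
    coefficients: dict[str, float]
    adj_r2: float
    adj_r2_main_only: float
    verdict: ConsistencyVerdict
    passed_gate: bool
    modes: list[ModeLabel] = field(default_factory=list)

    @property
    def interaction_features(self) -> list[str]:
        return [f for f in self.coefficients if ":" in f]

    @property
    def has_interactions(self) -> bool:
        return len(self.interaction_features) > 0


def sign_filter(profiles: ReplicateProfiles) -> np.ndarray:
    """Boolean mask of experiments where the replicates agree in sign.

    A row is retained iff both values are present and either measurement is
    exactly zero or the two signs are equal (a zero log-ratio means no
    enrichment in either direction and contradicts neither replicate).
    """
    f, r = profiles.forward, profiles.reverse
    present = np.isfinite(f) & np.isfinite(r)
    agree = (np.sign(f) == np.sign(r)) | (f == 0) | (r == 0)
    return present & agree


def nested_consistency(set_f, set_r) -> str:
    """Compare two selected feature sets: equal, nested or inconsistent.

    Two empty sets are *fully_consistent* (the shared null model); an empty
    set is nested in any nonempty one.
    """
    sf, sr = set(set_f), set(set_r)
    if sf == sr:
        return "fully_consistent"
    if sf < sr or sr < sf:
        return "nested"
    return "inconsistent"


def refit_ols(
    idesign: InteractionDesign,
    rows: np.ndarray,
    features: list[str],
    y_avg: np.ndarray,
) -> tuple[float, dict[str, float], float, float]:
    """OLS refit with intercept on the selected features over retained rows.

    Returns (intercept, coefficients, adj_r2, adj_r2_main_only).  The
    mains-only refit uses the main-effect subset of ``features`` and feeds
    the variance decomposition between additive and interaction models.
    Raises ``np.linalg.LinAlgError`` on a rank-deficient design submatrix.
    """
    rows = np.asarray(rows)
    if rows.dtype == bool:
        rows = np.flatnonzero(rows)
    sub = idesign.subset_rows(rows)
    frame = sub.to_frame()
    y = np.asarray(y_avg, dtype=float)[rows]

    def _fit(feats: list[str]) -> tuple[float, dict[str, float], float]:
        if not feats:
            # intercept-only null model; adjusted R^2 defined as 0 for gating
            return float(np.mean(y)), {}, 0.0
        X = frame[feats].to_numpy(dtype=float)
        Xd = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient refit design for features {feats}"
            )
        fit = sm.OLS(y, Xd).fit()
        coefs = dict(zip(feats, map(float, fit.params[1:])))
        return float(fit.params[0]), coefs, float(fit.rsquared_adj)

    intercept, coefs, adj = _fit(list(features))
    mains = [f for f in features if ":" not in f]
    _, _, adj_main = _fit(mains)
    return intercept, coefs, adj, adj_main


@dataclass(frozen=True)
class PipelineConfig:
    """Workflow configuration (CPSS settings, gates, seed policy)."""

    cpss: CpssConfig = CpssConfig()
    r2_gate: float = 0.2
    min_rows: int = 8
    seed: int = 0
    shared_subsamples: bool = False  # reuse the same half-sample draws for F and R


def _protein_seed(master: int, protein_id: str, replicate: str) -> np.random.SeedSequence:
    # stable per-(protein, replicate) stream: adding proteins never shifts
    # the draws of the others
    return np.random.SeedSequence(
        [int(master), zlib.crc32(protein_id.encode()), zlib.crc32(replicate.encode())]
    )


class ConsistencyPipeline:
    """Full workflow over a cohort of proteins.

    Parameters
    ----------
    design : DesignMatrix
        Binary modification design shared by all proteins.
    profiles : list of ReplicateProfiles
        One forward/reverse pair per protein, aligned to the design rows.
    config : PipelineConfig
    """

    def __init__(
        self,
        design: DesignMatrix,
        profiles: list[ReplicateProfiles],
        config: PipelineConfig | None = None,
    ):
        self.design = design
        self.idesign = expand_interactions(design)
        self.profiles = list(profiles)
        self.config = config or PipelineConfig()
        for p in self.profiles:
            if p.forward.shape[0] != design.n:
                raise ValueError(
                    f"protein {p.protein_id!r}: profile length {p.forward.shape[0]} "
                    f"does not match design rows {design.n}"
                )

    @classmethod
    def from_frames(
        cls,
        design: DesignMatrix,
        forward: pd.DataFrame,
        reverse: pd.DataFrame,
        config: PipelineConfig | None = None,
    ) -> "ConsistencyPipeline":
        """Build from nucleosome x protein replicate tables (rows indexed by
        the design's nucleosome labels, one column per protein)."""
        for name, df in (("forward", forward), ("reverse", reverse)):
            if list(df.index) != list(design.row_labels):
                raise ValueError(f"{name} table rows do not match design row labels")
        if list(forward.columns) != list(reverse.columns):
            raise ValueError("forward and reverse tables list different proteins")
        profiles = [
            ReplicateProfiles(str(c), forward[c].to_numpy(float), reverse[c].to_numpy(float))
            for c in forward.columns
        ]
        return cls(design, profiles, config)

    # ------------------------------------------------------------------ fit

    def fit_protein(self, prof: ReplicateProfiles) -> tuple[FinalModel, dict[str, StabilityProfile]]:
        cfg = self.config
        mask = sign_filter(prof)
        retained = [lab for lab, m in zip(self.design.row_labels, mask) if m]
        stab: dict[str, StabilityProfile] = {}

        def _no_model(note: str, sf=(), sr=()) -> FinalModel:
            verdict = ConsistencyVerdict(
                "no_model", retained, sorted(sf), sorted(sr), [], note=note
            )
            return FinalModel(prof.protein_id, float("nan"), {}, 0.0, 0.0, verdict, False)

        if mask.sum() < cfg.min_rows:
            return _no_model(f"only {int(mask.sum())} sign-consistent rows"), stab

        rows = np.flatnonzero(mask)
        sub = self.idesign.subset_rows(rows)
        sets: dict[str, set[str]] = {}
        shared_pairs = None
        if cfg.shared_subsamples:
            from .cpss import draw_complementary_pairs

            ss = _protein_seed(cfg.seed, prof.protein_id, "shared")
            shared_pairs = draw_complementary_pairs(
                len(rows), cfg.cpss.B, np.random.default_rng(ss)
            )
        for rep, y in (("forward", prof.forward), ("reverse", prof.reverse)):
            seed = _protein_seed(cfg.seed, prof.protein_id, rep)
            rep_cfg = CpssConfig(
                B=cfg.cpss.B,
                k=cfg.cpss.k,
                pi_thr=cfg.cpss.pi_thr,
                seed=0,  # unused when pairs are passed explicitly
                n_lambda=cfg.cpss.n_lambda,
                ratio=cfg.cpss.ratio,
                tol=cfg.cpss.tol,
                max_iter=cfg.cpss.max_iter,
                max_failure_rate=cfg.cpss.max_failure_rate,
            )
            if shared_pairs is None:
                from .cpss import draw_complementary_pairs

                pairs = draw_complementary_pairs(
                    len(rows), cfg.cpss.B, np.random.default_rng(seed)
                )
            else:
                pairs = shared_pairs
            try:
                profile = StabilitySelection(y[rows], sub, rep_cfg).fit(pairs=pairs)
            except RuntimeError as err:
                return _no_model(f"CPSS failed on {rep} replicate: {err}"), stab
            stab[rep] = profile
            sets[rep] = set(profile.selected)

        status = nested_consistency(sets["forward"], sets["reverse"])
        intersection = sorted(sets["forward"] & sets["reverse"])
        verdict = ConsistencyVerdict(
            status, retained, sorted(sets["forward"]), sorted(sets["reverse"]), intersection
        )
        if status == "inconsistent":
            return (
                FinalModel(prof.protein_id, float("nan"), {}, 0.0, 0.0, verdict, False),
                stab,
            )
        if not intersection:
            verdict.status = "no_model"
            verdict.note = "empty intersection (null model)"
            return (
                FinalModel(prof.protein_id, float("nan"), {}, 0.0, 0.0, verdict, False),
                stab,
            )
        y_avg = 0.5 * (prof.forward + prof.reverse)
        try:
            intercept, coefs, adj, adj_main = refit_ols(
                self.idesign, rows, intersection, y_avg
            )
        except np.linalg.LinAlgError as err:
            return _no_model(f"refit dropped: {err}", sets["forward"], sets["reverse"]), stab
        model = FinalModel(
            protein_id=prof.protein_id,
            intercept=intercept,
            coefficients=coefs,
            adj_r2=adj,
            adj_r2_main_only=adj_main,
            verdict=verdict,
            passed_gate=adj >= cfg.r2_gate,
        )
        for feat in model.interaction_features:
            a, b = feat.split(":")
            if a in coefs and b in coefs and coefs[a] != 0 and coefs[b] != 0 and coefs[feat] != 0:
                model.modes.append(
                    classify_mode(coefs[a], coefs[b], coefs[feat], pair=(a, b))
                )
        return model, stab

    def fit(self, verbose: bool = False) -> "PipelineResults":
        models: list[FinalModel] = []
        stability: dict[str, dict[str, StabilityProfile]] = {}
        for prof in self.profiles:
            model, stab = self.fit_protein(prof)
            models.append(model)
            stability[prof.protein_id] = stab
            if verbose:
                print(f"{prof.protein_id}: {model.verdict.status}, adj R2 = {model.adj_r2:.3f}")
        return PipelineResults(self, models, stability)


@dataclass
class PipelineResults:
    """Cohort-level results: per-protein final models and stability profiles."""

    pipeline: ConsistencyPipeline
    final_models: list[FinalModel]
    stability: dict[str, dict[str, StabilityProfile]]

    @property
    def counts(self) -> dict[str, int]:
        c = {"fully_consistent": 0, "nested": 0, "inconsistent": 0, "no_model": 0}
        with_int = 0
        with_int_gated = 0
        for m in self.final_models:
            c[m.verdict.status] += 1
            if m.has_interactions:
                with_int += 1
                if m.passed_gate:
                    with_int_gated += 1
        c["with_interactions"] = with_int
        c["with_interactions_after_gate"] = with_int_gated
        return c

    def table(self) -> pd.DataFrame:
        rows = []
        for m in self.final_models:
            rows.append(
                {
                    "protein": m.protein_id,
                    "status": m.verdict.status,
                    "n_retained": len(m.verdict.retained_rows),
                    "features": ";".join(sorted(m.coefficients)),
                    "intercept": m.intercept,
                    "coefficients": ";".join(
                        f"{k}={v:.6g}" for k, v in sorted(m.coefficients.items())
                    ),
                    "adj_r2": m.adj_r2,
                    "adj_r2_main_only": m.adj_r2_main_only,
                    "passed_gate": m.passed_gate,
                    "modes": ";".join(
                        f"{lab.pair[0]}:{lab.pair[1]}={lab.direction_code}" for lab in m.modes
                    ),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Replicate-consistency workflow summary",
            f"  proteins analysed:            {len(self.final_models)}",
            f"  fully consistent models:      {c['fully_consistent']}",
            f"  nested models:                {c['nested']}",
            f"  inconsistent (removed):       {c['inconsistent']}",
            f"  no model:                     {c['no_model']}",
            f"  models with interactions:     {c['with_interactions']}",
            f"  ... passing the R^2 gate:     {c['with_interactions_after_gate']}",
        ]
        return "\n".join(lines)


def run_pipeline(
    design: DesignMatrix,
    profiles: list[ReplicateProfiles],
    config: PipelineConfig | None = None,
) -> PipelineResults:
    """Run the full three-step workflow over a cohort (functional wrapper)."""
    return ConsistencyPipeline(design, profiles, config).fit()
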