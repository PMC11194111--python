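"""Binary modification design matrices and their pairwise-interaction expansion.

The experimental unit is an engineered nucleosome carrying a defined
combination of chromatin modifications; the design matrix ``L`` is a binary
``n x q`` table (nucleosomes x modifications).  For interaction modelling the
design is expanded with one product column per unordered modification pair.
Because the library is constructed from biologically motivated modification
combinations rather than a factorial design, product columns can be exactly
collinear with each other or with main-effect columns; such redundancy must
be detected (and optionally resolved) before any model fitting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignMatrix",
    "InteractionDesign",
    "DesignFormatError",
    "DesignValidationError",
    "CollinearityError",
    "load_design",
    "expand_interactions",
    "screen_collinearity",
]


class DesignFormatError(ValueError):
    """A design file cell could not be parsed as 0/1."""


class DesignValidationError(ValueError):
    """A structurally invalid design (duplicate labels, all-zero column...)."""


class CollinearityError(ValueError):
    """Exact collinearity that cannot be resolved under the chosen policy."""


@dataclass(frozen=True)
class DesignMatrix:
    """Validated binary nucleosome x modification matrix.

    Attributes
    ----------
    values : ndarray of shape (n, q)
        Binary entries; ``values[i, j] == 1`` iff modification ``j`` is
        installed on nucleosome ``i``.
    row_labels : list of str
        Nucleosome identifiers (unique).
    col_labels : list of str
        Modification names (unique), e.g. ``"H3K27me3"``, ``"m5C"``.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise DesignValidationError("design must be a 2-D matrix")
        if not np.isin(vals, (0, 1)).all():
            raise DesignFormatError("design entries must all be 0 or 1")
        object.__setattr__(self, "values", vals.astype(np.int8))
        if len(self.row_labels) != vals.shape[0]:
            raise DesignValidationError("row_labels length does not match matrix")
        if len(self.col_labels) != vals.shape[1]:
            raise DesignValidationError("col_labels length does not match matrix")
        for kind, labels in (("row", self.row_labels), ("column", self.col_labels)):
            dupes = {x for x in labels if labels.count(x) > 1}
            if dupes:
                raise DesignValidationError(f"duplicate {kind} label(s): {sorted(dupes)}")
        zero_cols = [c for c, s in zip(self.col_labels, vals.sum(axis=0)) if s == 0]
        if zero_cols:
            raise DesignValidationError(
                "all-zero column(s) carry no information: " + ", ".join(zero_cols)
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def subset_rows(self, keep: np.ndarray) -> "DesignMatrix":
        """Return the design restricted to a boolean/index row selection."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return DesignMatrix(
            self.values[keep],
            [self.row_labels[i] for i in keep],
            list(self.col_labels),
        )


@dataclass(frozen=True)
class _RowSubsetDesign:
    """Unvalidated row view of a design, for subsample fits.

    Subsampling can zero out a modification column; that is legitimate for a
    half-sample fit (the centered column simply never enters), so the
    all-zero-column invariant of ``DesignMatrix`` must not apply here.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]


def pair_name(a: str, b: str) -> str:
    """Canonical name of the product column of modifications *a* and *b*."""
    return f"{a}:{b}"


@dataclass
class InteractionDesign:
    """Main + pairwise-product feature space of a binary design.

    ``pair_cols`` holds one column per unordered pair (j, k), j < k, in
    lexicographic order of the parent indices; entry i is
    ``values[i, j] * values[i, k]``.
    """

    design: DesignMatrix
    main_cols: np.ndarray
    pair_cols: np.ndarray
    pair_index: list[tuple[int, int]]
    pair_labels: list[str]
    dropped_rows: list[str] = field(default_factory=list)
    redundant_pairs: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.main_cols.shape[1] + self.pair_cols.shape[1]

    @property
    def feature_labels(self) -> list[str]:
        return list(self.design.col_labels) + list(self.pair_labels)

    def matrix(self) -> np.ndarray:
        """Full feature matrix [mains | pairs] as float."""
        return np.hstack([self.main_cols, self.pair_cols]).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix(), index=self.design.row_labels, columns=self.feature_labels
        )

    def subset_rows(self, rows) -> "InteractionDesign":
        """Row-restricted view (used for subsample and refit fits)."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        dm = _RowSubsetDesign(
            self.design.values[rows],
            [self.design.row_labels[i] for i in rows],
            list(self.design.col_labels),
        )
        return InteractionDesign(
            design=dm,  # type: ignore[arg-type]
            main_cols=self.main_cols[rows],
            pair_cols=self.pair_cols[rows],
            pair_index=list(self.pair_index),
            pair_labels=list(self.pair_labels),
            dropped_rows=list(self.dropped_rows),
            redundant_pairs=list(self.redundant_pairs),
        )


def load_design(path, *, sep: str = ",") -> DesignMatrix:
    """Load a binary design CSV (header = modification names, first column = IDs).

    Raises
    ------
    DesignFormatError
        If any cell is not 0 or 1 (the offending row/column is named).
    DesignValidationError
        On duplicate labels or an all-zero column.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=np.int8)
    for i, row_lab in enumerate(df.index):
        for j, col_lab in enumerate(df.columns):
            cell = str(df.iat[i, j]).strip()
            if cell not in ("0", "1"):
                raise DesignFormatError(
                    f"non-binary cell {cell!r} at row {row_lab!r}, column {col_lab!r}"
                )
            values[i, j] = int(cell)
    return DesignMatrix(values, [str(x) for x in df.index], [str(x) for x in df.columns])


def expand_interactions(design: DesignMatrix) -> InteractionDesign:
    """Expand a design with one product column per unordered modification pair.

    Self-products are not generated: for binary entries ``L_ij**2 == L_ij``,
    so a diagonal term would alias the main effect.  The total feature count
    is therefore ``q + q*(q-1)/2``.
    """
    vals = design.values
    q = design.q
    pairs = list(itertools.combinations(range(q), 2))
    if pairs:
        pair_cols = np.stack([vals[:, j] * vals[:, k] for j, k in pairs], axis=1)
    else:
        pair_cols = np.empty((design.n, 0), dtype=np.int8)
    labels = [pair_name(design.col_labels[j], design.col_labels[k]) for j, k in pairs]
    return InteractionDesign(
        design=design,
        main_cols=vals.copy(),
        pair_cols=pair_cols,
        pair_index=pairs,
        pair_labels=labels,
    )


def _identical_groups(columns: np.ndarray, labels: list[str]) -> list[list[str]]:
    """Group labels of exactly identical columns (groups of size >= 2)."""
    seen: dict[bytes, list[str]] = {}
    for j, lab in enumerate(labels):
        seen.setdefault(columns[:, j].tobytes(), []).append(lab)
    return [grp for grp in seen.values() if len(grp) > 1]


def screen_collinearity(
    idesign: InteractionDesign,
    *,
    policy: str = "drop_columns",
    exclude_rows: list[str] | None = None,
    near_collinear_warn: float = 0.99,
) -> InteractionDesign:
    """Detect and resolve exactly identical columns among mains and pairs.

    Exact column identity is the collinearity criterion — well-posed for
    binary data.  Two policies:

    - ``"drop_columns"`` (default): within each identical group keep the
      lexicographically first label; a main column always outranks a pair.
    - ``"drop_rows"``: remove the rows named in *exclude_rows* (mirrors the
      exclusion of partial-acetylation nucleosomes from the full library)
      and re-expand; if redundancy survives, an error lists the groups.

    Near-collinear (|r| >= *near_collinear_warn*) column pairs are reported
    as warnings but never dropped automatically.
    """
    if policy == "drop_rows":
        if not exclude_rows:
            raise ValueError("policy='drop_rows' requires an exclude_rows list")
        keep = [lab not in set(exclude_rows) for lab in idesign.design.row_labels]
        sub = idesign.design.subset_rows(np.asarray(keep))
        out = expand_interactions(sub)
        out.dropped_rows = [lab for lab in idesign.design.row_labels if lab in set(exclude_rows)]
        full = np.hstack([out.main_cols, out.pair_cols])
        groups = _identical_groups(full, out.feature_labels)
        if groups:
            raise CollinearityError(
                f"identical column groups remain after row exclusion: {groups}"
            )
        _warn_near_collinear(full, out.feature_labels, near_collinear_warn)
        return out

    if policy != "drop_columns":
        raise ValueError(f"unknown screening policy {policy!r}")

    full = np.hstack([idesign.main_cols, idesign.pair_cols])
    labels = idesign.feature_labels
    q = idesign.design.q
    groups = _identical_groups(full, labels)
    drop: set[str] = set()
    for grp in groups:
        mains = [g for g in grp if g in idesign.design.col_labels]
        if len(mains) > 1:
            # two identical modification columns cannot be disambiguated by
            # dropping product columns
            raise CollinearityError(
                f"identical main-effect columns {mains}; resolve by row exclusion"
            )
        keeper = mains[0] if mains else sorted(grp)[0]
        drop.update(g for g in grp if g != keeper)
    keep_pair = [
        (idx, lab)
        for idx, lab in zip(idesign.pair_index, idesign.pair_labels)
        if lab not in drop
    ]
    out = InteractionDesign(
        design=idesign.design,
        main_cols=idesign.main_cols.copy(),
        pair_cols=(
            idesign.pair_cols[:, [i for i, lab in enumerate(idesign.pair_labels) if lab not in drop]]
            if idesign.pair_cols.shape[1]
            else idesign.pair_cols.copy()
        ),
        pair_index=[idx for idx, _ in keep_pair],
        pair_labels=[lab for _, lab in keep_pair],
        dropped_rows=list(idesign.dropped_rows),
        redundant_pairs=sorted(drop),
    )
    retained = np.hstack([out.main_cols, out.pair_cols])
    if _identical_groups(retained, out.feature_labels):  # pragma: no cover
        raise CollinearityError("column dropping failed to remove all redundancy")
    _warn_near_collinear(retained, out.feature_labels, near_collinear_warn)
    return out


def _warn_near_collinear(full: np.ndarray, labels: list[str], thr: float) -> None:
    X = full.astype(float)
    sd = X.std(axis=0)
    ok = sd > 0
    if ok.sum() < 2:
        return
    C = np.corrcoef(X[:, ok], rowvar=False)
    idx = np.flatnonzero(ok)
    hits = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if abs(C[a, b]) >= thr and abs(C[a, b]) < 1.0 - 1e-12:
                hits.append((labels[idx[a]], labels[idx[b]], C[a, b]))
    if hits:
        warnings.warn(
            "near-collinear column pairs (|r| >= %.2f): %s"
            % (thr, "; ".join(f"{a}~{b} (r={r:.3f})" for a, b, r in hits)),
            stacklevel=3,
        )
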