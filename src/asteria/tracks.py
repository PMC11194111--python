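"""Orthogonal genome-track validation: binning, contrasts, Kendall partials.

Signal tracks (ChIP-seq fold change, WGBS methylation fractions) arrive as
bedGraph; features (peaks, blacklist) as BED.  All coordinates are 0-based,
half-open.  The genome is tiled with fixed-width bins (default 1000 bp, no
gaps; the terminal remainder bin of each chromosome is dropped) and each
track is averaged per bin with coverage weighting.  Bins overlapping a
blacklist interval by >= 1 bp, or lacking coverage in any track, are
masked.  A modification-product column (elementwise product of two tracks)
stands in for their interaction, and rank-based Kendall partial
correlations across {protein, modification, modification, product} recover
the sign pattern of the fitted interaction model on independent data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinnedTrackMatrix",
    "PartialCorrMatrix",
    "read_bedgraph",
    "read_bed",
    "bin_tracks",
    "product_feature",
    "peak_contrast",
    "kendall_partial",
]


def read_bedgraph(path) -> pd.DataFrame:
    """Parse a bedGraph file (chrom, start, end, value); malformed lines
    raise with their line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields, got {len(parts)}")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: unparseable bedGraph line: {err}") from err
            if end <= start or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append((parts[0], start, end, value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_bed(path) -> pd.DataFrame:
    """Parse the first three columns of a BED file."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: unparseable BED line: {err}") from err
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class BinnedTrackMatrix:
    """Per-bin track means over the retained (unmasked) genome bins."""

    frame: pd.DataFrame  # columns: chrom, start, end, <signal columns>
    bin_width: int
    n_masked_blacklist: int = 0
    n_masked_coverage: int = 0

    @property
    def signal_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("chrom", "start", "end")]

    def values(self, columns=None) -> np.ndarray:
        cols = columns if columns is not None else self.signal_columns
        return self.frame[list(cols)].to_numpy(dtype=float)


def _accumulate(intervals: pd.DataFrame, n_bins: int, width: int):
    """Coverage-weighted sums per bin for one chromosome of one track."""
    total = np.zeros(n_bins)
    cover = np.zeros(n_bins)
    limit = n_bins * width
    for start, end, value in intervals[["start", "end", "value"]].itertuples(index=False):
        end = min(end, limit)
        if end <= start:
            continue
        b0 = start // width
        b1 = (end - 1) // width
        if b0 == b1:
            span = end - start
            total[b0] += span * value
            cover[b0] += span
            continue
        # first partial bin
        span = (b0 + 1) * width - start
        total[b0] += span * value
        cover[b0] += span
        # full interior bins
        if b1 > b0 + 1:
            total[b0 + 1 : b1] += width * value
            cover[b0 + 1 : b1] += width
        # last partial bin
        span = end - b1 * width
        total[b1] += span * value
        cover[b1] += span
    return total, cover


def _overlap_mask(n_bins: int, width: int, features: pd.DataFrame) -> np.ndarray:
    """Bins overlapping any feature interval by >= 1 bp."""
    mask = np.zeros(n_bins, dtype=bool)
    limit = n_bins * width
    for start, end in features[["start", "end"]].itertuples(index=False):
        end = min(end, limit)
        if end <= start:
            continue
        mask[start // width : (end - 1) // width + 1] = True
    return mask


def bin_tracks(
    tracks: dict[str, object],
    blacklist=None,
    bin_width: int = 1000,
) -> BinnedTrackMatrix:
    """Average named bedGraph tracks within fixed-width genome bins.

    ``tracks`` maps column name to a bedGraph path or a pre-parsed frame.
    Bins run 0, width, 2*width, ... per chromosome up to the last complete
    bin covered by any track; only chromosomes present in *every* track are
    binned (an empty intersection is an error).  Masked and dropped: bins
    with zero coverage in any track, and bins overlapping the blacklist.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not tracks:
        raise ValueError("no tracks given")
    data = {
        name: (src if isinstance(src, pd.DataFrame) else read_bedgraph(src))
        for name, src in tracks.items()
    }
    chrom_sets = [set(df["chrom"]) for df in data.values()]
    common = set.intersection(*chrom_sets)
    if not common:
        raise ValueError("tracks share no chromosomes")
    bl = None
    if blacklist is not None:
        bl = blacklist if isinstance(blacklist, pd.DataFrame) else read_bed(blacklist)

    frames = []
    n_bl = 0
    n_cov = 0
    for chrom in sorted(common):
        max_end = max(int(df.loc[df["chrom"] == chrom, "end"].max()) for df in data.values())
        n_bins = max_end // bin_width  # terminal remainder bin dropped
        if n_bins == 0:
            continue
        means = {}
        covered = np.ones(n_bins, dtype=bool)
        for name, df in data.items():
            total, cover = _accumulate(df[df["chrom"] == chrom], n_bins, bin_width)
            with np.errstate(invalid="ignore"):
                means[name] = np.where(cover > 0, total / np.maximum(cover, 1e-300), np.nan)
            covered &= cover > 0
        keep = covered.copy()
        n_cov += int((~covered).sum())
        if bl is not None:
            bl_mask = _overlap_mask(n_bins, bin_width, bl[bl["chrom"] == chrom])
            n_bl += int((bl_mask & keep).sum())
            keep &= ~bl_mask
        idx = np.flatnonzero(keep)
        chunk = pd.DataFrame(
            {
                "chrom": chrom,
                "start": idx * bin_width,
                "end": (idx + 1) * bin_width,
            }
        )
        for name in data:
            chunk[name] = means[name][idx]
        frames.append(chunk)
    frame = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", *data]
    )
    return BinnedTrackMatrix(
        frame=frame,
        bin_width=bin_width,
        n_masked_blacklist=n_bl,
        n_masked_coverage=n_cov,
    )


def product_feature(matrix: BinnedTrackMatrix, a: str, b: str) -> BinnedTrackMatrix:
    """Append the elementwise product column ``a:b`` (the interaction proxy)."""
    for col in (a, b):
        if col not in matrix.frame.columns:
            raise KeyError(f"column {col!r} not in binned matrix")
    name = f"{a}:{b}"
    if name in matrix.frame.columns:
        raise ValueError(f"column {name!r} already exists")
    frame = matrix.frame.copy()
    frame[name] = frame[a].to_numpy(float) * frame[b].to_numpy(float)
    return BinnedTrackMatrix(
        frame=frame,
        bin_width=matrix.bin_width,
        n_masked_blacklist=matrix.n_masked_blacklist,
        n_masked_coverage=matrix.n_masked_coverage,
    )


def peak_contrast(matrix: BinnedTrackMatrix, peaks, columns=None) -> pd.DataFrame:
    """Contrast per-column bin means inside vs outside peak regions.

    Returns one row per column with in/out means, their difference, a
    rank-biserial effect size and the Mann-Whitney p-value.
    """
    pk = peaks if isinstance(peaks, pd.DataFrame) else read_bed(peaks)
    cols = list(columns) if columns is not None else matrix.signal_columns
    starts = matrix.frame["start"].to_numpy()
    chroms = matrix.frame["chrom"].to_numpy()
    width = matrix.bin_width
    in_peak = np.zeros(len(matrix.frame), dtype=bool)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        sub = pk[pk["chrom"] == chrom]
        if sub.empty:
            continue
        bin_start = starts[sel]
        hit = np.zeros(bin_start.shape[0], dtype=bool)
        for ps, pe in sub[["start", "end"]].itertuples(index=False):
            hit |= (bin_start < pe) & (bin_start + width > ps)
        in_peak[sel] = hit
    if not in_peak.any():
        raise ValueError("no bins overlap the peak regions")
    rows = []
    for col in cols:
        v = matrix.frame[col].to_numpy(float)
        inside, outside = v[in_peak], v[~in_peak]
        if outside.size == 0:
            diff = 0.0
            effect, p = 0.0, 1.0
        elif np.all(v == v[0]):
            diff, effect, p = 0.0, 0.0, 1.0
        else:
            diff = float(inside.mean() - outside.mean())
            u, p = stats.mannwhitneyu(inside, outside, alternative="two-sided")
            effect = float(2.0 * u / (inside.size * outside.size) - 1.0)
        rows.append(
            {
                "column": col,
                "n_in": int(inside.size),
                "n_out": int(outside.size),
                "mean_in": float(inside.mean()),
                "mean_out": float(outside.mean()) if outside.size else float("nan"),
                "difference": diff,
                "rank_biserial": effect,
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PartialCorrMatrix:
    """Pairwise Kendall tau-b and the derived partial-correlation matrix."""

    variables: list[str]
    tau: np.ndarray
    partial: np.ndarray
    n_bins: int
    ridge: float = 0.0

    def tau_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tau, index=self.variables, columns=self.variables)

    def partial_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.partial, index=self.variables, columns=self.variables)


def kendall_partial(matrix, variables=None, *, max_ridge: float = 1e-2) -> PartialCorrMatrix:
    """Kendall tau-b partial correlations from the inverse tau matrix.

    partial[u, v] = -Omega[u, v] / sqrt(Omega[u, u] * Omega[v, v]) with
    Omega the inverse of the pairwise tau-b matrix.  Tau-b is used because
    methylation fractions and fold changes are heavily tied.  A
    near-singular tau matrix is regularised by escalating ridge inflation
    of the diagonal (logged via a warning); failure past ``max_ridge`` is
    an error.
    """
    if isinstance(matrix, BinnedTrackMatrix):
        frame = matrix.frame
        cols = list(variables) if variables is not None else matrix.signal_columns
    else:
        frame = pd.DataFrame(matrix)
        cols = list(variables) if variables is not None else list(frame.columns)
    if len(cols) < 3:
        raise ValueError("need at least 3 variables for partial correlations")
    X = frame[cols].to_numpy(dtype=float)
    n = X.shape[0]
    if n <= len(cols) + 2:
        raise ValueError("need n_bins > n_variables + 2")
    m = len(cols)
    tau = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            t = stats.kendalltau(X[:, i], X[:, j]).statistic
            tau[i, j] = tau[j, i] = 0.0 if np.isnan(t) else float(t)
    ridge = 0.0
    eps = 1e-10
    T = tau.copy()
    while True:
        try:
            if np.linalg.cond(T) > 1e12:
                raise np.linalg.LinAlgError("ill-conditioned tau matrix")
            omega = np.linalg.inv(T)
            break
        except np.linalg.LinAlgError:
            ridge = eps
            if ridge > max_ridge:
                raise np.linalg.LinAlgError(
                    f"tau matrix not invertible below ridge {max_ridge}"
                ) from None
            warnings.warn(f"tau matrix near-singular; ridge {ridge:g} applied", stacklevel=2)
            T = tau + ridge * np.eye(m)
            eps *= 10.0
    d = np.sqrt(np.diag(omega))
    partial = -omega / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    return PartialCorrMatrix(
        variables=cols, tau=tau, partial=partial, n_bins=n, ridge=ridge
    )
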