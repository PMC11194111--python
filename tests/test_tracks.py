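import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asteria.tracks import (
    bin_tracks,
    kendall_partial,
    peak_contrast,
    product_feature,
    read_bed,
    read_bedgraph,
)


def brute_force_bins(intervals, n_bins, width):
    """Per-base oracle: exact coverage-weighted bin means."""
    vals = np.full(n_bins * width, np.nan)
    for _, row in intervals.iterrows():
        vals[row.start : min(row.end, n_bins * width)] = row.value
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        chunk = vals[b * width : (b + 1) * width]
        if np.isfinite(chunk).any():
            means[b] = np.nanmean(chunk)
    return means


def toy_track(rng, chrom="chr1", length=10_000, gap_prob=0.2, width_hi=700):
    rows = []
    pos = 0
    while pos < length - 100:
        w = int(rng.integers(50, width_hi))
        if rng.random() > gap_prob:
            rows.append((chrom, pos, min(pos + w, length - 100), float(rng.normal(5, 2))))
        pos += w
    # always close the genome so every track spans the same bin grid
    rows.append((chrom, length - 100, length, float(rng.normal(5, 2))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


class TestParsing:
    def test_bedgraph_roundtrip(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("track type=bedGraph\nchr1\t0\t100\t2.5\nchr1\t100\t300\t-1\n")
        df = read_bedgraph(p)
        assert len(df) == 2
        assert df.loc[1, "value"] == -1.0

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr1\t0\t100\t1.0\nchr1\tzero\t200\t1.0\n")
        with pytest.raises(ValueError, match=":2:"):
            read_bedgraph(p)

    def test_bed_parse(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t10\t20\tname\t0\t+\n")
        df = read_bed(p)
        assert df.iloc[0].tolist() == ["chr1", 10, 20]


class TestBinning:
    def test_exact_cover_single_interval(self):
        df = pd.DataFrame([("chr1", 0, 1000, 5.0)], columns=["chrom", "start", "end", "value"])
        m = bin_tracks({"sig": df}, bin_width=1000)
        assert len(m.frame) == 1
        assert m.frame["sig"].iloc[0] == 5.0

    def test_equal_weight_mean(self):
        df = pd.DataFrame(
            [("chr1", 0, 500, 2.0), ("chr1", 500, 1000, 4.0)],
            columns=["chrom", "start", "end", "value"],
        )
        m = bin_tracks({"sig": df}, bin_width=1000)
        assert m.frame["sig"].iloc[0] == pytest.approx(3.0)

    def test_coverage_weighted_partial_bin(self):
        # 250 bases at 8 and 750 bases uncovered -> mean over covered = 8
        df = pd.DataFrame([("chr1", 0, 250, 8.0), ("chr1", 1000, 2000, 1.0)],
                          columns=["chrom", "start", "end", "value"])
        m = bin_tracks({"sig": df}, bin_width=1000)
        assert m.frame["sig"].tolist() == [8.0, 1.0]

    def test_terminal_remainder_bin_dropped(self):
        df = pd.DataFrame([("chr1", 0, 1700, 3.0)], columns=["chrom", "start", "end", "value"])
        m = bin_tracks({"sig": df}, bin_width=1000)
        assert m.frame["end"].max() == 1000

    def test_disjoint_chromosome_sets_error(self):
        a = pd.DataFrame([("chr1", 0, 1000, 1.0)], columns=["chrom", "start", "end", "value"])
        b = pd.DataFrame([("chr2", 0, 1000, 1.0)], columns=["chrom", "start", "end", "value"])
        with pytest.raises(ValueError, match="chromosome"):
            bin_tracks({"a": a, "b": b})

    def test_brute_force_oracle_with_blacklist(self):
        rng = np.random.default_rng(0)
        width = 1000
        t1, t2 = toy_track(rng), toy_track(rng)
        blacklist = pd.DataFrame(
            [("chr1", 3000, 4500), ("chr1", 7999, 8001)],
            columns=["chrom", "start", "end"],
        )
        m = bin_tracks({"a": t1, "b": t2}, blacklist=blacklist, bin_width=width)
        n_bins = 10
        oracle_a = brute_force_bins(t1, n_bins, width)
        oracle_b = brute_force_bins(t2, n_bins, width)
        bl_bins = {3, 4, 7, 8}  # any overlap, 0-based half-open
        for b in range(n_bins):
            retained = b in set(m.frame["start"] // width)
            expect = (
                b not in bl_bins
                and np.isfinite(oracle_a[b])
                and np.isfinite(oracle_b[b])
            )
            assert retained == expect, f"bin {b}"
            if retained:
                row = m.frame[m.frame["start"] == b * width].iloc[0]
                assert row["a"] == pytest.approx(oracle_a[b], rel=1e-12)
                assert row["b"] == pytest.approx(oracle_b[b], rel=1e-12)


class TestProductFeature:
    def _matrix(self):
        df = pd.DataFrame(
            [("chr1", 0, 2000, 1.0), ("chr1", 2000, 4000, 2.0)],
            columns=["chrom", "start", "end", "value"],
        )
        df2 = df.assign(value=[3.0, 0.0])
        return bin_tracks({"x": df, "y": df2}, bin_width=1000)

    def test_elementwise_product(self):
        m = product_feature(self._matrix(), "x", "y")
        assert m.frame["x:y"].tolist() == [3.0, 3.0, 0.0, 0.0]

    def test_zero_column_absorbs(self):
        m = self._matrix()
        m.frame["z"] = 0.0
        out = product_feature(m, "x", "z")
        assert (out.frame["x:z"] == 0).all()

    def test_name_collision_and_missing_column(self):
        m = product_feature(self._matrix(), "x", "y")
        with pytest.raises(ValueError, match="exists"):
            product_feature(m, "x", "y")
        with pytest.raises(KeyError):
            product_feature(m, "x", "nope")

    def test_product_tracks_positively_with_parents_on_lognormal(self):
        rng = np.random.default_rng(1)
        n = 500
        frame = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 1000,
                "end": (np.arange(n) + 1) * 1000,
                "u": rng.lognormal(size=n),
                "v": rng.lognormal(size=n),
            }
        )
        from asteria.tracks import BinnedTrackMatrix

        m = product_feature(BinnedTrackMatrix(frame, 1000), "u", "v")
        for parent in ("u", "v"):
            tau = stats.kendalltau(m.frame[parent], m.frame["u:v"]).statistic
            assert tau > 0


class TestPeakContrast:
    def _matrix(self, values):
        n = len(values)
        frame = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 1000,
                "end": (np.arange(n) + 1) * 1000,
                "sig": values,
            }
        )
        from asteria.tracks import BinnedTrackMatrix

        return BinnedTrackMatrix(frame, 1000)

    def test_constant_track_no_contrast(self):
        m = self._matrix(np.full(20, 2.0))
        peaks = pd.DataFrame([("chr1", 2000, 5000)], columns=["chrom", "start", "end"])
        row = peak_contrast(m, peaks).iloc[0]
        assert row["difference"] == 0.0
        assert row["rank_biserial"] == 0.0

    def test_planted_elevation_recovered(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(sigma=0.2, size=200)
        vals = base.copy()
        vals[50:100] *= 2.0
        m = self._matrix(vals)
        peaks = pd.DataFrame([("chr1", 50_000, 100_000)], columns=["chrom", "start", "end"])
        row = peak_contrast(m, peaks).iloc[0]
        assert row["difference"] > 0
        assert row["rank_biserial"] > 0.5
        assert row["p_value"] < 1e-6

    def test_no_overlapping_bins_is_error(self):
        m = self._matrix(np.ones(5))
        peaks = pd.DataFrame([("chr2", 0, 1000)], columns=["chrom", "start", "end"])
        with pytest.raises(ValueError, match="no bins"):
            peak_contrast(m, peaks)


class TestKendallPartial:
    def test_three_variable_closed_form(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n)
        z = 0.4 * y + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        pc = kendall_partial(df)
        assert pc.ridge == 0.0
        t = pc.tau
        # first-order partial tau for (x, z) given y
        expect = (t[0, 2] - t[0, 1] * t[1, 2]) / np.sqrt(
            (1 - t[0, 1] ** 2) * (1 - t[1, 2] ** 2)
        )
        assert pc.partial[0, 2] == pytest.approx(expect, abs=1e-6)

    def test_independent_variables_have_small_partials(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((2000, 3)), columns=list("abc"))
        pc = kendall_partial(df)
        off = pc.partial[~np.eye(3, dtype=bool)]
        assert (np.abs(off) < 0.05).all()

    def test_chain_conditional_independence(self):
        # x -> y -> z: conditioning on y must strongly attenuate the x-z
        # association.  The tau-based partial is only approximately zero
        # under conditional independence (the rank transform is nonlinear),
        # so moderate coupling is used and a small residual tolerated.
        rng = np.random.default_rng(5)
        n = 1500
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n)
        z = 0.6 * y + rng.standard_normal(n)
        pc = kendall_partial(pd.DataFrame({"x": x, "y": y, "z": z}))
        assert pc.tau[0, 2] > 0.1
        assert abs(pc.partial[0, 2]) < 0.1
        assert abs(pc.partial[0, 2]) < 0.5 * pc.tau[0, 2]

    def test_monotone_transform_invariance_of_tau(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.standard_normal((400, 3)), columns=list("abc"))
        pc1 = kendall_partial(df)
        df2 = df.assign(a=np.exp(df["a"]))
        pc2 = kendall_partial(df2)
        np.testing.assert_allclose(pc1.tau, pc2.tau, atol=1e-12)
        np.testing.assert_allclose(pc1.partial, pc2.partial, atol=1e-9)

    def test_too_few_variables_or_bins(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [2, 3, 1]})
        with pytest.raises(ValueError, match="3 variables"):
            kendall_partial(df)
        small = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValueError, match="n_bins"):
            kendall_partial(small)

    def test_symmetry_unit_diagonal_and_range(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
        pc = kendall_partial(df)
        for M in (pc.tau, pc.partial):
            np.testing.assert_allclose(M, M.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(M), 1.0)
            assert (np.abs(M) <= 1 + 1e-9).all()
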