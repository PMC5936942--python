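"""Temporal dbMEM construction, Moran's I, staggering and scale bands."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import fjordbeta as fb
from fjordbeta.dbmem import TimeGrid, dominant_period, morans_i


def brute_force_morans_i(x, w):
    """Double-sum oracle for Moran's I."""
    n = len(x)
    xbar = np.mean(x)
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
    den = sum((xi - xbar) ** 2 for xi in x)
    return (n / w.sum()) * num / den


def best_cosine_corr(v: np.ndarray, t: np.ndarray) -> float:
    """Correlation with the best-fitting cosine (free frequency, phase, amplitude)."""
    span = np.ptp(t)
    best = 0.0
    sst = float(((v - v.mean()) ** 2).sum())
    for m in np.linspace(0.2, 60.0, 1200):
        X = np.column_stack([np.ones_like(t),
                             np.cos(np.pi * m * t / span),
                             np.sin(np.pi * m * t / span)])
        beta, res, *_ = np.linalg.lstsq(X, v, rcond=None)
        if len(res):
            best = max(best, 1.0 - res[0] / sst)
    return np.sqrt(best)


def irregular_grid(seed=0, n=40):
    rng = np.random.default_rng(seed)
    offs = np.cumsum(rng.uniform(6, 30, size=n))
    return pd.Timestamp("2012-01-01") + pd.to_timedelta(offs, unit="h")


class TestSupplementaryPoints:
    def test_identity_when_no_large_gap(self):
        g = TimeGrid.from_timestamps(pd.date_range("2012-01-01", periods=10, freq="12h"))
        out = fb.insert_supplementary_points(g, "24h")
        assert len(out.timestamps) == 10
        assert not out.supplementary.any()

    def test_five_day_gap_gets_four_points(self):
        ts = pd.DatetimeIndex(["2012-01-01", "2012-01-02", "2012-01-07", "2012-01-08"])
        g = TimeGrid.from_timestamps(ts, block_gap="30D")
        out = fb.insert_supplementary_points(g, "24h")
        assert int(out.supplementary.sum()) == 4
        spacings = np.diff(out.timestamps.asi8) / 3.6e12
        assert spacings.max() <= 24.0 + 1e-9

    def test_between_block_gap_untouched(self):
        ts = pd.date_range("2012-01-01", periods=5, freq="D").append(
            pd.date_range("2012-02-01", periods=5, freq="D"))
        g = TimeGrid.from_timestamps(ts, block_gap="10D")
        out = fb.insert_supplementary_points(g, "24h")
        assert not out.supplementary.any()
        assert len(set(out.block)) == 2


class TestBuildDbmem:
    def test_orthonormal_basis(self):
        b = fb.build_dbmem(irregular_grid(1))
        f = b.functions.to_numpy()
        assert np.max(np.abs(f.T @ f - np.eye(b.k))) < 1e-8

    def test_morans_i_matches_brute_force(self):
        ts = irregular_grid(2, n=25)
        b = fb.build_dbmem(ts)
        t = (ts - ts[0]).total_seconds().to_numpy() / 86400.0
        d = np.abs(t[:, None] - t[None, :])
        trunc = list(b.truncation_days.values())[0]
        w = ((d <= trunc) & (d > 0)).astype(float)
        for c in b.functions.columns[:8]:
            x = b.functions[c].to_numpy()
            assert b.morans_i[c] == pytest.approx(brute_force_morans_i(x, w), abs=1e-10)

    def test_sign_classes_partition_basis(self):
        b = fb.build_dbmem(irregular_grid(3))
        pos = b.columns_of_class("positive")
        neg = b.columns_of_class("negative")
        assert len(pos) + len(neg) == b.k
        assert not set(pos) & set(neg)
        e_i = -1.0 / (len(b.functions) - 1)
        assert (b.morans_i[pos] > e_i).all()
        assert (b.morans_i[neg] <= e_i).all()

    def test_leading_positive_eigenfunction_has_one_sign_change(self):
        ts = pd.date_range("2012-01-01", periods=50, freq="D")
        b = fb.build_dbmem(ts)
        v = b.functions.iloc[:, 0].to_numpy()
        assert int((np.diff(np.sign(v)) != 0).sum()) == 1

    def test_regular_grid_eigenfunctions_are_sinusoidal(self):
        ts = pd.date_range("2012-01-01", periods=100, freq="D")
        b = fb.build_dbmem(ts)
        t = np.arange(100.0)
        for j in range(5):
            assert best_cosine_corr(b.functions.iloc[:, j].to_numpy(), t) >= 0.97

    def test_invariant_to_time_shift(self):
        ts = irregular_grid(4, n=20)
        b1 = fb.build_dbmem(ts)
        b2 = fb.build_dbmem(ts + pd.Timedelta(days=500))
        assert np.allclose(np.abs(b1.functions.to_numpy()),
                           np.abs(b2.functions.to_numpy()), atol=1e-9)
        assert np.allclose(b1.eigenvalues, b2.eigenvalues)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fb.build_dbmem(pd.DatetimeIndex(["2012-01-01", "2012-01-02"]))

    def test_matches_vegan_pcnm_reference(self, tmp_path):
        """Independent oracle: vegan::pcnm on a 30-point regular transect."""
        script = textwrap.dedent("""
            suppressMessages(library(vegan))
            p <- pcnm(dist(0:29))
            write.csv(data.frame(values=p$values), "%s/vals.csv", row.names=FALSE)
            write.csv(p$vectors, "%s/vecs.csv", row.names=FALSE)
        """) % (tmp_path, tmp_path)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        vals = pd.read_csv(tmp_path / "vals.csv")["values"].to_numpy()
        vecs = pd.read_csv(tmp_path / "vecs.csv").to_numpy()
        ts = pd.date_range("2012-01-01", periods=30, freq="D")
        b = fb.build_dbmem(ts, truncation=1.0)
        npos = vecs.shape[1]
        assert np.allclose(b.eigenvalues.to_numpy()[:npos], vals[:npos], atol=1e-8)
        ours = b.functions.to_numpy()[:, :npos]
        # same subspaces: each vegan eigenvector correlates +-1 with ours
        for j in range(npos):
            assert abs(np.corrcoef(ours[:, j], vecs[:, j])[0, 1]) > 1 - 1e-8


class TestStaggeredBasis:
    def _two_block_grid(self):
        ts = pd.date_range("2012-01-01", periods=40, freq="12h").append(
            pd.date_range("2012-02-20", periods=60, freq="12h"))
        return TimeGrid.from_timestamps(ts, block_gap="10D")

    def test_single_block_is_plain_basis(self):
        ts = pd.date_range("2012-01-01", periods=20, freq="D")
        g = TimeGrid.from_timestamps(ts)
        plain = fb.build_dbmem(g)
        stag = fb.staggered_basis([plain])
        pd.testing.assert_frame_equal(plain.functions, stag.functions)

    def test_block_diagonal_structure(self):
        g = self._two_block_grid()
        basis = fb.build_staggered_dbmem(g)
        blocks = basis.row_block.to_numpy()
        for c in basis.functions.columns:
            other = blocks != basis.col_block[c]
            assert (basis.functions[c].to_numpy()[other] == 0).all()
        k1 = sum(basis.col_block == 0)
        k2 = sum(basis.col_block == 1)
        assert basis.k == k1 + k2 and k1 > 0 and k2 > 0

    def test_cross_block_columns_exactly_orthogonal(self):
        basis = fb.build_staggered_dbmem(self._two_block_grid())
        f = basis.functions
        c1 = basis.col_block.index[basis.col_block == 0][0]
        c2 = basis.col_block.index[basis.col_block == 1][0]
        assert float(f[c1] @ f[c2]) == 0.0

    def test_overlapping_blocks_rejected(self):
        ts = pd.date_range("2012-01-01", periods=20, freq="D")
        b = fb.build_dbmem(ts)
        with pytest.raises(ValueError, match="overlap"):
            fb.staggered_basis([b, b])


class TestDropSupplementary:
    def test_identity_without_supplementary_points(self):
        b = fb.build_dbmem(irregular_grid(5, n=15))
        out = fb.drop_supplementary_rows(b)
        pd.testing.assert_frame_equal(out.functions, b.functions)
        assert out.gram_max_offdiag == 0.0 or out.gram_max_offdiag < 1e-8

    def test_row_count_and_gram_deviation(self):
        ts = pd.DatetimeIndex(
            ["2012-01-01", "2012-01-02", "2012-01-06", "2012-01-07",
             "2012-01-08", "2012-01-09", "2012-01-10"])
        g = TimeGrid.from_timestamps(ts, block_gap="30D")
        padded = fb.insert_supplementary_points(g, "24h")
        b = fb.build_dbmem(padded)
        out = fb.drop_supplementary_rows(b)
        assert len(out.functions) == len(ts)
        assert out.gram_max_offdiag > 0  # orthogonality slightly lost
        assert out.gram_max_offdiag < 1.0


class TestScaleBands:
    @pytest.mark.parametrize("period, band", [(20.0, "medium"), (100.0, "broad"),
                                              (5.0, "fine"), (1.0, None)])
    def test_dominant_period_maps_to_band(self, period, band):
        t = np.arange(0, 300.0, 0.5)
        per = dominant_period(t, np.sin(2 * np.pi * t / period))
        assert per == pytest.approx(period, rel=0.05)
        hit = None
        for name, (lo, hi) in fb.DEFAULT_SCALE_BANDS.items():
            if lo <= per <= hi:
                hit = name
        assert hit == band

    def test_bands_assigned_only_to_positive_class(self):
        ts = pd.date_range("2012-01-01", periods=120, freq="12h")
        b = fb.assign_scale_bands(fb.build_dbmem(ts))
        neg = b.columns_of_class("negative")
        assert (b.scale_band[neg] == "unassigned").all()
        pos = b.columns_of_class("positive")
        assert set(b.scale_band[pos]) <= {"broad", "medium", "fine", "unassigned"}

    def test_band_scales_with_time_dilation(self):
        # doubling all spacings doubles the dominant period of each eigenfunction
        t1 = np.arange(200.0)
        v = np.sin(2 * np.pi * t1 / 18.0)
        p1 = dominant_period(t1, v)
        p2 = dominant_period(2 * t1, v)
        assert p2 == pytest.approx(2 * p1, rel=0.02)


def test_morans_i_handles_degenerate_input():
    w = np.ones((4, 4)) - np.eye(4)
    assert np.isnan(morans_i(np.ones(4), w))
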