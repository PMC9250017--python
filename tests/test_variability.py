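import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clockvar.exceptions import (
    DegenerateStatisticError,
    EmptyInputError,
    ValidationError,
)
from clockvar.synthetic import SynthConfig, generate_cells
from clockvar.variability import (
    VariabilityModel,
    bin_curve,
    correlated_variability,
    mean_spatial_profile,
    slice_statistics,
    total_variability,
    uncorrelated_variability,
    volume_correct,
)

from conftest import make_table


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([10, 20, 30], [10, 20, 30], 0.0),
        ([10, 20], [20, 10], 2.0 / 9.0),
        ([1, 2, 3, 4], [4, 3, 2, 1], 0.4),
    ],
)
def test_uncorrelated_hand_values(x, y, expected):
    assert uncorrelated_variability(x, y) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([5, 5, 5], [1, 7, 3], 0.0),  # constant gene: zero covariance
        ([10, 20], [10, 20], 1.0 / 9.0),
        ([10, 20], [20, 10], -1.0 / 9.0),
    ],
)
def test_correlated_hand_values(x, y, expected):
    assert correlated_variability(x, y) == pytest.approx(expected, abs=1e-12)


def test_total_hand_value_and_cv2_identity():
    x, y = [10, 20], [20, 10]
    tot = total_variability(x, y)
    assert tot == pytest.approx(1.0 / 9.0, abs=1e-12)
    cv2 = np.var(x) / np.mean(x) ** 2
    assert tot == pytest.approx(0.5 * (cv2 + cv2), rel=1e-12)


@pytest.mark.parametrize("bad", [([10], [10]), ([1, 2], [1, 2, 3])])
def test_length_preconditions(bad):
    with pytest.raises(ValidationError):
        uncorrelated_variability(*bad)


def test_zero_mean_is_degenerate():
    with pytest.raises(DegenerateStatisticError):
        correlated_variability([0, 0, 0], [1, 2, 3])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 80))
def test_decomposition_identity(seed, n):
    """total = correlated + uncorrelated = (CV^2_x + CV^2_y)/2 on any input."""
    rng = np.random.default_rng(seed)
    x = rng.lognormal(3.0, 0.6, size=n)
    y = rng.lognormal(3.0, 0.6, size=n)
    corr = correlated_variability(x, y)
    unc = uncorrelated_variability(x, y)
    half_cv2 = 0.5 * (np.var(x) / x.mean() ** 2 + np.var(y) / y.mean() ** 2)
    assert corr + unc == pytest.approx(half_cv2, rel=1e-10, abs=1e-12)
    assert total_variability(x, y) == pytest.approx(corr + unc, rel=1e-10)


def test_permutation_kills_correlation_but_not_total():
    """Breaking the cell pairing removes covariance; total is pairing-free."""
    rng = np.random.default_rng(7)
    shared = rng.lognormal(0, 0.5, size=20_000)
    x = rng.poisson(30 * shared).astype(float)
    y = rng.poisson(30 * shared).astype(float)
    y_perm = rng.permutation(y)
    assert abs(correlated_variability(x, y_perm)) < 0.02
    assert correlated_variability(x, y) > 0.2
    assert total_variability(x, y_perm) == pytest.approx(
        total_variability(x, y), rel=1e-12
    )


class TestVolumeCorrect:
    def test_unit_volumes_are_identity(self):
        t = make_table(volume=1.0)
        out = volume_correct(t)
        np.testing.assert_allclose(out.df["her1_count"], t.df["her1_count"])

    def test_concentration_values(self):
        t = make_table(her1=10, her7=6, volume=2.0)
        out = volume_correct(t)
        assert (out.df["her1_count"] == 5.0).all()
        assert (out.df["her7_count"] == 3.0).all()

    def test_volume_scaling_leaves_statistics_unchanged(self):
        t = make_table(n_slices=3, cells_per_slice=15, seed=3)
        scaled = t.df.copy()
        scaled["volume"] *= 7.5
        from clockvar.io import CellTable

        a = slice_statistics(volume_correct(t)).points
        b = slice_statistics(volume_correct(CellTable(scaled))).points
        np.testing.assert_allclose(a["correlated"], b["correlated"], rtol=1e-12)
        np.testing.assert_allclose(a["uncorrelated"], b["uncorrelated"],
                                   rtol=1e-12)

    def test_volume_proportional_counts(self):
        """When counts track volume, correction strictly reduces correlated
        variability and leaves uncorrelated essentially unchanged."""
        cfg = SynthConfig(sigma_E=0.25, sigma_V=0.25, volume_coupling=1.0,
                          n_embryos=2, seed=11)
        table, _ = generate_cells(cfg)
        raw = slice_statistics(table).points
        cor = slice_statistics(volume_correct(table)).points
        assert cor["correlated"].mean() < 0.4 * raw["correlated"].mean()
        assert cor["uncorrelated"].mean() == pytest.approx(
            raw["uncorrelated"].mean(), rel=0.15
        )


class TestSliceStatistics:
    def test_counts_points_and_dropping(self):
        t = make_table(n_slices=2, cells_per_slice=10)
        res = slice_statistics(t, min_cells=5)
        assert len(res.points) == 2
        assert res.n_dropped == 0

        small = make_table(n_slices=1, cells_per_slice=3)
        merged = pd.concat([t.df, small.df.assign(slice_index=9)],
                           ignore_index=True)
        from clockvar.io import CellTable

        res2 = slice_statistics(CellTable(merged), min_cells=5)
        assert len(res2.points) == 2
        assert res2.n_dropped == 1
        assert res2.dropped["slice_index"].tolist() == [9]

    def test_no_group_passes_raises(self):
        t = make_table(n_slices=2, cells_per_slice=3)
        with pytest.raises(EmptyInputError):
            slice_statistics(t, min_cells=5)

    def test_points_match_direct_formula(self):
        t = make_table(n_slices=3, cells_per_slice=12, seed=5)
        res = slice_statistics(t, min_cells=5)
        for _, row in res.points.iterrows():
            g = t.df[t.df["slice_index"] == row["slice_index"]]
            x = g["her1_count"].to_numpy(float)
            y = g["her7_count"].to_numpy(float)
            assert row["correlated"] == pytest.approx(
                correlated_variability(x, y), rel=1e-12
            )
            assert row["uncorrelated"] == pytest.approx(
                uncorrelated_variability(x, y), rel=1e-12
            )
            assert row["mean_her"] == pytest.approx(x.mean() + y.mean())


class TestBinCurve:
    @staticmethod
    def _points(n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "mean_her": rng.uniform(10, 90, size=n),
            "correlated": rng.uniform(0.1, 0.4, size=n),
            "uncorrelated": rng.uniform(0.02, 0.2, size=n),
            "total": rng.uniform(0.1, 0.6, size=n),
        })

    def test_equal_count_bins_ordered(self):
        curve = bin_curve(self._points(10), n_bins=5)
        assert curve.n_slices.tolist() == [2, 2, 2, 2, 2]
        assert np.all(np.diff(curve.bin_mean_her) >= 0)

    def test_identical_points_zero_se(self):
        pts = pd.DataFrame({
            "mean_her": [30.0] * 10, "correlated": [0.2] * 10,
            "uncorrelated": [0.05] * 10, "total": [0.25] * 10,
        })
        curve = bin_curve(pts, n_bins=5)
        np.testing.assert_allclose(curve.mean_correlated, 0.2)
        np.testing.assert_allclose(curve.se_correlated, 0.0)

    def test_bin_means_bracketed_by_members(self):
        pts = self._points(37, seed=2)
        curve = bin_curve(pts, n_bins=5)
        srt = pts.sort_values("mean_her", kind="stable").reset_index(drop=True)
        start = 0
        for b in range(5):
            n = curve.n_slices[b]
            members = srt.iloc[start:start + n]
            assert members["mean_her"].min() - 1e-12 <= curve.bin_mean_her[b]
            assert curve.bin_mean_her[b] <= members["mean_her"].max() + 1e-12
            start += n
        assert int(curve.n_slices.sum()) == len(pts)

    def test_too_few_points_raises(self):
        with pytest.raises(ValidationError):
            bin_curve(self._points(4), n_bins=5)


class TestSpatialProfile:
    def test_constant_counts_flat_profile(self):
        t = make_table(n_slices=4, her1=12, her7=15)
        prof = mean_spatial_profile(t, "e1", "right", gene="her7")
        assert len(prof) == 4
        np.testing.assert_allclose(prof["mean"], 15.0)
        np.testing.assert_allclose(prof["two_sem"], 0.0)

    def test_single_slice(self):
        t = make_table(n_slices=1)
        prof = mean_spatial_profile(t, "e1", "right")
        assert len(prof) == 1

    def test_unknown_half_raises(self):
        t = make_table()
        with pytest.raises(EmptyInputError):
            mean_spatial_profile(t, "e1", "left")

    def test_kinematic_waves_show_three_maxima(self):
        cfg = SynthConfig(n_embryos=1, n_slices=30, cells_per_slice=200,
                          sigma_E=0.2, wave_count=3.0, seed=4)
        table, _ = generate_cells(cfg)
        prof = mean_spatial_profile(table, "embryo00", "left", gene="her7")
        m = prof["mean"].to_numpy()
        sm = np.convolve(m, np.ones(3) / 3, mode="valid")  # light denoising
        interior = np.sum((sm[1:-1] > sm[:-2]) & (sm[1:-1] > sm[2:]))
        boundary = int(sm[0] > sm[1]) + int(sm[-1] > sm[-2])
        assert 2 <= interior + boundary <= 3


class TestModelResults:
    def test_fit_summary_and_shares(self, wt_synth):
        table, _ = wt_synth
        res = VariabilityModel(table, volume_correct=False).fit()
        s = res.summary()
        assert "correlated share" in s and "wt" in s
        total_share = res.component_share("correlated") + res.component_share(
            "uncorrelated"
        )
        assert total_share == pytest.approx(1.0, rel=1e-10)

    def test_plot_returns_axes(self, wt_synth):
        import matplotlib

        matplotlib.use("Agg")
        table, _ = wt_synth
        res = VariabilityModel(table).fit()
        ax = res.plot()
        assert len(ax.lines) >= 2
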