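"""Deseasonalization, province PCA, synthetic indices, spectra."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bioregion import indices as bi
from bioregion.gridio import Grid

from conftest import make_field


def make_panel(data, n_cells, months=None, province=1):
    """Z-score a raw individuals-by-variables matrix into an AnomalyPanel."""
    data = np.asarray(data, dtype=float)
    n_t = data.shape[0] // n_cells
    months = months if months is not None else pd.date_range(
        "2002-01", periods=n_t, freq="MS")
    z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=0)
    return bi.AnomalyPanel(
        province=province, data=z, variables=bi.PCA_VARIABLES,
        month_index=np.repeat(np.arange(n_t), n_cells),
        cell_ids=np.tile(np.arange(n_cells), n_t), months=months)


def factor_panel(rng, n_months=120, n_cells=30, f1_vars=(0, 1, 6),
                 f2_vars=(2, 3), f1_weak=(5,), f2_weak=(4,),
                 loading=1.2, weak_loading=0.35, noise=0.6):
    """Two-factor model: f1 on classical-type, f2 on mesoscale-type vars.

    The remaining variables carry weak cross-loadings so every variable
    correlates with some mode and the trailing eigenvalues of the
    correlation matrix sit strictly below one.
    """
    n = n_months * n_cells
    f1 = np.repeat(rng.normal(size=n_months), n_cells)
    f2 = np.repeat(rng.normal(size=n_months), n_cells)
    data = rng.normal(size=(n, 7)) * noise
    for v in f1_vars:
        data[:, v] += loading * f1
    for v in f2_vars:
        data[:, v] += loading * f2
    for v in f1_weak:
        data[:, v] += weak_loading * f1
    for v in f2_weak:
        data[:, v] += weak_loading * f2
    return make_panel(data, n_cells)


class TestDeseasonalize:
    def test_annihilates_pure_seasonal_cycle(self, small_grid):
        times = pd.date_range("2002-01", periods=96, freq="MS")
        t = np.arange(96)
        cyc = np.sin(2 * np.pi * t / 12.0)
        vals = np.ones((96, *small_grid.shape)) * cyc[:, None, None]
        out = bi.deseasonalize(make_field(small_grid, vals, times))
        assert np.nanmax(np.abs(out.values)) < 1e-10

    def test_constant_field_gives_zero(self, small_grid):
        times = pd.date_range("2002-01", periods=36, freq="MS")
        vals = np.full((36, *small_grid.shape), 5.5)
        out = bi.deseasonalize(make_field(small_grid, vals, times))
        np.testing.assert_allclose(np.nan_to_num(out.values), 0.0,
                                   atol=1e-12)

    def test_matches_groupwise_oracle_with_trend(self, small_grid, rng):
        times = pd.date_range("2002-01", periods=48, freq="MS")
        t = np.arange(48)
        sig = (np.sin(2 * np.pi * t / 12.0) + 0.02 * t)[:, None, None]
        vals = sig + rng.normal(size=(48, *small_grid.shape)) * 0.1
        out = bi.deseasonalize(make_field(small_grid, vals, times))
        months = times.month
        oracle = vals.copy()
        for m in range(1, 13):
            sel = months == m
            oracle[sel] -= vals[sel].mean(axis=0, keepdims=True)
        np.testing.assert_allclose(out.values, oracle, atol=1e-12)

    def test_short_series_rejected(self, small_grid):
        times = pd.date_range("2002-01", periods=12, freq="MS")
        with pytest.raises(ValueError, match="24"):
            bi.deseasonalize(make_field(
                small_grid, np.ones((12, *small_grid.shape)), times))


class TestProvincePca:
    def test_correlated_pair_loads_equally(self, rng):
        """Two perfectly correlated variables share one component with
        equal-magnitude loadings (closed-form 2-block correlation PCA)."""
        n = 5000
        common = rng.normal(size=n)
        data = rng.normal(size=(n, 7))
        data[:, 0] = common
        data[:, 1] = common
        panel = make_panel(data, n_cells=50)
        loadings, evals = bi.province_pca(panel)
        # leading eigenvalue of the 2-block is 2; loadings 1/sqrt(2) each
        assert evals[0] == pytest.approx(2.0, abs=0.05)
        assert abs(loadings[0, 0]) == pytest.approx(1 / np.sqrt(2), abs=0.02)
        assert abs(loadings[1, 0]) == pytest.approx(abs(loadings[0, 0]),
                                                    abs=1e-6)

    def test_eigenvalues_sum_to_variable_count(self, rng):
        panel = factor_panel(rng)
        _, evals = bi.province_pca(panel)
        assert evals.sum() == pytest.approx(7.0, abs=1e-6)

    def test_identity_correlation_eigenvalues_near_one(self, rng):
        panel = make_panel(rng.normal(size=(10000, 7)), n_cells=100)
        _, evals = bi.province_pca(panel)
        assert np.all(np.abs(evals - 1.0) < 0.15)

    def test_planted_factor_variance_share(self, rng):
        """One factor loading 5 of 7 variables: PC1 share matches the
        model's analytic share within 3 points."""
        n = 30000
        f = rng.normal(size=n)
        noise = 0.8
        data = rng.normal(size=(n, 7)) * noise
        lam = 1.0
        for v in range(5):
            data[:, v] += lam * f
        panel = make_panel(data, n_cells=100)
        _, evals = bi.province_pca(panel)
        rho = lam ** 2 / (lam ** 2 + noise ** 2)  # pairwise correlation
        expected_ev1 = 1 + 4 * rho  # 5-block with equicorrelation rho
        assert evals[0] / 7 == pytest.approx(expected_ev1 / 7, abs=0.03)

    def test_sign_convention(self, rng):
        loadings, _ = bi.province_pca(factor_panel(rng))
        for j in range(loadings.shape[1]):
            i = np.argmax(np.abs(loadings[:, j]))
            assert loadings[i, j] > 0

    def test_scores_mutually_uncorrelated(self, rng):
        panel = factor_panel(rng)
        loadings, _ = bi.province_pca(panel)
        scores = panel.data @ loadings
        corr = np.corrcoef(scores.T)
        off = corr[~np.eye(7, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-6

    def test_too_few_individuals_rejected(self, rng):
        panel = factor_panel(rng, n_months=1, n_cells=3)
        with pytest.raises(ValueError, match="individuals"):
            bi.province_pca(panel)


class TestRetainPcs:
    @pytest.mark.parametrize("evals,default,strict", [
        ((2.2, 1.4, 0.9, 0.5, 0.4, 0.3, 0.3), 2, 2),
        ((7.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0), 1, 1),
        ((1.0,) * 7, 7, 1),  # boundary: >= keeps all, > floors at 1
    ])
    def test_rule_boundaries(self, evals, default, strict):
        ev = np.array(evals)
        assert bi.retain_pcs(ev) == default
        assert bi.retain_pcs(ev, strict=True) == strict

    def test_ascending_rejected(self):
        with pytest.raises(ValueError):
            bi.retain_pcs(np.array([0.5, 1.5]))


class TestIndexSeries:
    def test_identical_cells_equal_single_cell_score(self, rng):
        n_months, n_cells = 24, 10
        base = rng.normal(size=(n_months, 7))
        data = np.repeat(base, n_cells, axis=0)
        panel = make_panel(data, n_cells)
        loadings, _ = bi.province_pca(panel)
        series = bi.index_series(panel, loadings, 0)
        single = (panel.data[::n_cells] @ loadings[:, 0])
        np.testing.assert_allclose(series.to_numpy(), single, atol=1e-10)

    def test_zero_loading_gives_zero_series(self, rng):
        panel = factor_panel(rng, n_months=24, n_cells=5)
        zero = np.zeros((7, 7))
        series = bi.index_series(panel, zero, 3)
        np.testing.assert_allclose(series.to_numpy(), 0.0)

    def test_matches_brute_force_monthly_average(self, rng):
        for _ in range(100):
            n_months = int(rng.integers(3, 8))
            n_cells = int(rng.integers(2, 6))
            panel = make_panel(
                rng.normal(size=(n_months * n_cells, 7)), n_cells)
            loadings, _ = bi.province_pca(panel) if n_months * n_cells >= 7 \
                else (np.eye(7), np.ones(7))
            pc = int(rng.integers(0, 7))
            series = bi.index_series(panel, loadings, pc)
            for m in range(n_months):
                rows = panel.data[panel.month_index == m]
                expect = float(np.mean(rows @ loadings[:, pc]))
                assert series.iloc[m] == pytest.approx(expect, abs=1e-12)

    def test_linearity_with_fixed_loadings(self, rng):
        p1 = factor_panel(rng, n_months=24, n_cells=8)
        loadings, _ = bi.province_pca(p1)
        doubled = bi.AnomalyPanel(
            p1.province, 2 * p1.data, p1.variables, p1.month_index,
            p1.cell_ids, p1.months)
        s1 = bi.index_series(p1, loadings, 0)
        s2 = bi.index_series(doubled, loadings, 0)
        np.testing.assert_allclose(s2.to_numpy(), 2 * s1.to_numpy(),
                                   atol=1e-12)


class TestPowerSpectrum:
    def test_eight_month_sinusoid_peak(self):
        t = np.arange(101)
        s = pd.Series(np.sin(2 * np.pi * t / 8.0),
                      index=pd.date_range("2002-01", periods=101, freq="MS"))
        spec = bi.power_spectrum(s)
        fmax = spec.loc[spec["power"].idxmax(), "frequency"]
        assert fmax == pytest.approx(1 / 8, abs=0.01)

    def test_two_sinusoids_two_peaks(self):
        t = np.arange(256)
        x = np.sin(2 * np.pi * t / 8.0) + np.sin(2 * np.pi * t / 32.0)
        s = pd.Series(x, index=pd.date_range("2000-01", periods=256,
                                             freq="MS"))
        spec = bi.power_spectrum(s)
        top2 = spec.nlargest(2, "power")["frequency"].to_numpy()
        assert sorted(np.round(top2, 4).tolist()) == [
            pytest.approx(1 / 32, abs=1e-3), pytest.approx(1 / 8, abs=1e-3)]

    def test_white_noise_exceedance_rate(self, rng):
        """About 5% of periodogram ordinates exceed the 95% level."""
        rates = []
        for _ in range(30):
            x = rng.normal(size=1024)
            s = pd.Series(x, index=pd.date_range("1950-01", periods=1024,
                                                 freq="MS"))
            spec = bi.power_spectrum(s)
            rates.append((spec["power"] > spec["level95"]).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.01)

    def test_constant_series_warns_flat(self):
        s = pd.Series(np.ones(48),
                      index=pd.date_range("2002-01", periods=48, freq="MS"))
        with pytest.warns(UserWarning, match="constant"):
            spec = bi.power_spectrum(s)
        np.testing.assert_allclose(spec["power"], 0.0, atol=1e-25)

    def test_short_series_rejected(self):
        s = pd.Series(np.arange(10.0))
        with pytest.raises(ValueError):
            bi.power_spectrum(s)


class TestLaggedCorrelation:
    def test_shifted_copy_peaks_at_lag(self):
        months = pd.date_range("2002-01", periods=101, freq="MS")
        rng = np.random.default_rng(4)
        x = rng.normal(size=101)
        index = pd.Series(x, index=months)
        climate = pd.Series(x, index=months - pd.DateOffset(months=3))
        table = bi.lagged_correlation(index, climate, max_lag=6)
        row = table[table["lag"] == 3].iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-12)
        assert row["p"] < 1e-10

    def test_negated_series_anticorrelated_at_zero(self):
        months = pd.date_range("2002-01", periods=60, freq="MS")
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        table = bi.lagged_correlation(pd.Series(x, index=months),
                                      pd.Series(-x, index=months), 2)
        assert table[table["lag"] == 0].iloc[0]["r"] == pytest.approx(-1.0)

    def test_independent_noise_rarely_large(self, rng):
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            months = pd.date_range("2002-01", periods=101, freq="MS")
            a = pd.Series(rng.normal(size=101), index=months)
            b = pd.Series(rng.normal(size=101), index=months)
            table = bi.lagged_correlation(a, b, max_lag=6)
            if (table["r"].abs() >= 0.3).any():
                hits += 1
        assert hits <= 0.05 * n_sim + 1

    def test_insufficient_overlap_rows_missing(self):
        months = pd.date_range("2002-01", periods=30, freq="MS")
        a = pd.Series(np.arange(30.0), index=months)
        table = bi.lagged_correlation(a, a, max_lag=12)
        assert table["lag"].max() <= 6  # overlap < 24 months beyond that


class TestSignificantLoadings:
    def test_cutoff_is_strict(self):
        corr = np.array([[0.56, -0.5], [0.5, -0.51]])
        flags = bi.significant_loadings(corr)
        np.testing.assert_array_equal(flags,
                                      [[True, False], [False, True]])

    def test_zero_loadings_nothing_flagged(self):
        assert not bi.significant_loadings(np.zeros((7, 4))).any()


class TestBuildPanel:
    def test_panel_from_fields_shapes_and_scaling(self, rng):
        grid = Grid(np.arange(6) * 0.5, 35 + np.arange(5) * 0.5)
        times = pd.date_range("2002-01", periods=30, freq="MS")
        fields = {}
        for name in bi.PCA_VARIABLES:
            vals = rng.normal(size=(30, *grid.shape))
            fields[name] = make_field(grid, vals, times, name)
        labels = np.ones(grid.shape)
        labels[:, :3] = 2
        panel = bi.build_panel(fields, labels, 2)
        assert panel.data.shape == (30 * 15, 7)
        np.testing.assert_allclose(panel.data.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(panel.data.std(axis=0), 1, atol=1e-10)

    def test_gappy_individuals_dropped_and_counted(self, rng):
        grid = Grid(np.arange(4) * 0.5, 35 + np.arange(4) * 0.5)
        times = pd.date_range("2002-01", periods=26, freq="MS")
        fields = {}
        for name in bi.PCA_VARIABLES:
            vals = rng.normal(size=(26, *grid.shape))
            fields[name] = make_field(grid, vals, times, name)
        fields["eke"].values[3, 1, 1] = np.nan
        labels = np.ones(grid.shape)
        panel = bi.build_panel(fields, labels, 1)
        assert panel.n_dropped == 1
        assert panel.data.shape[0] == 26 * 16 - 1
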