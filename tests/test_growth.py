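"""Dendroband metrics, species pooling and water-potential summaries."""

import numpy as np
import pandas as pd
import pytest

from hydrotraits import growth
from hydrotraits.stats import pool_estimates
from hydrotraits.synth import (GeneratorConfig, default_truth,
                               generate_dendro_series)


def ramp_series(rate_mm_per_year=10.0, n=23, freq="17D",
                start="2021-11-01"):
    dates = pd.date_range(start, periods=n, freq=freq)
    t = (dates - dates[0]).days.to_numpy(float)
    return dates, 50.0 + rate_mm_per_year * t / 365.0


class TestBandToDiameter:
    def test_circumference_over_pi(self):
        d = growth.band_to_diameter([np.pi * 100, np.pi * 100 + 3.1416])
        assert d[1] - d[0] == pytest.approx(1.0, abs=1e-4)

    def test_zero_change_and_scaling(self):
        d = growth.band_to_diameter([100.0, 100.0])
        assert d[1] - d[0] == 0.0
        assert growth.band_to_diameter([200.0])[0] == \
            pytest.approx(2 * growth.band_to_diameter([100.0])[0])

    def test_negative_reading_rejected(self):
        with pytest.raises(ValueError):
            growth.band_to_diameter([-1.0])


class TestADI:
    def test_linear_ramp_exact(self):
        dates, d = ramp_series(10.0)
        adi, per_year = growth.compute_adi(dates, d)
        assert adi == pytest.approx(10.0, abs=1e-9)
        assert list(per_year) == [2021]

    def test_ramp_then_equal_shrinkage_nets_zero(self):
        dates = pd.date_range("2021-11-01", periods=74, freq="5D")
        t = (dates - dates[0]).days.to_numpy(float)
        d = 50.0 + np.where(t <= 182.5, 10 * t / 182.5,
                            10 * (365 - t) / 182.5)
        adi, _ = growth.compute_adi(dates, d)
        assert adi == pytest.approx(0.0, abs=1e-9)

    def test_telescoping_of_subperiod_changes(self):
        dates, d = ramp_series(7.3)
        rng = np.random.default_rng(5)
        d = d + rng.normal(0, 0.3, d.size)
        adi, per_year = growth.compute_adi(dates, d)
        # Net change interpolated to boundaries equals the sum of signed
        # sub-period changes within the year.
        t = (dates - dates[0]).days.to_numpy(float)
        hi = (pd.Timestamp("2022-11-01") - dates[0]).days
        d_hi = np.interp(hi, t, d)
        assert per_year[2021] == pytest.approx(d_hi - d[0], abs=1e-9)

    def test_short_coverage_year_excluded(self):
        dates = pd.date_range("2022-01-01", periods=10, freq="17D")
        d = np.linspace(50, 52, 10)
        with pytest.warns(UserWarning, match="excluded"):
            with pytest.raises(ValueError, match="coverage"):
                growth.compute_adi(dates, d)

    def test_generator_roundtrip(self, truth, quiet_cfg):
        df, gt = generate_dendro_series(truth, quiet_cfg)
        diam = growth.band_to_diameter(df.circumference_mm.to_numpy())
        adi, _ = growth.compute_adi(df.date, diam)
        assert adi == pytest.approx(gt["adi"], abs=0.05)


class TestPDGR:
    def test_linear_ramp_exact(self):
        dates, d = ramp_series(10.0)
        assert growth.compute_pdgr(dates, d) == pytest.approx(10.0, rel=1e-6)

    def test_flat_series_zero(self):
        dates, _ = ramp_series()
        assert growth.compute_pdgr(dates, np.full(23, 50.0)) == \
            pytest.approx(0.0, abs=1e-6)

    def test_offset_invariance(self):
        dates, d = ramp_series(8.0)
        assert growth.compute_pdgr(dates, d + 40.0) == \
            pytest.approx(growth.compute_pdgr(dates, d), rel=1e-9)

    def test_shrinking_series_truncated_at_zero(self):
        dates, d = ramp_series(10.0)
        assert growth.compute_pdgr(dates, d[::-1]) == 0.0

    def test_generator_roundtrip_within_5pct(self, truth, quiet_cfg):
        df, gt = generate_dendro_series(truth, quiet_cfg)
        diam = growth.band_to_diameter(df.circumference_mm.to_numpy())
        assert growth.compute_pdgr(df.date, diam) == pytest.approx(
            gt["pdgr"], rel=0.05)


class TestSeasonLength:
    def test_generator_roundtrip(self, truth, quiet_cfg):
        df, gt = generate_dendro_series(truth, quiet_cfg)
        diam = growth.band_to_diameter(df.circumference_mm.to_numpy())
        est = growth.growing_season_length(df.date, diam)
        assert est == pytest.approx(gt["season_length"], abs=5.0)

    def test_flat_series_zero_with_warning(self):
        dates, _ = ramp_series()
        with pytest.warns(UserWarning, match="season length 0"):
            assert growth.growing_season_length(
                dates, np.full(23, 50.0)) == 0.0

    def test_zero_threshold_spans_full_year(self):
        dates, d = ramp_series(10.0)
        est = growth.growing_season_length(dates, d, threshold=0.0)
        span = (dates[-1] - dates[0]).days
        # Single rainfall year boundary at Nov 1 2022 splits the grid.
        assert est >= 0.45 * span


class TestSpeciesPooling:
    def test_identical_values(self):
        pooled = growth.shrink_species_estimates([5.0, 5.0, 5.0])
        assert pooled.mean == 5.0
        assert pooled.ci95 == pytest.approx((5.0, 5.0))

    def test_symmetric_pair_midpoint(self):
        pooled = growth.shrink_species_estimates([4.0, 8.0])
        assert pooled.mean == pytest.approx(6.0)

    def test_size_covariate_regressed_out(self):
        size = np.array([10.0, 20.0, 30.0, 40.0])
        values = 5.0 + 0.1 * (size - size.mean())
        pooled = growth.shrink_species_estimates(values, initial_size=size)
        assert pooled.mean == pytest.approx(5.0, abs=1e-9)
        assert pooled.ci95 == pytest.approx((5.0, 5.0), abs=1e-6)

    def test_year_offsets_removed(self):
        values = np.array([5.0, 5.0, 7.0, 7.0])
        year = np.array([2021, 2021, 2022, 2022])
        pooled = growth.shrink_species_estimates(values, year=year)
        assert pooled.mean == pytest.approx(6.0)
        assert pooled.ci95 == pytest.approx((6.0, 6.0), abs=1e-9)

    def test_interval_coverage(self, rng):
        # 9 trees per species, known species mean: the 95% interval
        # should cover the truth in >= 90% of replicates.
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            y = 7.0 + rng.normal(0, 1.0, 9)
            pooled = growth.shrink_species_estimates(y)
            hits += pooled.ci95[0] <= 7.0 <= pooled.ci95[1]
        assert hits / n_rep >= 0.90

    def test_shrunk_estimates_between_value_and_mean(self, rng):
        y = rng.normal(10, 2, 6)
        pooled = pool_estimates(y, se=np.full(6, 0.5))
        lo = np.minimum(y, pooled.mean) - 1e-12
        hi = np.maximum(y, pooled.mean) + 1e-12
        assert np.all((pooled.shrunk >= lo) & (pooled.shrunk <= hi))


class TestWaterPotentials:
    def make_records(self):
        rows = []
        for tree, (pd_psi, md_psi) in enumerate(
                [(-0.4, -1.4), (-0.5, -1.5), (-0.6, -1.6)]):
            rows.append({"tree_id": f"t{tree}", "species": "SP1",
                         "date": "2022-01-15", "psi_pd": pd_psi,
                         "psi_md": md_psi, "soil_psi_15cm": -0.2,
                         "soil_psi_30cm": -0.3, "soil_psi_45cm": -0.4})
        return pd.DataFrame(rows)

    def test_monthly_means_and_delta(self):
        out = growth.summarize_water_potentials(self.make_records())
        row = out.iloc[0]
        assert row["psi_pd"] == pytest.approx(-0.5)
        assert row["psi_md"] == pytest.approx(-1.5)
        assert row["delta_psi"] == pytest.approx(-1.0)
        assert row["soil_psi_mean"] == pytest.approx(-0.3)

    def test_ci_matches_hand_t_interval(self):
        out = growth.summarize_water_potentials(self.make_records())
        row = out.iloc[0]
        vals = np.array([-0.4, -0.5, -0.6])
        half = 4.302652729911275 * vals.std(ddof=1) / np.sqrt(3)
        assert row["psi_pd_ci_lo"] == pytest.approx(-0.5 - half)
        assert row["psi_pd_ci_hi"] == pytest.approx(-0.5 + half)

    def test_single_depth_soil_mean(self):
        df = self.make_records().drop(
            columns=["soil_psi_30cm", "soil_psi_45cm"])
        out = growth.summarize_water_potentials(df)
        assert out.iloc[0]["soil_psi_mean"] == pytest.approx(-0.2)
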