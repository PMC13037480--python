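"""Air discharge, PAD scaling and vulnerability-curve fitting."""

import numpy as np
import pytest

from hydrotraits import pneumatics
from hydrotraits.synth import (GeneratorConfig, default_truth,
                               generate_pneumatron_series, psi_schedule)


def flat_plus_ramp(dp, n=180, p0=40.0):
    """Trace rising linearly by dp over the window."""
    return p0 + dp * np.linspace(0, 1, n)


class TestAirDischarge:
    def test_no_pressure_change_no_discharge(self):
        assert pneumatics.compute_ad(np.full(180, 40.0), 2.6e-6, 293) == 0.0

    def test_ideal_gas_arithmetic(self):
        # 5 kPa into 2.6 mL at 293 K, flat endpoint plateaus.
        tr = np.concatenate([np.full(90, 40.0), np.full(90, 45.0)])
        ad = pneumatics.compute_ad(tr, 2.6e-6, 293.0)
        assert ad == pytest.approx(5000 * 2.6e-6 / (8.314 * 293), rel=1e-9)

    def test_linear_in_volume(self):
        tr = flat_plus_ramp(5.0)
        assert pneumatics.compute_ad(tr, 5.2e-6, 293) == pytest.approx(
            2 * pneumatics.compute_ad(tr, 2.6e-6, 293))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            pneumatics.compute_ad(np.array([40.0, 45.0]), 2.6e-6, 293)

    def test_endpoints_resist_single_outlier(self):
        tr = flat_plus_ramp(5.0)
        spiked = tr.copy()
        spiked[0] += 30.0
        assert pneumatics.compute_ad(spiked, 2.6e-6, 293) == pytest.approx(
            pneumatics.compute_ad(tr, 2.6e-6, 293), rel=0.02)

    def test_detection_ceiling_warns_only(self):
        with pytest.warns(UserWarning, match="ceiling"):
            ad = pneumatics.compute_ad(flat_plus_ramp(60.0), 2.6e-6, 293)
        assert ad > 0


class TestPAD:
    def make_series(self, dps, psis):
        steps = [pneumatics.PneumatronStep(psi, flat_plus_ramp(dp))
                 for dp, psi in zip(dps, psis)]
        return pneumatics.PneumatronSeries("b", steps, 2.6e-6, 293.0)

    def test_endpoints_and_midpoint(self):
        series = self.make_series([2.0, 21.0, 40.0], [-1.0, -2.0, -3.0])
        pad = pneumatics.compute_pad(series)
        assert pad.pad == pytest.approx([0.0, 50.0, 100.0], abs=1e-9)

    def test_flat_series_rejected(self):
        series = self.make_series([5.0, 5.0, 5.0], [-1.0, -2.0, -3.0])
        with pytest.raises(ValueError, match="flat"):
            pneumatics.compute_pad(series)

    def test_bounded_zero_to_hundred(self, truth, rng):
        series, _ = generate_pneumatron_series(
            truth, psi_schedule(15), GeneratorConfig(seed=3), rng=rng)
        pad = pneumatics.compute_pad(series)
        assert pad.pad.min() == pytest.approx(0.0, abs=1e-12)
        assert pad.pad.max() == pytest.approx(100.0, abs=1e-9)

    def test_invalid_tubing_volume_rejected(self):
        with pytest.raises(ValueError, match="tubing"):
            pneumatics.PneumatronSeries("b", [], 0.0, 293.0)


class TestVulnerabilityFit:
    def sigmoid(self, psi, a, p50):
        return 100.0 / (1.0 + np.exp(a * (psi - p50)))

    def test_noiseless_identifiability(self):
        psi = np.linspace(-0.1, -6, 14)
        fit = pneumatics.VulnerabilityCurve().fit(
            psi, self.sigmoid(psi, 2.0, -2.0))
        assert fit.p50_ == pytest.approx(-2.0, abs=1e-6)
        assert fit.slope_a_ == pytest.approx(2.0, abs=1e-5)

    def test_midpoint_anchors_p50(self):
        psi = np.linspace(-0.1, -8, 17)
        fit = pneumatics.VulnerabilityCurve().fit(
            psi, self.sigmoid(psi, 2.0, -3.1))
        assert fit.p50_ == pytest.approx(-3.1, abs=1e-6)
        assert float(fit.predict([-3.1])[0]) == pytest.approx(50.0, abs=1e-6)

    def test_quantile_ordering(self):
        psi = np.linspace(-0.1, -6, 14)
        fit = pneumatics.VulnerabilityCurve().fit(
            psi, self.sigmoid(psi, 2.0, -2.0))
        assert fit.p12_ > fit.p50_ > fit.p88_

    def test_fitted_curve_monotone_in_psi(self):
        psi = np.linspace(-0.1, -6, 14)
        fit = pneumatics.VulnerabilityCurve().fit(
            psi, self.sigmoid(psi, 2.0, -2.0))
        grid = np.linspace(-8, 0, 200)
        assert np.all(np.diff(fit.predict(grid)) <= 0)

    def test_insufficient_span_reported(self):
        psi = np.linspace(-0.1, -1.5, 8)
        pad = self.sigmoid(psi, 2.0, -2.0)     # never exceeds 80%
        with pytest.raises(ValueError, match="span"):
            pneumatics.VulnerabilityCurve().fit(psi, pad)

    def test_p50_error_shrinks_with_noise(self, rng):
        psi = np.linspace(-0.1, -6, 20)
        meds = []
        for noise in (4.0, 1.0, 0.0):
            errs = []
            for _ in range(60):
                pad = self.sigmoid(psi, 2.0, -2.0) \
                    + rng.normal(0, noise, psi.size)
                fit = pneumatics.VulnerabilityCurve().fit(psi, pad)
                errs.append(abs(fit.p50_ + 2.0))
            meds.append(np.median(errs))
        assert meds[0] >= meds[1] >= meds[2]
        assert meds[2] < 1e-6


class TestGeneratorChain:
    def test_zero_noise_pad_matches_truth(self, truth, quiet_cfg):
        series, gt = generate_pneumatron_series(
            truth, psi_schedule(12), quiet_cfg)
        pad = pneumatics.compute_pad(series)
        np.testing.assert_allclose(pad.pad, gt["pad_true"], atol=1e-3)

    def test_zero_noise_p50_recovery(self, truth, quiet_cfg):
        series, _ = generate_pneumatron_series(
            truth, psi_schedule(12), quiet_cfg)
        fit = pneumatics.fit_vulnerability(pneumatics.compute_pad(series))
        assert fit.p50_ == pytest.approx(truth.p50, abs=1e-6)

    def test_nonmonotone_schedule_rejected(self, truth, quiet_cfg):
        with pytest.raises(ValueError, match="decreasing"):
            generate_pneumatron_series(truth, [-1.0, -0.5, -2.0], quiet_cfg)

    def test_pressure_noise_p50_error(self, truth, rng):
        cfg = GeneratorConfig(noise_pressure_kpa=0.5)
        sch = psi_schedule(12)
        errs = []
        for _ in range(100):
            series, _ = generate_pneumatron_series(truth, sch, cfg, rng=rng)
            fit = pneumatics.fit_vulnerability(
                pneumatics.compute_pad(series))
            errs.append(abs(fit.p50_ - truth.p50))
        assert np.median(errs) < 0.15

    def test_species_mean_with_interval(self):
        pooled = pneumatics.species_p50([-2.1, -1.9, -2.0])
        assert pooled.mean == pytest.approx(-2.0)
        assert pooled.ci95[0] < -2.0 < pooled.ci95[1]


def test_default_truth_constraints():
    t = default_truth()
    assert t.p50 < 0 and t.capacitance_slope > 0
    with pytest.raises(ValueError):
        default_truth(p50=1.0)
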