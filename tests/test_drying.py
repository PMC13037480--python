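"""Shoot drying curves: RWC bookkeeping, decay fit and capacitance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrotraits import drying
from hydrotraits.synth import GeneratorConfig, generate_drying_experiment


def make_experiment(sm, dm, specs):
    """specs: list of (fm_before, excised, psi)."""
    steps = [drying.DryingStep(fm, exc, (psi, psi))
             for fm, exc, psi in specs]
    return drying.ShootDryingExperiment("b1", sm, dm, steps)


class TestRWCSeries:
    def test_first_step_is_unity_by_definition(self):
        exp = make_experiment(50, 20, [(50, 0, -0.1), (45, 0, -1.0),
                                       (40, 0, -2.5)])
        assert drying.compute_rwc_series(exp).rwc[0] == 1.0

    def test_unit_ratios_keep_rwc_at_one(self):
        exp = make_experiment(50, 20, [(50, 0, -0.1), (50, 0, -1.0),
                                       (50, 0, -2.0)])
        assert drying.compute_rwc_series(exp).rwc == pytest.approx([1, 1, 1])

    def test_worked_example_with_intervening_excision(self):
        # SM=50, DM=20; ratios 0.9 and 0.9, a 5 g leaf excision between:
        # RWC_2 = (45-20)/30, RWC_3 = (0.9*0.9*50-20)/30.
        exp = make_experiment(50, 20, [(50, 0, -0.1), (45, 5, -1.0),
                                       (36, 0, -2.0)])
        rwc = drying.compute_rwc_series(exp).rwc
        assert rwc == pytest.approx([1.0, 0.8333, 0.6833], abs=1e-4)

    def test_excision_not_counted_as_water_loss(self):
        # Pure excision (no evaporation): next ratio divides by the
        # post-cut mass, so RWC is unchanged.
        exp = make_experiment(50, 20, [(50, 10, -0.1), (40, 0, -1.0)])
        assert drying.compute_rwc_series(exp).rwc[1] == pytest.approx(1.0)

    def test_mass_gain_flagged_not_dropped(self):
        exp = make_experiment(50, 20, [(50, 0, -0.1), (51, 0, -1.0),
                                       (45, 0, -2.0)])
        with pytest.warns(UserWarning, match="mass gain"):
            curve = drying.compute_rwc_series(exp)
        assert curve.mass_gain_flags[1]
        assert curve.rwc.size == 3

    def test_psi_is_mean_of_pair_and_spread_flagged(self):
        steps = [drying.DryingStep(50, 0, (-0.2, -0.4)),
                 drying.DryingStep(45, 0, (-1.0, -1.8))]
        exp = drying.ShootDryingExperiment("b", 50, 20, steps)
        curve = drying.compute_rwc_series(exp)
        assert curve.psi[0] == pytest.approx(-0.3)
        assert not curve.psi_spread_flags[0]
        assert curve.psi_spread_flags[1]

    def test_sm_not_above_dm_rejected(self):
        with pytest.raises(ValueError, match="SM > DM"):
            drying.ShootDryingExperiment("b", 20, 20, [])

    @given(st.lists(st.floats(0.80, 0.999), min_size=3, max_size=10))
    @settings(deadline=None)
    def test_roundtrip_masses_from_any_declining_rwc(self, ratios):
        # Invert the RWC bookkeeping for an arbitrary declining series.
        sm, dm = 40.0, 15.0
        rwc = np.concatenate([[1.0], np.cumprod(ratios)])
        s = rwc * (sm - dm) + dm
        specs, fm_after = [], None
        for i in range(rwc.size):
            fm = sm if i == 0 else fm_after * s[i] / s[i - 1]
            exc = 1.0 if i % 2 == 1 else 0.0
            specs.append((fm, exc, -0.1 * (i + 1)))
            fm_after = fm - exc
        exp = make_experiment(sm, dm, specs)
        out = drying.compute_rwc_series(exp).rwc
        np.testing.assert_allclose(out, rwc, atol=1e-9)


class TestSWC:
    @pytest.mark.parametrize("sm,dm,expected", [
        (50.0, 20.0, 1.5), (20.0, 10.0, 1.0), (30.0, 12.0, 1.5)])
    def test_values(self, sm, dm, expected):
        exp = drying.ShootDryingExperiment("b", sm, dm, [])
        assert drying.compute_swc(exp) == pytest.approx(expected, rel=1e-2)

    def test_generator_roundtrip_exact_at_zero_noise(self, truth, quiet_cfg):
        exp, _ = generate_drying_experiment(truth, quiet_cfg)
        assert drying.compute_swc(exp) == pytest.approx(truth.swc, abs=1e-12)


class TestExpDecay:
    def test_noiseless_parameter_recovery(self):
        psi = -np.geomspace(0.05, 8, 12)
        rwc = 0.2 + 0.8 * np.exp(1.2 * psi)
        fit = drying.ExpDecayCurve().fit(psi, rwc)
        assert fit.residual_ == pytest.approx(0.2, abs=1e-6)
        assert fit.rate_ == pytest.approx(1.2, abs=1e-6)
        assert fit.beats_linear_

    def test_saturation_anchor_and_asymptote(self):
        psi = -np.geomspace(0.05, 8, 12)
        fit = drying.ExpDecayCurve().fit(psi, 0.3 + 0.7 * np.exp(0.8 * psi))
        assert drying.rwc_at_psi(fit, 0.0) == pytest.approx(1.0, abs=1e-6)
        assert drying.rwc_at_psi(fit, -80.0) == pytest.approx(0.3, abs=1e-6)

    def test_evaluation_closed_form(self):
        psi = -np.geomspace(0.05, 8, 12)
        fit = drying.ExpDecayCurve().fit(psi, 0.2 + 0.8 * np.exp(1.2 * psi))
        expected = 0.2 + 0.8 * np.exp(-2.4)
        assert drying.rwc_at_psi(fit, -2.0) == pytest.approx(expected,
                                                            abs=1e-6)

    def test_positive_psi_rejected(self):
        psi = -np.geomspace(0.05, 8, 12)
        fit = drying.ExpDecayCurve().fit(psi, 0.2 + 0.8 * np.exp(1.2 * psi))
        with pytest.raises(ValueError):
            drying.rwc_at_psi(fit, 0.5)

    def test_narrow_span_rejected(self):
        psi = np.linspace(-0.1, -1.0, 6)
        with pytest.raises(ValueError, match="span"):
            drying.ExpDecayCurve().fit(psi, np.exp(psi))

    def test_rate_recovery_under_noise(self, rng):
        psi = -np.geomspace(0.05, 8, 15)
        errs = []
        for _ in range(200):
            rwc = 0.2 + 0.8 * np.exp(1.2 * psi)
            noisy = rwc * (1 + rng.normal(0, 0.05, psi.size))
            fit = drying.ExpDecayCurve().fit(psi, noisy)
            errs.append(abs(fit.rate_ - 1.2) / 1.2)
        assert np.median(errs) < 0.10


class TestCapacitance:
    def test_hand_standardization(self):
        # slope 0.05 g/g/MPa, SM 50 g, DM 20 g -> 0.05*1500/18.01.
        assert drying.compute_c_std(0.05, 50, 20) == pytest.approx(
            4.164, abs=2e-3)

    def test_unit_invariance_g_vs_kg(self):
        assert drying.compute_c_std(0.05, 50.0, 20.0) == pytest.approx(
            drying.compute_c_std(0.05, 0.050, 0.020))

    def test_zero_slope_zero_capacitance(self):
        assert drying.compute_c_std(0.0, 50, 20) == 0.0

    def test_linear_segment_slope_recovered_exactly(self):
        psi = np.linspace(-0.1, -8, 14)
        rwc = np.where(psi > -2, 1 + 0.3 * psi, 0.4 + 0.05 * (psi + 2))
        cap = drying.CapacitanceRegression().fit(psi, rwc)
        assert cap.slope_ == pytest.approx(0.05, abs=1e-9)

    def test_explicit_closure_override(self):
        psi = np.linspace(-0.1, -8, 14)
        rwc = np.where(psi > -2, 1 + 0.3 * psi, 0.4 + 0.05 * (psi + 2))
        cap = drying.CapacitanceRegression(closure_psi=-2.0).fit(psi, rwc)
        assert cap.slope_ == pytest.approx(0.05, abs=1e-9)

    def test_too_few_post_closure_points_rejected(self):
        psi = np.linspace(-0.1, -8, 8)
        with pytest.raises(ValueError, match="beyond closure"):
            drying.CapacitanceRegression(closure_psi=-7.5).fit(
                psi, np.exp(psi))

    def test_generator_roundtrip_recovers_slope(self, truth, quiet_cfg):
        exp, gt = generate_drying_experiment(truth, quiet_cfg)
        curve = drying.compute_rwc_series(exp)
        cap = drying.fit_capacitance(curve)
        assert cap.slope_ == pytest.approx(truth.capacitance_slope,
                                           rel=1e-6)
        assert cap.c_std(exp.sm, exp.dm) == pytest.approx(
            truth.capacitance_slope * truth.swc * 1000 / 18.01, rel=1e-6)


class TestGeneratorRoundTrip:
    def test_zero_noise_rwc_series_reproduced(self, truth, quiet_cfg):
        exp, gt = generate_drying_experiment(truth, quiet_cfg)
        curve = drying.compute_rwc_series(exp)
        np.testing.assert_allclose(curve.rwc, gt["rwc_true"], atol=1e-9)

    def test_rwc_non_increasing_within_noise(self, truth):
        cfg = GeneratorConfig(seed=7)
        exp, _ = generate_drying_experiment(truth, cfg)
        curve = drying.compute_rwc_series(exp)
        sm_dm = exp.sm - exp.dm
        tol = 3 * cfg.noise_mass_g / sm_dm * 3
        assert np.all(np.diff(curve.rwc) <= tol)

    def test_rwc50_not_above_rwctlp_when_p50_more_negative(self, truth,
                                                           quiet_cfg):
        exp, _ = generate_drying_experiment(truth, quiet_cfg)
        fit = drying.fit_rwc_psi(drying.compute_rwc_series(exp))
        assert truth.p50 <= truth.psi_tlp
        assert drying.rwc_at_psi(fit, truth.p50) <= \
            drying.rwc_at_psi(fit, truth.psi_tlp)
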