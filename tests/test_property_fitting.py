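"""Tests for viscosity/surface-drive recovery and stimulation read-out."""

import numpy as np
import pytest

import capiflow as cf
from capiflow.errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
)
from capiflow.flow_simulator import MEAN_DIAMETERS_UM
from capiflow.studies import circle

from conftest import model_velocity_series


HEIGHTS = np.linspace(0.010, 0.060, 60)


class TestLinearTransientFit:
    def test_hand_evaluated_water_line(self, water, circle_156):
        ser = model_velocity_series(water, circle_156, HEIGHTS)
        fit = cf.linear_transient_fit(ser, circle_156, water.density)
        assert fit.constraint_record["slope_m2_s"] == pytest.approx(
            469.7e-6, rel=1e-3
        )
        assert fit.constraint_record["intercept_m_s"] == pytest.approx(
            -7.19e-3, rel=1e-2
        )
        assert fit.viscosity == pytest.approx(1.04e-3, rel=5e-3)
        assert fit.surface_drive == pytest.approx(0.025, rel=5e-3)

    @pytest.mark.parametrize("d_um", MEAN_DIAMETERS_UM)
    def test_exact_recovery_every_diameter(self, water, d_um):
        geom = circle(d_um)
        h_eq = cf.equilibrium_height(water, geom)
        ser = model_velocity_series(water, geom, np.linspace(0.15, 0.85, 60) * h_eq)
        fit = cf.linear_transient_fit(ser, geom, water.density)
        assert fit.viscosity == pytest.approx(water.viscosity, rel=5e-3)
        assert fit.surface_drive == pytest.approx(water.sigma_eff, rel=5e-3)

    def test_doubled_viscosity_doubles_estimate(self, water, circle_156):
        thick = water.with_viscosity(2 * water.viscosity)
        fit1 = cf.linear_transient_fit(
            model_velocity_series(water, circle_156, HEIGHTS), circle_156, 998.0
        )
        fit2 = cf.linear_transient_fit(
            model_velocity_series(thick, circle_156, HEIGHTS), circle_156, 998.0
        )
        assert fit2.viscosity == pytest.approx(2 * fit1.viscosity, rel=5e-3)
        assert fit2.surface_drive == pytest.approx(fit1.surface_drive, rel=5e-3)

    def test_insufficient_points_rejected(self, water, circle_156):
        ser = model_velocity_series(water, circle_156, [0.02, 0.02, 0.02])
        with pytest.raises(InsufficientDataError):
            cf.linear_transient_fit(ser, circle_156, 998.0)

    def test_nonphysical_intercept_flagged(self, circle_156):
        # constant velocity carries no gravity signature: intercept >= 0
        ser = cf.VelocitySeries(
            times=np.arange(10.0), velocities=np.full(10, 5e-3),
            reciprocal_heights=1 / np.linspace(0.01, 0.05, 10),
            heights=np.linspace(0.01, 0.05, 10),
            clamped=np.zeros(10, bool),
            signed_velocities=np.full(10, 5e-3),
        )
        fit = cf.linear_transient_fit(ser, circle_156, 998.0)
        assert "nonphysical_intercept" in fit.flags
        assert fit.viscosity is None and not fit.viscosity_identifiable

    def test_removing_intercept_changes_viscosity(self, water, circle_156):
        # slope and intercept jointly identify the parameters: forcing the
        # line through the origin must move the viscosity estimate
        ser = model_velocity_series(water, circle_156, HEIGHTS)
        fit = cf.linear_transient_fit(ser, circle_156, 998.0)
        x, y = ser.reciprocal_heights, ser.velocities
        slope_no_c = float(np.sum(x * y) / np.sum(x * x))
        dp_l = cf.laplace_pressure(water, circle_156)
        mu_no_c = dp_l * circle_156.hydraulic_diameter**2 / (32 * slope_no_c)
        assert mu_no_c != pytest.approx(fit.viscosity, rel=1e-3)


class TestConstrainedFit:
    def test_matches_linear_fit_in_linear_regime(self, water, circle_156):
        ser = model_velocity_series(water, circle_156, HEIGHTS)
        lin = cf.linear_transient_fit(ser, circle_156, 998.0)
        con = cf.constrained_fit([ser], [circle_156], 998.0,
                                 cf.ConstraintSet(), dip_depth=0.0)
        assert con.viscosity == pytest.approx(lin.viscosity, rel=5e-3)
        assert con.surface_drive == pytest.approx(lin.surface_drive, rel=5e-3)

    def test_bound_inactive_when_truth_inside(self, circle_156):
        fluid = cf.FluidProperties(density=1025, viscosity=1.50e-3,
                                   surface_drive=0.023)
        ser = model_velocity_series(fluid, circle_156, HEIGHTS)
        cons = cf.ConstraintSet(viscosity_hi_cP=1.7)
        fit = cf.constrained_fit([ser], [circle_156], 1025.0, cons,
                                 dip_depth=0.0)
        assert not fit.constraint_record["mu_active"]
        assert fit.viscosity == pytest.approx(1.50e-3, rel=5e-3)

    def test_bound_active_when_truth_outside(self, circle_156):
        # plasma-like data generated above the plasma cap: the estimate
        # must sit on the bound with the active flag set
        fluid = cf.FluidProperties(density=1025, viscosity=2.2e-3,
                                   surface_drive=0.023)
        ser = model_velocity_series(fluid, circle_156, HEIGHTS)
        cons = cf.ConstraintSet(viscosity_hi_cP=1.7)
        fit = cf.constrained_fit([ser], [circle_156], 1025.0, cons,
                                 dip_depth=0.0)
        assert fit.constraint_record["mu_active"]
        assert fit.viscosity == pytest.approx(1.7e-3, rel=1e-6)

    def test_fixed_viscosity_only_fits_surface_drive(self, water, circle_156):
        ser = model_velocity_series(water, circle_156, HEIGHTS)
        cons = cf.TABLE_CONSTRAINTS["water"]
        fit = cf.constrained_fit([ser], [circle_156], 998.0, cons,
                                 dip_depth=0.0)
        assert fit.viscosity == pytest.approx(1.04e-3, rel=1e-12)
        assert fit.surface_drive == pytest.approx(0.025, rel=5e-3)

    def test_infeasible_box_rejected(self):
        with pytest.raises(ConfigurationError):
            cf.ConstraintSet(viscosity_lo_cP=6.0, viscosity_hi_cP=2.0)

    def test_pooled_noisy_recovery_within_margin(self, whole_blood):
        from capiflow.studies import noisy_recovery_study

        res = noisy_recovery_study(whole_blood, 156.3, n_replicates=5, seed=42)
        assert np.all(np.abs(res["sigma_dev_pct"]) <= 13.0)
        assert np.all(np.abs(res["mu_dev_pct"]) <= 13.0)


class TestEquilibriumOnlyFit:
    def test_viscosity_not_identifiable(self, water, circle_156):
        h_eq = cf.equilibrium_height(water, circle_156)
        fit = cf.equilibrium_only_fit(h_eq, circle_156, 998.0)
        assert fit.viscosity is None
        assert not fit.viscosity_identifiable
        assert fit.surface_drive == pytest.approx(water.sigma_eff, rel=1e-9)


class TestMultiplierCurves:
    def baseline(self, fluid, geom):
        return cf.FitResult(
            surface_drive=fluid.sigma_eff, viscosity=fluid.viscosity,
            density=fluid.density,
            equilibrium_height=cf.equilibrium_height(fluid, geom),
            residual_rms=0.0, geometry=geom,
        )

    def test_unit_multiplier_reproduces_baseline(self, whole_blood, circle_156):
        fam = cf.multiplier_curves(self.baseline(whole_blood, circle_156),
                                   circle_156, dip_depth=0.0)
        inv_h = 1 / np.linspace(0.01, 0.05, 20)
        u_direct = np.array(
            [cf.quasi_steady_velocity(whole_blood, circle_156, 1 / x,
                                      1 / x).velocity for x in inv_h]
        )
        np.testing.assert_allclose(fam.velocity(1.0, inv_h), u_direct,
                                   rtol=1e-12)

    def test_doubled_viscosity_halves_velocity(self, whole_blood, circle_156):
        fam = cf.multiplier_curves(self.baseline(whole_blood, circle_156),
                                   circle_156, dip_depth=0.0)
        inv_h = 1 / np.linspace(0.01, 0.05, 20)
        np.testing.assert_allclose(fam.velocity(2.0, inv_h),
                                   fam.velocity(1.0, inv_h) / 2, rtol=1e-12)

    def test_family_ordering(self, whole_blood, circle_156):
        fam = cf.multiplier_curves(self.baseline(whole_blood, circle_156),
                                   circle_156)
        assert fam.multipliers == (1.0, 2.0, 3.0, 4.0, 6.0)
        inv_h = 1 / np.linspace(0.01, 0.05, 20)
        for lo, hi in zip(fam.multipliers, fam.multipliers[1:]):
            assert np.all(fam.velocity(hi, inv_h) <= fam.velocity(lo, inv_h))

    def test_submultiplier_rejected(self, whole_blood, circle_156):
        with pytest.raises(DomainError):
            cf.multiplier_curves(self.baseline(whole_blood, circle_156),
                                 circle_156, multipliers=(0.5, 2.0))


class TestClassifyStimulatedSeries:
    def _family(self, fluid, geom, dip):
        base = cf.FitResult(
            surface_drive=fluid.sigma_eff, viscosity=fluid.viscosity,
            density=fluid.density,
            equilibrium_height=cf.equilibrium_height(fluid, geom),
            residual_rms=0.0, geometry=geom,
        )
        return cf.multiplier_curves(base, geom, dip_depth=dip)

    def test_unstimulated_series_terminal_one_no_onset(self, whole_blood,
                                                       circle_156, fast_cfg):
        tr = cf.integrate_rise(whole_blood, circle_156, fast_cfg)
        fam = self._family(whole_blood, circle_156, fast_cfg.dip_depth)
        cls = cf.classify_stimulated_series(cf.estimate_velocity(tr), fam)
        assert cls["terminal_multiplier"] == 1.0
        assert cls["onset_time"] is None

    def test_onset_recovered_and_ordered(self, whole_blood, circle_156):
        cfg = cf.SimulationConfig(time_step=5e-3, total_time=35.0,
                                  height_noise=0.0, time_jitter=0.0)
        fam = self._family(whole_blood, circle_156, cfg.dip_depth)
        onsets = []
        for t_on in (10.0, 25.0):
            sch = cf.StimulusSchedule(dose=50, plateau_multiplier=6,
                                      onset_time=t_on)
            tr = cf.simulate_stimulated_rise(whole_blood, circle_156, sch, cfg)
            cls = cf.classify_stimulated_series(cf.estimate_velocity(tr), fam)
            assert cls["terminal_multiplier"] == 6.0
            assert cls["onset_time"] == pytest.approx(t_on, abs=5.0)
            onsets.append(cls["onset_time"])
        assert onsets[0] < onsets[1]

    def test_empty_series_rejected(self, whole_blood, circle_156):
        fam = self._family(whole_blood, circle_156, 0.0)
        empty = cf.VelocitySeries(
            times=np.array([]), velocities=np.array([]),
            reciprocal_heights=np.array([]), heights=np.array([]),
            clamped=np.array([], dtype=bool),
        )
        with pytest.raises(InsufficientDataError):
            cf.classify_stimulated_series(empty, fam)


class TestRecoveryReport:
    def test_identical_parameters_zero_deviation(self, circle_156):
        fit = cf.FitResult(surface_drive=0.034, viscosity=4.58e-3,
                           density=1055, equilibrium_height=0.08,
                           residual_rms=0.0, geometry=circle_156)
        rep = cf.recovery_report(
            {"surface_drive": 0.034, "viscosity": 4.58e-3}, fit
        )
        assert rep["surface_drive_pct"] == 0.0
        assert rep["viscosity_pct"] == 0.0
        assert rep["max_abs_pct"] == 0.0

    def test_signed_percent_arithmetic(self, circle_156):
        fit = cf.FitResult(surface_drive=0.025, viscosity=1.17e-3,
                           density=998, equilibrium_height=0.065,
                           residual_rms=0.0, geometry=circle_156)
        rep = cf.recovery_report({"viscosity": 1.04e-3}, fit)
        assert rep["viscosity_pct"] == pytest.approx(12.5, abs=0.01)
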