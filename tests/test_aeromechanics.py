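"""Unit behaviour of the hovering-flight aeromechanic derivations."""

import math

import numpy as np
import pytest

import forceallometry as fa
from forceallometry.aeromechanics import (IndividualRecord, UnitSanityWarning,
                                          derive_all, records_from_frame)
from forceallometry.constants import ISA


def isa_density_oracle(h):
    # independent evaluation of the standard-atmosphere closed form
    exponent = ISA.g * ISA.molar_mass / (ISA.gas_constant * ISA.lapse_rate) - 1
    return ISA.rho0 * (1 - ISA.lapse_rate * h / ISA.T0) ** exponent


class TestAirDensity:
    def test_sea_level_is_reference(self):
        assert fa.air_density_from_elevation(0.0) == ISA.rho0

    def test_matches_closed_form_at_altitude(self):
        assert fa.air_density_from_elevation(4000.0) == pytest.approx(
            isa_density_oracle(4000.0), rel=1e-12)
        assert fa.air_density_from_elevation(4000.0) == pytest.approx(
            0.819, abs=5e-4)

    @pytest.mark.parametrize("h", [-1.0, 11000.0, 20000.0])
    def test_outside_troposphere_rejected(self, h):
        with pytest.raises(ValueError):
            fa.air_density_from_elevation(h)

    def test_strictly_decreasing(self):
        hs = np.linspace(0, 10999, 50)
        rhos = [fa.air_density_from_elevation(h) for h in hs]
        assert np.all(np.diff(rhos) < 0)

    def test_elevation_inverse_round_trip(self):
        for h in (0.0, 1234.5, 5000.0):
            rho = fa.air_density_from_elevation(h)
            assert fa.elevation_from_air_density(rho) == pytest.approx(
                h, abs=1e-6)


class TestWingVelocity:
    def test_zero_frequency(self):
        assert fa.mean_wing_velocity(0.0, 1.0, 0.02) == 0.0

    def test_cosine_convention_arithmetic(self):
        # 4 * 1.05 * 40 * 0.02
        assert fa.mean_wing_velocity(40, 1.05, 0.02,
                                     convention="cosine") == pytest.approx(3.36)

    def test_p2s_amplitude_is_halved(self):
        assert fa.mean_wing_velocity(40, 2.10, 0.02) == pytest.approx(3.36)

    def test_linear_in_frequency(self):
        assert fa.mean_wing_velocity(80, 1.05, 0.02, convention="cosine") == \
            pytest.approx(2 * fa.mean_wing_velocity(40, 1.05, 0.02,
                                                    convention="cosine"))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            fa.mean_wing_velocity(-1.0, 1.0, 0.02)


class TestForceCoefficient:
    def test_identity_case(self):
        rho, u, s = 1.2, 8.0, 8e-4
        assert fa.vertical_force_coefficient(0.5 * rho * u * u * s,
                                             rho, u, s) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        # 2 * 0.098 / (1.2 * 64 * 8e-4)
        assert fa.vertical_force_coefficient(0.098, 1.2, 8.0, 8e-4) == \
            pytest.approx(3.1901, abs=1e-4)

    def test_inverse_in_area(self):
        c1 = fa.vertical_force_coefficient(0.098, 1.2, 8.0, 8e-4)
        c2 = fa.vertical_force_coefficient(0.098, 1.2, 8.0, 3 * 8e-4)
        assert c1 == pytest.approx(3 * c2)

    def test_zero_velocity_rejected(self):
        with pytest.raises(ValueError, match="zero wing velocity"):
            fa.vertical_force_coefficient(0.1, 1.2, 0.0, 8e-4)


class TestLoadFactorAndInducedPower:
    def test_load_factor_values(self):
        assert fa.load_factor(0.049, 0.049) == 1.0
        assert fa.load_factor(0.147, 0.049) == pytest.approx(3.0)
        assert fa.load_factor(0.147 * 7, 0.049 * 7) == pytest.approx(3.0)

    def test_subweight_burst_warns(self):
        with pytest.warns(UnitSanityWarning):
            fa.load_factor(0.01, 0.049)

    def test_induced_velocity_unit_case(self):
        # F = 2 rho A  ->  v_ind = 1
        rho, phi, r = 1.2, 2.3, 0.031
        assert fa.rf_induced_velocity(2 * rho * phi * r * r,
                                      rho, phi, r) == pytest.approx(1.0)

    def test_induced_velocity_arithmetic(self):
        assert fa.rf_induced_velocity(0.049, 1.2, 2.3, 0.031) == \
            pytest.approx(3.039, abs=1e-3)

    def test_square_root_scaling(self):
        v1 = fa.rf_induced_velocity(0.049, 1.2, 2.3, 0.031)
        v4 = fa.rf_induced_velocity(4 * 0.049, 1.2, 2.3, 0.031)
        assert v4 == pytest.approx(2 * v1)

    def test_specific_power_modes(self):
        assert fa.specific_induced_power(1.0, 3.04) == pytest.approx(3.04)
        # 10-15% correction factors, midpoint
        assert fa.specific_induced_power(1.0, 3.04, tau=0.125) == \
            pytest.approx(3.42, abs=5e-3)
        v, u = 3.04, 6.0
        assert fa.specific_induced_power(
            1.5, v_ind=v) == pytest.approx(fa.specific_induced_power(
                1.5, mode="inflow_ratio", lambda_inflow=v / u, U=u))

    def test_inflow_mode_requires_ratio(self):
        with pytest.raises(ValueError):
            fa.specific_induced_power(1.0, mode="inflow_ratio", U=6.0)


def make_record(**overrides):
    base = dict(id="r1", species="sp", elevation=1000.0, body_mass=0.005,
                wing_area_S=1.2e-3, wing_length_R=0.049, r2_hat=0.49,
                r3_hat=0.55, hover_frequency_f=45.0, hover_amplitude_Phi=2.8)
    base.update(overrides)
    return IndividualRecord(**base)


class TestDeriveAll:
    def test_force_balance_round_trip(self):
        rec = make_record()
        d = derive_all(rec)
        force = 0.5 * d.air_density_rho * d.mean_wing_velocity_U ** 2 \
            * rec.wing_area_S * d.hover_force_coefficient
        assert force == pytest.approx(rec.weight, rel=1e-9)

    def test_idempotent(self):
        rec = make_record()
        assert derive_all(rec) == derive_all(rec)

    def test_burst_equal_to_weight(self):
        rec = make_record()
        rec.burst_force = rec.weight
        d = derive_all(rec)
        assert d.load_factor_n == pytest.approx(1.0)
        assert d.burst_force_coefficient == pytest.approx(
            d.hover_force_coefficient)

    def test_missing_mandatory_field(self):
        rec = make_record(hover_frequency_f=float("nan"))
        with pytest.raises(ValueError, match="hover_frequency_f"):
            derive_all(rec)

    def test_unit_error_flagged(self):
        # grams entered as kilograms inflates C_V a thousandfold
        rec = make_record(body_mass=5.0, weight=float("nan"))
        with pytest.warns(UnitSanityWarning, match="unit error"):
            derive_all(rec)

    def test_inflow_ratio_definition(self):
        d = derive_all(make_record())
        assert d.inflow_ratio == pytest.approx(
            d.induced_velocity / d.mean_wing_velocity_U)

    def test_aspect_ratio_invariant_enforced(self):
        rec = make_record(aspect_ratio=3.0)
        with pytest.raises(ValueError, match="aspect_ratio"):
            rec.validate()


def test_power_law_consistency_on_noise_free_records():
    """Log-log OLS on derived quantities returns the generating exponents."""
    cfg = fa.GeneratorConfig(
        seed=3, measurement_noise=0.0,
        species_scatter=dict(rho=0, R=0, AR=0, f=0, Phi=0, r2=0, n=0),
        within_scatter=dict(rho=0, R=0, AR=0, f=0, Phi=0, r2=0, n=0),
        mass_within_sd=0.0)
    derived = fa.derive_table(fa.simulate_records(cfg).records)
    lw = np.log10(derived["weight"])
    expected = {"air_density_rho": -0.06, "mean_wing_velocity_U": 0.01,
                "wing_area_S": 1.01, "hover_force_coefficient": 0.03}
    for col, b in expected.items():
        slope = np.polyfit(lw, np.log10(derived[col]), 1)[0]
        assert slope == pytest.approx(b, abs=1e-9)


def test_derive_table_round_trips_csv(tmp_path, among_dataset):
    ds, derived = among_dataset
    path = tmp_path / "records.csv"
    ds.records.to_csv(path, index=False)
    again = fa.derive_table(__import__("pandas").read_csv(path))
    assert np.allclose(again["hover_force_coefficient"],
                       derived["hover_force_coefficient"])
    recs = fa.read_records(path)
    assert len(recs) == len(ds.records)
    assert recs[0].species == ds.records["species"].iloc[0]
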