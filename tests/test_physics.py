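"""Constitutive-function tests: Langevin saturation, permittivity, densities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from langevinpb import (
    CONSTANTS,
    ElectrolyteModel,
    SurfaceCharge,
    boltzmann_ion_densities,
    cavity_factor,
    debye_length,
    field_permittivity,
    free_charge_density,
    langevin,
    langevin_ratio,
    mean_orientation,
    onsager_permittivity,
    orientational_polarization,
    quadrature_mean_orientation,
)
from langevinpb.constants import (
    Cm_to_debye,
    debye_to_Cm,
    mol_per_L_to_per_m3,
    per_m3_to_mol_per_L,
)


class TestLangevin:
    @pytest.mark.parametrize(
        "u, expected",
        [
            (0.0, 0.0),
            # coth(1) - 1, 25-digit series evaluation
            (1.0, 0.3130352854993313036361612),
            (-1.0, -0.3130352854993313036361612),
        ],
    )
    def test_values(self, u, expected):
        assert langevin(u) == pytest.approx(expected, abs=1e-15)

    def test_saturates_monotonically(self):
        u = np.logspace(-2, 3, 200)
        L = langevin(u)
        assert np.all(np.diff(L) > 0)
        assert np.all(np.abs(L) < 1.0)
        assert langevin(1e4) == pytest.approx(1.0, abs=1e-3)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-50, 50))
    def test_odd_and_bounded(self, u):
        assert langevin(-u) == pytest.approx(-langevin(u), abs=1e-14)
        assert abs(langevin(u)) < 1.0

    def test_ratio_limit_and_evenness(self):
        assert langevin_ratio(0.0) == pytest.approx(1.0 / 3.0, abs=1e-16)
        assert langevin_ratio(1e-6) == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert langevin_ratio(-2.0) == langevin_ratio(2.0)
        assert langevin_ratio(2.0) == pytest.approx(langevin(2.0) / 2.0, rel=1e-14)

    def test_series_switch_is_smooth(self):
        # C1 continuity across the series/closed-form switch point
        from langevinpb.physics import _SERIES_SWITCH

        S = _SERIES_SWITCH
        for f in (langevin, langevin_ratio):
            below, above = S * (1 - 1e-9), S * (1 + 1e-9)
            # value jump bounded by the true slope (<= 1/3) over the straddle
            assert abs(f(above) - f(below)) < (above - below) / 3 + 1e-13
            # one-sided second-order derivatives taken at the switch itself
            h = 3e-4
            d_below = (3 * f(S) - 4 * f(S - h) + f(S - 2 * h)) / (2 * h)
            d_above = (-3 * f(S) + 4 * f(S + h) - f(S + 2 * h)) / (2 * h)
            assert abs(d_above - d_below) < 1e-8

    def test_rejects_nonfinite(self):
        for f in (langevin, langevin_ratio):
            with pytest.raises(ValueError):
                f(float("nan"))
            with pytest.raises(ValueError):
                f(float("inf"))


class TestCavityAndOnsager:
    def test_cavity_factor_values(self):
        assert cavity_factor(1.33) == pytest.approx(1.88445, rel=1e-12)
        assert cavity_factor(1.0) == pytest.approx(1.5, rel=1e-15)
        assert cavity_factor(1.34) > cavity_factor(1.33)
        with pytest.raises(ValueError):
            cavity_factor(0.9)

    def test_onsager_reference_value(self, model):
        # 78.5 to 3 significant figures for the reference water parameters
        assert round(onsager_permittivity(model), 1) == 78.5

    def test_onsager_no_dipole_is_optical(self):
        m = ElectrolyteModel(p0=0.0)
        assert onsager_permittivity(m) == pytest.approx(1.33**2, rel=1e-15)

    def test_onsager_linear_in_water_density(self, model):
        doubled = ElectrolyteModel(nw=2 * model.nw)
        n2 = model.n**2
        assert onsager_permittivity(doubled) - n2 == pytest.approx(
            2 * (onsager_permittivity(model) - n2), rel=1e-12
        )


class TestFieldPermittivity:
    def test_zero_field_is_onsager(self, model):
        assert field_permittivity(0.0, model) == pytest.approx(
            onsager_permittivity(model), rel=1e-14
        )

    def test_strictly_decreasing_and_bounded(self, model):
        E = np.logspace(3, 11, 100)
        eps = field_permittivity(E, model)
        assert np.all(np.diff(eps) <= 0) and eps[0] > eps[-1]
        strong = E >= 1e6
        assert np.all(np.diff(eps[strong]) < 0)
        assert np.all(eps > model.n**2)
        assert np.all(eps <= model.eps_bulk)

    def test_saturation_approaches_optical(self, model):
        val = field_permittivity(1e9, model)
        n2 = model.n**2
        assert n2 < val < model.eps_bulk
        assert val - n2 < model.eps_bulk - val  # closer to n^2 than to the bulk value

    def test_rejects_negative_field(self, model):
        with pytest.raises(ValueError):
            field_permittivity(-1.0, model)


class TestOrientation:
    def test_quadrature_agreement(self, model):
        # closed Langevin form vs adaptive quadrature of the Boltzmann average
        for E in np.logspace(3, 10, 20):
            assert mean_orientation(E, model) == pytest.approx(
                quadrature_mean_orientation(E, model), abs=1e-10
            )

    def test_limits(self, model):
        assert mean_orientation(0.0, model) == 0.0
        assert mean_orientation(1e12, model) == pytest.approx(-1.0, abs=1e-3)
        E = np.logspace(3, 10, 50)
        mc = mean_orientation(E, model)
        assert np.all(mc <= 0.0) and np.all(mc >= -1.0)


class TestPolarization:
    def test_factorization_identity(self, model):
        # eps0*(eps_r(E) - n^2)*E == |P(E)|: the product-rule factorization
        # of the polarization divergence encoded as an identity
        for E in np.logspace(2, 10, 40):
            lhs = CONSTANTS.eps0 * (field_permittivity(E, model) - model.n**2) * E
            assert lhs == pytest.approx(
                abs(orientational_polarization(E, model)), rel=1e-12
            )

    def test_zero_and_saturation(self, model):
        assert orientational_polarization(0.0, model) == 0.0
        sat = model.nw * model.p0 * (2 + model.n**2) / 3.0
        assert abs(orientational_polarization(1e15, model)) == pytest.approx(sat, rel=1e-6)


class TestIonDensities:
    def test_bulk_and_unit_potential(self, model):
        np_, nm_ = boltzmann_ion_densities(0.0, model)
        assert np_ == model.n0 and nm_ == model.n0
        kTe = 1.0 / (model.beta * CONSTANTS.e0)
        np_, nm_ = boltzmann_ion_densities(-kTe, model)
        assert np_ == pytest.approx(model.n0 * math.e, rel=1e-12)
        assert nm_ == pytest.approx(model.n0 / math.e, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-0.5, 0.5))
    def test_boltzmann_reciprocity(self, model, phi):
        np_, nm_ = boltzmann_ion_densities(phi, model)
        assert np_ * nm_ == pytest.approx(model.n0**2, rel=1e-12)

    def test_free_charge_consistency(self, model):
        phi = -0.05
        np_, nm_ = boltzmann_ion_densities(phi, model)
        assert free_charge_density(phi, model) == pytest.approx(
            CONSTANTS.e0 * (np_ - nm_), rel=1e-12
        )
        assert free_charge_density(-0.05, model) > 0  # counterion excess
        assert free_charge_density(0.0, model) == 0.0

    def test_overflow_guard(self, model):
        with pytest.raises(ValueError):
            boltzmann_ion_densities(50.0, model)
        with pytest.raises(ValueError):
            free_charge_density(-50.0, model)


class TestDebyeLength:
    def test_reference_value(self, model):
        # closed-form evaluation for 0.15 mol/L, eps 78.5, 298 K
        assert debye_length(model) == pytest.approx(7.85281278475e-10, rel=1e-9)

    def test_scalings(self, model):
        quad_n0 = ElectrolyteModel(n0=4 * model.n0)
        assert debye_length(quad_n0, eps_r=model.eps_bulk) == pytest.approx(
            debye_length(model) / 2.0, rel=1e-12
        )
        assert debye_length(model, eps_r=4 * model.eps_bulk) == pytest.approx(
            2.0 * debye_length(model), rel=1e-12
        )


class TestUnitsAndTypes:
    @settings(derandomize=True, max_examples=100)
    @given(st.floats(1e-6, 1e3))
    def test_unit_round_trips(self, value):
        assert per_m3_to_mol_per_L(mol_per_L_to_per_m3(value)) == pytest.approx(
            value, rel=1e-14
        )
        assert Cm_to_debye(debye_to_Cm(value)) == pytest.approx(value, rel=1e-14)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            ElectrolyteModel(n0=-1.0)
        with pytest.raises(ValueError):
            ElectrolyteModel(T=0.0)
        with pytest.raises(ValueError):
            ElectrolyteModel(n=0.5)

    def test_surface_charge_validity_warning(self):
        with pytest.warns(UserWarning, match="mean-field"):
            SurfaceCharge(-0.4)
        with pytest.raises(ValueError):
            SurfaceCharge(float("nan"))

    def test_model_gamma_matches_cavity_factor(self, model):
        assert model.gamma == cavity_factor(model.n)
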