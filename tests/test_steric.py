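"""Langevin-Wicke-Eigen steric model: lattice closure, saturation, limits."""

import numpy as np
import pytest

from langevinpb import (
    ElectrolyteModel,
    StericParams,
    SurfaceCharge,
    f_function,
    field_permittivity,
    langevin,
    onsager_permittivity,
    solve_planar,
    solve_steric_planar,
    steric_denominator,
    steric_permittivity,
)


@pytest.fixture(scope="module")
def steric():
    return StericParams()


class TestFFunction:
    def test_values(self):
        assert f_function(0.0) == 0.0
        # L(1)*sinh(1) = cosh(1) - sinh(1) = exp(-1)
        assert f_function(1.0) == pytest.approx(np.exp(-1.0), rel=1e-12)
        assert f_function(2.0) == pytest.approx(
            langevin(2.0) * np.sinh(2.0) / 2.0, rel=1e-12
        )

    def test_small_argument_slope(self):
        for u in (1e-6, 1e-4, 1e-3):
            assert f_function(u) == pytest.approx(u / 3.0, rel=1e-5)

    def test_overflow_guard(self):
        with pytest.raises(OverflowError):
            f_function(1e4)


class TestStericParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            StericParams(alpha_plus=0.5)
        with pytest.raises(ValueError):
            StericParams(ns=-1.0)

    def test_water_closure(self, model, steric):
        n0w = steric.bulk_water_density(model)
        assert n0w == pytest.approx(steric.ns - 2 * model.n0, rel=1e-14)
        # too much salt for the lattice
        salty = ElectrolyteModel(n0=steric.ns)
        with pytest.raises(ValueError):
            steric.bulk_water_density(salty)


class TestStericDenominator:
    def test_bulk_normalization(self, model, steric):
        # DA(0, 0) = (alpha+ + alpha-)*n0 + n0w = ns: bulk densities are n0
        assert steric_denominator(0.0, 0.0, model, steric) == pytest.approx(
            steric.ns, rel=1e-14
        )
        asym = StericParams(alpha_plus=4.0, alpha_minus=2.0)
        expected = 6.0 * model.n0 + asym.bulk_water_density(model)
        assert steric_denominator(0.0, 0.0, model, asym) == pytest.approx(
            expected, rel=1e-14
        )

    def test_counterion_dominated_limit(self, model, steric):
        kTe = 1.0 / (model.beta * model.constants.e0)
        phi = -20 * kTe
        DA = steric_denominator(phi, 0.0, model, steric)
        assert DA == pytest.approx(
            steric.alpha_plus * model.n0 * np.exp(20.0), rel=1e-6
        )

    def test_ion_density_bound_pointwise(self, model):
        # n+ = ns*n0*exp(-psi)/DA <= ns/alpha+ for any potential and field
        st = StericParams(alpha_plus=3.0, alpha_minus=1.0)
        kTe = 1.0 / (model.beta * model.constants.e0)
        for phi in np.linspace(-15, 0, 16) * kTe:
            for E in (0.0, 1e8, 1e9):
                DA = steric_denominator(phi, E, model, st)
                n_plus = st.ns * model.n0 * np.exp(-model.beta * model.constants.e0 * phi) / DA
                assert n_plus <= st.ns / st.alpha_plus * (1 + 1e-12)


class TestStericPermittivity:
    def test_bulk_limit_is_onsager_with_water_density(self, model, steric):
        # E -> 0, phi = 0: Onsager formula with n0w in place of nw
        n0w = steric.bulk_water_density(model)
        expected = onsager_permittivity(ElectrolyteModel(nw=n0w))
        assert steric_permittivity(0.0, 0.0, model, steric) == pytest.approx(
            expected, rel=1e-12
        )
        assert steric_permittivity(0.0, 0.0, model, steric) < model.eps_bulk

    def test_counterion_crowding_depletes_water(self, model, steric):
        kTe = 1.0 / (model.beta * model.constants.e0)
        E = 1e8
        eps_bulk_phi = steric_permittivity(0.0, E, model, steric)
        eps_crowded = steric_permittivity(-8 * kTe, E, model, steric)
        assert eps_crowded < eps_bulk_phi

    def test_dilute_lattice_recovers_field_permittivity(self, model):
        # scaling up ns at fixed salt: ion occupancy -> 0 and the steric
        # permittivity approaches the point-ion Langevin form evaluated with
        # the matching water density
        E = 1e8
        for mult in (1.0, 10.0, 100.0):
            st = StericParams(ns=mult * StericParams().ns)
            matched = ElectrolyteModel(nw=st.ns)
            rel = abs(
                steric_permittivity(0.0, E, model, st) - field_permittivity(E, matched)
            ) / field_permittivity(E, matched)
            assert rel < 0.02 / mult


class TestStericSolve:
    def test_zero_sigma_trivial(self, model, steric):
        prof = solve_steric_planar(model, SurfaceCharge(0.0), steric)
        assert prof.converged and np.all(prof.phi == 0.0)

    def test_weak_field_agrees_with_lpb(self, model, steric):
        sig = SurfaceCharge(-0.01)
        st = solve_steric_planar(model, sig, steric)
        pb = solve_planar(model, sig)
        phi_pb = np.interp(st.coord, pb.coord, pb.phi)
        assert np.max(np.abs(st.phi - phi_pb)) / abs(pb.phi_wall) < 0.01

    def test_counterion_saturation_at_strong_charge(self, model, steric):
        prof = solve_steric_planar(model, SurfaceCharge(-0.25), steric)
        assert prof.converged
        assert np.all(prof.n_plus <= steric.ns / steric.alpha_plus * (1 + 1e-10))
        # larger hydrated cation -> lower ceiling, still respected
        big = StericParams(alpha_plus=4.0)
        prof4 = solve_steric_planar(model, SurfaceCharge(-0.25), big)
        assert np.all(prof4.n_plus <= big.ns / big.alpha_plus * (1 + 1e-10))
        assert prof4.n_plus[0] < prof.n_plus[0]

    def test_point_like_limit_recovers_lpb(self, model):
        # ns -> infinity with matched LPB water density: profiles converge
        sig = SurfaceCharge(-0.25)
        diffs = []
        for mult in (1.0, 10.0, 100.0):
            st = StericParams(ns=mult * StericParams().ns)
            prof = solve_steric_planar(model, sig, st)
            matched = ElectrolyteModel(nw=st.ns)
            pb = solve_planar(matched, sig)
            phi_pb = np.interp(prof.coord, pb.coord, pb.phi, right=0.0)
            diffs.append(np.max(np.abs(prof.phi - phi_pb)) / abs(pb.phi_wall))
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 1e-3

    def test_more_negative_wall_than_lpb(self, model, steric, planar_ref):
        # steric exclusion thins the counterion cloud, deepening the wall
        # potential at the same surface charge
        prof = solve_steric_planar(model, SurfaceCharge(-0.25), steric)
        assert prof.phi_wall < planar_ref.phi_wall

    def test_bulk_source_slope_matches_lpb(self, model, steric):
        # d(rhs)/d(psi) at the bulk state equals the non-steric value since
        # DA(0,0) = ns
        from langevinpb.steric import StericClosure

        closure = StericClosure(model, steric)
        eps_ = 1e-6
        slope = closure.rhs(np.array([eps_]), np.array([0.0]))[0] / eps_
        assert slope == pytest.approx(1.0, rel=1e-6)
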