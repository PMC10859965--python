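"""Measurable properties: pressure, density roots, enthalpies, activities."""

import numpy as np
import pytest

import saftgmie as sg
from saftgmie.eos import R
from saftgmie.properties import (
    activity_coefficient,
    chemical_potential,
    density,
    density_roots,
    excess_enthalpy,
    ln_phi,
    pressure,
    property_set,
    residual_enthalpy,
    saturation_pressure,
    vaporization_enthalpy,
)


class TestPressure:
    def test_ideal_gas_law(self, ideal_gas_eos):
        T, V, n = 250.0, 3e-3, np.array([2.0])
        assert pressure(ideal_gas_eos, T, V, n) == pytest.approx(2.0 * R * T / V, rel=1e-10)

    def test_mechanical_stability_on_liquid_branch(self, gbl_eos):
        T, P = 300.0, 1e5
        rho = density(gbl_eos, T, P, [1.0], phase="liquid")
        ps = [pressure(gbl_eos, T, 1.0 / r, np.array([1.0])) for r in (0.99 * rho, rho, 1.01 * rho)]
        assert ps[0] < ps[1] < ps[2]


class TestDensity:
    def test_ideal_fluid(self, ideal_gas_eos):
        rho = density(ideal_gas_eos, 300.0, 1e5, [1.0])
        assert rho == pytest.approx(1e5 / (R * 300.0), rel=1e-8)

    def test_vapor_root_near_ideal_at_low_pressure(self, gbl_eos):
        T, P = 400.0, 10.0
        rho = density(gbl_eos, T, P, [1.0], phase="vapor")
        assert rho == pytest.approx(P / (R * T), rel=1e-3)

    def test_liquid_density_decreases_with_temperature(self, gbl_eos):
        rhos = [density(gbl_eos, T, 1e5, [1.0], phase="liquid") for T in (290, 330, 370, 400)]
        assert all(a > b for a, b in zip(rhos, rhos[1:]))

    def test_all_roots_reported_in_two_phase_region(self, gbl_eos):
        P, _, _ = saturation_pressure(gbl_eos, 400.0)
        roots = density_roots(gbl_eos, 400.0, P, [1.0])
        assert len(roots) == 2  # stable vapor and liquid branches

    def test_lowest_gibbs_root_selected(self, gbl_eos):
        T = 400.0
        Psat, rho_l, rho_v = saturation_pressure(gbl_eos, T)
        assert density(gbl_eos, T, 2.0 * Psat, [1.0]) == pytest.approx(rho_l, rel=1e-2)
        assert density(gbl_eos, T, 0.5 * Psat, [1.0]) == pytest.approx(
            density(gbl_eos, T, 0.5 * Psat, [1.0], phase="vapor"), rel=1e-10
        )


class TestChemicalPotential:
    def test_pure_equals_molar_gibbs(self, gbl_eos):
        T, P = 330.0, 1e5
        rho = density(gbl_eos, T, P, [1.0], phase="liquid")
        V = 1.0 / rho
        mu = chemical_potential(gbl_eos, T, V, np.array([1.0]))[0]
        b = gbl_eos.helmholtz(sg.MixtureState(T=T, V=V, n=np.array([1.0])))
        g = b.total + pressure(gbl_eos, T, V, np.array([1.0])) * V
        assert mu == pytest.approx(g, rel=1e-8)

    def test_symmetry_of_identical_components(self):
        from saftgmie.groups import GroupLibrary, MieGroup
        from saftgmie.eos import GammaMieEoS

        lib = GroupLibrary([MieGroup("A", 1, 1.0, 4.0, 12.0, 6.0, 250.0)], [], [])
        lib.build_molecule("m1", {"A": 1})
        lib.build_molecule("m2", {"A": 1})
        eos = GammaMieEoS(lib, ["m1", "m2"])
        mu = chemical_potential(eos, 300.0, 2e-4, np.array([0.5, 0.5]))
        assert mu[0] == pytest.approx(mu[1], rel=1e-12)

    def test_gibbs_duhem_along_composition(self, gbl_water_eos):
        """Σ x_i dμ_i = 0 at fixed (T, P)."""
        T, P = 340.0, 1e5
        h = 1e-4

        def mus(x1):
            x = np.array([x1, 1.0 - x1])
            rho = density(gbl_water_eos, T, P, x, phase="liquid")
            return chemical_potential(gbl_water_eos, T, 1.0 / rho, x)

        x1 = 0.4
        dmu = (mus(x1 + h) - mus(x1 - h)) / (2 * h)
        resid = 0.4 * dmu[0] + 0.6 * dmu[1]
        assert abs(resid) / (R * T) < 1e-4 * max(abs(dmu[0]), abs(dmu[1])) / (R * T) + 1e-6


class TestSaturationAndVaporization:
    def test_clausius_clapeyron_consistency(self, gbl_eos):
        """dP/dT along saturation equals Δh_vap / (T Δv)."""
        T = 380.0
        dT = 0.05
        P1, rl1, rv1 = saturation_pressure(gbl_eos, T - dT)
        P2, rl2, rv2 = saturation_pressure(gbl_eos, T + dT)
        dPdT = (P2 - P1) / (2 * dT)
        P, rl, rv = saturation_pressure(gbl_eos, T)
        dv = 1.0 / rv - 1.0 / rl
        dh = vaporization_enthalpy(gbl_eos, T)
        assert dPdT == pytest.approx(dh / (T * dv), rel=1e-4)

    def test_vaporization_enthalpy_vanishes_toward_critical(self, lj_eos):
        dh_low = vaporization_enthalpy(lj_eos, 100.0)
        dh_high = vaporization_enthalpy(lj_eos, 128.0)   # model Tc* ≈ 1.31
        assert 0 < dh_high < 0.5 * dh_low

    def test_ring_size_ordering_of_vaporization_enthalpy(self, library):
        """Δh_vap increases with lactone ring size at fixed T."""
        vals = []
        for name in ("oxolan-2-one", "oxan-2-one", "oxepan-2-one"):
            eos = sg.GammaMieEoS(library, [name])
            vals.append(vaporization_enthalpy(eos, 350.0))
        assert vals[0] < vals[1] < vals[2]

    def test_side_chain_density_ordering(self, library):
        """Liquid density decreases with the 5-alkyl side-chain length."""
        rhos = []
        for name in ("5-methyloxolan-2-one", "5-propyloxolan-2-one", "5-hexyloxolan-2-one"):
            eos = sg.GammaMieEoS(library, [name])
            mw = eos.molar_masses()[0]
            rhos.append(density(eos, 320.0, 1e5, [1.0], phase="liquid") * mw)
        assert rhos[0] > rhos[1] > rhos[2]


class TestExcessEnthalpy:
    def test_endpoints_vanish(self, gbl_water_eos):
        assert excess_enthalpy(gbl_water_eos, 298.15, 1e5, [1.0, 0.0]) == pytest.approx(0.0, abs=1e-8)
        assert excess_enthalpy(gbl_water_eos, 298.15, 1e5, [0.0, 1.0]) == pytest.approx(0.0, abs=1e-8)

    def test_identical_components_have_zero_excess(self):
        from saftgmie.groups import GroupLibrary, MieGroup
        from saftgmie.eos import GammaMieEoS

        lib = GroupLibrary([MieGroup("A", 1, 1.0, 4.0, 12.0, 6.0, 250.0)], [], [])
        lib.build_molecule("m1", {"A": 1})
        lib.build_molecule("m2", {"A": 1})
        eos = GammaMieEoS(lib, ["m1", "m2"])
        assert excess_enthalpy(eos, 200.0, 1e6, [0.3, 0.7]) == pytest.approx(0.0, abs=1e-6)

    def test_gbl_methanol_magnitude(self, library):
        """Calculated maximum for oxolan-2-one + methanol is of order 1 kJ/mol."""
        eos = sg.GammaMieEoS(library, ["oxolan-2-one", "methanol"])
        h = max(
            excess_enthalpy(eos, 298.15, 101325.0, [u, 1 - u]) for u in (0.3, 0.5, 0.7)
        )
        assert 100.0 < h < 3000.0


class TestActivityCoefficients:
    def test_pure_limit(self, gbl_water_eos):
        g = activity_coefficient(gbl_water_eos, 340.0, 1e5, [1.0, 0.0])
        assert g[0] == pytest.approx(1.0, abs=1e-8)

    def test_identical_components_are_ideal(self):
        from saftgmie.groups import GroupLibrary, MieGroup
        from saftgmie.eos import GammaMieEoS

        lib = GroupLibrary([MieGroup("A", 1, 1.0, 4.0, 12.0, 6.0, 250.0)], [], [])
        lib.build_molecule("m1", {"A": 1})
        lib.build_molecule("m2", {"A": 1})
        eos = GammaMieEoS(lib, ["m1", "m2"])
        for u in (0.2, 0.5, 0.8):
            g = activity_coefficient(eos, 200.0, 1e6, [u, 1 - u])
            assert np.allclose(g, 1.0, atol=1e-8)

    def test_gibbs_duhem_for_ln_gamma(self, toy_binary):
        T, P = 210.0, 1e6
        h = 1e-4

        def lng(x1):
            return np.log(activity_coefficient(toy_binary, T, P, [x1, 1 - x1]))

        x1 = 0.45
        d = (lng(x1 + h) - lng(x1 - h)) / (2 * h)
        assert abs(x1 * d[0] + (1 - x1) * d[1]) < 1e-6 + 1e-3 * max(abs(d))

    def test_property_set_consistency(self, gbl_eos):
        ps = property_set(gbl_eos, 320.0, 1e5, [1.0])
        assert ps.rho_mass == pytest.approx(ps.rho_molar * gbl_eos.molar_masses()[0])
        assert ps.gamma[0] == pytest.approx(1.0, abs=1e-8)
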