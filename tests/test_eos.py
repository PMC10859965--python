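"""Free-energy surface: prefactor, potential, limits, association, derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import saftgmie as sg
from saftgmie.eos import NA, R, GammaMieEoS, MixtureState, kB


class TestMiePrefactor:
    def test_lennard_jones_limit(self):
        assert sg.mie_prefactor(12.0, 6.0) == pytest.approx(4.0, rel=1e-14)

    def test_closed_form(self):
        lr, la = 11.855, 6.0
        expected = (lr / (lr - la)) * (lr / la) ** (la / (lr - la))
        assert sg.mie_prefactor(lr, la) == pytest.approx(expected, rel=1e-14)

    def test_degenerate_exponents_rejected(self):
        with pytest.raises(ValueError):
            sg.mie_prefactor(6.0, 6.0)
        with pytest.raises(ValueError):
            sg.mie_prefactor(5.0, 6.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        lr=st.floats(min_value=7.0, max_value=40.0),
        la=st.floats(min_value=4.0, max_value=6.9),
    )
    def test_minimum_is_minus_epsilon(self, lr, la):
        sigma, eps = 3.5e-10, 1.0e-21
        r_min = sigma * (lr / la) ** (1.0 / (lr - la))
        assert sg.mie_pair_potential(r_min, sigma, eps, lr, la) == pytest.approx(-eps, rel=1e-12)


class TestMiePotential:
    def test_zero_at_contact(self):
        assert sg.mie_pair_potential(3.0e-10, 3.0e-10, 1e-21, 12, 6) == pytest.approx(0.0, abs=1e-40)

    def test_decays_to_zero_from_below(self):
        v = sg.mie_pair_potential(3.0e-9, 3.0e-10, 1e-21, 12, 6)
        assert -1e-24 < v < 0.0

    def test_rejects_nonpositive_r(self):
        with pytest.raises(ValueError):
            sg.mie_pair_potential(0.0, 3e-10, 1e-21, 12, 6)


class TestLimits:
    def test_ideal_gas_pressure(self, ideal_gas_eos):
        T, V, n = 300.0, 1e-3, np.array([1.0])
        assert sg.pressure(ideal_gas_eos, T, V, n) == pytest.approx(R * T / V, rel=1e-10)

    def test_noninteracting_monomer_and_association_vanish(self, ideal_gas_eos):
        _, a_mono, a_chain, a_assoc = ideal_gas_eos.a_residual(
            300.0, 1e-3, np.array([1.0]), breakdown=True
        )
        assert a_mono == pytest.approx(0.0, abs=1e-14)
        assert a_chain == pytest.approx(0.0, abs=1e-14)
        assert a_assoc == 0.0

    def test_indistinguishable_components(self):
        """Two components with identical decompositions mix ideally."""
        from saftgmie.groups import GroupLibrary, MieGroup

        lib = GroupLibrary([MieGroup("A", 1, 1.0, 4.0, 12.0, 6.0, 250.0)], [], [])
        lib.build_molecule("m1", {"A": 1})
        lib.build_molecule("m2", {"A": 1})
        pure = GammaMieEoS(lib, ["m1"])
        mix = GammaMieEoS(lib, ["m1", "m2"])
        T, V = 300.0, 2.0e-4
        a_pure = pure.a_residual(T, V, np.array([1.0]))
        a_mix = mix.a_residual(T, V, np.array([0.5, 0.5]))
        assert a_mix == pytest.approx(a_pure, rel=1e-12)

    @pytest.mark.parametrize("c", [2.0, 10.0])
    def test_extensivity(self, gbl_water_eos, c):
        T, V = 320.0, 1.2e-4
        n = np.array([0.4, 0.6])
        A1 = gbl_water_eos.a_residual(T, V, n)
        A2 = gbl_water_eos.a_residual(T, c * V, c * n)
        assert A2 == pytest.approx(c * A1, rel=1e-10)

    def test_close_packing_rejected(self, gbl_eos):
        with pytest.raises(ValueError, match="packing"):
            gbl_eos.a_residual(300.0, 1e-8, np.array([1.0]))


class TestSiteFractions:
    def test_zero_density_limit(self, gbl_water_eos):
        X, _, _ = gbl_water_eos.solve_site_fractions(300.0, 1e6, np.array([0.5, 0.5]))
        assert np.allclose(X, 1.0, atol=1e-6)

    def test_zero_association_energy(self, toy_binary):
        # no sites at all: all fractions returned as 1
        X, sites, s = toy_binary.solve_site_fractions(300.0, 1e-4, np.array([0.5, 0.5]))
        assert np.all(X == 1.0)

    def test_two_site_closed_form(self, toy_assoc):
        """Symmetric donor/acceptor model vs X = (−1+√(1+4ρΔ))/(2ρΔ)."""
        T, V = 280.0, 6.0e-5
        n = np.array([1.0, 0.0])
        X, sites, s = toy_assoc.solve_site_fractions(T, V, n)
        rho = NA / V
        # recompute Δ exactly as the model defines it
        rho_s = rho * (n / n.sum() @ toy_assoc.seg)
        xs = (n / n.sum() @ toy_assoc._seg_weight) / (n / n.sum() @ toy_assoc.seg)
        rho_star = rho_s * np.sum((xs[:, None] * xs[None, :]) * toy_assoc.sigma_kl**3)
        delta = np.real(toy_assoc._delta_matrix(T, rho_star))[0, 1]
        rd = rho * delta
        x_exact = (-1.0 + np.sqrt(1.0 + 4.0 * rd)) / (2.0 * rd)
        assert X[0] == pytest.approx(x_exact, abs=1e-10)
        assert X[1] == pytest.approx(x_exact, abs=1e-10)

    def test_bounds(self, gbl_water_eos):
        X, _, _ = gbl_water_eos.solve_site_fractions(298.15, 4.0e-5, np.array([0.5, 0.5]))
        assert np.all(X > 0.0) and np.all(X <= 1.0)

    def test_association_free_energy_nonpositive_and_monotone(self):
        from saftgmie.fixtures import toy_associating_binary

        T, V, n = 280.0, 6.0e-5, np.array([1.0, 0.0])
        prev = 0.0
        for eps_hb in (400.0, 1000.0, 1800.0, 2400.0):
            eos = toy_associating_binary(eps_hb=eps_hb)
            _, _, _, a_assoc = eos.a_residual(T, V, n, breakdown=True)
            assert a_assoc <= 1e-14
            assert a_assoc <= prev + 1e-12
            prev = a_assoc


class TestDerivatives:
    """Complex-step first derivatives vs central finite differences."""

    def test_pressure_matches_finite_difference(self, gbl_water_eos):
        T, V, n = 320.0, 1.1e-4, np.array([0.55, 0.45])
        P = sg.pressure(gbl_water_eos, T, V, n)
        h = V * 1e-6
        dA = (
            np.real(gbl_water_eos.a_residual(T, V + h, n))
            - np.real(gbl_water_eos.a_residual(T, V - h, n))
        ) / (2 * h)
        P_fd = n.sum() * R * T / V - dA
        assert P == pytest.approx(P_fd, rel=1e-7)

    def test_chemical_potential_matches_finite_difference(self, gbl_water_eos):
        T, V, n = 320.0, 1.1e-4, np.array([0.55, 0.45])
        mu = sg.residual_chemical_potential(gbl_water_eos, T, V, n)
        for i in range(2):
            h = 1e-6
            np_ = n.copy(); np_[i] += h
            nm_ = n.copy(); nm_[i] -= h
            fd = (
                np.real(gbl_water_eos.a_residual(T, V, np_))
                - np.real(gbl_water_eos.a_residual(T, V, nm_))
            ) / (2 * h)
            assert mu[i] == pytest.approx(fd, rel=1e-7)

    def test_entropy_derivative_matches_finite_difference(self, gbl_eos):
        T, V, n = 350.0, 9.0e-5, np.array([1.0])
        h = T * 1e-50
        dA_cs = float(np.imag(gbl_eos.a_residual(T + 1j * h, V, n)) / h)
        ht = T * 1e-6
        dA_fd = (
            np.real(gbl_eos.a_residual(T + ht, V, n))
            - np.real(gbl_eos.a_residual(T - ht, V, n))
        ) / (2 * ht)
        assert dA_cs == pytest.approx(dA_fd, rel=1e-7)


class TestBreakdown:
    def test_helmholtz_total_is_sum_of_parts(self, gbl_water_eos):
        st_ = MixtureState(T=320.0, V=1.1e-4, n=np.array([0.5, 0.5]))
        b = gbl_water_eos.helmholtz(st_)
        total = st_.n_total * R * st_.T * (b.a_ideal + b.a_monomer + b.a_chain + b.a_association)
        assert b.total == pytest.approx(total, rel=1e-14)
        assert b.a_association < 0.0  # water/lactone hydrogen bonding is active

    def test_site_fraction_map_keys(self, gbl_water_eos):
        st_ = MixtureState(T=320.0, V=1.1e-4, n=np.array([0.5, 0.5]))
        m = gbl_water_eos.site_fraction_map(st_)
        assert ("oxolan-2-one", "cCOO", "e1") in m
        assert ("water", "H2O", "H") in m
        assert all(0 < v <= 1 for v in m.values())
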