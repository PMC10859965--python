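"""Phase-equilibrium solvers: VLE, azeotropes, LLE, SLE, eutectics."""

import numpy as np
import pytest

import saftgmie as sg
from saftgmie.eos import R, GammaMieEoS
from saftgmie.equilibria import (
    bubble_point,
    eutectic,
    find_azeotrope,
    lle,
    liquidus_roots,
    sle_ideal,
    sle_solubility,
)
from saftgmie.fixtures import toy_nonassociating_binary
from saftgmie.groups import FusionData, GroupLibrary, MieGroup
from saftgmie.properties import saturation_pressure


@pytest.fixture(scope="module")
def identical_binary():
    lib = GroupLibrary([MieGroup("A", 1, 1.0, 4.0, 12.0, 6.0, 250.0)], [], [])
    lib.build_molecule("m1", {"A": 1})
    lib.build_molecule("m2", {"A": 1})
    return GammaMieEoS(lib, ["m1", "m2"])


@pytest.fixture(scope="module")
def demixing_binary():
    """Toy binary with a weakened cross interaction: opens an LLE gap."""
    return toy_nonassociating_binary(epsilon_12=190.0)


class TestBubbleDew:
    def test_pure_limit_recovers_saturation_pressure(self, toy_binary):
        T = 220.0
        res = bubble_point(toy_binary, np.array([1.0, 0.0]), T=T)
        P_sat, _, _ = saturation_pressure(toy_binary.pure(0), T)
        assert res.P == pytest.approx(P_sat, rel=1e-6)

    def test_identical_components_flat_txy(self, identical_binary):
        P = 1e5
        rs = [bubble_point(identical_binary, np.array([u, 1 - u]), P=P) for u in (0.2, 0.5, 0.8)]
        Ts = [r.T for r in rs]
        assert max(Ts) - min(Ts) < 1e-4
        for r, u in zip(rs, (0.2, 0.5, 0.8)):
            assert r.phases[1][1][0] == pytest.approx(u, abs=1e-6)

    def test_mu_equality_at_convergence(self, toy_binary):
        res = bubble_point(toy_binary, np.array([0.4, 0.6]), P=2e5)
        assert res.converged
        assert res.residuals["mu"] < 1e-8

    def test_bubble_below_dew_temperature(self, toy_binary):
        from saftgmie.equilibria import dew_point

        P = 2e5
        for u in (0.3, 0.6):
            z = np.array([u, 1 - u])
            tb = bubble_point(toy_binary, z, P=P).T
            td = dew_point(toy_binary, z, P=P).T
            assert tb <= td + 1e-6


class TestAzeotrope:
    @pytest.fixture(scope="class")
    def azeotropic_binary(self):
        """Similar volatilities plus a weak cross interaction: positive
        deviations strong enough for a minimum-boiling azeotrope."""
        lib = GroupLibrary(
            [
                MieGroup("A", 1, 1.0, 4.0, 12.0, 6.0, 250.0),
                MieGroup("B", 1, 1.0, 4.1, 12.0, 6.0, 262.0),
            ],
            [],
            [],
        )
        from saftgmie.groups import UnlikeDispersionEntry

        lib2 = GroupLibrary(
            list(lib.groups.values()),
            [UnlikeDispersionEntry(("A", "B"), 240.0, None)],
            [],
        )
        lib2.build_molecule("mA", {"A": 1})
        lib2.build_molecule("mB", {"B": 1})
        return GammaMieEoS(lib2, ["mA", "mB"])

    def test_azeotrope_found_and_is_temperature_extremum(self, azeotropic_binary):
        P = 1e5
        pts = find_azeotrope(azeotropic_binary, P)
        assert len(pts) == 1
        az = pts[0]
        assert 0.0 < az.x_az < 1.0
        # two detection routes: y = x coincides with the isobaric T extremum
        for dx in (-0.05, 0.05):
            res = bubble_point(
                azeotropic_binary, np.array([az.x_az + dx, 1 - az.x_az - dx]), P=P
            )
            assert res.T > az.T_az - 1e-4  # minimum-boiling

    def test_identical_components_degenerate(self, identical_binary):
        # y = x everywhere: no isolated azeotrope is reported
        pts = find_azeotrope(identical_binary, 1e5, x_grid=np.linspace(0.2, 0.8, 5))
        assert pts == []


class TestLLE:
    def test_identical_components_fully_miscible(self, identical_binary):
        assert lle(identical_binary, 200.0, 1e6) is None

    def test_demixing_detected(self, demixing_binary):
        res = lle(demixing_binary, 200.0, 1e6)
        assert res is not None and res.converged
        assert res.residuals["mu"] < 1e-8
        x1a = res.phases[0][1][0]
        x1b = res.phases[1][1][0]
        assert x1a < 0.35 and x1b > 0.65

    def test_relabeling_symmetry(self, demixing_binary):
        """Swapping component labels mirrors the phase compositions."""
        res = lle(demixing_binary, 200.0, 1e6)
        lib = demixing_binary.library
        swapped = GammaMieEoS(lib, ["toyB", "toyA"])
        res_sw = lle(swapped, 200.0, 1e6)
        a = sorted([res.phases[0][1][0], res.phases[1][1][0]])
        b = sorted([1.0 - res_sw.phases[0][1][0], 1.0 - res_sw.phases[1][1][0]])
        assert a[0] == pytest.approx(b[0], abs=1e-6)
        assert a[1] == pytest.approx(b[1], abs=1e-6)

    def test_raising_cross_energy_shrinks_gap(self):
        gaps = []
        for e12 in (190.0, 215.0):
            eos = toy_nonassociating_binary(epsilon_12=e12)
            res = lle(eos, 200.0, 1e6)
            assert res is not None
            gaps.append(res.phases[1][1][0] - res.phases[0][1][0])
        assert gaps[1] < gaps[0]


class TestSLE:
    def test_pure_melting_limit(self, library):
        eos = sg.GammaMieEoS(library, ["oxepan-2-one", "methanol"])
        f = library.fusion["oxepan-2-one"]
        pt = sle_solubility(eos, 0, f, f.T_fus, 101325.0)
        assert pt.x_sat == 1.0

    def test_ideal_mode_closed_form(self, library):
        f = library.fusion["oxepan-2-one"]
        T = 250.0
        expected = np.exp(-(13.82e3 / R) * (1.0 / T - 1.0 / 272.13))
        assert sle_ideal(f, T) == pytest.approx(expected, rel=1e-12)
        eos = sg.GammaMieEoS(library, ["oxepan-2-one", "methanol"])
        pt = sle_solubility(eos, 0, f, T, 101325.0, ideal=True)
        assert pt.x_sat == pytest.approx(expected, rel=1e-12)

    def test_solubility_decreases_on_cooling(self, library):
        eos = sg.GammaMieEoS(library, ["oxepan-2-one", "methanol"])
        f = library.fusion["oxepan-2-one"]
        xs = [sle_solubility(eos, 0, f, T, 101325.0).x_sat for T in (265.0, 255.0, 245.0)]
        assert xs[0] > xs[1] > xs[2]

    def test_fixed_point_satisfies_equilibrium(self, library):
        from saftgmie.properties import activity_coefficient

        eos = sg.GammaMieEoS(library, ["oxepan-2-one", "methanol"])
        f = library.fusion["oxepan-2-one"]
        T = 255.0
        pt = sle_solubility(eos, 0, f, T, 101325.0)
        gam = activity_coefficient(eos, T, 101325.0, [pt.x_sat, 1 - pt.x_sat])[0]
        lhs = np.log(pt.x_sat * gam)
        rhs = -(f.delta_h_fus / R) * (1.0 / T - 1.0 / f.T_fus)
        assert lhs == pytest.approx(rhs, abs=1e-8)


class TestEutectic:
    def test_symmetric_binary_at_half(self, identical_binary):
        f = FusionData(molecule="m", T_fus=260.0, delta_h_fus=12e3)
        sols = eutectic(identical_binary, f, f, 1e6, T_min=200.0)
        assert len(sols) >= 1
        x1, T = sols[0]
        assert x1 == pytest.approx(0.5, abs=1e-4)
        # γ ≡ 1 here, so the eutectic satisfies 2 x_ideal(T) = 1
        assert sle_ideal(f, T) == pytest.approx(0.5, abs=1e-4)

    def test_branches_interfering_with_lle_have_multiple_roots(self, library):
        eos = sg.GammaMieEoS(library, ["oxepan-2-one", "cyclohexane"])
        roots = liquidus_roots(eos, 1, library.fusion["cyclohexane"], 266.0, 101325.0)
        assert len(roots) >= 3  # dilute root, unstable middle, rich root
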