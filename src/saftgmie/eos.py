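"""SAFT-γ Mie Helmholtz free-energy surface.

Molecules are heteronuclear chains of fused Mie segments built from the
groups of a :class:`~saftgmie.groups.GroupLibrary`.  The total Helmholtz
energy is the sum of four contributions,

    A = A_ideal + A_monomer + A_chain + A_association,

with the monomer term a third-order Barker–Henderson perturbation expansion
about a hard-sphere reference (the standard Mie-fluid formulation with the
effective-packing-fraction c-matrix and the φ-coefficient correlations for
the second/third-order terms), the chain term built on molecularly averaged
Mie parameters, and the association term the Wertheim first-order (TPT1)
mass-action solution with strength

    Δ_kl,ab = [exp(ε^HB_kl,ab / kT) − 1] · K^HB_kl,ab · g^HS_kl(d_kl),

where g^HS is the contact value of the hard-sphere pair correlation of the
reference fluid.

Every routine accepts complex-valued (T, V, N) so that exact first
derivatives (pressure, chemical potentials, entropy) can be taken by
complex-step differentiation; the association mass-action equations are
solved at the real part of the state and the free energy is then evaluated
through the stationary Q-form, which leaves first derivatives exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .groups import GroupLibrary, Molecule

kB = 1.380649e-23          # J/K
NA = 6.02214076e23         # 1/mol
R = kB * NA                # J/(mol K)
_LAMBDA_TH = 1.0e-10       # fixed thermal-wavelength convention [m]
_ETA_MAX = 0.74            # close-packing bound on the hard-sphere packing fraction

# Gauss-Legendre rule for the Barker-Henderson diameter integral
_GL_X, _GL_W = np.polynomial.legendre.leggauss(64)

# effective packing fraction ζ_eff(ζx; λ) coefficient matrix
_C_ZEFF = np.array(
    [
        [0.81096, 1.7888, -37.578, 92.284],
        [1.0205, -19.341, 151.26, -463.50],
        [-1.9057, 22.845, -228.14, 973.92],
        [1.0885, -6.1962, 106.98, -677.64],
    ]
)

# φ-coefficients for f1..f6 (second/third-order dispersion corrections) and
# the γc chain correction constants
_PHI = np.array(
    [
        [7.5365557, -37.60463, 71.745953, -46.83552, -2.467982, -0.50272, 8.0956883],
        [-359.44, 1825.6, -3168.0, 1884.2, -0.82376, -3.1935, 3.7090],
        [1550.9, -5070.1, 6534.6, -3288.7, -0.60057, -8.7642, 4.7315],
        [-1.19932, 9.063632, -17.9482, 11.34027, 20.52142, -56.6377, 40.53683],
        [-1911.28, 21390.175, -51320.7, 37064.54, 1103.742, -3264.61, 2556.181],
        [9236.9, -129430.0, 357230.0, -315530.0, 1390.2, -4518.2, 4241.6],
    ]
)
_GAMMA_C = (10.0, 10.0, 0.57, -6.7, -8.0)

# association-kernel correlation I(ρ*, T*): polynomial coefficients c_ij of
# the dimensionless bonding integral of the Lennard-Jones reference fluid
# (the standard kernel used with bonding volumes K^HB of the ~10²-10³ Å³
# convention); I = Σ_{i+j≤10} c_ij ρ*^i T*^j
_ASSOC_C = np.zeros((11, 11))
_ASSOC_C[0, :11] = [
    7.56425183020431e-02, -1.28667137050961e-01, 1.28350632316055e-01,
    -7.25321780970292e-02, 2.57782547511452e-02, -6.01170055221687e-03,
    9.33363147191978e-04, -9.55607377143667e-05, 6.19576039900837e-06,
    -2.30466608213628e-07, 3.74605718435540e-09,
]
_ASSOC_C[1, :10] = [
    1.34228218276565e-01, -1.82682168504886e-01, 7.71662412959262e-02,
    -7.17458641164565e-04, -8.72427344283170e-03, 2.97971836051287e-03,
    -4.84863997651451e-04, 4.35262491516424e-05, -2.07789181640066e-06,
    4.13749349344802e-08,
]
_ASSOC_C[2, :9] = [
    -5.65116428942893e-01, 1.00930692226792e+00, -6.60166945915607e-01,
    2.14492212294301e-01, -3.88462990166792e-02, 4.06016982985030e-03,
    -2.39515566373142e-04, 7.25488368831468e-06, -8.58904640281928e-08,
]
_ASSOC_C[3, :8] = [
    -3.87336382687019e-01, -2.11614570109503e-01, 4.50442894490509e-01,
    -1.76931752538907e-01, 3.17171522104923e-02, -2.91368915845693e-03,
    1.30193710011706e-04, -2.14505500786531e-06,
]
_ASSOC_C[4, :7] = [
    2.13713180911797e+00, -2.02798460133021e+00, 3.36709255682693e-01,
    1.18106507393722e-03, -6.00058423301506e-03, 6.26343952584415e-04,
    -2.03636395699819e-05,
]
_ASSOC_C[5, :6] = [
    -3.00527494795524e-01, 2.89920714512243e+00, -5.67134839686498e-01,
    5.18085125423494e-02, -2.39326776760414e-03, 4.15107362643844e-05,
]
_ASSOC_C[6, :5] = [
    -6.21028065719194e+00, -1.92883360342573e+00, 2.84109761066570e-01,
    -1.57606767372364e-02, 3.68599073256615e-04,
]
_ASSOC_C[7, :4] = [
    1.16083532818029e+01, 7.42215544511197e-01, -8.23976531246117e-02,
    1.86167650098254e-03,
]
_ASSOC_C[8, :3] = [-1.02632535542427e+01, -1.25035689035085e-01, 1.14299144831867e-02]
_ASSOC_C[9, :2] = [4.65297446837297e+00, -1.92518067137033e-02]
_ASSOC_C[10, :1] = [-8.67296219639940e-01]

__all__ = [
    "MixtureState",
    "FreeEnergyBreakdown",
    "GammaMieEoS",
    "mie_prefactor",
    "mie_pair_potential",
]


def mie_prefactor(lambda_r, lambda_a):
    """Prefactor C(λr, λa) making the Mie-potential minimum equal −ε."""
    if np.any(np.real(lambda_r) <= np.real(lambda_a)) or np.any(np.real(lambda_a) <= 0):
        raise ValueError("Mie prefactor requires lambda_r > lambda_a > 0")
    dl = lambda_r - lambda_a
    return (lambda_r / dl) * (lambda_r / lambda_a) ** (lambda_a / dl)


def mie_pair_potential(r, sigma, epsilon, lambda_r, lambda_a):
    """Mie pair potential Φ(r) = C ε [(σ/r)^λr − (σ/r)^λa]."""
    if np.any(np.real(r) <= 0):
        raise ValueError("r must be positive")
    c = mie_prefactor(lambda_r, lambda_a)
    sr = sigma / np.asarray(r)
    return c * epsilon * (sr**lambda_r - sr**lambda_a)


@dataclass(frozen=True)
class MixtureState:
    """Temperature [K], volume [m³] and mole numbers [mol] per component."""

    T: float
    V: float
    n: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "n", np.asarray(self.n, dtype=float))
        if self.T <= 0 or self.V <= 0:
            raise ValueError("T and V must be positive")
        if np.any(self.n < 0) or self.n.sum() <= 0:
            raise ValueError("mole numbers must be nonnegative with a positive total")

    @property
    def n_total(self) -> float:
        return float(self.n.sum())

    @property
    def x(self) -> np.ndarray:
        return self.n / self.n.sum()

    @property
    def rho_molar(self) -> float:
        """Total molar density [mol/m³]."""
        return self.n_total / self.V


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """Dimensionless free-energy pieces per NkT and the total A [J]."""

    a_ideal: float
    a_monomer: float
    a_chain: float
    a_association: float
    total: float

    @property
    def a_residual(self) -> float:
        return self.a_monomer + self.a_chain + self.a_association


def _zeff_coeffs(lam):
    inv = 1.0 / np.asarray(lam, dtype=float)
    return np.tensordot(_C_ZEFF, np.stack([np.ones_like(inv), inv, inv**2, inv**3]), axes=(1, 0))


def _f16(alpha):
    """f1..f6(α) correlation functions, returned as a (6, ...) array."""
    alpha = np.asarray(alpha, dtype=float)
    num = sum(_PHI[:, n][:, None] * alpha[None, :] ** n for n in range(4))
    den = 1.0 + sum(_PHI[:, n][:, None] * alpha[None, :] ** (n - 3) for n in range(4, 7))
    return num / den


def _khs(zx):
    return (1.0 - zx) ** 4 / (1.0 + 4.0 * zx + 4.0 * zx**2 - 4.0 * zx**3 + zx**4)


def _dkhs(zx):
    den = 1.0 + 4.0 * zx + 4.0 * zx**2 - 4.0 * zx**3 + zx**4
    dden = 4.0 + 8.0 * zx - 12.0 * zx**2 + 4.0 * zx**3
    return (-4.0 * (1.0 - zx) ** 3 * den - (1.0 - zx) ** 4 * dden) / den**2


class _LamSet:
    """Precomputed λ-dependent pieces of the perturbation integrals.

    For one exponent array λ this stores the ζ_eff coefficients; the
    temperature-dependent pieces (powers of x0 = σ/d and the mean-value
    integrals I, J) are filled in per temperature.
    """

    __slots__ = ("lam", "c")

    def __init__(self, lam):
        self.lam = np.asarray(lam, dtype=float)
        self.c = _zeff_coeffs(self.lam)

    def tdep(self, x0):
        lam = self.lam
        x0pow = x0**lam
        I = (1.0 - x0 ** (3.0 - lam)) / (lam - 3.0)
        J = -(x0 ** (4.0 - lam) * (lam - 3.0) - x0 ** (3.0 - lam) * (lam - 4.0) - 1.0) / (
            (lam - 3.0) * (lam - 4.0)
        )
        return x0pow, I, J

    def G(self, zx, I, J):
        """(a1S + B)/(2π ρs ε d³)."""
        c = self.c
        ze = c[0] * zx + c[1] * zx**2 + c[2] * zx**3 + c[3] * zx**4
        gs = -(1.0 / (self.lam - 3.0)) * (1.0 - ze / 2.0) / (1.0 - ze) ** 3
        bt = (1.0 - zx / 2.0) / (1.0 - zx) ** 3 * I - (
            9.0 * zx * (1.0 + zx) / (2.0 * (1.0 - zx) ** 3)
        ) * J
        return gs + bt

    def dG(self, zx, I, J):
        c = self.c
        ze = c[0] * zx + c[1] * zx**2 + c[2] * zx**3 + c[3] * zx**4
        dze = c[0] + 2.0 * c[1] * zx + 3.0 * c[2] * zx**2 + 4.0 * c[3] * zx**3
        dgs = -(1.0 / (self.lam - 3.0)) * (5.0 - 2.0 * ze) / (2.0 * (1.0 - ze) ** 4) * dze
        dbt = I * (5.0 - 2.0 * zx) / (2.0 * (1.0 - zx) ** 4) - (9.0 / 2.0) * J * (
            1.0 + 4.0 * zx + zx**2
        ) / (1.0 - zx) ** 4
        return dgs + dbt


class GammaMieEoS:
    """SAFT-γ Mie free-energy model for a fixed list of components.

    Parameters
    ----------
    library:
        Group-parameter library providing like/unlike and association entries.
    components:
        Molecule names (resolved through the library) or Molecule objects.
    """

    def __init__(self, library: GroupLibrary, components: Sequence[str | Molecule]):
        self.library = library
        self.components: list[Molecule] = [
            library.get_molecule(c) if isinstance(c, str) else c for c in components
        ]
        self.names = [m.name for m in self.components]

        group_names: list[str] = []
        for m in self.components:
            for g in m.groups:
                if g not in group_names:
                    group_names.append(g)
        self.group_names = group_names
        K = len(group_names)
        gidx = {g: k for k, g in enumerate(group_names)}

        self.nu = np.zeros((len(self.components), K))
        for i, m in enumerate(self.components):
            for g, cnt in m.groups.items():
                self.nu[i, gidx[g]] = cnt

        gs = [library.groups[g] for g in group_names]
        self.nu_star = np.array([g.nu_star for g in gs], dtype=float)
        self.S = np.array([g.shape_factor for g in gs])
        self.sigma_like = np.array([g.sigma for g in gs]) * 1e-10          # m
        self.lam_r_like = np.array([g.lambda_r for g in gs])
        self.lam_a_like = np.array([g.lambda_a for g in gs])
        self.eps_like = np.array([g.epsilon_over_kB for g in gs]) * kB     # J

        self.sigma_kl = np.zeros((K, K))
        self.eps_kl = np.zeros((K, K))
        self.lam_r_kl = np.zeros((K, K))
        self.lam_a_kl = np.zeros((K, K))
        for k in range(K):
            for l in range(K):
                s, e, lr, la = library.resolve_unlike(group_names[k], group_names[l])
                self.sigma_kl[k, l] = s * 1e-10
                self.eps_kl[k, l] = e * kB
                self.lam_r_kl[k, l] = lr
                self.lam_a_kl[k, l] = la
        self.C_kl = mie_prefactor(self.lam_r_kl, self.lam_a_kl)
        self.alpha_kl = self.C_kl * (1.0 / (self.lam_a_kl - 3.0) - 1.0 / (self.lam_r_kl - 3.0))
        f = _f16(self.alpha_kl.reshape(-1)).reshape(6, K, K)
        self._f_kl = f

        # effective segments per molecule
        self.seg = self.nu @ (self.nu_star * self.S)
        self._seg_weight = self.nu * (self.nu_star * self.S)[None, :]

        # molecularly averaged chain parameters (z-weighted)
        self.z = self._seg_weight / self.seg[:, None]
        self.sigma3_bar = np.einsum("ik,il,kl->i", self.z, self.z, self.sigma_kl**3)
        self.eps_bar = np.einsum("ik,il,kl->i", self.z, self.z, self.eps_kl)
        self.lam_r_bar = np.einsum("ik,il,kl->i", self.z, self.z, self.lam_r_kl)
        self.lam_a_bar = np.einsum("ik,il,kl->i", self.z, self.z, self.lam_a_kl)
        self.C_bar = mie_prefactor(self.lam_r_bar, self.lam_a_bar)
        self.alpha_bar = self.C_bar * (1.0 / (self.lam_a_bar - 3.0) - 1.0 / (self.lam_r_bar - 3.0))
        self._f_bar = _f16(self.alpha_bar)

        # λ-sets for the perturbation integrals (monomer pairs and chain)
        self._ls_mono = {
            "a": _LamSet(self.lam_a_kl),
            "r": _LamSet(self.lam_r_kl),
            "2a": _LamSet(2.0 * self.lam_a_kl),
            "ar": _LamSet(self.lam_a_kl + self.lam_r_kl),
            "2r": _LamSet(2.0 * self.lam_r_kl),
        }
        self._ls_chain = {
            "a": _LamSet(self.lam_a_bar),
            "r": _LamSet(self.lam_r_bar),
            "2a": _LamSet(2.0 * self.lam_a_bar),
            "ar": _LamSet(self.lam_a_bar + self.lam_r_bar),
            "2r": _LamSet(2.0 * self.lam_r_bar),
        }

        # association sites present in this mixture: (group index, site, count)
        sites: list[tuple[int, str, int]] = []
        for k, g in enumerate(gs):
            for stype, cnt in g.site_counts.items():
                if cnt > 0:
                    sites.append((k, stype, cnt))
        self.sites = sites
        ns = len(sites)
        self.epsHB = np.zeros((ns, ns))
        self.KHB = np.zeros((ns, ns))
        for a, (k, sa, _) in enumerate(sites):
            for b, (l, sb, _) in enumerate(sites):
                eh, kh = library.association_strength_parameters(
                    group_names[k], sa, group_names[l], sb
                )
                self.epsHB[a, b] = eh * kB
                self.KHB[a, b] = kh * 1e-30
        self.has_association = bool(np.any(self.KHB > 0))
        # dispersion energy of the group pair carrying each site pair (sets
        # the reduced temperature of the association kernel)
        self.eps_disp_sites = np.array(
            [[self.eps_kl[k, l] for (l, _, _) in sites] for (k, _, _) in sites]
        )
        self.site_mult = np.array(
            [[self.nu[i, k] * cnt for (k, _, cnt) in sites] for i in range(len(self.components))]
        )

        self._t_cache: dict[float, dict] = {}
        self._pure_cache: dict[int, "GammaMieEoS"] = {}

    # ------------------------------------------------------------------
    def pure(self, i: int) -> "GammaMieEoS":
        """Single-component model for component ``i`` (cached)."""
        if i not in self._pure_cache:
            self._pure_cache[i] = GammaMieEoS(self.library, [self.components[i]])
        return self._pure_cache[i]

    def molar_masses(self) -> np.ndarray:
        """Molar masses [kg/mol]."""
        return np.array([self.library.molar_mass(m) for m in self.components]) * 1e-3

    # ------------------------------------------------------------------
    def _bh_diameter(self, T):
        """Barker–Henderson diameters d_kk = ∫_0^σ [1 − exp(−βΦ)] dr [m]."""
        beta = 1.0 / (kB * T)
        r = 0.5 * self.sigma_like[:, None] * (_GL_X[None, :] + 1.0)
        sr = self.sigma_like[:, None] / r
        phi = (
            self.C_kl.diagonal()[:, None]
            * self.eps_like[:, None]
            * (sr ** self.lam_r_like[:, None] - sr ** self.lam_a_like[:, None])
        )
        with np.errstate(over="ignore"):
            integrand = 1.0 - np.exp(-beta * phi)
        return 0.5 * self.sigma_like * (integrand @ _GL_W)

    def _tdep(self, T):
        """Temperature-dependent arrays (cached for real temperatures)."""
        is_complex = bool(np.iscomplexobj(np.asarray(T))) and np.imag(T) != 0
        if not is_complex:
            key = float(np.real(T))
            hit = self._t_cache.get(key)
            if hit is not None:
                return hit
        d = self._bh_diameter(T)
        d_kl = 0.5 * (d[:, None] + d[None, :])
        d_kl_safe = np.where(np.real(d_kl) > 0, d_kl, self.sigma_kl)
        x0 = self.sigma_kl / d_kl_safe
        d3_bar = np.einsum("ik,il,kl->i", self.z, self.z, d_kl**3)
        d3_safe = np.where(np.real(d3_bar) > 0, d3_bar, self.sigma3_bar)
        x0b = self.sigma3_bar ** (1.0 / 3.0) / d3_safe ** (1.0 / 3.0)
        td = {
            "d": d,
            "d_kl": d_kl,
            "d_kl3": d_kl**3,
            "x0b": x0b,
            "mono": {key: ls.tdep(x0) for key, ls in self._ls_mono.items()},
            "chain": {key: ls.tdep(x0b) for key, ls in self._ls_chain.items()},
        }
        if not is_complex:
            if len(self._t_cache) > 256:
                self._t_cache.clear()
            self._t_cache[float(np.real(T))] = td
        return td

    def max_molar_density(self, T: float, x: np.ndarray) -> float:
        """Molar density at the close-packing bound ζ3 = 0.74 [mol/m³]."""
        d = np.real(self._tdep(np.real(T))["d"])
        d = np.where(d > 0, d, self.sigma_like)  # ε = 0 groups have no BH diameter
        x = np.asarray(x, dtype=float)
        xs_unnorm = x @ self._seg_weight
        v_seg = (np.pi / 6.0) * np.sum(xs_unnorm * d**3)
        return _ETA_MAX / (v_seg * NA)

    # ------------------------------------------------------------------
    def a_residual(self, T, V, n, breakdown: bool = False):
        """Residual Helmholtz energy A_res(T, V, n) in J (complex-safe)."""
        n = np.atleast_1d(np.asarray(n))
        ntot = n.sum()
        x = n / ntot
        rho = ntot * NA / V                              # molecules / m³

        td = self._tdep(T)
        d = td["d"]
        d_kl3 = td["d_kl3"]
        beta = 1.0 / (kB * T)

        seg_mix = x @ self.seg
        rho_s = rho * seg_mix
        xs = (x @ self._seg_weight) / seg_mix
        xs_kl = xs[:, None] * xs[None, :]

        z0 = (np.pi / 6.0) * rho_s * np.sum(xs)
        z1 = (np.pi / 6.0) * rho_s * np.sum(xs * d)
        z2 = (np.pi / 6.0) * rho_s * np.sum(xs * d**2)
        z3 = (np.pi / 6.0) * rho_s * np.sum(xs * d**3)
        if np.real(z3) >= _ETA_MAX:
            raise ValueError(f"packing fraction {np.real(z3):.3f} at or above close packing")
        zx = (np.pi / 6.0) * rho_s * np.sum(xs_kl * d_kl3)
        zxb = (np.pi / 6.0) * rho_s * np.sum(xs_kl * self.sigma_kl**3)

        # hard-sphere reference (Boublík); zero when no segment has volume
        if np.real(z3) == 0.0:
            a_hs = 0.0 * z3
        else:
            a_hs = (6.0 / (np.pi * rho_s)) * (
                (z2**3 / z3**2 - z0) * np.log(1.0 - z3)
                + 3.0 * z1 * z2 / (1.0 - z3)
                + z2**3 / (z3 * (1.0 - z3) ** 2)
            )

        # first-order perturbation a1
        m = td["mono"]
        pa, Ia, Ja = m["a"]
        pr, Ir, Jr = m["r"]
        lsa, lsr = self._ls_mono["a"], self._ls_mono["r"]
        Ga = lsa.G(zx, Ia, Ja)
        Gr = lsr.G(zx, Ir, Jr)
        pref = 2.0 * np.pi * rho_s * self.eps_kl * d_kl3
        a1_kl = self.C_kl * pref * (pa * Ga - pr * Gr)
        a1 = np.sum(xs_kl * a1_kl)

        # second-order perturbation a2 with the χ correction
        khs = _khs(zx)
        chi_kl = self._f_kl[0] * zxb + self._f_kl[1] * zxb**5 + self._f_kl[2] * zxb**8
        p2a, I2a, J2a = m["2a"]
        par, Iar, Jar = m["ar"]
        p2r, I2r, J2r = m["2r"]
        m2 = (
            p2a * self._ls_mono["2a"].G(zx, I2a, J2a)
            - 2.0 * par * self._ls_mono["ar"].G(zx, Iar, Jar)
            + p2r * self._ls_mono["2r"].G(zx, I2r, J2r)
        )
        a2_kl = 0.5 * khs * (1.0 + chi_kl) * self.eps_kl * self.C_kl**2 * pref * m2
        a2 = np.sum(xs_kl * a2_kl)

        # third-order perturbation a3
        a3_kl = (
            -self.eps_kl**3 * self._f_kl[3] * zxb
            * np.exp(self._f_kl[4] * zxb + self._f_kl[5] * zxb**2)
        )
        a3 = np.sum(xs_kl * a3_kl)

        a_mono = seg_mix * (a_hs + beta * a1 + beta**2 * a2 + beta**3 * a3)

        # chain contribution from molecularly averaged Mie parameters
        c = td["chain"]
        x0b = td["x0b"]
        eb, lab, lrb, Cb = self.eps_bar, self.lam_a_bar, self.lam_r_bar, self.C_bar
        cpa, cIa, cJa = c["a"]
        cpr, cIr, cJr = c["r"]
        clsa, clsr = self._ls_chain["a"], self._ls_chain["r"]

        k0 = -np.log(1.0 - zx) + (
            42.0 * zx - 39.0 * zx**2 + 9.0 * zx**3 - 2.0 * zx**4
        ) / (6.0 * (1.0 - zx) ** 3)
        k1 = (zx**4 + 6.0 * zx**2 - 12.0 * zx) / (2.0 * (1.0 - zx) ** 3)
        k2 = -3.0 * zx**2 / (8.0 * (1.0 - zx) ** 2)
        k3 = (-zx**4 + 3.0 * zx**2 + 3.0 * zx) / (6.0 * (1.0 - zx) ** 3)
        g_hs = np.exp(k0 + k1 * x0b + k2 * x0b**2 + k3 * x0b**3)

        # ε and d³ prefactors cancel between the a1-type terms and the
        # 1/(2πεd³) normalisation of g1/g2: use the reduced forms
        bGa = clsa.G(zx, cIa, cJa)
        bGr = clsr.G(zx, cIr, cJr)
        H = Cb * (cpa * bGa - cpr * bGr)
        dH = Cb * (cpa * clsa.dG(zx, cIa, cJa) - cpr * clsr.dG(zx, cIr, cJr))
        g1 = 3.0 * (H + zx * dH) - Cb * (lab * cpa * bGa - lrb * cpr * bGr)

        cp2a, cI2a, cJ2a = c["2a"]
        cpar, cIar, cJar = c["ar"]
        cp2r, cI2r, cJ2r = c["2r"]
        G2a = self._ls_chain["2a"].G(zx, cI2a, cJ2a)
        Gar = self._ls_chain["ar"].G(zx, cIar, cJar)
        G2r = self._ls_chain["2r"].G(zx, cI2r, cJ2r)
        M = cp2a * G2a - 2.0 * cpar * Gar + cp2r * G2r
        dM = (
            cp2a * self._ls_chain["2a"].dG(zx, cI2a, cJ2a)
            - 2.0 * cpar * self._ls_chain["ar"].dG(zx, cIar, cJar)
            + cp2r * self._ls_chain["2r"].dG(zx, cI2r, cJ2r)
        )
        g2mca = 1.5 * Cb**2 * (khs * M + zx * (_dkhs(zx) * M + khs * dM)) - khs * Cb**2 * (
            lrb * cp2r * G2r - (lrb + lab) * cpar * Gar + lab * cp2a * G2a
        )
        theta = np.exp(beta * eb) - 1.0
        gamma_c = (
            _GAMMA_C[0]
            * (-np.tanh(_GAMMA_C[1] * (_GAMMA_C[2] - self.alpha_bar)) + 1.0)
            * zxb * theta
            * np.exp(_GAMMA_C[3] * zxb + _GAMMA_C[4] * zxb**2)
        )
        g2 = (1.0 + gamma_c) * g2mca
        ln_g_mie = np.log(g_hs) + (beta * eb * g1 + (beta * eb) ** 2 * g2) / g_hs
        a_chain = -np.sum(x * (self.seg - 1.0) * ln_g_mie)

        if self.has_association:
            a_assoc = self._a_assoc_q(T, rho, x, (6.0 / np.pi) * zxb)
        else:
            a_assoc = 0.0

        a_res = a_mono + a_chain + a_assoc
        A = ntot * R * T * a_res
        if breakdown:
            return A, a_mono, a_chain, a_assoc
        return A

    # ------------------------------------------------------------------
    def _delta_matrix(self, T, rho_star):
        """Association strengths Δ_ab [m³] between the mixture's site classes.

        Δ = [exp(βε^HB) − 1] K^HB I(ρ*, T*) with the dimensionless kernel I
        of the reference-fluid pair correlation, ρ* = ρ_s σ_x³ the reduced
        segment density and T* = kT/ε_kl reduced with the dispersion energy
        of the group pair carrying the two sites.
        """
        beta = 1.0 / (kB * T)
        ns = len(self.sites)
        tstar = kB * T / np.where(self.eps_disp_sites > 0, self.eps_disp_sites, kB * 300.0)
        # the kernel correlation is fitted for reduced densities up to ~1;
        # cap the extrapolation smoothly (C¹ at ρ* = 1) so that unphysical
        # high-density states keep a well-behaved pressure
        if np.real(rho_star) > 1.0:
            rho_star = 1.0 + 0.3 * np.tanh((rho_star - 1.0) / 0.3)
        I = np.zeros((ns, ns), dtype=np.result_type(rho_star, tstar))
        rp = 1.0
        for i in range(11):
            acc = np.zeros_like(tstar)
            tp = np.ones_like(tstar)
            for j in range(11 - i):
                if _ASSOC_C[i, j] != 0.0:
                    acc = acc + _ASSOC_C[i, j] * tp
                tp = tp * tstar
            I = I + rp * acc
            rp = rp * rho_star
        I = np.where(np.real(I) > 0.0, I, 0.0)
        with np.errstate(over="ignore"):
            F = np.exp(beta * self.epsHB) - 1.0
        return F * self.KHB * I

    def solve_site_fractions(self, T, V, n, tol: float = 1e-12, max_iter: int = 500):
        """Fraction of each site class NOT bonded, by damped substitution + Newton.

        Returns (X, sites, s) with X per site class, the site descriptors
        (group index, site type, multiplicity) and the per-molecule average
        site counts s entering the mass-action balance.
        """
        n = np.atleast_1d(np.asarray(n, dtype=float))
        ntot = n.sum()
        x = n / ntot
        rho = ntot * NA / V
        T = float(np.real(T))
        rho_s = rho * (x @ self.seg)
        xs = (x @ self._seg_weight) / (x @ self.seg)
        rho_star = rho_s * np.sum((xs[:, None] * xs[None, :]) * self.sigma_kl**3)
        s = x @ self.site_mult
        if not self.has_association or s.sum() == 0:
            return np.ones(len(self.sites)), self.sites, s
        delta = np.real(self._delta_matrix(T, rho_star))

        warm = getattr(self, "_X_warm", None)
        X = warm.copy() if warm is not None else np.full(len(self.sites), 0.2)
        damp = 0.5
        for _ in range(max_iter):
            kappa = rho * (delta * (s * X)[None, :]).sum(axis=1)
            X_new = 1.0 / (1.0 + kappa)
            X = (1.0 - damp) * X + damp * X_new
            if np.max(np.abs(X * (1.0 + kappa) - 1.0)) < 1e-6:
                break
        Rres = None
        for _ in range(50):
            kappa = rho * (delta * (s * X)[None, :]).sum(axis=1)
            Rres = X * (1.0 + kappa) - 1.0
            if np.max(np.abs(Rres)) < tol:
                self._X_warm = X.copy()
                return X, self.sites, s
            Jac = np.diag(1.0 + kappa) + X[:, None] * rho * delta * s[None, :]
            step = np.linalg.solve(Jac, Rres)
            X_try = X - step
            while np.any(X_try <= 0) or np.any(X_try > 1.0 + 1e-12):
                step *= 0.5
                X_try = X - step
            X = X_try
        raise RuntimeError(
            f"association mass-action solve did not converge (residual {np.max(np.abs(Rres)):.2e})"
        )

    def _a_assoc_q(self, T, rho, x, rho_star):
        """Association free energy per NkT via the stationary Q-form.

        Site fractions are solved at the real part of the state; the Q-form
        is stationary in X, so evaluating it with frozen X at a complex
        perturbed state still yields exact first derivatives.
        """
        nR = np.real(np.atleast_1d(x)) * 1.0
        X, _, _ = self.solve_site_fractions(np.real(T), NA / np.real(rho), nR / nR.sum())
        s = x @ self.site_mult
        delta = self._delta_matrix(T, rho_star)
        lin = np.sum(s * (np.log(X) - X + 1.0))
        bil = 0.5 * rho * ((s * X) @ delta @ (s * X))
        return lin - bil

    # ------------------------------------------------------------------
    def a_ideal(self, T, V, n):
        """Ideal contribution per NkT with a fixed thermal-wavelength convention."""
        n = np.atleast_1d(np.asarray(n))
        ntot = n.sum()
        x = n / ntot
        rho_i = n * NA / V
        acc = 0.0
        for xi, ri in zip(x, rho_i):
            if np.real(xi) > 0:
                acc = acc + xi * np.log(ri * _LAMBDA_TH**3)
        return acc - 1.0

    def helmholtz(self, state: MixtureState) -> FreeEnergyBreakdown:
        """Full free-energy breakdown at a state (real arithmetic)."""
        T, V, n = state.T, state.V, state.n
        A_res, a_mono, a_chain, a_assoc = self.a_residual(T, V, n, breakdown=True)
        a_id = self.a_ideal(T, V, n)
        total = state.n_total * R * T * (a_id + a_mono + a_chain + a_assoc)
        return FreeEnergyBreakdown(
            a_ideal=float(a_id),
            a_monomer=float(a_mono),
            a_chain=float(a_chain),
            a_association=float(a_assoc),
            total=float(total),
        )

    def site_fraction_map(self, state: MixtureState) -> dict[tuple[str, str, str], float]:
        """Site fractions keyed (component, group, site type)."""
        X, sites, _ = self.solve_site_fractions(state.T, state.V, state.n)
        out: dict[tuple[str, str, str], float] = {}
        for i, mol in enumerate(self.components):
            for a, (k, stype, cnt) in enumerate(sites):
                gname = self.group_names[k]
                if self.nu[i, k] > 0 and cnt > 0:
                    out[(mol.name, gname, stype)] = float(X[a])
        return out
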