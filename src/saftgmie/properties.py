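"""Measurable properties from the SAFT-γ Mie free-energy surface.

Pressure, chemical potentials and entropy are first derivatives of the
Helmholtz energy; they are evaluated by complex-step differentiation, which
is exact to machine precision for the analytic free-energy surface (central
finite differences serve as an independent cross-check in the test suite).
Enthalpic properties are built from residual (departure) quantities only, so
no ideal-gas heat-capacity input is required: vaporization and excess
enthalpies are equal-temperature differences in which the ideal parts cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eos import NA, R, GammaMieEoS, _LAMBDA_TH

_CS_REL = 1e-50  # relative complex-step size (no subtractive cancellation)

__all__ = [
    "PropertySet",
    "pressure",
    "chemical_potential",
    "residual_chemical_potential",
    "residual_enthalpy",
    "ln_phi",
    "density",
    "density_roots",
    "saturation_pressure",
    "vaporization_enthalpy",
    "excess_enthalpy",
    "activity_coefficient",
    "property_set",
]


def _dAres_dV(eos: GammaMieEoS, T, V, n) -> float:
    h = V * _CS_REL
    return float(np.imag(eos.a_residual(T, V + 1j * h, np.asarray(n, dtype=float))) / h)


def _dAres_dT(eos: GammaMieEoS, T, V, n) -> float:
    h = T * _CS_REL
    return float(np.imag(eos.a_residual(T + 1j * h, V, np.asarray(n, dtype=float))) / h)


def _dAres_dn(eos: GammaMieEoS, T, V, n) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    ntot = n.sum()
    out = np.zeros_like(n)
    for i in range(len(n)):
        h = ntot * _CS_REL
        nc = n.astype(complex).copy()
        nc[i] += 1j * h
        out[i] = np.imag(eos.a_residual(T, V, nc)) / h
    return out


def pressure(eos: GammaMieEoS, T: float, V: float, n) -> float:
    """P = −(∂A/∂V)_{T,N} [Pa]."""
    n = np.asarray(n, dtype=float)
    return n.sum() * R * T / V - _dAres_dV(eos, T, V, n)


def residual_chemical_potential(eos: GammaMieEoS, T: float, V: float, n) -> np.ndarray:
    """μ_i − μ_i^ideal-gas at the same (T, V, N) [J/mol]."""
    return _dAres_dn(eos, T, V, n)


def chemical_potential(eos: GammaMieEoS, T: float, V: float, n) -> np.ndarray:
    """μ_i = (∂A/∂N_i)_{T,V} [J/mol] (fixed thermal-wavelength convention)."""
    n = np.asarray(n, dtype=float)
    rho_i = n * NA / V
    mu_id = np.full_like(n, -np.inf)
    mask = n > 0
    mu_id[mask] = R * T * np.log(rho_i[mask] * _LAMBDA_TH**3)
    return mu_id + _dAres_dn(eos, T, V, n)


def residual_enthalpy(eos: GammaMieEoS, T: float, V: float, n) -> float:
    """Molar residual enthalpy h − h^ideal-gas [J/mol]."""
    n = np.asarray(n, dtype=float)
    ntot = n.sum()
    A = float(np.real(eos.a_residual(T, V, n)))
    A_T = _dAres_dT(eos, T, V, n)
    A_V = _dAres_dV(eos, T, V, n)
    # h_res = (A_res − T ∂A_res/∂T + (P − nRT/V) V)/n and P − nRT/V = −∂A_res/∂V
    return (A - T * A_T - V * A_V) / ntot


# ---------------------------------------------------------------------------
# density solution


def _p_of_rho(eos, T, rho, x):
    return pressure(eos, T, 1.0 / rho, x)


def _newton_density(eos, T, P, x, rho0, rho_max, tol=1e-12, max_iter=80):
    rho = rho0
    for _ in range(max_iter):
        f = _p_of_rho(eos, T, rho, x) - P
        h = rho * 1e-7
        fp = (_p_of_rho(eos, T, rho + h, x) - P - f) / h
        if fp == 0.0:
            return None
        step = f / fp
        rho_new = rho - step
        # keep inside the physical window
        while rho_new <= 0 or rho_new >= rho_max:
            step *= 0.5
            rho_new = rho - step
            if abs(step) < 1e-30 * rho:
                return None
        if abs(rho_new - rho) < tol * rho:
            rho = rho_new
            f = _p_of_rho(eos, T, rho, x) - P
            h = rho * 1e-7
            fp = (_p_of_rho(eos, T, rho + h, x) - P - f) / h
            if fp <= 0:
                return None  # mechanically unstable branch
            return rho
        rho = rho_new
    return None


def density_roots(eos: GammaMieEoS, T: float, P: float, x, n_grid: int = 160):
    """All mechanically stable density roots of P(T, ρ, x) = P [mol/m³].

    Returns a list of (rho, gibbs_per_mole) sorted by density.
    """
    from scipy.optimize import brentq

    x = np.asarray(x, dtype=float)
    x = x / x.sum()
    rho_max = eos.max_molar_density(T, x)
    etas = np.concatenate(
        [np.geomspace(1e-12, 0.05, n_grid // 3), np.linspace(0.052, 0.72, n_grid - n_grid // 3)]
    )
    rhos = etas / 0.74 * rho_max
    ps = np.array([_p_of_rho(eos, T, r, x) for r in rhos])
    roots = []
    f = ps - P
    for i in range(len(rhos) - 1):
        if f[i] == 0.0:
            roots.append(rhos[i])
        elif f[i] * f[i + 1] < 0:
            roots.append(brentq(lambda r: _p_of_rho(eos, T, r, x) - P, rhos[i], rhos[i + 1], xtol=1e-12 * rho_max))
    stable = []
    for r in roots:
        h = r * 1e-6
        slope = (_p_of_rho(eos, T, r + h, x) - _p_of_rho(eos, T, r - h, x)) / (2 * h)
        if slope > 0:
            stable.append((r, _gibbs_molar(eos, T, P, r, x)))
    return sorted(stable)


def _gibbs_molar(eos, T, P, rho, x) -> float:
    """Molar Gibbs energy g = A/n + P v (fixed Λ convention) [J/mol]."""
    V = 1.0 / rho
    a_res = float(np.real(eos.a_residual(T, V, x)))
    a_id = float(np.real(eos.a_ideal(T, V, x)))
    return a_res + R * T * a_id + P * V


def density(
    eos: GammaMieEoS,
    T: float,
    P: float,
    x,
    phase: str | None = None,
) -> float:
    """Molar density [mol/m³] at (T, P, x) on the requested branch.

    ``phase`` may be "liquid", "vapor" or None; with None the root with the
    lowest molar Gibbs energy is returned.
    """
    if P <= 0:
        raise ValueError("P must be positive")
    x = np.asarray(x, dtype=float)
    x = x / x.sum()
    rho_max = eos.max_molar_density(T, x)

    if phase == "vapor":
        r = _newton_density(eos, T, P, x, min(P / (R * T), 0.3 * rho_max), rho_max)
        if r is not None and r / rho_max * 0.74 < 0.45:
            return r
    elif phase == "liquid":
        for eta0 in (0.5, 0.55, 0.42, 0.62):
            r = _newton_density(eos, T, P, x, eta0 / 0.74 * rho_max, rho_max)
            if r is not None and r / rho_max * 0.74 > 0.2:
                return r

    roots = density_roots(eos, T, P, x)
    if not roots:
        raise RuntimeError(
            f"no physical density root at T={T} K, P={P} Pa for composition {x}"
        )
    if phase == "vapor":
        return roots[0][0]
    if phase == "liquid":
        rho = roots[-1][0]
        if rho / rho_max * 0.74 < 0.15:
            raise RuntimeError(
                f"no liquid-branch density root at T={T} K, P={P} Pa for composition {x}"
            )
        return rho
    return min(roots, key=lambda t: t[1])[0]


# ---------------------------------------------------------------------------
# fugacity and activity


def ln_phi(eos: GammaMieEoS, T: float, P: float, x, phase: str | None = None):
    """ln fugacity coefficients and the density used [mol/m³]."""
    x = np.asarray(x, dtype=float)
    x = x / x.sum()
    rho = density(eos, T, P, x, phase=phase)
    V = 1.0 / rho
    mu_res = residual_chemical_potential(eos, T, V, x)
    Z = P / (rho * R * T)
    return mu_res / (R * T) - np.log(Z), rho


def activity_coefficient(eos: GammaMieEoS, T: float, P: float, x) -> np.ndarray:
    """γ_i relative to the pure liquid of each component at the same (T, P)."""
    x = np.asarray(x, dtype=float)
    x = x / x.sum()
    lnphi_mix, _ = ln_phi(eos, T, P, x, phase="liquid")
    gam = np.zeros_like(x)
    for i in range(len(x)):
        try:
            lnphi_pure, _ = ln_phi(eos.pure(i), T, P, np.array([1.0]), phase="liquid")
        except RuntimeError as err:
            raise RuntimeError(
                f"pure-liquid reference state unavailable for {eos.names[i]} at "
                f"T={T} K, P={P} Pa"
            ) from err
        gam[i] = np.exp(lnphi_mix[i] - lnphi_pure[0])
    return gam


# ---------------------------------------------------------------------------
# saturation and enthalpic properties


def saturation_pressure(eos: GammaMieEoS, T: float, P_init: float | None = None):
    """Pure-component saturation (P_sat [Pa], rho_liq, rho_vap [mol/m³]).

    Raises RuntimeError when the model fluid has no sub-critical van der
    Waals loop at T.
    """
    x = np.array([1.0])
    rho_max = eos.max_molar_density(T, x)
    etas = np.concatenate([np.geomspace(1e-10, 0.05, 40), np.linspace(0.052, 0.72, 100)])
    rhos = etas / 0.74 * rho_max
    ps = np.array([_p_of_rho(eos, T, r, x) for r in rhos])
    dps = np.diff(ps)
    falling = np.where(dps < 0)[0]
    if len(falling) == 0:
        raise RuntimeError(f"no vapor-liquid coexistence at T={T} K (supercritical model state)")
    i_max = falling[0]
    i_min = i_max + int(np.argmin(ps[i_max:]))
    p_hi = ps[i_max]
    p_lo = max(ps[i_min], 0.0)
    P = P_init if P_init is not None else max(0.5 * (p_hi + p_lo), 1e-8 * p_hi)
    P = min(max(P, p_lo + 1e-12), p_hi * 0.999999)
    rho_v_prev = rhos[max(i_max - 2, 0)]
    rho_l_prev = rhos[min(i_min + 2, len(rhos) - 1)]

    for _ in range(100):
        rho_v = _newton_density(eos, T, P, x, rho_v_prev, rho_max) or density(
            eos, T, P, x, phase="vapor"
        )
        rho_l = _newton_density(eos, T, P, x, rho_l_prev, rho_max) or density(
            eos, T, P, x, phase="liquid"
        )
        if rho_v > rho_l:
            rho_v, rho_l = rho_l, rho_v
        if abs(rho_v - rho_l) / rho_l < 1e-8:
            raise RuntimeError(f"trivial root collapse in saturation solve at T={T} K")
        rho_v_prev, rho_l_prev = rho_v, rho_l
        g_v = _gibbs_molar(eos, T, P, rho_v, x)
        g_l = _gibbs_molar(eos, T, P, rho_l, x)
        dmu = g_l - g_v
        if abs(dmu) / (R * T) < 1e-10:
            return P, rho_l, rho_v
        # Newton on μ_l(P) − μ_v(P) = 0 with d(Δμ)/dP = v_l − v_v,
        # falling back to the log-fugacity substitution step when it leaves
        # the admissible window
        P_newton = P - dmu / (1.0 / rho_l - 1.0 / rho_v)
        if not (p_lo < P_newton < p_hi):
            P_newton = P * np.exp(dmu / (R * T))
        P = min(max(P_newton, p_lo + 1e-12), p_hi * 0.999999)
    raise RuntimeError(f"saturation pressure iteration did not converge at T={T} K")


def vaporization_enthalpy(eos: GammaMieEoS, T: float) -> float:
    """Δh_vap(T) = h_vap,sat − h_liq,sat [J/mol] for a pure component."""
    P, rho_l, rho_v = saturation_pressure(eos, T)
    x = np.array([1.0])
    h_v = residual_enthalpy(eos, T, 1.0 / rho_v, x)
    h_l = residual_enthalpy(eos, T, 1.0 / rho_l, x)
    return h_v - h_l


def excess_enthalpy(eos: GammaMieEoS, T: float, P: float, x) -> float:
    """Molar excess enthalpy h_E(T, P, x) [J/mol] of a liquid mixture."""
    x = np.asarray(x, dtype=float)
    x = x / x.sum()
    rho = density(eos, T, P, x, phase="liquid")
    h_mix = residual_enthalpy(eos, T, 1.0 / rho, x)
    h_pure = 0.0
    for i, xi in enumerate(x):
        if xi == 0.0:
            continue
        pe = eos.pure(i)
        rho_i = density(pe, T, P, np.array([1.0]), phase="liquid")
        h_pure += xi * residual_enthalpy(pe, T, 1.0 / rho_i, np.array([1.0]))
    return h_mix - h_pure


@dataclass(frozen=True)
class PropertySet:
    """Bundle of measurable properties at one (T, P, x) state."""

    T: float
    P: float
    x: np.ndarray
    rho_molar: float          # mol/m³
    rho_mass: float           # kg/m³
    mu: np.ndarray            # J/mol
    h_res: float              # J/mol
    phi: np.ndarray           # fugacity coefficients
    gamma: np.ndarray | None  # activity coefficients (liquid states)


def property_set(eos: GammaMieEoS, T: float, P: float, x, phase: str | None = "liquid") -> PropertySet:
    x = np.asarray(x, dtype=float)
    x = x / x.sum()
    rho = density(eos, T, P, x, phase=phase)
    V = 1.0 / rho
    mw = eos.molar_masses()
    lnphi, _ = ln_phi(eos, T, P, x, phase=phase)
    gamma = None
    if phase == "liquid":
        try:
            gamma = activity_coefficient(eos, T, P, x)
        except RuntimeError:
            gamma = None
    return PropertySet(
        T=T,
        P=P,
        x=x,
        rho_molar=rho,
        rho_mass=float(rho * (x @ mw)),
        mu=chemical_potential(eos, T, V, x),
        h_res=residual_enthalpy(eos, T, V, x),
        phi=np.exp(lnphi),
        gamma=gamma,
    )
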