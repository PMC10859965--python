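"""Phase-equilibrium solvers: VLE (bubble/dew), azeotropes, LLE with
tangent-plane screening, SLE solubility, eutectic points and three-phase
VLLE.

All solvers work on a binary (or pure) :class:`~saftgmie.eos.GammaMieEoS`
and reduce to equality of chemical potentials (equivalently fugacities) and
pressure across phases.  Solid phases are treated as pure, so solid-liquid
solubility follows

    ln(x_i γ_i) = −(Δh_i^fus / R) (1/T − 1/T_i^fus),

with the activity coefficient γ_i from the equation of state and the heat
capacity difference term neglected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .eos import R, GammaMieEoS
from .groups import FusionData
from .properties import density, ln_phi, saturation_pressure

__all__ = [
    "PhaseEquilibriumResult",
    "AzeotropePoint",
    "SolubilityPoint",
    "bubble_point",
    "dew_point",
    "find_azeotrope",
    "hetero_azeotrope",
    "lle",
    "tpd_scan",
    "sle_solubility",
    "sle_ideal",
    "liquidus_roots",
    "eutectic",
    "three_phase_vlle",
]


@dataclass
class PhaseEquilibriumResult:
    """Converged phase compositions and diagnostics."""

    spec: str
    T: float
    P: float
    phases: list[tuple[str, np.ndarray, float]]   # (label, composition, molar density)
    converged: bool
    residuals: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AzeotropePoint:
    x_az: float          # component-1 mole fraction
    T_az: float          # K
    P_az: float          # Pa


@dataclass(frozen=True)
class SolubilityPoint:
    T: float
    P: float
    x_sat: float
    branch: str


# ---------------------------------------------------------------------------
# fugacity helpers


def _lnfug(eos, T, P, x, phase):
    """ln(x_i φ_i) for the mixture at (T, P, x)."""
    x = np.asarray(x, dtype=float)
    lnphi, rho = ln_phi(eos, T, P, x, phase=phase)
    with np.errstate(divide="ignore"):
        return np.log(x) + lnphi, rho


def _mu_residuals(eos, T, P, phases):
    """Max relative μ-equality residual over distributed components."""
    lf = []
    for label, x, phase in phases:
        v, _ = _lnfug(eos, T, P, x, phase)
        lf.append(v)
    lf = np.array(lf)
    res = 0.0
    for i in range(lf.shape[1]):
        col = lf[:, i]
        col = col[np.isfinite(col)]
        if len(col) > 1:
            res = max(res, float(np.max(col) - np.min(col)))
    return res


# ---------------------------------------------------------------------------
# bubble and dew points


def _psat_cached(eos_pure, T):
    cache = getattr(eos_pure, "_psat_cache", None)
    if cache is None:
        cache = {}
        eos_pure._psat_cache = cache
    key = float(T)
    if key not in cache:
        if len(cache) > 4096:
            cache.clear()
        cache[key] = saturation_pressure(eos_pure, T)[0]
    return cache[key]


def _pure_boiling_temperature(eos_pure, P, T_lo=140.0, T_hi=900.0):
    """Temperature where the pure saturation pressure equals P.

    Secant iteration in Clausius-Clapeyron coordinates (ln P vs 1/T), which
    is close to linear; cached per (model, pressure).
    """
    cache = getattr(eos_pure, "_tboil_cache", None)
    if cache is None:
        cache = {}
        eos_pure._tboil_cache = cache
    if float(P) in cache:
        return cache[float(P)]

    def f(T):
        try:
            return np.log(_psat_cached(eos_pure, T) / P)
        except (RuntimeError, ValueError):
            return np.nan

    T0, T1 = 300.0, 360.0
    f0, f1 = f(T0), f(T1)
    # walk the start downward/upward until two finite anchors exist
    tries = 0
    while (not np.isfinite(f0) or not np.isfinite(f1)) and tries < 8:
        T0, T1 = max(T_lo, 0.8 * T0), max(T_lo * 1.1, 0.8 * T1)
        f0, f1 = f(T0), f(T1)
        tries += 1
    if not (np.isfinite(f0) and np.isfinite(f1)):
        raise RuntimeError("could not initialise the pure boiling-point search")
    u0, u1 = 1.0 / T0, 1.0 / T1
    for _ in range(60):
        if f1 == f0:
            break
        u2 = u1 - f1 * (u1 - u0) / (f1 - f0)
        u2 = min(max(u2, 1.0 / T_hi), 1.0 / T_lo)
        T2 = 1.0 / u2
        f2 = f(T2)
        if not np.isfinite(f2):
            T2 = 0.5 * (1.0 / u1 + T2)
            u2 = 1.0 / T2
            f2 = f(T2)
            if not np.isfinite(f2):
                raise RuntimeError("pure boiling-point search left the coexistence region")
        u0, f0, u1, f1 = u1, f1, u2, f2
        if abs(f1) < 1e-10:
            break
    cache[float(P)] = 1.0 / u1
    return 1.0 / u1


def bubble_point(
    eos: GammaMieEoS,
    x,
    P: float | None = None,
    T: float | None = None,
    T_guess: float | None = None,
    P_guess: float | None = None,
    y_guess=None,
    tol: float = 1e-10,
) -> PhaseEquilibriumResult:
    """Bubble solve for a liquid of composition x.

    Fix P to find the bubble temperature, or fix T to find the bubble
    pressure.  Degenerates to the pure saturation point at x = e_i.
    """
    x = np.asarray(x, dtype=float)
    x = x / x.sum()
    if (P is None) == (T is None):
        raise ValueError("fix exactly one of P and T")

    if P is not None:
        return _bubble_fixed_P(eos, x, P, T_guess, y_guess, tol)
    return _bubble_fixed_T(eos, x, T, P_guess, y_guess, tol)


def _bubble_inner(eos, x, T, P, y, n_iter=200, tol=1e-12):
    """Converge vapor composition at fixed (T, P); returns (y, lnS)."""
    lnf_liq, _ = _lnfug(eos, T, P, x, "liquid")
    for _ in range(n_iter):
        lnphi_v, _ = ln_phi(eos, T, P, y, phase="vapor")
        lny_new = lnf_liq - lnphi_v
        S = np.sum(np.exp(lny_new[np.isfinite(lny_new)]))
        y_new = np.exp(lny_new - np.log(S))
        y_new[~np.isfinite(y_new)] = 0.0
        if np.max(np.abs(y_new - y)) < tol:
            return y_new, np.log(S)
        y = y_new
    return y, np.log(S)


def _bubble_fixed_P(eos, x, P, T_guess, y_guess, tol):
    nc = len(x)
    if T_guess is None:
        Tb = [_pure_boiling_temperature(eos.pure(i), P) for i in range(nc)]
        T = float(np.dot(x, Tb))
    else:
        T = T_guess

    # initial vapor from Raoult with pure saturation pressures
    if y_guess is None:
        psat = []
        for i in range(nc):
            try:
                psat.append(_psat_cached(eos.pure(i), T))
            except RuntimeError:
                psat.append(P)
        y = x * np.array(psat) / P
        y = y / y.sum()
    else:
        y = np.asarray(y_guess, dtype=float)

    f_prev = None
    T_prev = None
    for it in range(80):
        y, lnS = _bubble_inner(eos, x, T, P, y)
        if abs(lnS) < tol:
            break
        if f_prev is None or abs(lnS - f_prev) < 1e-14:
            T_new = T * (1.0 + 0.02 * np.sign(lnS))  # S < 1: raise volatility
        else:
            T_new = T - lnS * (T - T_prev) / (lnS - f_prev)
            T_new = min(max(T_new, 0.7 * T), 1.3 * T)
        T_prev, f_prev = T, lnS
        T = T_new
    rho_l = density(eos, T, P, x, phase="liquid")
    rho_v = density(eos, T, P, y, phase="vapor")
    phases = [("liquid", x, rho_l), ("vapor", y, rho_v)]
    res = _mu_residuals(eos, T, P, [("liquid", x, "liquid"), ("vapor", y, "vapor")])
    return PhaseEquilibriumResult(
        spec="bubble-T", T=float(T), P=float(P), phases=phases,
        converged=bool(abs(lnS) < 1e-8), residuals={"lnS": float(lnS), "mu": res},
    )


def _bubble_fixed_T(eos, x, T, P_guess, y_guess, tol):
    nc = len(x)
    psat = []
    for i in range(nc):
        try:
            psat.append(_psat_cached(eos.pure(i), T))
        except RuntimeError:
            psat.append(np.nan)
    psat = np.array(psat)
    if P_guess is None:
        P = float(np.nansum(x * psat))
        if not np.isfinite(P) or P <= 0:
            raise RuntimeError("cannot build a Raoult initial bubble pressure")
    else:
        P = P_guess
    if y_guess is None:
        y = x * np.where(np.isfinite(psat), psat, P) / P
        y = y / y.sum()
    else:
        y = np.asarray(y_guess, dtype=float)

    lnS = np.inf
    for it in range(100):
        y, lnS = _bubble_inner(eos, x, T, P, y)
        if abs(lnS) < tol:
            break
        P = P * np.exp(lnS)
    rho_l = density(eos, T, P, x, phase="liquid")
    rho_v = density(eos, T, P, y, phase="vapor")
    phases = [("liquid", x, rho_l), ("vapor", y, rho_v)]
    res = _mu_residuals(eos, T, P, [("liquid", x, "liquid"), ("vapor", y, "vapor")])
    return PhaseEquilibriumResult(
        spec="bubble-P", T=float(T), P=float(P), phases=phases,
        converged=bool(abs(lnS) < 1e-8), residuals={"lnS": float(lnS), "mu": res},
    )


def dew_point(eos: GammaMieEoS, y, P: float, T_guess: float | None = None,
              x_guess=None, tol: float = 1e-10) -> PhaseEquilibriumResult:
    """Dew temperature for a vapor of composition y at fixed P."""
    y = np.asarray(y, dtype=float)
    y = y / y.sum()
    nc = len(y)
    if T_guess is None:
        Tb = [_pure_boiling_temperature(eos.pure(i), P) for i in range(nc)]
        T = float(np.dot(y, Tb))
    else:
        T = T_guess
    x = y.copy() if x_guess is None else np.asarray(x_guess, dtype=float)

    f_prev = T_prev = None
    lnS = np.inf
    for it in range(80):
        lnf_vap, _ = _lnfug(eos, T, P, y, "vapor")
        for _ in range(200):
            lnphi_l, _ = ln_phi(eos, T, P, x, phase="liquid")
            lnx_new = lnf_vap - lnphi_l
            S = np.sum(np.exp(lnx_new[np.isfinite(lnx_new)]))
            x_new = np.exp(lnx_new - np.log(S))
            x_new[~np.isfinite(x_new)] = 0.0
            if np.max(np.abs(x_new - x)) < 1e-12:
                break
            x = x_new
        lnS = np.log(S)
        if abs(lnS) < tol:
            break
        if f_prev is None or abs(lnS - f_prev) < 1e-14:
            T_new = T * (1.0 - 0.02 * np.sign(lnS))
        else:
            T_new = T - lnS * (T - T_prev) / (lnS - f_prev)
            T_new = min(max(T_new, 0.7 * T), 1.3 * T)
        T_prev, f_prev = T, lnS
        T = T_new
    rho_l = density(eos, T, P, x, phase="liquid")
    rho_v = density(eos, T, P, y, phase="vapor")
    phases = [("liquid", x, rho_l), ("vapor", y, rho_v)]
    res = _mu_residuals(eos, T, P, [("liquid", x, "liquid"), ("vapor", y, "vapor")])
    return PhaseEquilibriumResult(
        spec="dew-T", T=float(T), P=float(P), phases=phases,
        converged=bool(abs(lnS) < 1e-8), residuals={"lnS": float(lnS), "mu": res},
    )


# ---------------------------------------------------------------------------
# azeotropes


def find_azeotrope(
    eos: GammaMieEoS,
    P: float,
    x_grid=None,
) -> list[AzeotropePoint]:
    """Azeotropes of a binary at fixed P from sign changes of y1 − x1.

    Returns an empty list when no azeotrope exists; multiple azeotropes are
    returned ordered in x.
    """
    if x_grid is None:
        x_grid = np.linspace(0.05, 0.95, 13)

    warm = {"T": None, "y": None}

    def dev(x1):
        res = bubble_point(
            eos, np.array([x1, 1.0 - x1]), P=P, T_guess=warm["T"], y_guess=warm["y"]
        )
        if res.converged:
            warm["T"] = res.T
            warm["y"] = res.phases[1][1]
        return res.phases[1][1][0] - x1, res

    out = []
    d_prev, x_prev = None, None
    for x1 in x_grid:
        d, _ = dev(x1)
        if d_prev is not None and np.isfinite(d) and np.isfinite(d_prev) and d_prev * d < 0:
            x_az = brentq(lambda u: dev(u)[0], x_prev, x1, xtol=1e-6)
            _, res = dev(x_az)
            out.append(AzeotropePoint(x_az=float(x_az), T_az=res.T, P_az=P))
        d_prev, x_prev = d, x1
    return out


def hetero_azeotrope(
    eos: GammaMieEoS,
    P: float,
    T_lo: float,
    T_hi: float,
    n_grid: int = 12,
    dx: float = 0.02,
) -> tuple[AzeotropePoint, PhaseEquilibriumResult] | None:
    """Heterogeneous azeotrope (isobaric three-phase VLL line) of a binary.

    When a miscibility gap reaches the bubble surface the azeotropic point
    is the three-phase temperature where a vapor coexists with both
    liquids; the azeotrope composition is that vapor composition.  Scans
    temperature in [T_lo, T_hi] at fixed P; returns None when no
    three-phase state exists there.
    """

    def vapor_sum(T):
        r = lle(eos, T, P, dx=dx)
        if r is None:
            return None
        x_a = r.phases[0][1]
        lnf, _ = _lnfug(eos, T, P, x_a, "liquid")
        y = np.exp(lnf)
        y = y / y.sum()
        for _ in range(200):
            lnphi_v, _ = ln_phi(eos, T, P, y, phase="vapor")
            expo = np.exp(lnf - lnphi_v)
            s = expo.sum()
            y_new = expo / s
            if np.max(np.abs(y_new - y)) < 1e-12:
                break
            y = y_new
        return s, y, r

    Ts = np.linspace(T_lo, T_hi, n_grid)
    prev = None
    for T in Ts:
        out = vapor_sum(T)
        if out is None:
            prev = None
            continue
        s, y, r = out
        if prev is not None and (prev[1] - 1.0) * (s - 1.0) < 0:
            a, b = prev[0], T
            for _ in range(40):
                mid = 0.5 * (a + b)
                om = vapor_sum(mid)
                if om is None:
                    a = mid
                    continue
                sm, ym, rm = om
                if (prev[1] - 1.0) * (sm - 1.0) < 0:
                    b = mid
                else:
                    a = mid
                if b - a < 1e-3:
                    break
            T3 = 0.5 * (a + b)
            s3, y3, r3 = vapor_sum(T3)
            rho_v = density(eos, T3, P, y3, phase="vapor")
            phases = r3.phases + [("vapor", y3, rho_v)]
            res = PhaseEquilibriumResult(
                spec="hetero-azeotrope", T=float(T3), P=float(P), phases=phases,
                converged=True, residuals={"sumy": float(s3 - 1.0)},
            )
            return AzeotropePoint(x_az=float(y3[0]), T_az=float(T3), P_az=float(P)), res
        prev = (T, s)
    return None


# ---------------------------------------------------------------------------
# liquid-liquid equilibrium


def tpd_scan(eos: GammaMieEoS, T: float, P: float, dx: float = 0.02):
    """Dimensionless mixing Gibbs energy ĝ(x1) on a grid (liquid branch)."""
    xs = np.arange(dx, 1.0, dx)
    g = np.empty_like(xs)
    for i, x1 in enumerate(xs):
        try:
            lnf, _ = _lnfug(eos, T, P, np.array([x1, 1.0 - x1]), "liquid")
            # mixing part relative to the pure liquids (reference constant in
            # x, so any finite fallback keeps the tangent construction valid)
            lnf0 = []
            for j in range(2):
                try:
                    lnf0.append(_lnphi_pure_cached(eos, j, T, P))
                except RuntimeError:
                    lnf0.append(0.0)
            g[i] = x1 * (lnf[0] - lnf0[0]) + (1.0 - x1) * (lnf[1] - lnf0[1])
        except RuntimeError:
            g[i] = np.nan
    keep = np.isfinite(g)
    return xs[keep], g[keep]


def _lower_hull_gap(xs, g, dx):
    """Find non-convex regions of g(x) (double-tangent candidates)."""
    hull = [0]
    for i in range(1, len(xs)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = (xs[b] - xs[a]) * (g[i] - g[a]) - (g[b] - g[a]) * (xs[i] - xs[a])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    gaps = []
    for a, b in zip(hull[:-1], hull[1:]):
        if xs[b] - xs[a] > 1.5 * dx:
            gaps.append((xs[a], xs[b]))
    return gaps


def lle(eos: GammaMieEoS, T: float, P: float, dx: float = 0.02) -> PhaseEquilibriumResult | None:
    """Binary liquid-liquid equilibrium at (T, P), or None when stable.

    A composition-grid scan of the mixing Gibbs energy provides the
    stability screen and the double-tangent seed; the two-phase split is
    then refined by Newton iteration on the equal-fugacity conditions.
    """
    xs, g = tpd_scan(eos, T, P, dx)
    if len(xs) < 4:
        return None
    gaps = _lower_hull_gap(xs, g, dx)
    if not gaps:
        return None
    xa, xb = max(gaps, key=lambda ab: ab[1] - ab[0])

    def F(v):
        u1, u2 = v
        lf_a, _ = _lnfug(eos, T, P, np.array([u1, 1.0 - u1]), "liquid")
        lf_b, _ = _lnfug(eos, T, P, np.array([u2, 1.0 - u2]), "liquid")
        return np.array([lf_a[0] - lf_b[0], lf_a[1] - lf_b[1]])

    v = np.array([xa, xb])
    ok = False
    try:
        return _lle_newton(eos, T, P, F, v)
    except RuntimeError:
        return None


def _lle_newton(eos, T, P, F, v):
    ok = False
    for _ in range(60):
        f0 = F(v)
        if np.max(np.abs(f0)) < 1e-10:
            ok = True
            break
        J = np.empty((2, 2))
        h = 1e-7
        for j in range(2):
            vp = v.copy()
            vp[j] += h
            J[:, j] = (F(vp) - f0) / h
        try:
            step = np.linalg.solve(J, f0)
        except np.linalg.LinAlgError:
            break
        v_new = v - step
        while not (0 < v_new[0] < 1 and 0 < v_new[1] < 1) or v_new[1] - v_new[0] < 1e-10:
            step *= 0.5
            v_new = v - step
            if np.max(np.abs(step)) < 1e-15:
                break
        v = v_new
    if not ok or abs(v[1] - v[0]) < 5e-4:
        return None
    x_a = np.array([v[0], 1.0 - v[0]])
    x_b = np.array([v[1], 1.0 - v[1]])
    rho_a = density(eos, T, P, x_a, phase="liquid")
    rho_b = density(eos, T, P, x_b, phase="liquid")
    res = _mu_residuals(eos, T, P, [("L1", x_a, "liquid"), ("L2", x_b, "liquid")])
    return PhaseEquilibriumResult(
        spec="LLE", T=T, P=P,
        phases=[("liquid-1", x_a, rho_a), ("liquid-2", x_b, rho_b)],
        converged=ok, residuals={"mu": res},
    )


# ---------------------------------------------------------------------------
# solid-liquid equilibrium


def sle_ideal(fusion: FusionData, T: float) -> float:
    """Ideal-solution (γ = 1) solubility from the fusion properties."""
    if fusion.delta_h_fus is None:
        raise ValueError(f"{fusion.molecule}: enthalpy of fusion unavailable")
    return float(np.exp(-(fusion.delta_h_fus / R) * (1.0 / T - 1.0 / fusion.T_fus)))


def _lnphi_pure_cached(eos, i, T, P):
    cache = getattr(eos, "_lnphi_pure_cache", None)
    if cache is None:
        cache = {}
        eos._lnphi_pure_cache = cache
    key = (i, float(T), float(P))
    if key not in cache:
        if len(cache) > 4096:
            cache.clear()
        lnphi_pure, _ = ln_phi(eos.pure(i), T, P, np.array([1.0]), phase="liquid")
        cache[key] = float(lnphi_pure[0])
    return cache[key]


def _ln_gamma_component(eos, T, P, x, i):
    lnphi_mix, _ = ln_phi(eos, T, P, x, phase="liquid")
    return lnphi_mix[i] - _lnphi_pure_cached(eos, i, T, P)


def liquidus_roots(
    eos: GammaMieEoS,
    solute: int,
    fusion: FusionData,
    T: float,
    P: float,
    n_grid: int = 36,
) -> list[float]:
    """All solute mole fractions solving the SLE condition at (T, P).

    Multiple roots occur when the liquidus interferes with a miscibility
    gap (incipient SLLE); they are returned in increasing order.
    """
    rhs = np.log(sle_ideal(fusion, T))

    def f(xs):
        x = np.empty(2)
        x[solute] = xs
        x[1 - solute] = 1.0 - xs
        return np.log(xs) + _ln_gamma_component(eos, T, P, x, solute) - rhs

    grid = np.unique(np.concatenate([np.geomspace(1e-5, 0.1, n_grid // 3),
                                     np.linspace(0.1, 1.0 - 1e-9, n_grid - n_grid // 3)]))
    vals = np.array([f(u) for u in grid])
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if np.isfinite(fa) and np.isfinite(fb) and fa * fb <= 0 and fa != 0:
            roots.append(brentq(f, a, b, xtol=1e-12))
    return roots


def sle_solubility(
    eos: GammaMieEoS,
    solute: int,
    fusion: FusionData,
    T: float,
    P: float,
    ideal: bool = False,
    x_init: float | None = None,
    tol: float = 1e-10,
) -> SolubilityPoint:
    """Solubility of a pure solid solute in the binary liquid at (T, P).

    Damped successive substitution on x_sat; with ``ideal=True`` the closed
    form with γ ≡ 1 is returned.  At T = T_fus the pure melting limit
    x_sat = 1 is returned exactly.
    """
    if T > fusion.T_fus:
        raise ValueError(f"T={T} K above the melting temperature {fusion.T_fus} K")
    x_id = sle_ideal(fusion, T)
    if ideal or T == fusion.T_fus:
        return SolubilityPoint(T=T, P=P, x_sat=float(x_id), branch=f"{fusion.molecule} (ideal)" if ideal else fusion.molecule)

    rhs = np.log(x_id)

    def F(u):
        x = np.empty(2)
        x[solute] = u
        x[1 - solute] = 1.0 - u
        return np.log(u) + _ln_gamma_component(eos, T, P, x, solute) - rhs

    # secant iteration on ln(x γ) − rhs, seeded from the ideal solution and
    # one damped substitution step
    x0 = min(max(x_id if x_init is None else x_init, 1e-10), 1.0 - 1e-12)
    f0 = F(x0)
    x1 = min(max(0.5 * x0 + 0.5 * x0 * np.exp(-f0), 1e-12), 1.0 - 1e-12)
    if x1 == x0:
        x1 = 0.99 * x0
    f1 = F(x1)
    for _ in range(100):
        if abs(f1) < tol:
            return SolubilityPoint(T=T, P=P, x_sat=float(x1), branch=fusion.molecule)
        if f1 == f0:
            break
        x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        # safeguarded: stay in (0, 1] and damp huge jumps
        if not np.isfinite(x2) or x2 <= 0 or x2 > 1.0:
            x2 = 0.5 * (x1 + min(max(x2, 1e-12), 1.0)) if np.isfinite(x2) else 0.5 * x1
            x2 = min(max(x2, 1e-12), 1.0 - 1e-12)
        x0, f0, x1 = x1, f1, x2
        f1 = F(x1)
    warnings.warn(f"SLE solve slow to converge at T={T} K (x={x1:.4g}, residual={f1:.2g})")
    return SolubilityPoint(T=T, P=P, x_sat=float(x1), branch=fusion.molecule)


# ---------------------------------------------------------------------------
# eutectic point


def _eutectic_residual(eos, fusion_1, fusion_2, P, x1, T):
    """Both SLE conditions evaluated at one liquid composition (x1, 1−x1)."""
    x = np.array([x1, 1.0 - x1])
    lnphi_mix, _ = ln_phi(eos, T, P, x, phase="liquid")
    lg1 = lnphi_mix[0] - _lnphi_pure_cached(eos, 0, T, P)
    lg2 = lnphi_mix[1] - _lnphi_pure_cached(eos, 1, T, P)
    f1 = np.log(x1) + lg1 - np.log(sle_ideal(fusion_1, T))
    f2 = np.log(1.0 - x1) + lg2 - np.log(sle_ideal(fusion_2, T))
    return np.array([f1, f2])


def eutectic(
    eos: GammaMieEoS,
    fusion_1: FusionData,
    fusion_2: FusionData,
    P: float,
    T_min: float = 150.0,
    n_scan: int = 10,
) -> list[tuple[float, float]]:
    """Eutectic points (x1, T) of a binary at pressure P.

    The eutectic is the intersection of the two pure-solid liquidus
    branches, x_sat,1(T) + x_sat,2(T) = 1.  A descending temperature scan
    of the branch roots provides sign-change seeds; each seed is refined by
    a 2-by-2 Newton solve of the two solid-liquid equilibrium conditions in
    (x1, T) for a single liquid.  All crossings are returned ordered by
    temperature; when a miscibility gap interferes (incipient SLLE) the
    lowest-temperature crossing is the stable eutectic.
    """
    T_hi = min(fusion_1.T_fus, fusion_2.T_fus) * (1.0 - 1e-9)
    T_min = min(T_min, T_hi - 1.0)
    Ts = np.linspace(T_hi, T_min, n_scan)

    points = []   # (T, a, b, gap) with a = x1 on branch 1, b = x2 on branch 2
    for T in Ts:
        try:
            r1 = liquidus_roots(eos, 0, fusion_1, T, P, n_grid=24)
            r2 = liquidus_roots(eos, 1, fusion_2, T, P, n_grid=24)
        except RuntimeError:
            continue
        for a in r1:
            for b in r2:
                points.append((T, a, b, a + b - 1.0))

    seeds = []
    for (T1, a1, b1, g1) in points:
        for (T2, a2, b2, g2) in points:
            if 0 < T1 - T2 <= (Ts[0] - Ts[-1]) / (n_scan - 1) * 1.5:
                if abs(a1 - a2) < 0.2 and abs(b1 - b2) < 0.2 and g1 * g2 < 0:
                    w = abs(g1) / (abs(g1) + abs(g2))
                    seeds.append(((1 - w) * a1 + w * a2, (1 - w) * T1 + w * T2))

    sols: list[tuple[float, float]] = []
    for x0, T0 in seeds:
        x1, T = x0, T0
        ok = False
        try:
            for _ in range(40):
                f0 = _eutectic_residual(eos, fusion_1, fusion_2, P, x1, T)
                if np.max(np.abs(f0)) < 1e-9:
                    ok = True
                    break
                J = np.empty((2, 2))
                hx = max(1e-6, 1e-6 * x1)
                hT = 1e-4 * T
                J[:, 0] = (_eutectic_residual(eos, fusion_1, fusion_2, P, x1 + hx, T) - f0) / hx
                J[:, 1] = (_eutectic_residual(eos, fusion_1, fusion_2, P, x1, T + hT) - f0) / hT
                step = np.linalg.solve(J, f0)
                xn, Tn = x1 - step[0], T - step[1]
                while not (0 < xn < 1) or Tn <= T_min - 30 or Tn > T_hi + 1:
                    step *= 0.5
                    xn, Tn = x1 - step[0], T - step[1]
                    if np.max(np.abs(step)) < 1e-14:
                        break
                x1, T = xn, Tn
        except (RuntimeError, np.linalg.LinAlgError):
            continue
        if ok and not any(abs(T - s[1]) < 0.2 and abs(x1 - s[0]) < 5e-3 for s in sols):
            sols.append((float(x1), float(T)))
    sols.sort(key=lambda s: s[1])
    return sols


# ---------------------------------------------------------------------------
# three-phase (vapor-liquid-liquid) equilibrium


def three_phase_vlle(
    eos: GammaMieEoS,
    T: float,
    P_lo: float,
    P_hi: float,
    n_grid: int = 25,
) -> PhaseEquilibriumResult | None:
    """Locate the three-phase VLLE pressure of a binary at fixed T.

    Scans pressure for a window where two liquids coexist, then finds the
    pressure at which a vapor phase is simultaneously in equilibrium
    (Σ y_i = 1 constructed from the liquid fugacities).  Returns None when
    no three-phase state exists in [P_lo, P_hi].
    """

    def vapor_sum(P, lle_res):
        x_a = lle_res.phases[0][1]
        lnf, _ = _lnfug(eos, T, P, x_a, "liquid")
        lnphi_guess = np.zeros(2)
        y = np.exp(lnf)
        y = y / y.sum()
        for _ in range(100):
            lnphi_v, _ = ln_phi(eos, T, P, y, phase="vapor")
            y_new_ln = lnf - lnphi_v
            s = np.sum(np.exp(y_new_ln))
            y_new = np.exp(y_new_ln) / s
            if np.max(np.abs(y_new - y)) < 1e-12:
                return s, y_new
            y = y_new
        return s, y

    Ps = np.geomspace(P_lo, P_hi, n_grid)
    prev = None
    for P in Ps:
        r = lle(eos, T, P, dx=0.02)
        if r is None:
            prev = None
            continue
        s, y = vapor_sum(P, r)
        if prev is not None and (prev[1] - 1.0) * (s - 1.0) < 0:
            f = lambda Pm: vapor_sum(Pm, lle(eos, T, Pm, dx=0.02))[0] - 1.0
            P3 = brentq(f, prev[0], P, xtol=1e-3 * P)
            r3 = lle(eos, T, P3, dx=0.02)
            s3, y3 = vapor_sum(P3, r3)
            rho_v = density(eos, T, P3, y3, phase="vapor")
            phases = r3.phases + [("vapor", y3, rho_v)]
            res = _mu_residuals(
                eos, T, P3,
                [("L1", r3.phases[0][1], "liquid"), ("L2", r3.phases[1][1], "liquid"), ("V", y3, "vapor")],
            )
            return PhaseEquilibriumResult(
                spec="VLLE", T=T, P=float(P3), phases=phases,
                converged=True, residuals={"mu": res, "sumy": float(s3 - 1.0)},
            )
        prev = (P, s)
    return None
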