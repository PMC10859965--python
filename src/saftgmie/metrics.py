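"""Estimation objective, deviation metrics and fusion-enthalpy utilities.

The parameter-estimation objective is the mean of weighted squared relative
residuals over all experimental points; model accuracy is reported as the
percentage absolute average deviation (%AAD) and the absolute average
deviation (AAD, in the property's units).  A one-parameter estimator
recovers an unknown enthalpy of fusion from solid-liquid solubility data,
and the Joback group-contribution correlation provides an independent
fusion-enthalpy estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .eos import R

__all__ = [
    "ExperimentalDataset",
    "DeviationReport",
    "objective",
    "aad_metrics",
    "estimate_hfus",
    "joback_hfus",
    "JOBACK_HFUS_TABLE",
]


@dataclass
class ExperimentalDataset:
    """Tagged experimental points for one (system, property) pair.

    ``conditions`` is a DataFrame of state variables (e.g. T, P, x columns);
    ``values`` the measured property; ``weights`` default to 1 for every
    point.
    """

    system: str
    prop: str
    conditions: pd.DataFrame
    values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.weights is None:
            self.weights = np.ones_like(self.values)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.conditions) != len(self.values) or len(self.values) != len(self.weights):
            raise ValueError("conditions, values and weights must have equal length")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    @property
    def n_points(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DeviationReport:
    system: str
    prop: str
    n_points: int
    aad_percent: float
    aad: float


def _calc_values(dataset: ExperimentalDataset, model: Callable) -> np.ndarray:
    out = np.array([float(model(row)) for _, row in dataset.conditions.iterrows()])
    return out


def objective(datasets: Sequence[ExperimentalDataset], model: Callable) -> float:
    """f_obj = (1/N_exp) Σ_s Σ_p Σ_i w (ΔX/X_exp)² over all datasets.

    ``model`` maps a conditions row (pandas Series, with the dataset
    attached as ``row.dataset``) to the calculated property value.  Points
    with a zero measured value are rejected (the relative residual is
    undefined there).
    """
    n_exp = sum(d.n_points for d in datasets)
    if n_exp == 0:
        raise ValueError("no experimental points")
    total = 0.0
    for d in datasets:
        if np.any(d.values == 0.0):
            raise ValueError(
                f"dataset ({d.system}, {d.prop}) has a zero measured value; "
                "relative residuals are undefined"
            )
        calc = _calc_values(d, model)
        total += float(np.sum(d.weights * ((d.values - calc) / d.values) ** 2))
    return total / n_exp


def aad_metrics(dataset: ExperimentalDataset, model: Callable) -> DeviationReport:
    """%AAD = (100/N) Σ |ΔX|/|X_exp| and AAD = (1/N) Σ |ΔX|."""
    calc = _calc_values(dataset, model)
    err = np.abs(dataset.values - calc)
    aad = float(np.mean(err))
    if np.any(dataset.values == 0.0):
        raise ValueError(
            f"dataset ({dataset.system}, {dataset.prop}) has a zero measured "
            "value; %AAD is undefined (AAD remains available)"
        )
    aad_pct = float(100.0 * np.mean(err / np.abs(dataset.values)))
    return DeviationReport(
        system=dataset.system, prop=dataset.prop, n_points=dataset.n_points,
        aad_percent=aad_pct, aad=aad,
    )


def estimate_hfus(
    T_fus: float,
    sle_data: Sequence[tuple[float, float]],
    solubility_model: Callable[[float, float], float],
    bounds_kJ: tuple[float, float] = (1.0, 60.0),
) -> float:
    """Enthalpy of fusion [J/mol] minimizing the SLE %AAD.

    Parameters
    ----------
    T_fus:
        Known melting temperature [K].
    sle_data:
        (T, x_sat) experimental solubility points.
    solubility_model:
        Maps (delta_h_fus [J/mol], T [K]) to the model solubility; the
        caller closes over solvent, pressure and activity model.
    bounds_kJ:
        Search window for Δh_fus in kJ/mol (bounded Brent minimization).
    """
    Ts = np.array([t for t, _ in sle_data])
    xs = np.array([x for _, x in sle_data])
    if np.any(xs <= 0):
        raise ValueError("solubility data must be positive")

    def loss(dh_kJ):
        calc = np.array([solubility_model(dh_kJ * 1e3, T) for T in Ts])
        return float(np.mean(np.abs(calc - xs) / xs))

    res = minimize_scalar(loss, bounds=bounds_kJ, method="bounded",
                          options={"xatol": 1e-4})
    span = loss(bounds_kJ[0]) - loss(bounds_kJ[1])
    if abs(res.fun) > 0 and abs(span) < 1e-12:
        raise RuntimeError("SLE data are insensitive to the enthalpy of fusion")
    return float(res.x * 1e3)


# Joback fragment contributions to the enthalpy of fusion [kJ/mol];
# partial table covering the saturated fragments used here
JOBACK_HFUS_TABLE: dict[str, float] = {
    "-CH3": 0.908,
    "-CH2-": 2.590,
    ">CH-": 0.749,
    ">C<": -1.460,
    "-COO-": 4.370,       # ester
    "ring-CH2-": 0.490,
    "ring>CH-": 3.243,
}
_JOBACK_HFUS_CONSTANT = -0.88  # kJ/mol


def joback_hfus(fragments: dict[str, int]) -> float:
    """Joback group-contribution enthalpy of fusion [kJ/mol].

    Δh_fus = −0.88 + Σ_k n_k Δh_k over the fragment decomposition; an
    empty decomposition returns the method's constant alone.  Unknown
    fragments are rejected by name.
    """
    total = _JOBACK_HFUS_CONSTANT
    for frag, n in fragments.items():
        if frag not in JOBACK_HFUS_TABLE:
            raise KeyError(f"fragment {frag!r} not in the Joback fusion table")
        if n < 0:
            raise ValueError("fragment counts must be nonnegative")
        total += n * JOBACK_HFUS_TABLE[frag]
    return float(total)
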