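"""Synthetic systems and datasets for testing and demonstration.

The toy binaries are built from hypothetical single groups so that exact
limits (ideal gas, indistinguishable components, closed-form site
fractions) can be checked without the full parameter matrix; the dataset
generators produce solid-liquid and vapor-liquid data from closed forms or
the equation of state itself, with optional relative Gaussian noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .eos import GammaMieEoS
from .groups import FusionData, GroupLibrary, MieGroup
from .metrics import ExperimentalDataset

__all__ = [
    "toy_library",
    "toy_nonassociating_binary",
    "toy_associating_binary",
    "ideal_sle_dataset",
    "noisy_vle_dataset",
]


def toy_library(epsilon_12: float | None = None) -> GroupLibrary:
    """Two single-segment Mie groups A and B with an optional fitted ε_12.

    Group B is slightly larger and more cohesive than A; with the default
    combining-rule cross interaction the binary is nearly ideal, and
    lowering ``epsilon_12`` below the combining-rule value opens a
    miscibility gap.
    """
    groups = [
        MieGroup("A", 1, 1.0, 4.0, 12.0, 6.0, 250.0, {}, 50.0),
        MieGroup("B", 1, 1.0, 4.4, 12.0, 6.0, 320.0, {}, 70.0),
    ]
    unlike = []
    if epsilon_12 is not None:
        from .groups import UnlikeDispersionEntry

        unlike.append(UnlikeDispersionEntry(("A", "B"), epsilon_12, None))
    lib = GroupLibrary(groups, unlike, [])
    lib.build_molecule("toyA", {"A": 1})
    lib.build_molecule("toyB", {"B": 1})
    return lib


def toy_nonassociating_binary(epsilon_12: float | None = None) -> GammaMieEoS:
    return GammaMieEoS(toy_library(epsilon_12), ["toyA", "toyB"])


def toy_associating_binary(
    eps_hb: float = 1800.0, k_hb: float = 100.0
) -> GammaMieEoS:
    """One self-associating component (one H + one e1 site) plus an inert one."""
    from .groups import AssociationEntry

    groups = [
        MieGroup("D", 1, 1.0, 3.2, 14.0, 6.0, 300.0, {"H": 1, "e1": 1}, 40.0),
        MieGroup("E", 1, 1.0, 4.2, 12.0, 6.0, 260.0, {}, 60.0),
    ]
    assoc = [AssociationEntry(("D", "H"), ("D", "e1"), eps_hb, k_hb)]
    lib = GroupLibrary(groups, [], assoc)
    lib.build_molecule("toyD", {"D": 1})
    lib.build_molecule("toyE", {"E": 1})
    return GammaMieEoS(lib, ["toyD", "toyE"])


def ideal_sle_dataset(
    delta_h_fus: float,
    T_fus: float,
    T_grid,
    noise_rel: float = 0.0,
    seed: int | None = None,
    system: str = "synthetic-sle",
) -> ExperimentalDataset:
    """Ideal-solution solubility points from the closed form.

    x_sat(T) = exp[−(Δh_fus/R)(1/T − 1/T_fus)], optionally perturbed with
    relative Gaussian noise of standard deviation ``noise_rel``.
    Δh_fus in J/mol, temperatures in K.
    """
    from .eos import R

    T_grid = np.asarray(T_grid, dtype=float)
    if np.any(T_grid > T_fus):
        raise ValueError("SLE temperatures must not exceed T_fus")
    x = np.exp(-(delta_h_fus / R) * (1.0 / T_grid - 1.0 / T_fus))
    if noise_rel > 0.0:
        rng = np.random.default_rng(seed)
        x = x * (1.0 + noise_rel * rng.standard_normal(len(x)))
        x = np.clip(x, 1e-12, 1.0)
    cond = pd.DataFrame({"T": T_grid, "P": np.full(len(T_grid), 101325.0)})
    return ExperimentalDataset(system=system, prop="x_sat", conditions=cond, values=x)


def noisy_vle_dataset(
    eos: GammaMieEoS,
    P: float,
    x_grid,
    noise_rel: float = 0.0,
    seed: int | None = None,
    system: str = "synthetic-vle",
) -> ExperimentalDataset:
    """Bubble temperatures from the model itself plus relative noise."""
    from .equilibria import bubble_point

    x_grid = np.asarray(x_grid, dtype=float)
    Ts = []
    for x1 in x_grid:
        res = bubble_point(eos, np.array([x1, 1.0 - x1]), P=P)
        Ts.append(res.T)
    Ts = np.asarray(Ts)
    if noise_rel > 0.0:
        rng = np.random.default_rng(seed)
        Ts = Ts * (1.0 + noise_rel * rng.standard_normal(len(Ts)))
    cond = pd.DataFrame({"x1": x_grid, "P": np.full(len(x_grid), P)})
    return ExperimentalDataset(system=system, prop="T_bubble", conditions=cond, values=Ts)
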