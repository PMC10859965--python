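"""Group parameter library for the SAFT-γ Mie group-contribution approach.

Molecules are declared as multisets of functional groups (e.g. the cyclic
ester group ``cCOO`` plus ring ``cCH2`` groups for a ring lactone).  Each
group carries Mie-segment parameters (segment count ν*, shape factor S,
diameter σ, exponents λ^r/λ^a, dispersion energy ε/k_B) and, where relevant,
hydrogen-bonding association sites of type H, e1 or e2.  Unlike dispersion
interactions are either fitted values or fall back to the standard combining
rules; association strengths are defined only for the donor/acceptor pairs
listed in the parameter table and are exactly zero otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

SITE_TYPES = ("H", "e1", "e2")

__all__ = [
    "MieGroup",
    "UnlikeDispersionEntry",
    "AssociationEntry",
    "Molecule",
    "FusionData",
    "GroupLibrary",
    "load_group_library",
    "default_library",
    "n_alkane",
    "primary_alcohol",
    "secondary_alcohol",
    "methyl_ketone",
    "n_alkyl_acetate",
]


@dataclass(frozen=True)
class MieGroup:
    """Like (self-interaction) parameters of one functional group."""

    name: str
    nu_star: int                 # segments per group
    shape_factor: float          # S_k, dimensionless in [0, 1]
    sigma: float                 # segment diameter [Å]
    lambda_r: float              # repulsive Mie exponent
    lambda_a: float              # attractive Mie exponent
    epsilon_over_kB: float       # dispersion well depth [K]
    site_counts: Mapping[str, int] = field(default_factory=dict)
    mw: float = 0.0              # fragment molar mass [g/mol]

    def __post_init__(self) -> None:
        if self.nu_star < 1 or int(self.nu_star) != self.nu_star:
            raise ValueError(f"{self.name}: nu_star must be a positive integer")
        if not 0.0 <= self.shape_factor <= 1.0:
            raise ValueError(f"{self.name}: shape factor outside [0, 1]")
        if self.sigma <= 0.0:
            raise ValueError(f"{self.name}: sigma must be positive")
        if not self.lambda_r > self.lambda_a >= 0.0:
            raise ValueError(f"{self.name}: need lambda_r > lambda_a >= 0")
        if self.epsilon_over_kB < 0.0:
            raise ValueError(f"{self.name}: epsilon must be nonnegative")
        for site, n in self.site_counts.items():
            if site not in SITE_TYPES:
                raise ValueError(f"{self.name}: unknown site type {site!r}")
            if n < 0 or int(n) != n:
                raise ValueError(f"{self.name}: site counts must be nonnegative integers")


@dataclass(frozen=True)
class UnlikeDispersionEntry:
    """Fitted unlike dispersion entry for an unordered group pair.

    ``epsilon_over_kB`` or ``lambda_r`` equal to ``None`` means "apply the
    combining rule" (printed as CR in the parameter table).
    """

    pair: tuple[str, str]
    epsilon_over_kB: float | None
    lambda_r: float | None

    @property
    def provenance(self) -> str:
        if self.epsilon_over_kB is None and self.lambda_r is None:
            return "combining-rule"
        return "fitted"


@dataclass(frozen=True)
class AssociationEntry:
    """Association energy/bonding volume for a directed (group, site) pair."""

    donor: tuple[str, str]       # (group k, site a)
    acceptor: tuple[str, str]    # (group l, site b)
    epsilon_HB_over_kB: float    # [K]
    K_HB: float                  # bonding volume [Å³]

    def __post_init__(self) -> None:
        if self.epsilon_HB_over_kB <= 0.0:
            raise ValueError(f"association {self.donor}-{self.acceptor}: epsilon_HB must be positive")
        if self.K_HB <= 0.0:
            raise ValueError(f"association {self.donor}-{self.acceptor}: K_HB must be positive")


@dataclass(frozen=True)
class Molecule:
    """A named multiset of group counts."""

    name: str
    groups: Mapping[str, int]
    cas: str | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError(f"{self.name}: molecule needs at least one group")
        for g, n in self.groups.items():
            if n < 1 or int(n) != n:
                raise ValueError(f"{self.name}: group count for {g} must be a positive integer")


@dataclass(frozen=True)
class FusionData:
    """Melting point and (optionally) molar enthalpy of fusion."""

    molecule: str
    T_fus: float                     # [K]
    delta_h_fus: float | None = None  # [J/mol]
    delta_cp: float | None = None     # [J/mol/K], usually unavailable

    def __post_init__(self) -> None:
        if self.T_fus <= 0.0:
            raise ValueError(f"{self.molecule}: T_fus must be positive")
        if self.delta_h_fus is not None and self.delta_h_fus <= 0.0:
            raise ValueError(f"{self.molecule}: delta_h_fus must be positive when present")


def _pair_key(k: str, l: str) -> tuple[str, str]:
    return (k, l) if k <= l else (l, k)


class GroupLibrary:
    """The full group-interaction matrix with combining-rule fallbacks."""

    def __init__(
        self,
        groups: list[MieGroup],
        unlike: list[UnlikeDispersionEntry],
        association: list[AssociationEntry],
        molecules: list[Molecule] | None = None,
        fusion: list[FusionData] | None = None,
    ) -> None:
        self.groups: dict[str, MieGroup] = {}
        for g in groups:
            if g.name in self.groups:
                raise ValueError(f"duplicate group {g.name}")
            self.groups[g.name] = g

        self.unlike: dict[tuple[str, str], UnlikeDispersionEntry] = {}
        for e in unlike:
            key = _pair_key(*e.pair)
            for name in key:
                if name not in self.groups:
                    raise ValueError(f"unlike entry {e.pair}: unknown group {name}")
            if key in self.unlike and self.unlike[key] != UnlikeDispersionEntry(key, e.epsilon_over_kB, e.lambda_r):
                raise ValueError(f"conflicting duplicate unlike entry for pair {key}")
            self.unlike[key] = UnlikeDispersionEntry(key, e.epsilon_over_kB, e.lambda_r)

        # association is looked up symmetrically in ((k,a),(l,b))
        self.association: dict[tuple[tuple[str, str], tuple[str, str]], AssociationEntry] = {}
        for e in association:
            for name, site in (e.donor, e.acceptor):
                if name not in self.groups:
                    raise ValueError(f"association entry {e.donor}-{e.acceptor}: unknown group {name}")
                if site not in SITE_TYPES:
                    raise ValueError(f"association entry {e.donor}-{e.acceptor}: unknown site {site}")
            key = tuple(sorted((e.donor, e.acceptor)))
            if key in self.association:
                old = self.association[key]
                if (old.epsilon_HB_over_kB, old.K_HB) != (e.epsilon_HB_over_kB, e.K_HB):
                    raise ValueError(f"conflicting duplicate association entry for {key}")
            self.association[key] = e

        self.molecules: dict[str, Molecule] = {}
        for m in molecules or []:
            self.add_molecule(m)
        self.fusion: dict[str, FusionData] = {f.molecule: f for f in (fusion or [])}

    # -- molecules ---------------------------------------------------------

    def add_molecule(self, molecule: Molecule) -> Molecule:
        missing = [g for g in molecule.groups if g not in self.groups]
        if missing:
            raise ValueError(f"molecule {molecule.name}: groups {missing} not in library")
        self.molecules[molecule.name] = molecule
        return molecule

    def build_molecule(self, name: str, group_counts: Mapping[str, int], cas: str | None = None) -> Molecule:
        return self.add_molecule(Molecule(name=name, groups=dict(group_counts), cas=cas))

    def get_molecule(self, name: str) -> Molecule:
        if name not in self.molecules:
            raise KeyError(f"unknown molecule {name!r}; declare it with build_molecule")
        return self.molecules[name]

    def molar_mass(self, molecule: str | Molecule) -> float:
        """Molar mass [g/mol] from the group fragment masses."""
        mol = self.get_molecule(molecule) if isinstance(molecule, str) else molecule
        return sum(self.groups[g].mw * n for g, n in mol.groups.items())

    # -- unlike interactions ----------------------------------------------

    def resolve_unlike(self, k: str, l: str) -> tuple[float, float, float, float]:
        """Return (sigma_kl [Å], epsilon_kl [K], lambda_r_kl, lambda_a_kl).

        Fitted table entries override the combining rules; entries marked CR
        (or pairs absent from the table entirely) use the standard rules:
        arithmetic σ, geometric ε scaled by the σ³ ratio, and
        3 + sqrt((λ_kk−3)(λ_ll−3)) for exponents.
        """
        gk, gl = self.groups[k], self.groups[l]
        sigma_kl = 0.5 * (gk.sigma + gl.sigma)
        eps_cr = (
            math.sqrt(gk.sigma**3 * gl.sigma**3) / sigma_kl**3
            * math.sqrt(gk.epsilon_over_kB * gl.epsilon_over_kB)
        )
        lam_r_cr = 3.0 + math.sqrt((gk.lambda_r - 3.0) * (gl.lambda_r - 3.0))
        # λ^a stays at 6 unless both like values deviate from the default 6
        if gk.lambda_a != 6.0 and gl.lambda_a != 6.0:
            lam_a = 3.0 + math.sqrt((gk.lambda_a - 3.0) * (gl.lambda_a - 3.0))
        elif gk.lambda_a != 6.0 or gl.lambda_a != 6.0:
            lam_a = 6.0
        else:
            lam_a = 6.0

        entry = self.unlike.get(_pair_key(k, l))
        if entry is None and k != l:
            warnings.warn(
                f"no tabulated unlike entry for ({k}, {l}); using combining rules",
                stacklevel=2,
            )
        eps = entry.epsilon_over_kB if entry is not None and entry.epsilon_over_kB is not None else eps_cr
        lam_r = entry.lambda_r if entry is not None and entry.lambda_r is not None else lam_r_cr
        return sigma_kl, eps, lam_r, lam_a

    # -- association -------------------------------------------------------

    def association_entry(self, k: str, a: str, l: str, b: str) -> AssociationEntry | None:
        """Entry for site ``a`` on group ``k`` with site ``b`` on group ``l``.

        Returns ``None`` (zero association strength) for unlisted pairs.
        Lookup is symmetric in the two (group, site) arguments.
        """
        return self.association.get(tuple(sorted(((k, a), (l, b)))))

    def association_strength_parameters(self, k: str, a: str, l: str, b: str) -> tuple[float, float]:
        """(ε^HB/k_B [K], K^HB [Å³]); (0, 0) when the pair does not associate."""
        e = self.association_entry(k, a, l, b)
        return (0.0, 0.0) if e is None else (e.epsilon_HB_over_kB, e.K_HB)

    # -- validation & IO ---------------------------------------------------

    def validate(self) -> None:
        """Check cross-references: every group used by a molecule must exist."""
        for m in self.molecules.values():
            for g in m.groups:
                if g not in self.groups:
                    raise ValueError(f"molecule {m.name} references unknown group {g}")
        for f in self.fusion.values():
            # fusion data for undeclared molecules is allowed (solvents added later)
            if f.T_fus <= 0:
                raise ValueError(f"fusion data {f.molecule}: bad T_fus")

    def to_frames(self) -> dict[str, pd.DataFrame]:
        like = pd.DataFrame(
            [
                {
                    "name": g.name,
                    "nu_star": g.nu_star,
                    "shape_factor": g.shape_factor,
                    "sigma": g.sigma,
                    "lambda_r": g.lambda_r,
                    "lambda_a": g.lambda_a,
                    "epsilon_over_kB": g.epsilon_over_kB,
                    "n_H": g.site_counts.get("H", 0),
                    "n_e1": g.site_counts.get("e1", 0),
                    "n_e2": g.site_counts.get("e2", 0),
                    "mw": g.mw,
                }
                for g in self.groups.values()
            ]
        )
        unlike = pd.DataFrame(
            [
                {
                    "group_k": e.pair[0],
                    "group_l": e.pair[1],
                    "epsilon_over_kB": "CR" if e.epsilon_over_kB is None else "%.17g" % e.epsilon_over_kB,
                    "lambda_r": "CR" if e.lambda_r is None else "%.17g" % e.lambda_r,
                }
                for e in self.unlike.values()
            ]
        )
        assoc = pd.DataFrame(
            [
                {
                    "group_k": e.donor[0],
                    "site_a": e.donor[1],
                    "group_l": e.acceptor[0],
                    "site_b": e.acceptor[1],
                    "epsilon_HB_over_kB": e.epsilon_HB_over_kB,
                    "K_HB": e.K_HB,
                }
                for e in self.association.values()
            ]
        )
        return {"like": like, "unlike": unlike, "association": assoc}

    def write(self, directory: str | Path) -> None:
        """Write the three parameter tables as CSV (round-trips bit-exactly)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frames = self.to_frames()
        frames["like"].to_csv(directory / "like_groups.csv", index=False, float_format="%.17g")
        frames["unlike"].to_csv(directory / "unlike_dispersion.csv", index=False)
        frames["association"].to_csv(directory / "association.csv", index=False, float_format="%.17g")


# -- loaders ---------------------------------------------------------------


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True, float_precision="round_trip")


def _parse_cr(value) -> float | None:
    if isinstance(value, str) and value.strip().upper() == "CR":
        return None
    if pd.isna(value):
        return None
    return float(value)


def load_group_library(
    like_csv: str | Path,
    unlike_csv: str | Path | None = None,
    association_csv: str | Path | None = None,
    molecules_yaml: str | Path | None = None,
    fusion_csv: str | Path | None = None,
) -> GroupLibrary:
    """Load a :class:`GroupLibrary` from delimited parameter files."""
    like = _read_csv(like_csv)
    groups = [
        MieGroup(
            name=str(r["name"]),
            nu_star=int(r["nu_star"]),
            shape_factor=float(r["shape_factor"]),
            sigma=float(r["sigma"]),
            lambda_r=float(r["lambda_r"]),
            lambda_a=float(r["lambda_a"]),
            epsilon_over_kB=float(r["epsilon_over_kB"]),
            site_counts={
                s: int(r[f"n_{s}"]) for s in SITE_TYPES if f"n_{s}" in r and int(r[f"n_{s}"]) > 0
            },
            mw=float(r.get("mw", 0.0)),
        )
        for _, r in like.iterrows()
    ]

    unlike: list[UnlikeDispersionEntry] = []
    if unlike_csv is not None:
        for _, r in _read_csv(unlike_csv).iterrows():
            unlike.append(
                UnlikeDispersionEntry(
                    pair=(str(r["group_k"]), str(r["group_l"])),
                    epsilon_over_kB=_parse_cr(r["epsilon_over_kB"]),
                    lambda_r=_parse_cr(r["lambda_r"]),
                )
            )

    association: list[AssociationEntry] = []
    if association_csv is not None:
        for _, r in _read_csv(association_csv).iterrows():
            association.append(
                AssociationEntry(
                    donor=(str(r["group_k"]), str(r["site_a"])),
                    acceptor=(str(r["group_l"]), str(r["site_b"])),
                    epsilon_HB_over_kB=float(r["epsilon_HB_over_kB"]),
                    K_HB=float(r["K_HB"]),
                )
            )

    molecules: list[Molecule] = []
    if molecules_yaml is not None:
        with open(molecules_yaml) as fh:
            records = yaml.safe_load(fh) or {}
        for name, rec in records.items():
            molecules.append(
                Molecule(name=str(name), groups=dict(rec["groups"]), cas=str(rec.get("cas")) if rec.get("cas") else None)
            )

    fusion: list[FusionData] = []
    if fusion_csv is not None:
        for _, r in _read_csv(fusion_csv).iterrows():
            dh = None if pd.isna(r["delta_h_fus"]) else float(r["delta_h_fus"]) * 1e3  # kJ/mol → J/mol
            fusion.append(FusionData(molecule=str(r["molecule"]), T_fus=float(r["T_fus"]), delta_h_fus=dh))

    lib = GroupLibrary(groups, unlike, association, molecules, fusion)
    lib.validate()
    return lib


def default_library() -> GroupLibrary:
    """The library shipped with the package (cCOO matrix, lactones, solvents)."""
    root = resources.files("saftgmie") / "data"
    return load_group_library(
        like_csv=str(root / "like_groups.csv"),
        unlike_csv=str(root / "unlike_dispersion.csv"),
        association_csv=str(root / "association.csv"),
        molecules_yaml=str(root / "molecules.yaml"),
        fusion_csv=str(root / "fusion.csv"),
    )


# -- homologous series helpers --------------------------------------------


def n_alkane(n: int) -> Molecule:
    """CH3-(CH2)_{n-2}-CH3 for n >= 2."""
    if n < 2:
        raise ValueError("n_alkane requires n >= 2")
    groups = {"CH3": 2}
    if n > 2:
        groups["CH2"] = n - 2
    return Molecule(name=f"n-alkane-C{n}", groups=groups)


def primary_alcohol(n: int) -> Molecule:
    """CH3-(CH2)_{n-2}-OH modelled with a terminal CH2OH group, n >= 2."""
    if n < 2:
        raise ValueError("primary_alcohol requires n >= 2 (use methanol for n = 1)")
    groups = {"CH3": 1, "CH2OH": 1}
    if n > 2:
        groups["CH2"] = n - 2
    return Molecule(name=f"1-alcohol-C{n}", groups=groups)


def secondary_alcohol(n: int) -> Molecule:
    """2-alcohols modelled with a CHOH group, n >= 3."""
    if n < 3:
        raise ValueError("secondary_alcohol requires n >= 3")
    groups = {"CH3": 2, "CHOH": 1}
    if n > 3:
        groups["CH2"] = n - 3
    return Molecule(name=f"2-alcohol-C{n}", groups=groups)


def methyl_ketone(n: int) -> Molecule:
    """2-ketones (butan-2-one and longer) with the CH3CO group, n >= 4."""
    if n < 4:
        raise ValueError("methyl_ketone requires n >= 4 (use acetone for n = 3)")
    groups = {"CH3CO": 1, "CH3": 1}
    if n > 4:
        groups["CH2"] = n - 4
    return Molecule(name=f"2-ketone-C{n}", groups=groups)


def n_alkyl_acetate(n_alkyl: int) -> Molecule:
    """Linear alkyl acetates CH3-COO-CnH2n+1, n_alkyl >= 1."""
    if n_alkyl < 1:
        raise ValueError("n_alkyl_acetate requires n_alkyl >= 1")
    groups = {"COO": 1, "CH3": 2}
    if n_alkyl > 1:
        groups["CH2"] = n_alkyl - 1
    return Molecule(name=f"acetate-C{n_alkyl}", groups=groups)
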