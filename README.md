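# saftgmie

A SAFT-γ Mie group-contribution equation of state for saturated lactones
(cyclic esters such as γ-butyrolactone and ε-caprolactone) and the solvents
they are commonly processed in — alkanes, alcohols, ketones, linear esters,
aromatics, water and CO₂ — with solvers for every common phase-equilibrium
problem: vapor–liquid, liquid–liquid, solid–liquid (solubility), azeotropes,
eutectic points and three-phase vapor–liquid–liquid states.

Lactones are of growing interest as bio-based polar aprotic solvents and
polymer precursors, but experimental thermophysical data for them are
sparse. A group-contribution model closes that gap: each molecule is a
multiset of functional groups, and all thermodynamic properties follow from
transferable group parameters. The distributed parameter matrix includes a
cyclic-ester group **cCOO** (two fused Mie segments, two electron-donor
`e1` association sites) together with its interactions with the ring
(`cCH2`, `cCH`), alkyl (`CH3`, `CH2`, `CH`), hydroxyl (`CH3OH`, `CH2OH`,
`CHOH`), carbonyl (`CH3COCH3`, `CH3CO`), linear-ester (`COO`), aromatic
(`aCH`, `aCCH3`, `aCCH2`), water and CO₂ groups.

## The model

Molecules are heteronuclear chains of fused spherical segments interacting
through Mie potentials of variable range,

    Φ_kl(r) = C ε_kl [ (σ_kl/r)^λʳ_kl − (σ_kl/r)^λᵃ_kl ],
    C = λʳ/(λʳ−λᵃ) · (λʳ/λᵃ)^{λᵃ/(λʳ−λᵃ)},

with short-ranged square-well association sites where hydrogen bonding
matters. The Helmholtz energy is

    A = A_ideal + A_monomer + A_chain + A_association,

where the monomer term is a third-order Barker–Henderson perturbation
expansion about a hard-sphere reference, the chain term connects segments
using molecularly averaged Mie parameters, and the association term is the
Wertheim TPT1 mass-action solution. Pressure and chemical potentials are
exact first derivatives of A (complex-step differentiation), from which
densities, fugacity and activity coefficients, vaporization and excess
enthalpies, and all phase equilibria follow. Solid–liquid solubility treats
the solid as pure:

    ln(x_i γ_i) = −(Δh_i^fus / R) (1/T − 1/T_i^fus).

## Worked example

```python
import saftgmie as sg
from saftgmie.properties import density, vaporization_enthalpy
from saftgmie.equilibria import eutectic

lib = sg.default_library()                       # the shipped parameter matrix

# pure γ-butyrolactone (oxolan-2-one = cCOO + 3 cCH2)
gbl = sg.GammaMieEoS(lib, ["oxolan-2-one"])
rho = density(gbl, 298.15, 101325.0, [1.0], phase="liquid")
print(rho * gbl.molar_masses()[0])               # 1119.97  kg/m³ at 25 °C, 1 atm
print(vaporization_enthalpy(gbl, 350.0) / 1e3)   # 51.44    kJ/mol at 350 K

# eutectic of ε-caprolactone + cyclohexane at 1 atm
mix = sg.GammaMieEoS(lib, ["oxepan-2-one", "cyclohexane"])
sols = eutectic(mix, lib.fusion["oxepan-2-one"], lib.fusion["cyclohexane"],
                101325.0, T_min=220.0)
print(sols[0])                                   # (0.0789, 264.76)
```

The last line is the predicted eutectic: a liquid with ε-caprolactone mole
fraction 0.079 coexisting with both pure solids at 264.8 K. The lactone is
strongly non-ideal in cyclohexane (its activity coefficient at that
composition is ≈ 10.7), which pushes the eutectic far toward the
cyclohexane side — the same mixture also demixes into two liquids at
slightly higher temperatures, which the `lle` and `hetero_azeotrope`
solvers expose.

A command-line interface mirrors the library:

```bash
saftgmie eutectic --components "oxepan-2-one,cyclohexane" --pressure 1atm --out eut.csv
saftgmie sle --components "oxepan-2-one,methanol" --temperatures 240,250,260 --out sle.csv
saftgmie joback --fragments "-COO-:2,-CH2-:4,-CH3:2"
```

## Layout

- `src/saftgmie/groups.py` — parameter library, combining rules, molecules
- `src/saftgmie/eos.py` — the Helmholtz free-energy surface
- `src/saftgmie/properties.py` — P, μ, densities, enthalpies, activities
- `src/saftgmie/equilibria.py` — VLE/LLE/SLE/azeotrope/eutectic/VLLE solvers
- `src/saftgmie/metrics.py` — estimation objective, %AAD/AAD, Joback
- `src/saftgmie/fixtures.py` — synthetic systems and datasets
- `src/saftgmie/data/` — the parameter tables as versioned CSV/YAML
- `docs/methods.md` — model formulation, numerics and limitations
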