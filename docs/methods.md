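# Model formulation, numerics and scope

## Free-energy model

`saftgmie` implements the SAFT-γ Mie group-contribution equation of state.
A molecule *i* is a multiset of groups *k*; group *k* contributes ν*\_k*
identical spherical segments, scaled by a shape factor S\_k ∈ [0, 1] that
measures how much of the segment participates in the molecular properties.
Segments interact through Mie (generalized Lennard-Jones) potentials with
pair parameters (σ\_kl, ε\_kl, λʳ\_kl, λᵃ\_kl); hydrogen bonding is
represented by square-well association sites of types H, e1 and e2 placed
on the groups.

The total Helmholtz energy is the sum of four contributions:

* **Ideal.** Σ x\_i ln(ρ\_i Λ³) − 1 with a fixed thermal wavelength
  Λ = 1 Å. The convention shifts absolute entropies only; every property
  the package reports is either a derivative, an equal-temperature
  difference, or an equality of chemical potentials, and is therefore
  independent of Λ. Enthalpic properties are computed from *residual*
  quantities exclusively, so no ideal-gas heat-capacity input is needed.

* **Monomer.** Third-order Barker–Henderson perturbation expansion about a
  Boublík hard-sphere reference. The temperature-dependent diameters
  d\_kk(T) = ∫₀^σ [1 − exp(−βΦ)] dr are evaluated with 64-point
  Gauss–Legendre quadrature (relative error far below the solver
  tolerances, and smooth in T so that complex-step temperature derivatives
  are exact). The first- and second-order mean-attractive terms use the
  standard effective-packing-fraction mapping (the 4×4 c-matrix in 1/λ),
  and the second/third-order corrections use the published φ-coefficient
  correlations f₁…f₆ of the Mie-fluid formulation. The implementation was
  checked against the Lennard-Jones limit (λ = 12-6, single segment):
  critical temperature T\*c ≈ 1.313 and saturated liquid densities within
  ~2 % of simulation data, and against well-characterized real fluids
  (model CO₂ saturation pressure at 273 K within 0.2 % of experiment;
  ethane normal boiling point within 0.7 K).

* **Chain.** −Σ x\_i (n\_{s,i} − 1) ln g^Mie(d̄\_ii) with molecularly
  averaged parameters (z-weighted over the groups of molecule *i*) and the
  usual g^HS·exp(βε g₁/g^HS + (βε)² g₂/g^HS) closure. Cyclic molecules
  (cyclohexane, the lactone rings) use the same chain expression; ring
  effects are carried by the dedicated cyclic groups (cCH2, cCH, cCOO)
  exactly as the parameter tables assume.

* **Association.** Wertheim TPT1. The mass-action system
  X\_a = 1/(1 + ρ Σ\_b s\_b X\_b Δ\_ab) is solved by damped successive
  substitution (damping 0.5, warm-started between states) followed by
  Newton polishing to a residual of 10⁻¹². The association strength is
  Δ = [exp(βε^HB) − 1]·K^HB·I(ρ\*, T\*) with the dimensionless
  association-kernel correlation of the Lennard-Jones reference fluid
  (polynomial in reduced segment density ρ\* = ρ\_s σ\_x³ and reduced
  temperature T\* = kT/ε\_kl of the group pair carrying the sites). This is
  the kernel convention the shipped bonding volumes (10²–10³ Å³) presume;
  with it, model water, methanol, ethanol and acetone reproduce their
  normal boiling points to a few kelvin, whereas a bare contact-value
  kernel mis-scales Δ by roughly two orders of magnitude. The correlation
  is fitted up to ρ\* ≈ 1; beyond that the extrapolation is capped smoothly
  (C¹ at ρ\* = 1) so unphysically dense states retain a well-behaved
  pressure. For states outside the kernel's validity the correlation can
  turn negative; it is then clamped to zero (no association).

## Derivatives

Pressure, chemical potentials and entropy are first derivatives of A.
These are evaluated by complex-step differentiation with a relative step
of 10⁻⁵⁰: the free-energy code is written to be analytic in (T, V, N), so
the imaginary part yields the derivative with no truncation or subtractive
cancellation error. The association term is evaluated through the
Michelsen Q-form with the site fractions converged at the real part of the
state and then frozen; because the Q-form is stationary in X, first
derivatives remain exact. Central finite differences serve as the
independent cross-check in the test suite (agreement to 10⁻⁷ relative).

## Parameters

The parameter tables under `src/saftgmie/data/` are versioned CSV/YAML:
like group parameters, unlike dispersion energies (with "CR" markers where
the combining rules apply), association energies/bonding volumes, molecule
decompositions and fusion data. Units are Å, Å³ and K (ε/k\_B convention).
Combining rules: arithmetic σ, geometric ε scaled by the σ³ ratio, and
λ\_kl = 3 + √((λ\_kk−3)(λ\_ll−3)); the attractive exponent stays at the
default value 6 unless both like values differ from 6 (only CO₂ does).
Pairs printed as ε = 0 are stored and used as written (no cross
dispersion). Fitted table entries always override the rules. Re-estimation
of group parameters against user datasets is available through
`metrics.objective`; the shipped values are never modified by the package.

## Solvers and numerical choices

* **Density.** Safeguarded Newton from phase-specific seeds (vapor: ideal
  gas; liquid: packing fraction ≈ 0.5), with a sign-change scan over
  packing fractions (10⁻¹², 0.72) and Brent refinement as fallback. All
  mechanically stable roots can be listed; with no phase hint the lowest
  molar Gibbs energy root is returned. A "liquid" request fails loudly if
  no root with packing fraction above 0.15 exists — silently returning a
  vapor root would corrupt stability analyses.
* **Pure saturation.** Spinodal bracketing from the pressure isotherm,
  then Newton on μ_L(P) − μ_V(P) with d(Δμ)/dP = v_L − v_V, densities
  warm-started; tolerance 10⁻¹⁰ on Δμ/RT.
* **Bubble/dew.** Successive substitution on the vapor (liquid)
  composition inside a secant loop on T (or a pressure-multiplier loop at
  fixed T), initialized from Raoult ratios of the pure saturation
  pressures. Convergence: |ln Σy| < 10⁻¹⁰; converged results carry the
  equality-of-fugacity residual (≤ 10⁻⁸ required by the tests).
* **LLE.** Mixing-Gibbs scan on a Δx = 0.02 grid, non-convexity detected
  by a lower-hull construction, then Newton on the two equal-fugacity
  conditions. Compositions without liquid density roots are excluded from
  the scan (the pure-liquid reference only shifts the curve linearly, so
  missing references cannot create spurious gaps).
* **SLE.** ln(x γ) = −(Δh^fus/R)(1/T − 1/T^fus) with the solid pure and
  the Δc_p term neglected (it is unknown for most of the molecules
  covered). Solved by safeguarded secant; `liquidus_roots` returns *all*
  roots on a composition grid, since a miscibility gap can put three
  roots on one branch.
* **Eutectic.** Intersection of the two liquidus branches,
  x₁^sat(T) + x₂^sat(T) = 1. A descending temperature scan seeds a 2×2
  Newton solve in (x₁, T) on both solid-liquid conditions for a single
  liquid. All crossings are reported ordered in T; when a miscibility gap
  interferes the higher-T crossing lies inside the unstable region (the
  physical assembly there is solid-liquid-liquid), so the
  lowest-temperature crossing is the stable eutectic and is reported
  first.
* **Three-phase states.** `three_phase_vlle` scans pressure at fixed T for
  a window where two liquids coexist and locates Σy = 1 by bisection;
  `hetero_azeotrope` does the same in temperature at fixed pressure and
  reports the three-phase vapor composition as the azeotropic point. For
  lactone + short-alkane mixtures at low pressure the miscibility gap
  reaches the bubble surface, so the azeotropic locus continues through
  heteroazeotropic states; the azeotrope-composition trend with alkane
  length mixes the two solver routes accordingly.
* Gas constant R = 8.31446 J/(mol·K) via CODATA k_B·N_A; temperatures
  absolute.

## Synthetic systems

`fixtures.py` provides two-group toy fluids for exact limits (an ε = 0
ideal gas, identical-component binaries, a one-donor/one-acceptor
associating fluid with a closed-form site fraction) and dataset generators:
ideal-solution solubility curves from the closed form, and bubble-point
data from the model itself, both with optional seeded relative Gaussian
noise. These fixtures emulate the *structure* of real datasets (conditions,
values, unit weights), not real measurement error: noise is uncorrelated,
homoscedastic and unbiased. Tests passing on them demonstrate internal
consistency and invertibility of the estimation machinery, not agreement
with any laboratory measurement.

## Validation scope and known limitations

* The two eutectic predictions and the phase-diagram topology checks in
  the acceptance suite are genuine end-to-end computations from the
  shipped tables. Percentage-deviation tables against the full external
  experimental compilation are out of scope; `metrics` provides the
  %AAD/AAD machinery for users who have such data.
* Pure-fluid saturation pressures of long chains and strongly associating
  fluids deviate a few percent more here than the sub-percent deviations
  achievable with the original implementations — consistent with small
  formulation-revision differences (e.g. the third-order correlation
  constants) that the association-kernel and perturbation correlations
  absorb differently. Mixture activity coefficients, which control every
  acceptance-level prediction, benefit from cancellation of these pure-
  fluid offsets.
* The association-kernel correlation is an interpolation in (ρ\*, T\*);
  far outside its fitted window (very cold, very dense, or ε\_kl = 0
  pairs) the clamps described above apply.
* Solid phases are always treated as pure crystals: no solid solutions,
  no polymorphism, and no Δc_p correction to the solubility equation.
* Critical points are overestimated as with any classical EoS; near-
  critical CO₂ results (the 303 K three-phase state) are qualitative.
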