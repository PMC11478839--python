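# Methods

Thermodynamic formulation implemented by `slsorb`, with the modelling
decisions that are not forced by the equations themselves.

## 1. Sanchez–Lacombe equation of state

The lattice-fluid EoS of Sanchez and Lacombe (J. Phys. Chem. 80:2352,
1976; Macromolecules 11:1145, 1978) in reduced variables
ρ̃ = ρ/ρ\*, T̃ = T/T\*, P̃ = p/p\*:

    ρ̃² + P̃ + T̃ [ ln(1 − ρ̃) + (1 − 1/r) ρ̃ ] = 0

with chain size r = M p\* / (R T\* ρ\*) and R = 8.31446 MPa·cm³/(mol·K).
For polymers r → ∞ and the (1 − 1/r) factor is exactly 1; `slsorb`
represents this limit analytically rather than with a large finite r.

The residual can have up to three roots in ρ̃ ∈ (0, 1). `eos.find_reduced_roots`
brackets them on a dense scan grid and polishes with Brent's method;
`solve_reduced_density` picks the root by phase hint ("liquid" = densest,
"vapor" = most dilute) or, by default, by the lowest per-site Gibbs
energy

    g/(RT) = −ρ̃/T̃ + P̃/(ρ̃T̃) + (1 − ρ̃) ln(1 − ρ̃)/ρ̃ + (1/r) ln ρ̃,

which at a root of the EoS coincides with the chemical potential.

## 2. One-fluid mixing rules

With mass fractions w_i, close-packed volume fractions
φ_i = (w_i/ρ\*_i) / Σ_j (w_j/ρ\*_j):

- p\* = Σ_i Σ_j φ_i φ_j p\*_ij with p\*_ij = (1 − k_ij) √(p\*_i p\*_j),
- T\* = p\* / Σ_i (φ_i p\*_i / T\*_i),
- 1/ρ\* = Σ_i w_i/ρ\*_i (harmonic in mass fractions),
- v\* = R T\* / p\*, and segment numbers r_i = (M_i/ρ\*_i)/v\*.

Component chemical potentials follow from differentiating the total
Gibbs energy of the mixed lattice fluid at fixed T, p:

    μ_i/(RT) = ln(ρ̃ φ_i) + 1
             − r_i [ 1 + (1 + (1 − ρ̃)(1 − a_i)/ρ̃) ln(1 − ρ̃) ]
             − 2 ρ̃ r_i v\* P̄\*_i / (RT),

with a_i = (p\*_i/T\*_i) / Σ_j φ_j p\*_j/T\*_j and P̄\*_i = Σ_j φ_j p\*_ij.
This expression is verified in the test suite against finite differences
of an independent total-Gibbs oracle and against the Gibbs–Duhem
relation; it reduces to the classical pure-fluid μ when one component
vanishes.

## 3. Copolymer parameters

PHBV at HV mole fraction x is treated as a one-fluid blend of the two
homopolymer parameter sets. x is converted to an HV mass fraction with
monomer masses M_HB = 86.09 and M_HV = 100.12 g/mol, and the mixing
rules of §2 (k_ij = 0) give (T\*, p\*, ρ\*) at any composition. The
interpolated values reproduce the independently fitted intermediate
compositions to within 0.1 %.

## 4. PVT parameter estimation

`SanchezLacombePVT` minimises the mean absolute percentage error (MAPE)
between observed melt densities and liquid-root EoS predictions over
(T\*, p\*, ρ\*), using bounded Nelder–Mead. Identifiability note: on a
three-isobar grid the liquid density depends only weakly on p\*, so at
0.5 % multiplicative noise the fitted p\* (and to a lesser degree T\*)
can deviate from the generating value by several percent even though the
fit is at the true optimum of the objective; ρ\* is sharply identified.
The density-space metrics (MAPE, R²) remain tight.

## 5. Gas phase: Peng–Robinson anchor

The equilibrium condition equates each gas's chemical potential in the
polymer phase to its gas-phase value. The gas phase is described by the
Peng–Robinson EoS (Peng & Robinson, Ind. Eng. Chem. Fundam. 15:59,
1976) with van der Waals mixing and k_PR(CO2,CH4) = 0.09; fugacities
f_i are converted to an SL-consistent chemical potential through the
analytic ideal-gas form of the SL fluid,

    μ_i/(RT) = ln( f_i r_i v\* / (R T) ) + 1 − r_i,

which the tests verify against the low-pressure limit of the full SL μ.
An all-SL gas phase (`gas_phase="sl"`) is also provided and agrees with
the PR anchor in the Henry regime; PR is the default because cubic EoS
fugacities are the better description of the real gas phase at the
conditions of interest.

## 6. Sorption, swelling and selectivity

At fixed T and total pressure p with gas-phase mole fractions y_i, the
solver finds dissolved mass fractions w_i such that each polymer-phase
μ_i matches its gas-phase target (Brent in ln w for one gas; damped
Newton/hybrid in ln w for mixtures; residuals < 1e−8).

- Concentration: c_i = 22414 · w_i / ((1 − Σw) M_i) · ρ₀ in
  cm³(STP)/cm³ of unswollen polymer, ρ₀ the pure-polymer density at
  (T, 0.1 MPa).
- Solubility coefficient S_i = c_i / f_i with f_i in bar;
  solubility-selectivity α = S_CO2 / S_CH4; the "ideal" selectivity uses
  pure-gas S_i at the same total pressure, the mixed-gas value uses the
  coupled solve.
- Swelling is reported as the percent change of the **polymer-partial**
  density ρ_mix (1 − Σw_gas) relative to ρ₀, i.e. the change in polymer
  mass per unit volume of the swollen phase, so dissolved-gas mass does
  not mask the dilation.
- Semicrystalline correction: sorption occurs in the amorphous fraction
  only, S_amorphous = S_measured / (1 − x_c).

Known behaviour of this formulation, pinned by the unit tests: in
CO2/CH4 mixtures the CO2 uptake at matched own-fugacity is reduced by
the coabsorbed CH4 (competition), while the CH4 uptake is slightly
*enhanced* because CO2-induced swelling outweighs site competition for
the sparingly soluble gas.

## 7. Synthetic data and reproducibility

`generate_pvt` evaluates the liquid-root EoS on a pressure–temperature
grid and applies multiplicative Gaussian noise per replicate with a
seeded `numpy` generator; identical seeds give byte-identical tables.
The pipeline hashes its configuration (excluding the output directory)
and stamps every output table with the hash, so a run is reproducible
byte for byte from (config, seed).
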