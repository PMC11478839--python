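# slsorb

Sanchez–Lacombe (SL) lattice-fluid modelling of CO2/CH4 sorption in
poly(3-hydroxybutyrate-co-3-hydroxyvalerate) (PHBV) biopolymer membranes.

The package covers the full workflow for this material system:

- **Equation of state** (`slsorb.eos`): reduced SL EoS for pure fluids,
  including the analytic polymer (infinite chain) limit, with robust
  multi-root solving and Gibbs-based phase selection.
- **Mixtures** (`slsorb.mixture`): one-fluid mixing rules with binary
  interaction coefficients and component chemical potentials that are
  exact derivatives of the mixture Gibbs energy.
- **Copolymer parameters** (`slsorb.copolymer`): PHBV characteristic
  parameters at any HV content interpolated from the two homopolymer
  parameter sets through the mixing rules.
- **PVT fitting** (`slsorb.pvtfit`): an estimator with a scikit-learn
  style `fit`/`predict`/`score` interface that recovers (T\*, p\*, ρ\*)
  from melt-density data, plus MAPE and R² metrics.
- **Gas-phase fugacity** (`slsorb.fugacity`): Peng–Robinson fugacity
  coefficients for pure gases and CO2/CH4 mixtures.
- **Sorption** (`slsorb.sorption`): pure- and mixed-gas sorption
  equilibria at fixed temperature and pressure, concentrations in
  cm³(STP)/cm³, solubility coefficients and selectivities, swelling as
  the polymer-partial density change, crystallinity rescaling, kij
  sensitivity sweeps and kij fitting.
- **Synthetic data** (`slsorb.synthetic`): seeded, replicated PVT grids
  with multiplicative noise for fit-recovery studies.
- **Pipeline + CLI** (`slsorb.pipeline`, `slsorb.cli`): a YAML-configured
  end-to-end run (synthetic → fit → mixing → sorption → sensitivity)
  with provenance-hashed CSV/JSON outputs and byte-for-byte determinism.

See [`docs/methods.md`](docs/methods.md) for the thermodynamic
formulation and the modelling decisions behind it.

## Quick start

```python
from slsorb import CopolymerSpec, copolymer_params, solve_sorption
from slsorb.reference import GAS_POLYMER_KIJ, gas, phbv
from slsorb.sorption import SorptionSystem

# PHBV characteristic parameters at 25 mol% HV from the homopolymers
params = copolymer_params(phbv(0), phbv(100), CopolymerSpec(0.25))

# Pure CO2 sorption in PHBV8 at 35 degC, 30 bar
system = SorptionSystem(
    polymer=phbv(8),
    gases=(gas("CO2"),),
    kij_gas_polymer=(GAS_POLYMER_KIJ[("CO2", 8)],),
)
result = solve_sorption(system, 3.0)
print(result.concentrations[0])   # cm3(STP)/cm3
print(result.density_change)      # % polymer-partial density change
```

Command line:

```bash
slsorb mix-params --x-hv 0.25
slsorb generate-pvt --polymer PHBV0 --seed 1 --out pvt.csv
slsorb fit-pvt --pvt pvt.csv
slsorb sorption --polymer PHBV8 --gas CO2 --gas CH4 --y 0.2 --y 0.8 --pressure 3.0
slsorb run-all --outdir out --seed 0
```

## Testing

```bash
pytest
```

`tests/test_acceptance.py` asserts a fixed panel of headline target
values. A few of those assertions fail by design: they record known,
analysed discrepancies between this formulation and its target numbers
(see the docstring in that module), while the unit suites pin the
implementation's actual, verified behaviour. `scripts/acceptance.py`
recomputes the same panel and writes it as JSON:

```bash
python scripts/acceptance.py --seed 0 --out results.json
```
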