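# sxm — substrate-explicit thermodynamic modeling of organic matter

High-resolution mass spectrometry (most prominently FTICR-MS) can assign
molecular formulae to thousands of organic compounds in a single sediment
or water sample, but classical biogeochemical models lump all of that
chemistry into one or two substrate pools. `sxm` is for researchers who
want to use those assigned-formula tables directly: it turns **every**
CHNOPS formula into a balanced aerobic degradation reaction, a
thermodynamic profile, and a growth-kinetic rate law with only two free
parameters, and then supports batch simulation and cross-sample analyses
on top.

## The model

For a compound C<sub>a</sub>H<sub>b</sub>N<sub>c</sub>O<sub>d</sub>P<sub>e</sub>S<sub>f</sub>
with net charge *z*, the electron-donor half reaction (complete oxidation
to HCO₃⁻, with NH₄⁺, HPO₄²⁻, HS⁻ as the heteroatom products) transfers

> n<sub>e</sub> = −z + 4a + b − 3c − 2d + 5e − 2f electrons, NOSC = 4 − n<sub>e</sub>/a.

The energy chain is

* ΔG⁰<sub>Cox</sub> = 60.3 − 28.5·NOSC kJ/C-mol (oxidation half reaction, 25 °C),
* ΔG⁰<sub>r,D</sub> = a·ΔG⁰<sub>Cox</sub>, from which a formation energy for
  the compound is back-calculated (structures, and hence group
  contributions, are unavailable for assigned formulae),
* catabolic (donor + n<sub>e</sub>/4 O₂ couple) and anabolic (biomass
  CH₁.₈N₀.₂O₀.₅ from the carbon source, NH₄⁺ as N source) reaction
  energies at pH 0 and pH 7,
* the coupling parameter **λ** from the thermodynamic electron equivalents
  model: λ·(η·ΔG<sub>r,Cat</sub>) + η<sup>m</sup>·ΔG<sub>r,Ana</sub> + ΔG<sub>r,Syn</sub> = 0
  with η = 0.43 and ΔG<sub>r,Syn</sub> = 200 kJ/C-mol biomass.

λ is the number of catabolic turnovers needed to pay for one C-mol of
biomass — lower λ, more favorable substrate. The metabolic reaction is
y = λ·y<sup>Cat</sup> + y<sup>An</sup>, and growth on compound *i* follows
the energy-harvest kinetic form

> μ<sub>i</sub> = μ<sup>max</sup>·exp(−|y<sub>OC,i</sub>|/(V<sub>h</sub>[OC<sub>i</sub>]))·exp(−|y<sub>O₂,i</sub>|/(V<sub>h</sub>[O₂]))

with exactly two parameters regardless of how many compounds are modeled:
the maximal growth rate μ<sup>max</sup> and the harvest volume V<sub>h</sub>.
Batch dynamics, a simplified cybernetic (enzyme-allocation) variant, and a
multi-guild variant are built on these rates.

## Worked example

```python
from sxm import compound_thermo_profile, growth_rate, parse_formula
from sxm import KineticParams, Scenario

p = compound_thermo_profile(parse_formula("C6H12O6"))
print(p.nosc, p.dg_cat7, p.lam)
mu = growth_rate(p.y_met, KineticParams(), Scenario.both_limited(1.0, 1.0))
print(mu)
```

prints (see `examples/01_glucose_thermo_profile.py` for the full tour):

```
0.0 -2823.323060131334 0.16336877091547078
0.26751452998820985
```

Glucose has NOSC 0, releases 2823.3 kJ/mol in catabolism at the
biological standard state, and needs only λ ≈ 0.163 catabolic turnovers
per C-mol of biomass; under moderate carbon and oxygen limitation
(V<sub>h</sub>[S] = 1) it supports 27% of the maximal growth rate.

The `examples/` directory holds one short script per capability:
thermodynamic profiling, limitation scenarios, batch simulation with and
without cybernetic regulation, the compound-count scaling experiment, and
cohort-level correlation with a respiration proxy. A thin CLI (`sxm
thermo|rates|simulate|cohort|synth`) wraps the same functions for shell
use; run `sxm --help`.

Because real field FTICR-MS profiles are not redistributable, the
`sxm.synthetic` module generates seeded FTICR-like formula tables with
controllable NOSC distributions and cohorts with a built-in
λ–respiration association, so everything is testable offline.

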