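# myelosim

Simulation of human granulopoiesis with two interchangeable stem-cell
descriptions: a classical compartment (ODE) lineage model and a hybrid model
in which the stem cell compartment is replaced by a deterministic
difference-equation formulation of an agent-based stem-cell niche model.

The package is for systems biologists and pharmacometricians who want to
study blood-cell dynamics under perturbations for which the two stem-cell
views differ — bone marrow transplantation, chronic irradiation,
cell-cycle-specific chemotherapy toxicity — and under clinical forcing such
as CHOP-like polychemotherapy with or without G-CSF support.

## The models

**ODE lineage.** Concatenated compartments
S → CG → PGB → G4 → G5 → G6 → GRA (stem cells, CFU-GM progenitors,
proliferating precursors, three maturing marrow stages of five
subcompartments each, circulating granulocytes), each following

```
dC_X/dt = influx·A_X^in − C_X·a_X/T_X − k_X·Ψ_CX·C_X,
C_X^out = C_X·A_X^out·a_X/T_X
```

with Z-regulated amplifications `A_X` and transit times `T_X` (bounded
monotone regulation `Z(C^rel)` equal to `Y^nor` at `C^rel = 1`), feedbacks
mediated by stem and marrow cellularity (self-renewal probability
`p = p_δ tanh(−ϑ_S·x_S − ϑ_G (C_G^rel−1)) + 0.5`, proliferative fractions
`a_S`, `a_CG`) and by the explicitly modelled cytokines GM-CSF and G-CSF,
including a two-compartment subcutaneous G-CSF depot and
granulocyte-dependent clearance. The stem compartment itself evolves as
`dC_S/dt = (2p−1)·C_S·a_S/τ_S`, exporting `2(1−p)·C_S·a_S/τ_S` into CG
(0.01875/h at equilibrium). Chemotherapy acts as first-order kill `k_X·Ψ_CX`
during one day per application, with a 1.3-fold first-cycle effect;
prednisone prolongs the granulocyte life-time.

**Stem-cell difference model.** Stem cells live in two growth environments:
the quiescent niche Α, where niche affinity `a` regenerates
(`a_{t+1} = a·r`), and the proliferative environment Ω, where affinity
decays (`a/d`) and cells traverse a 49-position cell-cycle grid, dividing at
its end. With `r = e^{2ρ}`, `d = e^{ρ}` (ρ = 0.0488) all affinities live on
the grid `a_k = e^{−kρ}`, k = 0…127, and the population state is a vector
`A_k` plus a 128×49 matrix `Ω_{k,c}`. Switching intensities combine affinity
with sigmoidal capacity functions of the target environment
(`α = (a/a_max)·f_α(N_Α)`, `ω = (a_min/a)·f_ω(N_Ω)`); cells whose affinity
falls below `a_min` differentiate irreversibly and leave as efflux.
Transition counts are propagated as expectation values, making the update
deterministic.

**Hybrid coupling.** The difference model replaces the ODE stem
compartment: each hour its (rescaled) efflux is held constant as the CG
influx, `k_scaling` matching the two equilibrium effluxes; chemotherapy
kills only the proliferating Ω population; the marrow→stem feedback of the
ODE model is dropped in favour of the niche model's intrinsic regulation.

## Worked example

```python
from myelosim.scenarios import ScenarioRunner, leukocytes_per_ul

runner = ScenarioRunner()
course = runner.regimen("CHOP-21", engine="hybrid")
print(f"min total stem number: {100*course.markers['N_S_min']:.1f}%")
v = course.markers['GRA_cycle1_nadir_value']
print(f"cycle-1 leukocyte nadir: {100*v:.1f}% "
      f"({leukocytes_per_ul(v):.0f}/ul) on day "
      f"{course.markers['GRA_cycle1_nadir_day']:.1f}")
```

prints

```
min total stem number: 80.9%
cycle-1 leukocyte nadir: 14.8% (1036/ul) on day 10.8
```

meaning that over six 21-day CHOP cycles the hybrid stem cell compartment
never loses more than a fifth of its cells — the cytotoxic kill reaches only
the cycling Ω population while the quiescent niche pool re-seeds it each
cycle — yet circulating leukocytes still drop to ≈1000/µl around day 11 of
the first cycle, the clinically expected nadir window. The same course on
the ODE engine (`engine="ode"`) nearly eliminates the homogeneous stem pool
(minimum 0.03% of equilibrium) while producing similar circulating-cell
dynamics: the two stem-cell views are distinguishable only through
stem-directed perturbations.

The `examples/` directory holds one short script per capability (steady
state, stem-cell equilibrium, depletion, transplantation, chemotherapy,
irradiation); each prints the numbers it computes and what they mean. A thin
CLI offers the same scenarios (`myelosim --help`), plus `myelosim
dump-defaults` for the full YAML configuration, which can be edited and
passed back via `--config`.

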