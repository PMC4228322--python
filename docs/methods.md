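# Methods

## Scope and model structure

`myelosim` implements three coupled pieces:

1. an ODE compartment model of human granulopoiesis (stem cells S,
   progenitors CG, proliferating precursors PGB, maturing stages G4–G6 of
   five subcompartments each, circulating granulocytes GRA, the cytokines
   GM-CSF and G-CSF, and a two-compartment subcutaneous G-CSF depot);
2. a deterministic difference-equation model of hematopoietic stem cell
   organisation in two growth environments (quiescent niche Α with affinity
   regeneration, proliferative Ω with affinity decay and a 49-position
   cell-cycle grid) on the affinity grid `a_k = e^{−kρ}`, k = 0…127;
3. a lockstep hybrid coupling in which the difference model replaces the
   ODE stem compartment.

All cell counts of the lineage are normalised to the equilibrium stem-cell
number; times are hours. The shipped parameter sets are the published human
parameterisations of the two source models and are not fitted to anything by
this package.

## ODE model

**Balance convention.** Every non-stem compartment follows
`dC/dt = influx·A^in − C·a/T − k·Ψ·C` with efflux `C·A^out·a/T`. The
amplification split between influx and efflux is not printed in the source
material; it is exposed as `split_exponent` γ with `A^in = A^γ`,
`A^out = A^{1−γ}` and default γ = 0.5, which reproduces the published
equilibrium progenitor content (`A^in ≈ √64 = 8`). Probing γ ∈ {0, 0.5, 1}
moves the benchmark timings only mildly; all shipped numbers use 0.5.

**Maturing chains.** G4–G6 are chains of `n = 5` identical subcompartments
(per-subcompartment rate `n/T`), giving gamma-distributed transit times. The
G6 amplification `A < 1` (post-mitotic apoptosis) is applied per
subcompartment as `A^{1/n}` so the chain total equals `A`.

**Steady state.** With `p = 0.5`, `C_S = 1` and all regulations at nominal
values, the equilibrium follows in closed form (stem efflux
`a_S^nor/τ_S = 0.01875/h`, each stage holding `influx·A^in·T/a`). The right
hand side evaluated there vanishes to machine precision, and all relative
outputs are normalised by this self-consistent steady state. The originally
published equilibrium table is *not* jointly reproducible from the published
parameters under any flux-conserving split convention (e.g. the reported
maturing-stage content is smaller than the G4+G5 content implied by the
printed transit times alone); the package logs its deviation from that table
(≈ +1% for CG, ≈ +20–30% for PGB/MGB/GRA) instead of failing.

**Self-renewal regulation.** The published formula for
`p = p_δ tanh(·) + 0.5` is typographically damaged in the stem-cell term of
the tanh argument. Three candidate readings were discriminated against the
published transplantation outcomes (50%/100% stem recovery times under 8 and
20 days of G-CSF): a constant weight `−ϑ_S(C_S^rel−1)` makes the
transplantation scenario collapse outright; a `1/C_S^rel` weight recovers
far too fast; the implemented reading,

```
S-term = −ϑ_S·ln(C_S^rel)   (C_S^rel ≤ 1),
         −0.62·(C_S^rel−1)  (C_S^rel > 1),
```

uses the same logarithmic-below/linear-above coordinate as the printed
proliferative-fraction regulation and reproduces the published 100%-recovery
times to within a few percent in both G-CSF variants. It also pins the
maximal stem regrowth rate at `(2·0.6−1)·a_S^max/τ_S = 0.025/h`, which is
exactly the published chronic-irradiation collapse boundary of the ODE
model.

**Chemotherapy.** Each drug block kills compartments at first-order rates
during the half-open day `(t_i, t_i + 24 h]` after each application; the
first application of a block is amplified by `f_fc = 1.3`. The published
kill-rate table lists values for S, PGB and MGB but none for CG although the
model defines one. Shipping `k_CG = 0` would leave the CFU-GM pool intact,
which refills PGB within days and erases chemotherapy-induced neutropenia
entirely (cycle-1 granulocyte nadir 79% of normal instead of ~10–15%); the
package therefore ships `k_CG = k_PGB` (CFU-GM cycle as actively as the
precursors), a config knob, and the benchmark outcomes are insensitive to
the exact value once `k_CG ≳ 0.1/h`.

**G-CSF pharmacokinetics.** A subcutaneous administration deposits the
dose-equivalent `d_G-CSF` at a constant rate over the 2-minute infusion into
depot compartment 1; the depot chain `SC1 → SC2 → blood` uses the rate
`k_sc` on every transition (the printed second-compartment loss term lacks
its coefficient; `−k_sc·C_SC2` conserves the administered dose, which the
test suite verifies by quadrature). Clearance is
`1/T = 1/T^ren + C_GRA^rel/T^GRA`.

**Integration.** `scipy.integrate.solve_ivp` with LSODA,
`rtol = atol = 1e-8`, and hard restarts at every forcing discontinuity
(chemo window edges, prednisone edges, infusion start/end). Tiny negative
excursions (below 1e-6 of the compartment scale) are clipped at segment
boundaries; larger ones raise. Recovery-time markers shift by < 0.1 d under
tolerance refinement.

## Stem-cell difference model

One step (Δt = 1 h): (i) drug/irradiation kill as an elementwise survival
factor on Ω (optionally on Α for the "both-GEs" irradiation mode) — the
cell-cycle-specific toxicity; (ii) Α update: regeneration shifts the
affinity index by −2 (the cap at k = 0 collects indices 0–2), plus Ω→Α
switches summed over the G1 positions c = 0…31 only; (iii) Ω update:
differentiation shifts k by +1 while the cycle position advances, division
at c = 48 places two daughters at (k+1, 0), fresh Α→Ω switches enter the
mitotic phase at c = 32; (iv) any mass pushed past k_max = 127 — G1 cells
that neither switch nor stay, mitotic progression, and daughters of
divisions at k_max — leaves as efflux. Switch counts are expectation values,
so counts are continuous and the update is deterministic (a binomial
sampling mode is a deliberate extension hook, off by default).

The sigmoidal capacity functions are constructed exactly from their four
anchor values via the printed auxiliary-quantity scheme and reproduce the
anchors to 1e-10. Grid conventions: 49 cycle positions (G1 = 0…31, S/G2/M =
32…48, division between 48 and 0), consistent with a printed mitotic-phase
duration of "16 h" read as the 17 grid positions including both ends.

**Equilibrium.** Iterated from 1000 dormant cells at `a_max` until the
summaries (N_Α, N_Ω, efflux) are stationary to 1e-10 over a 1000-step
window (converges in a few tens of thousands of steps, < 1 s). The
equilibrium has ≈ 82.7% of cells in Α, a proliferative fraction of ≈ 0.17
and a relative efflux of ≈ 0.0030/h, and is globally attracting (seed size
irrelevant; ±50% perturbations return within 1%).

## Hybrid coupling

`k_scaling = Ĉ_S^out·Δt/N̂_Sout` converts the per-step efflux into ODE flux
units so the coupled equilibrium CG influx equals 0.01875/h; the
instantaneous coupled influx is `k_scaling·N_Sout(t)/Δt`, held constant over
each hour (the alternative normalisation by the current stem number is
retained behind the same coupling object). The relative stem number
`N_S/N̂_S` feeds the `a_CG` regulation; the ODE stem equation is disabled
and the marrow→stem feedback loop is dropped — the niche model's intrinsic
regulation replaces both (re-implementations of that loop via ω-activation
or global acceleration are documented dead ends of the source work and are
not shipped). Within each hour the lineage ODE is integrated with the usual
event restarts; the stem engine sees the chemotherapy factor evaluated at
the interval start, which yields exactly 24 kill steps per application. The
per-hour survival-factor kill in the stem engine versus the continuous-rate
kill in the lineage differs at O((kΔt)²).

The coupled equilibrium is a fixed point to < 0.1% drift over 100 days, and
scenarios that never signal the stem compartment (granulocyte-only
depletion) agree between the engines to < 2%.

## Scenarios and markers

Day 1 of any calendar is t ∈ [0, 24 h); applications sit at day starts.
Recovery times are linearly interpolated first upward crossings of a
threshold × equilibrium ("100%" thresholds use 0.99 to avoid asymptotic
never-crossing); nadirs are window minima; a non-crossing series reports an
infinite sentinel. "G-CSF until recovery" administers one dose per day until
relative granulocytes first reach 1, capped at 200 days. Leukocyte counts
assume proportionality to relative granulocytes with 7000/µl at normal.

**Collapse criterion.** Chronic irradiation records compartment contents
after 100 days; "collapse" is granulocytes below 1e-2 of normal at day 100.
This cutoff reads the steep cliff of the day-100-content curves directly; a
much smaller cutoff (e.g. 1e-6) would report the boundary where the decay
has *finished* rather than where it begins — +24% bias for the ODE engine
and no detection at all within 100 days for the slowly dying hybrid stem
compartment. Measured boundaries: ODE ≈ 0.026/h (analytic limit 0.025/h),
hybrid with both growth environments damaged ≈ 3e-3/h, an order of magnitude
lower.

## Known limitations and deviations

* The source models' own reference implementation is not published;
  several conventions (amplification split, `k_CG`, the damaged
  self-renewal formula) had to be reconstructed as described above.
  Residual quantitative deviations remain and are reported, not tuned away:
  ODE transplantation 50% stem recovery ≈ 24 d (published 18 d) although the
  100% times match (≈ 63 vs 61 d, and 14.7/19.9 vs 13.5/19 d with 20-day
  G-CSF); granulocyte 50% recovery ≈ 4.2 d (published 6 d); the ODE CHOP-21
  stem minimum ≈ 0.03% over the course (published 0.23%, reached in our
  implementation only after the first cycle); the hybrid cycle-1 leukocyte
  nadir ≈ 14.8% (published ≈ 10%); the hybrid Ω-only transplantation stem
  number at day 5 ≈ 95.8% (published 98%).
* No parameter fitting, no inter-patient variability, no pegylated G-CSF,
  no individual-cell tracking or clonal substructure, and no murine
  variants. Comparison against clinical quartile tables is descriptive
  coverage only.
* Simulations are deterministic; stochastic switch sampling and the
  modified (more cell-number-sensitive) transition characteristics for
  myeloablative scenarios are extension hooks — the latter's anchor values
  are user-configurable but carry no shipped defaults.
* Problem sizes used throughout (100–136 simulated days, hourly stem-engine
  steps, the 128×49 state) are the models' native scales; nothing is
  down-sampled.
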