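# Methods and modelling notes

This note documents the assumptions, parameters and numerical choices behind
`enteroflux`, in enough detail to audit every number the package produces.

## 1. Constraint-based framework

A metabolic model is a stoichiometric matrix `S` (metabolites × reactions)
with flux bounds `l ≤ v ≤ u`. Flux balance analysis (FBA) solves

```
optimize  c'v   subject to   S·v = 0,   l ≤ v ≤ u
```

for a single-reaction objective `c`. The backend is `scipy.optimize.linprog`
with the HiGHS solver; `cobra`/GLPK is used in the test suite as an
independent cross-check. Only the optimal objective value is
contract-guaranteed — individual fluxes are degenerate in general and should
be interrogated via flux-variability ranges (`flux_variability`).

Tolerances: steady state ‖S·v‖∞ ≤ 1e−6, bound feasibility 1e−9, optimality
band 1e−8·max(1, |opt|). The lexicographic (two-stage) optimizer pins the
stage-1 optimum within this band before optimizing the stage-2 objective;
it is used for "minimal oxygen uptake sustaining maximal chylomicron
secretion".

Exchange reactions touch exactly one metabolite; negative flux is uptake,
positive is secretion.

## 2. Diet → exchange bounds

Dietary intakes are given in mol·mouse⁻¹·day⁻¹; model fluxes are
mmol·gdw⁻¹·h⁻¹ (gdw: grams dry weight). The normalization uses:

| Parameter | Value | Meaning |
| --- | --- | --- |
| `si_wet_weight` | 1.094 g | mouse small-intestine wet mass |
| `water_fraction` | 0.76 | water content of the tissue |
| `enterocyte_cell_fraction` | 0.552 | enterocyte share of intestinal cells |
| hours | 24 | averaging window |

Dry mass = 1.094 × (1 − 0.76) × 0.552 = **0.1449 g**; the conversion factor
is `A = 1000 / (0.1449 · 24) = 287.49 ≈ 2.8749×10²`. Each nutrient's
exchange lower bound is `−intake · A`; upper bounds are left at the model
default so secretion stays possible. Nutrients mapped to `None` are
reported as unmodeled rather than silently dropped; unmapped nutrients
raise.

## 3. Species-resolved lipid pathways

Six dietary fatty-acid (FA) species are modelled: C14:0, C16:0, C18:0,
C18:1, C18:2, C18:3. Molar masses are computed from atomic masses
(free acid CnH(2n−2d)O2; MAG/DAG/TAG add glycerol minus 1/2/3 waters;
cholesteryl esters add cholesterol minus water). For **each** species the
generator emits:

* 1 luminal hydrolysis (TAG → MAG + 2 FFA, lipase),
* 3 absorption reactions (protein-mediated FFA uptake, passive FFA
  diffusion, MAG uptake) — **18 for six species**,
* 6 re-synthesis reactions (acyl-CoA activation, ER import of acyl-CoA and
  MAG, MGAT, DGAT, MTTP lipidation into ER-lumenal TAG) — **36 for six
  species**,
* 1 cholesteryl-ester (ACAT) reaction — 6 total.

All generated reactions are carbon-balanced (asserted in tests). TAG
positional isomers are deliberately not distinguished: hydrolysis operates
on one TAG pool per species, which keeps the reaction count linear instead
of cubic in the number of species.

### Chylomicron assembly

A chylomicron is a TAG-rich particle with mass fractions 95% TAG, 4%
phospholipid, 1% cholesteryl ester, 2% apolipoprotein (normalized by 1.02).
Molar coefficients are derived from a reference particle mass of 1×10⁵
g/mol (a documented scale-down; only ratios matter to FBA), phospholipid
775 g/mol, apolipoprotein 5×10⁴ g/mol. The toy model instantiates one
single-species assembly per FA species, so the FA composition of the
secreted chylomicron pool is an **outcome** of the optimization (the mix of
assembly fluxes), not a baked-in constant. `chylomicron_fa_composition`
reads it back from the solution.

## 4. The synthetic toy model

`build_toy_model` emulates the topology of the real enterocyte
reconstruction at auditable scale (126 reactions, 105 metabolites,
compartments: lumen `u`, cytosol `c`, mitochondrion `m`, ER `r`,
basolateral `e`). Design points, all configurable through `ToyModelSpec`:

* **SGLT1** couples 2 Na⁺ per glucose (configurable); the Na⁺/K⁺-ATPase
  exports 3 Na⁺ per ATP. **GLUT2** exists basolaterally (`GLCGLUT2`) and,
  switchably, apically (`GLUT2A`); **GLUT5** carries fructose.
* **Energy design (load-bearing):** the glycolysis lump is written
  ATP-neutral (glc → 2 pyr), so the respiratory lump
  (NADH + ½O₂ + 2.5 ADP → 2.5 ATP, P:O = 2.5) is the *only* net ATP
  source. Every ATP-consuming flux therefore has a closed-form oxygen
  cost — minimal O₂ = (total ATP demand)/(2·P:O) — which makes the
  chylomicron/oxygen scenario verifiable by hand. This deviates from
  textbook glycolysis (+2 ATP) and is a deliberate simplification at toy
  scale.
* Pyruvate oxidation is lumped (pyr[m] → 3 CO₂ + 5 NADH ≙ glycolytic +
  TCA redox equivalents), acetyl-CoA comes from a citrate-shuttle/ACL lump,
  and cholesterol biosynthesis costs 18 acetyl-CoA + 36 ATP (configurable).
* **Gluconeogenesis** is a switchable glutamine → glucose lump (2 gln →
  glc + 4 CO₂ + 4 NH₄⁺) with no ATP cost; ammonium handling is only
  instantiated together with it so every switch combination validates with
  no structural holes.
* An intracellular cholesterol source exchange (`EX_chol_src`, closed by
  default) stands in for luminal/biliary cholesterol absorption; opening it
  or the biosynthesis lump are the two cholesterol routes of the
  chylomicron scenario.

`validate_model` confirms no dead-end metabolites and no blocked reactions
for every switch setting.

## 5. Synthetic diets

Four diets named 10en%, 20en%, 30en%, 45en% by fat energy share; protein is
fixed at 20 en%, carbohydrate takes the remainder. Bookkeeping uses the
standard 4/4/9 kcal·g⁻¹ densities at 12 kcal·day⁻¹. Composition rules:

* carbohydrate: 10% of kcal as sucrose (→ glucose + fructose), rest as
  glucose equivalents (starch);
* protein: a casein-like 18-amino-acid mass profile;
* fat: a palm/soy oil blend; the soy-oil mass is pinned at half the 10en%
  diet's fat and stays constant, palm oil supplies the increments, so
  higher-fat diets are palmitate-enriched while the soy-derived C18:2/C18:3
  floor is constant. Each FA species is split 94/3/3% by mass over
  TAG/FFA/MAG forms (the pre-hydrolyzed forms also provide the dietary
  rescue route for lipase knockouts);
* sodium: 1.2×10⁻⁵ mol·kcal⁻¹; the diets are cholesterol-free.

This yields 39 nutrients (2 hexoses + 18 amino acids + 6 FA × 3 lipid forms
+ Na⁺). Generation is deterministic; an optional seeded jitter is off by
default.

## 6. Scenarios

1. **Glucose transport** — maximal apical absorption (−min luminal exchange
   flux) and basolateral secretion (max export flux) for glucose and
   fructose, with/without apical GLUT2. Expected pattern: full bolus
   absorption only with apical GLUT2; SGLT1 alone is Na⁺-capped at Na/2.
2. **Na⁺ titration** — absorption vs. Na⁺ availability: linear with slope
   1/(Na:glc stoichiometry) until the glucose bolus is exhausted, then a
   plateau; flat when apical GLUT2 bypasses SGLT1. The minimal Na⁺ reaching
   99.9% of the plateau is found by bisection (50 iterations) and compared
   with dietary Na⁺ (ratio ≈ 150 on the toy 10en% diet).
3. **Gluconeogenesis** — secretion capacity minus absorption capacity; a
   positive surplus demonstrates de novo glucose synthesis, attributed by
   re-computing the surplus with each amino-acid uptake individually closed.
4. **Chylomicron/oxygen** — chylomicron secretion is zero without a
   cholesterol source (cholesterol-free diets; esterification needs
   cholesterol); with biosynthesis enabled the minimal basolateral O₂
   sustaining maximal secretion is computed lexicographically and rises
   monotonically with fat en% (8.6×10⁻⁵ → 3.9×10⁻⁴ mol·mouse⁻¹·day⁻¹ on
   the toy diets).

## 7. Knockout screen and rescue

Every non-exchange reaction is deleted in turn (bounds zeroed) and the task
re-optimized. Classes: **Type II** if the task drops below 1e−6 × baseline
(complete blockage), **Type III** if the reduction strictly exceeds 5%,
otherwise **Type I**. The 5% threshold is applied with a 1e−9 slack so a
reduction of exactly 5% (up to round-off) stays Type I. Exchange reactions
are excluded by default — deleting a dietary input is a diet change, not an
enzymopathy — behind a documented flag. Dietary rescue scans
(nutrient class × scale) over {lipid, carbohydrate, amino_acid, mineral} ×
{1.5, 2, 5, 10}, scaling the uptake bounds of the tagged exchanges, and
reports the modification with the best recovered fraction; classes are
never reassigned, and rescue of Type I/II records is a flagged no-op.

## 8. File formats

* **TSV**: columns `id, equation, lower_bound, upper_bound, gene_rule,
  subsystem`; equations use `-->` / `<=>` with `met[compartment]` tokens.
* **SBML L3 + FBC** via cobra/libsbml; bracketed ids are sanitized
  (`glc[c]` ↔ `glc_c`) for SBML round trips.
* **COBRA `.mat`**: the struct dialect fields `rxns, mets, S, lb, ub,
  grRules, genes`; unknown fields are ignored with a warning.
* Diet CSV: `nutrient, intake_mol_per_mouse_per_day`.

## 9. Numerical/testing choices

* Micro-model LPs (≤ 12 reactions, finite bounds) are verified against a
  brute-force vertex-enumeration oracle written independently of the
  solver path (tests/conftest.py), to 1e−8.
* The toy model's optima are additionally checked against hand-derived
  closed forms (Na-capped absorption = Na·A/2, gluconeogenic surplus =
  gln·A/2, GLUT2A-knockout residual including the Na-pumping ATP cost,
  minimal O₂ from ATP accounting) and against cobra/GLPK.
* The full pipeline is deterministic: repeated runs produce byte-identical
  JSON (no timestamps are emitted; provenance carries a config hash).

## 10. Problem sizes and limitations

Everything ships at desk scale: the toy model is 126 reactions and solves
in milliseconds; a full screen (95 knockouts × 1 LP) takes < 1 s; the whole
test suite runs in ~20 s. Limitations: lumped energy metabolism (no
explicit TCA intermediates, P:O fixed), no biomass/growth objective (the
cell is post-mitotic), single-species chylomicron assemblies approximate a
mixed particle as a mixture of particles, no positional TAG isomers, no
micronutrients beyond Na⁺, and gluconeogenesis is modelled from glutamine
only. These are toy-scale stand-ins for a published genome-scale
reconstruction (1830 reactions, 708 unique metabolites, 717 genes) whose
distribution files are not bundled; integration tests against it activate
automatically when `data/mmu_ENT717.mat` is present.
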