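# Methods

## Scope and model

`nitroyield` treats the energy budget of an ammonia-oxidizing archaeon as
two independently computable yields joined by multiplication:

* the **theoretical ATP/NH₄⁺ yield** of an ammonia-oxidation pathway — a
  property of its electron-transport stoichiometry alone;
* the **ATP/Biomass yield** — the ATP + reducing-equivalent cost of building
  1 g dry biomass from CO₂, a property of the organism's biosynthetic
  network;
* their product with a measured **Biomass/NH₄⁺ yield** gives the *realized*
  ATP/NH₄⁺ yield, i.e. how much of the theoretically available energy the
  cell actually captures.

All flux computation is steady-state FBA: linear programming over
S·v = 0 (balanced species), lb ≤ v ≤ ub.  Species in the `boundary`
compartment are unbalanced; everything else must close.

## Pathway stoichiometry and its reconstruction

The three pathway fixtures (`src/nitroyield/data/pathway[123].tsv`) encode
the published reaction sets with two deliberate reconstructions, documented
in the fixture headers:

* **Nitrite reductase (NIR).**  The published reaction table prints for NIR
  a verbatim copy of the bc1-complex equation, which cannot be a nitrite
  reduction.  We reconstruct it as single-electron nitrite reduction from
  the reduced carrier pool, `HNO₂ + PCYme + 0.5 H⁺_out + 0.5 H⁺_in → NO +
  H₂O + PCYm`.  The substrate proton is deliberately split half-and-half
  across the membrane: this is the unique assignment under which the lumped
  pathways reproduce the published combined reactions coefficient-for-
  coefficient (ATP yields 1.75 and 1.625 for pathways 2 and 3).  Sourcing
  the proton wholly from outside gives 1.5/1.375; wholly from inside gives
  2.0/1.875.
* **NADH synthesis.**  The printed complex-I line is likewise inconsistent
  with the published NADH-mode combined reactions (it would force zero ATP
  alongside each NADH).  The chemically balanced `QH₂ + NAD⁺ → NADH + Q +
  H⁺_out` reproduces all three NADH-mode combined reactions exactly.  The
  4-proton cost of reverse electron transport is carried in the yield
  bookkeeping (one NADH ≡ 4 proton-equivalents ≡ 1 ATP), not in the
  reaction equation.

The published running text gives pathway yields 1.5/1.65/1.75; the
published table gives 1.5/1.75/1.625 together with fully specified
combined reactions.  The table is internally consistent and is what this
package reproduces.

Membership follows the pathway schematics: quinol-dependent AMO in pathways
1 and 3, the NO-dependent monooxygenase only in pathway 2, HAO in 1 and 2,
CuP460 only in 3; transport, quinone reductase, NIR, abiotic N₂O formation,
complexes III/IV, ATP synthase and the NADH step are common to all three.
The abiotic N₂O reaction and (in pathway 1) NIR waste hydroxylamine
electrons and provably carry zero flux at either optimum; they are included
for completeness and the tests assert their inactivity.

In ATP-maximizing mode NAD/NADH are internal (forcing the NADH branch to
zero); in NADH-maximizing mode they are boundary species.  H⁺_out is always
internal (the proton-motive force must close); H⁺_in is boundary, as in the
published combined reactions.

## The proton ledger

For any pathway solution, summing H⁺_out production over all reactions
except ATP synthase, plus 4 per NADH exported, gives the proton-equivalents
available per ammonium (6, 7 and 6.5 for the three pathways).  Dividing by
4 (protons per ATP) yields the ATP equivalent; in ATP mode the identity
`yield = ledger/4` is asserted exactly.  This hand-auditable bookkeeping is
the independent check on the LP.

## FBA engine

* LP backend: scipy `linprog`/HiGHS, presolve on, feasibility tolerance
  1e-9; reported values are compared at 1e-6.  HiGHS is deterministic for
  fixed input, so identical models give identical solutions.
* **Degeneracy.**  Only objective values are contractual; individual fluxes
  are asserted only where lexicographic minimization (below) or the problem
  structure makes them unique.
* **Loopless option** (`solve_loopless`): the null-space/energy-potential
  MILP — a binary direction indicator per loop-law reaction, a potential
  G_i forced to the sign opposite the flux (|G| ∈ [1, 1000]), and G
  orthogonal to a null-space basis of the internal stoichiometric matrix.
  Solved with scipy `milp` (HiGHS branch-and-bound).  Exempt from the loop
  law: declared exchanges, the biomass reaction, and any reaction touching
  a boundary species — such reactions exchange matter with the environment
  and cannot participate in a pure internal cycle.  A solution's
  loop-freeness is certified independently by `max_circulation`, an LP that
  maximizes circulation confined to the sign-support of the internal
  fluxes.
* **Lexicographic source minimization** (`minimize_sources`): minimize the
  first source flux, pin it, minimize the next.  ATP-then-NADH is the
  canonical order; the order matters exactly when interconversions make the
  pair non-unique, and a test documents this.

## Biomass energetics

`biomass_energy_cost` fixes the biomass flux at 1 gDW gDW⁻¹ h⁻¹, blocks
the ammonia-oxidation reaction list (explicit ids, or by subsystem tag),
adds artificial inputs `ADP + Pi + H⁺ → ATP + H₂O` and `NAD⁺ + H⁺ → NADH`,
and lexicographically minimizes them.  Fluxes in mmol gDW⁻¹ h⁻¹ divide by
1000 to mol/gDW.  NADH represents all reducing equivalents; models are
expected to contain NADH↔NADPH (1:1) and NADH → 2 reduced-ferredoxin
conversions so every reductant demand is expressible in NADH.

Growth-associated maintenance (GAM) is an ATP hydrolysis embedded in the
biomass reaction, default 25 mmol ATP/gDW (the value adopted from the
closest curated archaeal model).  Whether a reported ATP/Biomass figure
includes GAM is ambiguous in parts of the literature, so `EnergyCost`
carries a `gam_included` flag and `without_gam()` reports the alternative
(e.g. 0.120 vs 0.095 mol/gDW at GAM 25).

NADH→ATP equivalence factor: 1 by default (both cost four translocated
protons); exposed as `nadh_atp_factor` for sensitivity analysis.

## Biomass mass balance

A biomass equation in mmol/gDW must satisfy (Σ SᴿMᴿ − Σ SᴮMᴮ)/1000 = 1 g.
`normalize_biomass` rescales all coefficients uniformly to close the
residual, excluding the GAM couple (ATP/ADP/Pi/H₂O/H⁺) — mass-neutral by
construction — and the biomass pseudo-species.  The operation is
idempotent and leaves a residual below 1e-9 g; degenerate equations (zero
net scalable mass) raise instead of silently dividing.

## Synthetic fixtures

`make_toy_autotroph` plants an exactly known ground truth: a lumped carbon
fixation reaction consumes (1000·atp_cost)/10 mmol ATP and the same share
of NADPH per mmol of a single 100 g/mol precursor, 10 mmol of which (plus
GAM) make 1 g biomass — so the minimized inputs must recover
`atp_cost·1000 + gam` and `nadh_cost·1000` mmol exactly (the NADPH demand
exercises the NADH→NADPH conversion).  Molar masses are chosen so the GAM
couple is mass-neutral (507 + 18 = 427 + 97 + 1) and the biomass equation
is born balanced.  Optionally the pathway-1 oxidation module is wired in,
making the toy a complete chemolithoautotroph with closed-form maximum
growth rate 1.5/(1000·(atp_cost + nadh_cost) + gam) per mmol NH₄⁺ — used
as a hand-algebra oracle.

`make_loop_fixture` contains a legitimate catabolic ATP route (2 ATP per
substrate, uptake ≤ 10), an objective-neutral 3-cycle, and an erroneously
reversible kinase/phosphatase pair whose reverse operation together with
the ATP-maintenance reaction forms an internal cycle regenerating ATP from
nothing — plain FBA exploits it, loopless FBA (or making the pair
irreversible) eliminates it.

What the toys do **not** emulate: genome-scale redundancy and alternate
routes, realistic biomass composition, compartmentalized proton chemistry
beyond in/out, kinetic or thermodynamic (ΔG) detail.  Passing the planted-
cost grid therefore validates the *procedure* (blocking, sourcing,
lexicographic minimization, unit handling), not any particular organism's
numbers.

## Yield ledger

Raw measurements are normalized with: 20 fg dry weight per cell
(*Nitrosopumilus*-like cells), 26 g per C-mol biomass, 4 H⁺ per ATP, 12 g
carbon per C-mol.  Display rounding is 3 significant figures, half-up, and
each derived column is computed from the previously *displayed* value —
the scheme that reproduces the published table cell-for-cell (one cell was
truncated rather than rounded in print; the regression accepts ±1 in the
last digit there).  The global extrapolation converts an oceanic ammonium
oxidation flux given in Gt/yr on a nitrogen-mass basis (÷14 g/mol) through
the 1:25 molar yield and 12 g C per C-mol; this mass-basis reading is an
explicit assumption, being the only one consistent with the companion
figure of 0.16 Gt C/yr.

## Numerical choices

* Net-reaction coefficient pruning at 1e-9 (LP round-off floor).
* LP feasibility 1e-9; value comparisons 1e-6; exact rational cross-checks
  (sympy elimination on the pathway systems) where the system is small
  enough.
* Big-M in the loopless MILP: 1000, matching the conventional flux bound
  sentinel; default bounds on parse are (0, 1000) / (−1000, 1000).
* Ties/degeneracy: never asserted away — tests check objective values,
  uniqueness-forced fluxes, and certified loop-freeness only.

## Problem sizes

The shipped analyses are small by construction: pathway LPs have ~10
reactions and ~20 species; the toy autotroph ~20 reactions; loopless MILPs
a handful of binaries; the planted-cost grid runs 30 toy models.  The full
test suite solves a few hundred LP/MILP instances in seconds.  The same
code paths accept a genome-scale SBML model unchanged (the full-model test
runs when `data/NmrFL413.xml` is supplied).

## Known limitations

* Only molar-mass balance is enforced for biomass (no per-element or
  charge balancing).
* The SBML layer covers stoichiometry, bounds (FBC or kinetic-law style),
  objectives and boundary flags — not annotations, groups or gene rules.
* No FVA/pFBA/sampling; no non-growth-associated maintenance; no
  uncertainty propagation in the ledger (the sources publish none).
* The half/half proton split in the reconstructed NIR is a calibration to
  the published combined reactions, not an independently measured
  stoichiometry; it should be revisited if a corrected reaction table is
  published.
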