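# Methods

## Model and procedure

The package implements constraint-based strain design on a genome-scale
metabolic model: fluxes `v` (mmol/gDCW/h; biomass in h⁻¹) satisfy the
steady-state balance `S v = 0` and bounds, and every optimization is a
single-level LP.  The design loop alternates two FBAs under the
accumulated deletion constraints `v_j = 0`:

1. **Target maximization** — objective is the target exchange flux, with
   the growth floor `v_growth ≥ μ_min` active.  The wild-type instance of
   this solve fixes two run-level constants: the theoretical maximum
   production flux (the denominator of all reported yields) and `OUR_min`,
   the oxygen uptake realised at that optimum, which is enforced as a
   floor in every subsequent LP.  The wild-type solve itself runs without
   an oxygen floor (it defines it).
2. **Growth maximization** — objective is `biomass + ε·target` with
   `ε = 1e-5`.  The composite form exists because the growth optimum of a
   GEM is massively degenerate: the ε term selects, among the alternate
   growth optima, the vertex that also secretes the target, making the
   per-reaction fluxes (and hence the scores below) well defined.  An
   exact two-stage lexicographic mode (max growth; fix; max target) is
   provided as a cross-check; the two agree on growth to the LP tolerance
   because the composite perturbs the optimum by at most `ε·v^Tmax`.

Each deletion candidate `j` is scored by the relative flux change

    chg_j = (|v_j^Tmax| − |v_j^Gmax|) / |v_j^Gmax|,

with `|v_j^Gmax|` replaced by `1e-6` when below the zero tolerance.
Absolute values are used deliberately: bounds admit negative reversible
fluxes, and magnitudes are what make the score's case analysis coherent
(`chg = −1` exactly when a reaction carries growth flux but no target
flux, `chg ≥ −1` always, and a direction flip registers as a change).
Reactions with both fluxes below tolerance are recorded but ineligible —
they would trivially score −1 via the guard, yet deleting them is a no-op
at the current optimum (verified as an invariant test).

Selection uses the relaxed window `[chg_min, ko_r]`, `ko_r = r·chg_min`
with `r = 0.95` by default.  The window is interpreted as a *tie set*:
all reactions inside it are considered equally attractive and the one
with the largest `v^Gmax` is deleted, residual ties broken by
lexicographic id so a run is a pure function of its inputs.  The
rationale: reactions that are preferentially used for cell synthesis but
are not essential sit slightly above the literal minimum, and the stated
tie-break ("highest `v^Gmax`") only ever engages if near-minimal scores
are pooled.  A literal minimum-chg mode (`selection="minimum"`) is kept
for comparison.

Both FBAs are re-solved under the current deletion set each iteration, so
the per-reaction `chg` reference tracks the shrinking flux cone; only the
yield denominator and `OUR_min` stay pinned to the wild type.  A frozen
target-max reference (`refresh_tmax=False`) is available for comparison.

Termination: no eligible candidate (`no_candidate`), deletion cap
(`max_deletions`, default 30 — designs beyond 20 deletions are routinely
reachable, the cap merely guarantees termination), or exhaustion after
infeasible trials (`infeasible_next`).  A candidate whose deletion makes
the growth LP infeasible is discarded permanently and selection retries
within the same iteration, so one lethal candidate never ends a run.
`y_obj` (default 1e-3 mmol/gDCW/h) only flags productive steps; it stops
a run early only when `stop_at_yobj` is set.

## Candidate classification and exchange policy

Categories are assigned structurally at load time: single-metabolite
boundary reactions are exchanges; reactions moving the same base species
(compartment suffix stripped, BiGG `_c/_p/_e` convention, configurable
regex) between compartments are transport.  ABC transporters (annotation
match, gene-associated) and PTS reactions (annotation/id match) are
transport processes that remain deletable; explicit id lists override the
heuristics, and an exclusion-list file can pin the candidate set exactly
when annotations are ambiguous.  Biomass and ATP maintenance are never
candidates.

Before a run, every exchange secretion bound is closed except the target,
a whitelist of native byproducts (for *E. coli*: succinate, ethanol,
formate, acetate, D-lactate, urea, hydrogen sulfide, citrate), CO2, and
the obligatory outputs water and protons, which are opened to the global
bound (1000).  Without the obligatory-output exception the closed-bound
policy renders essentially every GEM infeasible; the open set is visible
in the configuration.  Uptake bounds are untouched except glucose,
clamped to `GUR_max`.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| GUR_max | 10 | mmol/gDCW/h | glucose uptake cap |
| OUR_min | auto | mmol/gDCW/h | oxygen floor, fixed from the wild-type target-max solve |
| NGAM | 3.15 | mmol/gDCW/h | ATP maintenance floor |
| μ_min | 0.05 | h⁻¹ | minimal growth rate |
| r | 0.95 | — | selection-window relaxation |
| ε (tie-break) | 1e-5 | — | target weight in the growth objective |
| max_deletions | 30 | — | termination cap |
| flux zero tolerance | 1e-9 | mmol/gDCW/h | zero-flux cutoff |
| v^Gmax zero guard | 1e-6 | mmol/gDCW/h | division guard in chg |

## Numerical choices

GLPK simplex (swiglpk) is the default backend — deterministic for a fixed
build, no randomized perturbation — with scipy's HiGHS interface as an
alternative behind the same two-function seam.  All physiological
constraints are bound tightenings, applied after deletion bounds so that
deleting a floor-carrying reaction (biomass, ATP maintenance, the oxygen
exchange) correctly yields infeasibility rather than silently dropping
the floor.  Deleting a reversible reaction fixes both bounds to zero.
Infeasibility is a return status used as a control signal, never an
exception, except for the initial model, where it is a hard error.
Optimal solutions satisfy `|S v| ≤ 1e-9·(1 + ‖v‖∞)` (measured residuals
are ~1e-15 at toy scale).  Degenerate alternate optima of the target-max
solve are taken as the solver's returned basic solution; only the
growth-max solve is de-degenerated (by ε), matching the score's
definition.  Window-membership comparisons carry a 1e-9 slack so exact
boundary scores (e.g. `(μ_min − c)/c` landing on `r·chg_min`) do not flip
on float rounding.

## Synthetic networks and what they show

`make_toy_network` emulates the one structural feature the search
exploits: competition between growth-coupled byproduct routes and the
target at the growth optimum.  A substrate hub (uptake 20 mmol/gDCW/h)
feeds a capacity-1 base growth route, `n` byproduct branches with
distinct small-integer capacities (drawn deterministically from the
seed), an ATP-generation reaction (biomass consumes 0.5 ATP per unit
growth, plus the NGAM floor), and an uncapped target branch.  At growth
maximum all precursor routes saturate, so each branch deletion frees its
substrate share for the target — and because the branches are equally
substrate-efficient and capacity-ordered, the greedy step-by-step optimum
provably coincides with the exhaustive optimum at every size, which is
what the enumeration oracle checks.  Integer capacities keep LP vertices
exactly representable, so tests assert at 1e-6..1e-9 rather than loose
tolerances.  Networks are emitted through the BiGG-JSON dict path and so
exercise the same loader, classifier and anchor detection as real models.

What the toys do *not* emulate: cofactor and redox coupling across
hundreds of reactions, reversible loops, alternate-optima plateaus of
realistic width, multi-compartment transport chains, and annotation noise
in candidate classification.  Passing the toy suite therefore validates
the algorithmic machinery (scoring, selection, termination, invariants,
oracle agreement), not the biological quality of designs on any
particular GEM; published-model replication runs are supported through
the CLI when model files are supplied, and are expected to track printed
designs only within the usual FBA degeneracy caveats.  Acceptance-script
problem sizes (20 networks, ≤ 3 branches, ≤ 7 candidates, enumeration up
to the greedy trace length) were chosen so enumeration is exact and the
whole report regenerates in seconds.

## Known limitations

- Reaction-level deletions only; gene-level knockouts via GPR boolean
  evaluation are out of scope (GPR is used solely as a classification
  flag for ABC transporters).
- The greedy loop has no optimality guarantee on general networks; the
  exhaustive oracle bound (`greedy ≤ best-of-size-k`) is the only
  universal property, and it is what the tests assert on non-greedy-
  optimal constructions.
- No loopless/thermodynamic constraints; flux-variability analysis of the
  returned designs is left to the caller.
- The 52/63 vs 68 productive-compound denominator discrepancy in the
  published multi-target statistics is noted and not resolved here.
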