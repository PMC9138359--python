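# aerith — growth-coupled strain design by iterative single-level LP

`aerith` identifies sets of metabolic-reaction deletions that couple the
production of a target compound to cell growth in a genome-scale metabolic
model (GEM).  It is aimed at metabolic engineers who want knockout designs
for microbial production strains (e.g. *E. coli* succinate or L-Phe
producers) without solving the bilevel mixed-integer programs of
OptKnock-style methods: every step here is a plain LP, so designs with 20+
deletions are reachable in seconds to minutes with a free solver (GLPK).

## Method

Flux balance analysis (FBA) treats metabolism at steady state: fluxes `v`
satisfy `S v = 0` for the stoichiometric matrix `S`, with bounds

```
v_glc_uptake ≤ GUR_max        (glucose uptake, default 10 mmol/gDCW/h)
v_o2_uptake  ≥ OUR_min        (fixed from the wild-type target-max solve)
v_atpm       ≥ NGAM           (ATP maintenance, default 3.15 mmol/gDCW/h)
v_growth     ≥ μ_min          (default 0.05 h⁻¹)
lb_j ≤ v_j ≤ ub_j             (lb_j = 0 for irreversible reactions)
```

Two LPs are solved per iteration: one maximizing the target exchange flux
(fluxes `v^Tmax`) and one maximizing growth with a small (1e-5) target
tie-break that selects a unique vertex among growth-degenerate optima
(fluxes `v^Gmax`).  Each deletion-candidate reaction is scored by its
relative flux change

```
chg_j = (|v_j^Tmax| − |v_j^Gmax|) / |v_j^Gmax|      (chg_j ≥ −1)
```

with `v_j^Gmax` replaced by 1e-6 when it is zero.  A reaction with `chg`
near −1 fuels growth but not production — the signature of a competing
byproduct route.  One reaction inside the relaxed window
`[chg_min, ko_r = r·chg_min]` (default `r = 0.95`; largest `v^Gmax` wins,
ties broken lexicographically) is deleted by adding `v_j = 0`, and the
procedure repeats until no candidate remains, a deletion cap is hit, or
every remaining candidate is growth-essential.  Candidates are all
non-exchange, non-transport reactions, plus gene-associated ABC
transporters and PTS reactions; before a run, every secretion bound except
the target, known native byproducts, CO2 and obligatory outputs is closed.

## Worked example

Generate a seeded toy network — a glucose hub feeding a biomass-precursor
route (capacity 1), two byproduct branches (capacities 2 and 3) and a
target branch — and run the search:

```
$ aerith make-toy --branches 2 --seed 1 --out toy.json
wrote toy_2branch_seed1: 15 reactions -> toy.json
$ printf 'EX_byp1_e\nEX_byp2_e\n' > whitelist.txt
$ aerith run --model toy.json --target EX_tgt_e \
    --gur-max 20 --ngam 1 --co2-exchange "" --whitelist whitelist.txt
step  0  deleted=-              biomass=  6.0000  target= 10.0000  yield= 52.8%
step  1  deleted=R_BRANCH2      biomass=  3.0000  target= 14.5000  yield= 76.6%
step  2  deleted=R_BRANCH1      biomass=  1.0000  target= 17.5000  yield= 92.5%
terminal status: infeasible_next
```

Step 0 is the undeleted strain: growth is capacity-limited at 6 h⁻¹ and 10
of the 20 mmol/gDCW/h glucose leaks to the target.  The search deletes the
byproduct branches in decreasing capacity order; each deletion lowers
growth and redirects the freed glucose, ending at 17.5 mmol/gDCW/h — 92.5 %
of the theoretical maximum of 18.925 (the remaining gap is the essential
base growth route plus maintenance).  `infeasible_next` means every
remaining scored candidate was growth-essential.  The same numbers are
reproduced by exhaustive enumeration of all deletion sets of size ≤ 2
(`aerith.brute_force_knockout_oracle`), and a fixed published design can be
scored with `aerith evaluate --deletions R_BRANCH2,R_BRANCH1 ...`.

On a real GEM the call is identical, e.g.
`aerith run --model iJO1366.xml --target EX_succ_e --whitelist native.txt`;
`aerith candidates --model iJO1366.xml` lists the deletion candidates, and
`aerith screen --targets targets.txt` aggregates multi-target runs into
yield-distribution and deletion-frequency tables.

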