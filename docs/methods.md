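# Methods

This note documents the models, numerical choices, and design decisions
behind `evostrain`, and states what the synthetic test networks do and do
not establish about behaviour on real genome-scale models.

## Constraint-based substrate

All computations operate on a stoichiometric model at steady state,
S·v = 0 with lb ≤ v ≤ ub (fluxes in mmol gDW⁻¹ h⁻¹). SBML reading/writing is
delegated to cobrapy (SBML L3+FBC preferred; legacy L2 models with
kinetic-law bound parameters and notes-field GPRs are accepted through the
same reader). Subsystems are serialized as `SUBSYSTEM` reaction notes, the
classic COBRA convention, because cobrapy's group writer does not order
members deterministically. Exchange reactions are detected structurally
(a single nonzero stoichiometric entry), never by id prefix; transporters
are reactions whose metabolites span more than one compartment.

Every LP — FBA, FVA, the MiMBl distance problem, and the yield-space
envelopes — is solved with HiGHS through `scipy.optimize.linprog`. Solutions
are asserted to satisfy steady state to 1e-6. Fluxes below 1e-9 in magnitude
are treated as zero (the solver noise floor); the same tolerance defines
"blocked" in FVA-based model compression.

## Preprocessing

`compress_model` first removes reactions touching a metabolite that occurs
in exactly one (non-exchange) reaction — such dead-end sinks/sources can
never carry steady-state flux — then iteratively deletes FVA-blocked
reactions to a fixed point, asserting the optimal objective value is
unchanged to 1e-6. Iterating to a fixed point (rather than a fixed pass
count) was an open choice; removal can only shrink feasible flux ranges, so
the iteration terminates.

`lump_genes` merges genes into one unit when (i) they occur in exactly the
same reactions and (ii) every containing GPR depends on them only through
their conjunction — verified by exhaustive truth-table enumeration (rules up
to 14 genes; larger rules are left untouched). This lumps obligate enzyme
subunits while provably never lumping isozyme (OR) pairs or genes reused in
other contexts. Deleting a lumped unit deletes all members; GPR truth values
over whole-unit knockouts are unchanged by construction.

`build_target_space` removes, case-insensitively by substring: reactions
without gene association, structural exchanges, cross-compartment
transporters (including gene-associated shuttles — the conservative choice),
and members of five default-excluded subsystems (cell envelope biosynthesis,
membrane lipid metabolism, murein biosynthesis, tRNA charging,
glycerophospholipid metabolism). The list is configurable per run.

Databank candidate reactions are appended with closed bounds (lb = ub = 0)
and only if all their metabolites are native — the search inserts new
network *edges*, not new pathways. Directionality is taken from the databank
as stated; thermodynamic curation is out of scope. An insertion in an
individual opens the reaction to its databank bounds.

## Encoding

Each deletion slot is an NB-bit binary number with
NB = ⌈log₂(50·NT)⌉ (*guaranteed* mode, the default). The rounded form
round(log₂(50·NT)) is available as *literal* mode but can fall one bit short
of the 50-values-per-target guarantee (e.g. NT = 200 → 13 bits < 10 000
values), so the ceiling is the default: the operative contract is that every
target owns ≥ 50 values and per-target draw probabilities differ by < 2%
relative. Values are assigned to targets in contiguous blocks of size
⌊2^NB/NT⌋ or that plus one (block decode is an integer search; a scattered
assignment would satisfy the same balance guarantee). Bits are
most-significant first. Insertion slots use an independent scheme sized from
the number of accepted candidates by the same rule. Crossover points fall
only on slot boundaries, so slots are never split mid-number.

## Phenotype prediction

**FBA** maximizes the biomass reaction; because the growth optimum is
usually degenerate in the product flux, the product rate is resolved by a
second LP with growth fixed at its maximum (within 1e-6) — maximized by
default (the optimistic, OptKnock-style inner problem) or minimized for a
pessimistic bound.

**MiMBl** minimizes Σᵢ |tᵢ(v) − tᵢ^ref| over mutant-feasible flux vectors,
where tᵢ = ½·Σⱼ |Sᵢⱼ·vⱼ| is the metabolite turnover. The L1 norm is used
because it is LP-representable; absolute values are linearized by splitting
each flux into nonnegative forward/backward parts. The split can in
principle overstate a turnover if both parts are used simultaneously; on
irreversible networks this cannot happen, and at optima with nonzero
deviation cost the minimization avoids it — the standard linearization
caveat, documented here once. The reference state is a user-supplied flux
table or, by default, the wild-type FBA distribution (with the
deterministic product tie-break). The LP objective value is reported with
the prediction; it is zero iff the mutant admits the reference turnovers,
and it is non-decreasing under added knockouts.

**Yield spaces** are computed on a grid of n_points = 20 growth rates
between 0 and μmax, minimizing and maximizing the product rate at each
point, with trapezoidal integration for areas. The substrate exchange is
pinned at its maximal uptake by default (the production-envelope
convention): with uptake left free, the minimum-product LP leaves the
uptake — and hence the yield — degenerate. The per-solution-uptake
behaviour remains available (`fix_substrate_uptake=False`). Infeasible grid
points are masked; a model with μmax ≤ 1e-9 yields zero areas.

## Fitness

* **BPCY** = v_P·μ/v_S, and 0 whenever the prediction is infeasible or
  v_S = 0 (no division by zero; scores never go negative, keeping roulette
  weights valid).
* **Production at maximal growth** (OptKnock criterion), tie-break as above.
* **GCS** (simplified growth-coupling strength) = (yield-space area below
  the minimum-yield curve)/(area below the maximum-yield curve), capped to
  [0, 1]; 0 for degenerate spaces. It is 0 exactly when some product-free
  flux distribution exists at every growth rate, and 1 when the yield is
  fully determined by growth.

A single objective is used raw (the natural units, e.g. mol mol⁻¹ h⁻¹ for
BPCY). Multiple objectives are combined linearly after normalizing each by
its wild-type theoretical maximum over the flux cone (equal weights by
default). The normalizers are computed once per run from the wild type —
not from the running population, which would make fitness non-stationary.
The BPCY maximum over the cone is found by a growth-grid scan refined with a
bounded 1-D search, so mutant components stay within [0, 1] up to solver
tolerance.

Parsimony is enforced by F̂ = F + F·y·(Imax − I), strictly decreasing in the
unique-intervention count I for F > 0, y > 0: a deletion that contributes
nothing is always dominated by a duplicate slot. Fitness results are
memoized on the canonical sorted intervention set — duplicate phenotype LPs
dominate GA runtime, and memoization typically reduces LP counts by an order
of magnitude.

## GA operators

* **Selection.** NS = round(NP·X) survivors, decremented by one when
  NP − NS is odd so whole offspring pairs restore the population exactly
  (the alternative — one surplus offspring discarded at random — is also
  implemented for the filling stage). Ties are broken by fewer
  interventions, then lexicographic genome order, making runs reproducible
  under a fixed seed. Configurations whose island-level NS would drop below
  2 are rejected at validation time.
* **Roulette weights.** P_i ∝ F_i − F_R with F_R the best discarded fitness;
  when any survivor has zero fitness (or all excesses vanish) the scaled
  path F*_i = F_i + P_min·ΣF/(1 − P_min·NS) guarantees every P_i ≥ P_min.
  P_min defaults to 0.1/NS — a floor scaled to the uniform weight; a floor
  proportional to NS itself would exceed 1 for NS ≥ 10 and cannot be a
  probability.
* **Pairing** rejects duplicate unordered pairs until the distinct pairs are
  exhausted, then permits repeats (logged).
* **Mutation** flips each bit independently; the single best individual per
  island per generation is exempt, which makes the maximal transformed
  fitness non-decreasing over generations. The adaptive schedule interpolates
  between X_min (at the population's best fitness) and X_max (at or below the
  mean), clamped; a degenerate population (max = mean) mutates at X_max.
* **Islands.** One RNG stream per island (seed + island index), so a
  sequential schedule is bit-identical to any concurrent one that honours
  the streams. Gene-flow events merge and randomly re-split; since merging
  conserves individuals, the all-time champion survives reshuffles (it is
  re-injected over the current worst individual in the rare event a future
  variant drops it), keeping the global best monotone across the whole run.
  Termination is the fixed NGFE·NG budget; an optional early stop on
  diversity stagnation (HD below a threshold for a window of generations) is
  provided but off by default.

Diversity is the normalized average Hamming distance; the default O(NP·L)
column-count evaluation Σ_b c_b·(NP − c_b)/(N_pairs·L) is validated against
the literal pairwise sum in a permanent test. HD is measured after mutation,
before the next selection.

## Synthetic test networks

`make_toy_model` builds a ~26-reaction fermentation caricature: substrate
uptake → two-step glycolysis (producing NADH and, via an AND-pair GPR, a
lumpable subunit gene pair) → pyruvate, drained by biomass, a redox-balanced
product branch (OR-isozyme GPR), a redox-consuming overflow branch, six
redox-neutral overflow branches, a transporter and an excluded-subsystem
reaction (both of which must be filtered from the target space), and two
capacity-limited respiration isozymes. The capacities make the wild type
secrete product (BPCY 3.6) while deleting both isozymes growth-couples
production (BPCY 10.0) — the designed, exhaustively verifiable optimum. The
databank adds a higher-yield heterologous product route (verified beneficial
by LP at generation time: BPCY 15.0 after the coupling knockouts), a
respiration duplicate (detrimental), and neutral overflow duplicates.

Insertion benefit is assessed with the FBA predictor: a minimal-adjustment
predictor like MiMBl by construction never activates a *voluntary* new
route (staying at the reference is always closer), so under MiMBl a
beneficial insertion leaves the predicted phenotype unchanged. This is a
property of minimal-adjustment phenotypes, not of the search.

What passing tests on these fixtures shows: the operators implement their
contracts, the encoding's balance guarantee holds for any NT, the GA
recovers exhaustively verified optima on a 12-target space, and the
premature-convergence phenomenology (low mutation rate → diversity collapse
→ sub-optimal convergence) is reproduced. What it does not show: solution
quality or parameter transfer on genome-scale models (thousands of targets,
LP times in the tens of milliseconds), realistic GPR complexity, or the
biology of any particular organism — the toy's stoichiometry is deliberately
schematic and its growth rates are not calibrated to physiological units.

## Defaults

| Parameter | Default | Meaning |
|---|---|---|
| NP | 20 | population size |
| X | 0.25 | selection rate |
| R | 0.05 | per-bit mutation rate |
| NC | 1 | islands |
| NG | 60 | generations per gene-flow event |
| y | 0 | parsimony trade-off factor |
| P_min coefficient | 0.1 | zero-fitness floor, P_min = 0.1/NS |
| min values per target | 50 | encoding balance guarantee |
| n_points | 20 | yield-space grid |
| blocked tolerance | 1e-9 | FVA compression threshold |
| steady-state tolerance | 1e-6 | post-solve assertion |

NP = 20, X = 0.25, R = 0.05 are the settings found to balance exploration
and intensification for strain-design problems of this class; tests use
smaller NG·NGFE budgets (50 generations) because the toy's 79-set search
space converges well within them.

## Known limitations

* Dense stoichiometric matrices: fine up to a few thousand reactions;
  genome-scale models work but would benefit from a sparse LP path.
* No MOMA (quadratic) predictor, regulatory/kinetic constraints, or
  knockdown/overexpression targets.
* The scalarized multi-objective combination carries no Pareto-front
  bookkeeping.
* Island evolution is executed sequentially (deterministically equivalent
  to concurrent execution by the RNG-stream contract); no distributed mode.
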