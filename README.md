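# evostrain

Genetic-algorithm strain design on constraint-based metabolic models.

`evostrain` searches for sets of reaction or gene deletions — optionally
combined with insertions of non-native reactions from a candidate databank —
that turn a microbe into an overproducer of a target metabolite. It is aimed
at metabolic engineers working with stoichiometric models (SBML, genome-scale
or reduced) who want growth-coupled production designs without formulating
bilevel MILPs: the genetic algorithm treats the phenotype predictor as a
black box, so nonlinear objectives and arbitrary prediction methods plug in
directly.

## The method

A candidate design (*individual*) is a fixed-length binary genome: ND
deletion slots of NB bits each (plus NI insertion slots). Every one of the
2^NB values of a slot maps to one of the NT targets in the *target space*;
NB is chosen so each target owns at least 50 binary values
(NB = ⌈log₂(50·NT)⌉), in contiguous blocks whose sizes differ by at most
one, keeping per-target draw probabilities within 2% of each other.
Duplicate slots collapse, so an individual may realize fewer than ND unique
perturbations.

Each generation applies, per island:

1. **Selection** — the NS = round(NP·X) fittest individuals survive
   (parity-adjusted so offspring pairs fill the gap exactly).
2. **Mating** — roulette-wheel pairing with weights
   P_i = (F_i − F_R)/Σ(F − F_R), where F_R is the best discarded fitness; a
   floor P_min keeps zero-fitness survivors matable.
3. **Crossover** — single-point at a slot boundary.
4. **Mutation** — per-bit flips at rate R (optionally adaptive per
   individual, X_i = (F_max−F_i)/(F_max−F′)·(X_max−X_min)+X_min); the best
   individual is exempt (elitism).

The population is split over NC islands; after NG generations the islands
merge and re-split at random (a *gene-flow event*), NGFE times. Population
diversity is tracked as the normalized average Hamming distance
HD = Σ_pairs (differing bits)/(N_pairs·L).

Fitness defaults to the biomass-product coupled yield
**BPCY = v_P·μ/v_S** (mol mol⁻¹ h⁻¹), computed from a MiMBl phenotype
prediction (minimal L1 distance between mutant and reference metabolite
turnovers t_i = ½·Σ_j |S_ij·v_j|) or from FBA. Multi-objective mode adds the
production rate at maximal growth (the OptKnock criterion) and a simplified
growth-coupling strength (GCS — the fraction of the yield-space area that
lies below the guaranteed-minimum-yield curve), each normalized by its
wild-type theoretical maximum. Fitness is transformed to favour parsimonious
designs, F̂ = F + F·y·(Imax − I), with trade-off factor y ≥ 0 and I the
number of unique interventions.

## Worked example

The built-in toy network is a caricature of fermentative central carbon
metabolism with a designed optimum: two respiration isozymes cap NADH
reoxidation, and deleting both forces the redox balance through the
secreted-product branch.

```python
import evostrain as es
from evostrain.fixtures import TOY_RATES

model, reference = es.make_toy_model()
space = es.build_target_space(model)                 # 12 deletion targets
spec = es.GenomeSpec.for_space(space, ND=2)          # 10 bits per slot
evaluator = es.FitnessEvaluator(model, space, spec, TOY_RATES,
                                reference=reference)
config = es.GAConfig(NP=20, X=0.25, R=0.05, ND=2, NC=2, NG=25, NGFE=2, seed=1)
result = es.run(evaluator, config, spec)
```

Running `python examples/02_knockout_search.py` prints:

```
target space: 12 deletion targets, 10 bits per slot
GA best: F = 10.000 mol/mol/h, deletions = ['RESP1', 'RESP2']
LP evaluations: 29 (memoization hits: 829)
exhaustive optimum: F = 10.000, deletions = ['RESP1', 'RESP2']
```

The GA recovers the globally optimal knockout pair (BPCY 10.0 vs the
wild-type 3.6 mol mol⁻¹ h⁻¹) while solving only 29 distinct phenotype LPs —
fitness memoization absorbs the remaining 829 lookups. The other examples
show phenotype prediction and yield spaces (`01_phenotype_prediction.py`:
the mutant's growth-coupling strength is 0.500) and gene-level targets plus
databank insertions (`03_gene_targets_and_insertions.py`: the GA combines
the coupling pair with a higher-yield heterologous product route, F = 15.0).

## Command line

```bash
evostrain fixtures --outdir fixtures/        # toy SBML + databank + reference
evostrain run run.yaml                       # trace.csv, summary.json, designs.csv
evostrain sweep run.yaml --grid 'R=0.001,0.05,0.5' --replicates 5
```

The YAML config names the model, the product/substrate/biomass reaction
ids, objectives, predictor, and the GA parameters; every run is reproducible
from the echoed config and seed in `summary.json`.

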