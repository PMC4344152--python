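# Methods

## The question

Modular organization — internally dense sub-networks with no connections
between them — is ubiquitous in biological networks, yet simulations with
small neural networks have repeatedly found that modularity does not, by
itself, improve information-processing efficiency. `modnets` implements a
simulation pipeline for asking how this conclusion depends on network
*size*: it evolves connection weights of structurally fixed feed-forward
networks of three connectivity types and compares their training speed and
plateau performance across sizes and task variants.

## Model

### Networks

Three-layer feed-forward networks with logistic units in the hidden and
output layers:

    h_j = g(Σ_i M_ij w_ij x_i + b_j),   y = g(Σ_j v_j h_j + c),
    g(z) = 1 / (1 + e^(−βz)),

where `M` is a fixed boolean input→hidden connectivity mask, `β` the
activation steepness, and input nodes pass values through unchanged.
A network of *m* modules has 8m input, 4m hidden and 1 output node.
The hidden→output layer is always complete; only `M` varies:

| kind  | mask                                  | edges |
|-------|---------------------------------------|-------|
| FCNMN | all true                              | 32 m² |
| PMN   | m diagonal 8×4 blocks                 | 32 m  |
| SNMN  | i.i.d. Bernoulli(1/m)                 | 32 m in expectation |

The SNMN edge probability is defined as the PMN edge count divided by the
FCNMN edge count, i.e. `32m / 32m² = 1/m`, so the sparse non-modular
network matches the modular network's connective density. A Bernoulli draw
may isolate a hidden node; such masks are kept as drawn (an exact-count
sampling variant is available via `build_mask(..., exact_count=True)` for
sensitivity checks). Each SNMN replicate draws its own mask.

### Inputs and tasks

Each module (or the corresponding input area of a non-modular network)
receives a 256×8 array of all binary patterns of length 8, row-randomized
independently per module; a size-m network sees the 256×8m concatenation.
One input set per size class is generated from the master seed and shared
by every architecture, state and replicate of that size.

Whether the m module arrays share one row randomization or each draw
their own is a genuine modelling choice with large consequences, because
it decides how much information a hidden node that samples inputs across
modules can see. With independent randomizations (the default), any 8
input columns carry nearly 8 bits about the pattern identity, so sparse
cross-module connectivity loses little information. With one
randomization tiled across modules (`make_input_set(...,
tile_modules=True)`, `ExperimentPlan(tile_modules=True)`), the network
has only 8 distinct input signals in total; duplicated columns make
cross-module sampling partially redundant, which selectively handicaps
the sparse non-modular network and flattens the fully connected network's
advantage. Our own runs show the choice flips which architecture
comparisons come out significant (see "What the test suite replicates"
below), so both constructions are first-class options; the default
follows the interpretation that different modules process different data
streams, which is the biological framing the architecture models.

Fitness of a network is the product of its two sub-task accuracies,

    fitness = (accepts correct / n_accept) × (rejects correct / n_reject),

with strict inequalities at the output threshold (an output exactly at the
threshold counts as incorrect for both sets; with sigmoid outputs ties are
measure-zero, the rule just fixes determinism). Four system states probe
robustness:

1. **baseline** — accept a random 100-pattern subset (output > 0.5),
   reject the other 156 (output < 0.5); β = 1.
2. **dull/intense** — 140 rows are "dulled": every 1 in the row is replaced
   by one per-row draw u ~ Uniform(0, 0.5). The network must accept the
   140 dulled rows and reject the 116 intense (unmodified) ones. The
   dulling is re-drawn per replicate and shared across architectures
   within a replicate index.
3. **hard output encoding** — as state 1 with threshold 0.9 for both sets.
4. **insensitive neurons** — as state 1 with β = 0.1. The task object is
   identical to state 1's; only the genome's β differs.

### Genetic algorithm

Populations of 50 genomes are initialized with every free parameter
(unmasked weights, all biases) i.i.d. Uniform(−3, 3). Each generation the
top 10 networks by fitness are selected (ties broken stably by population
index; a random tie-break is available in config), each is cloned 5 times,
and every free parameter of every clone is perturbed by an independent
Normal(0, 0.25) draw. There is no elitism, no crossover, and no bounds on
mutated weights — the population is entirely replaced each generation.
Masked weight positions are pinned to exactly zero throughout.

Per-replicate performance is summarized at two checkpoints: generation
1000 ("speed") and 10000 ("ultimate fitness"), except state 2, whose easy
task plateaus within ~100 generations and is therefore checkpointed at 15
and 500. The analysed per-replicate quantity is the population's **best**
fitness at the checkpoint; the population mean is recorded alongside so
the alternative reading can be analysed without re-running (the choice of
"best" is a design decision — the source experiments do not state which
summary the per-replicate value is).

### Analysis

Within each design cell the modular network is compared with each
non-modular network by an equal-variance two-sample t-test (df = n₁+n₂−2)
and by the pooled-SD standardized mean difference d (Cohen's d). Sign
conventions, chosen to match the usual presentation of these comparisons,
are opposed and documented in the report columns: `t_nonmod_minus_mod` is
positive when the non-modular network is better, `d_mod_minus_nonmod`
positive when the modular network is better. Group summaries carry 95%
t-intervals (mean ± t₀.₉₇₅,ₙ₋₁ · sd/√n). Significance bands: `**` for
p < 0.01, `*` for 0.01 ≤ p < 0.05. The Hedges small-sample correction
(1 − 3/(4 df − 1)) is available (`hedges=True`) but off by default, since
the conventional definition of d in this literature is ambiguous about it.
No multiple-testing correction is applied; the report carries the total
comparison count so users can apply their own, and marginal p-values near
0.05 deserve scepticism.

## Seed architecture and reproducibility

Every source of randomness derives from one master seed through keyed
`numpy.random.SeedSequence` derivation (`derive_seed(master, domain,
*keys)`): input set per size class; task seed per (size, replicate),
shared across architectures and across states 1/3/4 so those states differ
only in the stated manipulation; SNMN mask seed per (size, replicate);
run seed (initialization + mutation stream) per (state, size, replicate,
architecture). Consequences: identical seeds give bit-identical
trajectories; results are invariant to execution order and to serial vs.
parallel execution; and a run directory is resumable (finished cells are
loaded from disk, guarded by a plan-configuration hash).

## Numerical choices

* The forward pass is float64 throughout. The population-level evaluator
  computes all 50 networks' outputs in one matrix product per generation;
  block-diagonal (PMN) masks use a per-block product that skips the
  structurally zero weights. Both paths are tested against a per-node
  scalar oracle.
* The evaluator computes the logistic via `numpy.exp` in place;
  `exp(−βz)` may overflow to `inf` for strongly negative pre-activations
  (weights are unbounded under mutation), in which case the reciprocal
  correctly underflows to 0 and the overflow warning is suppressed.
* The activation is read as `1/(1 + e^(−β·input))`; the alternative parse
  `1/(1 + e^(−β)·input)` of the loosely-parenthesized formula is not a
  sigmoid and is rejected.
* Selection uses a stable argsort, so tied fitnesses prefer the lower
  population index deterministically.
* A degenerate zero pooled variance in the t-test is signalled explicitly
  (t = 0, p = 1 for equal means; t = ±inf, p = 0 otherwise) rather than
  returned as NaN.

## What the generator does and does not emulate

The synthetic inputs are the study's actual stimuli — exhaustive binary
pattern sets with randomized row order — not a proxy for external data, so
there is no approximation gap on the input side. What the pipeline does
*not* model: evolution of network structure (masks are static; only
weights evolve), recurrent or multi-hidden-layer architectures,
connection-cost terms in fitness, and real sensory statistics (patterns
are uniform-random subsets, not natural stimuli). Passing tests therefore
show that the *relative efficiency* effects hold for this idealized
weight-evolution system, not that modularity is favoured in any particular
biological network.

## What the test suite replicates, and at what size

The full coarse design (4 states × 2 sizes × 3 architectures × 20
replicates, 10000 generations) is expressible through `ExperimentPlan`
and was sized for multi-hour batch runs. The package's own test suite
checks the directional effects at reduced replication, a choice made so
the suite doubles as a quick end-to-end verification: small-network
FCNMN-vs-PMN at 5 replicates and full 10000 generations; large-network
(12-module) PMN-vs-FCNMN at 5 replicates and the 1000-generation speed
checkpoint; the PMN-vs-SNMN fine-sweep comparison at sizes
m ∈ {2, 3, 6, 9} with 2 replicates and full 10000 generations. The
acceptance script runs the small-network FCNMN-vs-PMN cell at the full
20 replicates and 10000 generations.

Under the default (independent-stream) stimulus construction, the
small-network effects are large and stable across master seeds: the
fully connected network beats the modular one decisively (t₃₈ ≈ 5 at
generation 1000 and ≈ 9 at 10000 in our 20-replicate runs), the sparse
network ties the modular one, and virtually every replicate gains
fitness during training. The large-network speed comparison and the
fine-sweep PMN-vs-SNMN comparison, by contrast, come out as statistical
ties or mixed signs under this construction (large networks:
|t| < 0.2 at 10 replicates), and the corresponding directional tests are
expected to fail; under the tiled construction those two effects are
strong (PMN ahead of FCNMN in large networks; SNMN far behind PMN at
every fine-sweep size) while the small-network ordering collapses to a
tie. The suite pins the default construction's behaviour; the tiled
variant is exercised structurally and left to users as a sensitivity
option.

## Known limitations

* Stochastic conclusions at 2–5 replicates are directional only; exact
  t statistics at reduced replication are noisy by construction.
* The SNMN fast path is dense; very large sparse networks would benefit
  from a sparse matrix product, which is not implemented.
* Parallelism is local-process (joblib) only; there is no cluster
  integration.
* `best_fitness` vs `mean_fitness` as the analysed quantity changes
  absolute levels (best > mean by construction) but not the directional
  comparisons in our runs; both columns are always recorded.
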