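# modnets

**Does network modularity pay off only at scale?** Most biological
networks — cortical sensory maps, gene-regulatory circuits, metabolic
pathways — are modular, yet classic simulations with *small* model neural
networks found that modularity does not improve functional efficiency.
`modnets` is a simulation pipeline for testing how that conclusion depends
on network size. It evolves the connection weights of structurally fixed,
three-layer feed-forward networks under a genetic algorithm and compares
three connectivity types with identical node counts:

* **FCNMN** — fully connected non-modular network (32 m² input→hidden edges
  for m modules),
* **PMN** — perfectly modular network (m independent 8-input/4-hidden
  blocks; 32 m edges),
* **SNMN** — sparse non-modular network (random edges at the PMN's density,
  p = 1/m).

Networks must accept a designated subset of 256 random binary input
patterns (output > threshold) and reject the rest, with fitness

    f = (accepts correct / n_accept) × (rejects correct / n_reject) ∈ [0, 1].

Training is truncation selection: each generation the top 10 of 50
networks are cloned 5× and every free parameter is perturbed by
Normal(0, 0.25) noise. Performance per replicate is summarized at a
"speed" checkpoint (generation 1000) and a plateau checkpoint (10000),
and architectures are compared by equal-variance t-tests and pooled-SD
effect sizes d across replicates. Four system states (baseline,
real-valued "dull/intense" inputs, a 0.9 output threshold, and
low-steepness β = 0.1 neurons) probe the robustness of the size effect.

The intended audience is researchers in systems biology and
neuroevolution who want a reproducible, seed-exact re-implementation of
this class of experiment to extend (new sizes, states, selection schemes)
rather than re-create from scratch.

See `docs/methods.md` for the full model description and design decisions.

## Worked example

Evolve small (16/8/1) networks of all three types for 1000 generations,
5 replicates each, and compare the modular network with each non-modular
one:

```python
from modnets import ExperimentPlan, run_plan, build_comparison_report

plan = ExperimentPlan(
    states=(1,), module_counts=(2,),
    architectures=("FCNMN", "PMN", "SNMN"),
    n_replicates=5, master_seed=42,
    checkpoints_by_state={1: (1000,)},
)
table = run_plan(plan)
report = build_comparison_report(table)
print(report[["comparison", "mean_mod", "mean_nonmod",
              "t_nonmod_minus_mod", "p_value", "d_mod_minus_nonmod", "stars"]].round(4))
```

```
     comparison  mean_mod  mean_nonmod  t_nonmod_minus_mod  p_value  d_mod_minus_nonmod stars
0  FCNMN_vs_PMN    0.6402       0.6957              3.1814   0.0130             -2.0121     *
1   SNMN_vs_PMN    0.6402       0.6350             -0.3660   0.7239              0.2314
```

Reading the output: `mean_mod`/`mean_nonmod` are mean best fitness over
the 5 replicates; `t_nonmod_minus_mod` is the pooled t statistic (df 8
here), positive when the non-modular network trains better; and
`d_mod_minus_nonmod` is Cohen's d, positive when the modular network is
better. In this small-network run the fully connected network is
significantly ahead of the modular one after 1000 generations
(t₈ = 3.18, d = −2.01, `*`), while the equally sparse SNMN is
statistically indistinguishable from the PMN — the classic small-network
ordering whose dependence on size the package exists to probe.

The same pipeline is available from the shell:

```sh
modnets run plan.yaml --out results/ --jobs 4     # resumable; seed-exact
modnets analyze results/results.csv --out report.csv
modnets report results/results.csv --out report/ --plot
```

where `plan.yaml` holds the `ExperimentPlan` fields
(`states`, `module_counts`, `architectures`, `n_replicates`,
`master_seed`, optional `ga` and `checkpoints_by_state`).

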