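"""Genetic training: truncation selection, cloning, Gaussian mutation.

Each generation the 10 fittest of the 50 networks are selected, each is
cloned 5 times, and every free parameter of every clone is perturbed by an
independent Normal(0, sd = 0.25) draw to form the next generation.  There
is no elitism -- all 50 members of the next generation are mutated clones
and the parent generation is discarded -- no crossover, and no bounds on
mutated weights (the Uniform(-3, 3) bounds apply to initialization only).

``run_evolution`` is the reproducible entry point: one integer seed
determines the initial population and every mutation draw, so identical
seeds give bit-identical trajectories.  Internally the population is kept
as a (50, n_free) matrix of free parameters and evaluated in a single
batched forward pass per generation; the public per-genome operations
(:func:`select_parents`, :func:`reproduce`) consume random draws in exactly
the same order, so one cycle of the batched loop equals one
select/reproduce cycle on Genome objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .input_generation import InputSet, TaskSpec
from .networks import (
    INIT_BOUND,
    ArchitectureKind,
    ArchitectureMask,
    Genome,
    genome_from_flat,
    genome_to_flat,
)

__all__ = [
    "GAConfig",
    "FitnessTrajectory",
    "select_parents",
    "reproduce",
    "run_evolution",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults are the standard training regime: population 50, top-10
    truncation selection, 5 clones per parent, Normal(0, 0.25) mutation,
    with fitness recorded at generations 1000 and 10000 ("speed" and
    "ultimate fitness" checkpoints).  ``tie_break`` controls selection when
    fitnesses tie: "stable" prefers the lower population index, "random"
    picks uniformly among ties.
    """

    population_size: int = 50
    n_parents: int = 10
    clones_per_parent: int = 5
    mutation_sd: float = 0.25
    n_generations: int = 10_000
    checkpoint_generations: tuple[int, ...] = (1000, 10_000)
    tie_break: str = "stable"

    def __post_init__(self) -> None:
        if self.n_parents * self.clones_per_parent != self.population_size:
            raise ValueError(
                "n_parents * clones_per_parent must equal population_size "
                f"({self.n_parents} * {self.clones_per_parent} != {self.population_size})"
            )
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd must be >= 0")
        if self.tie_break not in ("stable", "random"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        cps = tuple(sorted(set(int(c) for c in self.checkpoint_generations)))
        object.__setattr__(self, "checkpoint_generations", cps)
        if cps and (cps[0] < 0 or cps[-1] > self.n_generations):
            raise ValueError(
                f"checkpoint_generations {cps} must lie within [0, {self.n_generations}]"
            )


@dataclass(frozen=True, eq=False)
class FitnessTrajectory:
    """Per-checkpoint fitness summaries of one evolution run.

    ``best_fitness`` is the top performer's fitness in the generation-g
    population; ``mean_fitness`` the population mean.  Generation 0 is the
    freshly initialized population, generation g the population after g
    select/clone/mutate cycles.
    """

    generations: np.ndarray
    best_fitness: np.ndarray
    mean_fitness: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("generations", "best_fitness", "mean_fitness"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (self.best_fitness >= self.mean_fitness - 1e-12).all():
            raise ValueError("best_fitness must be >= mean_population_fitness")

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "generation": self.generations,
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
            }
        )
        for key, val in self.metadata.items():
            if np.isscalar(val) or isinstance(val, str):
                df[key] = val
        return df

    def at(self, generation: int) -> tuple[float, float]:
        """(best, mean) fitness at a recorded checkpoint generation."""
        idx = np.flatnonzero(self.generations == generation)
        if not len(idx):
            raise KeyError(f"generation {generation} was not recorded")
        return float(self.best_fitness[idx[0]]), float(self.mean_fitness[idx[0]])


# ---------------------------------------------------------------------------
# selection and reproduction on Genome lists (reference surface)
# ---------------------------------------------------------------------------

def _selection_order(
    fitnesses: np.ndarray, tie_break: str, rng: np.random.Generator | None
) -> np.ndarray:
    """Population indices sorted by descending fitness.

    Stable tie-break keeps lower indices first; random tie-break shuffles
    before the stable sort so equal-fitness members are ordered uniformly.
    """
    if tie_break == "random":
        if rng is None:
            raise ValueError("random tie-break requires an rng")
        perm = rng.permutation(len(fitnesses))
        return perm[np.argsort(-fitnesses[perm], kind="stable")]
    return np.argsort(-fitnesses, kind="stable")


def select_parents(
    population: Sequence[Genome],
    fitnesses: Sequence[float],
    config: GAConfig = GAConfig(),
    rng: np.random.Generator | None = None,
) -> list[Genome]:
    """The ``n_parents`` fittest genomes, ties broken per config."""
    fitnesses = np.asarray(fitnesses, dtype=np.float64)
    if len(population) != len(fitnesses):
        raise ValueError("population and fitnesses must have equal length")
    if len(population) != config.population_size:
        raise ValueError(
            f"expected population of {config.population_size}, got {len(population)}"
        )
    order = _selection_order(fitnesses, config.tie_break, rng)
    return [population[i] for i in order[: config.n_parents]]


def _mutate_clones(
    parent_flats: np.ndarray, config: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Clone each parent ``clones_per_parent`` times and add Gaussian noise.

    Offspring order is parent 0's clones, then parent 1's, and so on; the
    noise matrix is drawn row-major so the draw sequence matches a per-clone
    loop exactly.
    """
    clones = parent_flats[np.repeat(np.arange(len(parent_flats)), config.clones_per_parent)]
    noise = rng.standard_normal(clones.shape) * config.mutation_sd
    return clones + noise


def reproduce(
    parents: Sequence[Genome],
    seed: int | np.random.Generator,
    config: GAConfig = GAConfig(),
) -> list[Genome]:
    """Produce the next generation from the selected parents.

    Every free parameter (unmasked weights and all biases) of every clone
    receives an independent Normal(0, mutation_sd) perturbation; masked
    weight positions stay exactly zero.
    """
    if len(parents) != config.n_parents:
        raise ValueError(f"expected {config.n_parents} parents, got {len(parents)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = parents[0].architecture
    beta = parents[0].beta
    flats = np.stack([genome_to_flat(g) for g in parents])
    offspring = _mutate_clones(flats, config, rng)
    return [genome_from_flat(mask, row, beta) for row in offspring]


# ---------------------------------------------------------------------------
# batched population evaluation
# ---------------------------------------------------------------------------

def _sigmoid_(z: np.ndarray, beta: float) -> np.ndarray:
    """In-place logistic 1/(1 + exp(-beta z)).

    exp(-beta z) may overflow to inf for strongly negative pre-activations
    (weights are unbounded under mutation); the reciprocal then correctly
    underflows to 0, so the overflow warning is suppressed.
    """
    if beta != 1.0:
        z *= beta
    np.negative(z, out=z)
    with np.errstate(over="ignore"):
        np.exp(z, out=z)
    z += 1.0
    np.reciprocal(z, out=z)
    return z

class PopulationEvaluator:
    """Evaluates a whole population, stored flat, in one vectorized pass.

    The free-parameter layout per row is: unmasked input-to-hidden weights
    in row-major mask order, hidden-to-output weights, hidden biases,
    output bias -- identical to the per-genome layout in
    :func:`modnets.networks.genome_from_flat`.  Block-diagonal (PMN) masks
    use a per-block matmul that skips the structurally zero weights; the
    result is numerically identical to the dense path (same sums of the
    same terms, in the same intra-block order).
    """

    def __init__(
        self,
        mask: ArchitectureMask,
        input_set: InputSet,
        task: TaskSpec,
        beta: float,
        population_size: int,
    ) -> None:
        if input_set.n_inputs != mask.n_inputs:
            raise ValueError(
                f"input set has {input_set.n_inputs} columns but mask expects {mask.n_inputs}"
            )
        self.mask = mask
        self.beta = float(beta)
        self.task = task
        self.pop = population_size
        self.n_hidden = mask.n_hidden
        self.n_edges = mask.n_edges
        self.n_free = mask.n_edges + 2 * mask.n_hidden + 1
        self.x = np.ascontiguousarray(input_set.patterns)
        self._block = mask.kind is ArchitectureKind.PMN
        if self._block:
            m = mask.n_modules
            # (m, n_patterns, 8): pattern block per module
            self._xb = np.ascontiguousarray(
                self.x.reshape(len(self.x), m, -1).transpose(1, 0, 2)
            )
        else:
            rows, cols = np.nonzero(mask.mask)
            # scatter indices for all population members into one wide matrix
            self._rows = np.tile(rows, self.pop)
            self._cols = (
                np.arange(self.pop)[:, None] * self.n_hidden + cols[None, :]
            ).ravel()
            self._wide = np.zeros((mask.n_inputs, self.pop * self.n_hidden))

    def outputs(self, flat: np.ndarray) -> np.ndarray:
        """Network outputs for every (pattern, member): shape (256, pop)."""
        if flat.shape != (self.pop, self.n_free):
            raise ValueError("flat population has the wrong shape")
        n_e, n_h, p = self.n_edges, self.n_hidden, self.pop
        w_ho = flat[:, n_e : n_e + n_h]
        b_h = flat[:, n_e + n_h : n_e + 2 * n_h]
        b_o = flat[:, -1]
        if self._block:
            m = self.mask.n_modules
            wb = flat[:, :n_e].reshape(p, m, -1, 4).transpose(1, 2, 0, 3)
            wb = np.ascontiguousarray(wb).reshape(m, -1, p * 4)
            pre = np.matmul(self._xb, wb)  # (m, 256, p*4)
            pre = pre.reshape(m, -1, p, 4).transpose(1, 2, 0, 3).reshape(-1, p, n_h)
        else:
            self._wide[self._rows, self._cols] = flat[:, :n_e].ravel()
            pre = (self.x @ self._wide).reshape(-1, p, n_h)
        pre += b_h[None, :, :]
        hidden = _sigmoid_(pre, self.beta)
        out_pre = np.einsum("rpj,pj->rp", hidden, w_ho)
        out_pre += b_o[None, :]
        return _sigmoid_(out_pre, self.beta)

    def fitness(self, flat: np.ndarray) -> np.ndarray:
        """Per-member fitness: product of accept and reject accuracies."""
        y = self.outputs(flat)
        thr = self.task.accept_threshold
        acc = (y[self.task.accept_indices] > thr).mean(axis=0)
        rej = (y[self.task.reject_indices] < thr).mean(axis=0)
        return acc * rej


def run_evolution(
    mask: ArchitectureMask,
    task: TaskSpec,
    input_set: InputSet,
    ga: GAConfig = GAConfig(),
    beta: float = 1.0,
    seed: int = 0,
    metadata: dict | None = None,
) -> FitnessTrajectory:
    """Run one replicate of the genetic algorithm and record checkpoints.

    Generation 0 is the freshly initialized Uniform(-3, 3) population;
    generation g is the population after g select/clone/mutate cycles.
    All 50 fitnesses are evaluated every generation; (best, mean) records
    are emitted at ``ga.checkpoint_generations``.
    """
    evaluator = PopulationEvaluator(mask, input_set, task, beta, ga.population_size)
    rng = np.random.default_rng(seed)
    flat = rng.uniform(-INIT_BOUND, INIT_BOUND, size=(ga.population_size, evaluator.n_free))
    fit = evaluator.fitness(flat)

    checkpoints = set(ga.checkpoint_generations)
    gens, best, mean = [], [], []

    def record(g: int) -> None:
        gens.append(g)
        best.append(float(fit.max()))
        mean.append(float(fit.mean()))

    if 0 in checkpoints:
        record(0)
    n_parents = ga.n_parents
    for g in range(1, ga.n_generations + 1):
        order = _selection_order(fit, ga.tie_break, rng)
        flat = _mutate_clones(flat[order[:n_parents]], ga, rng)
        fit = evaluator.fitness(flat)
        if g in checkpoints:
            record(g)

    meta = {
        "architecture": mask.kind.value,
        "n_modules": mask.n_modules,
        "state": task.state_id,
        "beta": beta,
        "seed": seed,
    }
    if metadata:
        meta.update(metadata)
    return FitnessTrajectory(np.array(gens), np.array(best), np.array(mean), meta)
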