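"""Truncation selection, Gaussian mutation, and trajectory reproducibility."""

import math

import numpy as np
import pytest

from modnets.evolution import (
    GAConfig,
    PopulationEvaluator,
    reproduce,
    run_evolution,
    select_parents,
)
from modnets.fitness_tasks import evaluate_fitness, make_task
from modnets.input_generation import make_input_set
from modnets.networks import (
    ArchitectureKind,
    ArchitectureMask,
    build_mask,
    forward,
    genome_to_flat,
    init_genome,
)


@pytest.fixture(scope="module")
def setting():
    inp = make_input_set(2, seed=60)
    inp1, task = make_task(1, 61, inp)
    return inp1, task, build_mask("PMN", 2)


def make_population(mask, n=50, beta=1.0, seed=0):
    rng = np.random.default_rng(seed)
    return [init_genome(mask, beta=beta, seed=rng) for _ in range(n)]


class TestGAConfig:
    def test_defaults_are_the_standard_regime(self):
        ga = GAConfig()
        assert (ga.population_size, ga.n_parents, ga.clones_per_parent) == (50, 10, 5)
        assert ga.mutation_sd == 0.25

    def test_inconsistent_offspring_arithmetic_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=50, n_parents=7, clones_per_parent=5)

    def test_checkpoints_must_lie_within_run(self):
        with pytest.raises(ValueError):
            GAConfig(n_generations=100, checkpoint_generations=(50, 200))

    def test_negative_mutation_sd_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(mutation_sd=-0.1)


class TestSelection:
    def test_top_ten_by_fitness(self, setting):
        _, _, mask = setting
        pop = make_population(mask)
        fits = np.arange(50) / 100.0  # ascending: best are indices 40..49
        parents = select_parents(pop, fits)
        assert parents == [pop[i] for i in range(49, 39, -1)]

    def test_all_equal_fitness_keeps_lowest_indices(self, setting):
        _, _, mask = setting
        pop = make_population(mask)
        parents = select_parents(pop, np.ones(50))
        assert parents == pop[:10]

    def test_random_tie_break_samples_among_ties(self, setting):
        _, _, mask = setting
        pop = make_population(mask)
        cfg = GAConfig(tie_break="random")
        picks = {
            tuple(pop.index(g) for g in select_parents(pop, np.ones(50), cfg, np.random.default_rng(s)))
            for s in range(5)
        }
        assert len(picks) > 1

    def test_size_mismatch_raises(self, setting):
        _, _, mask = setting
        pop = make_population(mask)
        with pytest.raises(ValueError):
            select_parents(pop, np.ones(49))


class TestReproduce:
    def test_fifty_offspring_from_ten_parents(self, setting):
        _, _, mask = setting
        parents = make_population(mask, n=10)
        kids = reproduce(parents, seed=1)
        assert len(kids) == 50
        for kid in kids:
            assert np.all(kid.w_ih[~mask.mask] == 0.0)

    def test_zero_mutation_yields_exact_clones(self, setting):
        _, _, mask = setting
        parents = make_population(mask, n=10)
        kids = reproduce(parents, seed=1, config=GAConfig(mutation_sd=0.0))
        for i, kid in enumerate(kids):
            assert np.array_equal(genome_to_flat(kid), genome_to_flat(parents[i // 5]))

    def test_mean_absolute_perturbation_matches_half_normal(self, setting):
        # E|N(0, sd)| = sd * sqrt(2/pi); Monte-Carlo over ~32k free parameters
        _, _, mask = setting
        parents = make_population(mask, n=10)
        kids = reproduce(parents, seed=2)
        deltas = np.concatenate(
            [
                np.abs(genome_to_flat(kid) - genome_to_flat(parents[i // 5]))
                for i, kid in enumerate(kids)
            ]
        )
        expected = 0.25 * math.sqrt(2 / math.pi)  # 0.19947...
        se = 0.25 * math.sqrt(1 - 2 / math.pi) / math.sqrt(len(deltas))
        assert abs(deltas.mean() - expected) < 6 * se

    def test_wrong_parent_count_raises(self, setting):
        _, _, mask = setting
        with pytest.raises(ValueError):
            reproduce(make_population(mask, n=9), seed=0)


class TestRunEvolution:
    def test_seeded_runs_are_bit_identical(self, setting):
        inp, task, mask = setting
        ga = GAConfig(n_generations=30, checkpoint_generations=(0, 10, 30))
        a = run_evolution(mask, task, inp, ga, seed=5)
        b = run_evolution(mask, task, inp, ga, seed=5)
        assert np.array_equal(a.best_fitness, b.best_fitness)
        assert np.array_equal(a.mean_fitness, b.mean_fitness)
        c = run_evolution(mask, task, inp, ga, seed=6)
        assert not np.array_equal(a.best_fitness, c.best_fitness)

    def test_zero_mutation_is_an_exact_fixed_point(self, setting):
        inp, task, mask = setting
        ga = GAConfig(mutation_sd=0.0, n_generations=5, checkpoint_generations=tuple(range(6)))
        traj = run_evolution(mask, task, inp, ga, seed=3)
        # selection cannot lose the best clone when clones are exact
        assert np.all(traj.best_fitness[1:] == traj.best_fitness[1])
        assert traj.best_fitness[1] == traj.best_fitness[0]

    def test_trajectory_invariants(self, setting):
        inp, task, mask = setting
        ga = GAConfig(n_generations=20, checkpoint_generations=(0, 20))
        traj = run_evolution(mask, task, inp, ga, seed=8)
        assert np.all(traj.best_fitness >= traj.mean_fitness)
        assert np.all((traj.best_fitness >= 0) & (traj.best_fitness <= 1))
        assert list(traj.generations) == [0, 20]
        assert traj.metadata["architecture"] == "PMN"
        df = traj.to_dataframe()
        assert list(df["generation"]) == [0, 20]

    def test_batched_cycle_equals_per_genome_operations(self, setting):
        # one select/clone cycle of the flat loop == the Genome-level ops
        inp, task, mask = setting
        ga = GAConfig(mutation_sd=0.0, n_generations=1, checkpoint_generations=(0, 1))
        traj = run_evolution(mask, task, inp, ga, seed=44)
        rng = np.random.default_rng(44)
        pop = [init_genome(mask, beta=1.0, seed=rng) for _ in range(50)]
        fits = [evaluate_fitness(forward(g, inp), task).fitness for g in pop]
        assert traj.best_fitness[0] == pytest.approx(max(fits), abs=1e-12)
        assert traj.mean_fitness[0] == pytest.approx(np.mean(fits), abs=1e-12)
        kids = reproduce(select_parents(pop, fits), rng, GAConfig(mutation_sd=0.0))
        kid_fits = [evaluate_fitness(forward(g, inp), task).fitness for g in kids]
        assert traj.best_fitness[1] == pytest.approx(max(kid_fits), abs=1e-12)
        assert traj.mean_fitness[1] == pytest.approx(np.mean(kid_fits), abs=1e-12)


class TestPopulationEvaluator:
    def test_block_path_matches_dense_path(self, setting):
        inp, task, _ = setting
        pmn = build_mask("PMN", 3)
        inp3 = make_input_set(3, seed=70)
        # same block-diagonal pattern under a non-PMN kind forces the dense path
        dense_twin = ArchitectureMask(ArchitectureKind.SNMN, pmn.mask, 3)
        _, task3 = make_task(1, 71, inp3)
        rng = np.random.default_rng(9)
        flat = rng.uniform(-3, 3, (50, pmn.n_edges + 2 * pmn.n_hidden + 1))
        block = PopulationEvaluator(pmn, inp3, task3, 1.0, 50)
        dense = PopulationEvaluator(dense_twin, inp3, task3, 1.0, 50)
        np.testing.assert_allclose(block.outputs(flat), dense.outputs(flat), atol=1e-12)
        np.testing.assert_array_equal(block.fitness(flat), dense.fitness(flat))

    def test_batched_outputs_match_single_genome_forward(self, setting):
        inp, task, mask = setting
        g = init_genome(mask, seed=33)
        flat = genome_to_flat(g)[None, :].repeat(50, axis=0)
        ev = PopulationEvaluator(mask, inp, task, 1.0, 50)
        np.testing.assert_allclose(ev.outputs(flat)[:, 0], forward(g, inp), atol=1e-12)

    def test_input_mask_mismatch_raises(self, setting):
        inp, task, _ = setting
        with pytest.raises(ValueError):
            PopulationEvaluator(build_mask("FCNMN", 3), inp, task, 1.0, 50)
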