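"""Fitness metric and task construction for the four system states.

Fitness is the product of the two per-subset accuracies:

    fitness = (accepts correct / n_accept) * (rejects correct / n_reject)

so it is 1 only for perfect behaviour and 0 whenever either sub-task fails
completely -- some performance on both acceptance and rejection is required
for any fitness at all.  Correctness is strict: output > threshold counts
an accept row as correct, output < threshold a reject row; an output
exactly at the threshold is incorrect for either set (sigmoid outputs make
exact ties measure-zero, but the rule is fixed for determinism).

The four system states:

1. baseline -- binary inputs, random 100/156 accept/reject split, 0.5
   threshold, beta = 1;
2. dull/intense -- 140 rows dulled to values in (0, 0.5), accept the dulled
   rows (threshold 0.5);
3. as state 1 but the output threshold is 0.9 for both subsets;
4. as state 1 but beta = 0.1 (handled in the genome, not the task: a
   state-4 task is identical to the state-1 task from the same seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .input_generation import (
    N_PATTERNS,
    InputSet,
    TaskSpec,
    apply_dulling,
    select_target_subset,
)

__all__ = ["FitnessResult", "evaluate_fitness", "make_task", "STATE_IDS"]

STATE_IDS = (1, 2, 3, 4)

#: output threshold of the hard-encoding state 3; other states use 0.5
STATE3_THRESHOLD = 0.9


@dataclass(frozen=True)
class FitnessResult:
    fitness: float
    n_accept_correct: int
    n_reject_correct: int


def evaluate_fitness(outputs: np.ndarray, task: TaskSpec) -> FitnessResult:
    """Score one network's 256 outputs against a task."""
    outputs = np.asarray(outputs, dtype=np.float64)
    if outputs.shape != (N_PATTERNS,):
        raise ValueError(f"outputs must have shape ({N_PATTERNS},), got {outputs.shape}")
    thr = task.accept_threshold
    n_acc = int(np.count_nonzero(outputs[task.accept_indices] > thr))
    n_rej = int(np.count_nonzero(outputs[task.reject_indices] < thr))
    return FitnessResult(
        fitness=(n_acc / task.n_accept) * (n_rej / task.n_reject),
        n_accept_correct=n_acc,
        n_reject_correct=n_rej,
    )


def make_task(
    state_id: int,
    subset_seed: Union[int, np.random.SeedSequence],
    input_set: InputSet,
) -> tuple[InputSet, TaskSpec]:
    """Build the (possibly transformed) input set and task for one state.

    States 1, 3 and 4 draw the same 100/156 partition from ``subset_seed``
    (state 3 only raises the threshold to 0.9; state 4 differs from state 1
    solely through beta, which lives in the genome).  State 2 applies the
    dulling transformation, whose 140/116 partition replaces the subset.
    """
    if state_id not in STATE_IDS:
        raise ValueError(f"unknown system state {state_id!r}; expected one of {STATE_IDS}")
    if state_id == 2:
        return apply_dulling(input_set, subset_seed)
    task = select_target_subset(subset_seed)
    if state_id == 3:
        task = replace(task, state_id=3, accept_threshold=STATE3_THRESHOLD)
    elif state_id == 4:
        task = replace(task, state_id=4)
    return input_set, task
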