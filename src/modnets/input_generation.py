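"""Synthetic stimulus sets and task definitions.

All experiments in this package run on internally generated inputs; nothing
is downloaded.  The stimulus presented to one module (or the corresponding
input area of a non-modular network) is a 256 x 8 array containing every
binary pattern of length 8 exactly once, in a seed-determined random row
order.  A network with ``m`` modules sees the row-wise concatenation of
``m`` independently row-randomized module arrays: a 256 x 8m pattern matrix.

A task is a partition of the 256 pattern rows into an *accept* set (the
network must output above a threshold) and a *reject* set (below it):

* baseline task: a random 100-row accept subset vs. the remaining 156 rows,
  threshold 0.5;
* "dull/intense" task: 140 rows are *dulled* -- every 1 in the row is
  replaced by a single per-row draw u ~ Uniform(0, 0.5) -- and the network
  must accept the 140 dulled rows and reject the 116 untouched ones.

All generators are pure functions of their integer seeds: the same seed
reproduces byte-identical output.  Row indices are 0-based throughout,
including in serialized output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "MODULE_WIDTH",
    "N_PATTERNS",
    "N_ACCEPT_BASELINE",
    "N_DULLED",
    "InputSet",
    "TaskSpec",
    "make_module_array",
    "make_input_set",
    "select_target_subset",
    "apply_dulling",
]

#: patterns per module array: all binary vectors of length MODULE_WIDTH
MODULE_WIDTH = 8
N_PATTERNS = 2**MODULE_WIDTH  # 256

#: accept-subset size of the baseline (state 1/3/4) task
N_ACCEPT_BASELINE = 100

#: number of rows dulled by the state-2 transformation
N_DULLED = 140

SeedLike = Union[int, np.random.SeedSequence]


@dataclass(frozen=True, eq=False)
class InputSet:
    """A 256 x 8m pattern matrix for an m-module network.

    ``patterns`` holds float64 values: exactly {0.0, 1.0} for binary sets,
    real values in [0, 0.5] replacing 1s in dulled rows after the state-2
    transformation.
    """

    patterns: np.ndarray
    n_modules: int

    def __post_init__(self) -> None:
        p = np.asarray(self.patterns, dtype=np.float64)
        if p.shape != (N_PATTERNS, MODULE_WIDTH * self.n_modules):
            raise ValueError(
                f"patterns must have shape ({N_PATTERNS}, {MODULE_WIDTH * self.n_modules}), "
                f"got {p.shape}"
            )
        object.__setattr__(self, "patterns", p)

    @property
    def n_inputs(self) -> int:
        return MODULE_WIDTH * self.n_modules

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.patterns, (0.0, 1.0)).all())

    def module_block(self, j: int) -> np.ndarray:
        """Columns of module ``j`` (0-based), a 256 x 8 view."""
        return self.patterns[:, j * MODULE_WIDTH : (j + 1) * MODULE_WIDTH]

    def to_csv(self, path: Union[str, Path]) -> None:
        np.savetxt(path, self.patterns, delimiter=",", fmt="%.17g")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "InputSet":
        patterns = np.loadtxt(path, delimiter=",", ndmin=2)
        if patterns.shape[1] % MODULE_WIDTH:
            raise ValueError("column count is not a multiple of the module width")
        return cls(patterns, patterns.shape[1] // MODULE_WIDTH)


@dataclass(frozen=True, eq=False)
class TaskSpec:
    """Accept/reject partition of the 256 pattern rows plus output threshold.

    ``accept_indices`` and ``reject_indices`` are disjoint, sorted, 0-based,
    and together cover all 256 rows.  An output strictly above
    ``accept_threshold`` on an accept row, or strictly below it on a reject
    row, counts as correct.
    """

    state_id: int
    accept_indices: np.ndarray
    reject_indices: np.ndarray
    accept_threshold: float = 0.5
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        acc = np.sort(np.asarray(self.accept_indices, dtype=np.intp))
        rej = np.sort(np.asarray(self.reject_indices, dtype=np.intp))
        union = np.concatenate([acc, rej])
        if len(np.intersect1d(acc, rej)):
            raise ValueError("accept and reject sets overlap")
        if not np.array_equal(np.sort(union), np.arange(N_PATTERNS)):
            raise ValueError("accept and reject sets must partition rows 0..255")
        object.__setattr__(self, "accept_indices", acc)
        object.__setattr__(self, "reject_indices", rej)

    @property
    def n_accept(self) -> int:
        return len(self.accept_indices)

    @property
    def n_reject(self) -> int:
        return len(self.reject_indices)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = json.dumps(
            {
                "state_id": self.state_id,
                "accept_threshold": self.accept_threshold,
                "index_base": 0,
                "seed": self.seed,
                "accept_indices": self.accept_indices.tolist(),
                "reject_indices": self.reject_indices.tolist(),
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: Union[str, Path]) -> "TaskSpec":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        obj = json.loads(p.read_text() if p else text_or_path)
        return cls(
            state_id=obj["state_id"],
            accept_indices=np.array(obj["accept_indices"]),
            reject_indices=np.array(obj["reject_indices"]),
            accept_threshold=obj["accept_threshold"],
            seed=obj.get("seed"),
        )


def make_module_array(seed: SeedLike) -> np.ndarray:
    """All 256 binary length-8 row vectors in a seed-determined random order.

    Sorting the rows lexicographically recovers the canonical enumeration
    00000000 ... 11111111, each row exactly once.
    """
    rng = np.random.default_rng(seed)
    codes = np.arange(N_PATTERNS, dtype=np.uint16)
    bits = (codes[:, None] >> np.arange(MODULE_WIDTH - 1, -1, -1)) & 1
    return rng.permutation(bits.astype(np.float64), axis=0)


def make_input_set(n_modules: int, seed: SeedLike, tile_modules: bool = False) -> InputSet:
    """Concatenate ``n_modules`` row-randomized module arrays.

    By default each module's array is independently row-randomized
    (sub-seeds derived from ``seed`` with
    :meth:`numpy.random.SeedSequence.spawn`), so different modules carry
    different data streams.  ``tile_modules=True`` instead replicates one
    row randomization across all modules, making every module's stream
    identical -- a sensitivity variant that changes the information
    available to hidden nodes sampling across modules (see the methods
    note).  Either way the same seed always yields the identical InputSet.
    """
    if n_modules < 1:
        raise ValueError(f"n_modules must be >= 1, got {n_modules}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    if tile_modules:
        return InputSet(np.tile(make_module_array(ss), (1, n_modules)), n_modules)
    blocks = [make_module_array(child) for child in ss.spawn(n_modules)]
    return InputSet(np.hstack(blocks), n_modules)


def select_target_subset(seed: SeedLike) -> TaskSpec:
    """Baseline task: a uniformly random 100-row accept subset, threshold 0.5."""
    rng = np.random.default_rng(seed)
    accept = rng.choice(N_PATTERNS, size=N_ACCEPT_BASELINE, replace=False)
    reject = np.setdiff1d(np.arange(N_PATTERNS), accept)
    return TaskSpec(
        state_id=1,
        accept_indices=accept,
        reject_indices=reject,
        accept_threshold=0.5,
        seed=seed if isinstance(seed, int) else None,
    )


def apply_dulling(input_set: InputSet, seed: SeedLike) -> tuple[InputSet, TaskSpec]:
    """State-2 transformation: dull 140 rows and relabel the task.

    140 rows are chosen uniformly without replacement; within each chosen
    row every entry equal to 1 (across all module blocks) is replaced by the
    row's single draw u ~ Uniform(0, 0.5).  Zero entries are untouched, so a
    chosen all-zero row remains bit-identical.  The accept set is the 140
    dulled rows, the reject set the 116 unmodified ("intense") rows.
    """
    if not input_set.is_binary:
        raise ValueError("dulling requires a binary input set")
    rng = np.random.default_rng(seed)
    dull_rows = rng.choice(N_PATTERNS, size=N_DULLED, replace=False)
    u = rng.uniform(0.0, 0.5, size=N_DULLED)
    patterns = input_set.patterns.copy()
    patterns[dull_rows] = np.where(patterns[dull_rows] == 1.0, u[:, None], patterns[dull_rows])
    task = TaskSpec(
        state_id=2,
        accept_indices=dull_rows,
        reject_indices=np.setdiff1d(np.arange(N_PATTERNS), dull_rows),
        accept_threshold=0.5,
        seed=seed if isinstance(seed, int) else None,
    )
    return InputSet(patterns, input_set.n_modules), task
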