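"""Experiment orchestration: the coarse and fine designs, seeds, and tables.

Two standard designs are provided:

* **coarse** -- all four system states x {small (2 modules), large (12
  modules)} x all three architectures x 20 replicates, with fitness
  recorded at generations 1000 and 10000 (15 and 500 for the easy state-2
  task, which plateaus within ~100 generations);
* **fine** -- state 1 only, module counts {2, 3, 6, 9, 12, 15, 18}
  (16/8 up to 144/72 input/hidden nodes), 5 replicates.

Seed-sharing contract (all seeds keyed off one master seed):

* one input set per module count, shared by every state, architecture and
  replicate of that size class;
* one task seed per (module count, replicate), shared across architectures
  and across states 1/3/4 (which use the same accept subset); state 2
  derives its dulling from the same seed, re-drawn per replicate;
* one SNMN mask seed per (module count, replicate), shared across states;
* one run seed (initialization + mutation stream) per
  (state, module count, replicate, architecture).

Because every run's seeds are derived functionally, results are invariant
to execution order and to serial vs. parallel execution.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .evolution import GAConfig, run_evolution
from .fitness_tasks import STATE_IDS, make_task
from .input_generation import MODULE_WIDTH, make_input_set
from .networks import HIDDEN_PER_MODULE, ArchitectureKind, build_mask

__all__ = [
    "STATE_CHECKPOINTS",
    "ConfigMismatchError",
    "ExperimentPlan",
    "size_for_modules",
    "derive_seed",
    "run_plan",
]

logger = logging.getLogger(__name__)

#: ("speed", "ultimate fitness") checkpoint generations per system state
STATE_CHECKPOINTS: dict[int, tuple[int, int]] = {
    1: (1000, 10_000),
    2: (15, 500),
    3: (1000, 10_000),
    4: (1000, 10_000),
}

_DOMAIN_CODES = {"input_set": 1, "task": 2, "mask": 3, "run": 4}
_ARCH_CODES = {
    ArchitectureKind.FCNMN: 1,
    ArchitectureKind.PMN: 2,
    ArchitectureKind.SNMN: 3,
}


class ConfigMismatchError(RuntimeError):
    """Raised when resuming into an output directory written under a different plan."""


def size_for_modules(n_modules: int) -> tuple[int, int, int]:
    """(n_inputs, n_hidden, n_outputs) = (8m, 4m, 1) for m modules."""
    if n_modules < 1:
        raise ValueError(f"n_modules must be >= 1, got {n_modules}")
    return (MODULE_WIDTH * n_modules, HIDDEN_PER_MODULE * n_modules, 1)


def derive_seed(master_seed: int, domain: str, *keys: int) -> int:
    """Deterministic sub-seed for one well-known randomness domain.

    Uses a keyed :class:`numpy.random.SeedSequence` so any two distinct
    (domain, keys) tuples give statistically independent streams, and the
    derivation is independent of the order runs execute in.
    """
    ss = np.random.SeedSequence([int(master_seed), _DOMAIN_CODES[domain], *map(int, keys)])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentPlan:
    """Full description of one experiment sweep.

    A scaled-down variant (fewer replicates, earlier checkpoints) is
    expressed purely through these fields; no code change is needed.
    ``checkpoints_by_state`` overrides the per-state defaults in
    :data:`STATE_CHECKPOINTS`; ``record_every`` additionally records every
    N-th generation (trajectory output, off by default because it is
    large).
    """

    design: str = "coarse"
    states: tuple[int, ...] = (1, 2, 3, 4)
    module_counts: tuple[int, ...] = (2, 12)
    architectures: tuple[ArchitectureKind, ...] = (
        ArchitectureKind.FCNMN,
        ArchitectureKind.PMN,
        ArchitectureKind.SNMN,
    )
    n_replicates: int = 20
    master_seed: int = 0
    ga: GAConfig = field(default_factory=GAConfig)
    checkpoints_by_state: Mapping[int, tuple[int, ...]] | None = None
    record_every: int | None = None
    snmn_exact_count: bool = False
    tile_modules: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(int(s) for s in self.states))
        object.__setattr__(self, "module_counts", tuple(int(m) for m in self.module_counts))
        object.__setattr__(
            self,
            "architectures",
            tuple(ArchitectureKind(a) for a in self.architectures),
        )
        if self.checkpoints_by_state is not None:
            cbs = {int(k): tuple(int(g) for g in v) for k, v in self.checkpoints_by_state.items()}
            object.__setattr__(self, "checkpoints_by_state", cbs)
        bad = set(self.states) - set(STATE_IDS)
        if bad:
            raise ValueError(f"unknown system states: {sorted(bad)}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @classmethod
    def coarse(cls, master_seed: int = 0, n_replicates: int = 20, **kwargs) -> "ExperimentPlan":
        return cls(design="coarse", master_seed=master_seed, n_replicates=n_replicates, **kwargs)

    @classmethod
    def fine(cls, master_seed: int = 0, n_replicates: int = 5, **kwargs) -> "ExperimentPlan":
        kwargs.setdefault("states", (1,))
        kwargs.setdefault("module_counts", (2, 3, 6, 9, 12, 15, 18))
        return cls(design="fine", master_seed=master_seed, n_replicates=n_replicates, **kwargs)

    @classmethod
    def from_config(cls, config: Mapping) -> "ExperimentPlan":
        """Build a plan from a plain declarative mapping (e.g. parsed YAML)."""
        cfg = dict(config)
        ga_cfg = cfg.pop("ga", None)
        if ga_cfg is not None:
            cfg["ga"] = GAConfig(**ga_cfg)
        return cls(**cfg)

    def checkpoints_for_state(self, state: int) -> tuple[int, ...]:
        base: tuple[int, ...]
        if self.checkpoints_by_state and state in self.checkpoints_by_state:
            base = self.checkpoints_by_state[state]
        else:
            base = STATE_CHECKPOINTS[state]
        if self.record_every:
            extra = range(0, max(base) + 1, self.record_every)
            base = tuple(sorted(set(base) | set(extra)))
        return base

    def ga_for_state(self, state: int) -> GAConfig:
        cps = self.checkpoints_for_state(state)
        return replace(self.ga, n_generations=max(cps), checkpoint_generations=cps)

    def cells(self) -> list[tuple[int, int, ArchitectureKind, int]]:
        """All (state, n_modules, architecture, replicate) design cells."""
        return list(
            itertools.product(
                self.states,
                self.module_counts,
                self.architectures,
                range(self.n_replicates),
            )
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["architectures"] = [a.value for a in self.architectures]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def task_seed(plan: ExperimentPlan, n_modules: int, replicate: int) -> int:
    """Per-replicate task seed, shared across architectures and states."""
    return derive_seed(plan.master_seed, "task", n_modules, replicate)


def input_set_for(plan: ExperimentPlan, n_modules: int):
    """The one input set of a size class (shared across the whole design)."""
    return make_input_set(
        n_modules,
        derive_seed(plan.master_seed, "input_set", n_modules),
        tile_modules=plan.tile_modules,
    )


def run_cell(
    plan: ExperimentPlan,
    state: int,
    n_modules: int,
    architecture: Union[ArchitectureKind, str],
    replicate: int,
    input_set=None,
) -> pd.DataFrame:
    """Run one evolution replicate of the design and return its checkpoint rows.

    ``input_set`` may be passed to reuse a cached size-class input set; it
    must then equal the one derived from the plan's master seed.
    """
    architecture = ArchitectureKind(architecture)
    if input_set is None:
        input_set = input_set_for(plan, n_modules)
    inp, task = make_task(state, task_seed(plan, n_modules, replicate), input_set)
    if architecture is ArchitectureKind.SNMN:
        mask = build_mask(
            architecture,
            n_modules,
            derive_seed(plan.master_seed, "mask", n_modules, replicate),
            exact_count=plan.snmn_exact_count,
        )
    else:
        mask = build_mask(architecture, n_modules)
    beta = 0.1 if state == 4 else 1.0
    run_seed = derive_seed(
        plan.master_seed, "run", state, n_modules, replicate, _ARCH_CODES[architecture]
    )
    traj = run_evolution(
        mask,
        task,
        inp,
        plan.ga_for_state(state),
        beta=beta,
        seed=run_seed,
        metadata={"replicate": replicate},
    )
    return pd.DataFrame(
        {
            "state": state,
            "architecture": architecture.value,
            "n_modules": n_modules,
            "replicate": replicate,
            "generation": traj.generations,
            "best_fitness": traj.best_fitness,
            "mean_fitness": traj.mean_fitness,
        }
    )


def _cell_filename(state: int, n_modules: int, arch: ArchitectureKind, rep: int) -> str:
    return f"state{state}_m{n_modules}_{arch.value}_r{rep}.csv"


def run_plan(
    plan: ExperimentPlan,
    out_dir: Union[str, Path, None] = None,
    n_jobs: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Execute every cell of the plan and return the long-format results table.

    One row per (state, architecture, n_modules, replicate, checkpoint
    generation).  With ``out_dir`` set, each finished cell is written to
    ``out_dir/runs/`` and the run is resumable: existing cell files are
    loaded instead of recomputed, provided the stored plan hash matches
    (otherwise a :class:`ConfigMismatchError` refuses to merge).  Results
    are identical for any ``n_jobs`` and any execution order because all
    randomness is derived per cell from the master seed.
    """
    cells = plan.cells()
    runs_dir = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        runs_dir = out_dir / "runs"
        runs_dir.mkdir(parents=True, exist_ok=True)
        meta_path = out_dir / "plan.json"
        meta = {"config_hash": plan.config_hash(), "plan": plan.to_dict()}
        if meta_path.exists():
            prior = json.loads(meta_path.read_text())
            if prior.get("config_hash") != meta["config_hash"]:
                raise ConfigMismatchError(
                    f"{out_dir} holds results for plan hash {prior.get('config_hash')}, "
                    f"refusing to merge with plan hash {meta['config_hash']}"
                )
        else:
            meta_path.write_text(json.dumps(meta, indent=1))

    pending = []
    frames: dict[tuple, pd.DataFrame] = {}
    for cell in cells:
        if runs_dir is not None:
            path = runs_dir / _cell_filename(*cell)
            if path.exists():
                frames[cell] = pd.read_csv(path)
                continue
        pending.append(cell)

    if pending:
        input_sets = {m: input_set_for(plan, m) for m in plan.module_counts}

        def _one(cell):
            state, m, arch, rep = cell
            df = run_cell(plan, state, m, arch, rep, input_set=input_sets[m])
            if runs_dir is not None:
                # write as soon as the cell finishes so interrupted sweeps resume
                df.to_csv(runs_dir / _cell_filename(*cell), index=False)
            return df

        iterator: Iterable = pending
        if progress:
            from tqdm import tqdm

            iterator = tqdm(pending, desc="evolution runs", unit="run")
        if n_jobs == 1:
            results = [_one(cell) for cell in iterator]
        else:
            from joblib import Parallel, delayed

            results = Parallel(n_jobs=n_jobs)(delayed(_one)(cell) for cell in iterator)
        for cell, df in zip(pending, results):
            frames[cell] = df

    table = pd.concat([frames[c] for c in cells], ignore_index=True)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "results.csv", index=False)
    return table
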