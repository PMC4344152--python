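"""Masked feed-forward genomes and their forward evaluation.

Three input-to-hidden connectivity patterns are compared, all with the same
node counts (8m inputs, 4m hidden, 1 output for m modules):

* ``FCNMN`` -- fully connected non-modular network: every input connects to
  every hidden node (32 m^2 edges);
* ``PMN`` -- perfectly modular network: m fully connected 8-input/4-hidden
  blocks with no edges between blocks (32 m edges);
* ``SNMN`` -- sparse non-modular network: each input-to-hidden edge present
  independently with probability p = (PMN edge count)/(FCNMN edge count)
  = 1/m, matching the PMN's edge count in expectation.

Only the input-to-hidden layer varies; hidden-to-output connectivity is
always complete.  Hidden and output nodes apply the logistic squashing
function g(z) = 1/(1 + exp(-beta z)) with trainable bias; input nodes pass
their values through unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np
from scipy.special import expit

from .input_generation import MODULE_WIDTH, InputSet

__all__ = [
    "HIDDEN_PER_MODULE",
    "ArchitectureKind",
    "ArchitectureMask",
    "Genome",
    "build_mask",
    "init_genome",
    "forward",
]

#: hidden nodes per module; a module is 8 inputs -> 4 hidden
HIDDEN_PER_MODULE = 4

#: initial weights and biases are drawn from Uniform(-INIT_BOUND, INIT_BOUND)
INIT_BOUND = 3.0


class ArchitectureKind(str, Enum):
    FCNMN = "FCNMN"
    PMN = "PMN"
    SNMN = "SNMN"


@dataclass(frozen=True, eq=False)
class ArchitectureMask:
    """Boolean input-to-hidden connectivity, fixed for the life of a genome."""

    kind: ArchitectureKind
    mask: np.ndarray
    n_modules: int

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        expected = (MODULE_WIDTH * self.n_modules, HIDDEN_PER_MODULE * self.n_modules)
        if m.shape != expected:
            raise ValueError(f"mask must have shape {expected}, got {m.shape}")
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "kind", ArchitectureKind(self.kind))

    @property
    def n_inputs(self) -> int:
        return self.mask.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.mask.shape[1]

    @property
    def n_edges(self) -> int:
        return int(self.mask.sum())


def _block_diagonal_mask(n_modules: int) -> np.ndarray:
    mask = np.zeros((MODULE_WIDTH * n_modules, HIDDEN_PER_MODULE * n_modules), dtype=bool)
    for j in range(n_modules):
        mask[
            j * MODULE_WIDTH : (j + 1) * MODULE_WIDTH,
            j * HIDDEN_PER_MODULE : (j + 1) * HIDDEN_PER_MODULE,
        ] = True
    return mask


def snmn_edge_probability(n_modules: int) -> float:
    """PMN edge count over FCNMN edge count for the same node counts (= 1/m)."""
    pmn_edges = _block_diagonal_mask(n_modules).sum()
    fcnmn_edges = (MODULE_WIDTH * n_modules) * (HIDDEN_PER_MODULE * n_modules)
    return pmn_edges / fcnmn_edges


def build_mask(
    kind: Union[ArchitectureKind, str],
    n_modules: int,
    seed: int | np.random.SeedSequence | None = None,
    *,
    exact_count: bool = False,
) -> ArchitectureMask:
    """Construct the connectivity mask for one architecture.

    ``seed`` is consumed only for the SNMN, whose entries are i.i.d.
    Bernoulli(1/m) draws.  ``exact_count=True`` instead places exactly the
    PMN's 32m edges uniformly at random (a sensitivity-check variant; the
    default is the plain Bernoulli sample).  A SNMN draw may leave a hidden
    node with no inputs; such masks are accepted as drawn.
    """
    if n_modules < 1:
        raise ValueError(f"n_modules must be >= 1, got {n_modules}")
    kind = ArchitectureKind(kind)
    shape = (MODULE_WIDTH * n_modules, HIDDEN_PER_MODULE * n_modules)
    if kind is ArchitectureKind.FCNMN:
        mask = np.ones(shape, dtype=bool)
    elif kind is ArchitectureKind.PMN:
        mask = _block_diagonal_mask(n_modules)
    else:
        if seed is None:
            raise ValueError("SNMN mask construction requires a seed")
        rng = np.random.default_rng(seed)
        if exact_count:
            n_edges = int(_block_diagonal_mask(n_modules).sum())
            flat = np.zeros(shape[0] * shape[1], dtype=bool)
            flat[rng.choice(flat.size, size=n_edges, replace=False)] = True
            mask = flat.reshape(shape)
        else:
            mask = rng.random(shape) < snmn_edge_probability(n_modules)
    return ArchitectureMask(kind, mask, n_modules)


@dataclass(frozen=True, eq=False)
class Genome:
    """Trainable parameters of one network.

    ``w_ih`` is dense but identically zero wherever the mask is false; those
    positions are never initialized or mutated.  ``beta`` is the logistic
    steepness shared by the hidden and output layers (1.0 in the baseline
    system, 0.1 in the low-sensitivity variant).
    """

    architecture: ArchitectureMask
    w_ih: np.ndarray
    w_ho: np.ndarray
    b_h: np.ndarray
    b_o: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        w_ih = np.asarray(self.w_ih, dtype=np.float64)
        w_ho = np.asarray(self.w_ho, dtype=np.float64)
        b_h = np.asarray(self.b_h, dtype=np.float64)
        arch = self.architecture
        if w_ih.shape != arch.mask.shape:
            raise ValueError("w_ih shape does not match the architecture mask")
        if w_ho.shape != (arch.n_hidden,) or b_h.shape != (arch.n_hidden,):
            raise ValueError("hidden-layer parameter shapes do not match the mask")
        if np.any(w_ih[~arch.mask]):
            raise ValueError("w_ih has nonzero entries at masked positions")
        object.__setattr__(self, "w_ih", w_ih)
        object.__setattr__(self, "w_ho", w_ho)
        object.__setattr__(self, "b_h", b_h)
        object.__setattr__(self, "b_o", float(self.b_o))

    @property
    def n_free_parameters(self) -> int:
        """Unmasked weights plus hidden-to-output weights and all biases."""
        return self.architecture.n_edges + 2 * self.architecture.n_hidden + 1

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        rows, cols = np.nonzero(self.architecture.mask)
        payload = json.dumps(
            {
                "kind": self.architecture.kind.value,
                "n_modules": self.architecture.n_modules,
                "mask_rows": rows.tolist(),
                "mask_cols": cols.tolist(),
                "w_ih": self.w_ih[rows, cols].tolist(),
                "w_ho": self.w_ho.tolist(),
                "b_h": self.b_h.tolist(),
                "b_o": self.b_o,
                "beta": self.beta,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: Union[str, Path]) -> "Genome":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        obj = json.loads(p.read_text() if p else text_or_path)
        m = obj["n_modules"]
        mask = np.zeros((MODULE_WIDTH * m, HIDDEN_PER_MODULE * m), dtype=bool)
        rows = np.array(obj["mask_rows"], dtype=np.intp)
        cols = np.array(obj["mask_cols"], dtype=np.intp)
        mask[rows, cols] = True
        arch = ArchitectureMask(ArchitectureKind(obj["kind"]), mask, m)
        w_ih = np.zeros(mask.shape)
        w_ih[rows, cols] = obj["w_ih"]
        return cls(
            architecture=arch,
            w_ih=w_ih,
            w_ho=np.array(obj["w_ho"]),
            b_h=np.array(obj["b_h"]),
            b_o=obj["b_o"],
            beta=obj["beta"],
        )


def init_genome(
    mask: ArchitectureMask,
    beta: float = 1.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> Genome:
    """Draw every free parameter i.i.d. from Uniform(-3, 3).

    Biases are treated exactly like weights for initialization (and later
    mutation).  The draw order is: unmasked input-to-hidden weights in
    row-major mask order, hidden-to-output weights, hidden biases, output
    bias -- fixed so that a seed fully determines the genome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = rng.uniform(-INIT_BOUND, INIT_BOUND, size=mask.n_edges + 2 * mask.n_hidden + 1)
    return genome_from_flat(mask, flat, beta)


def genome_from_flat(mask: ArchitectureMask, flat: np.ndarray, beta: float) -> Genome:
    """Unpack a flat free-parameter vector (the order documented in init_genome)."""
    n_e, n_h = mask.n_edges, mask.n_hidden
    if flat.shape != (n_e + 2 * n_h + 1,):
        raise ValueError("flat parameter vector has the wrong length")
    w_ih = np.zeros(mask.mask.shape)
    w_ih[mask.mask] = flat[:n_e]
    return Genome(
        architecture=mask,
        w_ih=w_ih,
        w_ho=flat[n_e : n_e + n_h].copy(),
        b_h=flat[n_e + n_h : n_e + 2 * n_h].copy(),
        b_o=flat[-1],
        beta=beta,
    )


def genome_to_flat(genome: Genome) -> np.ndarray:
    """Inverse of genome_from_flat."""
    mask = genome.architecture.mask
    return np.concatenate(
        [genome.w_ih[mask], genome.w_ho, genome.b_h, [genome.b_o]]
    )


def forward(genome: Genome, inputs: Union[InputSet, np.ndarray]) -> np.ndarray:
    """Evaluate the network on every pattern row.

    For pattern x: h_j = g(sum_i w_ih[i, j] x_i + b_h[j]) and
    y = g(sum_j w_ho[j] h_j + b_o), with g(z) = 1/(1 + exp(-beta z)).
    Returns one output per row, each strictly inside (0, 1).
    """
    x = inputs.patterns if isinstance(inputs, InputSet) else np.asarray(inputs, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != genome.architecture.n_inputs:
        raise ValueError(
            f"inputs must have {genome.architecture.n_inputs} columns, got shape {x.shape}"
        )
    hidden = expit(genome.beta * (x @ genome.w_ih + genome.b_h))
    return expit(genome.beta * (hidden @ genome.w_ho + genome.b_o))
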