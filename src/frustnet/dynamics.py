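"""Asynchronous Boolean dynamics on signed regulatory networks.

Each gene holds a binary activity ``x_i``; its regulatory input is the signed
sum ``f_i = sum_j A_ij x_j`` over its regulators.  The threshold rule switches
the gene on when ``f_i > 0``, off when ``f_i < 0``, and keeps the current
value at ``f_i = 0``.  Updates are asynchronous: at every time step one gene
is drawn uniformly among the *unstable* genes (those whose bit disagrees with
the rule) and flipped, so every accepted step is exactly one flip.  A state
with no unstable genes is a fixed point and models a stable cell phenotype.

Perturbations (overexpression/knockdown) clamp genes to constant values; a
clamped gene is never a flip candidate and the clamp is never released.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_model import GeneRegulatoryNetwork, PerturbationSpec, _as_state

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "SteadyStateEnsemble",
    "ConvergenceError",
    "regulatory_input",
    "unstable_genes",
    "unstable_mask",
    "async_step",
    "relax",
    "relax_batch",
    "sample_ensemble",
]

#: Default flip budget per trajectory, as a multiple of the roster size.
#: Asynchronous threshold networks can in principle cycle, so relaxation is
#: guarded rather than allowed to loop forever.
MAX_STEPS_FACTOR = 100

#: Samples processed per vectorised chunk in ensemble sampling.  Fixed (not
#: user-tunable) so that a given master seed always yields the same stream
#: layout and therefore a bit-identical ensemble.
_CHUNK = 4096


class ConvergenceError(RuntimeError):
    """Relaxation exhausted its step budget without reaching a fixed point."""

    def __init__(self, message: str, last_state: np.ndarray):
        super().__init__(message)
        self.last_state = last_state


def _clamp_arrays(
    grn: GeneRegulatoryNetwork, clamp: PerturbationSpec | None
) -> tuple[np.ndarray, np.ndarray]:
    if clamp is None or len(clamp) == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.uint8)
    return clamp.indices(grn)


def regulatory_input(
    grn: GeneRegulatoryNetwork, state: np.ndarray, gene: str
) -> int:
    """Signed input sum ``sum_j A_ij x_j`` of one gene (0 if unregulated)."""
    i = grn.gene_index(gene)
    x = _as_state(state, grn.n_genes)
    return int(grn.adjacency[i].astype(np.int32) @ x)


def _fields(grn: GeneRegulatoryNetwork, states: np.ndarray) -> np.ndarray:
    """Input sums for a batch of states: (B, N) -> (B, N)."""
    return states.astype(np.int16) @ grn.adjacency.T.astype(np.int16)


def unstable_mask(
    grn: GeneRegulatoryNetwork,
    states: np.ndarray,
    clamp: PerturbationSpec | None = None,
    fields: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of genes mandated to flip, for one state or a batch.

    A gene is unstable when its input is positive while the gene is off, or
    negative while the gene is on; zero input keeps the current bit.  Clamped
    genes are never unstable.
    """
    x = np.atleast_2d(_as_state(states, grn.n_genes))
    f = _fields(grn, x) if fields is None else fields
    mask = ((f > 0) & (x == 0)) | ((f < 0) & (x == 1))
    idx, _ = _clamp_arrays(grn, clamp)
    if idx.size:
        mask[:, idx] = False
    return mask if np.asarray(states).ndim == 2 else mask[0]


def unstable_genes(
    grn: GeneRegulatoryNetwork,
    state: np.ndarray,
    clamp: PerturbationSpec | None = None,
) -> set[str]:
    """Names of the currently unstable genes of a single state."""
    mask = unstable_mask(grn, state, clamp)
    return {grn.genes[i] for i in np.flatnonzero(mask)}


def async_step(
    grn: GeneRegulatoryNetwork,
    state: np.ndarray,
    clamp: PerturbationSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, str]:
    """One asynchronous update: flip one uniformly chosen unstable gene.

    Raises ``ValueError`` on a fixed point (nothing to update).
    """
    rng = np.random.default_rng() if rng is None else rng
    x = _as_state(state, grn.n_genes).copy()
    candidates = np.flatnonzero(unstable_mask(grn, x, clamp))
    if candidates.size == 0:
        raise ValueError("async_step called on a fixed point")
    g = int(candidates[rng.integers(candidates.size)])
    x[g] ^= 1
    return x, grn.genes[g]


@dataclass(frozen=True)
class Trajectory:
    """A single relaxation path: snapshots plus the gene flipped at each step.

    ``states`` has shape (steps + 1, N): the clamped start state followed by
    one snapshot per accepted flip.  Consecutive snapshots differ in exactly
    one gene.
    """

    states: np.ndarray
    flipped: tuple[str, ...]
    clamp: PerturbationSpec | None
    seed: int | None

    @property
    def start(self) -> np.ndarray:
        return self.states[0]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    @property
    def n_steps(self) -> int:
        return len(self.flipped)


def relax(
    grn: GeneRegulatoryNetwork,
    state0: np.ndarray,
    clamp: PerturbationSpec | None = None,
    max_steps: int | None = None,
    rng: np.random.Generator | int | None = None,
    record: bool = False,
) -> Trajectory | tuple[np.ndarray, int]:
    """Relax a single state to a fixed point under the asynchronous rule.

    The clamp is applied to ``state0`` before iterating and held throughout.
    Returns ``(steady_state, n_steps)``, or a full :class:`Trajectory` when
    ``record=True``.  Raises :class:`ConvergenceError` if ``max_steps``
    (default ``100 * N``) accepted flips do not reach a fixed point.
    """
    n = grn.n_genes
    max_steps = MAX_STEPS_FACTOR * n if max_steps is None else max_steps
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = _as_state(state0, n).copy()
    cidx, cval = _clamp_arrays(grn, clamp)
    x[cidx] = cval
    f = grn.adjacency.astype(np.int16) @ x
    snapshots = [x.copy()] if record else None
    flipped: list[str] = []
    steps = 0
    while True:
        mask = ((f > 0) & (x == 0)) | ((f < 0) & (x == 1))
        if cidx.size:
            mask[cidx] = False
        candidates = np.flatnonzero(mask)
        if candidates.size == 0:
            break
        if steps >= max_steps:
            raise ConvergenceError(
                f"no fixed point after {max_steps} flips "
                f"(possible limit cycle); last state recorded",
                x,
            )
        g = int(candidates[rng.integers(candidates.size)])
        delta = np.int16(1 - 2 * int(x[g]))
        x[g] ^= 1
        f += grn.adjacency[:, g].astype(np.int16) * delta
        steps += 1
        if record:
            snapshots.append(x.copy())
            flipped.append(grn.genes[g])
    if record:
        return Trajectory(
            np.array(snapshots, dtype=np.uint8), tuple(flipped), clamp, seed
        )
    return x, steps


def relax_batch(
    grn: GeneRegulatoryNetwork,
    states0: np.ndarray,
    clamp: PerturbationSpec | None = None,
    max_steps: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised relaxation of many start states under one clamp.

    All chains advance in lock step; at each round every still-active chain
    flips one uniformly drawn unstable gene.  Returns ``(finals, steps,
    converged)`` where ``converged`` flags chains that reached a fixed point
    within the budget (the others hold their last state).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = grn.n_genes
    x = np.atleast_2d(_as_state(states0, n)).copy()
    b = x.shape[0]
    max_steps = MAX_STEPS_FACTOR * n if max_steps is None else max_steps
    cidx, cval = _clamp_arrays(grn, clamp)
    x[:, cidx] = cval
    f = _fields(grn, x)
    at = grn.adjacency.T.astype(np.int16)
    steps = np.zeros(b, dtype=np.int64)
    converged = np.zeros(b, dtype=bool)
    active = np.arange(b)
    while active.size:
        xa, fa = x[active], f[active]
        mask = ((fa > 0) & (xa == 0)) | ((fa < 0) & (xa == 1))
        if cidx.size:
            mask[:, cidx] = False
        counts = mask.sum(axis=1)
        done = counts == 0
        converged[active[done]] = True
        live = ~done
        if steps[active].max(initial=0) >= max_steps:
            over = live & (steps[active] >= max_steps)
            live &= ~over
        rows = active[live]
        if rows.size == 0:
            active = active[np.zeros(0, dtype=bool)]
            break
        m = mask[live]
        r = rng.integers(0, counts[live])
        genes = (m.cumsum(axis=1) > r[:, None]).argmax(axis=1)
        delta = (1 - 2 * x[rows, genes].astype(np.int16))
        x[rows, genes] ^= 1
        f[rows] += at[genes] * delta[:, None]
        steps[rows] += 1
        active = rows
    return x, steps, converged


@dataclass(frozen=True)
class SteadyStateEnsemble:
    """Unique fixed points found from random starts, with basin capacities.

    ``capacity[k]`` counts the sampled initial states that relaxed to
    ``states[k]`` (a basin-size estimate); capacities sum to the number of
    converged samples.
    """

    states: np.ndarray
    capacity: np.ndarray
    n_samples: int
    n_nonconverged: int
    mean_steps: float
    seed: int
    clamp: PerturbationSpec | None = None
    finals: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return int(self.states.shape[0])

    def expanded(self) -> np.ndarray:
        """All converged final states with multiplicity (one row per sample)."""
        if self.finals is not None:
            return self.finals
        return np.repeat(self.states, self.capacity, axis=0)


def sample_ensemble(
    grn: GeneRegulatoryNetwork,
    n_samples: int,
    clamp: PerturbationSpec | None = None,
    seed: int = 0,
    max_steps: int | None = None,
    max_fail_fraction: float = 0.0,
    keep_finals: bool = False,
) -> SteadyStateEnsemble:
    """Relax uniform random initial states and tally the fixed points reached.

    Initial bits are independent Bernoulli(0.5); clamped genes are overwritten
    after sampling.  Sampling is processed in fixed-size chunks, each driven
    by a child stream spawned deterministically from ``seed``, so results are
    bit-reproducible for a given seed.  Non-convergent chains raise unless a
    positive ``max_fail_fraction`` is configured, in which case they are
    counted, logged and excluded from the capacities.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n = grn.n_genes
    root = np.random.SeedSequence(seed)
    children = root.spawn(-(-n_samples // _CHUNK))
    finals, steps_all, conv_all = [], [], []
    for c, child in enumerate(children):
        size = min(_CHUNK, n_samples - c * _CHUNK)
        rng = np.random.default_rng(child)
        x0 = rng.integers(0, 2, size=(size, n), dtype=np.uint8)
        fin, steps, conv = relax_batch(grn, x0, clamp, max_steps, rng)
        finals.append(fin)
        steps_all.append(steps)
        conv_all.append(conv)
    finals = np.concatenate(finals)
    steps_all = np.concatenate(steps_all)
    conv_all = np.concatenate(conv_all)
    n_bad = int((~conv_all).sum())
    if n_bad:
        frac = n_bad / n_samples
        msg = f"{n_bad}/{n_samples} chains did not converge"
        if frac > max_fail_fraction:
            raise ConvergenceError(msg, finals[~conv_all][0])
        logger.warning("%s (within tolerance %.3g)", msg, max_fail_fraction)
    ok = finals[conv_all]
    states, capacity = np.unique(ok, axis=0, return_counts=True)
    return SteadyStateEnsemble(
        states=states,
        capacity=capacity,
        n_samples=n_samples,
        n_nonconverged=n_bad,
        mean_steps=float(steps_all[conv_all].mean()),
        seed=seed,
        clamp=clamp,
        finals=ok if keep_finals else None,
    )
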