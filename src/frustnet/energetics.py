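"""Scalar observables of cell states: phenotype scores and frustration.

The central quantity is a spin-glass-style pseudo-energy.  Writing each bit
as a spin ``s_i = 2 x_i - 1`` in {-1, +1}, every regulatory edge ``j -> i``
with sign ``A_ij`` contributes ``-A_ij s_i s_j``: -1 when the two genes'
states are consistent with the edge (the edge is "satisfied"), +1 when they
conflict (the edge is "frustrated").  The global pseudo-energy sums this over
all directed edges, each counted once; the single-site pseudo-energy of gene
``i`` sums only its incoming edges, so the site values add up exactly to the
global value.  Low pseudo-energy means a well-orchestrated, minimally
frustrated expression pattern; the quantity is a consistency score of a
nongradient dynamical system, not a thermodynamic energy.

The driving force counts the genes currently mandated to flip by the
threshold rule; it is zero exactly at fixed points and tracks how far a cell
is from a re-established order.
"""

from __future__ import annotations

from dataclasses import dataclass

from typing import Sequence

import numpy as np

from .core_model import (
    GeneRegulatoryNetwork,
    MarkerSet,
    PerturbationSpec,
    _as_state,
)
from .dynamics import unstable_mask

import logging

logger = logging.getLogger(__name__)

__all__ = [
    "ObservableRecord",
    "phenotypic_score",
    "pseudo_energy",
    "local_pseudo_energy",
    "local_pseudo_energy_vector",
    "driving_force",
    "state_distance",
    "phenotype_change",
    "mean_pairwise_distance",
    "observables",
]


def _marker_indices(
    grn: GeneRegulatoryNetwork, names: frozenset[str]
) -> np.ndarray:
    """Roster indices of marker genes; missing genes are dropped with a
    warning (expression matrices rarely cover the full marker panel)."""
    present = [g for g in names if g in grn.index]
    missing = names - set(present)
    if missing:
        logger.warning(
            "markers absent from roster, dropped from score: %s",
            sorted(missing),
        )
    return np.array([grn.index[g] for g in present], dtype=np.intp)


def phenotypic_score(
    grn: GeneRegulatoryNetwork,
    state: np.ndarray,
    markers: MarkerSet,
    axis: str,
) -> int | np.ndarray:
    """Phenotype score on one axis: active positive markers minus active
    negative markers.

    ``axis="PS"`` scores pluripotent-vs-somatic identity, ``axis="EM"``
    epithelial-vs-mesenchymal morphology.  Accepts a single state or a batch
    (rows of states).
    """
    if axis == "PS":
        pos, neg = markers.phiPS_pos, markers.phiPS_neg
    elif axis == "EM":
        pos, neg = markers.phiEM_pos, markers.phiEM_neg
    else:
        raise ValueError(f"axis must be 'PS' or 'EM', got {axis!r}")
    x = _as_state(state, grn.n_genes)
    ip = _marker_indices(grn, pos)
    im = _marker_indices(grn, neg)
    score = x[..., ip].sum(axis=-1).astype(np.int64) - x[..., im].sum(
        axis=-1
    ).astype(np.int64)
    return int(score) if score.ndim == 0 else score


def pseudo_energy(
    grn: GeneRegulatoryNetwork, state: np.ndarray
) -> int | np.ndarray:
    """Global pseudo-energy ``-sum_edges A_ij s_i s_j`` (each directed edge
    once); integer in [-M, +M] for M edges.  Accepts single states or
    batches."""
    x = _as_state(state, grn.n_genes)
    s = (2 * x.astype(np.int64) - 1)
    e = -(
        grn.edge_sign.astype(np.int64)
        * s[..., grn.edge_target]
        * s[..., grn.edge_source]
    ).sum(axis=-1)
    return int(e) if np.ndim(e) == 0 else e


def local_pseudo_energy_vector(
    grn: GeneRegulatoryNetwork, state: np.ndarray
) -> np.ndarray:
    """Per-gene single-site pseudo-energy (incoming edges only).

    Satisfies ``vector.sum(-1) == pseudo_energy`` by construction; genes
    with no regulators score 0.  Shape matches the input batch with a
    trailing gene axis.
    """
    x = np.atleast_2d(_as_state(state, grn.n_genes))
    s = 2 * x.astype(np.int64) - 1
    terms = -(
        grn.edge_sign.astype(np.int64)
        * s[:, grn.edge_target]
        * s[:, grn.edge_source]
    )
    out = np.zeros((x.shape[0], grn.n_genes), dtype=np.int64)
    np.add.at(out.T, grn.edge_target, terms.T)
    return out if np.asarray(state).ndim == 2 else out[0]


def local_pseudo_energy(
    grn: GeneRegulatoryNetwork, state: np.ndarray, gene: str
) -> int:
    """Single-site pseudo-energy of one gene (its local frustration)."""
    i = grn.gene_index(gene)
    return int(local_pseudo_energy_vector(grn, state)[..., i])


def driving_force(
    grn: GeneRegulatoryNetwork,
    state: np.ndarray,
    clamp: PerturbationSpec | None = None,
    include_clamped: bool = False,
) -> int | np.ndarray:
    """Number of genes whose bit disagrees with the threshold rule's mandate.

    Zero input contributes nothing (the rule keeps the bit), so the driving
    force is zero exactly at fixed points.  Clamped genes are excluded by
    default because they cannot respond; ``include_clamped=True`` counts them
    anyway (useful on expression data, where no clamp exists).
    """
    mask = unstable_mask(grn, state, None if include_clamped else clamp)
    df = mask.sum(axis=-1)
    return int(df) if np.ndim(df) == 0 else df


def _subset_indices(
    grn: GeneRegulatoryNetwork, gene_subset: Sequence[str] | None
) -> np.ndarray:
    if gene_subset is None:
        return np.arange(grn.n_genes)
    idx = np.array([grn.gene_index(g) for g in gene_subset], dtype=np.intp)
    if idx.size == 0:
        raise ValueError("gene_subset must be non-empty")
    return idx


def state_distance(
    grn: GeneRegulatoryNetwork,
    x: np.ndarray,
    y: np.ndarray,
    gene_subset: Sequence[str] | None = None,
) -> int:
    """Hamming distance between two states over a gene subset (full roster
    when omitted — the displacement used in perturbation screens)."""
    idx = _subset_indices(grn, gene_subset)
    xa = _as_state(x, grn.n_genes)[..., idx].astype(np.int64)
    ya = _as_state(y, grn.n_genes)[..., idx].astype(np.int64)
    return int(np.abs(xa - ya).sum())


def phenotype_change(
    grn: GeneRegulatoryNetwork,
    start: np.ndarray,
    final: np.ndarray,
    markers: MarkerSet,
) -> tuple[int, int]:
    """Score differences (final - start) on both axes: (dPhiPS, dPhiEM)."""
    dps = phenotypic_score(grn, final, markers, "PS") - phenotypic_score(
        grn, start, markers, "PS"
    )
    dem = phenotypic_score(grn, final, markers, "EM") - phenotypic_score(
        grn, start, markers, "EM"
    )
    return int(dps), int(dem)


def mean_pairwise_distance(
    grn: GeneRegulatoryNetwork,
    states: np.ndarray,
    gene_subset: Sequence[str] | None = None,
) -> float:
    """Mean Hamming distance over all unordered pairs of states — a
    heterogeneity measure of a cell population restricted to a gene panel."""
    x = np.atleast_2d(np.asarray(states))
    m = x.shape[0]
    if m < 2:
        raise ValueError("need at least 2 states")
    idx = _subset_indices(grn, gene_subset)
    sub = _as_state(x, grn.n_genes)[:, idx].astype(np.float64)
    # sum of pairwise |xi - yi| per gene: ones * zeros counts differing pairs
    ones = sub.sum(axis=0)
    diff_pairs = (ones * (m - ones)).sum()
    return float(diff_pairs / (m * (m - 1) / 2))


@dataclass(frozen=True)
class ObservableRecord:
    """All scalar observables of one state, computed consistently."""

    phi_ps: int
    phi_em: int
    energy: int
    local_energy: np.ndarray
    driving_force: int


def observables(
    grn: GeneRegulatoryNetwork,
    state: np.ndarray,
    markers: MarkerSet,
    clamp: PerturbationSpec | None = None,
) -> ObservableRecord:
    """Bundle phenotype scores, global/local pseudo-energy and driving force
    for a single state."""
    local = local_pseudo_energy_vector(grn, state)
    return ObservableRecord(
        phi_ps=int(phenotypic_score(grn, state, markers, "PS")),
        phi_em=int(phenotypic_score(grn, state, markers, "EM")),
        energy=int(local.sum()),
        local_energy=local,
        driving_force=int(driving_force(grn, state, clamp)),
    )
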