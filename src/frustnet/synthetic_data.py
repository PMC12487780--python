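"""Synthetic networks and expression data with known ground truth.

Three generator families make every pipeline stage testable without any
external download:

* uniform random signed networks with tunable size, density and activation
  fraction;
* networks with a *planted* pair of minimally frustrated attractors: edge
  signs are chosen so a designated anchor state (and, for complementary
  anchors, automatically its opposite) satisfies every regulatory edge, and
  a tunable fraction of signs is then flipped to inject frustration;
* bimodal (two-Gaussian) expression matrices over a known binary state
  matrix, with optional dropout to emulate single-cell sparsity.

The planted construction gives closed-form ground truth: at zero injected
frustration both anchors are fixed points of the threshold dynamics and
every gene's single-site pseudo-energy equals minus its in-degree.

:func:`reprogramming_network` builds the package's synthetic stand-in for a
curated reprogramming network: 88 genes (the 33 phenotype marker genes plus
auxiliary genes), 387 edges with hub-biased out-degree on the core
transcription factors, and complementary somatic-mesenchymal /
pluripotent-epithelial anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_model import (
    BUILTIN_MARKERS,
    GeneRegulatoryNetwork,
    MarkerSet,
)

__all__ = [
    "SyntheticSpec",
    "random_network",
    "planted_bistable_network",
    "synthetic_expression",
    "reprogramming_network",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generators.

    ``n_genes``/``n_edges`` size the network (defaults mirror the scale of a
    curated reprogramming network: 88 genes, 387 edges); ``p_act`` is the
    probability that a random edge activates; ``f_c`` the fraction of edge
    signs flipped after planting (the frustration dial).  Expression values
    are drawn from two Gaussians (``mu_off``/``mu_on``, shared ``sigma``, on
    a log-like scale) truncated at zero, with independent ``dropout``
    zeroing.
    """

    n_genes: int = 88
    n_edges: int = 387
    p_act: float = 0.5
    f_c: float = 0.1
    mu_off: float = 1.0
    mu_on: float = 6.0
    sigma: float = 1.0
    dropout: float = 0.0
    allow_self_loops: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        max_edges = self.n_genes * (
            self.n_genes if self.allow_self_loops else self.n_genes - 1
        )
        if not 0 < self.n_edges <= max_edges:
            raise ValueError(
                f"n_edges must be in [1, {max_edges}] for n_genes="
                f"{self.n_genes}, got {self.n_edges}"
            )
        if not 0 <= self.p_act <= 1:
            raise ValueError("p_act must be in [0, 1]")
        if not 0 <= self.f_c <= 1:
            raise ValueError("f_c must be in [0, 1]")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be in [0, 1]")
        if self.mu_on <= self.mu_off:
            raise ValueError("mu_on must exceed mu_off")


def _default_gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_edge_pairs(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform ordered pairs without replacement (optionally no self-loops)."""
    n = spec.n_genes
    if spec.allow_self_loops:
        flat = rng.choice(n * n, size=spec.n_edges, replace=False)
        return flat // n, flat % n
    flat = rng.choice(n * (n - 1), size=spec.n_edges, replace=False)
    src = flat // (n - 1)
    tgt = flat % (n - 1)
    tgt = np.where(tgt >= src, tgt + 1, tgt)  # skip the diagonal
    return src, tgt


def random_network(
    spec: SyntheticSpec, gene_names: Sequence[str] | None = None
) -> GeneRegulatoryNetwork:
    """Uniform random signed network: edges without replacement over ordered
    pairs, each activating with probability ``p_act``."""
    rng = np.random.default_rng(spec.seed)
    src, tgt = _sample_edge_pairs(spec, rng)
    signs = np.where(rng.random(spec.n_edges) < spec.p_act, 1, -1)
    names = (
        _default_gene_names(spec.n_genes) if gene_names is None else list(gene_names)
    )
    edges = [(names[j], names[i], int(s)) for j, i, s in zip(src, tgt, signs)]
    return GeneRegulatoryNetwork.from_edges(edges, genes=names)


def planted_bistable_network(
    spec: SyntheticSpec,
    anchor_a: np.ndarray | None = None,
    anchor_b: np.ndarray | None = None,
    gene_names: Sequence[str] | None = None,
    source_weights: np.ndarray | None = None,
) -> tuple[GeneRegulatoryNetwork, tuple[np.ndarray, np.ndarray]]:
    """Network with a planted pair of minimally frustrated attractor states.

    Each sampled edge ``j -> i`` receives the sign ``s_i s_j`` (spins of the
    anchor), which makes the edge satisfied; when the two anchors agree on
    that product — always, for complementary anchors, the default — the edge
    is satisfied in both, otherwise anchor A wins.  A fraction ``f_c`` of
    signs is then flipped to inject frustration.  ``source_weights`` biases
    which genes act as regulators (hub structure); sampling stays without
    replacement over ordered pairs.

    Returns the network and the ``(anchor_a, anchor_b)`` pair actually used.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    if anchor_a is None:
        anchor_a = rng.integers(0, 2, size=n, dtype=np.uint8)
    anchor_a = np.asarray(anchor_a, dtype=np.uint8)
    if anchor_b is None:
        anchor_b = (1 - anchor_a).astype(np.uint8)
    anchor_b = np.asarray(anchor_b, dtype=np.uint8)
    if anchor_a.shape != (n,) or anchor_b.shape != (n,):
        raise ValueError("anchors must be length-n binary vectors")
    if np.array_equal(anchor_a, anchor_b):
        raise ValueError("anchors must be distinct")
    if source_weights is None:
        src, tgt = _sample_edge_pairs(spec, rng)
    else:
        w = np.asarray(source_weights, dtype=np.float64)
        if w.shape != (n,) or (w <= 0).any():
            raise ValueError("source_weights must be n positive values")
        pairs: set[tuple[int, int]] = set()
        p = w / w.sum()
        while len(pairs) < spec.n_edges:
            j = int(rng.choice(n, p=p))
            i = int(rng.integers(n))
            if i == j and not spec.allow_self_loops:
                continue
            pairs.add((j, i))
        src = np.array([j for j, _ in sorted(pairs)], dtype=np.intp)
        tgt = np.array([i for _, i in sorted(pairs)], dtype=np.intp)
    sa = 2 * anchor_a.astype(np.int8) - 1
    # sign s_i*s_j satisfies the edge in anchor A; when the anchors agree on
    # the spin product (always, if complementary) it satisfies B too,
    # otherwise anchor A wins by construction.
    signs = (sa[tgt] * sa[src]).astype(np.int8)
    n_flip = int(round(spec.f_c * spec.n_edges))
    if n_flip:
        flip = rng.choice(spec.n_edges, size=n_flip, replace=False)
        signs[flip] = -signs[flip]
    names = (
        _default_gene_names(n) if gene_names is None else list(gene_names)
    )
    edges = [(names[j], names[i], int(s)) for j, i, s in zip(src, tgt, signs)]
    grn = GeneRegulatoryNetwork.from_edges(edges, genes=names)
    return grn, (anchor_a, anchor_b)


def synthetic_expression(
    binary_matrix: np.ndarray,
    spec: SyntheticSpec,
    seed: int | None = None,
) -> np.ndarray:
    """Two-Gaussian expression over a known binary ground truth.

    Entries with bit 0 draw from ``Normal(mu_off, sigma)`` and bit 1 from
    ``Normal(mu_on, sigma)``; negatives are truncated to zero (expression is
    nonnegative) and a ``dropout`` fraction of entries is then zeroed
    independently, emulating single-cell sparsity.
    """
    bits = np.asarray(binary_matrix)
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("binary_matrix must contain only 0/1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mu = np.where(bits == 1, spec.mu_on, spec.mu_off)
    values = rng.normal(mu, spec.sigma)
    values = np.clip(values, 0.0, None)
    if spec.dropout > 0:
        values = np.where(rng.random(values.shape) < spec.dropout, 0.0, values)
    return values


# ---------------------------------------------------------------------------
# Synthetic stand-in for a curated reprogramming network
# ---------------------------------------------------------------------------

#: Edge budget of the stand-in, as fractions of the total edge count, per
#: structural block.  Curated reprogramming networks are organised as two
#: antagonistic programs: a small, densely self-activating core of
#: transcription factors per program, mutual inhibition between the cores,
#: and a sparsely regulated periphery of downstream targets.  The
#: somatic-core -> pluripotency-core inhibition budget is deliberately the
#: smallest: pluripotency factors are silenced by relatively few somatic
#: repressors, which is what lets an overexpressed core factor occasionally
#: nucleate the pluripotency program.
_BLOCK_FRACTIONS = {
    "p_core": 30 / 387,       # pluripotency core mutual activation
    "s_core": 33 / 387,       # somatic core mutual activation
    "p_to_s": 33 / 387,       # pluripotency -> somatic inhibition
    "s_to_p": 8 / 387,        # somatic -> pluripotency-master inhibition
    "periph_to_core": 22 / 387,  # periphery feedback onto own core
    # periphery in-edges are drawn per gene (1-3 own-core activators, 1-2
    # opposite-core inhibitors); any remaining budget becomes
    # periphery-periphery edges
}

#: The pluripotency core is hierarchical: the canonical master triad
#: receives all direct somatic repression and densely activates the
#: secondary core factors, which feed back onto the masters.  Under integer
#: threshold dynamics a core whose every member is directly repressed could
#: never be nucleated by a single overexpressed factor; concentrating
#: repression on the masters reproduces the regime where single-factor
#: reprogramming is rare but possible, and succeeds preferentially from
#: frustrated somatic states whose repressors are incompletely engaged.
_MASTER_FACTORS = ("Pou5f1", "Sox2", "Nanog")


def _sample_block(
    rng: np.random.Generator,
    sources: np.ndarray,
    targets: np.ndarray,
    k: int,
) -> list[tuple[int, int]]:
    """k ordered pairs (source, target), no self-loops, without replacement."""
    pool = [
        (int(j), int(i)) for j in sources for i in targets if j != i
    ]
    k = min(k, len(pool))
    picks = rng.choice(len(pool), size=k, replace=False)
    return [pool[p] for p in picks]


def reprogramming_network(
    spec: SyntheticSpec | None = None,
    markers: MarkerSet = BUILTIN_MARKERS,
) -> tuple[GeneRegulatoryNetwork, Mapping[str, np.ndarray]]:
    """Synthetic stand-in for a curated somatic-reprogramming network.

    The roster holds the full marker panel plus auxiliary genes; the two
    complementary anchor states encode the terminal phenotypes (SM anchor:
    somatic and mesenchymal markers on, a MEF-like state; PE anchor: its
    complement, an iPSC-like state; auxiliary genes split evenly between the
    sides).  Topology follows the two-program architecture of curated
    reprogramming networks: the pluripotency markers form a densely
    self-activating core, the somatic markers another, the cores inhibit
    each other, and each core activates its own periphery (epithelial /
    mesenchymal markers and auxiliary genes, in-degree 1-3) while sparsely
    inhibiting the other side's.  Every edge sign initially satisfies both
    anchors (within-side activation, cross-side inhibition), then a fraction
    ``f_c`` of signs is flipped, so the two phenotypic attractors are low-
    but not zero-frustration states embedded in a rugged landscape.

    Returns the network and ``{"SM": ..., "PE": ...}`` anchor states.
    """
    spec = SyntheticSpec() if spec is None else spec
    rng = np.random.default_rng(spec.seed)
    marker_names = sorted(markers.all_genes)
    if spec.n_genes < len(marker_names):
        raise ValueError(
            f"n_genes must cover the {len(marker_names)} marker genes"
        )
    n_aux = spec.n_genes - len(marker_names)
    width = max(2, len(str(max(n_aux - 1, 0))))
    names = marker_names + [f"Aux{i:0{width}d}" for i in range(n_aux)]
    idx = {g: k for k, g in enumerate(names)}
    aux = np.arange(len(marker_names), spec.n_genes)
    aux_sm, aux_pe = aux[: n_aux // 2], aux[n_aux // 2:]
    p_core = np.array([idx[g] for g in sorted(markers.phiPS_pos)])
    s_core = np.array([idx[g] for g in sorted(markers.phiPS_neg)])
    e_block = np.array([idx[g] for g in sorted(markers.phiEM_pos)])
    m_block = np.array([idx[g] for g in sorted(markers.phiEM_neg)])
    pe_periph = np.concatenate([e_block, aux_pe])
    sm_periph = np.concatenate([m_block, aux_sm])
    sm = np.zeros(spec.n_genes, dtype=np.uint8)
    sm[s_core] = sm[sm_periph] = 1
    pe = (1 - sm).astype(np.uint8)

    m = spec.n_edges
    budget = {k: int(round(f * m)) for k, f in _BLOCK_FRACTIONS.items()}
    masters = np.array(
        [idx[g] for g in _MASTER_FACTORS if g in idx and idx[g] in p_core]
    )
    if masters.size == 0:  # custom marker panel: fall back to the first core gene
        masters = p_core[:1]
    secondaries = np.setdiff1d(p_core, masters)
    pairs: list[tuple[int, int]] = []
    # hierarchical pluripotency core: masters drive everything, secondaries
    # feed back onto masters, sparse secondary-secondary wiring
    n_pc = budget["p_core"]
    n_m = min(int(round(0.55 * n_pc)), masters.size * (p_core.size - 1))
    n_fb = min(int(round(0.25 * n_pc)), secondaries.size * masters.size)
    pairs += _sample_block(rng, masters, p_core, n_m)
    pairs += _sample_block(rng, secondaries, masters, n_fb)
    pairs += _sample_block(rng, secondaries, secondaries, n_pc - n_m - n_fb)
    pairs += _sample_block(rng, s_core, s_core, budget["s_core"])
    pairs += _sample_block(rng, p_core, s_core, budget["p_to_s"])
    pairs += _sample_block(rng, s_core, masters, budget["s_to_p"])
    # sparse somatic-periphery repression of the secondary core factors:
    # without it a secondary, having only activating inputs, could never
    # switch off, and the somatic attractor would not silence the core
    if secondaries.size:
        pairs += _sample_block(
            rng, sm_periph, secondaries, int(round(1.2 * secondaries.size))
        )
    # periphery wiring: every periphery gene gets 1-3 activators from its
    # own core and at least one inhibitor from the opposite core, so both
    # programs can switch the whole periphery on and off
    for gene_set, own, other in (
        (pe_periph, p_core, s_core),
        (sm_periph, s_core, p_core),
    ):
        for g in gene_set:
            acts = rng.choice(own, size=rng.integers(1, 4), replace=False)
            inhs = rng.choice(other, size=rng.integers(1, 3), replace=False)
            pairs += [(int(j), int(g)) for j in acts]
            pairs += [(int(j), int(g)) for j in inhs]
    n_fb = budget["periph_to_core"]
    pairs += _sample_block(rng, pe_periph, p_core, n_fb // 2)
    pairs += _sample_block(rng, sm_periph, s_core, n_fb - n_fb // 2)
    # fill (or trim) to the exact edge budget with periphery-periphery pairs
    periph = np.concatenate([pe_periph, sm_periph])
    taken = set(pairs)
    while len(pairs) > m:
        pairs.pop()  # sheds feedback edges only; block structure stays intact
    remainder = m - len(pairs)
    while remainder > 0:
        cand = _sample_block(rng, periph, periph, remainder)
        fresh = [p for p in cand if p not in taken]
        pairs += fresh
        taken.update(fresh)
        remainder = m - len(pairs)

    src = np.array([j for j, _ in pairs], dtype=np.intp)
    tgt = np.array([i for _, i in pairs], dtype=np.intp)
    sa = 2 * sm.astype(np.int8) - 1
    signs = (sa[tgt] * sa[src]).astype(np.int8)  # satisfied in both anchors
    n_flip = int(round(spec.f_c * m))
    if n_flip:
        flip = rng.choice(m, size=n_flip, replace=False)
        signs[flip] = -signs[flip]
    edges = [(names[j], names[i], int(s)) for j, i, s in zip(src, tgt, signs)]
    grn = GeneRegulatoryNetwork.from_edges(edges, genes=names)
    return grn, {"SM": sm, "PE": pe}
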