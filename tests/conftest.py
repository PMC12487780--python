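"""Shared fixtures: tiny hand-checkable networks and the synthetic stand-in."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import frustnet as fn


def brute_force_fixed_points(grn, clamp=None) -> set[tuple[int, ...]]:
    """Oracle: scan all 2^N states for the stability condition directly.

    Independent of the simulator: evaluates the threshold rule's mandate
    from the adjacency matrix for every state and keeps states where no
    unclamped gene is mandated to flip.
    """
    n = grn.n_genes
    cidx = []
    cval = {}
    if clamp is not None:
        for g, v in clamp.clamp.items():
            i = grn.gene_index(g)
            cidx.append(i)
            cval[i] = v
    out = set()
    for bits in itertools.product((0, 1), repeat=n):
        x = np.array(bits, dtype=np.int64)
        if any(x[i] != cval[i] for i in cidx):
            continue
        f = grn.adjacency.astype(np.int64) @ x
        unstable = ((f > 0) & (x == 0)) | ((f < 0) & (x == 1))
        unstable[cidx] = False
        if not unstable.any():
            out.add(tuple(int(b) for b in bits))
    return out


@pytest.fixture(scope="session")
def toy3():
    """3-gene toy: a<->b mutual activation, a<->c mutual inhibition."""
    return fn.GeneRegulatoryNetwork.from_edges(
        [("a", "b", 1), ("b", "a", 1), ("a", "c", -1), ("c", "a", -1)]
    )


@pytest.fixture(scope="session")
def mutual_activation():
    return fn.GeneRegulatoryNetwork.from_edges([("a", "b", 1), ("b", "a", 1)])


@pytest.fixture(scope="session")
def mutual_inhibition():
    return fn.GeneRegulatoryNetwork.from_edges([("a", "b", -1), ("b", "a", -1)])


@pytest.fixture(scope="session")
def standin():
    """The synthetic 88-gene reprogramming stand-in and its anchors."""
    return fn.reprogramming_network()


@pytest.fixture(scope="session")
def standin_ensemble(standin):
    grn, _ = standin
    return fn.sample_ensemble(grn, 20000, seed=1, keep_finals=True)


@pytest.fixture(scope="session")
def standin_labels(standin, standin_ensemble):
    grn, _ = standin
    mk = fn.BUILTIN_MARKERS
    ps = fn.phenotypic_score(grn, standin_ensemble.states, mk, "PS")
    em = fn.phenotypic_score(grn, standin_ensemble.states, mk, "EM")
    return fn.phenotype_extremes(ps, em)


@pytest.fixture(scope="session")
def small_planted():
    """12-gene planted bistable network, no injected frustration."""
    spec = fn.SyntheticSpec(n_genes=12, n_edges=40, f_c=0.0, seed=3)
    return fn.planted_bistable_network(spec)
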