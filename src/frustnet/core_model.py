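"""Domain types for signed Boolean gene regulatory networks.

A cell is modelled as a binary activity vector over an ordered gene roster;
the regulatory structure is a signed directed graph where an edge ``j -> i``
with sign +1 activates and sign -1 inhibits gene ``i``.  Everything downstream
(dynamics, energetics, screens) is expressed against the containers defined
here, so the roster order fixed at load time is the single alignment contract
for all vectors and matrices in the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRegulatoryNetwork",
    "MarkerSet",
    "PerturbationSpec",
    "NetworkError",
    "MarkerError",
    "load_network",
    "save_network",
    "network_summary",
    "load_markers",
    "save_markers",
    "load_states",
    "save_states",
    "to_spin",
    "from_spin",
    "BUILTIN_MARKERS",
]


class NetworkError(ValueError):
    """Invalid network structure or edge-list content."""


class MarkerError(ValueError):
    """Invalid marker-set definition."""


# Tokens accepted in the `sign` column of an edge list, canonicalised to +/-1.
_SIGN_TOKENS = {
    "+1": 1, "1": 1, "+": 1, "activate": 1, "activation": 1,
    "-1": -1, "−1": -1, "-": -1, "−": -1,
    "inhibit": -1, "inhibition": -1,
}


def _parse_sign(token: object) -> int:
    if isinstance(token, (int, np.integer)):
        value = int(token)
        if value in (1, -1):
            return value
        raise NetworkError(f"edge sign must be +1 or -1, got {value}")
    key = str(token).strip().lower()
    if key in _SIGN_TOKENS:
        return _SIGN_TOKENS[key]
    raise NetworkError(f"unrecognised edge sign token: {token!r}")


@dataclass(frozen=True)
class GeneRegulatoryNetwork:
    """Signed directed regulatory network over an ordered gene roster.

    Attributes
    ----------
    genes
        Ordered roster of unique gene names; all state vectors align to it.
    edge_source, edge_target, edge_sign
        Parallel integer arrays of length M (roster indices and signs +/-1).
    adjacency
        Dense ``(N, N)`` int8 matrix with ``adjacency[i, j]`` the sign of the
        edge ``j -> i`` (0 if absent), so the regulatory input of gene ``i``
        in state ``x`` is ``adjacency[i] @ x``.
    """

    genes: tuple[str, ...]
    edge_source: np.ndarray
    edge_target: np.ndarray
    edge_sign: np.ndarray
    adjacency: np.ndarray = field(repr=False)
    index: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, object]],
        genes: Sequence[str] | None = None,
        roster_order: str = "file",
    ) -> "GeneRegulatoryNetwork":
        """Build a network from ``(source, target, sign)`` triples.

        When ``genes`` is omitted the roster is the endpoints in order of
        first appearance (``roster_order="file"``) or sorted
        (``roster_order="sorted"``).
        """
        rows = [(str(s), str(t), _parse_sign(g)) for s, t, g in edges]
        if genes is None:
            seen: dict[str, None] = {}
            for s, t, _ in rows:
                seen.setdefault(s)
                seen.setdefault(t)
            roster = sorted(seen) if roster_order == "sorted" else list(seen)
        else:
            roster = [str(g) for g in genes]
            if len(set(roster)) != len(roster):
                raise NetworkError("roster contains duplicate gene names")
        if len(roster) < 1:
            raise NetworkError("network must contain at least one gene")
        index = {g: i for i, g in enumerate(roster)}
        pairs: set[tuple[str, str]] = set()
        for s, t, _ in rows:
            if s not in index or t not in index:
                missing = s if s not in index else t
                raise NetworkError(f"edge endpoint {missing!r} not in roster")
            if (s, t) in pairs:
                raise NetworkError(f"duplicate ordered edge {s!r} -> {t!r}")
            pairs.add((s, t))
        n = len(roster)
        src = np.array([index[s] for s, _, _ in rows], dtype=np.intp)
        tgt = np.array([index[t] for _, t, _ in rows], dtype=np.intp)
        sgn = np.array([g for _, _, g in rows], dtype=np.int8)
        adj = np.zeros((n, n), dtype=np.int8)
        adj[tgt, src] = sgn
        for a in (src, tgt, sgn, adj):
            a.setflags(write=False)
        return cls(tuple(roster), src, tgt, sgn, adj, index)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.edge_sign.size)

    @property
    def in_degree(self) -> np.ndarray:
        return np.bincount(self.edge_target, minlength=self.n_genes)

    @property
    def out_degree(self) -> np.ndarray:
        return np.bincount(self.edge_source, minlength=self.n_genes)

    def gene_index(self, gene: str) -> int:
        try:
            return self.index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in roster") from None

    def regulators_of(self, gene: str) -> list[tuple[str, int]]:
        """Incoming edges of ``gene`` as ``(regulator, sign)`` pairs."""
        i = self.gene_index(gene)
        mask = self.edge_target == i
        return [
            (self.genes[j], int(s))
            for j, s in zip(self.edge_source[mask], self.edge_sign[mask])
        ]

    def subnetwork(self, genes: Sequence[str]) -> "GeneRegulatoryNetwork":
        """Induced sub-network on ``genes`` (edges with both endpoints kept).

        Dropped edges are counted in the log; used when intersecting the
        model roster with the genes measured in an expression matrix.
        """
        keep = [g for g in genes if g in self.index]
        keepset = set(keep)
        edges = [
            (self.genes[s], self.genes[t], int(g))
            for s, t, g in zip(self.edge_source, self.edge_target, self.edge_sign)
            if self.genes[s] in keepset and self.genes[t] in keepset
        ]
        dropped = self.n_edges - len(edges)
        if dropped:
            logger.info(
                "subnetwork: dropped %d/%d edges with endpoints outside the "
                "%d common genes", dropped, self.n_edges, len(keep),
            )
        return GeneRegulatoryNetwork.from_edges(edges, genes=keep)


# ---------------------------------------------------------------------------
# Cell states: plain uint8 arrays aligned to a roster, with a spin view.
# ---------------------------------------------------------------------------

def _as_state(state: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(state)
    if x.shape[-1] != n:
        raise ValueError(f"state length {x.shape[-1]} != roster size {n}")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("state entries must be 0 or 1")
    return x.astype(np.uint8, copy=False)


def to_spin(state: np.ndarray) -> np.ndarray:
    """Map bits {0,1} to spins {-1,+1} via s = 2x - 1."""
    x = np.asarray(state)
    return (2 * x.astype(np.int8) - 1).astype(np.int8)


def from_spin(spins: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_spin`."""
    s = np.asarray(spins)
    if not np.isin(s, (-1, 1)).all():
        raise ValueError("spin entries must be -1 or +1")
    return ((s + 1) // 2).astype(np.uint8)


@dataclass(frozen=True)
class MarkerSet:
    """Phenotype marker clusters for the two scoring axes.

    The pluripotent-vs-somatic axis (PS) scores pluripotency markers
    positively and somatic markers negatively; the epithelial-vs-mesenchymal
    axis (EM) scores epithelial markers positively and mesenchymal markers
    negatively.
    """

    phiPS_pos: frozenset[str]
    phiPS_neg: frozenset[str]
    phiEM_pos: frozenset[str]
    phiEM_neg: frozenset[str]

    def __post_init__(self) -> None:
        if self.phiPS_pos & self.phiPS_neg:
            raise MarkerError(
                f"PS axis overlap: {sorted(self.phiPS_pos & self.phiPS_neg)}"
            )
        if self.phiEM_pos & self.phiEM_neg:
            raise MarkerError(
                f"EM axis overlap: {sorted(self.phiEM_pos & self.phiEM_neg)}"
            )

    @classmethod
    def from_dict(cls, data: Mapping[str, Iterable[str]]) -> "MarkerSet":
        keys = ("phiPS_pos", "phiPS_neg", "phiEM_pos", "phiEM_neg")
        missing = [k for k in keys if k not in data]
        if missing:
            raise MarkerError(f"marker definition missing keys: {missing}")
        return cls(*(frozenset(map(str, data[k])) for k in keys))

    def to_dict(self) -> dict[str, list[str]]:
        return {
            "phiPS_pos": sorted(self.phiPS_pos),
            "phiPS_neg": sorted(self.phiPS_neg),
            "phiEM_pos": sorted(self.phiEM_pos),
            "phiEM_neg": sorted(self.phiEM_neg),
        }

    @property
    def all_genes(self) -> frozenset[str]:
        return self.phiPS_pos | self.phiPS_neg | self.phiEM_pos | self.phiEM_neg


#: Curated reprogramming marker clusters: somatic (S, scores PS negatively),
#: pluripotent (P, positively), mesenchymal (M, EM negative), epithelial
#: (E, EM positive).
BUILTIN_MARKERS = MarkerSet(
    phiPS_pos=frozenset(
        ["Esrrb", "Nanog", "Klf4", "Pou5f1", "Sox2", "Myc", "Sall4"]
    ),
    phiPS_neg=frozenset(
        ["Gata6", "Gata4", "Bmp2", "Bmp4", "Cebpa", "Jun", "Sox17",
         "Sox7", "Cdx2", "Foxa1", "Foxa2"]
    ),
    phiEM_pos=frozenset(["Cdh1", "Tcf3", "Ovol2", "miR200", "miR34"]),
    phiEM_neg=frozenset(
        ["Vim", "Cdh2", "Zeb1", "Zeb2", "Foxc2", "Snai1", "Snai2",
         "Twist1", "Twist2", "miR9"]
    ),
)


@dataclass(frozen=True)
class PerturbationSpec:
    """Genes clamped to fixed values for a whole simulation.

    A value of 1 models overexpression (OE), 0 models knockdown (KD); the
    clamp is applied before relaxation and never released.
    """

    clamp: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, value in self.clamp.items():
            if value not in (0, 1):
                raise ValueError(
                    f"clamp value for {gene!r} must be 0 or 1, got {value}"
                )

    def indices(self, grn: GeneRegulatoryNetwork) -> tuple[np.ndarray, np.ndarray]:
        """Clamp as aligned (roster index, value) arrays; validates names."""
        idx = np.array(
            [grn.gene_index(g) for g in self.clamp], dtype=np.intp
        )
        values = np.array(list(self.clamp.values()), dtype=np.uint8)
        return idx, values

    def apply(self, grn: GeneRegulatoryNetwork, state: np.ndarray) -> np.ndarray:
        out = _as_state(state, grn.n_genes).copy()
        idx, values = self.indices(grn)
        out[..., idx] = values
        return out

    def __len__(self) -> int:
        return len(self.clamp)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def load_network(
    path: str | Path,
    roster_path: str | Path | None = None,
    roster_order: str = "file",
) -> GeneRegulatoryNetwork:
    """Read a signed edge list (TSV with columns source/target/sign).

    Lines starting with ``#`` are treated as comments.  Duplicate ordered
    pairs are rejected regardless of sign; sign tokens +1/-1/+/-/activate/
    inhibit are accepted and stored as integers.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"source", "target", "sign"}
    if not required.issubset(df.columns):
        raise NetworkError(
            f"edge list must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    roster = None
    if roster_path is not None:
        roster = [
            line.strip()
            for line in Path(roster_path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
    grn = GeneRegulatoryNetwork.from_edges(
        df[["source", "target", "sign"]].itertuples(index=False, name=None),
        genes=roster,
        roster_order=roster_order,
    )
    logger.info(
        "loaded network from %s: %d genes, %d edges", path, grn.n_genes, grn.n_edges
    )
    return grn


def save_network(grn: GeneRegulatoryNetwork, path: str | Path) -> None:
    """Write the edge list as TSV (source, target, sign), preserving order."""
    df = pd.DataFrame(
        {
            "source": [grn.genes[j] for j in grn.edge_source],
            "target": [grn.genes[i] for i in grn.edge_target],
            "sign": grn.edge_sign.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def network_summary(grn: GeneRegulatoryNetwork) -> dict[str, object]:
    """Basic structural report: size, edge balance, degree ranges."""
    act = int((grn.edge_sign == 1).sum())
    indeg, outdeg = grn.in_degree, grn.out_degree
    return {
        "n_genes": grn.n_genes,
        "n_edges": grn.n_edges,
        "n_activations": act,
        "n_inhibitions": grn.n_edges - act,
        "n_self_loops": int((grn.edge_source == grn.edge_target).sum()),
        "in_degree_min": int(indeg.min()),
        "in_degree_max": int(indeg.max()),
        "out_degree_min": int(outdeg.min()),
        "out_degree_max": int(outdeg.max()),
    }


def load_markers(source: str | Path = "builtin") -> MarkerSet:
    """Load marker clusters: the builtin curated set, or a JSON file with
    keys phiPS_pos / phiPS_neg / phiEM_pos / phiEM_neg."""
    if source == "builtin":
        return BUILTIN_MARKERS
    with open(source) as fh:
        return MarkerSet.from_dict(json.load(fh))


def save_markers(markers: MarkerSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(markers.to_dict(), indent=2) + "\n")


def load_states(path: str | Path, grn: GeneRegulatoryNetwork) -> np.ndarray:
    """Read a CSV of binary states (rows = cells, columns = genes) and align
    the columns to the network roster."""
    df = pd.read_csv(path, index_col=0)
    missing = [g for g in grn.genes if g not in df.columns]
    if missing:
        raise NetworkError(f"state file missing roster genes: {missing[:5]}...")
    return _as_state(df[list(grn.genes)].to_numpy(), grn.n_genes)


def save_states(
    states: np.ndarray, grn: GeneRegulatoryNetwork, path: str | Path
) -> None:
    states = np.atleast_2d(np.asarray(states))
    pd.DataFrame(states, columns=list(grn.genes)).to_csv(path)
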