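"""In-silico perturbation experiments on the Boolean network.

Two experiment families are implemented.  The *reprogramming assay* clamps a
factor (canonically Pou5f1, i.e. Oct4, held overexpressed) in a pool of
somatic-mesenchymal start states and relaxes each to a new fixed point;
trajectories whose pluripotency score rises by more than a threshold count as
productive reprogramming, and the productive/failed groups are compared on
the pseudo-energy of their start states.  The *OE/KD screen* clamps every
gene in turn to 1 (overexpression) or 0 (knockdown) from every start state
and records the full-roster Hamming displacement between start and final
state — a per-gene measure of order-reshaping potential whose distribution
is heavy-tailed, with a small set of core factors producing the largest
cascades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import GeneRegulatoryNetwork, MarkerSet, PerturbationSpec
from .dynamics import Trajectory, relax, relax_batch
from .energetics import (
    local_pseudo_energy_vector,
    phenotypic_score,
    pseudo_energy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AssayResult",
    "ScreenTable",
    "ScreenRanking",
    "SusceptibilityResult",
    "DEFAULT_PRODUCTIVE_THRESHOLD",
    "reprogramming_assay",
    "susceptibility_analysis",
    "oe_kd_screen",
    "screen_rank",
]

#: Productive reprogramming requires the PS score to rise by strictly more
#: than this value.  A change exactly at the threshold is counted as
#: unproductive (and logged).
DEFAULT_PRODUCTIVE_THRESHOLD = 6

DEFAULT_DELTA_CUTOFF = 32
DEFAULT_MIN_OCCURRENCE = 10
DEFAULT_MIN_MEAN = 1.0


@dataclass(frozen=True)
class AssayResult:
    """Outcome of a clamped reprogramming assay.

    ``table`` has one row per trajectory (start/final scores, score changes,
    start pseudo-energy, step count, productive flag); ``trajectories``
    retains the full snapshot paths for landscape profiling.
    """

    table: pd.DataFrame
    trajectories: tuple[Trajectory, ...]
    clamp: PerturbationSpec
    threshold: float

    @property
    def productive(self) -> pd.DataFrame:
        return self.table[self.table["productive"]]

    @property
    def failed(self) -> pd.DataFrame:
        return self.table[~self.table["productive"]]

    def group_energy_summary(self) -> pd.DataFrame:
        """Mean/SD/count of start pseudo-energies for the productive and
        failed groups."""
        return (
            self.table.groupby("productive")["start_energy"]
            .agg(["mean", "std", "count"])
            .rename(index={True: "productive", False: "failed"})
        )


def reprogramming_assay(
    grn: GeneRegulatoryNetwork,
    start_pool: np.ndarray,
    markers: MarkerSet,
    clamp: PerturbationSpec | None = None,
    threshold: float = DEFAULT_PRODUCTIVE_THRESHOLD,
    seed: int = 0,
    max_steps: int | None = None,
) -> AssayResult:
    """Clamp, relax and score every state of a start pool.

    ``clamp`` defaults to overexpression of Pou5f1.  Productive trajectories
    are those with a PS-score gain strictly above ``threshold``; score
    changes are measured from the *unclamped* start state, so the clamp's
    own bit flip counts toward the response.
    """
    starts = np.atleast_2d(np.asarray(start_pool, dtype=np.uint8))
    if starts.shape[0] == 0:
        raise ValueError("start pool is empty")
    if clamp is None:
        clamp = PerturbationSpec({"Pou5f1": 1})
    root = np.random.SeedSequence(seed)
    rows = []
    trajectories = []
    n_ties = 0
    for k, child in enumerate(root.spawn(starts.shape[0])):
        traj = relax(
            grn,
            starts[k],
            clamp=clamp,
            max_steps=max_steps,
            rng=np.random.default_rng(child),
            record=True,
        )
        start, final = starts[k], traj.final
        ps0 = int(phenotypic_score(grn, start, markers, "PS"))
        em0 = int(phenotypic_score(grn, start, markers, "EM"))
        ps1 = int(phenotypic_score(grn, final, markers, "PS"))
        em1 = int(phenotypic_score(grn, final, markers, "EM"))
        dps = ps1 - ps0
        if dps == threshold:
            n_ties += 1
        rows.append(
            {
                "start_id": k,
                "phi_ps_start": ps0,
                "phi_em_start": em0,
                "phi_ps_final": ps1,
                "phi_em_final": em1,
                "delta_phi_ps": dps,
                "delta_phi_em": em1 - em0,
                "start_energy": int(pseudo_energy(grn, start)),
                "final_energy": int(pseudo_energy(grn, final)),
                "steps": traj.n_steps,
                "productive": dps > threshold,
            }
        )
        trajectories.append(traj)
    if n_ties:
        logger.info(
            "%d trajectories at the threshold (dPhiPS == %s) counted as "
            "unproductive", n_ties, threshold,
        )
    return AssayResult(
        table=pd.DataFrame(rows),
        trajectories=tuple(trajectories),
        clamp=clamp,
        threshold=threshold,
    )


@dataclass(frozen=True)
class SusceptibilityResult:
    """Per-gene state-change statistics of a set of reprogramming runs."""

    flip_probability: np.ndarray  # per roster gene
    mean_local_frustration: np.ndarray  # at the clamped start states
    high_susceptibility: tuple[str, ...]
    pearson_rho: float
    cutoff: float


def susceptibility_analysis(
    grn: GeneRegulatoryNetwork,
    starts: np.ndarray,
    finals: np.ndarray,
    clamp: PerturbationSpec | None = None,
    cutoff: float = 0.5,
) -> SusceptibilityResult:
    """Which genes change state during reprogramming, and how frustrated
    they were to begin with.

    Flip probability of a gene is the fraction of (start, final) pairs in
    which its bit differs; genes at or above ``cutoff`` form the
    high-susceptibility set.  The per-gene mean single-site pseudo-energy is
    evaluated at the clamped start states and correlated (Pearson) with the
    flip probabilities.
    """
    s = np.atleast_2d(np.asarray(starts, dtype=np.uint8))
    f = np.atleast_2d(np.asarray(finals, dtype=np.uint8))
    if s.shape != f.shape or s.shape[0] == 0:
        raise ValueError("starts and finals must be non-empty and paired")
    if clamp is not None:
        s_clamped = np.stack([clamp.apply(grn, row) for row in s])
    else:
        s_clamped = s
    flip = (s != f).mean(axis=0)
    local_frust = local_pseudo_energy_vector(grn, s_clamped).mean(axis=0)
    if flip.std() == 0 or local_frust.std() == 0:
        rho = float("nan")
    else:
        rho = float(np.corrcoef(flip, local_frust)[0, 1])
    high = tuple(
        grn.genes[i] for i in np.flatnonzero(flip >= cutoff)
    )
    return SusceptibilityResult(
        flip_probability=flip,
        mean_local_frustration=local_frust,
        high_susceptibility=high,
        pearson_rho=rho,
        cutoff=cutoff,
    )


@dataclass(frozen=True)
class ScreenTable:
    """Raw OE/KD screen results: one row per (gene, protocol, start)."""

    table: pd.DataFrame  # columns: gene, protocol, start_id, delta
    n_nonconverged: int
    seed: int


def oe_kd_screen(
    grn: GeneRegulatoryNetwork,
    start_states: np.ndarray,
    seed: int = 0,
    genes: Sequence[str] | None = None,
    max_steps: int | None = None,
) -> ScreenTable:
    """Perturb every gene in both directions from every start state.

    For each gene and protocol (OE clamps to 1, KD to 0) every start state is
    clamped and relaxed, and the full-roster Hamming displacement between the
    original start and the final fixed point is recorded.  Start states
    should be unique fixed points (duplicates would only reweight the
    displacement distribution).  Non-convergent runs are excluded and
    counted.  Identical seeds reproduce the table bit-for-bit.
    """
    starts = np.atleast_2d(np.asarray(start_states, dtype=np.uint8))
    if starts.shape[0] == 0:
        raise ValueError("no start states given")
    gene_list = list(grn.genes) if genes is None else list(genes)
    frames = []
    n_bad = 0
    for gi, gene in enumerate(gene_list):
        for pi, (protocol, value) in enumerate((("OE", 1), ("KD", 0))):
            clamp = PerturbationSpec({gene: value})
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(gi, pi))
            )
            finals, _, conv = relax_batch(
                grn, starts, clamp=clamp, max_steps=max_steps, rng=rng
            )
            delta = np.abs(
                starts.astype(np.int64) - finals.astype(np.int64)
            ).sum(axis=1)
            n_bad += int((~conv).sum())
            frames.append(
                pd.DataFrame(
                    {
                        "gene": gene,
                        "protocol": protocol,
                        "start_id": np.flatnonzero(conv),
                        "delta": delta[conv],
                    }
                )
            )
    if n_bad:
        logger.warning("screen: %d non-convergent runs excluded", n_bad)
    return ScreenTable(
        table=pd.concat(frames, ignore_index=True),
        n_nonconverged=n_bad,
        seed=seed,
    )


@dataclass(frozen=True)
class ScreenRanking:
    """Per-gene screen statistics and the filtered ranking views."""

    stats: pd.DataFrame  # gene, protocol, lambda_hat, occurrence, n
    ranked: pd.DataFrame  # filtered to lambda_hat > min_mean, sorted
    occurrences: pd.DataFrame  # filtered to occurrence > min_occurrence
    delta_cutoff: int
    min_occurrence: int
    min_mean: float

    def mean_effect(self, protocol: str) -> float:
        """Mean displacement rate over genes for one protocol."""
        sub = self.stats[self.stats["protocol"] == protocol]
        return float(sub["lambda_hat"].mean())


def screen_rank(
    screen: ScreenTable,
    delta_cutoff: int = DEFAULT_DELTA_CUTOFF,
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
    min_mean: float = DEFAULT_MIN_MEAN,
) -> ScreenRanking:
    """Rank genes by their mean displacement under perturbation.

    The per-gene rate ``lambda_hat`` is the Poisson maximum-likelihood
    estimate (the sample mean of the displacements), used purely as a
    ranking statistic.  The occurrence report counts displacements at or
    above ``delta_cutoff`` and keeps genes with more than ``min_occurrence``
    such events; the ranking view keeps genes with ``lambda_hat`` above
    ``min_mean``.
    """
    df = screen.table
    if df.empty:
        raise ValueError("empty screen table")
    stats = (
        df.groupby(["gene", "protocol"], sort=True)["delta"]
        .agg(
            lambda_hat="mean",
            occurrence=lambda s: int((s >= delta_cutoff).sum()),
            n="count",
        )
        .reset_index()
    )
    ranked = (
        stats[stats["lambda_hat"] > min_mean]
        .sort_values(["protocol", "lambda_hat"], ascending=[True, False])
        .reset_index(drop=True)
    )
    occurrences = (
        stats[stats["occurrence"] > min_occurrence]
        .sort_values("occurrence", ascending=False)
        .reset_index(drop=True)
    )
    return ScreenRanking(
        stats=stats,
        ranked=ranked,
        occurrences=occurrences,
        delta_cutoff=delta_cutoff,
        min_occurrence=min_occurrence,
        min_mean=min_mean,
    )
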