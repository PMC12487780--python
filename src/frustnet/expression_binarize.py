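"""From expression matrices to binary network states and observables.

Measured transcriptomes (bulk or single-cell) are mapped onto the Boolean
model in three steps: quality-filter cells by their expressed-gene count
(single-cell only, where dropout dominates), binarize each gene with a
two-component Gaussian mixture on log-transformed values, and evaluate the
network observables (phenotype scores, pseudo-energy, local frustration,
driving force) on the sub-network induced by the genes common to the matrix
and the model roster.  A PCA embedding fitted on simulated states of that
same sub-network places the measured samples on the reaction coordinate, so
experimental reprogramming time courses can be read against the simulated
landscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .core_model import GeneRegulatoryNetwork, MarkerSet
from .energetics import (
    driving_force,
    local_pseudo_energy_vector,
    phenotypic_score,
    pseudo_energy,
)
from .landscape import EmbeddingModel, project

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "BinarizedSeries",
    "filter_cells",
    "gmm_binarize",
    "trajectory_observables",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative genes x samples matrix with optional sample annotations.

    ``annotations`` is indexed by sample id; conventional columns are
    ``time`` (collection point), ``protocol`` and ``cell_type``
    (e.g. MEF / iPSC / ESC / Other).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.values.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if self.annotations is not None:
            missing = self.values.columns.difference(self.annotations.index)
            if len(missing):
                raise ValueError(
                    f"samples without annotation: {list(missing)[:5]}..."
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        annotations_path: str | Path | None = None,
        sep: str | None = None,
    ) -> "ExpressionMatrix":
        """Dense genes x samples table (CSV/TSV by extension)."""
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        values = pd.read_csv(path, sep=sep, index_col=0)
        ann = (
            pd.read_csv(annotations_path, index_col=0)
            if annotations_path is not None
            else None
        )
        return cls(values=values, annotations=ann)

    @classmethod
    def from_mtx(
        cls,
        mtx_path: str | Path,
        genes_path: str | Path,
        samples_path: str | Path,
        annotations_path: str | Path | None = None,
    ) -> "ExpressionMatrix":
        """Sparse MatrixMarket triplet with separate gene/sample id files."""
        from scipy.io import mmread

        mat = np.asarray(mmread(mtx_path).todense())
        genes = [
            s.strip() for s in Path(genes_path).read_text().splitlines() if s.strip()
        ]
        samples = [
            s.strip() for s in Path(samples_path).read_text().splitlines() if s.strip()
        ]
        values = pd.DataFrame(mat, index=genes, columns=samples)
        ann = (
            pd.read_csv(annotations_path, index_col=0)
            if annotations_path is not None
            else None
        )
        return cls(values=values, annotations=ann)


def filter_cells(
    expr: ExpressionMatrix, q_low: float = 0.05, q_high: float = 0.95
) -> ExpressionMatrix:
    """Drop cells whose expressed-gene count is outside a quantile band.

    The expressed-gene count is the number of entries > 0 per sample; the
    retained band is the closed interval between the empirical ``q_low`` and
    ``q_high`` quantiles (linear interpolation), the standard guard against
    empty and doublet-like cells in single-cell data.  Bulk matrices should
    skip this filter.
    """
    if not 0 <= q_low < q_high <= 1:
        raise ValueError("need 0 <= q_low < q_high <= 1")
    counts = (expr.values.to_numpy() > 0).sum(axis=0)
    lo = np.quantile(counts, q_low, method="linear")
    hi = np.quantile(counts, q_high, method="linear")
    keep = (counts >= lo) & (counts <= hi)
    if not keep.any():
        raise ValueError("cell filter removed every sample")
    kept = expr.values.loc[:, keep]
    logger.info(
        "filter_cells: kept %d/%d samples (expressed-gene count in "
        "[%.1f, %.1f])", kept.shape[1], expr.n_samples, lo, hi,
    )
    ann = (
        expr.annotations.loc[kept.columns]
        if expr.annotations is not None
        else None
    )
    return ExpressionMatrix(values=kept, annotations=ann)


def gmm_binarize(
    expr: ExpressionMatrix | pd.DataFrame,
    seed: int = 0,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene two-Gaussian binarization of an expression matrix.

    For every gene a two-component univariate Gaussian mixture is fitted on
    ``log2(x + 1)`` values (configurable); the higher-mean component is the
    active one and a sample scores 1 iff its posterior for that component
    exceeds 0.5 (ties are inactive).  Exact zeros are treated as silent
    without entering the fit: in sparse single-cell data they are dominated
    by dropout, and including them would hand the mixture a zero-inflation
    mode instead of the on/off split.  Genes whose (positive) values are
    (near-)constant cannot support two components and binarize to all zeros.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.size == 0:
        raise ValueError("empty expression matrix")
    data = values.to_numpy(dtype=np.float64)
    if log_transform:
        data = np.log2(data + 1.0)
    bits = np.zeros(data.shape, dtype=np.uint8)
    root = np.random.SeedSequence(seed)
    for k, child in enumerate(root.spawn(data.shape[0])):
        row = data[k]
        pos = row > 0
        fit_vals = row[pos]
        if (
            fit_vals.size < 4
            or fit_vals.std() < 1e-6
            or np.unique(fit_vals).size < 2
        ):
            # two-valued {0, c} genes split zeros-vs-positive; genes that
            # are constant across all samples stay silent
            if fit_vals.size >= 4 and pos.sum() < row.size:
                bits[k, pos] = 1
            continue
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            random_state=int(child.generate_state(1)[0] % (2**31)),
            n_init=3,
        )
        gm.fit(fit_vals[:, None])
        active = int(np.argmax(gm.means_.ravel()))
        posterior = gm.predict_proba(fit_vals[:, None])[:, active]
        bits[k, pos] = posterior > 0.5
    return pd.DataFrame(bits, index=values.index, columns=values.columns)


@dataclass(frozen=True)
class BinarizedSeries:
    """Binary states plus network observables for a sample series.

    All observables are computed on the sub-network induced by the genes
    common to the matrix and the model roster; ``observables`` has one row
    per sample, ``group_stats`` summarises per-time-point means/SDs, and
    ``adjacent_tests`` reports Welch t-test p-values between consecutive
    time points for the driving force and pseudo-energy.
    """

    binary: pd.DataFrame  # common genes x samples
    observables: pd.DataFrame
    subnetwork: GeneRegulatoryNetwork = field(repr=False)
    coordinates: pd.DataFrame | None = None
    group_stats: pd.DataFrame | None = None
    adjacent_tests: pd.DataFrame | None = None


def trajectory_observables(
    binary: pd.DataFrame,
    grn: GeneRegulatoryNetwork,
    markers: MarkerSet,
    model: EmbeddingModel | None = None,
    annotations: pd.DataFrame | None = None,
    frustration_genes: Sequence[str] | None = None,
) -> BinarizedSeries:
    """Evaluate network observables for every binarized sample.

    ``model`` should be an embedding fitted on simulated states of the same
    common-gene sub-network (the coordinates are then comparable with the
    simulated landscape).  ``frustration_genes`` restricts the mean local
    frustration to a panel (e.g. the high-susceptibility genes); default is
    the full common roster.  With a ``time`` annotation column, per-time
    group statistics and adjacent-time Welch t-tests are included.
    """
    common = [g in binary.index for g in grn.genes]
    common_genes = [g for g, ok in zip(grn.genes, common) if ok]
    if not common_genes:
        raise ValueError("no genes shared between matrix and roster")
    sub = grn.subnetwork(common_genes)
    x = (
        binary.loc[list(sub.genes)]
        .to_numpy(dtype=np.uint8)
        .T  # samples x genes
    )
    samples = list(binary.columns)
    if frustration_genes is None:
        fr_idx = np.arange(sub.n_genes)
    else:
        fr_idx = np.array(
            [sub.gene_index(g) for g in frustration_genes if g in sub.index],
            dtype=np.intp,
        )
        if fr_idx.size == 0:
            raise ValueError("no frustration_genes present in sub-network")
    local = local_pseudo_energy_vector(sub, x)
    obs = pd.DataFrame(
        {
            "phi_ps": phenotypic_score(sub, x, markers, "PS"),
            "phi_em": phenotypic_score(sub, x, markers, "EM"),
            "energy": pseudo_energy(sub, x),
            "mean_local_frustration": local[:, fr_idx].mean(axis=1),
            "driving_force": driving_force(sub, x),
        },
        index=pd.Index(samples, name="sample"),
    )
    coords = None
    if model is not None:
        c = project(model, x)
        coords = pd.DataFrame(
            c,
            index=obs.index,
            columns=[f"PC{k}" for k in model.components],
        )
    group_stats = adjacent = None
    if annotations is not None and "time" in annotations.columns:
        obs = obs.join(annotations.loc[samples, ["time"]])
        group_stats = obs.groupby("time").agg(["mean", "std", "count"])
        times = sorted(obs["time"].unique())
        rows = []
        for t0, t1 in zip(times[:-1], times[1:]):
            a = obs[obs["time"] == t0]
            b = obs[obs["time"] == t1]
            for col in ("driving_force", "energy"):
                if len(a) < 2 or len(b) < 2:
                    p = np.nan
                else:
                    p = float(
                        stats.ttest_ind(a[col], b[col], equal_var=False).pvalue
                    )
                rows.append(
                    {"from": t0, "to": t1, "observable": col, "p_value": p}
                )
        adjacent = pd.DataFrame(rows)
    return BinarizedSeries(
        binary=binary.loc[list(sub.genes)],
        observables=obs,
        subnetwork=sub,
        coordinates=coords,
        group_stats=group_stats,
        adjacent_tests=adjacent,
    )
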