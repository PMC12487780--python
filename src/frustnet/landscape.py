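"""Ensemble-level geometry of the pseudo-energy landscape.

Steady states sampled from random initial conditions are embedded by PCA on
the raw 0/1 state matrix (with multiplicity).  By convention the second and
third principal components span the "essential space" in which the two
phenotype axes separate; the PS-correlated component serves as the reaction
coordinate for reprogramming, oriented so that somatic-mesenchymal (SM)
states sit at higher coordinate values than pluripotent-epithelial (PE)
states — reprogramming progresses from right to left.

Observables (phenotype scores, pseudo-energy, local frustration, driving
force) are summarised along this coordinate as binned mean profiles; the
non-monotonic bump between the SM and PE basins is the transition barrier,
and comparing a perturbed profile against the unperturbed reference yields
the barrier statistics (initial-end elevation, barrier-height reduction,
barrier shift).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "EmbeddingModel",
    "Profile",
    "BarrierStats",
    "PowerLawFit",
    "CapacityDistribution",
    "fit_embedding",
    "project",
    "knn_smooth",
    "phenotype_extremes",
    "profile_along_axis",
    "joint_histogram",
    "barrier_stats",
    "fit_power_law",
    "capacity_distribution",
]

DEFAULT_COMPONENTS = (2, 3)  # 1-based PCA component indices
DEFAULT_QUANTILE = 0.20
DEFAULT_BINS = 30
DEFAULT_MIN_COUNT = 10
DEFAULT_KNN = 5


@dataclass(frozen=True)
class EmbeddingModel:
    """A fitted, sign-oriented PCA projection onto selected components.

    ``loadings`` holds one orthonormal row per selected component, already
    sign-flipped so that the first selected axis anti-correlates with the PS
    score (SM right, PE left) and the second with the EM score when scores
    were supplied at fit time.
    """

    mean: np.ndarray
    loadings: np.ndarray
    components: tuple[int, ...]
    explained_variance_ratio: np.ndarray = field(repr=False)

    @property
    def n_features(self) -> int:
        return int(self.mean.size)


def fit_embedding(
    states: np.ndarray,
    scores_ps: np.ndarray | None = None,
    scores_em: np.ndarray | None = None,
    components: Sequence[int] = DEFAULT_COMPONENTS,
) -> EmbeddingModel:
    """PCA on a mean-centred 0/1 state matrix, keeping selected components.

    ``components`` are 1-based indices in decreasing-variance order (default
    2 and 3).  The matrix is used as given, so repeated rows weight the fit
    by multiplicity.  Axis signs are oriented with ``scores_ps`` (first
    selected axis) and ``scores_em`` (second), when provided, so that the
    score decreases along the axis.  Raises on input whose variance cannot
    support the requested components.
    """
    x = np.asarray(states, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 states")
    if (x == x[0]).all():
        raise ValueError("states have zero variance (all rows identical)")
    components = tuple(int(c) for c in components)
    if min(components) < 1:
        raise ValueError("components are 1-based indices")
    n_comp = max(components)
    if n_comp > min(x.shape):
        raise ValueError(
            f"cannot extract component {n_comp} from a {x.shape} matrix"
        )
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(x)
    if np.any(pca.explained_variance_[np.array(components) - 1] <= 1e-12):
        raise ValueError(
            "input matrix is rank-deficient below the requested components"
        )
    loadings = pca.components_[np.array(components) - 1].copy()
    coords = (x - pca.mean_) @ loadings.T
    for axis, scores in enumerate((scores_ps, scores_em)):
        if scores is None or axis >= len(components):
            continue
        scores = np.asarray(scores, dtype=np.float64)
        if scores.std() == 0 or coords[:, axis].std() == 0:
            continue
        rho = np.corrcoef(coords[:, axis], scores)[0, 1]
        if rho > 0:
            loadings[axis] = -loadings[axis]
    return EmbeddingModel(
        mean=pca.mean_,
        loadings=loadings,
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def project(model: EmbeddingModel, states: np.ndarray) -> np.ndarray:
    """Project states onto the model's selected components.

    Returns an ``(n, k)`` array (or ``(k,)`` for a single state); the
    training mean maps to the origin.
    """
    x = np.asarray(states, dtype=np.float64)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"state length {x.shape[1]} != model features {model.n_features}"
        )
    coords = (x - model.mean) @ model.loadings.T
    return coords[0] if single else coords


def knn_smooth(
    coords: np.ndarray, values: np.ndarray, k: int = DEFAULT_KNN
) -> np.ndarray:
    """Replace each value by the mean over its k nearest neighbours
    (Euclidean in embedding space, the point itself included)."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 1:
        coords = coords[:, None]
    values = np.asarray(values, dtype=np.float64)
    n = coords.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, idx = nn.kneighbors(coords)
    return values[idx].mean(axis=1)


def phenotype_extremes(
    scores_ps: np.ndarray,
    scores_em: np.ndarray,
    q: float = DEFAULT_QUANTILE,
) -> np.ndarray:
    """Classify states by joint phenotype extremity.

    A state is labelled only if *both* scores rank in the top or bottom
    ``q`` fraction: SM (bottom PS, bottom EM — somatic-mesenchymal, the
    reprogramming source), PE (top/top, the target), SE and PM for the mixed
    corners, "none" otherwise.  Average ranks handle ties, so all-equal
    scores produce no extremes.
    """
    if not 0 < q < 0.5:
        raise ValueError("quantile must be in (0, 0.5)")
    ps = np.asarray(scores_ps, dtype=np.float64)
    em = np.asarray(scores_em, dtype=np.float64)
    if ps.shape != em.shape:
        raise ValueError("score vectors must align")
    n = ps.size
    rp = stats.rankdata(ps, method="average")
    re = stats.rankdata(em, method="average")
    lo, hi = q * n, n + 1 - q * n
    labels = np.full(n, "none", dtype=object)
    labels[(rp <= lo) & (re <= lo)] = "SM"
    labels[(rp >= hi) & (re >= hi)] = "PE"
    labels[(rp <= lo) & (re >= hi)] = "SE"
    labels[(rp >= hi) & (re <= lo)] = "PM"
    return labels


@dataclass(frozen=True)
class Profile:
    """Binned mean of an observable along a 1-D coordinate."""

    edges: np.ndarray
    mean: np.ndarray  # NaN where count < min_count
    count: np.ndarray
    min_count: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def profile_along_axis(
    coords: np.ndarray,
    values: np.ndarray,
    n_bins: int = DEFAULT_BINS,
    min_count: int = DEFAULT_MIN_COUNT,
    edges: np.ndarray | None = None,
) -> Profile:
    """Mean observable in equal-width bins along a coordinate.

    Bins span the coordinate range unless explicit ``edges`` are given
    (needed to compare profiles on a common axis); bins with fewer than
    ``min_count`` points report NaN.
    """
    coords = np.asarray(coords, dtype=np.float64).ravel()
    values = np.asarray(values, dtype=np.float64).ravel()
    if coords.size != values.size:
        raise ValueError("coords and values must align")
    if edges is None:
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        edges = np.linspace(coords.min(), coords.max(), n_bins + 1)
    edges = np.asarray(edges, dtype=np.float64)
    n_bins = edges.size - 1
    idx = np.clip(np.digitize(coords, edges) - 1, 0, n_bins - 1)
    in_range = (coords >= edges[0]) & (coords <= edges[-1])
    count = np.bincount(idx[in_range], minlength=n_bins)
    total = np.bincount(idx[in_range], weights=values[in_range], minlength=n_bins)
    mean = np.full(n_bins, np.nan)
    ok = count >= max(1, min_count)
    mean[ok] = total[ok] / count[ok]
    return Profile(edges=edges, mean=mean, count=count, min_count=min_count)


def joint_histogram(
    values_x: np.ndarray,
    values_y: np.ndarray,
    bins: int | Sequence[int] = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D occupancy histogram (e.g. driving force vs local frustration of
    transient states); counts sum to the sample count."""
    x = np.asarray(values_x, dtype=np.float64).ravel()
    y = np.asarray(values_y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("inputs must align")
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    return counts, xe, ye


@dataclass(frozen=True)
class BarrierStats:
    """Changes between a reference and a perturbed landscape profile.

    ``delta_e1``: elevation of the perturbed profile at the initial-state
    end; ``delta_e2``: reduction of the barrier height (max minus initial
    end); ``delta_coord``: absolute shift of the barrier location, in
    coordinate units, with ``toward_initial`` flagging whether the
    perturbed barrier moved toward the initial-state end.
    """

    delta_e1: float
    delta_e2: float
    delta_coord: float
    toward_initial: bool = False


def _end_value(profile: Profile, initial_end: str) -> tuple[float, float]:
    """(value, barrier height) of a profile; the initial end is the first
    non-missing bin from the chosen side."""
    valid = np.flatnonzero(~np.isnan(profile.mean))
    if valid.size == 0:
        raise ValueError("profile has no populated bins")
    end = valid[-1] if initial_end == "upper" else valid[0]
    e0 = float(profile.mean[end])
    peak = float(np.nanmax(profile.mean))
    return e0, peak - e0


def barrier_stats(
    reference: Profile,
    perturbed: Profile,
    initial_end: str = "upper",
) -> BarrierStats:
    """Compare two profiles on a common coordinate.

    ``initial_end`` names the side of the axis holding the initial (SM)
    states — "upper" under the standard right-to-left reprogramming
    orientation.
    """
    if initial_end not in ("upper", "lower"):
        raise ValueError("initial_end must be 'upper' or 'lower'")
    if reference.edges.shape != perturbed.edges.shape or not np.allclose(
        reference.edges, perturbed.edges
    ):
        raise ValueError("profiles must share bin edges")
    ref0, ref_height = _end_value(reference, initial_end)
    per0, per_height = _end_value(perturbed, initial_end)
    ref_arg = int(np.nanargmax(reference.mean))
    per_arg = int(np.nanargmax(perturbed.mean))
    shift = float(perturbed.centers[per_arg] - reference.centers[ref_arg])
    toward = shift > 0 if initial_end == "upper" else shift < 0
    return BarrierStats(
        delta_e1=per0 - ref0,
        delta_e2=ref_height - per_height,
        delta_coord=abs(shift),
        toward_initial=bool(toward and shift != 0),
    )


# ---------------------------------------------------------------------------
# Capacity (basin size) distribution and discrete power-law tail fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerLawFit:
    """Discrete power-law tail fit p(x) ∝ x^(-alpha) for x >= x_min.

    Fitted by maximum likelihood (Hurwitz-zeta normalisation); when x_min is
    not fixed it is chosen by minimising the Kolmogorov–Smirnov distance
    between the model and the empirical tail.  ``alpha`` is None when the
    data cannot support a fit (fewer than two distinct values).
    """

    alpha: float | None
    x_min: int | None
    n_tail: int
    ks: float | None


def _discrete_powerlaw_mle(x: np.ndarray, x_min: int) -> tuple[float, float]:
    tail = x[x >= x_min].astype(np.float64)
    slog = np.log(tail).sum()
    n = tail.size

    def nll(alpha: float) -> float:
        z = special.zeta(alpha, x_min)
        return alpha * slog + n * np.log(z)

    res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    return float(res.x), float(res.fun)


def _ks_distance(x: np.ndarray, alpha: float, x_min: int) -> float:
    tail = np.sort(x[x >= x_min])
    values = np.unique(tail)
    # model survival P(X >= v) = zeta(alpha, v) / zeta(alpha, x_min)
    z0 = special.zeta(alpha, x_min)
    model_cdf = 1.0 - special.zeta(alpha, values + 1) / z0
    emp_cdf = np.searchsorted(tail, values, side="right") / tail.size
    return float(np.abs(model_cdf - emp_cdf).max())


def fit_power_law(
    samples: np.ndarray, x_min: int | None = None, max_scan: int = 50
) -> PowerLawFit:
    """Fit a discrete power-law tail to positive-integer samples.

    When ``x_min`` is None, candidate cutoffs are the smallest ``max_scan``
    distinct sample values (tails with < 10 points are skipped) and the one
    with minimal KS distance wins.
    """
    x = np.asarray(samples)
    x = x[x >= 1]
    if x.size == 0 or np.unique(x).size < 2:
        return PowerLawFit(alpha=None, x_min=None, n_tail=int(x.size), ks=None)
    if x_min is not None:
        alpha, _ = _discrete_powerlaw_mle(x, x_min)
        return PowerLawFit(
            alpha=alpha,
            x_min=int(x_min),
            n_tail=int((x >= x_min).sum()),
            ks=_ks_distance(x, alpha, x_min),
        )
    best: PowerLawFit | None = None
    for cand in np.unique(x)[:max_scan]:
        cand = int(cand)
        if (x >= cand).sum() < 10 or np.unique(x[x >= cand]).size < 2:
            continue
        alpha, _ = _discrete_powerlaw_mle(x, cand)
        ks = _ks_distance(x, alpha, cand)
        if best is None or ks < best.ks:
            best = PowerLawFit(
                alpha=alpha, x_min=cand, n_tail=int((x >= cand).sum()), ks=ks
            )
    if best is None:
        return PowerLawFit(alpha=None, x_min=None, n_tail=int(x.size), ks=None)
    return best


@dataclass(frozen=True)
class CapacityDistribution:
    """Histogram and tail behaviour of basin capacities C(x).

    A scale-free capacity distribution means most fixed points attract only
    a handful of initial states while a few attract very many; those
    large-basin states tend to be the low-pseudo-energy, well-ordered ones.
    """

    values: np.ndarray  # distinct capacity values
    frequency: np.ndarray  # number of steady states with each capacity
    fit: PowerLawFit
    energy_by_class: Mapping[str, np.ndarray] | None = None


#: Capacity classes for the per-class pseudo-energy summaries (log decades).
_CAPACITY_CLASSES = ((1, 1, "C=1"), (2, 9, "2<=C<10"), (10, 99, "10<=C<100"),
                     (100, np.inf, "C>=100"))


def capacity_distribution(
    ensemble,
    grn=None,
    x_min: int | None = None,
) -> CapacityDistribution:
    """Summarise the basin-capacity distribution of a steady-state ensemble.

    With ``grn`` given, also groups the steady states' pseudo-energies by
    capacity class.  An all-equal capacity vector yields an undefined tail
    fit rather than an error.
    """
    caps = np.asarray(ensemble.capacity)
    if caps.size == 0:
        raise ValueError("ensemble is empty")
    values, frequency = np.unique(caps, return_counts=True)
    fit = fit_power_law(caps, x_min=x_min)
    energy_by_class = None
    if grn is not None:
        from .energetics import pseudo_energy

        energies = np.asarray(pseudo_energy(grn, ensemble.states))
        energy_by_class = {
            label: energies[(caps >= lo) & (caps <= hi)]
            for lo, hi, label in _CAPACITY_CLASSES
        }
    return CapacityDistribution(
        values=values, frequency=frequency, fit=fit,
        energy_by_class=energy_by_class,
    )
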