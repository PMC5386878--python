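"""Do composition metrics separate species or gene classes?

Provides the histogram-intersection overlap between two metric distributions
(the percentage-overlap statistic of the species comparison table), a helper
assembling the full overlap table with its median row, and the two
unsupervised clusterings of the per-gene feature matrix (mean-shift mode
seeking and DBSCAN density clustering) used to ask whether any group of genes
stands apart compositionally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, MeanShift
from sklearn.neighbors import NearestNeighbors

from .composition import CompositionProfile, profiles_to_frame
from .errors import InvalidArgumentError

__all__ = [
    "OverlapResult",
    "ClusteringResult",
    "distribution_overlap",
    "overlap_table",
    "feature_matrix",
    "estimate_bandwidth_knn",
    "cluster_mode_seeking",
    "cluster_density",
]

MIN_SAMPLE = 30

METRIC_COLUMNS = ("gc", "gc3", "cai", "enc")


@dataclass(frozen=True)
class OverlapResult:
    """Percentage overlap of two samples of one metric on a shared bin grid."""

    metric: str
    pair: tuple[str, str]
    overlap_percent: float
    n_bins: int
    bin_width: float


def _freedman_diaconis_bins(pooled: np.ndarray) -> int:
    """Bin count from the Freedman–Diaconis width on the pooled sample."""
    q75, q25 = np.percentile(pooled, [75, 25])
    iqr = q75 - q25
    span = pooled.max() - pooled.min()
    if span == 0:
        return 1
    if iqr == 0:
        return max(int(math.ceil(math.sqrt(pooled.size))), 1)
    width = 2.0 * iqr / pooled.size ** (1.0 / 3.0)
    return max(int(math.ceil(span / width)), 1)


def distribution_overlap(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    n_bins: int | None = None,
    metric: str = "",
    pair: tuple[str, str] = ("a", "b"),
) -> OverlapResult:
    """Histogram-intersection overlap, in percent.

    Both samples are binned on one grid spanning the pooled range (bin count
    by the Freedman–Diaconis rule on the pooled sample unless given); the
    overlap is 100 * sum_b min(f_a(b), f_b(b)) over within-sample proportions
    f. Identical samples give exactly 100; samples with disjoint supports give
    0. The statistic is symmetric in the two samples.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < MIN_SAMPLE or b.size < MIN_SAMPLE:
        raise InvalidArgumentError(
            f"need at least {MIN_SAMPLE} values per sample, got {a.size} and {b.size}"
        )
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if n_bins is None:
        n_bins = _freedman_diaconis_bins(pooled)
    if hi == lo:
        # all values identical across both samples: total overlap
        return OverlapResult(metric, pair, 100.0, 1, 0.0)
    edges = np.linspace(lo, hi, n_bins + 1)
    fa, _ = np.histogram(a, bins=edges)
    fb, _ = np.histogram(b, bins=edges)
    # min(fa/na, fb/nb) summed, done in integers so identical samples give 100.0
    num = int(np.minimum(fa.astype(np.int64) * b.size, fb.astype(np.int64) * a.size).sum())
    overlap = num / (a.size * b.size)
    return OverlapResult(metric, pair, 100.0 * overlap, n_bins, edges[1] - edges[0])


def overlap_table(
    reference_profiles: Sequence[CompositionProfile],
    other_profile_sets: Mapping[str, Sequence[CompositionProfile]],
    metrics: Sequence[str] = METRIC_COLUMNS,
    exclude_from_median: Sequence[str] = (),
    n_bins: int | None = None,
) -> pd.DataFrame:
    """Overlap of each comparison set with the reference, one row per set.

    Mirrors the layout of the species-comparison table: rows are comparison
    sets plus a final ``Median`` row holding the per-column median. Sets named
    in ``exclude_from_median`` (e.g. a random-sequence control) contribute a
    row but are excluded from the median.
    """
    if not other_profile_sets:
        raise InvalidArgumentError("need at least one comparison set")
    ref = profiles_to_frame(reference_profiles)
    for m in metrics:
        if m not in ref.columns:
            raise InvalidArgumentError(f"metric {m!r} not in profiles")
    rows = {}
    for name, profiles in other_profile_sets.items():
        other = profiles_to_frame(profiles)
        rows[name] = [
            distribution_overlap(
                ref[m].to_numpy(), other[m].to_numpy(), n_bins=n_bins,
                metric=m, pair=("reference", name),
            ).overlap_percent
            for m in metrics
        ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(metrics))
    median_base = table.drop(index=[r for r in exclude_from_median if r in table.index])
    table.loc["Median"] = median_base.median(axis=0)
    return table


@dataclass
class ClusteringResult:
    """Cluster labels for the gene feature matrix (-1 = noise for DBSCAN)."""

    labels: np.ndarray = field(repr=False)
    n_clusters: int
    parameters: dict


def feature_matrix(
    profiles: Sequence[CompositionProfile],
    top_tetra: int | None = None,
) -> np.ndarray:
    """Stack (gc, gc3, cai, enc, tetranucleotides) into an (n, 4+256) array.

    ``top_tetra`` optionally truncates the tetranucleotide block to the k
    highest-variance 4-mers (a speed knob; off by default).
    """
    frame = profiles_to_frame(profiles)
    metrics = frame[list(METRIC_COLUMNS)].to_numpy(dtype=float)
    tetra = frame.iloc[:, 6:].to_numpy(dtype=float)
    if top_tetra is not None:
        order = np.argsort(-tetra.var(axis=0), kind="stable")[:top_tetra]
        tetra = tetra[:, np.sort(order)]
    return np.hstack([metrics, tetra])


def _zscore(x: np.ndarray) -> np.ndarray:
    """Z-score columns; constant columns are dropped (they carry no signal)."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return np.zeros((x.shape[0], 1))
    return (x[:, keep] - mu[keep]) / sd[keep]


def estimate_bandwidth_knn(x: np.ndarray, quantile: float = 0.3) -> float:
    """Mean-shift bandwidth: mean distance to each point's ceil(q*n)-th nearest neighbour."""
    n = x.shape[0]
    k = min(max(int(math.ceil(quantile * n)), 1), n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, _ = nn.kneighbors(x)
    return float(dist[:, -1].mean())


def cluster_mode_seeking(
    features: np.ndarray | Sequence[CompositionProfile],
    quantile: float = 0.3,
    min_mode_fraction: float = 0.05,
) -> ClusteringResult:
    """Mean-shift clustering with a k-nearest-neighbour bandwidth estimate.

    Features are z-scored per column first. Kernel mode seeking routinely
    leaves satellite modes holding a handful of outlying genes; a mode with
    fewer than ``min_mode_fraction`` of the points is absorbed into the
    nearest substantial mode (the question asked of this clustering is
    whether a *substantial* group of genes stands apart compositionally).
    If the estimated bandwidth is zero (all points identical) a single
    cluster is returned with a warning.
    """
    x = features if isinstance(features, np.ndarray) else feature_matrix(features)
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 10:
        raise InvalidArgumentError("need at least 10 rows for clustering")
    if not np.isfinite(x).all():
        raise InvalidArgumentError("feature matrix contains non-finite values")
    z = _zscore(x)
    bandwidth = estimate_bandwidth_knn(z, quantile=quantile)
    if bandwidth == 0:
        warnings.warn("zero bandwidth (all points identical); returning one cluster")
        return ClusteringResult(
            labels=np.zeros(x.shape[0], dtype=int), n_clusters=1,
            parameters={"bandwidth": 0.0, "quantile": quantile},
        )
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=False, cluster_all=True)
    labels = ms.fit_predict(z)
    centers = ms.cluster_centers_
    sizes = np.bincount(labels, minlength=centers.shape[0])
    min_size = max(2, int(math.ceil(min_mode_fraction * x.shape[0])))
    major = np.where(sizes >= min_size)[0]
    if major.size == 0:
        major = np.array([int(sizes.argmax())])
    if major.size < centers.shape[0]:
        # reassign satellite points to the nearest substantial mode
        for k in range(centers.shape[0]):
            if k in major:
                continue
            nearest = major[
                np.argmin(np.linalg.norm(centers[major] - centers[k], axis=1))
            ]
            labels[labels == k] = nearest
    remap = {int(old): new for new, old in enumerate(
        sorted(set(labels), key=lambda k: (-sizes[k], k))
    )}
    labels = np.array([remap[int(k)] for k in labels])
    return ClusteringResult(
        labels=labels,
        n_clusters=int(len(remap)),
        parameters={"bandwidth": bandwidth, "quantile": quantile,
                    "min_mode_fraction": min_mode_fraction},
    )


def suggest_dbscan_eps(
    features: np.ndarray, min_samples: int = 5, quantile: float = 0.90,
    inflation: float = 1.5,
) -> float:
    """DBSCAN eps from the k-distance curve of the z-scored features.

    The ``quantile`` of the distances to each point's ``min_samples``-th
    nearest neighbour, inflated by 50%: dense single-population data become
    one cluster, while gaps much larger than the within-population
    neighbourhood scale still separate.
    """
    z = _zscore(np.asarray(features, dtype=float))
    n = z.shape[0]
    k = min(min_samples, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    dist, _ = nn.kneighbors(z)
    return float(np.percentile(dist[:, -1], 100 * quantile) * inflation)


def cluster_density(
    features: np.ndarray | Sequence[CompositionProfile],
    eps: float | None = None,
    min_samples: int = 5,
) -> ClusteringResult:
    """DBSCAN on the z-scored feature matrix; noise points get label -1.

    ``eps=None`` picks the k-distance heuristic of
    :func:`suggest_dbscan_eps`.
    """
    if eps is None:
        eps = suggest_dbscan_eps(
            features if isinstance(features, np.ndarray) else feature_matrix(features),
            min_samples=min_samples,
        )
    if eps <= 0:
        raise InvalidArgumentError("eps must be > 0")
    if min_samples < 2:
        raise InvalidArgumentError("min_samples must be >= 2")
    x = features if isinstance(features, np.ndarray) else feature_matrix(features)
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 10:
        raise InvalidArgumentError("need at least 10 rows for clustering")
    if not np.isfinite(x).all():
        raise InvalidArgumentError("feature matrix contains non-finite values")
    z = _zscore(x)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(z)
    n_clusters = int(len(set(labels) - {-1}))
    return ClusteringResult(
        labels=labels, n_clusters=n_clusters,
        parameters={"eps": eps, "min_samples": min_samples},
    )
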