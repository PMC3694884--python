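"""Agglomerative clustering of per-locus (Theta, R) intensity points.

The calling procedure this package rescues mis-called loci with is
deliberately simple: hierarchically agglomerate each locus's points by
Euclidean distance in the (Theta, R) plane, stop merging once the closest
pair of clusters is farther apart than a distance threshold, and drop
clusters smaller than a minimum size (default 3 individuals).  The
threshold sweep {0.1, 0.15, 0.2, 0.3, 0.4, 0.5} brackets the scale of
separation between genotype clouds on the [0, 1]-normalized axes.

Determinism: samples are canonicalized to sample-id order on entry, and
ties on merge distance are broken toward the pair whose smallest member id
sorts lexicographically first, so the partition is invariant to the input
order of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LocusIntensities

__all__ = [
    "PAPER_THRESHOLDS",
    "ClusterConfig",
    "Cluster",
    "ClusterSet",
    "UnusableLocusError",
    "cluster_locus",
    "sweep_thresholds",
    "write_cluster_table",
]

#: the canonical similarity-threshold sweep
PAPER_THRESHOLDS: tuple[float, ...] = (0.1, 0.15, 0.2, 0.3, 0.4, 0.5)

_LINKAGES = ("complete", "average", "single")


class UnusableLocusError(ValueError):
    """Raised when a locus has too few non-missing points to cluster."""


@dataclass(frozen=True)
class ClusterConfig:
    """Distance cut, small-cluster filter and linkage for one clustering run.

    ``r_weight`` scales the R axis in the distance (1.0 = unweighted, the
    default and the documented convention).
    """

    threshold: float = 0.15
    min_cluster_size: int = 3
    linkage: str = "average"
    r_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"linkage must be one of {_LINKAGES}")
        if self.r_weight <= 0:
            raise ValueError("r_weight must be positive")


@dataclass(frozen=True)
class Cluster:
    members: tuple[str, ...]
    mean_theta: float
    mean_r: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """Clusters found at one locus at one threshold, plus the samples the
    small-cluster filter removed.  Clusters are sorted by mean Theta."""

    locus_id: str
    clusters: list[Cluster]
    removed: list[str]
    config: ClusterConfig = field(default_factory=ClusterConfig)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]


def _merge_order(ids: list[str], coords: np.ndarray, threshold: float,
                 linkage: str) -> list[list[int]]:
    """Greedy agglomeration with Lance-Williams updates; returns member
    index lists.  ``ids`` must be sorted; indices refer into it."""
    n = len(ids)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, np.inf)

    members: list[list[int] | None] = [[i] for i in range(n)]
    sizes = np.ones(n)
    # smallest member id per cluster; ids sorted, so min index == min id
    active = np.ones(n, dtype=bool)

    while active.sum() > 1:
        m = d.min()
        if not np.isfinite(m) or m > threshold:
            break
        pairs = np.argwhere(d == m)
        # tie-break: lexicographically least smallest-member id, then the
        # partner's smallest-member id; members[i][0] is minimal since
        # merges keep lists sorted
        best = min(
            ((min(p), max(p)) for p in pairs),
            key=lambda ij: (members[ij[0]][0], members[ij[1]][0]),
        )
        i, j = best
        members[i] = sorted(members[i] + members[j])
        members[j] = None
        ni, nj = sizes[i], sizes[j]
        row_i, row_j = d[i].copy(), d[j].copy()
        if linkage == "complete":
            new = np.maximum(row_i, row_j)
        elif linkage == "single":
            new = np.minimum(row_i, row_j)
        else:  # average (UPGMA); exact Lance-Williams update
            new = (ni * row_i + nj * row_j) / (ni + nj)
        d[i, :] = new
        d[:, i] = new
        d[i, i] = np.inf
        d[j, :] = np.inf
        d[:, j] = np.inf
        sizes[i] = ni + nj
        active[j] = False
    return [m for m in members if m is not None]


def cluster_locus(
    points: LocusIntensities, config: ClusterConfig | None = None
) -> ClusterSet:
    """Cluster one locus's non-missing (Theta, R) points.

    Raises :class:`UnusableLocusError` when fewer than two points carry
    intensities.  Clusters smaller than ``min_cluster_size`` are removed
    after the cut and their members listed in :attr:`ClusterSet.removed`.
    """
    config = config or ClusterConfig()
    keep = ~points.missing
    ids = [s for s, k in zip(points.sample_ids, keep) if k]
    if len(ids) < 2:
        raise UnusableLocusError(
            f"locus {points.locus_id}: {len(ids)} non-missing point(s)"
        )
    order = np.argsort(np.array(points.sample_ids, dtype=object)[keep])
    theta = points.theta[keep][order]
    r = points.r[keep][order]
    ids = sorted(ids)
    coords = np.column_stack([theta, r * config.r_weight])

    groups = _merge_order(ids, coords, config.threshold, config.linkage)

    clusters: list[Cluster] = []
    removed: list[str] = []
    for g in groups:
        if len(g) < config.min_cluster_size:
            removed.extend(ids[i] for i in g)
            continue
        clusters.append(
            Cluster(
                members=tuple(ids[i] for i in g),
                mean_theta=float(np.mean(theta[g])),
                mean_r=float(np.mean(r[g])),
            )
        )
    clusters.sort(key=lambda c: (c.mean_theta, c.mean_r, c.members))
    return ClusterSet(
        locus_id=points.locus_id,
        clusters=clusters,
        removed=sorted(removed),
        config=config,
    )


def sweep_thresholds(
    points: LocusIntensities,
    thresholds: tuple[float, ...] = PAPER_THRESHOLDS,
    config: ClusterConfig | None = None,
) -> dict[float, ClusterSet]:
    """Run :func:`cluster_locus` at each threshold of the sweep."""
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    base = config or ClusterConfig()
    out = {}
    for t in thresholds:
        cfg = ClusterConfig(
            threshold=t,
            min_cluster_size=base.min_cluster_size,
            linkage=base.linkage,
            r_weight=base.r_weight,
        )
        out[t] = cluster_locus(points, cfg)
    return out


def write_cluster_table(cluster_sets, path) -> None:
    """Per-locus cluster TSV: snp_id, cluster_idx, n, mean_theta, mean_r,
    members (comma-joined sample ids)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("snp_id\tcluster_idx\tn\tmean_theta\tmean_r\tmembers\n")
        for cs in cluster_sets:
            for idx, c in enumerate(cs.clusters):
                fh.write(
                    f"{cs.locus_id}\t{idx}\t{c.size}\t{c.mean_theta:.6f}\t"
                    f"{c.mean_r:.6f}\t{','.join(c.members)}\n"
                )
            if cs.removed:
                fh.write(
                    f"{cs.locus_id}\t-1\t{len(cs.removed)}\tNA\tNA\t"
                    f"{','.join(cs.removed)}\n"
                )
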