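from __future__ import annotations

import numpy as np
import pytest

from paraprobe.cluster import Cluster, ClusterSet
from paraprobe.io import LocusIntensities


def make_locus(points, locus_id="LOC1", ids=None):
    """Build a LocusIntensities from a list of (theta, r) tuples."""
    points = list(points)
    ids = ids or [f"S{i + 1:03d}" for i in range(len(points))]
    theta = np.array([p[0] for p in points], dtype=float)
    r = np.array([p[1] for p in points], dtype=float)
    return LocusIntensities(locus_id=locus_id, sample_ids=ids, theta=theta, r=r)


def make_cluster_set(specs, locus_id="LOC1", removed=()):
    """Build a ClusterSet from (mean_theta, mean_r, size) specs."""
    clusters = []
    start = 0
    for theta, r, size in specs:
        members = tuple(f"S{start + i + 1:03d}" for i in range(size))
        start += size
        clusters.append(Cluster(members=members, mean_theta=theta, mean_r=r))
    clusters.sort(key=lambda c: (c.mean_theta, c.mean_r))
    return ClusterSet(
        locus_id=locus_id, clusters=clusters, removed=list(removed)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230627)
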