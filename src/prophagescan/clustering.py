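"""Density-based clustering of phage-homologous gene coordinates.

A prophage is, operationally, a dense run of phage-like genes along the
chromosome.  Each gene contributes one 1-D point — its genomic midpoint —
and a density-based algorithm groups points into candidate regions while
leaving isolated spurious hits as noise.

HDBSCAN* is the production algorithm (mutual-reachability distances with a
core distance over ``min_pts`` neighbours, minimum spanning tree, condensed
tree, excess-of-mass cluster selection); DBSCAN and OPTICS are provided as
alternatives and as cross-checks, together with a textbook O(n^2) DBSCAN
oracle used by the test suite.

The single density parameter exposed to users is MinPts — the minimum
number of phage-homologous genes a region must contain.  It maps to both
``min_cluster_size`` and ``min_samples`` of HDBSCAN* and to ``min_samples``
of DBSCAN/OPTICS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, List, Sequence, Tuple

import numpy as np
from sklearn.cluster import DBSCAN, HDBSCAN, OPTICS

if TYPE_CHECKING:  # pragma: no cover
    from .genome_io import GeneFeature, GenomeRecord
    from .regions import ProphageRegion

logger = logging.getLogger(__name__)

DEFAULT_MIN_PTS = 4
DEFAULT_EPS = 10000.0


@dataclass
class ClusterParams:
    method: str = "hdbscan"  # hdbscan | dbscan | optics
    min_pts: int = DEFAULT_MIN_PTS
    eps: float = DEFAULT_EPS  # dbscan/optics only

    def __post_init__(self) -> None:
        if self.method not in ("hdbscan", "dbscan", "optics"):
            raise ValueError(f"unknown clustering method {self.method!r}")
        if self.min_pts < 2:
            raise ValueError(f"min_pts must be >= 2, got {self.min_pts}")
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")


@dataclass
class ClusterLabeling:
    """Point-to-cluster assignment; label -1 marks noise.

    Labels are canonical: contiguous integers 0..k-1 assigned in order of
    each cluster's leftmost member, so identical partitions always carry
    identical labels.
    """

    points: List[Tuple[str, int]] = field(default_factory=list)
    labels: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels must be aligned")

    @property
    def n_clusters(self) -> int:
        return len({l for l in self.labels if l != -1})


def canonicalize_labels(
    coords: Sequence[float], labels: Sequence[int]
) -> List[int]:
    """Relabel clusters 0..k-1 by leftmost member coordinate; noise stays -1."""
    leftmost = {}
    for x, l in zip(coords, labels):
        if l == -1:
            continue
        if l not in leftmost or x < leftmost[l]:
            leftmost[l] = x
    order = sorted(leftmost, key=lambda l: leftmost[l])
    remap = {old: new for new, old in enumerate(order)}
    return [remap.get(l, -1) for l in labels]


def _run_method(X: np.ndarray, params: ClusterParams) -> np.ndarray:
    if params.method == "hdbscan":
        labels = HDBSCAN(
            min_cluster_size=params.min_pts,
            min_samples=params.min_pts,
            allow_single_cluster=False,
            copy=True,
        ).fit_predict(X)
        if (labels == -1).all():
            # Excess-of-mass selection cannot pick the hierarchy root, so a
            # genome with a single dense group would come back all-noise;
            # retry permitting a single cluster.
            labels = HDBSCAN(
                min_cluster_size=params.min_pts,
                min_samples=params.min_pts,
                allow_single_cluster=True,
                copy=True,
            ).fit_predict(X)
        return labels
    if params.method == "dbscan":
        return DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(X)
    # OPTICS extracting DBSCAN-like clusters at cut eps
    return OPTICS(
        min_samples=params.min_pts,
        cluster_method="dbscan",
        eps=params.eps,
        max_eps=params.eps,
    ).fit_predict(X)


def cluster_phage_genes(
    genes: Sequence["GeneFeature"], params: ClusterParams | None = None
) -> ClusterLabeling:
    """Cluster phage-homologous genes by their genomic midpoints.

    Deterministic for fixed input and parameters.  Fewer than ``min_pts``
    input genes cannot form any cluster: all points are labeled noise and a
    warning is logged.
    """
    if params is None:
        params = ClusterParams()
    points = [(g.feature_id, g.midpoint) for g in genes]
    if len(points) < params.min_pts:
        if points:
            logger.warning(
                "%d phage-homologous genes < MinPts=%d; no clusters possible",
                len(points),
                params.min_pts,
            )
        return ClusterLabeling(points=points, labels=[-1] * len(points))
    # sort by coordinate for deterministic tie-breaking, then restore order
    order = sorted(range(len(points)), key=lambda i: (points[i][1], points[i][0]))
    X = np.array([[float(points[i][1])] for i in order])
    raw = _run_method(X, params)
    labels_sorted = canonicalize_labels(X[:, 0], raw)
    labels = [0] * len(points)
    for pos, i in enumerate(order):
        labels[i] = labels_sorted[pos]
    return ClusterLabeling(points=points, labels=labels)


def dbscan_1d_oracle(
    coords: Sequence[float], eps: float, min_pts: int
) -> List[int]:
    """Textbook O(n^2) DBSCAN by direct density-reachability expansion.

    Core point: >= min_pts neighbours within eps (the point itself
    included).  Clusters grow by breadth-first expansion from core points;
    a border point in reach of two clusters joins the one whose expansion
    reaches it first, with points visited in coordinate order (the same
    deterministic convention the production path uses).  Labels are
    canonicalized by leftmost member.  Serves as the independent oracle for
    the production DBSCAN path.
    """
    n = len(coords)
    coords = [float(c) for c in coords]
    order = sorted(range(n), key=lambda i: coords[i])
    neighbours = [
        [j for j in order if abs(coords[i] - coords[j]) <= eps]
        for i in range(n)
    ]
    is_core = [len(neighbours[i]) >= min_pts for i in range(n)]
    labels = [-1] * n
    cluster = 0
    for i in order:
        if labels[i] != -1 or not is_core[i]:
            continue
        # BFS over density-reachable points
        labels[i] = cluster
        queue = [i]
        while queue:
            p = queue.pop(0)
            if not is_core[p]:
                continue
            for q in neighbours[p]:
                if labels[q] == -1:
                    labels[q] = cluster
                    if is_core[q]:
                        queue.append(q)
        cluster += 1
    return canonicalize_labels(coords, labels)


def labeling_to_regions(
    labeling: ClusterLabeling,
    genes: Sequence["GeneFeature"],
    genome: "GenomeRecord",
) -> List["ProphageRegion"]:
    """Turn a cluster labeling into candidate regions.

    One region per non-noise cluster; the region spans the extent of its
    member genes (min start .. max end).  Regions are sorted by start and
    numbered region_1, region_2, ...
    """
    from .regions import ProphageRegion

    by_id = {g.feature_id: g for g in genes}
    members: dict = {}
    for (fid, _mid), label in zip(labeling.points, labeling.labels):
        if label == -1:
            continue
        members.setdefault(label, []).append(by_id[fid])
    raw_regions = []
    for label, gs in members.items():
        gs.sort(key=lambda g: (g.start, g.end, g.feature_id))
        raw_regions.append((min(g.start for g in gs), max(g.end for g in gs), gs))
    raw_regions.sort(key=lambda r: (r[0], r[1]))
    return [
        ProphageRegion(
            region_id=f"region_{i + 1}",
            start=start,
            end=end,
            genes=gs,
            genome_id=genome.id,
        )
        for i, (start, end, gs) in enumerate(raw_regions)
    ]
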