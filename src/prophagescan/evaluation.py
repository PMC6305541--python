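"""Benchmarking machinery: interval matching with Sn/PPV, and cluster
validity indices (Silhouette, Dunn, Davies-Bouldin, DBCV).

Region matching follows the usual prophage-benchmark bookkeeping:
sensitivity Sn = detected reference prophages / total reference prophages,
and positive predictive value PPV = detected / (detected + non-reference
predictions).  A reference is *detected* when some prediction overlaps it
(>= 1 bp under the default ``any_overlap`` rule, or >= a fraction of the
reference length under ``min_fraction``); many predictions matching one
reference count it once.

The validity indices operate on 1-D coordinates with noise-labeled points
(-1) excluded.  Silhouette and Davies-Bouldin delegate to scikit-learn;
Dunn and DBCV are implemented here from their definitions (no scikit-learn
equivalent exists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import silhouette_score as _sk_silhouette

from .errors import UndefinedMetricError

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]


# ---------------------------------------------------------------------------
# Sn / PPV interval matching
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    n_reference: int
    n_detected: int
    n_false_positive: int
    sensitivity: float
    ppv: float
    match_rule: str
    detected_reference: List[Interval] = field(default_factory=list)
    missed_reference: List[Interval] = field(default_factory=list)
    false_positive_predictions: List[Interval] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_reference": self.n_reference,
            "n_detected": self.n_detected,
            "n_false_positive": self.n_false_positive,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "match_rule": self.match_rule,
            "detected_reference": [list(i) for i in self.detected_reference],
            "missed_reference": [list(i) for i in self.missed_reference],
            "false_positive_predictions": [
                list(i) for i in self.false_positive_predictions
            ],
        }


def _overlap(a: Interval, b: Interval) -> int:
    """Overlap length in bp of two 1-based inclusive intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _validate(intervals: Sequence[Interval], what: str) -> List[Interval]:
    out = []
    for iv in intervals:
        start, end = int(iv[0]), int(iv[1])
        if end < start:
            raise ValueError(f"invalid {what} interval: end {end} < start {start}")
        out.append((start, end))
    return out


def match_regions(
    predicted: Sequence[Interval],
    reference: Sequence[Interval],
    rule: str = "any_overlap",
    min_fraction: float = 0.5,
) -> EvaluationResult:
    """Match predicted regions against reference prophages and compute
    Sn and PPV.

    ``rule`` is ``any_overlap`` (a single shared base pair counts) or
    ``min_fraction`` (the overlap must cover >= ``min_fraction`` of the
    reference length).  With an empty reference list Sn is NaN; with no
    predictions matching anything and none false positive, PPV is NaN.
    """
    predicted = _validate(predicted, "predicted")
    reference = _validate(reference, "reference")
    if rule not in ("any_overlap", "min_fraction"):
        raise ValueError(f"unknown match rule {rule!r}")

    def matches(pred: Interval, ref: Interval) -> bool:
        ov = _overlap(pred, ref)
        if rule == "any_overlap":
            return ov >= 1
        ref_len = ref[1] - ref[0] + 1
        return ov >= min_fraction * ref_len

    detected = [r for r in reference if any(matches(p, r) for p in predicted)]
    missed = [r for r in reference if r not in detected]
    false_pos = [p for p in predicted if not any(matches(p, r) for r in reference)]

    n_det, n_fp = len(detected), len(false_pos)
    sensitivity = n_det / len(reference) if reference else float("nan")
    ppv = n_det / (n_det + n_fp) if (n_det + n_fp) > 0 else float("nan")
    rule_str = rule if rule == "any_overlap" else f"min_fraction({min_fraction})"
    return EvaluationResult(
        n_reference=len(reference),
        n_detected=n_det,
        n_false_positive=n_fp,
        sensitivity=sensitivity,
        ppv=ppv,
        match_rule=rule_str,
        detected_reference=detected,
        missed_reference=missed,
        false_positive_predictions=false_pos,
    )


def read_reference_intervals(path) -> List[Interval]:
    """Read reference prophage coordinates from BED (0-based half-open) or
    a 1-based inclusive TSV with start/end in columns 2-3.

    Files ending in ``.bed`` are converted from BED convention; anything
    else is taken as 1-based inclusive.  Lines starting with ``#`` or
    ``track`` are skipped, as is a ``start``-containing header row.
    """
    path = Path(path)
    is_bed = path.suffix.lower() == ".bed"
    out: List[Interval] = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}: cannot parse interval line {line!r}")
        if fields[1].lower() in ("start", "chromstart"):
            continue
        start, end = int(fields[1]), int(fields[2])
        out.append((start + 1, end) if is_bed else (start, end))
    return out


# ---------------------------------------------------------------------------
# Cluster validity indices
# ---------------------------------------------------------------------------


@dataclass
class ValidityScores:
    silhouette: float
    dunn: float
    davies_bouldin: float
    dbcv: float
    n_clusters: int

    def to_dict(self) -> dict:
        return {
            "silhouette": self.silhouette,
            "dunn": self.dunn,
            "davies_bouldin": self.davies_bouldin,
            "dbcv": self.dbcv,
            "n_clusters": self.n_clusters,
        }


def _drop_noise(
    coords: Sequence[float], labels: Sequence[int], metric: str
) -> Tuple[np.ndarray, np.ndarray]:
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels, dtype=int)
    keep = labels != -1
    coords, labels = coords[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError(
            f"{metric} undefined: fewer than 2 clusters after removing noise"
        )
    return coords, labels


def silhouette(coords: Sequence[float], labels: Sequence[int]) -> float:
    """Mean silhouette coefficient over non-noise points: (b-a)/max(a,b)
    with a = mean intra-cluster distance, b = min over other clusters of
    the mean distance to that cluster."""
    coords, labels = _drop_noise(coords, labels, "silhouette")
    return float(_sk_silhouette(coords.reshape(-1, 1), labels))


def dunn_index(coords: Sequence[float], labels: Sequence[int]) -> float:
    """(min inter-cluster single-linkage distance) / (max intra-cluster
    diameter).  A zero maximum diameter (all clusters are point-masses)
    gives +inf."""
    coords, labels = _drop_noise(coords, labels, "dunn")
    clusters = [coords[labels == l] for l in np.unique(labels)]
    max_diam = max(
        (c.max() - c.min()) if len(c) > 1 else 0.0 for c in clusters
    )
    min_sep = min(
        cdist(a.reshape(-1, 1), b.reshape(-1, 1)).min()
        for i, a in enumerate(clusters)
        for b in clusters[i + 1 :]
    )
    if max_diam == 0.0:
        logger.warning("dunn index: zero max diameter; returning +inf")
        return float("inf")
    return float(min_sep / max_diam)


def davies_bouldin(coords: Sequence[float], labels: Sequence[int]) -> float:
    """Mean over clusters i of max_{j!=i} (s_i+s_j)/d(c_i,c_j), with s the
    mean distance to the cluster centroid and c the centroid.

    Computed directly from the definition (rather than via
    sklearn.metrics.davies_bouldin_score, which rejects the legitimate
    degenerate case of all-singleton clusters, where the score is 0).
    """
    coords, labels = _drop_noise(coords, labels, "davies_bouldin")
    uniq = np.unique(labels)
    centroids = np.array([coords[labels == l].mean() for l in uniq])
    scatter = np.array(
        [np.abs(coords[labels == l] - c).mean()
         for l, c in zip(uniq, centroids)]
    )
    k = len(uniq)
    total = 0.0
    for i in range(k):
        ratios = [
            (scatter[i] + scatter[j]) / abs(centroids[i] - centroids[j])
            for j in range(k)
            if j != i
        ]
        total += max(ratios)
    return float(total / k)


# --- DBCV -------------------------------------------------------------------
# Density-Based Clustering Validation: all-points core distances feed
# mutual-reachability distances; per-cluster minimum spanning trees give a
# density sparseness (max internal MST edge) that is compared with the
# density separation between clusters.  Score in [-1, 1]; negative means
# clusters are sparser inside than they are separated.  The dimension
# exponent d is 1 (genomic coordinates are one-dimensional).

_DBCV_DIM = 1


def _core_distances(dist: np.ndarray) -> np.ndarray:
    """All-points core distance for each point within its cluster:
    the inverse-distance power mean over the other members."""
    n = dist.shape[0]
    if n == 1:
        return np.zeros(1)
    core = np.empty(n)
    for i in range(n):
        d = np.delete(dist[i], i)
        if (d == 0).any():
            core[i] = 0.0
            continue
        core[i] = (np.sum((1.0 / d) ** _DBCV_DIM) / (n - 1)) ** (-1.0 / _DBCV_DIM)
    return core


def _mutual_reachability(
    dist: np.ndarray, core_a: np.ndarray, core_b: Optional[np.ndarray] = None
) -> np.ndarray:
    if core_b is None:
        core_b = core_a
    return np.maximum(dist, np.maximum.outer(core_a, core_b))


def _mst_edges(mreach: np.ndarray) -> List[Tuple[int, int, float]]:
    mst = minimum_spanning_tree(mreach).toarray()
    edges = []
    for i, j in zip(*np.nonzero(mst)):
        edges.append((int(i), int(j), float(mst[i, j])))
    return edges


def _sparseness(mreach: np.ndarray) -> float:
    """Density sparseness of a cluster: the maximum internal edge of the
    mutual-reachability MST (internal = both endpoints of degree > 1),
    falling back to the maximum edge when the MST has no internal edge."""
    n = mreach.shape[0]
    if n < 2:
        return 0.0
    edges = _mst_edges(mreach)
    degree = np.zeros(n, dtype=int)
    for i, j, _w in edges:
        degree[i] += 1
        degree[j] += 1
    internal = [w for i, j, w in edges if degree[i] > 1 and degree[j] > 1]
    if internal:
        return max(internal)
    return max(w for _i, _j, w in edges)


def dbcv(coords: Sequence[float], labels: Sequence[int]) -> float:
    """Density-Based Clustering Validation index on 1-D coordinates.

    Per cluster, validity = (separation - sparseness) / max(separation,
    sparseness) where separation is the minimum mutual-reachability
    distance to any other cluster; the index is the cluster-size-weighted
    mean over the non-noise points.
    """
    coords, labels = _drop_noise(coords, labels, "dbcv")
    uniq = np.unique(labels)
    members = {l: np.nonzero(labels == l)[0] for l in uniq}
    full_dist = squareform(pdist(coords.reshape(-1, 1)))
    core = {l: _core_distances(full_dist[np.ix_(idx, idx)]) for l, idx in members.items()}

    sparseness = {}
    for l, idx in members.items():
        d = full_dist[np.ix_(idx, idx)]
        sparseness[l] = _sparseness(_mutual_reachability(d, core[l]))

    separation = {}
    for a in uniq:
        seps = []
        for b in uniq:
            if a == b:
                continue
            d = full_dist[np.ix_(members[a], members[b])]
            seps.append(_mutual_reachability(d, core[a], core[b]).min())
        separation[a] = min(seps)

    n_total = len(coords)
    score = 0.0
    for l, idx in members.items():
        sep, spa = separation[l], sparseness[l]
        denom = max(sep, spa)
        validity = 0.0 if denom == 0 else (sep - spa) / denom
        score += (len(idx) / n_total) * validity
    return float(score)


def validity_scores(coords: Sequence[float], labels: Sequence[int]) -> ValidityScores:
    """All four indices for one labeling (noise excluded)."""
    _, lab = _drop_noise(coords, labels, "validity")
    return ValidityScores(
        silhouette=silhouette(coords, labels),
        dunn=dunn_index(coords, labels),
        davies_bouldin=davies_bouldin(coords, labels),
        dbcv=dbcv(coords, labels),
        n_clusters=len(np.unique(lab)),
    )
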