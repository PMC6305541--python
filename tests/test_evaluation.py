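"""Interval matching (Sn/PPV) and cluster-validity indices, checked
against brute-force evaluations of their defining formulas."""

import math

import numpy as np
import pytest

from prophagescan import (
    davies_bouldin,
    dbcv,
    dunn_index,
    match_regions,
    silhouette,
    validity_scores,
)
from prophagescan.errors import UndefinedMetricError
from prophagescan.evaluation import read_reference_intervals


class TestMatchRegions:
    def test_exact_predictions_are_perfect(self):
        ref = [(100, 200), (500, 900)]
        res = match_regions(ref, ref)
        assert res.sensitivity == 1.0 and res.ppv == 1.0
        assert res.n_false_positive == 0

    def test_single_base_overlap_counts_under_any_overlap(self):
        res = match_regions([(200, 300)], [(100, 200)])
        assert res.n_detected == 1 and res.sensitivity == 1.0

    def test_non_overlapping_prediction_is_false_positive(self):
        res = match_regions([(100, 200), (1000, 1100)], [(100, 200)])
        assert res.n_detected == 1
        assert res.n_false_positive == 1
        assert res.ppv == pytest.approx(0.5)

    def test_many_predictions_count_reference_once(self):
        res = match_regions([(100, 150), (160, 200)], [(100, 200)])
        assert res.n_detected == 1 and res.sensitivity == 1.0
        assert res.ppv == 1.0

    def test_min_fraction_rule_requires_coverage(self):
        ref = [(1, 1000)]
        # 100/1000 = 10% coverage
        low = match_regions([(901, 1000)], ref, rule="min_fraction",
                            min_fraction=0.5)
        assert low.n_detected == 0 and low.n_false_positive == 1
        high = match_regions([(401, 1000)], ref, rule="min_fraction",
                             min_fraction=0.5)
        assert high.n_detected == 1

    def test_invalid_interval_raises(self):
        with pytest.raises(ValueError, match="end"):
            match_regions([(200, 100)], [(1, 10)])

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(0)
        pred = [(int(s), int(s) + int(l)) for s, l in
                zip(rng.integers(0, 10_000, 8), rng.integers(10, 500, 8))]
        ref = [(int(s), int(s) + int(l)) for s, l in
               zip(rng.integers(0, 10_000, 5), rng.integers(10, 500, 5))]
        a = match_regions(pred, ref)
        b = match_regions(list(reversed(pred)), list(reversed(ref)))
        assert (a.n_detected, a.n_false_positive) == (
            b.n_detected, b.n_false_positive
        )

    def test_adding_prediction_never_decreases_detection(self):
        ref = [(100, 200), (500, 600), (900, 1000)]
        preds = [(110, 150), (510, 550), (5000, 5100), (905, 950)]
        prev = 0
        for k in range(1, len(preds) + 1):
            res = match_regions(preds[:k], ref)
            assert res.n_detected >= prev
            prev = res.n_detected

    def test_bed_and_tsv_reference_readers_agree(self, tmp_path):
        bed = tmp_path / "ref.bed"
        bed.write_text("chr\t99\t200\tp1\t0\t.\nchr\t499\t900\tp2\t0\t.\n")
        tsv = tmp_path / "ref.tsv"
        tsv.write_text("name\tstart\tend\np1\t100\t200\np2\t500\t900\n")
        assert read_reference_intervals(bed) == read_reference_intervals(tsv)
        assert read_reference_intervals(bed) == [(100, 200), (500, 900)]


# ---------------------------------------------------------------------------
# brute-force oracles, written directly from the defining formulas
# ---------------------------------------------------------------------------


def brute_silhouette(coords, labels):
    pts = [(c, l) for c, l in zip(coords, labels) if l != -1]
    vals = []
    for c, l in pts:
        own = [abs(c - c2) for c2, l2 in pts if l2 == l and (c2, l2) != (c, l)]
        # sklearn convention: points whose cluster has a single member get 0
        same_cluster = [1 for _c2, l2 in pts if l2 == l]
        if len(same_cluster) == 1:
            vals.append(0.0)
            continue
        a = sum(own) / len(own)
        b = min(
            sum(abs(c - c2) for c2, l2 in pts if l2 == other)
            / sum(1 for _c2, l2 in pts if l2 == other)
            for other in {l2 for _c2, l2 in pts} - {l}
        )
        vals.append((b - a) / max(a, b))
    return sum(vals) / len(vals)


def brute_dunn(coords, labels):
    clusters = {}
    for c, l in zip(coords, labels):
        if l != -1:
            clusters.setdefault(l, []).append(c)
    groups = list(clusters.values())
    diam = max(
        max((abs(a - b) for a in g for b in g), default=0.0) for g in groups
    )
    sep = min(
        abs(a - b)
        for i, g1 in enumerate(groups)
        for g2 in groups[i + 1 :]
        for a in g1
        for b in g2
    )
    return math.inf if diam == 0 else sep / diam


def brute_davies_bouldin(coords, labels):
    clusters = {}
    for c, l in zip(coords, labels):
        if l != -1:
            clusters.setdefault(l, []).append(c)
    ids = sorted(clusters)
    centroid = {l: sum(clusters[l]) / len(clusters[l]) for l in ids}
    sigma = {
        l: sum(abs(c - centroid[l]) for c in clusters[l]) / len(clusters[l])
        for l in ids
    }
    total = 0.0
    for i in ids:
        total += max(
            (sigma[i] + sigma[j]) / abs(centroid[i] - centroid[j])
            for j in ids
            if j != i
        )
    return total / len(ids)


def brute_dbcv(coords, labels):
    """Independent DBCV evaluation: pure-python all-points core distances,
    Prim's MST, internal-edge sparseness with max-edge fallback."""
    clusters = {}
    for c, l in zip(coords, labels):
        if l != -1:
            clusters.setdefault(l, []).append(float(c))
    ids = sorted(clusters)

    def core_dists(group):
        n = len(group)
        if n == 1:
            return [0.0]
        out = []
        for i, x in enumerate(group):
            ds = [abs(x - y) for j, y in enumerate(group) if j != i]
            if any(d == 0 for d in ds):
                out.append(0.0)
            else:
                out.append((sum(1.0 / d for d in ds) / (n - 1)) ** -1.0)
        return out

    core = {l: core_dists(clusters[l]) for l in ids}

    def prim_mst(group, cd):
        n = len(group)
        if n < 2:
            return []
        def mrd(i, j):
            return max(abs(group[i] - group[j]), cd[i], cd[j])
        in_tree = {0}
        edges = []
        while len(in_tree) < n:
            best = None
            for i in in_tree:
                for j in range(n):
                    if j in in_tree:
                        continue
                    w = mrd(i, j)
                    if best is None or w < best[2]:
                        best = (i, j, w)
            in_tree.add(best[1])
            edges.append(best)
        return edges

    def sparseness(group, cd):
        edges = prim_mst(group, cd)
        if not edges:
            return 0.0
        deg = {}
        for i, j, _w in edges:
            deg[i] = deg.get(i, 0) + 1
            deg[j] = deg.get(j, 0) + 1
        internal = [w for i, j, w in edges if deg[i] > 1 and deg[j] > 1]
        return max(internal) if internal else max(w for _i, _j, w in edges)

    spars = {l: sparseness(clusters[l], core[l]) for l in ids}
    sep = {}
    for a in ids:
        best = math.inf
        for b in ids:
            if a == b:
                continue
            for i, x in enumerate(clusters[a]):
                for j, y in enumerate(clusters[b]):
                    best = min(best, max(abs(x - y), core[a][i], core[b][j]))
        sep[a] = best
    n_total = sum(len(g) for g in clusters.values())
    score = 0.0
    for l in ids:
        denom = max(sep[l], spars[l])
        v = 0.0 if denom == 0 else (sep[l] - spars[l]) / denom
        score += len(clusters[l]) / n_total * v
    return score


def random_labeled_instance(seed, max_n=30, with_noise=True):
    rng = np.random.default_rng(seed)
    k = 3
    coords, labels = [], []
    centers = np.cumsum(rng.uniform(50, 200, k))
    for l, c in enumerate(centers):
        n = int(rng.integers(3, max(4, max_n // k + 1)))
        pts = c + rng.uniform(-10, 10, n)
        coords.extend(float(p) for p in pts)
        labels.extend([l] * n)
    if with_noise:
        for _ in range(int(rng.integers(0, 4))):
            coords.append(float(rng.uniform(0, centers[-1] + 100)))
            labels.append(-1)
    return coords, labels


class TestValidityMetrics:
    def test_dunn_hand_case(self):
        coords, labels = [0, 1, 10, 11], [0, 0, 1, 1]
        assert dunn_index(coords, labels) == pytest.approx(9.0)

    def test_davies_bouldin_hand_case(self):
        coords, labels = [0, 1, 10, 11], [0, 0, 1, 1]
        assert davies_bouldin(coords, labels) == pytest.approx(0.1)

    def test_silhouette_hand_case(self):
        coords, labels = [0, 1, 10, 11], [0, 0, 1, 1]
        expected = (9.5 / 10.5 + 8.5 / 9.5 + 8.5 / 9.5 + 9.5 / 10.5) / 4
        assert silhouette(coords, labels) == pytest.approx(expected, abs=1e-9)

    def test_davies_bouldin_degenerate_singletons(self):
        assert davies_bouldin([0, 10], [0, 1]) == pytest.approx(0.0)

    def test_dunn_zero_diameter_is_infinite(self):
        assert dunn_index([0.0, 0.0, 5.0, 5.0], [0, 0, 1, 1]) == math.inf

    def test_fewer_than_two_clusters_is_undefined(self):
        with pytest.raises(UndefinedMetricError, match="silhouette"):
            silhouette([0, 1, 2], [0, 0, 0])
        with pytest.raises(UndefinedMetricError, match="dunn"):
            dunn_index([0, 1, 2, 100], [0, 0, 0, -1])

    def test_noise_points_are_excluded(self):
        base = dunn_index([0, 1, 10, 11], [0, 0, 1, 1])
        with_noise = dunn_index([0, 1, 10, 11, 500], [0, 0, 1, 1, -1])
        assert base == with_noise

    @pytest.mark.parametrize("seed", range(5))
    def test_davies_bouldin_agrees_with_sklearn(self, seed):
        from sklearn.metrics import davies_bouldin_score

        coords, labels = random_labeled_instance(seed, with_noise=False)
        expected = davies_bouldin_score(
            np.asarray(coords).reshape(-1, 1), labels
        )
        assert davies_bouldin(coords, labels) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_all_metrics_match_bruteforce_on_random_instances(self, seed):
        coords, labels = random_labeled_instance(seed)
        assert silhouette(coords, labels) == pytest.approx(
            brute_silhouette(coords, labels), abs=1e-9
        )
        assert dunn_index(coords, labels) == pytest.approx(
            brute_dunn(coords, labels), abs=1e-9
        )
        assert davies_bouldin(coords, labels) == pytest.approx(
            brute_davies_bouldin(coords, labels), abs=1e-9
        )
        assert dbcv(coords, labels) == pytest.approx(
            brute_dbcv(coords, labels), abs=1e-9
        )

    def test_dbcv_in_range_and_prefers_good_clustering(self):
        coords = [0, 1, 2, 3, 100, 101, 102, 103]
        good = [0, 0, 0, 0, 1, 1, 1, 1]
        bad = [0, 1, 0, 1, 0, 1, 0, 1]
        g, b = dbcv(coords, good), dbcv(coords, bad)
        assert -1.0 <= b <= 1.0 and -1.0 <= g <= 1.0
        assert g > 0 > b

    def test_translation_and_scale_invariance(self):
        coords, labels = random_labeled_instance(7)
        shifted = [c + 1234.5 for c in coords]
        scaled = [c * 3.25 for c in coords]
        for metric in (silhouette, dunn_index, davies_bouldin, dbcv):
            ref = metric(coords, labels)
            assert metric(shifted, labels) == pytest.approx(ref, abs=1e-9)
            assert metric(scaled, labels) == pytest.approx(ref, rel=1e-9)

    def test_validity_scores_bundle(self):
        coords, labels = random_labeled_instance(3)
        scores = validity_scores(coords, labels)
        assert scores.n_clusters == 3
        assert -1 <= scores.silhouette <= 1
        assert scores.dunn >= 0 and scores.davies_bouldin >= 0
        assert -1 <= scores.dbcv <= 1
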