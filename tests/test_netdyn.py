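"""Synchronization, communities, transfer entropy and 3D geometry."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caltrace.netdyn import (ClusterAssignment, FunctionalGraph, Raster,
                             _bin_counts, _cosine_similarity, cluster_geometry,
                             cluster_trains, functional_connectivity,
                             iei_preserving_shuffle, intra_inter_strength,
                             link_angles, silhouette_test, spike_sync,
                             te_significance, transfer_entropy)

import networkx as nx
import pandas as pd


# ---------------------------------------------------------------------------
# SPIKE-synchronization


def brute_force_spike_sync(trains):
    """Independent exhaustive loop over events and pairs."""
    total = coincident = 0
    for i, ti in enumerate(trains):
        for j, tj in enumerate(trains):
            if i == j or len(ti) == 0 or len(tj) == 0:
                continue
            for k, t in enumerate(ti):
                l = int(np.argmin(np.abs(np.asarray(tj) - t)))
                ivs = []
                if k > 0:
                    ivs.append(ti[k] - ti[k - 1])
                if k < len(ti) - 1:
                    ivs.append(ti[k + 1] - ti[k])
                if l > 0:
                    ivs.append(tj[l] - tj[l - 1])
                if l < len(tj) - 1:
                    ivs.append(tj[l + 1] - tj[l])
                tau = 0.5 * min(ivs) if ivs else np.inf
                total += 1
                if abs(t - tj[l]) < tau:
                    coincident += 1
    return coincident / total


class TestSpikeSync:
    def test_identical_trains_fully_synchronous(self):
        t = [np.array([1.0, 2.0, 3.5, 7.0])] * 4
        assert spike_sync(t) == 1.0

    def test_disjoint_trains_zero(self):
        a = np.array([1.0, 1.2, 1.4, 1.6])
        b = a + 100.0
        assert spike_sync([a, b]) == 0.0

    def test_matches_brute_force_enumeration(self):
        trains = [
            np.array([1.0, 4.0, 9.0, 11.0]),
            np.array([1.2, 5.0, 9.1]),
            np.array([3.0, 4.1, 12.0, 15.0, 16.0]),
        ]
        assert spike_sync(trains) == pytest.approx(
            brute_force_spike_sync([t.tolist() for t in trains]), abs=1e-12)

    def test_symmetric_under_relabeling(self, rng):
        trains = [np.sort(rng.uniform(0, 60, rng.integers(5, 15)))
                  for _ in range(5)]
        si = spike_sync(trains)
        perm = [trains[i] for i in rng.permutation(5)]
        assert spike_sync(perm) == pytest.approx(si, abs=1e-12)

    def test_needs_two_trains(self):
        with pytest.raises(ValueError):
            spike_sync([np.array([1.0])])


# ---------------------------------------------------------------------------
# communities


def _raster_from_onsets(onsets, fs, n_samples):
    mat = np.zeros((len(onsets), n_samples), np.uint8)
    for c, t in enumerate(onsets):
        mat[c, (np.asarray(t) * fs).astype(int)] = 1
    return Raster(mat, fs, [np.asarray(t, float) for t in onsets])


class TestClusterTrains:
    def test_disjoint_epochs_perfectly_recovered(self, rng):
        fs, dur = 65.0, 60.0
        base1 = np.sort(rng.uniform(0, 28, 15))
        base2 = np.sort(rng.uniform(32, 59, 15))
        onsets = [np.clip(np.sort(b + rng.normal(0, 0.05, b.size)), 0, dur - 0.1)
                  for b in [base1] * 4 + [base2] * 4]
        raster = _raster_from_onsets(onsets, fs, int(dur * fs))
        assign = cluster_trains(raster)
        from sklearn.metrics import adjusted_rand_score

        truth = [0] * 4 + [1] * 4
        assert adjusted_rand_score(truth, assign.labels) == 1.0
        assert assign.n_clusters == 2

    def test_identical_trains_single_community(self):
        fs = 65.0
        t = np.array([1.0, 5.0, 9.0])
        raster = _raster_from_onsets([t, t, t], fs, int(12 * fs))
        assert cluster_trains(raster).n_clusters == 1

    def test_partition_modularity_matches_exhaustive_search(self, rng):
        """The selected partition attains the best modularity over all
        partitions of the similarity graph into <= 3 groups."""
        fs, dur = 65.0, 40.0
        g1 = np.sort(rng.uniform(0, 18, 12))
        g2 = np.sort(rng.uniform(22, 39, 12))
        onsets = [np.clip(np.sort(b + rng.normal(0, 0.03, b.size)), 0, dur - 0.1)
                  for b in [g1] * 3 + [g2] * 3]
        raster = _raster_from_onsets(onsets, fs, int(dur * fs))
        assign = cluster_trains(raster)

        counts = _bin_counts(raster.onsets, assign.bin_size, dur)
        sim = _cosine_similarity(counts)
        g = nx.from_numpy_array(sim)
        best = -np.inf
        n = len(onsets)
        for labels in itertools.product(range(3), repeat=n):
            groups = [
                {i for i in range(n) if labels[i] == k}
                for k in range(3)
            ]
            groups = [grp for grp in groups if grp]
            q = nx.community.modularity(g, groups, weight="weight")
            best = max(best, q)
        assert assign.modularity == pytest.approx(best, abs=1e-9)

    def test_single_active_cell_warns(self):
        raster = _raster_from_onsets([[1.0], []], 65.0, 200)
        with pytest.warns(UserWarning):
            assign = cluster_trains(raster)
        assert assign.n_clusters == 1


# ---------------------------------------------------------------------------
# transfer entropy


def manual_te_m1(x, y):
    """Dictionary-based plug-in TE(Y→X), m = 1, base 2."""
    from collections import Counter

    triples = Counter()
    pairs_xx = Counter()
    pairs_hh = Counter()
    hist = Counter()
    n = len(x) - 1
    for t in range(n):
        triples[(x[t + 1], x[t], y[t])] += 1
        pairs_xx[(x[t + 1], x[t])] += 1
        pairs_hh[(x[t], y[t])] += 1
        hist[x[t]] += 1
    te = 0.0
    for (xf, xh, yh), c in triples.items():
        p_xyz = c / n
        num = c / pairs_hh[(xh, yh)]
        den = pairs_xx[(xf, xh)] / hist[xh]
        te += p_xyz * math.log2(num / den)
    return te


class TestTransferEntropy:
    def test_independent_trains_vanish(self, rng):
        x = rng.integers(0, 2, 100_000)
        y = rng.integers(0, 2, 100_000)
        assert transfer_entropy(x, y) < 0.01

    def test_perfect_echo_is_one_bit(self, rng):
        x = rng.integers(0, 2, 100_000)
        y = np.roll(x, 1)  # y_{n+1} = x_n
        assert transfer_entropy(y, x) == pytest.approx(1.0, abs=1e-3)

    def test_hand_pair_matches_manual_histogram(self):
        x = np.array([0, 1, 1, 0, 1, 0, 0, 1, 1, 1, 0, 0, 1, 0, 1, 1, 0, 0, 0, 1])
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 1, 0, 1, 0, 0, 1, 1, 0, 0])
        assert transfer_entropy(x, y) == pytest.approx(manual_te_m1(x, y), abs=1e-12)

    def test_constant_target_zero(self):
        assert transfer_entropy(np.zeros(100, int), np.ones(100, int)) == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        x = (rng.random(300) < 0.2).astype(int)
        y = (rng.random(300) < 0.2).astype(int)
        assert transfer_entropy(x, y) >= 0.0


class TestTeSignificance:
    def test_shuffle_preserves_iei_multiset_exactly(self, rng):
        y = (rng.random(5000) < 0.02).astype(int)
        for _ in range(10):
            s = iei_preserving_shuffle(y, rng)
            assert s.sum() == y.sum()
            iei = lambda v: sorted(np.diff(np.flatnonzero(v)).tolist())
            assert iei(s) == iei(y)

    def test_coupled_pair_strongly_significant(self, rng):
        x = (rng.random(10_000) < 0.1).astype(int)
        y = np.roll(x, 1)
        te, z, sig = te_significance(y, x, n_shuffles=100, seed=1)
        assert sig and z > 2.0

    def test_false_positive_rate_near_nominal(self, rng):
        """Independent Poisson pairs pass the 95th-percentile rule at about
        the nominal 5% rate."""
        hits = 0
        reps = 100
        for r in range(reps):
            x = (rng.random(4000) < 0.03).astype(int)
            y = (rng.random(4000) < 0.03).astype(int)
            _, _, sig = te_significance(x, y, n_shuffles=60, seed=r)
            hits += sig
        assert 1 <= hits <= 12  # binomial 95% band around 5 of 100

    def test_requires_enough_shuffles(self):
        with pytest.raises(ValueError):
            te_significance(np.zeros(10, int), np.zeros(10, int), n_shuffles=5)


# ---------------------------------------------------------------------------
# geometry


def _graph(rows):
    return FunctionalGraph(pd.DataFrame(rows))


class TestLinkAngles:
    def test_axis_aligned_links(self):
        pos = np.array([[0, 0, 0], [0, 0, 10], [10, 0, 0], [0, 0, -10]], float)
        rows = [
            dict(src=0, dst=1, te_bits=1.0, z=3.0, significant=True),   # +z
            dict(src=0, dst=2, te_bits=1.0, z=3.0, significant=True),   # +x
            dict(src=0, dst=3, te_bits=1.0, z=3.0, significant=True),   # -z
        ]
        edges, _ = link_angles(_graph(rows), pos)
        assert edges["azimuth_rad"].tolist() == pytest.approx(
            [0.0, np.pi / 2, np.pi], abs=1e-12)
        assert edges["polar_rad"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_vertical_graph_concentrates_histogram(self, rng):
        n = 30
        pos = np.column_stack([rng.uniform(0, 100, n), rng.uniform(0, 100, n),
                               rng.uniform(0, 300, n)])
        rows = []
        for i in range(n - 1):
            pos[i + 1][:2] = pos[i][:2]  # stack cells vertically in pairs
            rows.append(dict(src=i, dst=i + 1, te_bits=1.0, z=3.0, significant=True))
            i += 1
        edges, hists = link_angles(_graph(rows), pos, n_bins=18)
        counts, bins = hists["azimuth"]
        mass_ends = counts[0] + counts[-1]
        assert mass_ends > 0.8 * counts.sum()

    def test_zero_length_link_skipped(self):
        pos = np.zeros((2, 3))
        rows = [dict(src=0, dst=1, te_bits=1.0, z=1.0, significant=True)]
        with pytest.warns(UserWarning):
            edges, _ = link_angles(_graph(rows), pos)
        assert edges.empty


class TestClusterGeometry:
    def test_unit_square_hull(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        assign = ClusterAssignment(np.zeros(4, int), 0.1, 0.5)
        out = cluster_geometry(assign, pos)
        assert out.loc[0, "transverse_per_cell"] == pytest.approx(1.0 / 4)

    def test_columnar_cluster_ratio_below_one(self, rng):
        n = 40
        pos = np.column_stack([
            rng.uniform(0, 50, n), rng.uniform(0, 50, n), rng.uniform(0, 300, n)])
        assign = ClusterAssignment(np.zeros(n, int), 0.1, 0.5)
        out = cluster_geometry(assign, pos)
        assert out.loc[0, "ratio"] < 1.0

    def test_isotropic_cloud_ratio_near_one(self):
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pos = rng.uniform(0, 100, size=(40, 3))
            assign = ClusterAssignment(np.zeros(40, int), 0.1, 0.5)
            ratios.append(cluster_geometry(assign, pos).loc[0, "ratio"])
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.2)

    def test_degenerate_cluster_reported_with_nan(self):
        pos = np.array([[0, 0, 0], [1, 1, 0], [2, 2, 0]], float)  # collinear in x-y
        assign = ClusterAssignment(np.zeros(3, int), 0.1, 0.5)
        out = cluster_geometry(assign, pos)
        assert np.isnan(out.loc[0, "ratio"])


def manual_silhouette(xy, labels):
    xy = np.asarray(xy, float)
    n = len(xy)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = np.mean([np.linalg.norm(xy[i] - xy[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(xy[i] - xy[j])
                     for j in range(n) if labels[j] == lab])
            for lab in set(labels) if lab != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestSilhouette:
    XY6 = np.array([[0, 0], [0, 1], [1, 0], [10, 10], [10, 11], [11, 10]], float)

    def test_separated_blobs_segregated(self, rng):
        xy = np.r_[rng.normal(0, 0.3, (10, 2)), rng.normal(10, 0.3, (10, 2))]
        assign = ClusterAssignment([0] * 10 + [1] * 10, 0.1, 0.5)
        coef, p95, seg = silhouette_test(assign, xy, seed=0)
        assert coef > 0.8 and seg

    def test_matches_hand_computation(self):
        labels = [0, 0, 0, 1, 1, 1]
        assign = ClusterAssignment(labels, 0.1, 0.5)
        coef, _, _ = silhouette_test(assign, self.XY6, n_randomizations=20, seed=0)
        assert coef == pytest.approx(manual_silhouette(self.XY6, labels), abs=1e-12)

    def test_random_labels_rarely_segregated(self, rng):
        xy = rng.uniform(0, 10, size=(30, 2))
        seg_count = 0
        for s in range(20):
            labels = rng.integers(0, 2, 30)
            if len(np.unique(labels)) < 2:
                continue
            assign = ClusterAssignment(labels, 0.1, 0.5)
            _, _, seg = silhouette_test(assign, xy, n_randomizations=100, seed=s)
            seg_count += seg
        assert seg_count <= 4

    def test_single_cluster_flagged(self):
        assign = ClusterAssignment(np.zeros(5, int), 0.1, 0.5)
        with pytest.warns(UserWarning):
            coef, _, seg = silhouette_test(assign, np.random.rand(5, 2))
        assert np.isnan(coef) and not seg


class TestIntraInter:
    def test_hand_graph_arithmetic(self):
        rows = [
            dict(src=0, dst=1, te_bits=1.0, z=4.0, significant=True),  # intra (0,0)
            dict(src=2, dst=3, te_bits=1.0, z=2.0, significant=True),  # intra (1,1)
            dict(src=0, dst=2, te_bits=1.0, z=1.0, significant=True),  # inter
            dict(src=1, dst=3, te_bits=1.0, z=3.0, significant=True),  # inter
        ]
        assign = ClusterAssignment([0, 0, 1, 1], 0.1, 0.5)
        intra, inter, excess = intra_inter_strength(_graph(rows), assign)
        assert intra == pytest.approx(3.0)
        assert inter == pytest.approx(2.0)
        assert excess == pytest.approx(50.0)

    def test_all_intra_flagged(self):
        rows = [dict(src=0, dst=1, te_bits=1.0, z=1.0, significant=True)]
        assign = ClusterAssignment([0, 0], 0.1, 0.5)
        with pytest.warns(UserWarning):
            _, _, excess = intra_inter_strength(_graph(rows), assign)
        assert np.isnan(excess)

    def test_planted_coupling_gives_positive_excess(self, rng):
        """Cells coupled within communities produce stronger intra links."""
        n, L = 6, 6000
        drivers = [(rng.random(L) < 0.05).astype(int) for _ in range(2)]
        mat = np.zeros((n, L), np.uint8)
        for c in range(n):
            d = drivers[c // 3]
            echo = np.roll(d, c % 3)  # staggered propagation inside a community
            noise = (rng.random(L) < 0.01).astype(int)
            mat[c] = np.clip(echo | noise, 0, 1)
        onsets = [np.flatnonzero(m) / 65.0 for m in mat]
        raster = Raster(mat, 65.0, onsets)
        graph = functional_connectivity(raster, n_shuffles=50, seed=2)
        assign = ClusterAssignment([0, 0, 0, 1, 1, 1], 0.1, 0.5)
        if graph.significant().shape[0] and \
                (~(assign.labels[graph.significant()["src"]] ==
                   assign.labels[graph.significant()["dst"]])).any():
            _, _, excess = intra_inter_strength(graph, assign)
            assert excess > 0
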