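"""Clustering and validation indices against exhaustive and hand oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mdtop.clustering import (
    ClusterModel,
    average_linkage,
    contingency,
    count_transitions,
    davies_bouldin,
    dunn_index,
    gromos_cluster,
    kmedoids,
    scan_k,
    wss,
)
from mdtop.errors import UsageError


def _sym(rng, n, lo=0.2, hi=2.0):
    a = rng.uniform(lo, hi, size=(n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def _blob_matrix(rng, sizes, intra=0.1, inter=2.0):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(
        labels[:, None] == labels[None, :],
        rng.uniform(0.02, intra, size=(n, n)),
        rng.uniform(inter, inter + 0.5, size=(n, n)),
    )
    d = np.triu(d, 1)
    d = d + d.T
    return d, labels


class TestKMedoids:
    def test_two_blobs_exact_recovery(self, rng):
        d, labels = _blob_matrix(rng, [6, 5])
        model = kmedoids(d, 2, seed=0)
        a = model.labels
        assert len(set(zip(a, labels))) == 2  # one-to-one relabelling

    def test_k_equals_n_zero_wss(self, rng):
        d = _sym(rng, 6)
        model = kmedoids(d, 6, seed=0)
        assert sorted(model.medoids) == list(range(6))
        assert wss(d, model) == 0.0

    def test_seven_point_exhaustive_oracle(self, rng):
        """PAM with restarts finds the same optimum as exhaustive search over
        all C(7,2) medoid pairs (squared-cost objective)."""
        for trial in range(5):
            d = _sym(rng, 7)
            best_cost, best_set = np.inf, None
            for medoids in itertools.combinations(range(7), 2):
                cost = (d[:, medoids].min(axis=1) ** 2).sum()
                if cost < best_cost - 1e-12:
                    best_cost, best_set = cost, set(medoids)
            model = kmedoids(d, 2, seed=trial, restarts=10)
            assert set(model.medoids) == best_set
            assert model.params["cost"] == pytest.approx(best_cost)

    def test_k_out_of_range_rejected(self, rng):
        d = _sym(rng, 5)
        with pytest.raises(UsageError):
            kmedoids(d, 6, seed=0)
        with pytest.raises(UsageError):
            kmedoids(d, 1, seed=0)

    def test_deterministic_under_seed(self, rng):
        d = _sym(rng, 12)
        a = kmedoids(d, 3, seed=5)
        b = kmedoids(d, 3, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.medoids, b.medoids)


def _gromos_oracle(d, cutoff):
    """Hand simulation of neighbour peeling, written independently."""
    n = d.shape[0]
    pool = set(range(n))
    clusters = []
    while pool:
        best_center, best_neighbors = None, None
        for i in sorted(pool):
            neigh = {j for j in pool if j != i and d[i, j] < cutoff}
            if best_neighbors is None or len(neigh) > len(best_neighbors):
                best_center, best_neighbors = i, neigh
        members = {best_center} | best_neighbors
        clusters.append((best_center, sorted(members)))
        pool -= members
    return clusters


class TestGromos:
    def test_cutoff_above_max_single_cluster(self, rng):
        d = _sym(rng, 8)
        model = gromos_cluster(d, d.max() + 1.0)
        assert model.n_clusters == 1
        assert set(model.labels) == {0}

    def test_cutoff_below_min_all_singletons(self, rng):
        d = _sym(rng, 8, lo=0.5, hi=1.0)
        model = gromos_cluster(d, 0.4)
        assert model.n_clusters == 8

    def test_six_point_peeling_matches_hand_oracle(self, rng):
        for trial in range(5):
            d = _sym(np.random.default_rng(trial), 6, lo=0.1, hi=1.0)
            cutoff = 0.5
            oracle = _gromos_oracle(d, cutoff)
            model = gromos_cluster(d, cutoff)
            assert model.n_clusters == len(oracle)
            for c, (center, members) in enumerate(oracle):
                assert model.medoids[c] == center
                assert sorted(model.members(c)) == members

    def test_every_frame_assigned_once(self, rmsd_matrix):
        model = gromos_cluster(rmsd_matrix, 2.2)
        assert np.all(model.labels >= 0)
        assert model.sizes().sum() == rmsd_matrix.n

    def test_neighbor_counts_non_increasing_across_peeling(self, rng):
        d = _sym(rng, 20, lo=0.1, hi=1.5)
        cutoff = 0.8
        sizes = gromos_cluster(d, cutoff).sizes()
        oracle = _gromos_oracle(d, cutoff)
        counts = [len(m) for _, m in oracle]
        assert list(sizes) == counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def _average_linkage_oracle(d, cutoff):
    """Naive agglomerative merging by mean inter-cluster distance."""
    clusters = [[i] for i in range(d.shape[0])]
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if avg < best[0]:
                    best = (avg, (i, j))
        if best[0] > cutoff:
            break
        i, j = best[1]
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(sorted(c) for c in clusters)


class TestAverageLinkage:
    def test_cutoff_below_min_all_singletons(self, rng):
        d = _sym(rng, 7, lo=0.5, hi=1.0)
        model = average_linkage(d, 0.3)
        assert model.n_clusters == 7

    def test_two_blobs_recovered(self, rng):
        d, labels = _blob_matrix(rng, [5, 6])
        model = average_linkage(d, 1.0)
        assert model.n_clusters == 2
        assert len(set(zip(model.labels, labels))) == 2

    def test_five_point_merge_against_naive_oracle(self):
        for trial in range(6):
            d = _sym(np.random.default_rng(100 + trial), 5, lo=0.1, hi=1.2)
            cutoff = 0.6
            oracle = _average_linkage_oracle(d, cutoff)
            model = average_linkage(d, cutoff)
            got = sorted(
                sorted(model.members(c).tolist()) for c in range(model.n_clusters)
            )
            assert got == oracle


class TestValidation:
    def test_wss_direct_summation(self, rng):
        d = _sym(rng, 6)
        model = kmedoids(d, 2, seed=0)
        direct = 0.0
        for i, lab in enumerate(model.labels):
            direct += d[i, model.medoids[lab]] ** 2
        assert wss(d, model) == pytest.approx(direct)

    def test_wss_two_point_cluster(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        model = ClusterModel(
            labels=np.array([0, 0]), medoids=np.array([0]), method="manual"
        )
        assert wss(d, model) == pytest.approx(0.49)

    def test_dunn_direct_value(self):
        # two 2-point clusters: intra distances 0.1, inter-centroid 1.0
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        for i in (0, 1):
            for j in (2, 3):
                d[i, j] = d[j, i] = 1.0
        model = ClusterModel(
            labels=np.array([0, 0, 1, 1]),
            medoids=np.array([0, 2]),
            method="manual",
        )
        assert dunn_index(d, model) == pytest.approx(10.0)

    def test_dunn_degenerate_point_clusters(self):
        d = np.zeros((2, 2))
        d[0, 1] = d[1, 0] = 1.0
        model = ClusterModel(
            labels=np.array([0, 1]), medoids=np.array([0, 1]), method="manual"
        )
        assert dunn_index(d, model) == np.inf

    def test_davies_bouldin_direct_value(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 0.05
        d[2, 3] = d[3, 2] = 0.05
        for i in (0, 1):
            for j in (2, 3):
                d[i, j] = d[j, i] = 1.0
        model = ClusterModel(
            labels=np.array([0, 0, 1, 1]),
            medoids=np.array([0, 2]),
            method="manual",
        )
        # d_i = mean(0, 0.05) = 0.025; DBI = (0.025 + 0.025) / 1.0
        assert davies_bouldin(d, model) == pytest.approx(0.05)

    def test_davies_bouldin_coincident_medoids_rejected(self):
        d = np.zeros((4, 4))
        model = ClusterModel(
            labels=np.array([0, 0, 1, 1]),
            medoids=np.array([0, 2]),
            method="manual",
        )
        with pytest.raises(UsageError):
            davies_bouldin(d, model)

    def test_scan_identifies_three_basins(self, rmsd_matrix):
        scores = scan_k(rmsd_matrix, range(2, 6), seed=3)
        assert scores.best_by_dunn() == 3
        assert scores.best_by_davies_bouldin() == 3
        w = scores.table.sort_values("k")["wss"].to_numpy()
        assert np.all(np.diff(w) <= 1e-9)  # WSS non-increasing in k

    def test_scan_reproducible(self, rmsd_matrix):
        a = scan_k(rmsd_matrix, (2, 3), seed=4)
        b = scan_k(rmsd_matrix, (2, 3), seed=4)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_degenerate_identical_frames_zero_wss(self):
        d = np.zeros((6, 6))
        for k in (2, 3):
            model = kmedoids(d, k, seed=0)
            assert wss(d, model) == 0.0


class TestContingencyAndTransitions:
    def test_single_system_single_row(self):
        prov = pd.DataFrame(
            {"system": ["A"] * 4, "source": ["long"] * 4, "time_ps": range(4)}
        )
        model = ClusterModel(
            labels=np.array([0, 0, 1, 1]),
            medoids=np.array([0, 2]),
            method="manual",
        )
        table = contingency(model, prov)
        assert list(table.index) == ["A"]
        assert table.to_numpy().sum() == 4

    def test_shared_basin_design_contingency(self, rmsd_matrix, artificial):
        model = gromos_cluster(rmsd_matrix, 2.2)
        table = contingency(model, artificial.provenance)
        assert table.to_numpy().sum() == artificial.n_frames
        # the three shared-basin systems land in one pure cluster
        shared = table.loc[["F429A", "F429E", "F429H"]]
        main_cluster = shared.sum(axis=0).idxmax()
        assert shared[main_cluster].sum() / shared.to_numpy().sum() >= 0.99
        for label in ("WT", "F429L"):
            row = table.loc[label]
            assert row.max() / row.sum() >= 0.99
            assert row.idxmax() != main_cluster

    def test_constant_labels_no_transitions(self):
        prov = pd.DataFrame(
            {"system": ["A"] * 5, "source": ["long"] * 5, "time_ps": range(5)}
        )
        model = ClusterModel(
            labels=np.zeros(5, dtype=int), medoids=np.array([0]), method="m"
        )
        trans = count_transitions(model, prov)
        assert trans[0, 0] == 4

    def test_alternating_labels_three_transitions(self):
        prov = pd.DataFrame(
            {"system": ["A"] * 4, "source": ["long"] * 4, "time_ps": range(4)}
        )
        model = ClusterModel(
            labels=np.array([0, 1, 0, 1]),
            medoids=np.array([0, 1]),
            method="m",
        )
        trans = count_transitions(model, prov)
        off_diag = trans.sum() - np.trace(trans)
        assert off_diag == 3

    def test_no_transitions_across_concatenation_boundaries(self):
        prov = pd.DataFrame(
            {
                "system": ["A", "A", "B", "B"],
                "source": ["long"] * 4,
                "time_ps": [0, 1, 0, 1],
            }
        )
        model = ClusterModel(
            labels=np.array([0, 0, 1, 1]),
            medoids=np.array([0, 2]),
            method="m",
        )
        trans = count_transitions(model, prov)
        assert trans[0, 1] == 0 and trans[1, 0] == 0

    def test_scheduled_switches_recovered(self, topology):
        """A 3-window occupancy schedule yields exactly 2 basin transitions in
        the sampled artificial trajectory."""
        from mdtop import synthetic
        from mdtop.trajectory import SamplingProtocol, build_artificial_trajectory

        long_ps = 3000.0
        ref = topology.reference_coords
        system = synthetic.SystemSpec(
            "S",
            {0: synthetic.BasinSpec(ref, 0.05), 1: synthetic.BasinSpec(ref + 2.0, 0.05)},
            ((0.0, 1000.0, 0), (1000.0, 2000.0, 1), (2000.0, long_ps, 0)),
        )
        spec = synthetic.EnsembleSpec(
            systems=(system,), long_ns=3.0, restart_ns=(0.5,),
            restart_branch_ns=(0.5,), interval_ps=10.0, seed=2,
        )
        systems = synthetic.generate_ensemble(topology, spec)
        at = build_artificial_trajectory(
            [type(systems[0])(label="S", long=systems[0].long)],
            SamplingProtocol(100.0, 0.10, discard_ns=0.0, seed=3),
        )
        truth = at.provenance["basin"].to_numpy()
        model = ClusterModel(
            labels=truth,
            medoids=np.array(
                [int(np.flatnonzero(truth == c)[0]) for c in (0, 1)]
            ),
            method="truth",
        )
        trans = count_transitions(model, at.provenance)
        assert trans.sum() - np.trace(trans) == 2
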