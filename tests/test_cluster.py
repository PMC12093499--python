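"""Feature selection, distances, UPGMA, k-means elbow, MDS, ARI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import parcelfp as p
from parcelfp.cluster import _elbow_k


def fp_from(values, rows=None, cols=None):
    values = np.asarray(values, dtype=float)
    rows = rows or [f"r{i}" for i in range(values.shape[0])]
    cols = cols or [f"t{j}" for j in range(values.shape[1])]
    return p.Fingerprint(pd.DataFrame(values, index=rows, columns=cols))


def spec_map_from(levels):
    levels = pd.DataFrame(levels)
    vals = pd.DataFrame(np.zeros(levels.shape), index=levels.index, columns=levels.columns)
    thr = pd.Series(0.0, index=levels.columns)
    return p.SpecificityMap(levels=levels, values=vals, target_thresholds=thr,
                            global_threshold=0.0, percentile=99.0)


class TestSelectFeatures:
    def test_all_none_is_an_error(self):
        smap = spec_map_from({"t1": ["none"], "t2": ["none"]})
        with pytest.raises(ValueError, match="specificity screen"):
            p.select_features(smap)

    def test_single_flag_gives_singleton(self):
        smap = spec_map_from({"t1": ["none", "target_specific"], "t2": ["none", "none"]})
        assert p.select_features(smap) == ["t1"]

    def test_selected_set_matches_planted_affinities(self, paper_atlas):
        # mean Jaccard against the planted affinity union over replicates;
        # every planted target must be recovered (the ~1% per-seed false-
        # positive rate admits a couple of extra targets per replicate)
        atlas, truth = paper_atlas
        planted = {t for ts, _ in truth.affinity.values() for t in ts}
        jaccards = []
        for r in range(5):
            conns = p.simulate_cohort(atlas, truth, 200, rng_seed=200 + r)
            cohort = p.assemble_cohort(conns, atlas)
            fp = p.fingerprint_matrix(cohort)
            smap = p.classify_specificity(
                fp, p.all_target_nulls(cohort, 2000, rng_seed=r),
                p.global_null(cohort, 2000, rng_seed=r))
            selected = set(p.select_features(smap))
            assert planted <= selected
            jaccards.append(len(selected & planted) / len(selected | planted))
        assert np.mean(jaccards) >= 0.95


class TestManhattan:
    def test_identical_rows_have_zero_distance(self):
        fp = fp_from([[1, 2, 3], [1, 2, 3]])
        d = p.manhattan_matrix(fp)
        assert d.iat[0, 1] == 0

    def test_hand_summed_distance(self):
        fp = fp_from([[0, 0], [1, 2]])
        assert p.manhattan_matrix(fp).iat[0, 1] == 3

    def test_metric_axioms_on_random_fingerprints(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            fp = fp_from(rng.random((5, 7)))
            d = p.manhattan_matrix(fp).to_numpy()
            assert np.allclose(d, d.T)
            assert (np.diagonal(d) == 0).all()
            for i in range(5):
                for j in range(5):
                    for k in range(5):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestHierarchical:
    def test_two_separated_clouds_recovered_at_k2(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 0.1, (4, 3)), rng.normal(10, 0.1, (4, 3))])
        fp = fp_from(x)
        sol = p.hierarchical_cluster(p.manhattan_matrix(fp), k=2)
        labels = sol.label_vector()
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_ultrametric_input_has_cophenetic_correlation_one(self):
        # 2-level ultrametric on 4 points: within-pair 1, across 4
        d = np.array([[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0]], float)
        dist = pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))
        sol = p.hierarchical_cluster(dist)
        assert sol.cophenetic_correlation == pytest.approx(1.0)

    def test_five_point_merge_trace_matches_hand_executed_upgma(self):
        # points on a line at 0, 1, 4, 10, 20 with Manhattan distance.
        # hand trace: {0,1}@1 -> {0,1,4}@3.5 -> {..,10}@25/3 -> {..,20}@16.25
        pos = np.array([0.0, 1.0, 4.0, 10.0, 20.0])
        d = np.abs(pos[:, None] - pos[None, :])
        ids = [f"p{i}" for i in range(5)]
        sol = p.hierarchical_cluster(pd.DataFrame(d, index=ids, columns=ids))
        tree = sol.linkage_tree
        np.testing.assert_allclose(tree[:, 2], [1.0, 3.5, 25.0 / 3.0, 16.25], rtol=1e-12)
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}
        assert {int(tree[1, 0]), int(tree[1, 1])} == {2, 5}
        assert {int(tree[2, 0]), int(tree[2, 1])} == {3, 6}
        assert {int(tree[3, 0]), int(tree[3, 1])} == {4, 7}


class TestKmeansElbow:
    def test_three_planted_blobs_selected(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0, 0], [50, 0], [0, 50]])
        x = np.vstack([c + rng.normal(0, 0.5, (5, 2)) for c in centers])
        sol = p.kmeans_elbow(fp_from(x), k_range=range(2, 9), rng_seed=0)
        assert sol.k == 3

    def test_duplicate_entities_share_a_label(self):
        x = np.array([[0, 0], [0, 0], [9, 9], [9, 9], [5, 0], [0, 5]])
        sol = p.kmeans_elbow(fp_from(x), k_range=range(2, 5), rng_seed=0)
        assert sol.labels["r0"] == sol.labels["r1"]
        assert sol.labels["r2"] == sol.labels["r3"]

    def test_paper_structured_cohort_selects_planted_group_count(self, small_cohort):
        atlas, truth, _, cohort = small_cohort
        fp = p.fingerprint_matrix(cohort)
        smap = p.classify_specificity(
            fp, p.all_target_nulls(cohort, 1000, rng_seed=5),
            p.global_null(cohort, 1000, rng_seed=5))
        sol = p.kmeans_elbow(fp, p.select_features(smap), range(2, 9), rng_seed=5)
        assert sol.k == 6

    def test_inertia_curve_non_increasing(self, small_cohort):
        _, _, _, cohort = small_cohort
        fp = p.fingerprint_matrix(cohort)
        sol = p.kmeans_elbow(fp, k_range=range(2, 9), rng_seed=1)
        curve = [sol.inertia_curve[k] for k in sorted(sol.inertia_curve)]
        assert all(a >= b - 1e-9 for a, b in zip(curve, curve[1:]))

    def test_elbow_invariant_to_global_rescaling(self, small_cohort):
        _, _, _, cohort = small_cohort
        fp = p.fingerprint_matrix(cohort)
        a = p.kmeans_elbow(fp, k_range=range(2, 9), rng_seed=1)
        scaled = p.Fingerprint(fp.values * 1000.0, fp.trim_fraction)
        b = p.kmeans_elbow(scaled, k_range=range(2, 9), rng_seed=1)
        assert a.k == b.k

    def test_singleton_k_range_warns_and_returns_it(self):
        rng = np.random.default_rng(3)
        fp = fp_from(rng.random((6, 4)))
        with pytest.warns(UserWarning, match="elbow"):
            sol = p.kmeans_elbow(fp, k_range=[3], rng_seed=0)
        assert sol.k == 3

    def test_elbow_ties_break_to_smallest_k(self):
        # geometric curve has zero log-second-difference everywhere: a tie
        assert _elbow_k({2: 100.0, 3: 50.0, 4: 25.0, 5: 12.5}, [3, 4]) == 3

    def test_agrees_with_hierarchical_on_separated_structure(self):
        rng = np.random.default_rng(4)
        centers = rng.random((4, 6)) * 100
        x = np.vstack([c + rng.normal(0, 0.3, (4, 6)) for c in centers])
        fp = fp_from(x)
        km = p.kmeans_elbow(fp, k_range=range(2, 9), rng_seed=0)
        hier = p.hierarchical_cluster(p.manhattan_matrix(fp), k=4)
        assert km.k == 4
        assert p.adjusted_rand(km.labels, hier.labels) == 1.0


class TestMDS:
    def test_collinear_points_stay_collinear(self):
        pos = np.array([0.0, 3.0, 7.0])
        d = np.abs(pos[:, None] - pos[None, :])
        dist = pd.DataFrame(d, index=list("abc"), columns=list("abc"))
        coords = p.mds_embed(dist).to_numpy()
        # second axis carries no variance
        assert np.abs(coords[:, 1]).max() < 1e-8

    def test_planar_distances_recovered_up_to_rotation(self):
        rng = np.random.default_rng(5)
        pts = rng.random((8, 2)) * 10
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"p{i}" for i in range(8)]
        coords = p.mds_embed(pd.DataFrame(d, index=ids, columns=ids)).to_numpy()
        d2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        pts = rng.random((6, 2)) * 5
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"p{i}" for i in range(6)]
        dist = pd.DataFrame(d, index=ids, columns=ids)
        coords = p.mds_embed(dist)
        perm = ids[::-1]
        coords_p = p.mds_embed(dist.loc[perm, perm])
        # same pairwise geometry after permutation
        a = coords.to_numpy()
        b = coords_p.loc[ids].to_numpy()
        da = np.sqrt(((a[:, None] - a[None, :]) ** 2).sum(-1))
        db = np.sqrt(((b[:, None] - b[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(da, db, atol=1e-8)

    def test_matches_principal_coordinates_reference(self):
        # classical MDS is principal-coordinates analysis: cross-check the
        # embedded distances against scikit-bio's implementation
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        pts = rng.random((7, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"p{i}" for i in range(7)]
        ours = p.mds_embed(pd.DataFrame(d, index=ids, columns=ids)).to_numpy()
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, ids),
                                          number_of_dimensions=2).samples.to_numpy()
        np.testing.assert_allclose(np.abs(ours), np.abs(ref), atol=1e-8)


class TestClusterOfClusters:
    def test_identical_clusters_have_zero_distance(self, small_cohort):
        _, _, _, cohort = small_cohort
        labels = {s: "all" for s in cohort.seed_ids}
        clfp = p.cluster_fingerprint(cohort, labels)
        assert clfp.values.shape[0] == 1

    def test_planted_two_supergroups_selected(self):
        rng = np.random.default_rng(8)
        # 6 cluster rows: 3 near prototype A, 3 near prototype B
        a, b = rng.random(10) * 5, rng.random(10) * 5 + 50
        x = np.vstack([a + rng.normal(0, 0.1, 10) for _ in range(3)]
                      + [b + rng.normal(0, 0.1, 10) for _ in range(3)])
        clfp = fp_from(x)
        hier, km = p.cluster_of_clusters(clfp, k_range=range(2, 5), rng_seed=0)
        assert km.k == 2

    def test_posterior_groups_with_shared_affinity_merge_first(self, paper_atlas):
        # planting overlapping target affinity for the two posterior groups
        # makes them the most similar pair, so UPGMA merges them first
        from dataclasses import replace

        atlas, truth = paper_atlas
        aff = dict(truth.affinity)
        shared = aff["superior_posterior"][0] + aff["inferior_middle_posterior"][0]
        aff["superior_posterior"] = (shared, 3.0)
        aff["inferior_middle_posterior"] = (shared, 3.0)
        truth = replace(truth, affinity=aff)
        cohort = p.assemble_cohort(p.simulate_cohort(atlas, truth, 80, rng_seed=12), atlas)
        clfp = p.cluster_fingerprint(cohort, truth.true_labels())
        hier, _ = p.cluster_of_clusters(clfp, k_range=range(2, 5), rng_seed=0)
        names = list(clfp.row_ids)
        first = {names[int(hier.linkage_tree[0, 0])], names[int(hier.linkage_tree[0, 1])]}
        assert first == {"superior_posterior", "inferior_middle_posterior"}

    def test_needs_at_least_three_clusters(self):
        clfp = fp_from(np.random.default_rng(9).random((2, 4)))
        with pytest.raises(ValueError, match="at least 3"):
            p.cluster_of_clusters(clfp)


def brute_force_ari(a, b):
    """Contingency-table ARI computed from first principles."""
    from math import comb

    ents = sorted(a)
    la = [a[e] for e in ents]
    lb = [b[e] for e in ents]
    n = len(ents)
    cats_a, cats_b = sorted(set(la)), sorted(set(lb))
    nij = [[sum(1 for x, y in zip(la, lb) if x == i and y == j) for j in cats_b]
           for i in cats_a]
    sum_ij = sum(comb(v, 2) for row in nij for v in row)
    sum_a = sum(comb(sum(row), 2) for row in nij)
    sum_b = sum(comb(sum(row[j] for row in nij), 2) for j in range(len(cats_b)))
    expected = sum_a * sum_b / comb(n, 2)
    max_idx = (sum_a + sum_b) / 2
    if max_idx == expected:
        return 1.0
    return (sum_ij - expected) / (max_idx - expected)


class TestAdjustedRand:
    def test_identical_partitions_score_one(self):
        labels = {"a": 1, "b": 1, "c": 2, "d": 3}
        assert p.adjusted_rand(labels, labels) == 1.0

    def test_singletons_vs_one_group_not_positive(self):
        a = {f"e{i}": i for i in range(6)}
        b = {f"e{i}": 0 for i in range(6)}
        assert p.adjusted_rand(a, b) <= 0.0

    def test_matches_brute_force_contingency_on_random_partitions(self):
        rng = np.random.default_rng(10)
        ents = [f"e{i}" for i in range(8)]
        for _ in range(50):
            a = {e: int(rng.integers(1, 4)) for e in ents}
            b = {e: int(rng.integers(1, 4)) for e in ents}
            assert p.adjusted_rand(a, b) == pytest.approx(brute_force_ari(a, b), abs=1e-12)

    def test_mismatched_entity_sets_rejected(self):
        with pytest.raises(ValueError):
            p.adjusted_rand({"a": 1}, {"b": 1})
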