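"""Melody-space distances, clustering, Newick output and correlation statistics."""

import io
import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from gemusica import (
    DistanceMatrix,
    ScaleConfig,
    compare_groups,
    complete_linkage,
    melody_feature_matrix,
    pairwise_manhattan,
    pearson,
    permutation_test_means,
    relative_correlation,
    sonify_matrix,
    to_newick,
)
from .conftest import make_matrix


def random_distance_matrix(n, rng):
    coords = rng.normal(0, 1, size=(n, 3))
    d = np.abs(coords[:, None, :] - coords[None, :, :]).sum(axis=2)
    return DistanceMatrix(tuple(f"s{i}" for i in range(n)), d)


def brute_force_complete_linkage(dm):
    """Exhaustive oracle: recompute max-pairwise distances from scratch each merge."""
    clusters = {(sid,): {i} for i, sid in enumerate(dm.sample_ids)}
    heights = []
    while len(clusters) > 1:
        best = None
        for ka, kb in itertools.combinations(sorted(clusters), 2):
            dist = max(dm.d[i, j] for i in clusters[ka] for j in clusters[kb])
            if best is None or (dist, (ka, kb)) < best:
                best = (dist, (ka, kb))
        dist, (ka, kb) = best
        heights.append(dist)
        members = clusters.pop(ka) | clusters.pop(kb)
        clusters[tuple(sorted(ka + kb))] = members
    return sorted(heights)


class TestFeatureMatrix:
    def melodies(self, rng, n_probes=6, n_samples=4):
        m = make_matrix(rng.normal(7, 2, size=(n_probes, n_samples)))
        return sonify_matrix(m, ScaleConfig())

    def test_grid_shape_and_alignment(self, rng):
        mels = self.melodies(rng)
        f = melody_feature_matrix(mels)
        assert f.values.shape == (6, 4)
        assert f.sample_ids == tuple(m.sample_id for m in mels)
        assert f.probe_ids == tuple(n.probe_id for n in mels[0].notes)

    def test_key_and_frequency_spaces_consistent(self, rng):
        mels = self.melodies(rng)
        freq = melody_feature_matrix(mels, "frequency")
        key = melody_feature_matrix(mels, "key")
        np.testing.assert_allclose(freq.values, 27.5 * 2 ** (key.values / 12), rtol=1e-12)

    def test_single_melody_allowed(self, rng):
        f = melody_feature_matrix(self.melodies(rng)[:1])
        assert f.values.shape == (6, 1)

    def test_mixed_configs_rejected(self, rng):
        mels = self.melodies(rng)
        other = sonify_matrix(make_matrix(rng.normal(7, 2, size=(6, 1))), ScaleConfig(vol=9))
        with pytest.raises(ValueError, match="incompatible"):
            melody_feature_matrix([mels[0], other[0]])


class TestManhattan:
    def test_hand_example(self):
        f = make_matrix(np.array([[0.0, 3.0], [0.0, 4.0]]), scale_tag="log2")
        dm = pairwise_manhattan(f)
        assert dm.get("s0", "s1") == 7.0

    def test_identical_columns_distance_zero(self):
        f = make_matrix(np.array([[1.0, 1.0], [2.0, 2.0]]))
        assert pairwise_manhattan(f).d[0, 1] == 0.0

    def test_sample_permutation_equivariance(self, rng):
        vals = rng.normal(0, 1, size=(5, 4))
        dm = pairwise_manhattan(make_matrix(vals))
        perm = [2, 0, 3, 1]
        dm2 = pairwise_manhattan(
            make_matrix(vals[:, perm], sample_ids=tuple(f"s{j}" for j in perm))
        )
        for a, b in itertools.combinations(dm.sample_ids, 2):
            assert dm.get(a, b) == pytest.approx(dm2.get(a, b))

    def test_metric_axioms_all_triples(self, rng):
        # symmetry / identity enforced by the container; check triangle inequality
        for n in (3, 5, 8):
            dm = random_distance_matrix(n, rng)
            for i, j, k in itertools.permutations(range(n), 3):
                assert dm.d[i, j] <= dm.d[i, k] + dm.d[k, j] + 1e-12

    def test_scipy_cityblock_cross_check(self, rng):
        vals = rng.normal(0, 1, size=(7, 5))
        dm = pairwise_manhattan(make_matrix(vals))
        from scipy.spatial.distance import cdist

        np.testing.assert_allclose(dm.d, cdist(vals.T, vals.T, "cityblock"), rtol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pairwise_manhattan(make_matrix(np.array([[1.0], [2.0]])))


class TestCompleteLinkage:
    def test_three_sample_hand_example(self):
        d = np.array([[0, 1, 5], [1, 0, 4], [5, 4, 0]], float)
        dm = DistanceMatrix(("A", "B", "C"), d)
        tree = complete_linkage(dm)
        assert tree.merge_heights() == [1.0, 5.0]
        assert to_newick(tree) == "((A:1,B:1):4,C:5);"

    def test_identical_samples_merge_at_zero(self):
        f = make_matrix(np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0]]))
        tree = complete_linkage(pairwise_manhattan(f))
        assert min(tree.merge_heights()) == 0.0

    def test_brute_force_oracle_small_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            dm = random_distance_matrix(n, rng)
            tree = complete_linkage(dm)
            assert tree.merge_heights() == pytest.approx(brute_force_complete_linkage(dm))

    def test_scipy_linkage_heights_cross_check(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            dm = random_distance_matrix(n, rng)
            tree = complete_linkage(dm)
            z = hierarchy.linkage(squareform(dm.d, checks=False), method="complete")
            np.testing.assert_allclose(tree.merge_heights(), sorted(z[:, 2]), rtol=1e-9)

    def test_heights_non_decreasing_to_root(self, rng):
        dm = random_distance_matrix(10, rng)
        tree = complete_linkage(dm)

        def walk(node):
            if node.children is None:
                return
            for child in node.children:
                assert child.height <= node.height + 1e-12
                walk(child)

        walk(tree.root)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            complete_linkage(DistanceMatrix(("A",), np.zeros((1, 1))))

    def test_cut_recovers_blocks(self):
        # two tight pairs far apart
        d = np.array(
            [[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]], float
        )
        tree = complete_linkage(DistanceMatrix(("A", "B", "C", "D"), d))
        part = tree.cut(2)
        assert part["A"] == part["B"] != part["C"] == part["D"]


class TestNewick:
    def test_two_leaf_tree(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert to_newick(complete_linkage(dm)) == "(A:3,B:3);"

    def test_round_trip_with_skbio(self, rng):
        from skbio import TreeNode

        dm = random_distance_matrix(6, rng)
        tree = complete_linkage(dm)
        parsed = TreeNode.read(io.StringIO(to_newick(tree)))
        assert sorted(t.name for t in parsed.tips()) == sorted(dm.sample_ids)
        # leaf depth in the parsed tree equals the root merge height
        root_height = max(tree.merge_heights())
        for tip in parsed.tips():
            assert tip.accumulate_to_ancestor(parsed) == pytest.approx(root_height)


class TestPearson:
    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 20)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert pearson(np.array([1, 2, 3]), np.array([1, 3, 2])) == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson(np.array([1, 2]), np.array([1, 2]))
        with pytest.raises(ValueError):
            pearson(np.array([1.0, 1.0, 1.0]), np.array([1, 2, 3]))


class TestRelativeCorrelation:
    def features(self, rng, shift=0.0):
        # references track a shared profile; controls share it only partially,
        # so the control-anchored normalizer rho0 is solidly positive
        base = rng.normal(7, 2, size=30)
        ref = np.column_stack([base + rng.normal(0, 0.3, 30) for _ in range(3)])
        ctrl = np.column_stack([0.5 * base + rng.normal(0, 1.5, 30) for _ in range(3)])
        pert = ctrl + shift * (base[:, None] - ctrl)
        vals = np.column_stack([ref, ctrl, pert])
        ids = tuple([f"ref{i}" for i in range(3)] + [f"c{i}" for i in range(3)] + [f"k{i}" for i in range(3)])
        return make_matrix(vals, sample_ids=ids)

    def test_control_relative_values_average_to_one(self, rng):
        f = self.features(rng)
        rep = relative_correlation(f, ["c0", "c1", "c2"], ["k0", "k1", "k2"], ["ref0", "ref1", "ref2"])
        assert np.mean(rep.group_values("control")) == pytest.approx(1.0, abs=1e-9)
        assert rep.control_mean == pytest.approx(1.0, abs=1e-9)

    def test_perturbed_identical_to_controls_is_null(self, rng):
        f = self.features(rng, shift=0.0)
        rep = relative_correlation(f, ["c0", "c1", "c2"], ["c0", "c1", "c2"], ["ref0", "ref1", "ref2"])
        assert rep.perturbed_mean == pytest.approx(1.0, abs=1e-9)

    def test_shift_toward_reference_raises_relative_value(self, rng):
        f = self.features(rng, shift=0.6)
        rep = relative_correlation(f, ["c0", "c1", "c2"], ["k0", "k1", "k2"], ["ref0", "ref1", "ref2"])
        assert rep.perturbed_mean > 1.0
        # sign agrees with direct rho computation
        assert all(rep.rho[k] > rep.rho[c] for k, c in zip(["k0", "k1", "k2"], ["c0", "c1", "c2"]))


class TestGroupComparison:
    def report_from(self, ctrl, pert):
        from gemusica.comparison import RelativeCorrelationReport

        rho = {f"c{i}": v for i, v in enumerate(ctrl)} | {f"k{i}": v for i, v in enumerate(pert)}
        return RelativeCorrelationReport(
            reference_group="ref",
            control_ids=tuple(f"c{i}" for i in range(len(ctrl))),
            perturbed_ids=tuple(f"k{i}" for i in range(len(pert))),
            rho=rho,
            rho_rel=rho,
            rho0_mean=1.0,
            control_mean=float(np.mean(ctrl)),
            control_sd=float(np.std(ctrl, ddof=1)) if len(ctrl) > 1 else 0.0,
            perturbed_mean=float(np.mean(pert)),
            perturbed_sd=float(np.std(pert, ddof=1)) if len(pert) > 1 else 0.0,
        )

    def test_identical_groups_null(self):
        res = compare_groups(self.report_from([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]))
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_separated_groups_tiny_p(self, rng):
        ctrl = 1.0 + rng.normal(0, 1e-6, 4)
        pert = 2.0 + rng.normal(0, 1e-6, 4)
        res = compare_groups(self.report_from(list(ctrl), list(pert)))
        assert res.pvalue < 1e-10

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(self.report_from([1.0], [1.0, 2.0]))

    def test_welch_agrees_with_scipy(self, rng):
        ctrl = list(rng.normal(1.0, 0.1, 5))
        pert = list(rng.normal(1.2, 0.2, 4))
        res = compare_groups(self.report_from(ctrl, pert))
        from scipy import stats

        ref = stats.ttest_ind(ctrl, pert, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue)
        assert res.df == pytest.approx(ref.df)

    def test_welch_matches_permutation_oracle_4v4(self, rng):
        ctrl = np.array([1.02, 0.97, 1.05, 0.96])
        pert = np.array([1.14, 1.22, 1.08, 1.19])
        res = compare_groups(self.report_from(list(ctrl), list(pert)))
        p_perm = permutation_test_means(ctrl, pert, n_permutations=10_000, seed=7)
        assert abs(res.pvalue - p_perm) < 0.05
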