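"""Response-vector normalization, VRC, elbow, clustering, consistency."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from locustal.responses import (ResponseMatrix, VRCCurve, choose_k_elbow,
                                cluster_vectors, consistency_analysis,
                                linkage_to_newick, mixture_specific_fraction,
                                normalize_matrix, vrc)

import pandas as pd

STIMULI = ("Laa", "Lct", "LaaLct", "Z3hl", "Z3hlLct", "Oct", "OctLct",
           "Z3hlLaa", "OctLaa")


def brute_force_vrc(points, labels):
    """Direct double-loop implementation of the variance ratio criterion."""
    points = np.atleast_2d(np.asarray(points, float))
    if points.shape[0] == 1:
        points = points.T
    labels = np.asarray(labels)
    N = points.shape[0]
    uniq = list(dict.fromkeys(labels.tolist()))
    k = len(uniq)
    grand = points.mean(axis=0)
    ssb = ssw = 0.0
    for lab in uniq:
        members = [points[i] for i in range(N) if labels[i] == lab]
        mu = np.mean(members, axis=0)
        ssb += len(members) * np.sum((mu - grand) ** 2)
        for x in members:
            ssw += np.sum((x - mu) ** 2)
    return ssb * (N - k) / (ssw * (k - 1))


class TestNormalize:
    def _raw(self):
        vals = np.array([[0.0, 1.0, 0.5], [2.0, 0.0, 1.0],
                         [1.0, 3.0, 0.0], [0.5, 0.5, 2.0]])
        return ResponseMatrix(vals, ("a", "b", "c"),
                              np.array(["A", "A", "B", "B"]))

    def test_rows_span_minus_one_to_one(self):
        out = normalize_matrix(self._raw())
        assert np.allclose(out.values.min(axis=1), -1)
        assert np.allclose(out.values.max(axis=1), 1)

    def test_hand_computed_two_by_two(self):
        raw = ResponseMatrix(np.array([[0.0, 1.0], [4.0, 9.0]]), ("a", "b"),
                             np.array(["A", "A"]))
        out = normalize_matrix(raw)
        # sqrt -> [[0,1],[2,3]]; z-scale is monotone; row rescale gives +-1
        assert np.allclose(out.values, [[-1, 1], [-1, 1]])

    def test_per_animal_independence(self):
        base = self._raw()
        out1 = normalize_matrix(base)
        dup = ResponseMatrix(np.vstack([base.values, base.values[2:]]),
                             base.stimuli,
                             np.concatenate([base.animal, ["C", "C"]]))
        out2 = normalize_matrix(dup)
        assert np.allclose(out1.values[:2], out2.values[:2])

    def test_constant_row_zeroed(self):
        raw = ResponseMatrix(np.array([[1.0, 1.0], [0.0, 2.0]]), ("a", "b"),
                             np.array(["A", "A"]))
        with pytest.warns(UserWarning):
            out = normalize_matrix(raw)
        assert np.allclose(out.values[0], 0.0)


class TestVRC:
    def test_hand_case_200(self):
        assert vrc([0, 1, 10, 11], [0, 0, 1, 1]) == pytest.approx(200.0)

    def test_hand_case_50(self):
        assert vrc([0, 2, 10, 12], [0, 0, 1, 1]) == pytest.approx(50.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(10, 200)
            d = rng.integers(1, 6)
            k = rng.integers(2, 6)
            pts = rng.normal(size=(n, d))
            labels = rng.integers(0, k, size=n)
            if np.unique(labels).size < 2:
                continue
            assert vrc(pts, labels) == pytest.approx(
                brute_force_vrc(pts, labels), abs=1e-10, rel=1e-10)

    def test_random_labels_near_one_below_true_split(self):
        rng = np.random.default_rng(1)
        pts = np.concatenate([rng.normal(0, 1, 100), rng.normal(8, 1, 100)])
        true = np.repeat([0, 1], 100)
        rand_vals = [vrc(pts, rng.permutation(true)) for _ in range(20)]
        assert np.mean(rand_vals) < 2.0
        assert vrc(pts, true) > 10 * np.mean(rand_vals)

    def test_zero_ssw_is_infinite(self):
        assert vrc([0, 0, 1, 1], [0, 0, 1, 1]) == np.inf

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            vrc([1, 2, 3], [0, 0, 0])


def _curve(k, v):
    k = np.asarray(k, float)
    v = np.asarray(v, float)
    return VRCCurve(k, v, np.zeros_like(v), np.zeros_like(v), N=100)


class TestElbow:
    def test_linear_curve_ties_to_smallest_k(self):
        k = np.arange(2, 21)
        assert choose_k_elbow(_curve(k, 100 - 3 * k)) == 2

    def test_single_corner(self):
        k = np.arange(2, 21)
        v = np.where(k <= 6, 400 - 50 * k, 100 - 0.5 * k)
        assert choose_k_elbow(_curve(k, v)) == 6

    def test_scale_invariance_of_exponential_decay(self):
        k = np.arange(2, 21)
        v = 500 * np.exp(-0.4 * k)
        best = choose_k_elbow(_curve(k, v))
        assert 2 < best < 20
        scaled = choose_k_elbow(_curve(k * 3, v * 3))
        assert scaled == best * 3

    def test_non_finite_excluded(self):
        k = np.arange(2, 8)
        v = np.array([np.inf, 30, 20, 15, 12, 11.0])
        with pytest.warns(UserWarning):
            best = choose_k_elbow(_curve(k, v))
        assert 3 <= best <= 7


class TestClusterVectors:
    def _planted(self, seed=0, noise=0.05, rows_per=50):
        # six +-1 archetype tuning patterns, pairwise Hamming distance >= 4
        rng = np.random.default_rng(seed)
        arch = []
        while len(arch) < 6:
            cand = rng.choice([-1.0, 1.0], size=len(STIMULI))
            if all((cand != a).sum() >= 4 for a in arch):
                arch.append(cand)
        arch = np.array(arch)
        labels = np.repeat(np.arange(6), rows_per)
        vals = arch[labels] + rng.normal(0, noise, (6 * rows_per, len(STIMULI)))
        perm = rng.permutation(vals.shape[0])
        vals, labels = vals[perm], labels[perm]
        animals = np.repeat([f"an{i}" for i in range(10)], 6 * rows_per // 10)
        return ResponseMatrix(vals, STIMULI, animals), labels

    def test_recovers_planted_archetypes(self):
        mat, truth = self._planted()
        labels, centroids, curve = cluster_vectors(mat, n_replicates=20, seed=0)
        assert curve.chosen_k == 6
        assert adjusted_rand_score(truth, labels) > 0.95
        assert centroids.shape == (6, len(STIMULI))

    def test_duplicated_rows_keep_centroids(self):
        mat, _ = self._planted(rows_per=20)
        dup = ResponseMatrix(np.vstack([mat.values, mat.values]), mat.stimuli,
                             np.concatenate([mat.animal, mat.animal]))
        _, c1, _ = cluster_vectors(mat, k_range=[6], n_replicates=20, seed=0)
        _, c2, _ = cluster_vectors(dup, k_range=[6], n_replicates=20, seed=0)
        order1 = np.lexsort(c1.T)
        order2 = np.lexsort(c2.T)
        assert np.allclose(c1[order1], c2[order2], atol=1e-6)

    def test_deterministic_under_seed(self):
        mat, _ = self._planted()
        l1, _, _ = cluster_vectors(mat, n_replicates=10, seed=3)
        l2, _, _ = cluster_vectors(mat, n_replicates=10, seed=3)
        assert np.array_equal(l1, l2)

    def test_too_few_rows_rejected(self):
        mat = ResponseMatrix(np.random.default_rng(0).random((3, 4)),
                             ("a", "b", "c", "d"), np.array(["A"] * 3))
        with pytest.raises(ValueError):
            cluster_vectors(mat, k_range=[5])


class TestMixtureSpecific:
    def _flags(self, rows):
        return pd.DataFrame(rows, columns=["LaaLct", "Laa", "Lct"]).astype(bool)

    def test_no_specific_units(self):
        flags = self._flags([[1, 1, 0], [1, 0, 1], [0, 0, 0]])
        assert mixture_specific_fraction(flags, "LaaLct", ("Laa", "Lct")) == 0.0

    def test_counting(self):
        rows = [[1, 0, 0]] * 3 + [[1, 1, 0]] * 7 + [[0, 1, 1]] * 5
        frac = mixture_specific_fraction(self._flags(rows), "LaaLct",
                                         ("Laa", "Lct"))
        assert frac == pytest.approx(0.3)

    def test_planted_population_within_binomial_ci(self):
        rng = np.random.default_rng(0)
        n = 400
        specific = rng.random(n) < 0.2
        rows = np.zeros((n, 3), bool)
        rows[:, 0] = True
        rows[~specific, 1] = True
        frac = mixture_specific_fraction(self._flags(rows), "LaaLct",
                                         ("Laa", "Lct"))
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < 3 * se

    def test_zero_denominator_flagged(self):
        flags = self._flags([[0, 1, 0], [0, 0, 1]])
        with pytest.warns(UserWarning):
            frac = mixture_specific_fraction(flags, "LaaLct", ("Laa", "Lct"))
        assert np.isnan(frac)


class TestConsistency:
    def _maps(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        patterns = {o: rng.random((16, 16)) for o in ("Oct", "Laa", "Hex")}
        return {o: [patterns[o] + rng.normal(0, noise, (16, 16))
                    for _ in range(5)] for o in patterns}

    def test_identical_within_distinct_between(self):
        res = consistency_analysis(self._maps(noise=0.0))
        assert res.within == pytest.approx(0.0, abs=1e-9)
        assert res.between > 0
        assert res.cophenetic > 0.99
        assert res.newick.endswith(";")

    def test_all_identical_maps(self):
        m = np.random.default_rng(1).random((8, 8))
        maps = {o: [m] * 3 for o in ("a", "b")}
        res = consistency_analysis(maps)
        assert res.within == pytest.approx(0.0, abs=1e-9)
        assert res.between == pytest.approx(0.0, abs=1e-9)

    def test_margin_grows_as_noise_shrinks(self):
        margins = []
        for noise in (0.3, 0.1, 0.02):
            res = consistency_analysis(self._maps(noise=noise, seed=2))
            margins.append(res.between - res.within)
            assert res.within < res.between
        assert margins[0] < margins[1] < margins[2]

    def test_single_trials_rejected(self):
        maps = {o: [np.random.default_rng(0).random((4, 4))]
                for o in ("a", "b")}
        with pytest.raises(ValueError):
            consistency_analysis(maps)


def test_linkage_to_newick_leaf_names():
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import pdist

    pts = np.array([[0.0], [0.1], [5.0]])
    Z = average(pdist(pts))
    nwk = linkage_to_newick(Z, ["x", "y", "z"])
    assert set("xyz") <= set(nwk)
    assert nwk.count("(") == 2
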