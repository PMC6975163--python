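"""Gene collapsing, k-means clustering, PCoA, cluster classifier, and the
two curation metrics."""

import itertools

import numpy as np
import pytest

from gemcurate import (
    Ensemble,
    EssentialityMatrix,
    ValidationError,
    cluster_members,
    cluster_ratio,
    collapse_correlated_genes,
    compute_curation_metrics,
    curation_targets,
    fractional_importance,
    pcoa_hamming,
    train_cluster_classifier,
)
from gemcurate.curation import CurationMetrics, holdout_accuracy


def _matrix(values, genes=None, members=None):
    values = np.asarray(values, dtype=bool)
    return EssentialityMatrix(
        values=values,
        genes=genes or [f"g{j}" for j in range(values.shape[1])],
        member_ids=members or [f"m{i}" for i in range(values.shape[0])],
        threshold=1e-6,
        medium_name="complete",
    )


class TestCollapse:
    def test_identical_columns_merge(self):
        matrix = _matrix(
            [[1, 1, 0], [0, 0, 0], [1, 1, 1]], genes=["g1", "g2", "g3"]
        )
        reduced, reps, groups = collapse_correlated_genes(matrix)
        assert reduced.shape == (3, 2)
        assert groups == [["g1", "g2"], ["g3"]]
        assert reps == ["g1", "g3"]

    def test_constant_columns_dropped(self):
        matrix = _matrix([[1, 1], [1, 0]], genes=["always", "varies"])
        reduced, reps, _ = collapse_correlated_genes(matrix)
        assert reps == ["varies"]
        assert reduced.shape == (2, 1)

    def test_all_constant_rejected(self):
        matrix = _matrix([[1, 0], [1, 0]])
        with pytest.raises(ValidationError, match="no variable"):
            collapse_correlated_genes(matrix)

    def test_groups_match_pairwise_equality_oracle(self, rng):
        """Reduced columns equal the equivalence classes of exact column
        equality, per O(n²) pairwise comparison."""
        for trial in range(10):
            values = rng.random((8, 10)) < 0.5
            matrix = _matrix(values)
            variable = [
                j for j in range(10)
                if values[:, j].any() and not values[:, j].all()
            ]
            if not variable:
                continue
            _, _, groups = collapse_correlated_genes(matrix)
            # oracle: union-find by pairwise equality over variable columns
            classes = []
            for j in variable:
                for cls in classes:
                    if np.array_equal(values[:, j], values[:, cls[0]]):
                        cls.append(j)
                        break
                else:
                    classes.append([j])
            oracle = [[f"g{j}" for j in cls] for cls in classes]
            assert sorted(map(tuple, groups)) == sorted(map(tuple, oracle))


class TestKMeans:
    def test_two_point_masses_recovered(self):
        X = np.array([[0, 0]] * 5 + [[1, 1]] * 4, dtype=float)
        members = [f"m{i}" for i in range(9)]
        asg = cluster_members(X, members, seed=0)
        labels = asg.label_array(members)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[-1]
        assert asg.inertia == pytest.approx(0.0, abs=1e-12)

    def test_fewer_distinct_rows_than_k_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValidationError, match="distinct"):
            cluster_members(X, [f"m{i}" for i in range(4)])

    def test_inertia_matches_exhaustive_best_partition(self, rng):
        """k-means inertia equals the best over all 2-partitions of ≤ 10
        members (exhaustive oracle)."""
        for trial in range(5):
            n = 8
            X = (rng.random((n, 4)) < 0.5).astype(float)
            if len({tuple(r) for r in X}) < 2:
                continue
            members = [f"m{i}" for i in range(n)]
            asg = cluster_members(X, members, seed=trial)
            best = np.inf
            for assignment in itertools.product([0, 1], repeat=n):
                assignment = np.array(assignment)
                if assignment.min() == assignment.max():
                    continue
                inertia = sum(
                    ((X[assignment == c] - X[assignment == c].mean(0)) ** 2).sum()
                    for c in (0, 1)
                )
                best = min(best, inertia)
            assert asg.inertia == pytest.approx(best, abs=1e-9)


class TestPcoa:
    def test_two_maximally_different_members(self):
        matrix = _matrix([[1, 1, 1], [0, 0, 0]])
        res = pcoa_hamming(matrix)
        assert res.explained_fraction[0] == pytest.approx(1.0)
        # Hamming distance 1 apart → coordinates ±0.5 on the single axis
        assert abs(res.coordinates[0, 0] - res.coordinates[1, 0]) == pytest.approx(1.0)

    def test_identical_members_degenerate_to_zero(self):
        matrix = _matrix([[1, 0], [1, 0], [1, 0]])
        res = pcoa_hamming(matrix)
        assert np.allclose(res.coordinates, 0.0)
        assert np.allclose(res.explained_fraction, 0.0)

    def test_explained_fractions_non_increasing(self, rng):
        matrix = _matrix(rng.random((6, 8)) < 0.5)
        res = pcoa_hamming(matrix)
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)
        assert np.all(res.explained_fraction >= 0)

    def test_matches_gram_matrix_eigendecomposition_oracle(self, rng):
        """Coordinates agree (up to axis sign) with an independent
        double-centering + eigh implementation on random 6×8 matrices."""
        from scipy.spatial.distance import pdist, squareform

        for trial in range(5):
            values = rng.random((6, 8)) < 0.5
            if len({tuple(r) for r in values}) < 2:
                continue
            matrix = _matrix(values)
            res = pcoa_hamming(matrix)
            D = squareform(pdist(values.astype(float), metric="hamming"))
            n = D.shape[0]
            J = np.eye(n) - np.ones((n, n)) / n
            B = -0.5 * J @ (D**2) @ J
            eigval, eigvec = np.linalg.eigh(B)
            order = np.argsort(eigval)[::-1]
            eigval, eigvec = eigval[order], eigvec[:, order]
            pos = eigval > 1e-10
            oracle = eigvec[:, pos] * np.sqrt(eigval[pos])
            k = oracle.shape[1]
            got = res.coordinates[:, :k]
            for axis in range(k):
                a, b = got[:, axis], oracle[:, axis]
                assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)
            expl = eigval[pos] / eigval[pos].sum()
            assert np.allclose(res.explained_fraction[:k], expl, atol=1e-8)


class TestClassifier:
    def _separable(self, rng, n=200, n_noise=10):
        labels = rng.integers(0, 2, n)
        features = rng.random((n, 1 + n_noise)) < 0.5
        features[:, 0] = labels.astype(bool)  # perfect separator
        return features, labels

    def test_separable_fixture_high_oob(self, rng):
        features, labels = self._separable(rng)
        _, oob = train_cluster_classifier(features, labels, seed=0)
        assert oob > 0.95

    def test_shuffled_labels_oob_near_chance(self, rng):
        features, labels = self._separable(rng)
        rng.shuffle(labels)  # break the association
        features[:, 0] = rng.random(len(labels)) < 0.5
        _, oob = train_cluster_classifier(features, labels, seed=0)
        assert 0.4 <= oob <= 0.6

    def test_holdout_consistent_with_oob(self, rng):
        features, labels = self._separable(rng)
        _, oob = train_cluster_classifier(features, labels, seed=0)
        acc = holdout_accuracy(features, labels, seed=0)
        assert abs(acc - oob) < 0.1

    def test_single_class_rejected(self, rng):
        features = rng.random((10, 3)) < 0.5
        with pytest.raises(ValidationError, match="single class"):
            train_cluster_classifier(features, np.zeros(10, dtype=int))

    def test_importances_sum_to_one(self, rng):
        features, labels = self._separable(rng)
        clf, _ = train_cluster_classifier(features, labels, seed=0)
        imp = fractional_importance(clf, [f"r{j}" for j in range(features.shape[1])])
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in imp.values())

    def test_separator_ranks_first(self, rng):
        features, labels = self._separable(rng)
        clf, _ = train_cluster_classifier(features, labels, seed=0)
        imp = fractional_importance(clf, [f"r{j}" for j in range(features.shape[1])])
        assert max(imp, key=imp.get) == "r0"

    def test_single_feature_has_importance_one(self, rng):
        labels = rng.integers(0, 2, 50)
        features = labels.reshape(-1, 1).astype(bool)
        clf, _ = train_cluster_classifier(features, labels, seed=0)
        imp = fractional_importance(clf, ["only"])
        assert imp["only"] == pytest.approx(1.0)


class TestClusterRatio:
    @pytest.mark.parametrize(
        "f1,f2,expected",
        [(0.4, 0.2, 0.5), (0.3, 0.3, 0.0), (0.2, 0.0, 1.0)],
    )
    def test_printed_anchor_values(self, f1, f2, expected):
        """The three analytic anchors: twice-as-abundant → 0.5, even → 0,
        cluster-exclusive → 1."""
        n = 50  # members per cluster
        presence = np.concatenate([
            np.arange(n) < round(f1 * n), np.arange(n) < round(f2 * n)
        ]).reshape(-1, 1)
        labels = np.repeat([0, 1], n)
        out = cluster_ratio(presence, labels, ["rxn"])
        ratio, got_f1, got_f2 = out["rxn"]
        assert ratio == pytest.approx(expected, abs=1e-12)
        assert got_f1 == pytest.approx(f1)
        assert got_f2 == pytest.approx(f2)

    def test_symmetric_under_label_swap_and_member_order(self, rng):
        X = rng.random((30, 5)) < 0.5
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        ids = [f"r{j}" for j in range(5)]
        a = cluster_ratio(X, labels, ids)
        b = cluster_ratio(X, 1 - labels, ids)
        perm = rng.permutation(30)
        c = cluster_ratio(X[perm], labels[perm], ids)
        for rid in a:
            assert a[rid][0] == pytest.approx(b[rid][0])
            assert a[rid][0] == pytest.approx(c[rid][0])

    def test_absent_everywhere_excluded(self):
        X = np.zeros((10, 1), dtype=bool)
        labels = np.repeat([0, 1], 5)
        assert cluster_ratio(X, labels, ["dead"]) == {}

    def test_empty_cluster_rejected(self):
        X = np.ones((4, 1), dtype=bool)
        with pytest.raises(ValidationError):
            cluster_ratio(X, np.zeros(4, dtype=int), ["r"])


class TestCurationTargets:
    def _metrics(self, rows):
        import pandas as pd

        table = pd.DataFrame(
            rows,
            columns=["reaction_id", "fractional_importance", "cluster_ratio",
                     "f1", "f2"],
        ).set_index("reaction_id")
        return CurationMetrics(table, oob_accuracy=1.0)

    def test_sorted_by_importance_then_ratio_then_id(self):
        metrics = self._metrics([
            ("rB", 0.3, 0.1, 0.1, 0.2),
            ("rA", 0.3, 0.1, 0.1, 0.2),
            ("rC", 0.3, 0.9, 0.0, 0.2),
            ("rD", 0.1, 1.0, 0.0, 0.2),
        ])
        out = curation_targets(metrics)
        assert out["reaction_id"].tolist() == ["rC", "rA", "rB", "rD"]

    def test_top_larger_than_table_returns_all(self):
        metrics = self._metrics([("rA", 0.6, 1.0, 0.0, 0.5),
                                 ("rB", 0.4, 0.0, 0.5, 0.5)])
        assert len(curation_targets(metrics, top=10)) == 2


class TestEndToEndRecovery:
    def test_splitter_recovered_on_split_ensemble(
        self, split_ensemble, split_essentiality
    ):
        """Parameter recovery: the engineered splitter attains cluster
        ratio 1 and the top fractional importance; k-means recovers the
        split; OOB accuracy is high."""
        ensemble, truth = split_ensemble
        reduced, _, groups = collapse_correlated_genes(split_essentiality)
        assert groups == [["gA", "gD"]]
        asg = cluster_members(reduced, split_essentiality.member_ids, seed=0,
                              collapsed_groups=groups)
        labels = asg.label_array(ensemble.member_ids)
        split = truth["splitter_present"]
        assert max((labels == split).mean(), (labels != split).mean()) == 1.0
        metrics = compute_curation_metrics(ensemble, asg, seed=0)
        top = curation_targets(metrics)
        assert top.iloc[0]["reaction_id"] == truth["splitter"]
        assert top.iloc[0]["cluster_ratio"] == pytest.approx(1.0)
        assert metrics.oob_accuracy > 0.95
        assert metrics.table["fractional_importance"].sum() == pytest.approx(
            1.0, abs=1e-9
        )
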