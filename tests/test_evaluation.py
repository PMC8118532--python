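"""Validation battery: splits, baselines, metrics, similarity structure."""

import numpy as np
import pandas as pd
import pytest

import cogdecode as cd
from cogdecode.evaluation import (
    SplitError,
    accuracy_per_study,
    balanced_accuracy_per_contrast,
    split_corpus,
)
from cogdecode.functional_units import Dictionary
from tests.conftest import make_study


class TestHalfSplits:
    def test_even_split_disjoint_and_exhaustive(self, tiny_corpus):
        splits = cd.subject_half_splits(tiny_corpus, n_repeats=3, seed=0)
        assert splits.n_repeats == 3
        for assignment in splits.assignments:
            for study in tiny_corpus.studies:
                train, test = assignment[study.study_id]
                subjects = np.unique(study.subject_ids)
                assert len(set(train) & set(test)) == 0
                assert sorted(np.concatenate([train, test])) == sorted(subjects)
                assert abs(len(train) - len(test)) <= 1

    def test_every_contrast_on_both_sides(self, tiny_corpus):
        splits = cd.subject_half_splits(tiny_corpus, n_repeats=5, seed=1)
        for assignment in splits.assignments:
            train_c, test_c = split_corpus(tiny_corpus, assignment)
            for tr, te in zip(train_c.studies, test_c.studies):
                assert set(tr.labels) == set(range(1, tr.n_contrasts + 1))
                assert set(te.labels) == set(range(1, te.n_contrasts + 1))

    def test_deterministic(self, tiny_corpus):
        a = cd.subject_half_splits(tiny_corpus, n_repeats=4, seed=9)
        b = cd.subject_half_splits(tiny_corpus, n_repeats=4, seed=9)
        for ra, rb in zip(a.assignments, b.assignments):
            for sid in ra:
                np.testing.assert_array_equal(ra[sid][0], rb[sid][0])
                np.testing.assert_array_equal(ra[sid][1], rb[sid][1])

    def test_infeasible_coverage_raises(self):
        # contrast 2 exists only for subject 0: no half-split can cover it
        # on both sides.
        study = make_study(
            maps=np.zeros((3, 5)),
            labels=[1, 2, 1],
            subject_ids=[0, 0, 1],
            names=["a", "b"],
        )
        include = np.zeros((5, 1, 1), dtype=bool)
        include[:5, 0, 0] = True
        mask = cd.BrainMask(include=include, affine=np.eye(4))
        corpus = cd.MultiStudyCorpus(studies=[study], mask=mask)
        with pytest.raises(SplitError, match="could not cover"):
            cd.subject_half_splits(corpus, n_repeats=1, seed=0)


class TestBaselines:
    def test_separable_toy_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        n = 40
        X = rng.normal(size=(n, 10)) * 0.1
        y = np.array([1, 2] * (n // 2))
        X[:, 0] += np.where(y == 1, 5.0, -5.0)
        study = make_study(X, y, np.arange(n), ["a", "b"])
        baseline = cd.fit_baseline(study, mode="voxel")
        assert np.mean(baseline.predict(X) == y) == 1.0

    def test_voxel_equals_network_with_identity_dictionary(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        y = np.array([1, 2, 3, 4] * 5)
        study = make_study(X, y, np.arange(20), list("abcd"))
        vox = cd.fit_baseline(study, mode="voxel")
        net = cd.fit_baseline(
            study, mode="network", dictionary=Dictionary(D=np.eye(6)),
            standardize=False,
        )
        rng2 = np.random.default_rng(2)
        probe = rng2.normal(size=(30, 6))
        np.testing.assert_array_equal(vox.predict(probe), net.predict(probe))

    def test_single_class_fold_rejected(self):
        study = make_study(np.zeros((4, 3)), [1, 1, 1, 1], [0, 1, 2, 3], ["a", "b"])
        with pytest.raises(ValueError, match="single-class"):
            cd.fit_baseline(study, mode="voxel")

    def test_network_mode_requires_dictionary(self):
        study = make_study(np.zeros((4, 3)), [1, 2, 1, 2], [0, 1, 2, 3], ["a", "b"])
        with pytest.raises(ValueError, match="requires a dictionary"):
            cd.fit_baseline(study, mode="network")


class TestAccuracyMetrics:
    def test_plain_accuracy(self):
        assert accuracy_per_study(np.array([1, 2, 3]), np.array([1, 2, 3])) == 1.0
        assert np.isclose(
            accuracy_per_study(np.array([1, 2, 1]), np.array([1, 2, 3])), 2 / 3
        )
        with pytest.raises(ValueError):
            accuracy_per_study(np.array([1]), np.array([1, 2]))

    def test_random_predictor_near_chance(self):
        rng = np.random.default_rng(0)
        n, c = 2000, 4
        truth = rng.integers(1, c + 1, size=n)
        pred = rng.integers(1, c + 1, size=n)
        acc = accuracy_per_study(pred, truth)
        assert abs(acc - 0.25) <= 3 * np.sqrt(0.25 * 0.75 / n)

    def test_balanced_accuracy_hand_example(self):
        # contrast 1: TP=1, FN=1, TN=2, FP=0 -> (0.5 + 1.0)/2 = 0.75
        out = balanced_accuracy_per_contrast(
            np.array([1, 2, 2, 3]), np.array([1, 1, 2, 3]), 3
        )
        assert np.isclose(out[1], 0.75)
        # contrast 2: TP=1, FN=0, TN=2, FP=1 -> (1.0 + 2/3)/2 = 5/6
        assert np.isclose(out[2], 5 / 6)
        assert np.isclose(out[3], 1.0)

    def test_perfect_predictions(self):
        out = balanced_accuracy_per_contrast(np.array([1, 2, 3]), np.array([1, 2, 3]), 3)
        assert all(np.isclose(v, 1.0) for v in out.values())

    def test_uniform_random_is_half(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(1, 6, size=5000)
        pred = rng.integers(1, 6, size=5000)
        out = balanced_accuracy_per_contrast(pred, truth, 5)
        for v in out.values():
            assert abs(v - 0.5) < 0.03

    def test_absent_contrast_is_nan_not_zero(self):
        out = balanced_accuracy_per_contrast(np.array([1, 1]), np.array([1, 1]), 2)
        assert np.isnan(out[2])


class TestTransferSummary:
    @staticmethod
    def _table(deltas):
        rows = []
        for i, d in enumerate(deltas):
            rows.append({"repeat": i, "study": "s", "method": "a", "accuracy": 0.5 + d})
            rows.append({"repeat": i, "study": "s", "method": "b", "accuracy": 0.5})
        return pd.DataFrame(rows)

    def test_identical_tables_give_zero(self):
        table = self._table([0.0, 0.0])
        out = cd.transfer_gain_summary(table, "a", "b")
        assert out["mean_gain"] == 0.0
        assert out["fraction_experiments_improved"] == 0.0

    def test_arithmetic_example(self):
        out = cd.transfer_gain_summary(self._table([0.1, 0.1, -0.1, 0.1]), "a", "b")
        assert np.isclose(out["mean_gain"], 0.05)
        assert np.isclose(out["median_gain"], 0.1)
        assert np.isclose(out["fraction_experiments_improved"], 0.75)

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(2)
        rows = []
        for rep in range(5):
            for study in ("s1", "s2", "s3"):
                for method in ("a", "b"):
                    rows.append(
                        {
                            "repeat": rep,
                            "study": study,
                            "method": method,
                            "accuracy": rng.random(),
                        }
                    )
        table = pd.DataFrame(rows)
        out = cd.transfer_gain_summary(table, "a", "b")
        deltas = []
        for rep in range(5):
            for study in ("s1", "s2", "s3"):
                sel = table[(table["repeat"] == rep) & (table["study"] == study)]
                a = sel[sel["method"] == "a"]["accuracy"].iloc[0]
                b = sel[sel["method"] == "b"]["accuracy"].iloc[0]
                deltas.append(a - b)
        deltas = np.array(deltas)
        assert np.isclose(out["mean_gain"], deltas.mean(), atol=1e-12)
        assert np.isclose(out["median_gain"], np.median(deltas), atol=1e-12)
        assert np.isclose(
            out["fraction_experiments_improved"], (deltas > 0).mean(), atol=1e-12
        )

    def test_coverage_mismatch_rejected(self):
        table = self._table([0.1])
        table = table[~((table["method"] == "b") & (table["repeat"] == 0))]
        extra = pd.DataFrame(
            [{"repeat": 1, "study": "s", "method": "b", "accuracy": 0.5}]
        )
        with pytest.raises(ValueError, match="cover"):
            cd.transfer_gain_summary(pd.concat([table, extra]), "a", "b")


class TestLearningCurve:
    def test_deterministic_and_clipping(self, tiny_corpus, tiny_dictionary):
        cfg = cd.TrainConfig(latent_dim=3, n_epochs=10, seed=0)
        a = cd.learning_curve(
            tiny_corpus, tiny_dictionary, cfg, subject_counts=[2, 99],
            n_repeats=1, seed=0,
        )
        b = cd.learning_curve(
            tiny_corpus, tiny_dictionary, cfg, subject_counts=[2, 99],
            n_repeats=1, seed=0,
        )
        pd.testing.assert_frame_equal(a, b)
        assert a[a["n_subjects_requested"] == 99]["clipped"].all()
        assert not a[a["n_subjects_requested"] == 2]["clipped"].any()

    def test_full_count_matches_standard_evaluation(self, tiny_corpus, tiny_dictionary):
        """Requesting more subjects than available degenerates to the plain
        half-split evaluation."""
        cfg = cd.TrainConfig(latent_dim=3, n_epochs=10, seed=0)
        curve = cd.learning_curve(
            tiny_corpus, tiny_dictionary, cfg, subject_counts=[99], n_repeats=1, seed=3
        )
        splits = cd.subject_half_splits(tiny_corpus, n_repeats=1, seed=3)
        scores = cd.evaluate_methods(
            tiny_corpus, tiny_dictionary, cfg, splits, methods=("multistudy", "voxel")
        )
        merged = curve.merge(
            scores.accuracy, on=["repeat", "study", "method"], suffixes=("_lc", "_std")
        )
        assert len(merged) == len(curve)
        np.testing.assert_allclose(
            merged["accuracy_lc"], merged["accuracy_std"], atol=1e-12
        )


class TestChanceCalibration:
    def test_untrained_model_chance_levels(self, tiny_corpus, tiny_dictionary):
        cfg = cd.TrainConfig(latent_dim=3, n_epochs=0, seed=0)
        model = cd.train_multistudy(tiny_corpus, tiny_dictionary, cfg)
        for study in tiny_corpus.studies:
            pred = cd.predict(model, study.study_id, study.maps)
            acc = accuracy_per_study(pred, study.labels)
            assert np.isclose(acc, 1 / study.n_contrasts, atol=1e-12)
            bal = balanced_accuracy_per_contrast(pred, study.labels, study.n_contrasts)
            for v in bal.values():
                assert np.isclose(v, 0.5, atol=1e-12)


class TestSimilarityClustering:
    def test_two_tight_clusters_have_high_cophenetic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        maps = np.vstack([a, a + 1e-3 * rng.normal(size=30),
                          b, b + 1e-3 * rng.normal(size=30)])
        report = cd.similarity_clustering(maps, list("pqrs"))
        assert report.cophenetic_coefficient > 0.99
        np.testing.assert_allclose(np.diag(report.cosine), 1.0)

    def test_matches_brute_force_average_linkage_and_cophenet(self):
        """Independent brute-force agglomeration reproduces the cophenetic
        coefficient to 1e-10 on 10 random maps."""
        rng = np.random.default_rng(1)
        maps = rng.normal(size=(10, 25))
        report = cd.similarity_clustering(maps, [f"m{i}" for i in range(10)])

        # brute-force average-linkage agglomeration
        unit = maps / np.linalg.norm(maps, axis=1, keepdims=True)
        dist = 1.0 - unit @ unit.T
        clusters = {i: [i] for i in range(10)}
        coph = np.zeros((10, 10))
        active = list(range(10))
        while len(active) > 1:
            best = None
            for i in active:
                for j in active:
                    if i < j:
                        d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                        if best is None or d < best[0]:
                            best = (d, i, j)
            d, i, j = best
            for a in clusters[i]:
                for b in clusters[j]:
                    coph[a, b] = coph[b, a] = d
            clusters[i] = clusters[i] + clusters[j]
            active.remove(j)
        iu = np.triu_indices(10, k=1)
        orig = dist[iu]
        expect = np.corrcoef(orig, coph[iu])[0, 1]
        assert np.isclose(report.cophenetic_coefficient, expect, atol=1e-10)
        assert np.isclose(
            report.mean_abs_cosine, np.mean(np.abs((unit @ unit.T)[iu])), atol=1e-12
        )

    def test_newick_export_covers_all_maps(self):
        rng = np.random.default_rng(2)
        maps = rng.normal(size=(5, 12))
        names = [f"map{i}" for i in range(5)]
        report = cd.similarity_clustering(maps, names)
        newick = report.to_newick()
        for name in names:
            assert name in newick

    def test_error_paths(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="at least 3"):
            cd.similarity_clustering(rng.normal(size=(2, 5)), ["a", "b"])
        maps = rng.normal(size=(4, 5))
        maps[2] = 0.0
        with pytest.raises(ValueError, match="zero-norm"):
            cd.similarity_clustering(maps, list("abcd"))
        with pytest.raises(ValueError, match="undefined"):
            cd.similarity_clustering(np.eye(4), list("abcd"))
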