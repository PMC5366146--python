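import numpy as np
import pandas as pd
import pytest

from cofunmir import (
    ExpressionStudy,
    PairSample,
    SimilarityMatrix,
    ensemble_predict,
    evaluate,
    fold_changes,
    permutation_test,
    predict,
    sample_balanced_negatives,
    select_negatives,
    train,
)
from cofunmir.errors import (
    DegenerateTrainingError,
    InvalidInputError,
    SamplingError,
)


def make_study(data: dict[str, list[float]], n_case: int, disease="d1", study_id="s1"):
    samples = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(len(next(iter(data.values()))) - n_case)]
    expr = pd.DataFrame(data, index=samples).T
    groups = {s: ("case" if s.startswith("c") else "control") for s in samples}
    return ExpressionStudy(disease=disease, expression=expr, groups=groups, study_id=study_id)


@pytest.fixture()
def separable_similarities():
    """Block similarities: within-group 0.9, cross-group 0.1, diagonal 1."""
    def block(ids_a, ids_b):
        ids = ids_a + ids_b
        n = len(ids)
        values = np.full((n, n), 0.1)
        values[: len(ids_a), : len(ids_a)] = 0.9
        values[len(ids_a):, len(ids_a):] = 0.9
        np.fill_diagonal(values, 1.0)
        return SimilarityMatrix(ids, values)

    dis = block([f"pd{i}" for i in range(4)], [f"nd{i}" for i in range(4)])
    mir = block([f"pm{i}" for i in range(2)], [f"nm{i}" for i in range(2)])
    return dis, mir


@pytest.fixture()
def separable_samples(separable_similarities):
    positives = [PairSample(f"pd{i}", f"pm{j}", 1) for i in range(4) for j in range(2)]
    negatives = [PairSample(f"nd{i}", f"nm{j}", -1) for i in range(4) for j in range(2)]
    return positives + negatives


# ---------------------------------------------------------------------------
# fold changes and negative selection
# ---------------------------------------------------------------------------

class TestFoldChanges:
    def test_identical_groups_zero(self):
        study = make_study({"m1": [3.0, 3.0, 3.0, 3.0]}, n_case=2)
        assert fold_changes(study)["m1"] == pytest.approx(0.0)

    def test_doubled_case_mean_is_one(self):
        study = make_study({"m1": [4.0, 4.0, 2.0, 2.0]}, n_case=2)
        assert fold_changes(study)["m1"] == pytest.approx(1.0, abs=1e-7)

    def test_single_sample_groups_defined(self):
        study = make_study({"m1": [8.0, 2.0]}, n_case=1)
        assert fold_changes(study)["m1"] == pytest.approx(2.0, abs=1e-7)

    def test_all_zero_row_uses_pseudocount(self, caplog):
        study = make_study({"m1": [0.0, 0.0]}, n_case=1)
        with caplog.at_level("WARNING"):
            fc = fold_changes(study)
        assert fc["m1"] == pytest.approx(0.0)
        assert "pseudocount" in caplog.text

    def test_group_validation(self):
        with pytest.raises(InvalidInputError):
            make_study({"m1": [1.0, 2.0]}, n_case=2)  # no control


class TestSelectNegatives:
    def test_planted_counts(self):
        """10 flat miRNAs, 5 dysregulated, 2 flat ones positive: 8 survive."""
        data = {}
        for i in range(1, 6):  # m1..m5 dysregulated (2-fold)
            data[f"m{i}"] = [4.0, 4.0, 2.0, 2.0]
        for i in range(6, 16):  # m6..m15 flat
            data[f"m{i}"] = [2.0, 2.0, 2.0, 2.0]
        study = make_study(data, n_case=2, disease="d1")
        positives = [PairSample("d1", "m6", 1), PairSample("d1", "m7", 1)]
        # the other flat miRNAs are positive for a different disease, so the
        # positive-entity refinement keeps them
        positives += [PairSample("d2", f"m{i}", 1) for i in range(8, 16)]
        negs = select_negatives([study], positives, threshold=0.05)
        assert negs.pairs == {("d1", f"m{i}") for i in range(8, 16)}
        assert len(negs) == 8

    def test_flat_positive_pair_excluded(self):
        study = make_study({"m1": [2.0, 2.0]}, n_case=1)
        negs = select_negatives([study], [PairSample("d1", "m1", 1)])
        assert len(negs) == 0

    def test_flat_nonpositive_pair_included(self):
        study = make_study({"m1": [2.0, 2.0], "m2": [2.0, 2.0]}, n_case=1)
        positives = [PairSample("d1", "m2", 1), PairSample("d9", "m1", 1)]
        negs = select_negatives([study], positives)
        assert ("d1", "m1") in negs.pairs

    def test_no_studies_rejected(self):
        with pytest.raises(InvalidInputError):
            select_negatives([], [])

    def test_disjoint_from_positives(self, default_fixture):
        fx = default_fixture
        negs = select_negatives(fx.studies, fx.positives)
        assert not negs.pairs & {(p.disease, p.mirna) for p in fx.positives}
        assert len(negs) > 0

    def test_pool_too_small_for_balancing(self):
        study = make_study({"m1": [2.0, 2.0]}, n_case=1)
        negs = select_negatives([study], [PairSample("d9", "m1", 1)])
        with pytest.raises(SamplingError):
            sample_balanced_negatives(negs, 5, seed=0)


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

class TestTrainPredict:
    def test_separable_training_accuracy(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        model = train(separable_samples, "average", dis, mir, seed=0)
        records = predict(model, separable_samples, dis, mir)
        by_pair = {(r.disease, r.mirna): r for r in records}
        for s in separable_samples:
            assert by_pair[(s.disease, s.mirna)].label == s.label

    def test_training_positive_scores_high(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        model = train(separable_samples, "average", dis, mir, seed=0)
        records = predict(model, [PairSample("pd0", "pm0")], dis, mir)
        assert records[0].probability > 0.5

    def test_same_seed_identical_predictions(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        cands = [PairSample("pd1", "nm0"), PairSample("nd2", "pm1")]
        runs = []
        for _ in range(2):
            model = train(separable_samples, "sqrt", dis, mir, seed=42)
            runs.append(predict(model, cands, dis, mir))
        assert [(r.disease, r.mirna, r.label, r.probability, r.rank) for r in runs[0]] == \
               [(r.disease, r.mirna, r.label, r.probability, r.rank) for r in runs[1]]

    def test_single_class_rejected(self, separable_similarities):
        dis, mir = separable_similarities
        samples = [PairSample(f"pd{i}", "pm0", 1) for i in range(3)]
        with pytest.raises(DegenerateTrainingError):
            train(samples, "average", dis, mir)

    def test_ranks_are_permutation(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        model = train(separable_samples, "average", dis, mir, seed=0)
        cands = [PairSample(d, m) for d in dis.ids for m in mir.ids]
        records = predict(model, cands, dis, mir)
        assert sorted(r.rank for r in records) == list(range(1, len(cands) + 1))
        probs = [r.probability for r in records]
        assert probs == sorted(probs, reverse=True)

    def test_labels_match_decision_sign(self, separable_similarities, separable_samples):
        """Predicted labels agree with the sign of the decision values."""
        from cofunmir.pairkernel import prediction_kernel

        dis, mir = separable_similarities
        model = train(separable_samples, "average", dis, mir, seed=0)
        cands = [PairSample(d, m) for d in dis.ids[:3] for m in mir.ids]
        records = predict(model, cands, dis, mir)
        pkm = prediction_kernel(cands, list(model.train_pairs), "average", dis, mir)
        decisions = model.classifier.decision_function(pkm.values)
        by_pair = {(r.disease, r.mirna): r.label for r in records}
        for cand, dec in zip(cands, decisions):
            expected = 1 if dec > 0 else -1
            assert by_pair[(cand.disease, cand.mirna)] == expected


class TestEnsemble:
    def test_single_model_strong_equals_positive_label(
        self, separable_similarities, separable_samples
    ):
        dis, mir = separable_similarities
        positives = [s for s in separable_samples if s.label == 1]
        pool = [s for s in separable_samples if s.label == -1]
        cands = [PairSample("pd3", "pm1"), PairSample("nd3", "nm1")]
        records = ensemble_predict(positives, pool, cands, dis, mir, n_models=1, seed=0)
        for r in records:
            assert r.strong == (r.label == 1)

    def test_separable_strong_set(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        positives = [s for s in separable_samples if s.label == 1]
        pool = [s for s in separable_samples if s.label == -1]
        cands = [PairSample("pd0", "pm1"), PairSample("nd0", "nm1")]
        records = ensemble_predict(positives, pool, cands, dis, mir, n_models=5, seed=1)
        by_pair = {(r.disease, r.mirna): r for r in records}
        assert by_pair[("pd0", "pm1")].strong is True
        assert by_pair[("nd0", "nm1")].strong is False
        assert by_pair[("pd0", "pm1")].rank == 1

    def test_deterministic_per_seed(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        positives = [s for s in separable_samples if s.label == 1]
        pool = [s for s in separable_samples if s.label == -1]
        cands = [PairSample("pd1", "pm0"), PairSample("nd1", "nm0")]
        a = ensemble_predict(positives, pool, cands, dis, mir, n_models=3, seed=9)
        b = ensemble_predict(positives, pool, cands, dis, mir, n_models=3, seed=9)
        assert [(r.probability, r.rank, r.strong) for r in a] == \
               [(r.probability, r.rank, r.strong) for r in b]

    def test_pool_smaller_than_positives(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        positives = [s for s in separable_samples if s.label == 1]
        pool = positives[:3]  # too small
        with pytest.raises(SamplingError):
            ensemble_predict(positives, pool, [PairSample("pd0", "pm0")], dis, mir, n_models=1)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

class TestEvaluate:
    def test_separable_loocv_perfect(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        report = evaluate(separable_samples, "loocv", "average", dis, mir, seed=0)
        assert report.auc == pytest.approx(1.0)
        assert report.accuracy == pytest.approx(1.0)
        assert report.sensitivity == pytest.approx(1.0)
        assert report.specificity == pytest.approx(1.0)

    def test_loocv_fold_count_equals_n(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        report = evaluate(separable_samples, "loocv", "average", dis, mir)
        assert len(report.fold_details) == len(separable_samples)

    def test_metrics_bounded(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        report = evaluate(separable_samples, "kfold", "sqrt", dis, mir, seed=1, k=4)
        for value in report.metrics().values():
            assert 0.0 <= value <= 1.0

    def test_random_labels_auc_near_half(self, default_fixture, default_similarities):
        """Labels independent of kernel structure give chance-level AUC."""
        fx = default_fixture
        dis, mir = default_similarities
        rng = np.random.default_rng(0)
        pool = fx.positives + fx.planted_negative_pairs
        idx = rng.choice(len(pool), size=32, replace=False)
        aucs = []
        for rep in range(10):
            labels = rng.permutation([1] * 16 + [-1] * 16)
            samples = [
                PairSample(pool[i].disease, pool[i].mirna, int(l))
                for i, l in zip(idx, labels)
            ]
            aucs.append(evaluate(samples, "kfold", "sqrt", dis, mir, seed=rep, k=4).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_k_exceeding_n_rejected(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        with pytest.raises(InvalidInputError):
            evaluate(separable_samples, "kfold", "average", dis, mir, k=len(separable_samples) + 1)

    def test_seeded_determinism(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        a = evaluate(separable_samples, "kfold", "sqrt", dis, mir, seed=3, k=4)
        b = evaluate(separable_samples, "kfold", "sqrt", dis, mir, seed=3, k=4)
        assert a.metrics() == b.metrics()


class TestPermutationTest:
    def test_observed_above_all_null(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        obs, null, p = permutation_test(
            separable_samples, 19, "kfold", "average", dis, mir, seed=0, k=4
        )
        assert obs == pytest.approx(1.0)
        assert len(null) == 19
        assert p == pytest.approx(1 / 20)

    def test_minimum_permutations_enforced(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        with pytest.raises(InvalidInputError):
            permutation_test(separable_samples, 5, "kfold", "average", dis, mir, k=4)

    def test_p_at_most_one(self, separable_similarities, separable_samples):
        dis, mir = separable_similarities
        _, _, p = permutation_test(
            separable_samples, 10, "kfold", "average", dis, mir, seed=2, k=4
        )
        assert 0.0 < p <= 1.0
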