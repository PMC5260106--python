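import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rwrscreen.errors import ValidationError
from rwrscreen.evaluation import (
    average_precision,
    kfold_split,
    knn_scores,
    precision_recall,
    run_cv,
    similarity_contrast,
)
from rwrscreen.propagation import LabelSet
from rwrscreen.similarity import (
    SimilarityMatrix,
    cosine_similarity,
    integrate_similarities,
    to_distance,
)
from rwrscreen.synthetic import SyntheticSpec, generate_network, generate_profiles

from conftest import make_network


def labeled_map(n_pos, n_neg):
    out = {f"pos{i}": "effective" for i in range(n_pos)}
    out.update({f"neg{i}": "ineffective" for i in range(n_neg)})
    return out


class TestKFoldSplit:
    def test_exact_division(self):
        folds = kfold_split(labeled_map(5, 5), k=5, seed=0)
        sizes = np.bincount(list(folds.fold_of.values()), minlength=5)
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_remainder_rule(self):
        folds = kfold_split(labeled_map(5, 6), k=5, seed=0)
        sizes = sorted(np.bincount(list(folds.fold_of.values()), minlength=5).tolist())
        assert sizes == [2, 2, 2, 2, 3]

    def test_same_seed_identical(self):
        a = kfold_split(labeled_map(10, 20), k=5, seed=7)
        b = kfold_split(labeled_map(10, 20), k=5, seed=7)
        assert a.fold_of == b.fold_of

    def test_stratification_balances_positives(self):
        labeled = labeled_map(7, 23)
        folds = kfold_split(labeled, k=5, seed=3, stratified=True)
        pos_counts = np.bincount(
            [folds.fold_of[d] for d in labeled if labeled[d] == "effective"], minlength=5
        )
        assert pos_counts.max() - pos_counts.min() <= 1

    def test_too_few_positives_with_stratification(self):
        with pytest.raises(ValidationError, match="stratified"):
            kfold_split(labeled_map(3, 20), k=5, seed=0, stratified=True)

    def test_unstratified_allows_few_positives(self):
        folds = kfold_split(labeled_map(3, 20), k=5, seed=0, stratified=False)
        assert folds.k == 5

    @given(
        n_pos=st.integers(5, 20),
        n_neg=st.integers(5, 40),
        k=st.integers(2, 5),
        seed=st.integers(0, 1000),
        stratified=st.booleans(),
    )
    @settings(max_examples=40, deadline=None)
    def test_partition_invariants(self, n_pos, n_neg, k, seed, stratified):
        labeled = labeled_map(n_pos, n_neg)
        folds = kfold_split(labeled, k=k, seed=seed, stratified=stratified)
        assert set(folds.fold_of) == set(labeled)
        sizes = np.bincount(list(folds.fold_of.values()), minlength=k)
        assert sizes.max() - sizes.min() <= 1
        if stratified:
            pos = np.bincount(
                [folds.fold_of[d] for d in labeled if labeled[d] == "effective"],
                minlength=k,
            )
            assert pos.max() - pos.min() <= 1


class TestPrecisionRecall:
    def test_enumerated_confusion_matrix(self):
        curve = precision_recall(
            {"a": 3.0, "b": 2.0, "c": 1.0},
            {"a": True, "b": True, "c": False},
            thresholds=[1.5],
        )
        assert curve.precision[0] == 1.0
        assert curve.recall[0] == 1.0

    def test_threshold_above_max_empty_prediction_policy(self):
        curve = precision_recall(
            {"a": 3.0, "b": 2.0}, {"a": True, "b": False}, thresholds=[5.0]
        )
        assert curve.precision[0] == 1.0
        assert curve.recall[0] == 0.0

    def test_threshold_zero_recall_one_precision_prevalence(self):
        curve = precision_recall(
            {"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5},
            {"a": True, "b": False, "c": False, "d": False},
            thresholds=[0.0],
        )
        assert curve.recall[0] == 1.0
        assert curve.precision[0] == pytest.approx(0.25)

    def test_recall_non_increasing_default_grid(self):
        rng = np.random.default_rng(0)
        scores = {f"d{i}": float(rng.uniform(0, 5)) for i in range(30)}
        truth = {d: bool(rng.integers(2)) for d in scores}
        curve = precision_recall(scores, truth)
        assert np.all(np.diff(curve.recall) <= 1e-12)
        assert curve.recall[0] == 1.0  # low endpoint predicts everything

    def test_missing_score_rejected(self):
        with pytest.raises(ValidationError):
            precision_recall({"a": 1.0}, {"a": True, "b": False})


class TestRunCV:
    def separable_case(self, seed=0):
        spec = SyntheticSpec(
            n_effective_drugs=8, n_ineffective_drugs=16, n_candidate_drugs=0,
            n_proteins=60, p_within=0.5, p_between=0.01, seed=seed,
        )
        return generate_network(spec)

    def test_bookkeeping_k2_on_toy(self):
        net = make_network([
            ("a", "p1", 1.0), ("b", "p1", 1.0), ("c", "p2", 1.0), ("d", "p2", 1.0),
            ("a", "p2", 0.5), ("c", "p1", 0.5),
        ])
        labels = LabelSet(effective_drugs={"a", "b"}, ineffective_drugs={"c", "d"})
        folds = kfold_split({"a": "effective", "b": "effective", "c": "ineffective", "d": "ineffective"}, k=2, seed=0)
        cv = run_cv(net, labels, folds)
        assert len(cv.scores) == 4
        assert set(cv.scores["drug_id"]) == {"a", "b", "c", "d"}
        assert sorted(cv.scores["fold"].unique()) == [0, 1]

    def test_perfect_separation_gives_unit_precision(self):
        net, labels, _ = self.separable_case()
        labeled = {d: "effective" for d in labels.effective_drugs}
        labeled.update({d: "ineffective" for d in labels.ineffective_drugs})
        folds = kfold_split(labeled, k=4, seed=1)
        cv = run_cv(net, labels, folds)
        pos_scores = cv.scores.loc[cv.scores["label"] == "effective", "score"]
        neg_scores = cv.scores.loc[cv.scores["label"] == "ineffective", "score"]
        assert pos_scores.min() > neg_scores.max()
        # every threshold below the minimum positive score keeps precision 1
        below = cv.curve.thresholds >= neg_scores.max()
        assert np.allclose(cv.curve.precision[below], 1.0)

    def test_no_leakage_test_labels_do_not_matter(self):
        net, labels, _ = self.separable_case(seed=2)
        labeled = {d: "effective" for d in labels.effective_drugs}
        labeled.update({d: "ineffective" for d in labels.ineffective_drugs})
        folds = kfold_split(labeled, k=3, seed=5)
        cv = run_cv(net, labels, folds)

        # swap the classes of two fold-0 test drugs; fold-0 training labels
        # are untouched, so fold-0 scores must be bit-identical
        test0 = folds.test_ids(0)
        pos = next(d for d in test0 if d in labels.effective_drugs)
        neg = next(d for d in test0 if d in labels.ineffective_drugs)
        swapped = LabelSet(
            effective_drugs=(labels.effective_drugs - {pos}) | {neg},
            ineffective_drugs=(labels.ineffective_drugs - {neg}) | {pos},
        )
        cv2 = run_cv(net, swapped, folds)
        s1 = cv.scores[cv.scores["fold"] == 0].set_index("drug_id")["score"]
        s2 = cv2.scores[cv2.scores["fold"] == 0].set_index("drug_id")["score"]
        assert (s1 == s2.loc[s1.index]).all()

    def test_fold_without_training_class_rejected(self):
        net = make_network([
            ("a", "p1", 1.0), ("b", "p1", 1.0), ("c", "p1", 1.0), ("d", "p1", 1.0),
        ])
        labels = LabelSet(effective_drugs={"a"}, ineffective_drugs={"b", "c", "d"})
        folds = kfold_split(
            {"a": "effective", "b": "ineffective", "c": "ineffective", "d": "ineffective"},
            k=2, seed=0, stratified=False,
        )
        # whichever fold holds 'a' leaves no effective training seed
        with pytest.raises(ValidationError, match="effective"):
            run_cv(net, labels, folds)


class TestKnnScores:
    def make_distance(self, n, seed=0):
        rng = np.random.default_rng(seed)
        S = rng.uniform(0, 1, size=(n, n))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        ids = [f"d{i:02d}" for i in range(n)]
        return to_distance(SimilarityMatrix(ids=ids, S=S, kind="target")), ids

    def test_all_effective_neighbors(self):
        D, ids = self.make_distance(6)
        train = {ids[0]: True, ids[1]: True, ids[2]: True}
        scores = knn_scores(D, ids, train, k=3)
        assert all(v == 1.0 for v in scores.values())

    def test_k1_nearest_ineffective(self):
        D = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.5], [0.9, 0.5, 0.0]])
        ids = ["t", "near", "far"]
        scores = knn_scores(D, ids, {"near": False, "far": True}, k=1)
        assert scores["t"] == 0.0

    def test_k1_matches_brute_force_oracle(self):
        D, ids = self.make_distance(20, seed=3)
        rng = np.random.default_rng(4)
        train = {d: bool(rng.integers(2)) for d in ids[:12]}
        scores = knn_scores(D, ids, train, k=1)
        index = {d: i for i, d in enumerate(ids)}
        for d, s in scores.items():
            nearest = min(sorted(train), key=lambda t: (D[index[d], index[t]], t))
            assert s == float(train[nearest])

    def test_k_exceeding_training_pool_rejected(self):
        D, ids = self.make_distance(4)
        with pytest.raises(ValidationError):
            knn_scores(D, ids, {ids[0]: True}, k=2)

    def test_training_drug_never_its_own_neighbor(self):
        D, ids = self.make_distance(5)
        train = {ids[0]: True, ids[1]: False, ids[2]: False}
        scores = knn_scores(D, ids, train, k=2, test_ids=[ids[0]])
        assert scores[ids[0]] == 0.0  # its 2 neighbors are the two negatives

    def test_separable_profiles_perfect_curve(self):
        spec = SyntheticSpec(class_shift=5.0, noise_sd=1.0, attr_dim=32, seed=9)
        class_of = {f"D{i:03d}": i < 30 for i in range(60)}
        chem, _ = generate_profiles(class_of, spec)
        S = integrate_similarities([cosine_similarity(chem)])
        D = to_distance(S)
        ids = [p.drug_id for p in chem]
        train = {d: class_of[d] for i, d in enumerate(ids) if i % 2 == 0}
        test = [d for d in ids if d not in train]
        scores = knn_scores(D, ids, train, k=3, test_ids=test)
        curve = precision_recall(scores, {d: class_of[d] for d in test})
        assert any(p == 1.0 and r == 1.0 for p, r in zip(curve.precision, curve.recall))


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision({"a": 3.0, "b": 2.0, "c": 1.0}, {"a": True, "b": False, "c": False}) == 1.0

    def test_worst_ranking(self):
        ap = average_precision({"a": 1.0, "b": 2.0, "c": 3.0}, {"a": True, "b": False, "c": False})
        assert ap == pytest.approx(1 / 3)

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        scores = {f"d{i}": float(rng.normal()) for i in range(50)}
        truth = {d: bool(rng.integers(2)) for d in scores}
        ids = sorted(truth)
        expected = sklearn.average_precision_score(
            [truth[d] for d in ids], [scores[d] for d in ids]
        )
        assert average_precision(scores, truth) == pytest.approx(expected, abs=1e-12)


class TestSimilarityContrast:
    def uniform_similarity(self, ids, value=0.4):
        n = len(ids)
        S = np.full((n, n), value)
        np.fill_diagonal(S, 1.0)
        return SimilarityMatrix(ids=list(ids), S=S, kind="target")

    def test_zero_variance_reports_no_evidence(self):
        ids = ["s1", "s2", "s3", "e1", "n1"]
        res = similarity_contrast(["s1", "s2", "s3"], ["e1"], ["n1"], self.uniform_similarity(ids))
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_df_is_n_screened_minus_one(self):
        ids = [f"s{i}" for i in range(10)] + ["e1", "n1"]
        rng = np.random.default_rng(6)
        S = rng.uniform(0, 1, size=(12, 12))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        sim = SimilarityMatrix(ids=ids, S=S, kind="target")
        res = similarity_contrast([f"s{i}" for i in range(10)], ["e1"], ["n1"], sim)
        assert res.df == 9

    def test_screened_excluded_from_own_average(self):
        ids = ["x", "e1", "e2", "n1", "n2"]
        S = np.eye(5)
        S[0, 1] = S[1, 0] = 0.8
        S[0, 3] = S[3, 0] = 0.2
        S[1, 2] = S[2, 1] = 0.9
        sim = SimilarityMatrix(ids=ids, S=S, kind="target")
        res = similarity_contrast(["x", "e1"], ["e1", "e2"], ["n1", "n2"], sim)
        row = res.table.set_index("drug_id").loc["e1"]
        assert row["mean_effective"] == pytest.approx(0.9)  # only e2 counts

    def test_planted_structure_rejects_null(self):
        spec = SyntheticSpec(class_shift=3.0, noise_sd=1.0, attr_dim=32, seed=12)
        class_of = {f"S{i:03d}": True for i in range(20)}
        class_of.update({f"E{i:03d}": True for i in range(10)})
        class_of.update({f"N{i:03d}": False for i in range(10)})
        chem, _ = generate_profiles(class_of, spec)
        sim = cosine_similarity(chem)
        res = similarity_contrast(
            [f"S{i:03d}" for i in range(20)],
            [f"E{i:03d}" for i in range(10)],
            [f"N{i:03d}" for i in range(10)],
            sim,
        )
        assert res.p_value < 0.01
        assert res.df == 19

    def test_too_few_screened_rejected(self):
        ids = ["s1", "e1", "n1"]
        with pytest.raises(ValidationError):
            similarity_contrast(["s1"], ["e1"], ["n1"], self.uniform_similarity(ids))
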