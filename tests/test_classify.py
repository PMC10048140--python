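import numpy as np
import pandas as pd
import pytest

from edrw.activity import PathwayActivityMatrix
from edrw.classify import (
    auc_score,
    evaluate_test_auc,
    greedy_forward_selection,
    make_classifier,
    run_repeated_experiment,
    stratified_split,
)
from oracles import brute_force_auc


class TestStratifiedSplit:
    def test_lung_cohort_rounding(self):
        # 58 tumor / 49 normal -> (35,12,11) and (29,10,10)
        y = np.array([1] * 58 + [0] * 49)
        split = stratified_split(y, seed=0)
        tumor = set(np.flatnonzero(y == 1))
        assert sum(i in tumor for i in split.train) == 35
        assert sum(i in tumor for i in split.validation) == 12
        assert sum(i in tumor for i in split.test) == 11
        assert sum(i not in tumor for i in split.train) == 29
        assert sum(i not in tumor for i in split.validation) == 10
        assert sum(i not in tumor for i in split.test) == 10

    def test_balanced_ten_per_class(self):
        y = np.array([0] * 10 + [1] * 10)
        split = stratified_split(y, seed=3)
        for cls in (0, 1):
            members = set(np.flatnonzero(y == cls))
            assert sum(i in members for i in split.train) == 6
            assert sum(i in members for i in split.validation) == 2
            assert sum(i in members for i in split.test) == 2

    def test_partition_is_disjoint_and_complete(self):
        y = np.array([0] * 23 + [1] * 31)
        split = stratified_split(y, seed=11)
        parts = [set(split.train), set(split.validation), set(split.test)]
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        assert parts[0] | parts[1] | parts[2] == set(range(len(y)))

    def test_same_seed_reproduces(self):
        y = np.array([0] * 20 + [1] * 25)
        s1, s2 = stratified_split(y, seed=42), stratified_split(y, seed=42)
        assert np.array_equal(s1.train, s2.train)
        assert np.array_equal(s1.test, s2.test)

    def test_tiny_class_raises(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0] * 3 + [1] * 10), seed=0)


class TestAuc:
    def test_hand_example(self):
        # scores .9,.8,.4,.3 with labels 1,0,1,0: 3 of 4 pairs concordant
        assert auc_score([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3]) == pytest.approx(0.75)

    def test_perfect_and_inverted_ordering(self):
        assert auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auc_score([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_agrees_with_pairwise_concordance(self, rng):
        for _ in range(500):
            n = int(rng.integers(4, 25))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            # coarse scores so ties actually occur
            scores = np.round(rng.uniform(size=n), 1)
            assert auc_score(y, scores) == pytest.approx(
                brute_force_auc(scores, y), abs=1e-12
            )


def activity_from(frame):
    return PathwayActivityMatrix(frame=frame)


class TestGreedySelection:
    def test_perfect_feature_alone_is_kept(self, rng):
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        perfect = 3.0 * y + 0.1 * rng.normal(size=n)  # effect size ~3
        rows = np.vstack([perfect] + [rng.normal(size=n) for _ in range(9)])
        frame = pd.DataFrame(rows, index=[f"p{i}" for i in range(10)],
                             columns=[f"s{j}" for j in range(n)])
        selected, trajectory = greedy_forward_selection(
            activity_from(frame), list(frame.index), y,
            classifier="nb", folds=10, seed=5,
        )
        assert selected[0] == "p0"
        assert trajectory[-1] == pytest.approx(1.0)

    def test_trajectory_strictly_increasing(self, rng):
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        rows = rng.normal(size=(8, n)) + 0.8 * y
        frame = pd.DataFrame(rows, index=[f"p{i}" for i in range(8)],
                             columns=[f"s{j}" for j in range(n)])
        _, trajectory = greedy_forward_selection(
            activity_from(frame), list(frame.index), y,
            classifier="lr", folds=5, seed=1,
        )
        assert all(b > a for a, b in zip(trajectory, trajectory[1:]))

    def test_single_candidate_selected_trivially(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        frame = pd.DataFrame(rng.normal(size=(1, 20)), index=["only"],
                             columns=[f"s{j}" for j in range(20)])
        selected, _ = greedy_forward_selection(
            activity_from(frame), ["only"], y, classifier="knn", folds=5, seed=2
        )
        assert selected == ["only"]

    def test_null_features_stay_near_chance(self, rng):
        aucs = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            n = 100
            y = np.array([0] * 50 + [1] * 50)
            frame = pd.DataFrame(local.normal(size=(6, n)),
                                 index=[f"p{i}" for i in range(6)],
                                 columns=[f"s{j}" for j in range(n)])
            _, trajectory = greedy_forward_selection(
                activity_from(frame), list(frame.index), y,
                classifier="nb", folds=10, seed=seed,
            )
            aucs.append(trajectory[-1])
        # selection optimism keeps CV AUC slightly above 0.5 on pure noise
        assert 0.4 <= float(np.mean(aucs)) <= 0.75

    def test_impossible_folds_raise(self, rng):
        y = np.array([0] * 4 + [1] * 4)
        frame = pd.DataFrame(rng.normal(size=(2, 8)), index=["a", "b"],
                             columns=[f"s{j}" for j in range(8)])
        with pytest.raises(ValueError, match="fold"):
            greedy_forward_selection(activity_from(frame), ["a", "b"], y,
                                     classifier="nb", folds=10, seed=0)


class TestEvaluateTestAuc:
    def test_fits_on_train_scores_on_test(self, rng):
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        frame = pd.DataFrame(
            np.vstack([2.5 * y + 0.2 * rng.normal(size=n)]),
            index=["p"], columns=[f"s{j}" for j in range(n)],
        )
        train, test = np.arange(0, n, 2), np.arange(1, n, 2)
        auc = evaluate_test_auc(activity_from(frame), ["p"], y, train, test,
                                classifier="lr")
        assert auc == pytest.approx(1.0)

    def test_single_class_test_raises(self, rng):
        frame = pd.DataFrame(rng.normal(size=(1, 8)), index=["p"],
                             columns=[f"s{j}" for j in range(8)])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="single class"):
            evaluate_test_auc(activity_from(frame), ["p"], y,
                              np.array([0, 1, 4, 5]), np.array([2, 3]),
                              classifier="nb")

    def test_empty_feature_set_raises(self, rng):
        frame = pd.DataFrame(rng.normal(size=(1, 4)), index=["p"],
                             columns=list("abcd"))
        with pytest.raises(ValueError):
            evaluate_test_auc(activity_from(frame), [], np.array([0, 0, 1, 1]),
                              np.array([0, 2]), np.array([1, 3]))


class TestClassifierFactory:
    @pytest.mark.parametrize("name", ["nb", "knn", "lr"])
    def test_known_names(self, name):
        est = make_classifier(name)
        assert hasattr(est, "fit")

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError):
            make_classifier("svm")


class TestRepeatedExperiment:
    def test_fixed_seed_reproduces(self, tiny_cohort):
        kwargs = dict(
            expression=tiny_cohort["expr"],
            labels=tiny_cohort["labels"],
            networks=[tiny_cohort["net_a"], tiny_cohort["net_b"]],
            pathways=tiny_cohort["pathways"],
            classifier="knn", repeats=2, base_seed=17, top_k=10, cv_folds=5,
        )
        r1 = run_repeated_experiment(**kwargs)
        r2 = run_repeated_experiment(**kwargs)
        assert r1.mean_auc == r2.mean_auc
        assert [rec.selected for rec in r1.repeats] == [
            rec.selected for rec in r2.repeats
        ]

    def test_planted_cohort_classifies_well(self, tiny_cohort):
        result = run_repeated_experiment(
            tiny_cohort["expr"], tiny_cohort["labels"],
            [tiny_cohort["net_a"], tiny_cohort["net_b"]],
            tiny_cohort["pathways"],
            classifier="knn", repeats=3, base_seed=1, top_k=10, cv_folds=5,
        )
        assert result.mean_auc >= 0.9
        assert len(result.repeats) == 3
        assert all(0.0 <= a <= 1.0 for a in result.test_aucs)

    def test_selection_frequency_counts_repeats(self, tiny_cohort):
        result = run_repeated_experiment(
            tiny_cohort["expr"], tiny_cohort["labels"],
            [tiny_cohort["net_a"], tiny_cohort["net_b"]],
            tiny_cohort["pathways"],
            classifier="nb", repeats=2, base_seed=5, top_k=10, cv_folds=5,
        )
        freq = result.selection_frequency()
        assert sum(freq.values()) == sum(len(r.selected) for r in result.repeats)
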