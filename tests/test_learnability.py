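"""Classifier plumbing: normalization, partitioning, the network's sanity
oracles (separable / permuted / confusable data), learnability arithmetic,
ranking and benchmark comparison."""

import numpy as np
import pandas as pd
import pytest

import dcnlearn as d
from dcnlearn.learnability import (
    ClassifierSpec,
    PartitionScheme,
    LearnabilityResult,
    normalize_features,
    inverse_transform,
    partition,
    loo_folds,
    train_eval_once,
    run_learnability,
    rank_results,
    near_benchmark,
    fl_from_confusion,
)

from conftest import separable_feature_table, gaussian_feature_table


def _dummy_table(n_per_nerve=220, animal="a1", rng=None):
    rng = rng or np.random.default_rng(0)
    return gaussian_feature_table({}, n_per_nerve, rng, animal=animal)


def _result(per_animal, fl_mean=None, descriptor="x"):
    diag = np.full(4, fl_mean if fl_mean is not None else np.mean(list(per_animal.values())))
    conf = np.diag(diag) + (100.0 - diag)[:, None] * (np.ones((4, 4)) - np.eye(4)) / 3
    m, s = fl_from_confusion(conf)
    return LearnabilityResult(
        descriptor=descriptor, inputs=[], scheme="WIA", classes=d.NERVES,
        confusion=conf, fl_mean=m, fl_sem=s, per_animal_fl=per_animal,
        n_repeats=10,
    )


class TestNormalize:
    def test_min_max_to_unit_interval(self):
        df = pd.DataFrame({"animal": "a1", "nerve": "RSN", "trial": [0, 1, 2],
                           "f": [2.0, 4.0, 6.0]})
        scaled, _ = normalize_features(df, ["f"])
        np.testing.assert_allclose(scaled["f"], [-1.0, 0.0, 1.0])

    def test_constant_feature_maps_to_zero_with_warning(self):
        df = pd.DataFrame({"animal": "a1", "nerve": "RSN", "trial": [0, 1, 2],
                           "f": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            scaled, _ = normalize_features(df, ["f"])
        assert (scaled["f"] == 0.0).all()

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"animal": "a1", "nerve": "RSN",
                           "trial": np.arange(50),
                           "f": rng.normal(3, 7, 50), "g": rng.uniform(-2, 9, 50)})
        scaled, tf = normalize_features(df, ["f", "g"])
        back = inverse_transform(scaled, tf)
        np.testing.assert_allclose(back["f"], df["f"], rtol=1e-12)
        np.testing.assert_allclose(back["g"], df["g"], rtol=1e-12)


class TestPartition:
    def test_wia_880_trials_split_616_132_132(self):
        table = _dummy_table(220)
        tr, val, te = partition(table, PartitionScheme("WIA"), seed=0)
        assert (len(tr), len(val), len(te)) == (616, 132, 132)
        combined = np.concatenate([tr, val, te])
        assert len(np.unique(combined)) == 880  # disjoint and exhaustive

    def test_splits_are_stratified(self):
        table = _dummy_table(220)
        tr, val, te = partition(table, PartitionScheme("WIA"), seed=3)
        for pool in (tr, val, te):
            assert set(table.loc[pool, "nerve"]) == set(d.NERVES)

    def test_same_seed_reproduces_split(self):
        table = _dummy_table(50)
        a = partition(table, PartitionScheme("WIA"), seed=5)
        b = partition(table, PartitionScheme("WIA"), seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_wia_requires_single_animal(self):
        t1 = _dummy_table(20, animal="a1")
        t2 = _dummy_table(20, animal="a2")
        both = pd.concat([t1, t2], ignore_index=True)
        with pytest.raises(ValueError, match="single animal"):
            partition(both, PartitionScheme("WIA"), seed=0)

    def test_loo_folds_hold_out_each_animal_once(self):
        rng = np.random.default_rng(2)
        table = pd.concat(
            [_dummy_table(20, animal=f"a{i}", rng=rng) for i in range(1, 8)],
            ignore_index=True,
        )
        folds = loo_folds(table, PartitionScheme("LOO"), seed=1)
        assert len(folds) == 7
        held = []
        for animal, tr, val, te in folds:
            held.append(animal)
            assert set(table.loc[te, "animal"]) == {animal}
            assert len(te) == 80  # all trials of the held-out animal
            assert animal not in set(table.loc[np.concatenate([tr, val]), "animal"])
        assert sorted(held) == [f"a{i}" for i in range(1, 8)]

    def test_tiny_table_with_missing_class_rejected(self):
        table = _dummy_table(2)
        with pytest.raises(ValueError):
            partition(table, PartitionScheme("WIA"), seed=0)


class TestNetwork:
    def test_separable_clusters_classified_perfectly(self):
        rng = np.random.default_rng(0)
        table = separable_feature_table(40, rng)
        scaled, _ = normalize_features(table)
        cols = [c for c in table.columns if c.startswith("e")]
        X = scaled[cols].to_numpy()
        y = scaled["nerve"].to_numpy()
        conf = train_eval_once((X, y), (X, y), (X, y), ClassifierSpec(), seed=0)
        np.testing.assert_allclose(np.diag(conf), 100.0)

    def test_missing_training_class_rejected(self):
        rng = np.random.default_rng(0)
        table = separable_feature_table(10, rng)
        scaled, _ = normalize_features(table)
        cols = [c for c in table.columns if c.startswith("e")]
        X = scaled[cols].to_numpy()
        y = scaled["nerve"].to_numpy()
        keep = y != "RSN"
        with pytest.raises(ValueError, match="classes"):
            train_eval_once((X[keep], y[keep]), (X, y), (X, y),
                            ClassifierSpec(), seed=0, classes=d.NERVES)

    def test_confusable_pair_errors_concentrate_on_each_other(self):
        """Two nerves drawn from one distribution confuse mostly with each
        other, not with the two well-separated nerves."""
        rng = np.random.default_rng(4)
        means = {"RSN": 0.0, "LSN": 0.0, "RPN": 12.0, "LPN": 24.0}
        table = gaussian_feature_table(means, 80, rng)
        res = run_learnability(table, (tuple(range(1, 8)), d.SF_NAMES),
                               scheme="WIA", n_repeats=5, seed=0)
        conf = res.confusion
        i, j = d.NERVES.index("RSN"), d.NERVES.index("LSN")
        for a, b in ((i, j), (j, i)):
            row_errors = conf[a].sum() - conf[a, a]
            assert conf[a, b] > 0.25 * row_errors

    def test_permuted_labels_learn_nothing(self):
        rng = np.random.default_rng(5)
        table = separable_feature_table(50, rng)
        table["nerve"] = rng.permutation(table["nerve"].to_numpy())
        res = run_learnability(table, (tuple(range(1, 8)), d.SF_NAMES),
                               scheme="WIA", n_repeats=10, seed=1)
        assert 10.0 < res.fl_mean < 45.0  # near the 25% chance level


class TestLearnabilityAggregation:
    def test_fl_sem_arithmetic(self):
        """Diagonal (100, 100, 90, 90) -> FL 95 +/- 2.887."""
        conf = np.array(
            [
                [100.0, 0, 0, 0],
                [0, 100.0, 0, 0],
                [10.0 / 3, 10.0 / 3, 90.0, 10.0 / 3],
                [10.0 / 3, 10.0 / 3, 10.0 / 3, 90.0],
            ]
        )
        mean, sem = fl_from_confusion(conf)
        assert mean == pytest.approx(95.0)
        assert sem == pytest.approx(2.8868, abs=1e-3)

    def test_identity_confusion_is_perfect(self):
        mean, sem = fl_from_confusion(100.0 * np.eye(4))
        assert (mean, sem) == (100.0, 0.0)

    def test_confusion_rows_sum_to_100_everywhere(self, small_table):
        for scheme in ("WIA", "PP", "LOO"):
            res = run_learnability(
                small_table, [(4, "hf_integral"), (4, "p1n1_amplitude")],
                scheme=scheme, n_repeats=2, seed=0,
            )
            np.testing.assert_allclose(res.confusion.sum(axis=1), 100.0,
                                       atol=1e-6)
            assert 0.0 <= res.fl_mean <= 100.0
            assert res.fl_sem >= 0.0

    def test_scheme_ordering_wia_pp_loo(self, small_table):
        """With inter-animal variability, within-animal learning is at
        least as good as pooled, which beats leave-one-animal-out
        (non-strict, 2-point tolerance)."""
        inputs = (tuple(range(1, 8)), d.SF_NAMES)
        wia = run_learnability(small_table, inputs, "WIA", n_repeats=3, seed=1)
        pp = run_learnability(small_table, inputs, "PP", n_repeats=3, seed=1)
        loo = run_learnability(small_table, inputs, "LOO", n_repeats=3, seed=1)
        assert wia.fl_mean >= pp.fl_mean - 2.0
        assert pp.fl_mean >= loo.fl_mean - 2.0

    def test_adding_informative_input_does_not_hurt(self, small_table):
        base = run_learnability(small_table, [(4, "p1n1_amplitude")],
                                "WIA", n_repeats=3, seed=2)
        more = run_learnability(
            small_table, [(4, "p1n1_amplitude"), (4, "hf_integral")],
            "WIA", n_repeats=3, seed=2,
        )
        assert more.fl_mean >= base.fl_mean - 2.0

    def test_unknown_scheme_rejected(self, small_table):
        with pytest.raises(ValueError):
            run_learnability(small_table, [(4, "hf_integral")], "XYZ")


class TestRanking:
    def test_smaller_sem_outranks_on_tied_mean(self):
        a = _result({"a1": 90.0}, 90.0, "A")
        b = _result({"a1": 90.0}, 90.0, "B")
        a.fl_sem, b.fl_sem = 2.0, 1.0
        assert [r.descriptor for r in rank_results([a, b])] == ["B", "A"]

    def test_mean_dominates_sem(self):
        a = _result({"a1": 95.0}, 95.0, "A")
        b = _result({"a1": 90.0}, 90.0, "B")
        a.fl_sem, b.fl_sem = 5.0, 0.1
        assert [r.descriptor for r in rank_results([b, a])] == ["A", "B"]

    def test_full_tie_breaks_lexicographically(self):
        a = _result({"a1": 90.0}, 90.0, "B")
        b = _result({"a1": 90.0}, 90.0, "A")
        a.fl_sem = b.fl_sem = 1.0
        assert [r.descriptor for r in rank_results([a, b])] == ["A", "B"]


class TestNearBenchmark:
    def test_identical_results_are_near(self):
        pa = {f"a{i}": 90.0 + i for i in range(1, 8)}
        near, p = near_benchmark(_result(dict(pa)), _result(dict(pa)))
        assert near and p == 1.0

    def test_ten_points_below_is_not_near(self):
        rng = np.random.default_rng(0)
        bench = {f"a{i}": 92.0 + rng.normal(0, 1) for i in range(1, 8)}
        cand = {k: v - 10.0 + rng.normal(0, 0.5) for k, v in bench.items()}
        near, p = near_benchmark(_result(cand), _result(bench))
        assert not near and p < 0.05

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError, match="2 animals"):
            near_benchmark(_result({"a1": 90.0}), _result({"a1": 95.0}))

    def test_mismatched_animals_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            near_benchmark(_result({"a1": 90.0, "a2": 91.0}),
                           _result({"a1": 90.0, "a3": 91.0}))

    def test_result_json_round_trip(self, tmp_path):
        res = _result({"a1": 90.0, "a2": 95.0}, 92.0, "roundtrip")
        path = tmp_path / "res.json"
        res.to_json(path)
        back = LearnabilityResult.from_json(path)
        assert back.descriptor == res.descriptor
        np.testing.assert_allclose(back.confusion, res.confusion)
        assert back.per_animal_fl == res.per_animal_fl
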