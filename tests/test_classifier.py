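import numpy as np
import pytest

from conftest import gold_to_records

from enzdis.classifier import (
    CATEGORIES,
    UNASSIGNED,
    ConfidenceScheme,
    GridEntry,
    ModelParams,
    assign_confidence,
    cross_validate_category,
    default_grid,
    ensemble_vote,
    grid_search,
    make_balanced_set,
    make_category_pipeline,
    passes_selection,
    train_binary,
    train_ensemble,
)
from enzdis.evaluation import CVResult, MetricSet


class TestModelParams:
    def test_kernel_names(self):
        for k in ("linear", "polynomial", "radial_basis", "sigmoid"):
            ModelParams(kernel=k)
        with pytest.raises(ValueError):
            ModelParams(kernel="string")

    def test_cost_positive(self):
        with pytest.raises(ValueError):
            ModelParams(cost=0)

    def test_default_grid_spans_kernels_and_modes(self):
        grid = default_grid()
        assert {p.kernel for p in grid} == {"linear", "polynomial",
                                            "radial_basis", "sigmoid"}
        assert {p.mode for p in grid} == {"removal", "replacement"}


class TestMakeBalancedSet:
    def units(self):
        units = [f"u{i}" for i in range(20)]
        labels = [frozenset({"causal_interaction"}) if i < 6 else frozenset()
                  for i in range(20)]
        return units, labels

    def test_output_is_twice_the_positives(self):
        units, labels = self.units()
        chosen, y = make_balanced_set(units, labels, "causal_interaction", seed=0)
        assert len(chosen) == 12
        assert y.sum() == 6 and (y == 0).sum() == 6

    def test_same_seed_same_sample(self):
        units, labels = self.units()
        a, _ = make_balanced_set(units, labels, "causal_interaction", seed=5)
        b, _ = make_balanced_set(units, labels, "causal_interaction", seed=5)
        c, _ = make_balanced_set(units, labels, "causal_interaction", seed=6)
        assert a == b
        assert a != c  # overwhelmingly likely with 14 choose 6 samples

    def test_no_positives_is_an_error(self):
        units, labels = self.units()
        with pytest.raises(ValueError, match="no positive"):
            make_balanced_set(units, labels, "ongoing_research", seed=0)

    def test_insufficient_negatives_names_shortfall(self):
        units = ["a", "b", "c"]
        labels = [frozenset({"diagnostic_usage"})] * 2 + [frozenset()]
        with pytest.raises(ValueError, match="short by 1"):
            make_balanced_set(units, labels, "diagnostic_usage", seed=0)

    def test_ineligible_negatives_excluded(self):
        units, labels = self.units()
        eligible = [True] * 12 + [False] * 8  # only u6..u11 are eligible negatives
        chosen, y = make_balanced_set(units, labels, "causal_interaction",
                                      seed=0, eligible=eligible)
        negs = {u for u, lab in zip(chosen, y) if lab == 0}
        assert negs == {f"u{i}" for i in range(6, 12)}

    def test_ineligible_negatives_error_when_pool_too_small(self):
        units, labels = self.units()
        eligible = [True] * 6 + [False] * 14
        with pytest.raises(ValueError):
            make_balanced_set(units, labels, "causal_interaction",
                              seed=0, eligible=eligible)


SEP_X = [["on"], ["on", "on"], ["off"], ["off", "off"], ["on", "up"], ["off", "up"]]
SEP_Y = [1, 1, 0, 0, 1, 0]


class TestTrainBinary:
    def test_separable_training_accuracy_is_one(self):
        model = train_binary(SEP_X, SEP_Y, ModelParams("linear", cost=10.0))
        pred = (model.decision_function(SEP_X) > 0).astype(int)
        assert list(pred) == SEP_Y

    def test_determinism(self):
        p = ModelParams("radial_basis", cost=1.0, gamma=1.0)
        s1 = train_binary(SEP_X, SEP_Y, p).decision_function(SEP_X)
        s2 = train_binary(SEP_X, SEP_Y, p).decision_function(SEP_X)
        assert np.array_equal(s1, s2)

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError):
            train_binary(SEP_X[:2], [1, 1], ModelParams())

    def test_conflicting_duplicates_cap_training_accuracy(self):
        # identical feature vectors with opposite labels are irreducible noise
        X = [["a"], ["a"], ["b"], ["b"]]
        y = [1, 0, 1, 0]
        model = train_binary(X, y, ModelParams("linear", cost=100.0))
        pred = (model.decision_function(X) > 0).astype(int)
        acc = float(np.mean(pred == y))
        assert acc <= 0.5


class TestEnsembleVote:
    def _const_models(self, signs):
        class Fake:
            def __init__(self, s):
                self.s = s

            def decision_function(self, X):
                return np.full(len(X), self.s, dtype=float)

        return [Fake(s) for s in signs]

    def test_unanimous(self):
        assert ensemble_vote(self._const_models([1] * 5), [["x"]])[0] == 1.0
        assert ensemble_vote(self._const_models([-1] * 5), [["x"]])[0] == 0.0

    def test_counting(self):
        votes = ensemble_vote(self._const_models([1, 1, 1, -1]), [["x"]])
        assert votes[0] == 0.75

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_vote([], [["x"]])


class TestAssignConfidence:
    @pytest.mark.parametrize("vote,expected", [
        (1.0, 4), (0.95, 4), (0.90, 4),
        (0.70, 3), (0.60, 2), (0.50, 2),
        (0.30, 1), (0.25, 1),
        (0.10, UNASSIGNED), (0.0, UNASSIGNED),
    ])
    def test_default_scheme(self, vote, expected):
        assert assign_confidence(vote) == expected

    def test_out_of_range_vote(self):
        with pytest.raises(ValueError):
            assign_confidence(1.5)

    def test_thresholds_strictly_decreasing(self):
        with pytest.raises(ValueError):
            ConfidenceScheme((0.9, 0.9, 0.5, 0.2))

    def test_level_monotone_in_vote(self):
        votes = np.linspace(0, 1, 101)
        levels = [assign_confidence(v) for v in votes]
        assert levels == sorted(levels)


class TestSelectionFilter:
    def _cv(self, precision, f1):
        m = MetricSet(precision, 0.5, 0.5, 0.5, f1, 0.0, 0.5)
        return CVResult(folds=[m], mean=m.as_dict(), sd={})

    def test_low_precision_fails(self):
        assert not passes_selection({"c": self._cv(0.6, 0.9)})

    def test_low_f1_fails(self):
        assert not passes_selection({"c": self._cv(0.9, 0.4)})

    def test_one_passing_category_suffices(self):
        per_cat = {"a": self._cv(0.6, 0.4), "b": self._cv(0.75, 0.55)}
        assert passes_selection(per_cat)

    def test_boundary_values_pass(self):
        assert passes_selection({"c": self._cv(0.7, 0.5)})


class TestGridSearchAndEnsemble:
    def test_grid_search_ranks_by_mean_f1(self, small_synth):
        _, _, corpus = small_synth
        records, labels = gold_to_records(corpus)
        grid = [ModelParams("linear", 1.0), ModelParams("linear", 0.001)]
        entries = grid_search(records, labels, grid, k=3, seed=0)
        assert len(entries) == 2
        assert entries[0].mean_f1 >= entries[1].mean_f1
        assert all(isinstance(e, GridEntry) for e in entries)

    def test_empty_grid_rejected(self, small_synth):
        _, _, corpus = small_synth
        records, labels = gold_to_records(corpus)
        with pytest.raises(ValueError):
            grid_search(records, labels, [], k=3, seed=0)

    def test_single_entry_grid_is_identity_ranking(self, small_synth):
        _, _, corpus = small_synth
        records, labels = gold_to_records(corpus)
        entries = grid_search(records, labels, [ModelParams("linear", 1.0)],
                              k=3, seed=0)
        assert len(entries) == 1

    def test_trained_ensemble_classifies_every_category(self, small_synth):
        _, _, corpus = small_synth
        records, labels = gold_to_records(corpus)
        ens = train_ensemble(records, labels,
                             [ModelParams("linear", 1.0),
                              ModelParams("linear", 10.0)], seed=0)
        levels = ens.classify(records)
        assert set(levels) == set(CATEGORIES)
        for lv in levels.values():
            assert set(np.unique(lv)) <= {0, 1, 2, 3, 4}

    def test_separable_corpus_cv_f1_high(self, small_synth):
        # cue strength 0.9 corpus: a linear model should be strong
        _, _, corpus = small_synth
        records, labels = gold_to_records(corpus)
        cv = cross_validate_category(records, labels, "causal_interaction",
                                     ModelParams("linear", 1.0), k=5, seed=0)
        assert cv.mean["f1"] >= 0.8
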