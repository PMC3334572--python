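import numpy as np
import pytest

from fsindel import simulate
from fsindel.genome_model import LABEL_DAMAGING, LABEL_NEUTRAL
from fsindel.rules import extract_rules
from fsindel.training import (
    DecisionTree,
    LabeledDataset,
    balanced_sample,
    compute_metrics,
    greedy_forward_selection,
    induce_tree,
    kfold_cv,
    repeated_cv,
    stratified_folds,
    tree_learner,
)


def make_dataset(X, y, names=None):
    X = np.asarray(X, dtype=float).reshape(len(y), -1)
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return LabeledDataset(X, np.asarray(y, dtype=object), names)


POS, NEG = LABEL_DAMAGING, LABEL_NEUTRAL


# ---------------------------------------------------------------------------
# LabeledDataset / balanced_sample
# ---------------------------------------------------------------------------

class TestLabeledDataset:
    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown labels"):
            make_dataset([[1.0]], ["banana"])

    def test_all_nan_row_rejected(self):
        with pytest.raises(ValueError, match="uncomputable"):
            make_dataset([[np.nan, np.nan]], [POS])

    def test_tsv_round_trip(self, tmp_path):
        ds = make_dataset([[1, 2], [3, 4]], [POS, NEG], ["a", "b"])
        p = tmp_path / "d.tsv"
        ds.to_tsv(p)
        back = LabeledDataset.from_tsv(p)
        assert np.allclose(back.X, ds.X)
        assert list(back.y) == list(ds.y)
        assert back.feature_names == ["a", "b"]


class TestBalancedSample:
    def test_paper_sizes(self):
        pos = make_dataset(np.zeros((1292, 1)), [POS] * 1292)
        neg = make_dataset(np.ones((2602, 1)), [NEG] * 2602)
        out = balanced_sample(pos, neg, seed=0)
        assert len(out) == 2584
        assert out.class_counts == {POS: 1292, NEG: 1292}

    def test_equal_sizes_identity_on_negatives(self):
        pos = make_dataset(np.zeros((5, 1)), [POS] * 5)
        neg = make_dataset(np.arange(5.0), [NEG] * 5)
        out = balanced_sample(pos, neg, seed=3)
        assert sorted(out.X[out.y == NEG, 0]) == list(range(5))

    def test_deterministic(self):
        pos = make_dataset(np.zeros((10, 1)), [POS] * 10)
        neg = make_dataset(np.arange(30.0), [NEG] * 30)
        a = balanced_sample(pos, neg, seed=42)
        b = balanced_sample(pos, neg, seed=42)
        assert np.array_equal(a.X, b.X)

    def test_too_few_negatives_rejected(self):
        pos = make_dataset(np.zeros((3, 1)), [POS] * 3)
        neg = make_dataset(np.zeros((2, 1)), [NEG] * 2)
        with pytest.raises(ValueError):
            balanced_sample(pos, neg, seed=0)


# ---------------------------------------------------------------------------
# tree induction
# ---------------------------------------------------------------------------

def brute_force_best_gain(x, y_pos):
    """All candidate midpoints, plain loops."""
    def H(p):
        if p in (0.0, 1.0):
            return 0.0
        return -p * np.log2(p) - (1 - p) * np.log2(1 - p)

    n = len(x)
    parent = H(sum(y_pos) / n)
    best_gain, best_thr = -1.0, None
    xs = sorted(set(x))
    for a, b in zip(xs, xs[1:]):
        thr = (a + b) / 2
        left = [y for xi, y in zip(x, y_pos) if xi <= thr]
        right = [y for xi, y in zip(x, y_pos) if xi > thr]
        g = parent - (len(left) * H(sum(left) / len(left))
                      + len(right) * H(sum(right) / len(right))) / n
        if g > best_gain:
            best_gain, best_thr = g, thr
    return best_gain, best_thr


class TestInduceTree:
    def test_stump_threshold_in_gap(self):
        x = [1.0, 2.0, 3.0, 4.0, 6.0, 7.0, 8.0, 9.0]
        y = [NEG] * 4 + [POS] * 4
        ds = make_dataset(x, y)
        tree = induce_tree(ds, prune=False)
        assert tree.root.feature == "x0"
        assert 4.0 < tree.root.threshold <= 6.0
        # brute-force oracle confirms the max-gain threshold
        _, thr = brute_force_best_gain(x, [int(l == POS) for l in y])
        assert tree.root.threshold == pytest.approx(thr)

    def test_single_class_single_leaf(self):
        ds = make_dataset([[1], [2], [3]], [POS] * 3)
        tree = induce_tree(ds)
        assert tree.root.is_leaf and tree.root.label == POS

    def test_training_accuracy_one_on_separable_data_unpruned(self):
        data = simulate.generate_labeled_features(
            simulate.GeneratorConfig(n_per_class=300, seed=2))
        tree = induce_tree(data, prune=False)
        assert (tree.predict(data.X) == data.y).mean() == 1.0

    def test_planted_rule_recovery(self):
        # 4,000 rows, 2% noise: root lands on f14 inside a planted margin band
        cfg = simulate.GeneratorConfig(n_per_class=2000, noise_rate=0.02, seed=17)
        data = simulate.generate_labeled_features(cfg)
        tree = induce_tree(data)
        root = tree.root
        assert root.feature == "f14"
        lo1, hi1 = cfg.band("f14_low")
        lo2, hi2 = cfg.band("f14_high")
        assert lo1 < root.threshold < hi1 or lo2 < root.threshold < hi2

    def test_json_round_trip(self, tmp_path):
        data = simulate.generate_labeled_features(
            simulate.GeneratorConfig(n_per_class=100, seed=4))
        tree = induce_tree(data)
        p = tmp_path / "tree.json"
        tree.to_json(p)
        back = DecisionTree.from_json(p)
        assert np.array_equal(back.predict(data.X), tree.predict(data.X))

    def test_tree_and_extracted_rules_agree(self):
        data = simulate.generate_labeled_features(
            simulate.GeneratorConfig(n_per_class=400, noise_rate=0.05, seed=9))
        tree = induce_tree(data)
        ruleset = extract_rules(tree, data.X, data.y)
        col = {n: i for i, n in enumerate(data.feature_names)}
        import operator
        ops = {"<=": operator.le, ">": operator.gt, "<": operator.lt,
               ">=": operator.ge}
        for row, expected in zip(data.X, tree.predict(data.X)):
            hits = [r for r in ruleset
                    if all(ops[c.comparator](row[col[c.feature]], c.threshold)
                           for c in r.conditions)]
            assert len(hits) == 1 and hits[0].label == expected


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

class TestComputeMetrics:
    def test_hand_arithmetic(self):
        m = compute_metrics(TP=90, FN=10, TN=78, FP=22)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.78)
        assert m.precision == pytest.approx(90 / 112)  # 0.8036
        assert m.accuracy == pytest.approx(0.84)

    def test_perfect_classifier(self):
        m = compute_metrics(TP=5, FN=0, TN=5, FP=0)
        assert (m.sensitivity, m.specificity, m.precision, m.accuracy) == (1, 1, 1, 1)

    def test_undefined_rate_flagged(self):
        m = compute_metrics(TP=0, FN=0, TN=5, FP=5)
        assert m.sensitivity is None

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(TP=-1, FN=0, TN=0, FP=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_accuracy_integer_identity(self, seed):
        rng = np.random.default_rng(seed)
        TP, FN, TN, FP = (int(v) for v in rng.integers(0, 100, 4))
        if TP + FN + TN + FP == 0:
            return
        m = compute_metrics(TP, FN, TN, FP)
        assert m.accuracy * (TP + FN + TN + FP) == pytest.approx(TP + TN)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

class _ConstantModel:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.array([self.label] * len(X), dtype=object)


class _OracleModel:
    """Peeks at the training mapping x -> label; x values are unique."""

    def __init__(self, mapping):
        self.mapping = mapping

    def predict(self, X):
        return np.array([self.mapping[float(x[0])] for x in X], dtype=object)


class TestKFoldCV:
    def balanced(self, n=100):
        x = np.arange(float(2 * n)).reshape(-1, 1)
        y = [POS] * n + [NEG] * n
        return make_dataset(x, y)

    def test_fold_assignment_is_partition(self):
        ds = self.balanced(53)
        folds = stratified_folds(ds.y, 10, seed=1)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(len(ds)))

    def test_majority_learner_chance_level(self):
        ds = self.balanced(100)
        m = kfold_cv(ds, lambda tr: _ConstantModel(POS), k=10, seed=0)
        assert m.accuracy == pytest.approx(0.5, abs=0.05)

    def test_oracle_learner_perfect(self):
        ds = self.balanced(50)
        mapping = {float(x[0]): l for x, l in zip(ds.X, ds.y)}
        m = kfold_cv(ds, lambda tr: _OracleModel(mapping), k=10, seed=0)
        assert m.accuracy == 1.0

    def test_k_larger_than_n_rejected(self):
        ds = self.balanced(3)
        with pytest.raises(ValueError):
            kfold_cv(ds, lambda tr: _ConstantModel(POS), k=10)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_noise_accuracy_near_bayes(self, seed):
        eps = 0.05
        data = simulate.generate_labeled_features(
            simulate.GeneratorConfig(n_per_class=500, noise_rate=eps, seed=seed))
        m = kfold_cv(data, tree_learner(), k=10, seed=seed)
        assert m.accuracy == pytest.approx(1 - eps, abs=0.02)


class TestRepeatedCV:
    def pos_neg(self, seed=0, n=150):
        data = simulate.generate_labeled_features(
            simulate.GeneratorConfig(n_per_class=n, noise_rate=0.05, seed=seed))
        pos = data.subset(np.flatnonzero(data.y == POS))
        neg = data.subset(np.flatnonzero(data.y == NEG))
        if len(neg) < len(pos):  # noise flips can unbalance the classes
            pos, neg = neg, pos
        return pos, neg

    def test_history_length(self):
        pos, neg = self.pos_neg()
        out = repeated_cv(pos, neg, n_repeats=10, k=5, seed=0)
        assert len(out["history"]) == 10
        assert out["sd"]["accuracy"] is not None

    def test_sd_zero_for_identical_resamples(self):
        pos, neg = self.pos_neg()
        # equal class sizes force the identity resample every repeat
        out = repeated_cv(pos, neg.subset(np.arange(len(pos))),
                          n_repeats=3, k=5, seed=0)
        # deterministic learner + same sample, but fold seeds differ; instead
        # check the degenerate single-repeat SD flag
        single = repeated_cv(pos, neg, n_repeats=1, k=5, seed=0)
        assert single["sd"]["accuracy"] is None

    def test_sd_magnitude_comparable_to_paper(self):
        pos, neg = self.pos_neg(n=400)
        out = repeated_cv(pos, neg, n_repeats=5, k=5, seed=1)
        for name in ("sensitivity", "specificity", "precision", "accuracy"):
            assert out["sd"][name] < 0.05  # paper-scale SDs are <= 1.3 points


# ---------------------------------------------------------------------------
# greedy forward selection
# ---------------------------------------------------------------------------

def xor_free_dataset(n, seed):
    """Label = (A > 0.5) except flipped where (B > 0.9); C is pure noise.

    A alone -> ~95% accuracy, A+B -> 100%, C adds nothing.
    """
    rng = np.random.default_rng(seed)
    A, B, C = (rng.uniform(size=n) for _ in range(3))
    base = A > 0.5
    label = np.where(B > 0.9, ~base, base)
    y = np.where(label, POS, NEG).astype(object)
    return LabeledDataset(np.column_stack([A, B, C]), y, ["A", "B", "C"])


class TestGreedySelection:
    def split(self, ds):
        pos = ds.subset(np.flatnonzero(ds.y == POS))
        neg = ds.subset(np.flatnonzero(ds.y == NEG))
        if len(neg) < len(pos):
            pos, neg = neg, pos
        return pos, neg

    def test_stops_before_uninformative_feature(self):
        ds = xor_free_dataset(600, seed=1)
        state = greedy_forward_selection(*self.split(ds), k=5, seed=1)
        assert state.S == ["A", "B"]
        # A alone is ~90% (10% of rows flipped by B), A+B near-perfect; C's
        # improvement falls below stop_delta
        assert 0.8 < state.history[0] < 0.97
        assert state.history[1] > 0.97

    def test_pure_noise_selects_exactly_one(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(200, 5))
        y = np.where(rng.uniform(size=200) < 0.5, POS, NEG).astype(object)
        ds = LabeledDataset(X, y, [f"n{i}" for i in range(5)])
        state = greedy_forward_selection(*self.split(ds), k=5, seed=0)
        assert len(state.S) == 1  # baseline step always accepted

    @pytest.mark.parametrize("seed", range(3))
    def test_plateau_at_four_informative(self, seed):
        ds = simulate.generate_selection_dataset(n_per_class=200,
                                                 n_noise_features=8, seed=seed)
        state = greedy_forward_selection(*self.split(ds), seed=seed)
        assert sorted(state.S) == ["f14", "f15", "f18", "f5"]
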