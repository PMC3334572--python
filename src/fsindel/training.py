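"""Decision-tree induction, cross-validation and greedy feature selection.

The learner is a C4.5-style binary tree over numeric features: splits are
chosen by information-gain maximization over midpoints of adjacent distinct
values, followed by confidence-based pessimistic pruning (subtree
replacement, default confidence 0.25, minimum leaf size 2).  It is not a
bit-identical reimplementation of J48; the claims it supports are at the
threshold/rule level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

from .genome_model import LABEL_DAMAGING, LABEL_NEUTRAL

LABELS = (LABEL_DAMAGING, LABEL_NEUTRAL)  # positive class first
POSITIVE_LABEL = LABEL_DAMAGING


# ---------------------------------------------------------------------------
# LabeledDataset
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Feature matrix + labels.  Labels are 'gene-damaging' (positive) or
    'neutral' (negative); rows with every feature missing are rejected."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    provenance: str = ""
    meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D and aligned with y")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X columns")
        bad = set(self.y) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if len(self.X) and np.isnan(self.X).all(axis=1).any():
            raise ValueError("row with all features uncomputable")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def class_counts(self) -> dict[str, int]:
        return {label: int((self.y == label).sum()) for label in LABELS}

    def subset(self, idx) -> "LabeledDataset":
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return LabeledDataset(self.X[idx], self.y[idx], list(self.feature_names),
                              self.provenance, meta)

    def select_features(self, names: Sequence[str]) -> "LabeledDataset":
        cols = [self.feature_names.index(n) for n in names]
        return LabeledDataset(self.X[:, cols], self.y, list(names),
                              self.provenance, self.meta)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.y
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "LabeledDataset":
        df = pd.read_csv(path, sep="\t")
        if "label" not in df.columns:
            raise ValueError(f"{path}: no 'label' column")
        names = [c for c in df.columns if c != "label"]
        return cls(df[names].to_numpy(dtype=float), df["label"].to_numpy(),
                   names, provenance or str(path))

    @classmethod
    def from_feature_vectors(cls, rows, provenance: str = "") -> "LabeledDataset":
        """rows: iterable of (FeatureVector, label); uses the four core features."""
        from .features import FEATURE_NAMES

        X, y = [], []
        for fv, label in rows:
            X.append([fv.value(n) if fv.is_computable(n) else np.nan
                      for n in FEATURE_NAMES])
            y.append(label)
        return cls(np.asarray(X, dtype=float), np.asarray(y, dtype=object),
                   list(FEATURE_NAMES), provenance)


def balanced_sample(positives: LabeledDataset, negatives: LabeledDataset,
                    seed: int) -> LabeledDataset:
    """All positives plus an equal-size uniform sample of negatives."""
    if positives.feature_names != negatives.feature_names:
        raise ValueError("feature names differ between classes")
    n_pos, n_neg = len(positives), len(negatives)
    if n_neg < n_pos:
        raise ValueError(f"need at least {n_pos} negatives, have {n_neg}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_neg, size=n_pos, replace=False) if n_neg > n_pos \
        else np.arange(n_neg)
    sampled = negatives.subset(np.sort(idx))
    return LabeledDataset(
        np.vstack([positives.X, sampled.X]),
        np.concatenate([positives.y, sampled.y]),
        list(positives.feature_names),
        provenance=f"balanced(seed={seed})",
    )


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------

@dataclass
class Node:
    counts: dict[str, int]
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["Node"] = None
    right: Optional["Node"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def label(self) -> str:
        # deterministic tie-break: positive class first in LABELS
        return max(LABELS, key=lambda l: self.counts.get(l, 0))

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass
class DecisionTree:
    root: Optional[Node]
    feature_names: list[str]
    params: dict = field(default_factory=dict)

    def predict_row(self, values: Sequence[float]) -> str:
        node = self.root
        col = {n: i for i, n in enumerate(self.feature_names)}
        while not node.is_leaf:
            node = node.left if values[col[node.feature]] <= node.threshold else node.right
        return node.label

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array([self.predict_row(row) for row in X], dtype=object)

    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))
        return d(self.root) if self.root else 0

    def n_leaves(self) -> int:
        def c(node):
            return 1 if node.is_leaf else c(node.left) + c(node.right)
        return c(self.root) if self.root else 0

    def to_json(self, path) -> None:
        def enc(node):
            if node is None:
                return None
            return {
                "counts": node.counts,
                "feature": node.feature,
                "threshold": node.threshold,
                "left": enc(node.left),
                "right": enc(node.right),
            }
        with open(path, "w") as fh:
            json.dump({"feature_names": self.feature_names, "params": self.params,
                       "root": enc(self.root)}, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "DecisionTree":
        with open(path) as fh:
            payload = json.load(fh)

        def dec(d):
            if d is None:
                return None
            return Node(counts=d["counts"], feature=d["feature"],
                        threshold=d["threshold"],
                        left=dec(d["left"]), right=dec(d["right"]))
        return cls(root=dec(payload["root"]), feature_names=payload["feature_names"],
                   params=payload.get("params", {}))


def _entropy(n_pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary entropy in bits; vectorized, 0*log0 = 0."""
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, n_pos / np.maximum(n, 1), 0.0)
        h = -p * np.log2(np.where(p > 0, p, 1)) \
            - (1 - p) * np.log2(np.where(p < 1, 1 - p, 1))
    return np.where(n > 0, h, 0.0)


def _best_split(X: np.ndarray, y_pos: np.ndarray, min_leaf: int):
    """Best (feature_index, threshold, gain) by information gain, or None."""
    n = len(y_pos)
    total_pos = int(y_pos.sum())
    parent_h = float(_entropy(np.array([total_pos]), np.array([n]))[0])
    best = None
    for j in range(X.shape[1]):
        xj = X[:, j]
        order = np.argsort(xj, kind="mergesort")
        xs, ys = xj[order], y_pos[order]
        # candidate split after index i (left size i+1)
        left_pos = np.cumsum(ys)[:-1]
        left_n = np.arange(1, n)
        distinct = xs[:-1] < xs[1:]
        valid = distinct & (left_n >= min_leaf) & ((n - left_n) >= min_leaf)
        if not valid.any():
            continue
        right_pos = total_pos - left_pos
        right_n = n - left_n
        child_h = (left_n * _entropy(left_pos, left_n)
                   + right_n * _entropy(right_pos, right_n)) / n
        gain = parent_h - child_h
        gain[~valid] = -np.inf
        i = int(np.argmax(gain))
        if gain[i] > 1e-12 and (best is None or gain[i] > best[2] + 1e-12):
            best = (j, float((xs[i] + xs[i + 1]) / 2.0), float(gain[i]))
    return best


def _pessimistic_errors(n: int, e: int, cf: float) -> float:
    """C4.5-style pessimistic error count: n times the exact binomial upper
    confidence limit on the error rate (for e=0 this is 1 - cf**(1/n))."""
    if n == 0:
        return 0.0
    if e >= n:
        return float(n)
    return float(n * beta.ppf(1.0 - cf, e + 1, n - e))


def induce_tree(
    data: LabeledDataset,
    features: Optional[Sequence[str]] = None,
    pruning_confidence: float = 0.25,
    min_leaf: int = 2,
    prune: bool = True,
) -> DecisionTree:
    """Grow a binary information-gain tree, then prune by subtree replacement
    using the pessimistic error estimate.  Single-class data yields a single
    leaf."""
    if len(data) < 2:
        raise ValueError("need at least 2 rows")
    ds = data.select_features(list(features)) if features is not None else data
    if not ds.feature_names:
        raise ValueError("need at least one feature")
    X = ds.X
    if np.isnan(X).any():
        raise ValueError("NaN feature values; drop or impute before training")
    y_pos = (ds.y == POSITIVE_LABEL).astype(np.int64)

    def counts_of(ypos_sub) -> dict[str, int]:
        npos = int(ypos_sub.sum())
        return {POSITIVE_LABEL: npos, LABEL_NEUTRAL: len(ypos_sub) - npos}

    def grow(idx: np.ndarray) -> Node:
        node = Node(counts=counts_of(y_pos[idx]))
        npos = node.counts[POSITIVE_LABEL]
        if npos == 0 or npos == len(idx):
            return node
        split = _best_split(X[idx], y_pos[idx], min_leaf)
        if split is None:
            return node
        j, thr, _ = split
        mask = X[idx, j] <= thr
        node.feature = ds.feature_names[j]
        node.threshold = thr
        node.left = grow(idx[mask])
        node.right = grow(idx[~mask])
        return node

    root = grow(np.arange(len(ds)))

    if prune:
        def prune_node(node: Node) -> float:
            n = node.n
            e_leaf_count = n - node.counts.get(node.label, 0)
            e_leaf = _pessimistic_errors(n, e_leaf_count, pruning_confidence)
            if node.is_leaf:
                return e_leaf
            e_subtree = prune_node(node.left) + prune_node(node.right)
            if e_leaf <= e_subtree + 1e-9:
                node.feature = node.threshold = node.left = node.right = None
                return e_leaf
            return e_subtree

        prune_node(root)

    return DecisionTree(
        root=root,
        feature_names=list(ds.feature_names),
        params={"pruning_confidence": pruning_confidence, "min_leaf": min_leaf,
                "pruned": prune},
    )


def tree_learner(**params) -> Callable[[LabeledDataset], DecisionTree]:
    """Learner factory for :func:`kfold_cv`."""
    def fit(train: LabeledDataset) -> DecisionTree:
        return induce_tree(train, **params)
    return fit


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerformanceMetrics:
    TP: int
    TN: int
    FP: int
    FN: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    accuracy: Optional[float]

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "accuracy": self.accuracy,
        }


def compute_metrics(TP: int, FN: int, TN: int, FP: int) -> PerformanceMetrics:
    """sensitivity=TP/(TP+FN), specificity=TN/(TN+FP), precision=TP/(TP+FP),
    accuracy=(TP+TN)/(TP+FN+TN+FP); a rate with zero denominator is None."""
    for name, v in (("TP", TP), ("FN", FN), ("TN", TN), ("FP", FP)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")

    def rate(num, den):
        return num / den if den > 0 else None

    return PerformanceMetrics(
        TP=TP, TN=TN, FP=FP, FN=FN,
        sensitivity=rate(TP, TP + FN),
        specificity=rate(TN, TN + FP),
        precision=rate(TP, TP + FP),
        accuracy=rate(TP + TN, TP + FN + TN + FP),
    )


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    pos = y_true == POSITIVE_LABEL
    pred_pos = y_pred == POSITIVE_LABEL
    TP = int((pos & pred_pos).sum())
    FN = int((pos & ~pred_pos).sum())
    TN = int((~pos & ~pred_pos).sum())
    FP = int((~pos & pred_pos).sum())
    return TP, FN, TN, FP


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified partition: shuffle within class, deal round-robin."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in LABELS:
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        for i, row in enumerate(idx):
            folds[i % k].append(int(row))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def kfold_cv(
    data: LabeledDataset,
    learner: Callable[[LabeledDataset], object],
    k: int = 10,
    seed: int = 0,
    mode: str = "pooled",
) -> PerformanceMetrics:
    """Stratified k-fold cross-validation.

    mode='pooled' (default) pools the confusion counts over folds and
    computes the metrics once; mode='fold-mean' averages per-fold rates.
    """
    if k > len(data):
        raise ValueError(f"k={k} exceeds dataset size {len(data)}")
    folds = stratified_folds(data.y, k, seed)
    counts = np.zeros(4, dtype=int)
    fold_metrics = []
    all_idx = np.arange(len(data))
    for test_idx in folds:
        if len(test_idx) == 0:
            continue
        train_idx = np.setdiff1d(all_idx, test_idx)
        model = learner(data.subset(train_idx))
        pred = model.predict(data.X[test_idx])
        c = _confusion(data.y[test_idx], np.asarray(pred, dtype=object))
        counts += np.array(c)
        fold_metrics.append(compute_metrics(*c))
    if mode == "pooled":
        return compute_metrics(*counts)
    if mode == "fold-mean":
        def mean(attr):
            vals = [getattr(m, attr) for m in fold_metrics if getattr(m, attr) is not None]
            return float(np.mean(vals)) if vals else None
        return PerformanceMetrics(
            TP=int(counts[0]), FN=int(counts[1]), TN=int(counts[2]), FP=int(counts[3]),
            sensitivity=mean("sensitivity"), specificity=mean("specificity"),
            precision=mean("precision"), accuracy=mean("accuracy"),
        )
    raise ValueError(f"unknown mode {mode!r}")


METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy")


def repeated_cv(
    positives: LabeledDataset,
    negatives: LabeledDataset,
    learner: Optional[Callable[[LabeledDataset], object]] = None,
    n_repeats: int = 10,
    k: int = 10,
    seed: int = 0,
    mode: str = "pooled",
) -> dict:
    """n_repeats x (resample negatives, k-fold CV); mean and sample SD per metric.

    Returns {"history": [metrics...], "mean": {...}, "sd": {...}, "seeds": [...]}.
    SD entries are None (flagged) when n_repeats < 2.
    """
    learner = learner or tree_learner()
    child_seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    history: list[PerformanceMetrics] = []
    seeds_used: list[int] = []
    for ss in child_seeds:
        s = int(ss.generate_state(1)[0] % (2**31 - 1))
        seeds_used.append(s)
        sample = balanced_sample(positives, negatives, seed=s)
        history.append(kfold_cv(sample, learner, k=k, seed=s, mode=mode))
    out = {"history": history, "seeds": seeds_used, "mean": {}, "sd": {}}
    for name in METRIC_NAMES:
        vals = [getattr(m, name) for m in history if getattr(m, name) is not None]
        out["mean"][name] = float(np.mean(vals)) if vals else None
        out["sd"][name] = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
    return out


# ---------------------------------------------------------------------------
# greedy forward feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionState:
    """S: chosen features in order; A: remaining candidates; history:
    CV accuracy after each addition (the first feature is always accepted)."""

    S: list[str]
    A: list[str]
    history: list[float]
    ties: list[list[str]] = field(default_factory=list)

    @property
    def N(self) -> int:
        return len(self.A)


def greedy_forward_selection(
    positives: LabeledDataset,
    negatives: LabeledDataset,
    all_features: Optional[Sequence[str]] = None,
    stop_delta: float = 0.001,
    k: int = 10,
    seed: int = 0,
    learner_params: Optional[dict] = None,
) -> SelectionState:
    """Add the feature with the largest CV-accuracy improvement each round;
    stop when the best improvement is below ``stop_delta`` (accuracies as
    fractions, so 0.001 = 0.1%).  One balanced sampling is drawn up front
    and reused for every evaluation.  Ties go to feature-list order."""
    sample = balanced_sample(positives, negatives, seed=seed)
    A = list(all_features) if all_features is not None else list(sample.feature_names)
    if not A:
        raise ValueError("need at least one candidate feature")
    params = learner_params or {}
    S: list[str] = []
    history: list[float] = []
    ties: list[list[str]] = []
    best_so_far = -np.inf
    while A:
        accs = []
        for f in A:
            learner = tree_learner(features=None, **params)
            acc = kfold_cv(sample.select_features(S + [f]), learner, k=k, seed=seed).accuracy
            accs.append(acc if acc is not None else 0.0)
        i = int(np.argmax(accs))
        improvement = accs[i] - best_so_far if S else np.inf  # first always accepted
        if improvement < stop_delta:
            break
        tied = [A[j] for j, a in enumerate(accs) if abs(a - accs[i]) < 1e-12]
        if len(tied) > 1:
            ties.append(tied)
        best_so_far = accs[i]
        S.append(A.pop(i))
        history.append(accs[i])
    return SelectionState(S=S, A=A, history=history, ties=ties)


def write_cv_report(result: dict, path) -> None:
    """Per-repeat metric rows plus mean/SD summary rows, as TSV."""
    with open(path, "w") as fh:
        fh.write("repeat\tseed\tTP\tFN\tTN\tFP\tsensitivity\tspecificity\tprecision\taccuracy\n")
        for i, (m, s) in enumerate(zip(result["history"], result["seeds"]), start=1):
            fh.write(
                f"{i}\t{s}\t{m.TP}\t{m.FN}\t{m.TN}\t{m.FP}\t"
                + "\t".join(_fmt(getattr(m, n)) for n in METRIC_NAMES) + "\n"
            )
        for row_name, stats in (("mean", result["mean"]), ("sd", result["sd"])):
            fh.write(f"{row_name}\t\t\t\t\t\t"
                     + "\t".join(_fmt(stats[n]) for n in METRIC_NAMES) + "\n")


def _fmt(x) -> str:
    return "" if x is None else f"{x:.4f}"
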