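"""Random-forest evaluation of higher-order AGO sorting signals.

The classifier is a class-balanced random forest over categorical
per-position features: each tree is grown on a bootstrap of a fixed number
of draws (with replacement) from every class, splits are found by
exhaustive enumeration of binary category subsets minimizing Gini impurity
(feasible because the alphabets have at most five symbols), and trees grow
to purity.  Accuracy, margins, and variable importance all come from the
out-of-bag (OOB) samples, the forest's internal cross-validation.

The comparison protocol trains forests under two feature conditions over
many repeated runs and reports the median two-sided Wilcoxon rank-sum
p-value between the per-sample OOB margin vectors, a bootstrap-style
estimate that respects the original dataset size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .confidence import ConfidenceSet
from .duplex import UNPAIRED, WC, WOBBLE, DuplexPattern

logger = logging.getLogger("agosort")

SEQUENCE_ALPHABET = ("A", "C", "G", "U", "N")
PAIRING_ALPHABET = ("bound", "unbound", "wobble")


@dataclass
class FeatureMatrix:
    """Samples x positions categorical feature matrix.

    ``X`` holds integer category codes into ``alphabet``; ``positions``
    keeps the original 1-based sequence positions of the columns (so a
    matrix without the first position still reports importance against the
    right coordinates).
    """

    X: np.ndarray
    alphabet: tuple
    positions: list[int]
    mode: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.X.shape[1] != len(self.positions):
            raise ValueError("positions do not match matrix columns")
        if self.X.size and (self.X.min() < 0 or self.X.max() >= len(self.alphabet)):
            raise ValueError("category codes outside the declared alphabet")


def encode_features(
    cset: ConfidenceSet,
    mode: str = "sequence",
    include_first: bool = True,
    patterns: Mapping[str, DuplexPattern] | None = None,
    length: int = 24,
) -> FeatureMatrix:
    """Encode confidence-set members as categorical position features.

    ``sequence`` mode: the 5'-anchored mature sequence over {A,C,G,U,N},
    3'-padded with N to ``length`` (24 by default, so sequence length is
    implicitly encoded by the trailing Ns).  ``pairing`` mode: the duplex
    state per position over {bound, unbound, wobble}, where bound means a
    Watson-Crick pair; positions beyond the inferred duplex are assumed
    unbound.  ``include_first=False`` drops position 1, used to isolate
    signals beyond the already-established 5'-terminal base.
    """
    if mode == "sequence":
        code = {b: i for i, b in enumerate(SEQUENCE_ALPHABET)}
        rows = []
        for e in cset.entries:
            seq = (e.full_seq[:length]).ljust(length, "N")
            rows.append([code[c] for c in seq])
        alphabet = SEQUENCE_ALPHABET
    elif mode == "pairing":
        if patterns is None:
            raise ValueError("pairing mode requires duplex patterns")
        state_code = {WC: 0, UNPAIRED: 1, WOBBLE: 2}
        rows = []
        for e in cset.entries:
            if e.id not in patterns:
                raise ValueError(f"no duplex pattern for {e.id}")
            states = patterns[e.id].states[:length]
            row = [state_code[s] for s in states]
            row.extend([1] * (length - len(row)))  # 3' end assumed unbound
            rows.append(row)
        alphabet = PAIRING_ALPHABET
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    X = np.array(rows, dtype=np.int64)
    positions = list(range(1, length + 1))
    if not include_first:
        X = X[:, 1:]
        positions = positions[1:]
    return FeatureMatrix(X=X, alphabet=alphabet, positions=positions, mode=mode)


def first_position_only(features: FeatureMatrix) -> FeatureMatrix:
    """Restrict a feature matrix to position 1 (the 5'-terminal base)."""
    if features.positions[0] != 1:
        raise ValueError("feature matrix does not contain position 1")
    return FeatureMatrix(
        X=features.X[:, :1],
        alphabet=features.alphabet,
        positions=[1],
        mode=features.mode,
    )


@dataclass
class _Tree:
    feature: np.ndarray      # split feature per node, -1 at leaves
    left_mask: np.ndarray    # bitmask over category codes routed left
    left: np.ndarray
    right: np.ndarray
    leaf_class: np.ndarray   # class code at leaves, -1 at internal nodes
    oob_idx: np.ndarray      # sample indices never drawn into the bootstrap


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    mtry: int,
    n_classes: int,
    n_cat: int,
    rng: np.random.Generator,
) -> tuple[list, list, list, list, list]:
    n_features = X.shape[1]
    feature: list[int] = []
    left_mask: list[int] = []
    left: list[int] = []
    right: list[int] = []
    leaf: list[int] = []

    def new_node() -> int:
        feature.append(-1)
        left_mask.append(0)
        left.append(-1)
        right.append(-1)
        leaf.append(-1)
        return len(feature) - 1

    def grow(indices: np.ndarray) -> int:
        node = new_node()
        ys = y[indices]
        counts = np.bincount(ys, minlength=n_classes)
        n_node = len(indices)
        if counts.max() == n_node:
            leaf[node] = int(np.argmax(counts))
            return node
        parent_gini = 1.0 - float(((counts / n_node) ** 2).sum())
        feats = rng.choice(n_features, size=min(mtry, n_features), replace=False)
        best_dec = 1e-12
        best_f = -1
        best_mask = 0
        for f in feats:
            xv = X[indices, f]
            cnt = np.bincount(ys * n_cat + xv, minlength=n_classes * n_cat).reshape(
                n_classes, n_cat
            )
            cats = np.flatnonzero(cnt.sum(axis=0))
            k = len(cats)
            if k < 2:
                continue
            # column class-count vectors as plain lists: the subset loop is
            # pure-Python arithmetic on at most 5 columns
            cols = [cnt[:, c].tolist() for c in cats]
            tot = counts.tolist()
            for m in range(1, 1 << (k - 1)):
                lc = [0.0] * n_classes
                for t in range(k - 1):
                    if m >> t & 1:
                        col = cols[t]
                        for c in range(n_classes):
                            lc[c] += col[c]
                nl = sum(lc)
                nr = n_node - nl
                if nl == 0 or nr == 0:
                    continue
                sl = sum(v * v for v in lc)
                sr = sum((tot[c] - lc[c]) ** 2 for c in range(n_classes))
                dec = parent_gini - ((nl - sl / nl) + (nr - sr / nr)) / n_node
                if dec > best_dec:
                    best_dec = dec
                    best_f = int(f)
                    bm = 0
                    for t in range(k - 1):
                        if m >> t & 1:
                            bm |= 1 << int(cats[t])
                    best_mask = bm
        if best_f < 0:
            leaf[node] = int(np.argmax(counts))
            return node
        go_left = (best_mask >> X[indices, best_f]) & 1
        li = grow(indices[go_left == 1])
        ri = grow(indices[go_left == 0])
        feature[node] = best_f
        left_mask[node] = best_mask
        left[node] = li
        right[node] = ri
        return node

    grow(idx)
    return feature, left_mask, left, right, leaf


def _predict_tree(tree: _Tree, X: np.ndarray, rows: np.ndarray) -> np.ndarray:
    node = np.zeros(len(rows), dtype=np.int64)
    active = tree.leaf_class[node] < 0
    while np.any(active):
        act_nodes = node[active]
        f = tree.feature[act_nodes]
        xv = X[rows[active], f]
        go_left = ((tree.left_mask[act_nodes] >> xv) & 1).astype(bool)
        nxt = np.where(go_left, tree.left[act_nodes], tree.right[act_nodes])
        node[active] = nxt
        active = tree.leaf_class[node] < 0
    return tree.leaf_class[node]


@dataclass
class ForestResult:
    """A fitted forest with its OOB bookkeeping."""

    classes: list[str]
    trees: list[_Tree] = field(repr=False, default_factory=list)
    oob_votes: np.ndarray = field(repr=False, default=None)  # samples x classes
    oob_tree_counts: np.ndarray = field(repr=False, default=None)
    oob_accuracy: float = 0.0
    n_trees: int = 0
    sampsize: int = 0
    mtry: int = 0
    seed: int = 0

    def vote_fractions(self) -> np.ndarray:
        """Per-sample OOB vote fractions (rows sum to 1 where defined)."""
        counts = self.oob_votes.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, self.oob_votes / counts, np.nan)


def train_forest(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str],
    n_trees: int = 500,
    sampsize: int = 20,
    mtry: int | None = None,
    seed: int | np.random.Generator = 0,
) -> ForestResult:
    """Fit a class-balanced categorical random forest and collect OOB votes.

    Every tree draws ``sampsize`` samples with replacement from each class
    (balanced bootstrap), splits by exhaustive binary category-subset
    search on ``mtry`` candidate features per node (default
    floor(sqrt(p))), and grows to purity.  OOB votes are aggregated over
    the trees for which a sample was out of bag; the OOB accuracy is the
    fraction of correct majority-vote assignments, with ties broken by the
    fixed (sorted) class order.
    """
    if isinstance(features, FeatureMatrix):
        X = features.X
        n_cat = len(features.alphabet)
    else:
        X = np.asarray(features, dtype=np.int64)
        n_cat = int(X.max()) + 1 if X.size else 1
    labels = list(labels)
    if X.shape[0] != len(labels):
        raise ValueError("features and labels differ in length")
    classes = sorted(set(labels))
    class_code = {c: i for i, c in enumerate(classes)}
    y = np.array([class_code[c] for c in labels])
    for c in classes:
        if labels.count(c) < 2:
            raise ValueError(f"class {c} has fewer than 2 members")
    n, p = X.shape
    if mtry is None:
        mtry = max(1, int(np.sqrt(p)))
    if isinstance(seed, np.random.Generator):
        rng = seed
        seed_val = -1
    else:
        rng = np.random.default_rng(seed)
        seed_val = int(seed)

    class_indices = [np.flatnonzero(y == class_code[c]) for c in classes]
    oob_votes = np.zeros((n, len(classes)), dtype=np.int64)
    oob_tree_counts = np.zeros(n, dtype=np.int64)
    trees: list[_Tree] = []
    all_idx = np.arange(n)
    for _ in range(n_trees):
        inbag_parts = [rng.choice(ci, size=sampsize, replace=True) for ci in class_indices]
        inbag = np.concatenate(inbag_parts)
        oob = np.setdiff1d(all_idx, inbag, assume_unique=False)
        fa, ma, la, ra, lf = _grow_tree(X, y, inbag, mtry, len(classes), n_cat, rng)
        tree = _Tree(
            feature=np.array(fa, dtype=np.int64),
            left_mask=np.array(ma, dtype=np.int64),
            left=np.array(la, dtype=np.int64),
            right=np.array(ra, dtype=np.int64),
            leaf_class=np.array(lf, dtype=np.int64),
            oob_idx=oob,
        )
        trees.append(tree)
        if len(oob):
            pred = _predict_tree(tree, X, oob)
            oob_votes[oob, pred] += 1
            oob_tree_counts[oob] += 1

    covered = oob_tree_counts > 0
    n_uncovered = int(np.sum(~covered))
    if n_uncovered:
        logger.info("train_forest: %d samples never out of bag, excluded from OOB metrics", n_uncovered)
    majority = np.argmax(oob_votes[covered], axis=1)  # ties resolve to the lowest class code
    oob_accuracy = float(np.mean(majority == y[covered])) if covered.any() else float("nan")
    return ForestResult(
        classes=classes,
        trees=trees,
        oob_votes=oob_votes,
        oob_tree_counts=oob_tree_counts,
        oob_accuracy=oob_accuracy,
        n_trees=n_trees,
        sampsize=sampsize,
        mtry=mtry,
        seed=seed_val,
    )


def margins(result: ForestResult, labels: Sequence[str]) -> np.ndarray:
    """OOB margin per sample: vote fraction for the true class minus the
    maximum vote fraction for any other class.  Samples never out of bag
    are excluded (logged by train_forest)."""
    class_code = {c: i for i, c in enumerate(result.classes)}
    y = np.array([class_code[c] for c in labels])
    fracs = result.vote_fractions()
    covered = result.oob_tree_counts > 0
    out = []
    for i in np.flatnonzero(covered):
        true_frac = fracs[i, y[i]]
        others = np.delete(fracs[i], y[i])
        out.append(true_frac - others.max())
    return np.array(out)


def variable_importance(
    result: ForestResult,
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Mean-decrease-accuracy importance per feature (unscaled).

    For every tree, each feature's values are permuted within the tree's
    OOB set and the drop in OOB accuracy recorded; the importance is the
    average drop over trees.  A feature the forest never uses — or one
    constant across samples — scores zero in expectation.
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features)
    class_code = {c: i for i, c in enumerate(result.classes)}
    y = np.array([class_code[c] for c in labels])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = X.shape[1]
    total = np.zeros(p)
    n_used = 0
    for tree in result.trees:
        oob = tree.oob_idx
        if len(oob) == 0:
            continue
        n_used += 1
        Xo = X[oob].copy()
        rows = np.arange(len(oob))
        base_acc = float(np.mean(_predict_tree_local(tree, Xo, rows) == y[oob]))
        for f in range(p):
            saved = Xo[:, f].copy()
            Xo[:, f] = saved[rng.permutation(len(oob))]
            acc = float(np.mean(_predict_tree_local(tree, Xo, rows) == y[oob]))
            Xo[:, f] = saved
            total[f] += base_acc - acc
    if n_used == 0:
        raise ValueError("forest has no OOB samples")
    return total / n_used


def _predict_tree_local(tree: _Tree, X: np.ndarray, rows: np.ndarray) -> np.ndarray:
    return _predict_tree(tree, X, rows)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two samples.

    Exact for small samples (<= 25 per group, no ties), otherwise the
    normal approximation with midranks and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_conditions(
    features_a: FeatureMatrix,
    features_b: FeatureMatrix,
    labels: Sequence[str],
    n_runs: int = 1000,
    seed: int = 0,
    shuffle: str | None = None,
    n_trees: int = 500,
    sampsize: int = 20,
) -> dict:
    """Repeated-run forest comparison between two feature conditions.

    Per run both conditions are trained with the same bootstrap seed and
    their OOB margin vectors compared by a two-sided Wilcoxon rank-sum
    test; the reported p-value is the median over runs.  ``shuffle``
    ('a' or 'b') makes that condition a class-shuffled null, with a fresh
    label permutation drawn on every run.
    """
    labels = list(labels)
    base = np.random.SeedSequence(seed)
    children = base.spawn(n_runs)
    p_values: list[float] = []
    acc_a: list[float] = []
    acc_b: list[float] = []
    for child in children:
        rng = np.random.default_rng(child)
        run_seed = int(rng.integers(0, 2**31 - 1))
        labels_a = labels
        labels_b = labels
        if shuffle == "a":
            labels_a = [labels[i] for i in rng.permutation(len(labels))]
        elif shuffle == "b":
            labels_b = [labels[i] for i in rng.permutation(len(labels))]
        elif shuffle is not None:
            raise ValueError("shuffle must be None, 'a', or 'b'")
        res_a = train_forest(features_a, labels_a, n_trees=n_trees, sampsize=sampsize, seed=run_seed)
        res_b = train_forest(features_b, labels_b, n_trees=n_trees, sampsize=sampsize, seed=run_seed)
        m_a = margins(res_a, labels_a)
        m_b = margins(res_b, labels_b)
        p_values.append(wilcoxon_rank_sum(m_a, m_b))
        acc_a.append(res_a.oob_accuracy)
        acc_b.append(res_b.oob_accuracy)
    return {
        "median_p": float(np.median(p_values)),
        "p_values": p_values,
        "acc_a": acc_a,
        "acc_b": acc_b,
        "mean_acc_a": float(np.mean(acc_a)),
        "mean_acc_b": float(np.mean(acc_b)),
        "n_runs": n_runs,
    }
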