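"""Homology-aware splits, forward feature selection and the classifier.

Instances (pentamer pairs) reference source proteins; proteins connected by
a similarity edge — from an external all-vs-all search or from the global
identity fallback — must never end up on opposite sides of a train/test
boundary.  Connected components of the similarity graph are therefore
assigned atomically, both for the one-fifth selection holdout and for the
10-fold rotation.

The classifier is an L2-regularized logistic regression (scikit-learn
LBFGS backend); forward selection greedily grows the descriptor set by
mean cross-validated AUC and stops when the best improvement is at most
``stop_delta``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Hashable, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .evaluation import roc_auc

__all__ = [
    "FoldAssignment",
    "SelectionStep",
    "SelectionTrace",
    "TrainedModel",
    "assign_folds",
    "holdout_selection_split",
    "train_logreg",
    "predict_proba",
    "forward_select",
]


@dataclass
class FoldAssignment:
    """Map from instance id to fold index in ``0..k-1``."""

    fold_of: dict[Hashable, int]
    k: int

    def members(self, fold: int) -> list[Hashable]:
        return [i for i, f in self.fold_of.items() if f == fold]


@dataclass(frozen=True)
class SelectionStep:
    name: str
    fold_aucs: tuple[float, ...]
    mean_auc: float


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    stopped_reason: str = "exhausted"  # "converged" or "exhausted"

    @property
    def selected(self) -> list[str]:
        return [s.name for s in self.steps]


@dataclass
class TrainedModel:
    """Logistic model: probability of class "change" from a feature vector."""

    weights: np.ndarray
    intercept: float
    regularization: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": list(map(float, self.weights)),
                "intercept": float(self.intercept),
                "regularization": float(self.regularization),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        data = json.loads(text)
        return cls(
            weights=np.array(data["weights"], dtype=float),
            intercept=float(data["intercept"]),
            regularization=float(data["regularization"]),
        )


# ---------------------------------------------------------------------------
# similarity components

class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[Hashable, Hashable] = {}

    def find(self, x: Hashable) -> Hashable:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: Hashable, b: Hashable) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _instance_components(
    instances: Sequence[tuple[Hashable, Iterable[Hashable]]],
    similarity_edges: Iterable[tuple[Hashable, Hashable]],
) -> list[list[Hashable]]:
    """Group instances whose source proteins are transitively similar.

    Proteins referenced by the same instance are implicitly similar (the
    instance itself ties them together).
    """
    uf = _UnionFind()
    for _, proteins in instances:
        proteins = list(proteins)
        for p in proteins:
            uf.find(p)
        for p in proteins[1:]:
            uf.union(proteins[0], p)
    for a, b in similarity_edges:
        uf.union(a, b)

    groups: dict[Hashable, list[Hashable]] = {}
    for inst_id, proteins in instances:
        root = uf.find(next(iter(proteins)))
        groups.setdefault(root, []).append(inst_id)
    return list(groups.values())


def assign_folds(
    instances: Sequence[tuple[Hashable, Iterable[Hashable]]],
    similarity_edges: Iterable[tuple[Hashable, Hashable]],
    k: int = 10,
    seed: int = 0,
) -> FoldAssignment:
    """Assign instances to ``k`` folds without splitting similarity components.

    Components go to folds atomically, largest first, each into the
    currently smallest fold; ties are broken by a seeded shuffle.  A
    component larger than ``n/k`` triggers a warning but stays atomic.
    """
    components = _instance_components(instances, similarity_edges)
    rng = np.random.default_rng(seed)
    rng.shuffle(components)
    components.sort(key=len, reverse=True)  # stable: ties keep shuffled order

    total = sum(len(c) for c in components)
    if components and len(components[0]) > total / k:
        warnings.warn(
            f"similarity component of size {len(components[0])} exceeds the "
            f"balanced fold size {total / k:.1f}; fold sizes will be skewed",
            stacklevel=2,
        )

    fold_sizes = [0] * k
    fold_of: dict[Hashable, int] = {}
    for comp in components:
        fold = int(np.argmin(fold_sizes))
        for inst in comp:
            fold_of[inst] = fold
        fold_sizes[fold] += len(comp)
    return FoldAssignment(fold_of=fold_of, k=k)


def holdout_selection_split(
    instances: Sequence[tuple[Hashable, Iterable[Hashable]]],
    similarity_edges: Iterable[tuple[Hashable, Hashable]],
    fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[Hashable], list[Hashable]]:
    """Split off a feature-selection holdout with no cross-split similarity.

    Components are accumulated in seeded random order into the selection
    set until it holds at least ``fraction`` of all instances; everything
    else is the main set.  Raises if the main set would be empty (e.g. a
    single giant component).
    """
    components = _instance_components(instances, similarity_edges)
    rng = np.random.default_rng(seed)
    rng.shuffle(components)

    total = sum(len(c) for c in components)
    target = fraction * total
    selection: list[Hashable] = []
    main: list[Hashable] = []
    for comp in components:
        if len(selection) < target:
            selection.extend(comp)
        else:
            main.extend(comp)
    if not main:
        sizes = sorted((len(c) for c in components), reverse=True)
        raise ValueError(
            f"cannot split: selection set swallowed all {total} instances "
            f"(component sizes {sizes[:5]}...); similarity graph too connected"
        )
    return selection, main


# ---------------------------------------------------------------------------
# classifier

def train_logreg(
    X: np.ndarray, y: np.ndarray, reg_strength: float = 1.0
) -> TrainedModel:
    """Fit an L2-regularized logistic regression.

    Minimizes ``0.5 * lambda * ||w||^2 + sum_i log(1 + exp(-y_i f(x_i)))``
    with ``lambda = reg_strength`` (intercept unpenalized), to gradient
    tolerance 1e-6.  Deterministic given identical inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, d) with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    clf = LogisticRegression(
        C=1.0 / reg_strength,
        solver="lbfgs",
        tol=1e-6,
        max_iter=10_000,
    )
    clf.fit(X, y)
    return TrainedModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        regularization=reg_strength,
    )


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Probability of class "change"; always in the open interval (0, 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.weights):
        raise ValueError(
            f"feature width {X.shape[-1]} does not match model width "
            f"{len(model.weights)}"
        )
    z = np.clip(X @ model.weights + model.intercept, -700.0, 700.0)
    p = 1.0 / (1.0 + np.exp(-z))
    eps = 1e-15
    return np.clip(p, eps, 1.0 - eps)


# ---------------------------------------------------------------------------
# forward selection

def _cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    cols: np.ndarray,
    fold_idx: np.ndarray,
    k: int,
    reg_strength: float,
) -> tuple[float, ...]:
    aucs = []
    for f in range(k):
        test = fold_idx == f
        train = ~test
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            continue
        model = train_logreg(X[np.ix_(train, cols)], y[train], reg_strength)
        probs = predict_proba(model, X[np.ix_(test, cols)])
        aucs.append(roc_auc(probs, y[test])[1])
    if not aucs:
        raise ValueError("no fold had both classes in train and test")
    return tuple(aucs)


def forward_select(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[tuple[str, Sequence[int]]],
    folds: FoldAssignment,
    stop_delta: float = 1e-3,
    reg_strength: float = 1.0,
    max_rounds: Optional[int] = None,
) -> SelectionTrace:
    """Greedy forward feature selection by mean cross-validated AUC.

    ``candidates`` maps candidate names to column index groups in ``X``;
    ``folds.fold_of`` must map row indices to folds.  Each round, every
    remaining candidate is appended to the accepted set and scored by a
    full k-fold rotation; the best is accepted while it improves the mean
    AUC by more than ``stop_delta`` over the current level (baseline 0.5).
    Ties break lexicographically by candidate name.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    trace = SelectionTrace()
    if not candidates:
        return trace

    fold_idx = np.array([folds.fold_of[i] for i in range(len(y))])
    remaining = sorted(
        ((name, np.asarray(cols, dtype=int)) for name, cols in candidates),
        key=lambda item: item[0],
    )
    accepted_cols: list[int] = []
    current_auc = 0.5
    rounds = 0
    while remaining:
        if max_rounds is not None and rounds >= max_rounds:
            trace.stopped_reason = "exhausted"
            return trace
        rounds += 1
        best = None
        for name, cols in remaining:
            trial = np.concatenate([accepted_cols, cols]).astype(int)
            fold_aucs = _cv_auc(X, y, trial, fold_idx, folds.k, reg_strength)
            mean_auc = float(np.mean(fold_aucs))
            if best is None or mean_auc > best[2]:
                best = (name, fold_aucs, mean_auc, cols)
        name, fold_aucs, mean_auc, cols = best
        if mean_auc - current_auc <= stop_delta:
            trace.stopped_reason = "converged"
            return trace
        trace.steps.append(
            SelectionStep(name=name, fold_aucs=fold_aucs, mean_auc=mean_auc)
        )
        accepted_cols.extend(cols.tolist())
        current_auc = mean_auc
        remaining = [(n, c) for n, c in remaining if n != name]
    trace.stopped_reason = "exhausted"
    return trace
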