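"""Random-subspace ensemble of single-hidden-layer perceptrons.

The random subspace method (RSM) builds an ensemble by training each base
classifier on a random subset of *feature dimensions* (not of samples, as in
bagging):

1. draw ``M`` distinct feature indices from the ``d``-dimensional space;
2. project the training data onto those features;
3. train an MLP on the projection;
4. repeat ``L`` times (features may recur across members);
5. classify by majority vote over the ``L`` member predictions.

Base classifiers are single-hidden-layer perceptrons with sigmoidal hidden
units and one output per class, trained with a full-batch quasi-Newton
optimizer (L-BFGS) for up to 500 epochs.  Member diversity comes from the
random subspaces and from hidden-layer widths drawn uniformly from a range
(default 30..50).  Evaluation uses repeated stratified holdout: per run, a
fraction of each class is reserved for testing, a fresh ensemble is trained,
and row-normalized confusion matrices (in percent) are averaged over runs.
Feature normalization to [-1, 1] is refit on each run's training rows so no
test information leaks into the preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix
from sklearn.neural_network import MLPClassifier

from .fusion import FeatureTable, apply_normalizer, fit_normalizer

__all__ = [
    "BaseClassifierConfig",
    "SubspaceSpec",
    "EnsembleMember",
    "EnsembleModel",
    "EvaluationReport",
    "subspace_dim",
    "sample_subspaces",
    "train_mlp",
    "train_rs_ensemble",
    "predict_ensemble",
    "evaluate_holdout",
]


@dataclass(frozen=True)
class BaseClassifierConfig:
    """Contract for the MLP base classifier.

    ``hidden_range`` is the inclusive interval from which each member's
    hidden-layer width is drawn; ``epochs`` caps the optimizer iterations.
    """

    hidden_range: tuple[int, int] = (30, 50)
    epochs: int = 500

    def __post_init__(self) -> None:
        lo, hi = self.hidden_range
        if lo < 1 or hi < lo:
            raise ValueError("hidden_range must be a non-empty positive interval")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class SubspaceSpec:
    """Sorted, duplicate-free feature indices of one random subspace."""

    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class EnsembleMember:
    subspace: SubspaceSpec
    classifier: MLPClassifier
    hidden_units: int
    seed: int


@dataclass
class EnsembleModel:
    members: list[EnsembleMember]
    classes: np.ndarray
    feature_names: list[str]
    M: int
    L: int
    seed: int
    normalizer: object = None  # NormalizerParams fitted on the training rows

    def __post_init__(self) -> None:
        assert len(self.members) == self.L
        assert all(len(m.subspace) == self.M for m in self.members)


def subspace_dim(d: int, fraction: float) -> int:
    """Subspace dimensionality: nearest integer to ``fraction * d``, ties to even.

    Nearest-even rounding matters: 75% of 438 features is 328.5, which must
    round to 328 (half-up would give 329).  Always at least 1.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    return max(1, int(np.rint(fraction * d)))


def sample_subspaces(
    d: int, M: int, L: int, seed: int | np.random.Generator = 0
) -> list[SubspaceSpec]:
    """``L`` independent uniform draws of ``M`` distinct indices from ``[0, d)``."""
    if not (1 <= M <= d):
        raise ValueError("require 1 <= M <= d")
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        SubspaceSpec(indices=tuple(sorted(rng.choice(d, size=M, replace=False))))
        for _ in range(L)
    ]


def _mlp(hidden_units: int, epochs: int, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        activation="logistic",
        solver="lbfgs",
        max_iter=epochs,
        random_state=int(seed),
    )


def _fit(clf: MLPClassifier, x: np.ndarray, y: np.ndarray) -> MLPClassifier:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x, y)
    return clf


def train_mlp(
    table: FeatureTable, hidden_units: int = 20, epochs: int = 500, seed: int = 0
) -> MLPClassifier:
    """Single-classifier path: one MLP on the full feature space.

    The default 20 hidden units is the single-network baseline configuration.
    """
    return _fit(_mlp(hidden_units, epochs, seed), table.X.to_numpy(float), table.y.to_numpy())


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def train_rs_ensemble(
    table: FeatureTable,
    L: int = 20,
    fraction: float = 0.8,
    base_config: BaseClassifierConfig = BaseClassifierConfig(),
    seed: int = 0,
) -> EnsembleModel:
    """Train ``L`` MLPs on independent random feature subspaces."""
    classes = np.asarray(sorted(table.y.unique()))
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    d = table.n_features
    m_dim = subspace_dim(d, fraction)
    root = np.random.SeedSequence(seed)
    ss_subspace, ss_members = root.spawn(2)
    rng = np.random.default_rng(ss_subspace)
    subspaces = sample_subspaces(d, m_dim, L, rng)
    lo, hi = base_config.hidden_range
    hidden = rng.integers(lo, hi + 1, size=L)
    x = table.X.to_numpy(float)
    y = table.y.to_numpy()
    members = []
    for spec, h, child in zip(subspaces, hidden, ss_members.spawn(L)):
        mseed = _child_seed(child)
        clf = _fit(_mlp(int(h), base_config.epochs, mseed), x[:, list(spec.indices)], y)
        members.append(
            EnsembleMember(subspace=spec, classifier=clf, hidden_units=int(h), seed=mseed)
        )
    return EnsembleModel(
        members=members,
        classes=classes,
        feature_names=table.feature_names,
        M=m_dim,
        L=L,
        seed=seed,
    )


def predict_ensemble(model: EnsembleModel, table: FeatureTable) -> np.ndarray:
    """Majority vote over member predictions.

    Ties are broken by the larger summed member score (class probability)
    among the tied labels, then by the smallest class index.  The vote is
    invariant to member ordering.
    """
    if table.feature_names != model.feature_names:
        raise ValueError("feature names do not match the trained ensemble")
    x = table.X.to_numpy(float)
    n = x.shape[0]
    k = len(model.classes)
    class_pos = {c: i for i, c in enumerate(model.classes)}
    votes = np.zeros((n, k), dtype=int)
    scores = np.zeros((n, k), dtype=float)
    for member in model.members:
        xs = x[:, list(member.subspace.indices)]
        pred = member.classifier.predict(xs)
        proba = member.classifier.predict_proba(xs)
        cols = [class_pos[c] for c in member.classifier.classes_]
        scores[:, cols] += proba
        for i, p in enumerate(pred):
            votes[i, class_pos[p]] += 1
    out = np.empty(n, dtype=model.classes.dtype)
    for i in range(n):
        top = votes[i].max()
        tied = np.flatnonzero(votes[i] == top)
        if len(tied) > 1:
            best = scores[i, tied].max()
            tied = tied[scores[i, tied] == best]  # smallest index wins residual ties
        out[i] = model.classes[tied[0]]
    return out


@dataclass
class EvaluationReport:
    """Repeated-holdout results: per-run accuracies and averaged confusion."""

    accuracies: np.ndarray          # percent, one entry per run
    confusion: pd.DataFrame         # percent, rows = true class (sum to 100)
    classes: list
    runs: int
    config: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.accuracies.std())

    def to_dict(self) -> dict:
        return {
            "runs": self.runs,
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "per_run_accuracy": [float(a) for a in self.accuracies],
            "classes": [str(c) for c in self.classes],
            "confusion": [[float(v) for v in row] for row in self.confusion.to_numpy()],
            "config": self.config,
            "seed": self.seed,
        }


def _stratified_split(
    y: pd.Series, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class holdout: floor(n * test_fraction) test samples, at least 1."""
    train_idx, test_idx = [], []
    for cls in sorted(y.unique()):
        idx = y.index[y == cls].to_numpy()
        n_test = max(1, int(np.floor(len(idx) * test_fraction)))
        if n_test >= len(idx):
            raise ValueError(f"class {cls!r} too small for holdout evaluation")
        perm = rng.permutation(len(idx))
        test_idx.extend(idx[perm[:n_test]])
        train_idx.extend(idx[perm[n_test:]])
    return np.asarray(train_idx), np.asarray(test_idx)


def evaluate_holdout(
    table: FeatureTable,
    L: int = 20,
    fraction: float = 0.8,
    runs: int = 100,
    test_fraction: float = 0.2,
    base_config: BaseClassifierConfig = BaseClassifierConfig(),
    seed: int = 0,
    normalize: bool = True,
) -> EvaluationReport:
    """Repeated stratified holdout with a fresh ensemble per split.

    Per run: split each class (``test_fraction`` held out), optionally fit
    the [-1, 1] normalizer on the training rows and apply it to both sides,
    train a random-subspace ensemble, and record accuracy and the
    row-normalized confusion matrix in percent.  Matrices are averaged over
    runs.  Identical seeds give identical reports.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    classes = sorted(table.y.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = table.y.value_counts()
    if (counts * test_fraction < 1).any() and (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")
    root = np.random.SeedSequence(seed)
    accs = np.empty(runs)
    conf_sum = np.zeros((len(classes), len(classes)))
    for r, ss in enumerate(root.spawn(runs)):
        rng = np.random.default_rng(ss)
        train_idx, test_idx = _stratified_split(table.y, test_fraction, rng)
        train, test = table.subset(train_idx), table.subset(test_idx)
        if normalize:
            params = fit_normalizer(train)
            train = apply_normalizer(train, params)
            test = apply_normalizer(test, params)
        model = train_rs_ensemble(
            train, L=L, fraction=fraction, base_config=base_config, seed=_child_seed(ss)
        )
        pred = predict_ensemble(model, test)
        truth = test.y.to_numpy()
        accs[r] = 100.0 * float((pred == truth).mean())
        conf_sum += 100.0 * confusion_matrix(
            truth, pred, labels=classes, normalize="true"
        )
    confusion = pd.DataFrame(conf_sum / runs, index=classes, columns=classes)
    return EvaluationReport(
        accuracies=accs,
        confusion=confusion,
        classes=classes,
        runs=runs,
        config={
            "L": L,
            "fraction": fraction,
            "test_fraction": test_fraction,
            "hidden_range": list(base_config.hidden_range),
            "epochs": base_config.epochs,
            "normalize": normalize,
        },
        seed=seed,
    )
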