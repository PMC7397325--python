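"""Consensus non-negative matrix factorisation of pathway activation scores.

Samples are clustered by factorising the (nonnegativised) pathway-score
matrix as X ~ WH with multiplicative Frobenius updates, assigning each
sample to the factor with the largest coefficient in its H column.  The
number of subgroups is chosen by running the factorisation many times from
random restarts at each candidate rank, forming the consensus
(co-assignment frequency) matrix, and picking the rank whose consensus
matrix is most consistent with a hierarchical clustering of itself — the
cophenetic coefficient criterion of consensus clustering.

Because activation z-scores carry sign, each pathway row r is split into a
positive part max(r, 0) and a negative part max(-r, 0) before
factorisation; this preserves the sign information exactly (the original
row is the difference of the two parts).

A bagged-decision-tree classifier (random-forest style, with per-tree
down-sampling of every class to the smallest class frequency) is provided
to transfer a subgroup labelling onto new cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, TrainingError, UnassignableError

__all__ = [
    "NMFResult",
    "ConsensusResult",
    "SubgroupAssignment",
    "nonneg_transform",
    "nmf",
    "consensus",
    "cophenetic_coefficient",
    "select_rank",
    "assign_subgroups",
    "align_labels",
    "DownsampledBaggedTrees",
    "train_subgroup_classifier",
    "apply_classifier",
]

_EPS = 1e-12


def nonneg_transform(z: pd.DataFrame) -> pd.DataFrame:
    """Split every row into positive and negative parts (2P x N output).

    Row ``name`` becomes rows ``name+`` (max(r, 0)) and ``name-``
    (max(-r, 0)); the original row is exactly ``name+`` minus ``name-``.
    """
    values = z.to_numpy(dtype=float)
    pos = np.maximum(values, 0.0)
    neg = np.maximum(-values, 0.0)
    index = [f"{n}+" for n in z.index] + [f"{n}-" for n in z.index]
    return pd.DataFrame(np.vstack([pos, neg]), index=index, columns=z.columns)


@dataclass
class NMFResult:
    """One factorisation X ~ WH (W: features x rank, H: rank x samples)."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    seed: int


def nmf(X, rank: int, seed: int = 0, max_iter: int = 2000, tol: float = 1e-6) -> NMFResult:
    """Multiplicative-update NMF minimising the Frobenius loss ||X - WH||^2.

    Stops at ``max_iter`` or when the relative objective decrease in one
    iteration falls below ``tol``.  W and H are initialised uniformly at
    random (scaled to the data magnitude) from ``seed``, so identical seeds
    give identical factorisations.
    """
    A = np.asarray(X, dtype=float)
    if A.ndim != 2:
        raise ConfigError("X must be a 2-D nonnegative array")
    if (A < 0).any():
        raise ConfigError("X must be entrywise nonnegative")
    m, n = A.shape
    if not 1 <= rank < min(m, n):
        raise ConfigError(f"rank must satisfy 1 <= rank < min(dims)={min(m, n)}, got {rank}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(A.mean(), _EPS) / rank)
    W = scale * (rng.random((m, rank)) + _EPS)
    H = scale * (rng.random((rank, n)) + _EPS)

    trace: list[float] = []
    prev = np.linalg.norm(A - W @ H) ** 2
    trace.append(prev)
    for _ in range(max_iter):
        H *= (W.T @ A) / (W.T @ W @ H + _EPS)
        W *= (A @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = np.linalg.norm(A - W @ H) ** 2
        trace.append(obj)
        if prev - obj < tol * max(prev, _EPS):
            break
        prev = obj
    return NMFResult(W=W, H=H, objective_trace=trace, seed=seed)


@dataclass
class ConsensusResult:
    """Consensus matrix over random NMF restarts at one rank."""

    rank: int
    consensus: np.ndarray
    cophenetic: float
    sample_ids: list[str] = field(default_factory=list)


def _hard_labels(H: np.ndarray) -> np.ndarray:
    if (H.sum(axis=0) == 0).any():
        raise UnassignableError("a sample has an all-zero H column")
    return H.argmax(axis=0)


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus-derived distance matrix.

    Distances d = 1 - consensus are clustered by average linkage; the
    returned value is the Pearson correlation between the original and the
    cophenetic distances.  A perfectly block-structured (all 0/1) consensus
    matrix gives 1.0; a constant distance matrix (no structure to mismatch)
    is defined as 1.0.
    """
    d = 1.0 - np.asarray(consensus, dtype=float)
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if np.ptp(condensed) == 0.0:
        return 1.0
    Z = average(condensed)
    c, _ = cophenet(Z, condensed)
    return float(c)


def consensus(X, rank: int, n_runs: int = 30, seed: int = 0,
              max_iter: int = 2000, tol: float = 1e-6,
              sample_ids: list[str] | None = None) -> ConsensusResult:
    """Consensus matrix and cophenetic coefficient at one rank.

    Each of ``n_runs`` restarts assigns samples to their argmax H factor;
    consensus[i, j] is the fraction of runs co-assigning samples i and j.
    """
    if n_runs < 2:
        raise ConfigError("consensus requires n_runs >= 2")
    A = np.asarray(X, dtype=float)
    n = A.shape[1]
    run_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs)
    counts = np.zeros((n, n))
    for run_seed in run_seeds:
        labels = _hard_labels(nmf(A, rank, seed=int(run_seed), max_iter=max_iter, tol=tol).H)
        counts += (labels[:, None] == labels[None, :]).astype(float)
    C = counts / n_runs
    np.fill_diagonal(C, 1.0)
    if hasattr(X, "columns") and sample_ids is None:
        sample_ids = list(X.columns)
    return ConsensusResult(rank=rank, consensus=C,
                           cophenetic=cophenetic_coefficient(C),
                           sample_ids=sample_ids or [])


def select_rank(X, ranks=range(2, 7), n_runs: int = 30, seed: int = 0,
                max_iter: int = 2000, tol: float = 1e-6) -> tuple[int, pd.Series]:
    """Choose the rank maximising the cophenetic coefficient.

    Returns the chosen rank and the full per-rank cophenetic table; ties
    break toward the smallest rank.
    """
    ranks = list(ranks)
    if not ranks:
        raise ConfigError("no candidate ranks supplied")
    coph = pd.Series(
        {r: consensus(X, r, n_runs=n_runs, seed=seed, max_iter=max_iter, tol=tol).cophenetic
         for r in ranks},
        name="cophenetic",
    )
    best = int(coph.idxmax())  # idxmax keeps the first (smallest) rank on ties
    return best, coph


@dataclass
class SubgroupAssignment:
    """Hard subgroup labels (1-based) for every sample."""

    labels: pd.Series
    rank: int


def assign_subgroups(result: NMFResult, sample_ids: list[str] | None = None) -> SubgroupAssignment:
    """Assign each sample to the argmax row of H (ties -> lowest index)."""
    labels = _hard_labels(result.H) + 1
    rank = result.H.shape[0]
    index = sample_ids if sample_ids is not None else list(range(len(labels)))
    return SubgroupAssignment(labels=pd.Series(labels, index=index, name="subgroup"), rank=rank)


def align_labels(pred: pd.Series, truth: pd.Series) -> pd.Series:
    """Permute predicted label names to best match a reference labelling.

    Solves the assignment problem on the confusion matrix (Hungarian
    algorithm) and returns the relabelled predictions.  Useful because NMF
    factor order is arbitrary.
    """
    pred, truth = pred.align(truth, join="inner")
    conf = pd.crosstab(pred, truth)
    rows, cols = linear_sum_assignment(-conf.to_numpy())
    mapping = {conf.index[i]: conf.columns[j] for i, j in zip(rows, cols)}
    # predicted labels without a matched reference class keep themselves
    return pred.map(lambda v: mapping.get(v, v))


class DownsampledBaggedTrees:
    """Bagged decision trees with per-tree class-balanced down-sampling.

    Every tree is grown on a bootstrap drawn by sampling, with replacement,
    ``min-class-size`` samples from each class, so rare classes carry the
    same weight as common ones.  Out-of-bag (OOB) votes give an unbiased
    accuracy estimate and per-class one-vs-rest AUCs.
    """

    def __init__(self, n_trees: int = 5001, seed: int = 0, max_features: str | float = "sqrt"):
        if n_trees < 1:
            raise ConfigError("n_trees must be positive")
        self.n_trees = n_trees
        self.seed = seed
        self.max_features = max_features

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "DownsampledBaggedTrees":
        """Fit on samples x features ``X`` and per-sample labels ``y``."""
        X, y = X.align(y, join="inner", axis=0)
        self.feature_names_ = list(X.columns)
        self.classes_ = np.array(sorted(pd.unique(y)))
        if len(self.classes_) < 2:
            raise TrainingError("training requires at least two classes")
        counts = y.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise TrainingError(f"class(es) with fewer than two samples: {small}")
        A = X.to_numpy(dtype=float)
        labels = np.searchsorted(self.classes_, y.to_numpy())
        n = len(labels)
        m = int(counts.min())
        class_idx = [np.flatnonzero(labels == k) for k in range(len(self.classes_))]
        rng = np.random.default_rng(self.seed)
        self.trees_: list[DecisionTreeClassifier] = []
        oob_votes = np.zeros((n, len(self.classes_)))
        for b in range(self.n_trees):
            boot = np.concatenate([rng.choice(idx, size=m, replace=True) for idx in class_idx])
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(A[boot], labels[boot])
            self.trees_.append(tree)
            oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
            if len(oob):
                pred = tree.predict(A[oob])
                oob_votes[oob, pred] += 1
        voted = oob_votes.sum(axis=1) > 0
        self.oob_accuracy_ = float(
            (oob_votes[voted].argmax(axis=1) == labels[voted]).mean()
        ) if voted.any() else float("nan")
        with np.errstate(invalid="ignore"):
            frac = oob_votes[voted] / oob_votes[voted].sum(axis=1, keepdims=True)
        self.class_auc_ = {}
        for k, cls in enumerate(self.classes_):
            truth_k = (labels[voted] == k).astype(int)
            if 0 < truth_k.sum() < len(truth_k):
                self.class_auc_[cls] = float(roc_auc_score(truth_k, frac[:, k]))
            else:
                self.class_auc_[cls] = float("nan")
        return self

    def vote_fractions(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-class fraction of tree votes for every sample."""
        A = X[self.feature_names_].to_numpy(dtype=float)
        votes = np.zeros((A.shape[0], len(self.classes_)))
        for tree in self.trees_:
            votes[np.arange(A.shape[0]), tree.predict(A)] += 1
        return pd.DataFrame(votes / len(self.trees_), index=X.index, columns=self.classes_)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Majority-vote class per sample (ties -> lowest class)."""
        frac = self.vote_fractions(X)
        return pd.Series(self.classes_[frac.to_numpy().argmax(axis=1)],
                         index=X.index, name="predicted")


def train_subgroup_classifier(features: pd.DataFrame, labels: SubgroupAssignment | pd.Series,
                              n_trees: int = 5001, seed: int = 0) -> DownsampledBaggedTrees:
    """Train the subgroup classifier on a features x samples matrix.

    ``features`` is a pathway-score (or expression) matrix with samples as
    columns; labels may be a :class:`SubgroupAssignment` or a plain Series.
    """
    y = labels.labels if isinstance(labels, SubgroupAssignment) else labels
    clf = DownsampledBaggedTrees(n_trees=n_trees, seed=seed)
    return clf.fit(features.T, y)


def apply_classifier(clf: DownsampledBaggedTrees, features: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Apply a trained classifier to a features x samples matrix."""
    X = features.T
    return clf.predict(X), clf.vote_fractions(X)
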