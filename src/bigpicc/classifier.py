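"""Multi-hit tumor/normal classification and tumor-ratio threshold learning.

The selected combinations C_rho act as a rule-list classifier: a sample is
predicted tumor iff it harbors a joint mutation of at least one selected
combination. :class:`MultiHitClassifier` packages the whole pipeline
(candidate pooling by iterative bipartite partitioning, tumor-ratio
filtering, greedy set cover) as a scikit-learn estimator, so it composes
with sklearn model selection and pipelines: ``X`` is a binary
(n_samples, n_genes) array (samples are rows, the transpose of the on-disk
gene-by-sample matrix) and ``y`` holds tumor/normal labels.

The threshold rho is the single hyperparameter. With ``rho="auto"`` it is
learned by stratified k-fold cross-validation over the grid 0.00..1.00 in
steps of 0.01, choosing the value with the highest mean held-out MCC
(largest rho on ties, which favors the strongest precision control).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted, validate_data

from .community import build_candidate_pool
from .cover import filter_candidates, greedy_min_cover, score_candidates
from .matrix import TUMOR, NORMAL, EmptyClassError, MutationMatrix
from .metrics import ConfusionCounts, MetricReport, compute_metrics, confusion_counts

logger = logging.getLogger(__name__)

__all__ = [
    "MultiHitClassifier",
    "CVResult",
    "predict_with_combinations",
    "predict_sample",
    "split_train_test",
    "cross_validate_rho",
    "fit_final",
    "evaluate_on_matrix",
]

RHO_GRID = np.round(np.arange(0, 101) * 0.01, 2)


def predict_with_combinations(matrix: MutationMatrix, combinations, sample_ids=None):
    """Boolean tumor predictions: sample has a joint mutation of any combination."""
    if sample_ids is None:
        cols = np.arange(matrix.n_samples)
    else:
        cols = np.array([matrix.sample_index(s) for s in sample_ids])
    pred = np.zeros(cols.size, dtype=bool)
    for genes in combinations:
        rows = [matrix.gene_index(g) for g in genes]
        pred |= matrix.data[np.ix_(rows, cols)].all(axis=0)
    return pred


def predict_sample(classifier, matrix: MutationMatrix, sample_id: str) -> str:
    """Predicted label for one sample of a matrix (``classifier`` must be fitted)."""
    check_is_fitted(classifier, "combinations_")
    hit = predict_with_combinations(matrix, classifier.combinations_, [sample_id])[0]
    return TUMOR if hit else NORMAL


class MultiHitClassifier(ClassifierMixin, BaseEstimator):
    """Tumor/normal classifier built from multi-hit gene combinations.

    Parameters
    ----------
    min_hits, max_hits
        Hit range (l, u): bounds on the number of genes per combination,
        taken from the literature for the cancer type under study.
    passes
        Number p of independent iterative-partitioning passes pooled into
        the candidate set.
    rho
        Tumor-ratio threshold in [0, 1], or ``"auto"`` to learn it by
        cross-validation on the training data.
    folds
        Folds for the rho cross-validation (used only with ``rho="auto"``).
    random_state
        Integer seed controlling partitioning, folding, and pass seeds.

    Attributes
    ----------
    combinations_ : list of tuple of str
        Selected carcinogenic combinations, in greedy cover order.
    rho_ : float
        Threshold used for the final fit.
    cv_result_ : CVResult or None
        Cross-validation curve when rho was learned.
    cover_ : CoverSolution
        The greedy cover that produced ``combinations_``.
    """

    def __init__(
        self,
        min_hits: int = 2,
        max_hits: int = 7,
        passes: int = 100,
        rho="auto",
        folds: int = 4,
        random_state=None,
    ):
        self.min_hits = min_hits
        self.max_hits = max_hits
        self.passes = passes
        self.rho = rho
        self.folds = folds
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------

    def _seed(self) -> int:
        return 0 if self.random_state is None else int(self.random_state)

    def _to_matrix(self, X, y) -> MutationMatrix:
        genes = (
            list(self.feature_names_in_)
            if hasattr(self, "feature_names_in_")
            else [f"g{i}" for i in range(X.shape[1])]
        )
        samples = [f"s{j}" for j in range(X.shape[0])]
        labels = [TUMOR if t else NORMAL for t in y]
        return MutationMatrix(genes, samples, labels, X.T)

    @staticmethod
    def _tumor_mask(y) -> np.ndarray:
        return np.asarray([v in (1, True, TUMOR) for v in np.asarray(y).ravel()])

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=None, ensure_2d=True)
        X = np.asarray(X)
        if X.size and not np.isin(X, (0, 1)).all():
            raise ValueError("X must be a binary mutation indicator matrix")
        self.classes_ = np.unique(y)
        is_tumor = self._tumor_mask(y)
        if not is_tumor.any():
            raise EmptyClassError("training data has no tumor samples")
        mat = self._to_matrix(X.astype(np.uint8), is_tumor)
        seed = self._seed()

        if isinstance(self.rho, str):
            if self.rho != "auto":
                raise ValueError("rho must be a float in [0, 1] or 'auto'")
            self.cv_result_ = cross_validate_rho(
                mat,
                self.min_hits,
                self.max_hits,
                self.passes,
                folds=self.folds,
                seed=seed,
            )
            self.rho_ = float(self.cv_result_.best_rho)
        else:
            if not 0.0 <= float(self.rho) <= 1.0:
                raise ValueError("rho must be in [0, 1]")
            self.cv_result_ = None
            self.rho_ = float(self.rho)

        self.pool_ = build_candidate_pool(
            mat, self.min_hits, self.max_hits, self.passes, base_seed=seed
        )
        scored = score_candidates(self.pool_, mat)
        self.cover_ = greedy_min_cover(
            filter_candidates(scored, self.rho_), self.rho_
        )
        self.combinations_ = [c.genes for c in self.cover_.selected]
        if not self.combinations_:
            warnings.warn(
                "empty model: no candidate survived filtering; "
                "all samples will be predicted normal",
                UserWarning,
            )
        gene_pos = {g: i for i, g in enumerate(mat.gene_ids)}
        self._combination_columns = [
            [gene_pos[g] for g in genes] for genes in self.combinations_
        ]
        return self

    def predict(self, X):
        check_is_fitted(self, "combinations_")
        X = validate_data(self, X, dtype=None, reset=False)
        X = np.asarray(X)
        hit = np.zeros(X.shape[0], dtype=bool)
        for cols in self._combination_columns:
            hit |= np.asarray(X[:, cols] == 1).all(axis=1)
        pos, neg = self._output_labels()
        return np.where(hit, pos, neg)

    def _output_labels(self):
        tumorish = [c for c in self.classes_ if c in (1, True, TUMOR)]
        normish = [c for c in self.classes_ if c not in (1, True, TUMOR)]
        pos = tumorish[0] if tumorish else TUMOR
        if normish:
            neg = normish[0]
        elif isinstance(pos, str):
            neg = NORMAL
        else:
            neg = type(pos)(0)
        return pos, neg


@dataclass
class CVResult:
    """Mean held-out MCC per rho over the grid 0.00..1.00 (step 0.01)."""

    rho_grid: np.ndarray
    mean_mcc: np.ndarray
    fold_mcc: np.ndarray  # (folds, len(grid))
    best_rho: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rho": self.rho_grid,
                "mean_MCC": self.mean_mcc,
                "fold_MCCs": [
                    ",".join(f"{v:.6f}" for v in col) for col in self.fold_mcc.T
                ],
            }
        )


def split_train_test(matrix: MutationMatrix, test_fraction: float, seed: int = 0):
    """Label-stratified random train/test split over samples.

    Genes are unchanged; a 25% hold-out is the standard protocol.
    Falls back to an unstratified split with a warning when a class has
    fewer than two samples.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(matrix.n_samples)
    labels = matrix.labels
    counts = pd.Series(labels).value_counts()
    stratify = labels if (counts >= 2).all() and len(counts) > 1 else None
    if stratify is None:
        warnings.warn(
            "a sample class has < 2 members; splitting without stratification",
            UserWarning,
        )
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=stratify
    )
    ids = np.asarray(matrix.sample_ids)
    return (
        matrix.subset_samples(ids[np.sort(train_idx)]),
        matrix.subset_samples(ids[np.sort(test_idx)]),
    )


def cross_validate_rho(
    matrix: MutationMatrix,
    min_hits: int,
    max_hits: int,
    passes: int,
    folds: int = 4,
    seed: int = 0,
) -> CVResult:
    """Learn the tumor-ratio threshold by stratified k-fold cross-validation.

    For each fold, one candidate pool is built on the fold-training samples
    (tumor ratios computed on those samples only) and reused across the
    whole rho grid; each rho's filtered pool is covered greedily and the
    resulting combinations are scored by MCC on the held-out fold. On ties
    in mean MCC the largest rho wins.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = matrix.labels
    if matrix.n_tumor == 0 or matrix.n_tumor == matrix.n_samples:
        raise EmptyClassError("cross-validation needs both tumor and normal samples")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ids = np.asarray(matrix.sample_ids)
    fold_mcc = np.zeros((folds, RHO_GRID.size))
    for k, (train_idx, test_idx) in enumerate(skf.split(ids, labels)):
        if not matrix.is_tumor[train_idx].any():
            raise EmptyClassError(f"fold {k} training part has no tumor samples")
        train_mat = matrix.subset_samples(ids[np.sort(train_idx)])
        pool = build_candidate_pool(
            train_mat,
            min_hits,
            max_hits,
            passes,
            base_seed=seed + 100003 * (k + 1),
        )
        scored = score_candidates(pool, train_mat)
        test_ids = ids[np.sort(test_idx)]
        y_true = matrix.is_tumor[np.sort(test_idx)]
        for j, rho in enumerate(RHO_GRID):
            solution = greedy_min_cover(filter_candidates(scored, rho), rho)
            y_pred = predict_with_combinations(
                matrix, solution.combinations, test_ids
            )
            fold_mcc[k, j] = compute_metrics(confusion_counts(y_true, y_pred)).mcc
    mean_mcc = fold_mcc.mean(axis=0)
    best_j = np.flatnonzero(mean_mcc == mean_mcc.max())[-1]  # largest rho on ties
    return CVResult(RHO_GRID.copy(), mean_mcc, fold_mcc, float(RHO_GRID[best_j]))


def fit_final(
    matrix: MutationMatrix,
    rho: float,
    min_hits: int,
    max_hits: int,
    passes: int,
    seed: int = 0,
) -> MultiHitClassifier:
    """Re-run the full pipeline on a training matrix at a fixed rho."""
    X = pd.DataFrame(
        matrix.data.T, columns=list(matrix.gene_ids), index=list(matrix.sample_ids)
    )
    clf = MultiHitClassifier(
        min_hits=min_hits,
        max_hits=max_hits,
        passes=passes,
        rho=rho,
        random_state=seed,
    )
    return clf.fit(X, matrix.labels)


def evaluate_on_matrix(classifier, matrix: MutationMatrix):
    """Confusion counts and metrics of a fitted classifier on a matrix."""
    check_is_fitted(classifier, "combinations_")
    y_pred = predict_with_combinations(matrix, classifier.combinations_)
    counts = confusion_counts(matrix.is_tumor, y_pred)
    return counts, compute_metrics(counts)
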