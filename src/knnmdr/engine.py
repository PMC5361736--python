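"""Status prediction and cross-validated balanced accuracy.

Two predictors share the same scoring pipeline:

* the KNN vote — a test individual takes the majority status of its K
  nearest training individuals under a combined window squared distance;
* the classic multi-locus cell vote — each observed multi-locus genotype
  cell is labeled high/low risk from the training case:control ratio,
  and test individuals falling in unseen cells are unclassifiable.

All tie-breaks are explicit and deterministic: distance ties go to the
ascending individual index (stable sort), vote ties default to the
status of the single nearest neighbor.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("knnmdr")

__all__ = [
    "TIE_RULES",
    "KnnConfig",
    "CVPlan",
    "ConfusionCounts",
    "make_cv_plan",
    "balanced_accuracy",
    "confusion_counts",
    "knn_predict",
    "mdr_predict",
    "cross_validated_ba",
    "knn_cv_ba_batch",
    "mdr_cv_ba_batch",
]

TIE_RULES = ("nearest_neighbor_breaks", "case_wins", "control_wins")

#: prediction code for a test individual in a training-unseen genotype cell
UNCLASSIFIABLE = -1


@dataclasses.dataclass(frozen=True)
class KnnConfig:
    """Neighborhood size and vote tie rule for the KNN predictor."""

    k: int = 10
    tie_rule: str = "nearest_neighbor_breaks"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.tie_rule not in TIE_RULES:
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")


@dataclasses.dataclass(frozen=True)
class CVPlan:
    """Fold assignment per individual for cross-validation."""

    fold_ids: np.ndarray
    n_folds: int
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        folds = np.asarray(self.fold_ids)
        counts = np.bincount(folds, minlength=self.n_folds)
        if len(counts) != self.n_folds or (counts == 0).any():
            raise ValueError("every fold must contain at least one individual")

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_ids) == fold)


def make_cv_plan(
    is_case: np.ndarray,
    n_folds: int = 10,
    stratified: bool = True,
    seed: int = 0,
) -> CVPlan:
    """Assign individuals to folds, stratified by status by default.

    Stratification deals shuffled cases and controls round-robin into
    folds, so each fold's case fraction is within one individual of the
    global fraction.
    """
    is_case = np.asarray(is_case, dtype=bool)
    n = len(is_case)
    if n_folds < 2 or n_folds > n:
        raise ValueError("need 2 <= n_folds <= n_individuals")
    rng = np.random.default_rng(seed)
    fold_ids = np.empty(n, dtype=np.int32)
    if stratified:
        for mask in (is_case, ~is_case):
            idx = np.flatnonzero(mask)
            rng.shuffle(idx)
            fold_ids[idx] = np.arange(len(idx)) % n_folds
    else:
        idx = rng.permutation(n)
        fold_ids[idx] = np.arange(n) % n_folds
    return CVPlan(fold_ids, n_folds, stratified, seed)


@dataclasses.dataclass
class ConfusionCounts:
    """Case/control confusion tallies; unclassified applies to MDR only."""

    tp: int
    fn: int
    tn: int
    fp: int
    unclassified: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp, self.unclassified) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_counts(is_case: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    """Tally a prediction vector; ``UNCLASSIFIABLE`` entries are excluded."""
    is_case = np.asarray(is_case, dtype=bool)
    predicted = np.asarray(predicted)
    classified = predicted != UNCLASSIFIABLE
    pred_case = predicted == 1
    return ConfusionCounts(
        tp=int(np.sum(classified & is_case & pred_case)),
        fn=int(np.sum(classified & is_case & ~pred_case)),
        tn=int(np.sum(classified & ~is_case & ~pred_case)),
        fp=int(np.sum(classified & ~is_case & pred_case)),
        unclassified=int(np.sum(~classified)),
    )


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity over the classified individuals.

    When a class is absent among the classified individuals its rate is
    defined as 0.5 (degenerate-fold rule) and a warning is emitted.
    """
    if c.tp + c.fn > 0:
        sens = c.tp / (c.tp + c.fn)
    else:
        warnings.warn("no classified cases; sensitivity defined as 0.5")
        sens = 0.5
    if c.tn + c.fp > 0:
        spec = c.tn / (c.tn + c.fp)
    else:
        warnings.warn("no classified controls; specificity defined as 0.5")
        spec = 0.5
    return 0.5 * (sens + spec)


def knn_predict(
    d2: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    is_case: np.ndarray,
    cfg: KnnConfig,
) -> np.ndarray:
    """Predict test statuses by majority vote of the K nearest trainees.

    Distance ties are broken by ascending individual index; vote ties by
    ``cfg.tie_rule`` (default: status of the single nearest neighbor).
    Returns a bool array (``True`` = case) aligned with *test_idx*.
    """
    train_idx = np.sort(np.asarray(train_idx))
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test sets must be disjoint")
    if cfg.k > len(train_idx):
        raise ValueError(f"K={cfg.k} exceeds training-set size {len(train_idx)}")
    if len(test_idx) == 0:
        return np.zeros(0, dtype=bool)
    is_case = np.asarray(is_case, dtype=bool)
    sub = d2[np.ix_(test_idx, train_idx)]
    order = np.argsort(sub, axis=1, kind="stable")[:, : cfg.k]
    nb = train_idx[order]  # (n_test, K) neighbor indices, nearest first
    votes = is_case[nb].sum(axis=1)
    pred = votes * 2 > cfg.k
    tie = votes * 2 == cfg.k
    if tie.any():
        if cfg.tie_rule == "nearest_neighbor_breaks":
            pred[tie] = is_case[nb[tie, 0]]
        elif cfg.tie_rule == "case_wins":
            pred[tie] = True
        else:
            pred[tie] = False
    return pred


def mdr_predict(
    values: np.ndarray,
    marker_idx: Sequence[int],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    is_case: np.ndarray,
) -> np.ndarray:
    """Classic multi-locus cell vote.

    A training cell is labeled case (high risk) iff its case:control
    ratio strictly exceeds the overall training ratio; exact equality is
    low risk (control).  Test individuals in cells unseen in training get
    :data:`UNCLASSIFIABLE`.  Returns int8 codes (1 case, 0 control, -1).
    """
    marker_idx = list(marker_idx)
    if len(marker_idx) < 1:
        raise ValueError("at least one marker required")
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    is_case = np.asarray(is_case, dtype=bool)
    codes = _cell_codes(values, marker_idx)
    n_cells = 3 ** len(marker_idx)
    y_tr = is_case[train_idx]
    case_c = np.bincount(codes[train_idx][y_tr], minlength=n_cells)
    ctrl_c = np.bincount(codes[train_idx][~y_tr], minlength=n_cells)
    total_cases, total_ctrls = int(y_tr.sum()), int((~y_tr).sum())
    high = case_c * total_ctrls > ctrl_c * total_cases
    seen = (case_c + ctrl_c) > 0
    pred = np.where(seen, high.astype(np.int8), np.int8(UNCLASSIFIABLE))
    return pred[codes[test_idx]]


def _cell_codes(values: np.ndarray, marker_idx: Sequence[int]) -> np.ndarray:
    powers = 3 ** np.arange(len(marker_idx), dtype=np.int64)
    return values[:, list(marker_idx)].astype(np.int64) @ powers


def _ba_from_rates(
    pred: np.ndarray, Y: np.ndarray, classified: np.ndarray, fold_onehot: np.ndarray
) -> np.ndarray:
    """Fold-averaged balanced accuracy for R label rows at once.

    pred, Y, classified: (R, n) boolean; fold_onehot: (n, n_folds).
    Degenerate folds (no classified case or control) contribute rate 0.5.
    """
    Yc = Y & classified
    Nc = ~Y & classified
    tp = ((pred & Yc) @ fold_onehot).astype(np.float64)
    pos = (Yc @ fold_onehot).astype(np.float64)
    tn = ((~pred & Nc) @ fold_onehot).astype(np.float64)
    neg = (Nc @ fold_onehot).astype(np.float64)
    sens = np.divide(tp, pos, out=np.full_like(tp, 0.5), where=pos > 0)
    spec = np.divide(tn, neg, out=np.full_like(tn, 0.5), where=neg > 0)
    return (0.5 * (sens + spec)).mean(axis=1)


def knn_cv_ba_batch(
    d2: np.ndarray,
    plan: CVPlan,
    Y: np.ndarray,
    cfg: KnnConfig,
    neighbors: np.ndarray | None = None,
) -> np.ndarray:
    """Cross-validated BA of the KNN vote for R phenotype rows at once.

    The neighbor lists depend only on the distances and the fold plan,
    never on the labels, so they are computed once and the (possibly
    permuted) label rows ``Y`` (shape ``(R, n)``) are voted in a single
    vectorized pass — this is what makes permutation testing affordable.
    A precomputed ``neighbors`` array (from :func:`cv_neighbors`) may be
    passed to amortize the sort across calls.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=bool))
    nb = cv_neighbors(d2, plan, cfg.k) if neighbors is None else neighbors
    votes = Y[:, nb].sum(axis=2)
    pred = votes * 2 > cfg.k
    tie = votes * 2 == cfg.k
    if tie.any():
        if cfg.tie_rule == "nearest_neighbor_breaks":
            nearest = Y[:, nb[:, 0]]
            pred = np.where(tie, nearest, pred)
        elif cfg.tie_rule == "case_wins":
            pred = np.where(tie, True, pred)
        else:
            pred = np.where(tie, False, pred)
    onehot = _fold_onehot(plan)
    classified = np.ones_like(Y)
    return _ba_from_rates(pred, Y, classified, onehot)


def cv_neighbors(d2: np.ndarray, plan: CVPlan, k: int) -> np.ndarray:
    """K nearest out-of-fold neighbors of every individual, nearest first.

    Distance ties are broken by ascending individual index.  Implemented
    as a partition on the K-th smallest value followed by a stable sort
    of the (tie-padded) candidate block, which matches a full stable
    argsort but avoids its O(n log n) per row cost.
    """
    folds = np.asarray(plan.fold_ids)
    if k >= np.min(len(folds) - np.bincount(folds)):
        raise ValueError("K must be smaller than every training-fold size")
    masked = d2 + np.where(folds[:, None] == folds[None, :], np.inf, 0.0)
    n = masked.shape[0]
    kth = np.partition(masked, k - 1, axis=1)[:, k - 1 : k]
    lt = masked < kth
    eq = masked == kth
    need = k - lt.sum(axis=1, keepdims=True)
    # keep the lowest-indexed ties at the K-th value only
    sel = lt | (eq & (np.cumsum(eq, axis=1) <= need))
    nb_asc = np.nonzero(sel)[1].reshape(n, k).astype(np.int32)
    vals = np.take_along_axis(masked, nb_asc, axis=1)
    order = np.argsort(vals, axis=1, kind="stable")
    return np.take_along_axis(nb_asc, order, axis=1)


def _fold_onehot(plan: CVPlan) -> np.ndarray:
    folds = np.asarray(plan.fold_ids)
    return (folds[:, None] == np.arange(plan.n_folds)[None, :]).astype(np.float64)


def mdr_cv_ba_batch(
    values: np.ndarray,
    marker_idx: Sequence[int],
    plan: CVPlan,
    Y: np.ndarray,
) -> np.ndarray:
    """Cross-validated BA of the classic cell vote for R label rows."""
    Y = np.atleast_2d(np.asarray(Y, dtype=bool))
    codes = _cell_codes(values, marker_idx)
    n_cells = 3 ** len(list(marker_idx))
    n = len(codes)
    onehot_cells = np.zeros((n, n_cells))
    onehot_cells[np.arange(n), codes] = 1.0
    folds = np.asarray(plan.fold_ids)
    R = Y.shape[0]
    pred = np.zeros((R, n), dtype=bool)
    classified = np.zeros((R, n), dtype=bool)
    for f in range(plan.n_folds):
        test = folds == f
        train = ~test
        tot = onehot_cells[train].sum(axis=0)
        case_c = Y[:, train].astype(np.float64) @ onehot_cells[train]
        ctrl_c = tot[None, :] - case_c
        n_cases = Y[:, train].sum(axis=1, keepdims=True).astype(np.float64)
        n_ctrls = train.sum() - n_cases
        high = case_c * n_ctrls > ctrl_c * n_cases
        test_codes = codes[test]
        pred[:, test] = high[:, test_codes]
        classified[:, test] = (tot > 0)[test_codes][None, :]
    return _ba_from_rates(pred, Y, classified, _fold_onehot(plan))


def cross_validated_ba(
    is_case: np.ndarray,
    plan: CVPlan,
    method: str | Callable[[np.ndarray, np.ndarray], np.ndarray] = "knn_mdr",
    d2: np.ndarray | None = None,
    knn_cfg: KnnConfig | None = None,
    values: np.ndarray | None = None,
    marker_idx: Sequence[int] | None = None,
) -> float:
    """Unweighted mean test-fold balanced accuracy over the CV plan.

    ``method`` selects the KNN vote (needs ``d2`` + ``knn_cfg``), the
    classic cell vote (needs ``values`` + ``marker_idx``), or any
    callable ``(train_idx, test_idx) -> int8 predictions`` for testing.
    """
    is_case = np.asarray(is_case, dtype=bool)
    bas = []
    for f in range(plan.n_folds):
        test_idx = plan.fold_indices(f)
        train_idx = np.flatnonzero(np.asarray(plan.fold_ids) != f)
        if method == "knn_mdr":
            if d2 is None or knn_cfg is None:
                raise ValueError("knn_mdr needs d2 and knn_cfg")
            pred = knn_predict(d2, train_idx, test_idx, is_case, cfg=knn_cfg)
            pred = pred.astype(np.int8)
        elif method == "mdr":
            if values is None or marker_idx is None:
                raise ValueError("mdr needs values and marker_idx")
            pred = mdr_predict(values, marker_idx, train_idx, test_idx, is_case)
        elif callable(method):
            pred = np.asarray(method(train_idx, test_idx), dtype=np.int8)
        else:
            raise ValueError(f"unknown method {method!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bas.append(balanced_accuracy(confusion_counts(is_case[test_idx], pred)))
    return float(np.mean(bas))
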