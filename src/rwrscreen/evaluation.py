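"""Cross-validated recall-precision evaluation, kNN baseline, contrast test.

Labeled drugs are split into k folds; each fold in turn has its seed labels
removed, the walk is rerun on the remaining seeds, and the held-out drugs'
F-ratios are collected.  Precision and recall are swept over the score range
(predicted positive iff score strictly exceeds the threshold) and averaged
across folds both threshold-wise on a shared grid and recall-wise on a common
recall grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .network import BipartiteNetwork, transition_matrix
from .propagation import LabelSet, build_label_matrix, f_ratio, propagate
from .similarity import SimilarityMatrix

__all__ = [
    "FoldAssignment",
    "PRCurve",
    "CVResult",
    "ContrastResult",
    "kfold_split",
    "run_cv",
    "precision_recall",
    "average_precision",
    "knn_scores",
    "similarity_contrast",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of labeled drugs into k folds, reproducible from the seed."""

    fold_of: Mapping[str, int]
    k: int
    seed: int

    def test_ids(self, fold: int) -> list[str]:
        return sorted(d for d, f in self.fold_of.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(d for d, f in self.fold_of.items() if f != fold)


@dataclass
class PRCurve:
    """Precision/recall traced over an ascending threshold grid."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        self.recall = np.asarray(self.recall, dtype=float)
        if not (len(self.thresholds) == len(self.precision) == len(self.recall)):
            raise ValidationError("curve arrays must share one length")
        if np.any(np.diff(self.thresholds) < 0):
            raise ValidationError("thresholds must be ascending")
        if np.any(np.diff(self.recall) > 1e-12):
            raise ValidationError("recall must be non-increasing in the threshold")


@dataclass
class CVResult:
    """Held-out scores plus fold-averaged curves (two averaging conventions)."""

    scores: pd.DataFrame  # columns: drug_id, fold, score, label
    curve: PRCurve  # threshold-wise average on the shared grid
    recall_grid: np.ndarray
    precision_at_recall: np.ndarray  # recall-wise average
    fold_curves: list[PRCurve]


@dataclass
class ContrastResult:
    """Paired mean-similarity contrast of screened drugs vs the two seed sets."""

    table: pd.DataFrame  # columns: drug_id, mean_effective, mean_ineffective
    t_statistic: float
    p_value: float
    df: int


def kfold_split(
    labeled_drugs: Mapping[str, str],
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> FoldAssignment:
    """Randomly partition labeled drugs into k folds of near-equal size.

    With ``stratified`` (default) each class is dealt round-robin through a
    running fold pointer, so per-fold class counts also differ by at most one.
    Deterministic for a given seed.
    """
    ids = sorted(labeled_drugs)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if len(ids) < k:
        raise ValidationError(f"need at least k={k} labeled drugs, got {len(ids)}")
    rng = np.random.default_rng(seed)

    fold_of: dict[str, int] = {}
    if stratified:
        classes = sorted({labeled_drugs[d] for d in ids})
        for cls in classes:
            if sum(labeled_drugs[d] == cls for d in ids) < k:
                raise ValidationError(
                    f"fewer {cls!r} drugs than folds; use stratified=False or smaller k"
                )
        pointer = 0
        for cls in classes:
            members = [d for d in ids if labeled_drugs[d] == cls]
            rng.shuffle(members)
            for d in members:
                fold_of[d] = pointer % k
                pointer += 1
    else:
        shuffled = list(ids)
        rng.shuffle(shuffled)
        for pos, d in enumerate(shuffled):
            fold_of[d] = pos % k
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


def precision_recall(
    scores: Mapping[str, float],
    truth: Mapping[str, bool],
    thresholds: Sequence[float] | None = None,
) -> PRCurve:
    """Sweep a threshold over the scores: positive iff ``score > theta``.

    When no predictions are made, precision is reported as 1.0 (standard
    convention for the empty-prediction boundary).  Default thresholds are
    the sorted unique scores plus a low endpoint giving recall 1.
    """
    missing = [d for d in truth if d not in scores]
    if missing:
        raise ValidationError(f"no score for labeled drug(s) {missing[:5]}")
    ids = sorted(truth)
    s = np.array([scores[d] for d in ids], dtype=float)
    y = np.array([bool(truth[d]) for d in ids])
    if thresholds is None:
        uniq = np.unique(s[np.isfinite(s)])
        low = (uniq[0] - 1.0) if uniq.size else 0.0
        thresholds = np.concatenate([[low], uniq, [np.inf] if np.isinf(s).any() else []])
    thresholds = np.asarray(thresholds, dtype=float)

    n_pos = int(y.sum())
    precision = np.empty(len(thresholds))
    recall = np.empty(len(thresholds))
    for i, theta in enumerate(thresholds):
        pred = s > theta
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        precision[i] = tp / (tp + fp) if (tp + fp) else 1.0
        recall[i] = tp / n_pos if n_pos else 0.0
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall)


def average_precision(scores: Mapping[str, float], truth: Mapping[str, bool]) -> float:
    """Area under the precision-recall curve (step-wise AP, descending scores).

    Ties in score are broken by drug id for determinism.
    """
    ids = sorted(truth, key=lambda d: (-scores[d], d))
    y = np.array([bool(truth[d]) for d in ids])
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValidationError("average precision undefined without positives")
    hits = np.cumsum(y)
    prec_at_hit = hits[y] / (np.flatnonzero(y) + 1)
    return float(prec_at_hit.sum() / n_pos)


def run_cv(
    net: BipartiteNetwork,
    labels: LabelSet,
    folds: FoldAssignment,
    alpha: float = 0.5,
    epsilon: float = 1e-9,
    max_iter: int = 10_000,
    pseudocount: float = 0.0,
    recall_grid_size: int = 51,
) -> CVResult:
    """k-fold cross-validation of the restarting-walk screen.

    Per fold, the held-out drugs' seed labels are removed before the walk is
    run (no leakage: a test drug never contributes to its own score), and
    their F-ratios are recorded.  Gene seeds, when present, always stay in
    the training side.
    """
    labels.validate_against(net)
    labeled = {d: "effective" for d in labels.effective_drugs}
    labeled.update({d: "ineffective" for d in labels.ineffective_drugs})
    unknown = set(folds.fold_of) - set(labeled)
    if unknown:
        raise ValidationError(f"fold assignment covers unlabeled drugs {sorted(unknown)[:5]}")

    T = transition_matrix(net)
    rows = []
    fold_curves: list[PRCurve] = []
    for fold in range(folds.k):
        test = set(folds.test_ids(fold))
        train_labels = LabelSet(
            effective_drugs=labels.effective_drugs - test,
            ineffective_drugs=labels.ineffective_drugs - test,
            aging_genes=labels.aging_genes,
        )
        if not (train_labels.effective_drugs | train_labels.aging_genes):
            raise ValidationError(f"fold {fold}: training set has no effective seeds")
        if not train_labels.ineffective_drugs:
            raise ValidationError(f"fold {fold}: training set has no ineffective seeds")
        L = build_label_matrix(net, train_labels)
        result = propagate(T, L, alpha=alpha, epsilon=epsilon, max_iter=max_iter)
        F = f_ratio(result.P_star, pseudocount=pseudocount)
        for d in sorted(test):
            rows.append(
                {
                    "drug_id": d,
                    "fold": fold,
                    "score": float(F[net.index_of(d)]),
                    "label": labeled[d],
                }
            )
    scores_df = pd.DataFrame(rows)

    # shared threshold grid over all held-out scores
    all_scores = scores_df["score"].to_numpy()
    uniq = np.unique(all_scores[np.isfinite(all_scores)])
    low = (uniq[0] - 1.0) if uniq.size else 0.0
    grid = np.concatenate(
        [[low], uniq, [np.inf] if np.isinf(all_scores).any() else []]
    )
    for fold in range(folds.k):
        part = scores_df[scores_df["fold"] == fold]
        sc = dict(zip(part["drug_id"], part["score"]))
        tr = {d: labeled[d] == "effective" for d in sc}
        fold_curves.append(precision_recall(sc, tr, thresholds=grid))

    mean_precision = np.mean([c.precision for c in fold_curves], axis=0)
    mean_recall = np.mean([c.recall for c in fold_curves], axis=0)
    curve = PRCurve(thresholds=grid, precision=mean_precision, recall=mean_recall)

    recall_grid = np.linspace(0.0, 1.0, recall_grid_size)
    per_fold_at_recall = []
    for c in fold_curves:
        order = np.argsort(c.recall, kind="stable")
        per_fold_at_recall.append(
            np.interp(recall_grid, c.recall[order], c.precision[order])
        )
    precision_at_recall = np.mean(per_fold_at_recall, axis=0)

    return CVResult(
        scores=scores_df,
        curve=curve,
        recall_grid=recall_grid,
        precision_at_recall=precision_at_recall,
        fold_curves=fold_curves,
    )


def knn_scores(
    distances: np.ndarray,
    ids: Sequence[str],
    train_labels: Mapping[str, bool],
    k: int = 3,
    test_ids: Sequence[str] | None = None,
) -> dict[str, float]:
    """Score drugs by the effective fraction among their k nearest neighbors.

    Neighbors are drawn from the labeled training drugs only; distance ties
    are broken by drug id.  A drug present in the training set never counts
    itself as a neighbor.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    ids = list(ids)
    index = {d: i for i, d in enumerate(ids)}
    missing = [d for d in train_labels if d not in index]
    if missing:
        raise ValidationError(f"training drug(s) not in distance matrix: {missing[:5]}")
    if test_ids is None:
        test_ids = [d for d in ids if d not in train_labels]
    train = sorted(train_labels)

    out: dict[str, float] = {}
    for d in test_ids:
        pool = [t for t in train if t != d]
        if k > len(pool):
            raise ValidationError(f"k={k} exceeds {len(pool)} available training drugs")
        pool.sort(key=lambda t: (distances[index[d], index[t]], t))
        nearest = pool[:k]
        out[d] = sum(bool(train_labels[t]) for t in nearest) / k
    return out


def similarity_contrast(
    screened: Sequence[str],
    effective: Sequence[str],
    ineffective: Sequence[str],
    sim: SimilarityMatrix,
) -> ContrastResult:
    """Per-screened-drug mean similarity to each seed set, plus a paired test.

    One-sided paired t-test of the alternative "mean similarity to effective
    drugs exceeds that to ineffective drugs", df = n_screened - 1.  A screened
    drug is excluded from its own averaging set.  With zero variance in the
    paired differences the test carries no evidence: t = 0, p = 1 (policy).
    """
    screened = list(dict.fromkeys(screened))
    if len(screened) < 2:
        raise ValidationError("need at least 2 screened drugs for the paired t-test")
    if not effective or not ineffective:
        raise ValidationError("effective and ineffective sets must be non-empty")
    for group_name, group in (("screened", screened), ("effective", effective), ("ineffective", ineffective)):
        absent = [d for d in group if d not in sim.ids]
        if absent:
            raise ValidationError(f"{group_name} drug(s) absent from similarity matrix: {absent[:5]}")

    idx = {d: sim.index_of(d) for d in set(screened) | set(effective) | set(ineffective)}
    rows = []
    for d in screened:
        eff = [sim.S[idx[d], idx[e]] for e in effective if e != d]
        ine = [sim.S[idx[d], idx[e]] for e in ineffective if e != d]
        if not eff or not ine:
            raise ValidationError(f"averaging set empty after excluding {d!r}")
        rows.append(
            {
                "drug_id": d,
                "mean_effective": float(np.mean(eff)),
                "mean_ineffective": float(np.mean(ine)),
            }
        )
    table = pd.DataFrame(rows)
    diffs = table["mean_effective"] - table["mean_ineffective"]
    if np.allclose(diffs.std(ddof=1), 0.0):
        t_stat, p_val = 0.0, 1.0
    else:
        res = stats.ttest_rel(
            table["mean_effective"], table["mean_ineffective"], alternative="greater"
        )
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return ContrastResult(
        table=table, t_statistic=t_stat, p_value=p_val, df=len(screened) - 1
    )
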