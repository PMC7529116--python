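"""Serial one-vs-all cascade, performance metrics, and nested CV.

The cascade mirrors the serial hardware control flow: classifiers are tried
in task order and the first one whose task probability reaches the decision
threshold labels the window; when none fires, the window is labelled REST
(0). Metrics (accuracy, macro precision/recall/F1, confusion matrix, ROC
AUC) go through scikit-learn. Hyper-parameter selection uses nested
cross-validation grouped at the trial level, so the outer score is computed
on trials never seen by the inner grid search.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .cnn import (
    ModelConfig,
    TrainConfig,
    TrainedBinaryModel,
    predict_proba,
    predict_proba_batch,
    train_binary,
)

__all__ = [
    "REST",
    "CascadeModel",
    "EvalReport",
    "train_cascade",
    "classify_cascade",
    "classify_cascade_batch",
    "compute_metrics",
    "nested_cv_gridsearch",
]

logger = logging.getLogger(__name__)

#: label returned when no classifier in the cascade fires
REST = 0


@dataclass
class CascadeModel:
    """Ordered one-vs-all classifiers; first to fire wins, else REST."""

    models: list[TrainedBinaryModel]
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("cascade needs at least one classifier")
        ids = [m.task_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError(f"task ids must be unique, got {ids}")
        if sorted(ids) != ids:
            raise ValueError(f"task ids must be in increasing order, got {ids}")
        lens = {m.config.input_len for m in self.models}
        if len(lens) != 1:
            raise ValueError(f"all cascade members must share input_len, got {lens}")

    @property
    def input_len(self) -> int:
        return self.models[0].config.input_len


@dataclass
class EvalReport:
    """Aggregate metrics over a labelled window set."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    confusion: np.ndarray
    classes: list[int]
    per_task: dict[int, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "per_task": self.per_task,
        }


def train_cascade(
    train_X: np.ndarray,
    train_y: np.ndarray,
    task_ids: list[int],
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    val_X: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
) -> CascadeModel:
    """Train one one-vs-all classifier per task and assemble the cascade.

    ``train_y`` holds multi-class task labels; each binary problem relabels
    the specified task as 1 and everything else 0.
    """
    models = []
    for t in sorted(task_ids):
        by = (np.asarray(train_y) == t).astype(np.int64)
        bv = None if val_y is None else (np.asarray(val_y) == t).astype(np.int64)
        models.append(train_binary(train_X, by, val_X, bv, mcfg, tcfg, task_id=t))
    return CascadeModel(models=models)


def classify_cascade(cascade: CascadeModel, w: np.ndarray) -> int:
    """Label one window: first task (in order) with p_task >= threshold, else REST.

    Later classifiers are never evaluated once one fires — the serial
    short-circuit of the hardware flow.
    """
    for m in cascade.models:
        p_task, _ = predict_proba(m, w)
        if p_task >= cascade.decision_threshold:
            return m.task_id
    return REST


def classify_cascade_batch(
    cascade: CascadeModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized cascade over (B, L) windows.

    Returns (labels, scores) where scores[i] is the firing classifier's task
    probability (or the maximum task probability across the cascade when the
    window falls through to REST). Semantically identical to calling
    :func:`classify_cascade` per window; every model runs on the full batch
    for speed, so the short-circuit here is logical, not computational.
    """
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    labels = np.full(n, REST, dtype=np.int64)
    fired = np.zeros(n, dtype=bool)
    score = np.zeros(n)
    best = np.zeros(n)
    for m in cascade.models:
        p_task = predict_proba_batch(m, X)[:, 0]
        hit = (~fired) & (p_task >= cascade.decision_threshold)
        labels[hit] = m.task_id
        score[hit] = p_task[hit]
        fired |= hit
        best = np.maximum(best, p_task)
    score[~fired] = best[~fired]
    return labels, score


def cascade_score_matrix(cascade: CascadeModel, X: np.ndarray) -> np.ndarray:
    """(B, K) matrix of every member classifier's task probability.

    Column order follows the cascade's task order; suitable as the 2-D
    ``y_score`` of :func:`compute_metrics` for macro one-vs-rest ROC.
    """
    return np.column_stack([predict_proba_batch(m, X)[:, 0]
                            for m in cascade.models])


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_score: np.ndarray | None = None,
) -> EvalReport:
    """Accuracy, macro precision/recall/F1, confusion matrix, and ROC AUC.

    Precision/recall/F1 are macro-averaged over the task classes present in
    ``y_true`` (REST excluded from the macro set when tasks exist, since the
    cascade treats it as the fall-through). For binary ``y_true`` with a 1-D
    score vector, AUC is the area under the ROC by trapezoidal integration
    over all thresholds. For multi-class truth pass a 2-D score matrix with
    one column per task class (each one-vs-all classifier's task
    probability): AUC is then the macro average of the per-task one-vs-rest
    AUCs. A 1-D score for multi-class truth falls back to per-task AUCs over
    the windows involving that task, skipping degenerate tasks.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")

    classes = sorted(set(np.unique(y_true)) | set(np.unique(y_pred)))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    accuracy = float(np.trace(cm) / cm.sum())

    task_classes = [c for c in classes if c != REST] or classes
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=task_classes, average="macro", zero_division=0.0
    )

    per_task: dict[int, dict[str, float]] = {}
    p_i, r_i, f_i, sup = precision_recall_fscore_support(
        y_true, y_pred, labels=task_classes, average=None, zero_division=0.0
    )
    for c, p, r, f, s in zip(task_classes, p_i, r_i, f_i, sup):
        per_task[int(c)] = {"precision": float(p), "recall": float(r),
                            "f1": float(f), "support": int(s)}

    auc = None
    if y_score is not None:
        y_score = np.asarray(y_score, dtype=np.float64)
        if len(y_score) != len(y_true):
            raise ValueError("y_score must match y_true in length")
        uniq = np.unique(y_true)
        if y_score.ndim == 2:
            if y_score.shape[1] != len(task_classes):
                raise ValueError(
                    f"score matrix has {y_score.shape[1]} columns, expected one "
                    f"per task class ({len(task_classes)})"
                )
            aucs = []
            for j, c in enumerate(task_classes):
                pos = (y_true == c).astype(int)
                if 0 < pos.sum() < len(pos):
                    aucs.append(roc_auc_score(pos, y_score[:, j]))
            auc = float(np.mean(aucs)) if aucs else None
        elif len(uniq) == 2:
            positive = uniq.max()
            auc = float(roc_auc_score((y_true == positive).astype(int), y_score))
        else:
            aucs = []
            for c in task_classes:
                mask_pos = y_true == c
                # score is meaningful for class c where the cascade predicted c
                rel = mask_pos | (y_pred == c)
                if 0 < mask_pos[rel].sum() < rel.sum():
                    aucs.append(roc_auc_score(mask_pos[rel].astype(int), y_score[rel]))
            auc = float(np.mean(aucs)) if aucs else None

    return EvalReport(accuracy=accuracy, precision=float(prec), recall=float(rec),
                      f1=float(f1), auc=auc, confusion=cm,
                      classes=[int(c) for c in classes], per_task=per_task)


# ---------------------------------------------------------------------------
# nested cross-validation

def _trial_folds(tags: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition unique (subject, session, trial) groups into k folds."""
    groups = np.unique(tags, axis=0)
    if len(groups) < k:
        raise ValueError(
            f"nested CV needs at least k={k} distinct trials, got {len(groups)}"
        )
    order = rng.permutation(len(groups))
    folds = [order[i::k] for i in range(k)]
    keys = [tuple(g) for g in groups]
    tag_keys = [tuple(t) for t in tags]
    out = []
    for f in folds:
        members = {keys[i] for i in f}
        out.append(np.array([i for i, t in enumerate(tag_keys) if t in members]))
    return out


def nested_cv_gridsearch(
    X: np.ndarray,
    y: np.ndarray,
    tags: np.ndarray,
    grid: list[tuple[ModelConfig, TrainConfig]],
    k: int,
    seed: int = 0,
) -> tuple[tuple[ModelConfig, TrainConfig], list[dict]]:
    """Nested k-fold CV with trial-level grouping for binary problems.

    The outer loop holds out one fold of trials; the inner loop re-splits
    the remaining trials into k folds and scores every grid point by its
    mean inner-validation accuracy. The winning grid point is retrained on
    all outer-training trials and scored once on the held-out fold, so the
    outer score never sees data that influenced selection. Grid points whose
    construction or training raises are logged and skipped.

    Returns (best config — the most frequently selected grid point, ties to
    the lower index — and per-fold records with the selected index, outer
    accuracy, and the provenance tags of outer-test vs inner-train trials).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not grid:
        raise ValueError("empty hyper-parameter grid")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    tags = np.asarray(tags)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCF]))

    outer = _trial_folds(tags, k, rng)
    fold_records: list[dict] = []
    selections: list[int] = []

    for fold_i, test_idx in enumerate(outer):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        tr_idx = np.flatnonzero(train_mask)
        inner = _trial_folds(tags[tr_idx], min(k, max(2, k)), rng)

        mean_scores = []
        for gi, (mcfg, tcfg) in enumerate(grid):
            scores = []
            try:
                for v in inner:
                    v_glob = tr_idx[v]
                    t_mask = np.ones(len(tr_idx), dtype=bool)
                    t_mask[v] = False
                    t_glob = tr_idx[t_mask]
                    if len(np.unique(y[t_glob])) < 2:
                        raise ValueError("single-class inner-training fold")
                    m = train_binary(X[t_glob], y[t_glob], None, None, mcfg, tcfg)
                    p = predict_proba_batch(m, X[v_glob])[:, 0]
                    scores.append(float(((p >= 0.5).astype(int) == y[v_glob]).mean()))
                mean_scores.append(float(np.mean(scores)))
            except Exception as exc:  # broken grid point: log, never select
                logger.warning("grid point %d failed in fold %d: %s", gi, fold_i, exc)
                mean_scores.append(-np.inf)
        best_gi = int(np.argmax(mean_scores))
        if not np.isfinite(mean_scores[best_gi]):
            raise RuntimeError("every grid point failed during inner CV")
        selections.append(best_gi)

        mcfg, tcfg = grid[best_gi]
        model = train_binary(X[tr_idx], y[tr_idx], None, None, mcfg, tcfg)
        p = predict_proba_batch(model, X[test_idx])[:, 0]
        outer_acc = float(((p >= 0.5).astype(int) == y[test_idx]).mean())
        fold_records.append({
            "fold": fold_i,
            "selected": best_gi,
            "outer_accuracy": outer_acc,
            "inner_mean_scores": mean_scores,
            "outer_test_trials": sorted({tuple(t) for t in tags[test_idx]}),
            "inner_train_trials": sorted({tuple(t) for t in tags[tr_idx]}),
        })

    winner = Counter(selections).most_common()
    top = min(gi for gi, cnt in winner if cnt == winner[0][1])
    return grid[top], fold_records
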