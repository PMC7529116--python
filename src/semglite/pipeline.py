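"""End-to-end orchestration: generate -> window -> normalize -> compress ->
train one-vs-all cascade -> weight sharing -> evaluate.

Convenience layer used by the CLI and the acceptance harness; every step is
a thin call into the corresponding module, with the standard protocol
defaults (250 ms windows, 50% overlap, trials {1,3,4} for training and
trial 2 for validation).
"""

from __future__ import annotations

import numpy as np

from .synthetic import SyntheticProtocol, generate_dataset, make_class_params
from .preprocessing import (
    SplitSpec,
    apply_normalizer,
    fit_normalizer,
    segment_windows,
    split_by_trial,
)
from .compression import compress_window, default_target_len
from .cnn import ModelConfig, TrainConfig, windows_to_arrays
from .evaluation import (
    CascadeModel,
    cascade_score_matrix,
    classify_cascade_batch,
    compute_metrics,
    train_cascade,
)
from .weight_sharing import apply_sharing_to_model

__all__ = ["build_dataset", "run_pipeline", "DEFAULT_SPLIT"]

DEFAULT_SPLIT = SplitSpec(train_trials={1, 3, 4}, validate_trials={2})


def build_dataset(
    n_classes: int = 4,
    seed: int = 0,
    compressed: bool = True,
    window_ms: float = 250.0,
    overlap: float = 0.5,
    sessions: int = 2,
    n_subjects: int = 1,
    split: SplitSpec = DEFAULT_SPLIT,
    target_len: int | None = None,
) -> dict:
    """Synthetic windows ready for training, split by trial and normalized.

    Normalization statistics come from the training windows only; Min/Max
    compression (when requested) is applied after normalization, which is
    equivalent up to the affine rescale since strict extrema positions are
    invariant under affine maps.
    """
    proto = SyntheticProtocol(n_classes=n_classes, sessions=sessions, seed=seed)
    params = make_class_params(n_classes, seed)
    recs = generate_dataset(proto, params, n_subjects=n_subjects)

    windows = []
    for rec in recs:
        windows.extend(segment_windows(rec, window_ms=window_ms, overlap_frac=overlap))
    train_w, val_w = split_by_trial(windows, split)
    stats = fit_normalizer(train_w)
    train_w = [apply_normalizer(stats, w) for w in train_w]
    val_w = [apply_normalizer(stats, w) for w in val_w]

    raw_len = len(train_w[0].x)
    if compressed:
        L = target_len if target_len is not None else default_target_len(raw_len)
        train_w = [compress_window(w, L) for w in train_w]
        val_w = [compress_window(w, L) for w in val_w]
        input_len = L
    else:
        input_len = raw_len

    train_X, train_y, train_tags = windows_to_arrays(train_w)
    val_X, val_y, val_tags = windows_to_arrays(val_w)
    return {
        "train_X": train_X, "train_y": train_y, "train_tags": train_tags,
        "val_X": val_X, "val_y": val_y, "val_tags": val_tags,
        "input_len": input_len, "norm_stats": stats, "protocol": proto,
    }


def run_pipeline(
    n_classes: int = 4,
    seed: int = 0,
    epochs: int = 50,
    compressed: bool = True,
    share: bool = False,
    sessions: int = 2,
    mcfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
) -> dict:
    """Train and evaluate the full cascade on a synthetic dataset.

    Returns the cascade, its validation EvalReport, and (when ``share`` is
    set) the weight-shared cascade with its report and per-model sharing
    statistics.
    """
    data = build_dataset(n_classes=n_classes, seed=seed, compressed=compressed,
                         sessions=sessions)
    if mcfg is None:
        mcfg = ModelConfig(input_len=data["input_len"])
    if tcfg is None:
        tcfg = TrainConfig(max_epochs=epochs, seed=seed)

    cascade = train_cascade(data["train_X"], data["train_y"],
                            task_ids=list(range(1, n_classes + 1)),
                            mcfg=mcfg, tcfg=tcfg)
    labels, _ = classify_cascade_batch(cascade, data["val_X"])
    scores = cascade_score_matrix(cascade, data["val_X"])
    report = compute_metrics(data["val_y"], labels, scores)

    out = {"data": data, "cascade": cascade, "report": report}
    if share:
        shared_models, share_reports = [], []
        for m in cascade.models:
            sm, rep = apply_sharing_to_model(m)
            shared_models.append(sm)
            share_reports.append(rep)
        shared = CascadeModel(models=shared_models,
                              decision_threshold=cascade.decision_threshold)
        s_labels, _ = classify_cascade_batch(shared, data["val_X"])
        s_scores = cascade_score_matrix(shared, data["val_X"])
        out["shared_cascade"] = shared
        out["shared_report"] = compute_metrics(data["val_y"], s_labels, s_scores)
        out["share_reports"] = share_reports
    return out
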