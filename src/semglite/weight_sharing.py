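"""Data-driven weight sharing: stage-2 (offline) compression of FC weights.

A trained fully connected weight sequence, plotted against its index,
resembles an irregular triangular waveform. Sharing keeps the strict local
extrema of that sequence and assigns every other weight the value of its
nearest extremum by index distance (ties go to the left extremum), turning
the sequence into a piecewise-constant square-like waveform. Because many
connections then share one value, only the distinct effective weights plus a
per-position index need to be stored.

Sharing is applied offline to a trained model — only the fully connected
weights are transformed (row-wise: each output neuron's incoming weights are
one sequence); convolution weights and all biases are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil, log2

import numpy as np

from .cnn import TrainedBinaryModel

__all__ = [
    "SharedWeightCodebook",
    "share_weights",
    "encode_codebook",
    "decode_codebook",
    "apply_sharing_to_model",
    "distinct_weight_count",
    "storage_bits",
]


@dataclass(frozen=True)
class SharedWeightCodebook:
    """Effective weight values plus per-position references; decode is exact."""

    values: np.ndarray
    index_map: np.ndarray
    original_len: int

    def __post_init__(self) -> None:
        if len(self.index_map) != self.original_len:
            raise ValueError("index_map length must equal original_len")
        if self.original_len and self.index_map.max(initial=-1) >= len(self.values):
            raise ValueError("index_map refers past the end of values")


def _nonstrict_extrema(x: np.ndarray) -> np.ndarray:
    """Interior indices that are >= both neighbours or <= both neighbours.

    On a weight vector with no repeated values this is exactly the strict
    extremum set of :func:`detect_local_extrema`; the non-strict form is what
    makes sharing idempotent, because every sample of a piecewise-constant
    output qualifies and therefore keeps its value on a second pass.
    """
    if len(x) < 3:
        return np.empty(0, dtype=np.intp)
    left, mid, right = x[:-2], x[1:-1], x[2:]
    keep = ((mid >= left) & (mid >= right)) | ((mid <= left) & (mid <= right))
    return np.flatnonzero(keep) + 1


def share_weights(w: np.ndarray) -> np.ndarray:
    """Replace each weight with its nearest local extremum's value.

    Extremum positions keep their own values; every other position (endpoints
    included) adopts the value of the closest extremum by index distance,
    with ties resolved toward the left (smaller-index) extremum. A sequence
    with no interior extrema is returned unchanged.

    The extremum set here is the non-strict one (>= / <= both neighbours),
    which coincides with the strict comparator rule whenever neighbouring
    weights are distinct — always the case for real-valued trained weights —
    and guarantees idempotence: single-point plateaus of the output would
    remain strict extrema and collapse further under a strict-only rule.
    """
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 1:
        raise ValueError("expected a 1-D weight vector")
    if len(w) == 0:
        return w.copy()
    ext = _nonstrict_extrema(w)
    if len(ext) == 0:
        return w.copy()
    pos = np.arange(len(w))
    # nearest extremum index per position; searchsorted gives the insertion
    # point, compare the two candidates with tie -> left
    right = np.searchsorted(ext, pos)
    left = np.clip(right - 1, 0, len(ext) - 1)
    right = np.clip(right, 0, len(ext) - 1)
    d_left = np.abs(pos - ext[left])
    d_right = np.abs(ext[right] - pos)
    choose = np.where(d_left <= d_right, ext[left], ext[right])
    return w[choose]


def encode_codebook(shared: np.ndarray) -> SharedWeightCodebook:
    """Distinct values (in order of first appearance) + per-position indices."""
    shared = np.asarray(shared, dtype=np.float64)
    values, inverse = np.unique(shared, return_inverse=True)
    if len(shared) == 0:
        return SharedWeightCodebook(values=np.empty(0), index_map=np.empty(0, dtype=np.intp),
                                    original_len=0)
    # reorder to first-appearance order for a stable, readable codebook
    first_pos = np.full(len(values), len(shared))
    np.minimum.at(first_pos, inverse, np.arange(len(shared)))
    order = np.argsort(first_pos, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return SharedWeightCodebook(
        values=values[order],
        index_map=rank[inverse].astype(np.intp),
        original_len=len(shared),
    )


def decode_codebook(cb: SharedWeightCodebook) -> np.ndarray:
    """Exact (bit-equal) reconstruction of the shared weight vector."""
    if cb.original_len == 0:
        return np.empty(0)
    return cb.values[cb.index_map]


def distinct_weight_count(model: TrainedBinaryModel) -> int:
    """Number of distinct values across all FC weight matrices (biases excluded)."""
    mats = [model.fc_weights[0]]
    if model.fc_hidden_weights is not None:
        mats.append(model.fc_hidden_weights[0])
    return len(np.unique(np.concatenate([m.ravel() for m in mats])))


def apply_sharing_to_model(
    model: TrainedBinaryModel, mode: str = "rowwise"
) -> tuple[TrainedBinaryModel, dict]:
    """Share the FC weights of a trained model; conv weights and biases untouched.

    ``mode='rowwise'`` treats each output neuron's incoming weight column as
    one sequence (the default, preserving neuron-level structure);
    ``mode='flat'`` concatenates the whole matrix into a single sequence.
    Returns the compressed model plus a report with distinct-weight counts
    before/after and storage bits at 16-bit words.
    """
    if mode not in ("rowwise", "flat"):
        raise ValueError(f"mode must be 'rowwise' or 'flat', got {mode!r}")

    def share_matrix(w: np.ndarray) -> np.ndarray:
        # w has shape (in_features, out_neurons); a "row" in the sharing sense
        # is one output neuron's incoming sequence, i.e. a column of w
        if mode == "flat":
            return share_weights(w.ravel(order="F")).reshape(
                w.shape[::-1]).T if w.size else w.copy()
        out = np.empty_like(w)
        for j in range(w.shape[1]):
            out[:, j] = share_weights(w[:, j])
        return out

    before = distinct_weight_count(model)
    new_fc = (share_matrix(model.fc_weights[0]), model.fc_weights[1].copy())
    new_fch = None
    if model.fc_hidden_weights is not None:
        new_fch = (share_matrix(model.fc_hidden_weights[0]),
                   model.fc_hidden_weights[1].copy())
    shared_model = TrainedBinaryModel(
        config=model.config,
        conv_weights=[(w.copy(), b.copy()) for w, b in model.conv_weights],
        fc_weights=new_fc,
        fc_hidden_weights=new_fch,
        task_id=model.task_id,
        train_history=list(model.train_history),
    )
    after = distinct_weight_count(shared_model)
    report = {
        "distinct_before": before,
        "distinct_after": after,
        "storage_bits_unshared": storage_bits(model, 16, shared=False),
        "storage_bits_shared": storage_bits(shared_model, 16, shared=True),
    }
    return shared_model, report


def storage_bits(model: TrainedBinaryModel, word_bits: int = 16,
                 shared: bool = False) -> int:
    """FC weight storage cost in bits at the given word length.

    Unshared: every weight stored at full word length. Shared: distinct
    effective values at full word length plus one ceil(log2(n_values)) index
    per position (at least 1 bit per index).
    """
    if word_bits < 1:
        raise ValueError("word_bits must be >= 1")
    mats = [model.fc_weights[0]]
    if model.fc_hidden_weights is not None:
        mats.append(model.fc_hidden_weights[0])
    n_weights = sum(m.size for m in mats)
    if not shared:
        return n_weights * word_bits
    n_values = distinct_weight_count(model)
    index_bits = ceil(log2(max(n_values, 2)))
    return n_values * word_bits + n_weights * index_bits
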