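"""One-vs-all binary 1D-CNN: construction, shape accounting, training, prediction.

Topology: two 1-D convolution layers (7 filters of length 5, stride 1, valid
padding), each followed by ReLU, 2x1 max-pooling and dropout; a flatten
layer; and a fully connected softmax output over the two classes
{specified task, other}. Training uses categorical cross-entropy with the
RMSprop optimizer (learning rate 0.001), batch size 15, and at most 50
epochs; dropout probability is 0.5 during training and disabled at
inference, so the forward pass of a trained model is deterministic.

The network is implemented directly in numpy (forward, backprop, RMSprop):
the topology is small and fixed, and a dependency-free implementation keeps
both training and inference bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocessing import Window
from .compression import CompressedWindow

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedBinaryModel",
    "layer_shapes",
    "count_parameters",
    "init_model",
    "train_binary",
    "predict_proba",
    "predict_proba_batch",
    "windows_to_arrays",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters of one binary classifier.

    ``fc_hidden`` optionally inserts a hidden dense layer of that width
    between flatten and the softmax output; by default the flatten vector
    feeds the 2-way softmax directly (shapes then follow from the conv/pool
    arithmetic alone).
    """

    input_len: int
    n_conv_layers: int = 2
    n_filters: int = 7
    kernel_len: int = 5
    stride: int = 1
    pool_len: int = 2
    dropout_rate: float = 0.5
    n_outputs: int = 2
    fc_hidden: int | None = None

    def __post_init__(self) -> None:
        for name in ("input_len", "n_conv_layers", "n_filters", "kernel_len",
                     "stride", "pool_len", "n_outputs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.fc_hidden is not None and self.fc_hidden < 1:
            raise ValueError("fc_hidden must be >= 1 when given")


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe: RMSprop(0.001), batch 15, up to 50 epochs, CE loss.

    ``shuffle_labels`` is a permutation-control: when set, training labels
    are randomly permuted once before fitting, which destroys the
    signal/label association and should drive validation accuracy to chance.
    ``class_weight`` optionally reweights the loss inversely to class
    frequency (off by default; class imbalance is instead surfaced through
    precision/recall/F1 reporting).
    """

    learning_rate: float = 0.001
    batch_size: int = 15
    max_epochs: int = 50
    seed: int = 0
    rho: float = 0.9
    eps: float = 1e-7
    shuffle_labels: bool = False
    class_weight: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


def layer_shapes(config: ModelConfig) -> list[tuple[str, int, int]]:
    """Ordered (layer name, output length, channels) through the network.

    Valid (no-padding) convolution: out = floor((in - F)/s) + 1;
    non-overlapping max-pool: out = floor(in / p). Raises a shape error
    naming the first layer whose output length would fall below 1.
    """
    shapes = [("input", config.input_len, 1)]
    length, chans = config.input_len, 1
    for j in range(1, config.n_conv_layers + 1):
        conv_out = (length - config.kernel_len) // config.stride + 1
        if length < config.kernel_len or conv_out < 1:
            raise ValueError(
                f"layer conv{j}: input length {length} too short for "
                f"kernel {config.kernel_len}"
            )
        shapes.append((f"conv{j}", conv_out, config.n_filters))
        pool_out = conv_out // config.pool_len
        if pool_out < 1:
            raise ValueError(
                f"layer pool{j}: input length {conv_out} shorter than "
                f"pool size {config.pool_len}"
            )
        shapes.append((f"pool{j}", pool_out, config.n_filters))
        length, chans = pool_out, config.n_filters
    shapes.append(("flatten", length * chans, 1))
    if config.fc_hidden is not None:
        shapes.append(("dense_hidden", config.fc_hidden, 1))
    shapes.append(("output", config.n_outputs, 1))
    return shapes


def count_parameters(config: ModelConfig) -> int:
    """Total trainable parameters: conv_j = N*(F*K_in + 1), dense = (in+1)*out."""
    total = 0
    k_in = 1
    for _ in range(config.n_conv_layers):
        total += config.n_filters * (config.kernel_len * k_in + 1)
        k_in = config.n_filters
    flat = dict((n, l) for n, l, _ in layer_shapes(config))["flatten"]
    if config.fc_hidden is not None:
        total += (flat + 1) * config.fc_hidden
        total += (config.fc_hidden + 1) * config.n_outputs
    else:
        total += (flat + 1) * config.n_outputs
    return total


@dataclass
class TrainedBinaryModel:
    """Weights of one one-vs-all classifier plus its architecture config.

    ``conv_weights`` holds (filters, bias) per conv layer with filter tensors
    shaped (N, K_in, F); ``fc_weights`` is the (in_features, n_outputs) output
    matrix with its bias, after the optional hidden dense layer
    ``fc_hidden_weights``. Output column 0 is the specified task, column 1
    is "other".
    """

    config: ModelConfig
    conv_weights: list[tuple[np.ndarray, np.ndarray]]
    fc_weights: tuple[np.ndarray, np.ndarray]
    fc_hidden_weights: tuple[np.ndarray, np.ndarray] | None = None
    task_id: int = 1
    train_history: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# forward / backward primitives

def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                    stride: int) -> np.ndarray:
    """Valid 1-D cross-correlation. x: (B,K,L), w: (N,K,F) -> (B,N,O)."""
    xw = sliding_window_view(x, w.shape[2], axis=2)[:, :, ::stride, :]
    return np.einsum("bkof,nkf->bno", xw, w, optimize=True) + b[None, :, None]


def _conv1d_backward(x: np.ndarray, w: np.ndarray, dz: np.ndarray,
                     stride: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of the valid cross-correlation."""
    F = w.shape[2]
    xw = sliding_window_view(x, F, axis=2)[:, :, ::stride, :]
    dw = np.einsum("bkof,bno->nkf", xw, dz, optimize=True)
    db = dz.sum(axis=(0, 2))
    # transpose conv for dx: upsample dz by the stride, full-correlate with
    # the length-flipped filters
    B, N, O = dz.shape
    if stride > 1:
        up = np.zeros((B, N, (O - 1) * stride + 1))
        up[:, :, ::stride] = dz
    else:
        up = dz
    pad = np.pad(up, ((0, 0), (0, 0), (F - 1, F - 1)))
    dzw = sliding_window_view(pad, F, axis=2)
    dx = np.einsum("bnif,nkf->bki", dzw, w[:, :, ::-1], optimize=True)
    return dx, dw, db


def _maxpool_forward(a: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pool with floor truncation; returns (pooled, argmax)."""
    B, N, L = a.shape
    Lp = L // p
    blocks = a[:, :, : Lp * p].reshape(B, N, Lp, p)
    arg = blocks.argmax(axis=3)
    return blocks.max(axis=3), arg


def _maxpool_backward(dpool: np.ndarray, arg: np.ndarray, p: int,
                      in_len: int) -> np.ndarray:
    B, N, Lp = dpool.shape
    da = np.zeros((B, N, in_len))
    bi, ni, li = np.ogrid[:B, :N, :Lp]
    da_blocks = da[:, :, : Lp * p].reshape(B, N, Lp, p)
    da_blocks[bi, ni, li, arg] = dpool
    return da


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_model(config: ModelConfig, seed: int = 0, task_id: int = 1,
               zero: bool = False) -> TrainedBinaryModel:
    """Glorot-uniform initialized (or all-zero) model with consistent shapes."""
    shapes = layer_shapes(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC22]))
    conv_weights = []
    k_in = 1
    for _ in range(config.n_conv_layers):
        shp = (config.n_filters, k_in, config.kernel_len)
        fan_in = k_in * config.kernel_len
        w = np.zeros(shp) if zero else _glorot(rng, shp, fan_in, config.n_filters)
        conv_weights.append((w, np.zeros(config.n_filters)))
        k_in = config.n_filters
    flat = dict((n, l) for n, l, _ in shapes)["flatten"]
    fc_hidden_weights = None
    fc_in = flat
    if config.fc_hidden is not None:
        shp = (flat, config.fc_hidden)
        wh = np.zeros(shp) if zero else _glorot(rng, shp, flat, config.fc_hidden)
        fc_hidden_weights = (wh, np.zeros(config.fc_hidden))
        fc_in = config.fc_hidden
    shp = (fc_in, config.n_outputs)
    wo = np.zeros(shp) if zero else _glorot(rng, shp, fc_in, config.n_outputs)
    return TrainedBinaryModel(
        config=config,
        conv_weights=conv_weights,
        fc_weights=(wo, np.zeros(config.n_outputs)),
        fc_hidden_weights=fc_hidden_weights,
        task_id=task_id,
    )


def _forward(model: TrainedBinaryModel, x: np.ndarray,
             dropout_rng: np.random.Generator | None = None) -> tuple:
    """Forward pass on a batch (B, input_len); dropout active iff rng given.

    Returns (probabilities, cache-for-backward).
    """
    cfg = model.config
    a = x[:, None, :]  # (B, 1, L)
    cache = {"x": x, "conv": [], "drop_masks": []}
    for (w, b) in model.conv_weights:
        z = _conv1d_forward(a, w, b, cfg.stride)
        r = np.maximum(z, 0.0)
        pooled, arg = _maxpool_forward(r, cfg.pool_len)
        if dropout_rng is not None and cfg.dropout_rate > 0:
            keep = 1.0 - cfg.dropout_rate
            mask = (dropout_rng.random(pooled.shape) < keep) / keep
            out = pooled * mask
        else:
            mask = None
            out = pooled
        cache["conv"].append({"in": a, "z": z, "relu": r, "arg": arg,
                              "pool_in_len": r.shape[2]})
        cache["drop_masks"].append(mask)
        a = out
    B = a.shape[0]
    flat = a.reshape(B, -1)
    cache["flat_shape"] = a.shape
    cache["flat"] = flat
    h = flat
    if model.fc_hidden_weights is not None:
        wh, bh = model.fc_hidden_weights
        zh = flat @ wh + bh
        h = np.maximum(zh, 0.0)
        cache["zh"] = zh
        cache["h"] = h
    wo, bo = model.fc_weights
    logits = h @ wo + bo
    probs = _softmax(logits)
    cache["head_in"] = h
    return probs, cache


def _backward(model: TrainedBinaryModel, cache: dict, probs: np.ndarray,
              onehot: np.ndarray, sample_w: np.ndarray) -> dict:
    """Gradients of the weighted mean cross-entropy wrt every parameter."""
    cfg = model.config
    B = probs.shape[0]
    dlogits = (probs - onehot) * sample_w[:, None] / B
    wo, _ = model.fc_weights
    grads: dict = {}
    grads["fc_w"] = cache["head_in"].T @ dlogits
    grads["fc_b"] = dlogits.sum(axis=0)
    dh = dlogits @ wo.T
    if model.fc_hidden_weights is not None:
        wh, _ = model.fc_hidden_weights
        dzh = dh * (cache["zh"] > 0)
        grads["fch_w"] = cache["flat"].T @ dzh
        grads["fch_b"] = dzh.sum(axis=0)
        dflat = dzh @ wh.T
    else:
        dflat = dh
    da = dflat.reshape(cache["flat_shape"])
    grads["conv"] = [None] * len(model.conv_weights)
    for j in range(len(model.conv_weights) - 1, -1, -1):
        c = cache["conv"][j]
        mask = cache["drop_masks"][j]
        if mask is not None:
            da = da * mask
        dr = _maxpool_backward(da, c["arg"], cfg.pool_len, c["pool_in_len"])
        dz = dr * (c["z"] > 0)
        w, _ = model.conv_weights[j]
        da, dw, db = _conv1d_backward(c["in"], w, dz, cfg.stride)
        grads["conv"][j] = (dw, db)
    return grads


# ---------------------------------------------------------------------------
# training

def windows_to_arrays(
    windows: list[Window] | list[CompressedWindow],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into (X, labels, trial_tags); tags are (subject, session, trial)."""
    X = np.stack([w.x if isinstance(w, Window) else w.y for w in windows])
    y = np.array([w.label for w in windows], dtype=np.int64)
    tags = np.array([(w.subject_id, w.session_id, w.trial_id) for w in windows],
                    dtype=np.int64)
    return X, y, tags


def _accuracy(model: TrainedBinaryModel, X: np.ndarray, y: np.ndarray) -> float:
    p = predict_proba_batch(model, X)
    pred = (p[:, 0] >= 0.5).astype(np.int64)
    return float((pred == y).mean())


def train_binary(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray | None,
    val_y: np.ndarray | None,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    task_id: int = 1,
) -> TrainedBinaryModel:
    """Fit one one-vs-all classifier with RMSprop on cross-entropy.

    ``train_y`` is binary: 1 for the specified task, 0 for "other"; both
    classes must be present. ``max_epochs=0`` returns the initialized model
    untouched with an empty history. Validation data, when given, is used
    for per-epoch reporting only — never for early stopping or selection.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.int64)
    if train_X.ndim != 2 or train_X.shape[1] != mcfg.input_len:
        raise ValueError(
            f"training windows have length {train_X.shape[-1]}, "
            f"config expects {mcfg.input_len}"
        )
    classes = np.unique(train_y)
    if not np.array_equal(np.sort(classes), [0, 1]):
        raise ValueError(
            "training labels must contain both classes {0 (other), 1 (task)}; "
            f"got {classes.tolist()}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(tcfg.seed), task_id]))
    if tcfg.shuffle_labels:
        train_y = rng.permutation(train_y)

    model = init_model(mcfg, seed=tcfg.seed, task_id=task_id)
    if tcfg.max_epochs == 0:
        return model

    if tcfg.class_weight:
        n, counts = len(train_y), np.bincount(train_y, minlength=2)
        cw = n / (2.0 * np.maximum(counts, 1))
    else:
        cw = np.ones(2)

    # RMSprop caches, one per parameter tensor
    def zeros_like_params():
        return {
            "conv": [(np.zeros_like(w), np.zeros_like(b)) for w, b in model.conv_weights],
            "fch": (None if model.fc_hidden_weights is None else
                    tuple(np.zeros_like(a) for a in model.fc_hidden_weights)),
            "fc": tuple(np.zeros_like(a) for a in model.fc_weights),
        }

    cache_sq = zeros_like_params()

    def rms_step(param: np.ndarray, grad: np.ndarray, sq: np.ndarray) -> None:
        sq *= tcfg.rho
        sq += (1.0 - tcfg.rho) * grad * grad
        param -= tcfg.learning_rate * grad / (np.sqrt(sq) + tcfg.eps)

    # column convention: output[:, 0] is p_task, output[:, 1] is p_other
    n = len(train_y)
    onehot_all = np.zeros((n, 2))
    onehot_all[np.arange(n), 1 - train_y] = 1.0

    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            xb, yb = train_X[idx], train_y[idx]
            ob = onehot_all[idx]
            wb = cw[yb]
            probs, cch = _forward(model, xb, dropout_rng=rng)
            eps = 1e-12
            ep_loss += float(-(wb * np.log(probs[np.arange(len(idx)), 1 - yb] + eps)).sum())
            ep_correct += int(((probs[:, 0] >= 0.5).astype(np.int64) == yb).sum())
            grads = _backward(model, cch, probs, ob, wb)
            for (w, b), (dw, db), (sw, sb) in zip(model.conv_weights, grads["conv"],
                                                  cache_sq["conv"]):
                rms_step(w, dw, sw)
                rms_step(b, db, sb)
            if model.fc_hidden_weights is not None:
                rms_step(model.fc_hidden_weights[0], grads["fch_w"], cache_sq["fch"][0])
                rms_step(model.fc_hidden_weights[1], grads["fch_b"], cache_sq["fch"][1])
            rms_step(model.fc_weights[0], grads["fc_w"], cache_sq["fc"][0])
            rms_step(model.fc_weights[1], grads["fc_b"], cache_sq["fc"][1])
        rec = {
            "epoch": epoch,
            "train_loss": ep_loss / n,
            "train_acc": ep_correct / n,
        }
        if val_X is not None and val_y is not None and len(val_y):
            rec["val_acc"] = _accuracy(model, np.asarray(val_X, dtype=np.float64),
                                       np.asarray(val_y, dtype=np.int64))
        model.train_history.append(rec)
    return model


# ---------------------------------------------------------------------------
# inference

def predict_proba_batch(model: TrainedBinaryModel, X: np.ndarray) -> np.ndarray:
    """(B, 2) array of (p_task, p_other) rows; dropout disabled."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.config.input_len:
        raise ValueError(
            f"input length {X.shape[1]} != configured {model.config.input_len}"
        )
    probs, _ = _forward(model, X, dropout_rng=None)
    return probs


def predict_proba(model: TrainedBinaryModel, w: np.ndarray) -> tuple[float, float]:
    """(p_task, p_other) for a single window vector; always sums to 1."""
    p = predict_proba_batch(model, np.asarray(w, dtype=np.float64))
    return float(p[0, 0]), float(p[0, 1])


# ---------------------------------------------------------------------------
# serialization: portable array container + JSON config sidecar

def save_model(model: TrainedBinaryModel, path: str | Path) -> Path:
    path = Path(path)
    arrays = {}
    for j, (w, b) in enumerate(model.conv_weights):
        arrays[f"conv{j}_w"], arrays[f"conv{j}_b"] = w, b
    if model.fc_hidden_weights is not None:
        arrays["fch_w"], arrays["fch_b"] = model.fc_hidden_weights
    arrays["fc_w"], arrays["fc_b"] = model.fc_weights
    np.savez(path, **arrays)
    meta = {"config": model.config.__dict__, "task_id": model.task_id,
            "train_history": model.train_history}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_model(path: str | Path) -> TrainedBinaryModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(**meta["config"])
    with np.load(path) as z:
        conv = [(z[f"conv{j}_w"], z[f"conv{j}_b"]) for j in range(cfg.n_conv_layers)]
        fch = (z["fch_w"], z["fch_b"]) if "fch_w" in z else None
        fc = (z["fc_w"], z["fc_b"])
    return TrainedBinaryModel(config=cfg, conv_weights=conv, fc_weights=fc,
                              fc_hidden_weights=fch, task_id=meta["task_id"],
                              train_history=meta["train_history"])
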