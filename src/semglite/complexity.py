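"""Analytical operation counts and multi-channel scalability of the CNN.

For a convolution layer producing N output feature maps of size O_V from K
input maps with filters of size F_V, the multiplication and addition counts
are

    M = (O_V * F_V * K) * N        A = (O_V * (F_V - 1) * K) * N

(each output sample needs F_V*K products and F_V*K - 1 accumulations per
filter). Dense-layer multiplications are counted as in_features*out_features
with out_features*(in_features - 1) accumulate additions and a bias add per
output, reported in the same units. Pooling/ReLU/softmax comparison counts
are listed separately, outside the M/A totals, which cover convolution and
dense arithmetic only.

Scaling to n input channels replicates the per-channel convolution/pooling
pipeline n times while the flatten and dense stages are evaluated once on
the n-fold wider flatten vector:

    total(n) = n * (conv1 + conv2 + pool1 + pool2) + flatten + dense(n)
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cnn import ModelConfig, TrainedBinaryModel, layer_shapes, count_parameters
from .weight_sharing import distinct_weight_count, storage_bits

__all__ = [
    "LayerComplexity",
    "ComplexityReport",
    "layer_mults_adds",
    "model_complexity",
]


@dataclass(frozen=True)
class LayerComplexity:
    """Operation counts of one layer: M = O_V*F_V*K*N, A = O_V*(F_V-1)*K*N."""

    name: str
    O_V: int
    F_V: int
    K: int
    N: int
    M: int
    A: int


@dataclass
class ComplexityReport:
    """Per-layer operation counts plus totals, parameters and storage costs."""

    layers: list[LayerComplexity]
    dense: list[LayerComplexity]
    n_channels: int
    total_M: int
    total_A: int
    n_parameters: int
    pool_comparisons: int
    relu_comparisons: int
    storage_bits_16: int
    distinct_fc_weights: int | None = None
    storage_bits_16_shared: int | None = None

    def eq1_identity(self) -> tuple[int, int]:
        """Recompute (total_M, total_A) from parts: n*(conv terms) + dense terms."""
        conv_M = sum(l.M for l in self.layers)
        conv_A = sum(l.A for l in self.layers)
        dense_M = sum(l.M for l in self.dense)
        dense_A = sum(l.A for l in self.dense)
        return self.n_channels * conv_M + dense_M, self.n_channels * conv_A + dense_A


def layer_mults_adds(O_V: int, F_V: int, K: int, N: int) -> tuple[int, int]:
    """(M, A) for one convolution layer; all arguments must be >= 1."""
    for name, v in (("O_V", O_V), ("F_V", F_V), ("K", K), ("N", N)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    M = O_V * F_V * K * N
    A = O_V * (F_V - 1) * K * N
    return M, A


def model_complexity(
    mcfg: ModelConfig,
    n_channels: int = 1,
    model: TrainedBinaryModel | None = None,
) -> ComplexityReport:
    """Full operation-count report for one binary classifier.

    Convolution/pooling costs are per single channel and scale linearly with
    ``n_channels``; the dense stage is counted once, on a flatten vector
    ``n_channels`` times wider. When a trained ``model`` is passed, the
    report also carries its distinct-FC-weight count and shared storage cost.
    """
    if n_channels < 1:
        raise ValueError(f"n_channels must be >= 1, got {n_channels}")
    shapes = layer_shapes(mcfg)
    by_name = {name: (length, chans) for name, length, chans in shapes}

    layers: list[LayerComplexity] = []
    pool_cmp = 0
    relu_cmp = 0
    k_in = 1
    for j in range(1, mcfg.n_conv_layers + 1):
        conv_len, n_f = by_name[f"conv{j}"]
        M, A = layer_mults_adds(conv_len, mcfg.kernel_len, k_in, n_f)
        layers.append(LayerComplexity(f"conv{j}", conv_len, mcfg.kernel_len,
                                      k_in, n_f, M, A))
        relu_cmp += conv_len * n_f
        pool_len, _ = by_name[f"pool{j}"]
        pool_cmp += pool_len * (mcfg.pool_len - 1) * n_f
        k_in = n_f

    flat = by_name["flatten"][0] * n_channels
    dense: list[LayerComplexity] = []
    fc_in = flat
    if mcfg.fc_hidden is not None:
        dense.append(LayerComplexity(
            "dense_hidden", mcfg.fc_hidden, fc_in, 1, 1,
            fc_in * mcfg.fc_hidden, mcfg.fc_hidden * (fc_in - 1) + mcfg.fc_hidden))
        fc_in = mcfg.fc_hidden
    dense.append(LayerComplexity(
        "dense_out", mcfg.n_outputs, fc_in, 1, 1,
        fc_in * mcfg.n_outputs, mcfg.n_outputs * (fc_in - 1) + mcfg.n_outputs))

    total_M = n_channels * sum(l.M for l in layers) + sum(l.M for l in dense)
    total_A = n_channels * sum(l.A for l in layers) + sum(l.A for l in dense)

    n_params = count_parameters(mcfg)
    report = ComplexityReport(
        layers=layers,
        dense=dense,
        n_channels=n_channels,
        total_M=total_M,
        total_A=total_A,
        n_parameters=n_params,
        pool_comparisons=n_channels * pool_cmp,
        relu_comparisons=n_channels * relu_cmp,
        storage_bits_16=n_params * 16,
    )
    if model is not None:
        report.distinct_fc_weights = distinct_weight_count(model)
        report.storage_bits_16_shared = storage_bits(model, 16, shared=True)
    return report
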