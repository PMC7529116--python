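import numpy as np
import pytest

from semglite import (
    SyntheticProtocol,
    generate_recording,
    make_class_params,
    segment_windows,
)


@pytest.fixture(scope="session")
def small_protocol():
    """Short 2-class protocol: 1 s rest + 4 x 2 s trials at 1000 Hz."""
    return SyntheticProtocol(n_classes=2, rest_s=1.0, trial_s=2.0, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_protocol):
    params = make_class_params(2, small_protocol.seed)
    return generate_recording(small_protocol, 1, params[0])


@pytest.fixture(scope="session")
def small_windows(small_recording):
    return segment_windows(small_recording, window_ms=250.0, overlap_frac=0.5)


def brute_force_extrema(x):
    """Independent oracle: exhaustive scan with the strict comparator rule."""
    out = []
    for i in range(1, len(x) - 1):
        if (x[i] > x[i - 1] and x[i] > x[i + 1]) or (
            x[i] < x[i - 1] and x[i] < x[i + 1]
        ):
            out.append(i)
    return out


def brute_force_auc(y_true, y_score):
    """Independent AUC oracle: Mann-Whitney statistic over all +/- pairs."""
    pos = [s for t, s in zip(y_true, y_score) if t == 1]
    neg = [s for t, s in zip(y_true, y_score) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
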