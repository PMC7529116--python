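import itertools

import numpy as np
import pytest

from semglite import (
    REST,
    CascadeModel,
    ModelConfig,
    TrainConfig,
    classify_cascade,
    classify_cascade_batch,
    compute_metrics,
    init_model,
    nested_cv_gridsearch,
)
from semglite.cnn import TrainedBinaryModel
from .conftest import brute_force_auc


class _StubModel(TrainedBinaryModel):
    """Constant-output classifier that counts its own evaluations."""

    def __init__(self, task_id, p_task, input_len=10):
        cfg = ModelConfig(input_len=input_len, kernel_len=2)
        base = init_model(cfg, seed=0, zero=True)
        super().__init__(config=cfg, conv_weights=base.conv_weights,
                         fc_weights=base.fc_weights, task_id=task_id)
        self.p_task = p_task
        self.calls = 0


def _stub_cascade(probs, threshold=0.5):
    models = [_StubModel(i + 1, p) for i, p in enumerate(probs)]
    casc = CascadeModel(models=models, decision_threshold=threshold)
    return casc, models


@pytest.fixture(autouse=True)
def _patch_stub_predict(monkeypatch):
    import semglite.evaluation as ev

    real = ev.predict_proba

    def fake(model, w):
        if isinstance(model, _StubModel):
            model.calls += 1
            return model.p_task, 1.0 - model.p_task
        return real(model, w)

    monkeypatch.setattr(ev, "predict_proba", fake)


class TestClassifyCascade:
    def test_first_firing_model_short_circuits(self):
        casc, models = _stub_cascade([0.9, 0.9, 0.9])
        assert classify_cascade(casc, np.zeros(10)) == 1
        assert [m.calls for m in models] == [1, 0, 0]

    def test_falls_through_to_rest(self):
        casc, models = _stub_cascade([0.1, 0.2, 0.3])
        assert classify_cascade(casc, np.zeros(10)) == REST
        assert [m.calls for m in models] == [1, 1, 1]

    def test_earlier_task_wins_when_two_would_fire(self):
        casc, models = _stub_cascade([0.2, 0.8, 0.9])
        assert classify_cascade(casc, np.zeros(10)) == 2
        assert models[2].calls == 0

    def test_empty_cascade_rejected(self):
        with pytest.raises(ValueError):
            CascadeModel(models=[])

    def test_duplicate_or_unordered_task_ids_rejected(self):
        with pytest.raises(ValueError):
            CascadeModel(models=[_StubModel(1, 0.5), _StubModel(1, 0.5)])
        with pytest.raises(ValueError):
            CascadeModel(models=[_StubModel(2, 0.5), _StubModel(1, 0.5)])

    def test_batch_agrees_with_scalar_path(self):
        """Vectorized cascade must equal the per-window serial result."""
        rng = np.random.default_rng(8)
        models = [init_model(ModelConfig(input_len=12, kernel_len=3), seed=s,
                             task_id=t)
                  for t, s in [(1, 1), (2, 2), (3, 3)]]
        casc = CascadeModel(models=models)
        X = rng.standard_normal((30, 12))
        labels, _ = classify_cascade_batch(casc, X)
        serial = [classify_cascade(casc, x) for x in X]
        assert labels.tolist() == serial


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 2, 1, 2])
        rep = compute_metrics(y, y, y_score=np.array([0.9, 0.1, 0.8, 0.2]))
        assert rep.accuracy == 1.0 and rep.f1 == 1.0

    def test_hand_computed_auc(self):
        """One discordant pair among the 2x4 positive-negative pairs -> 7/8."""
        y = np.array([1, 1, 0, 0, 0, 0])
        s = np.array([0.9, 0.5, 0.6, 0.3, 0.2, 0.1])
        rep = compute_metrics(y, y, y_score=s)
        assert rep.auc == pytest.approx(0.875)
        assert rep.auc == pytest.approx(brute_force_auc(y, s))

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(17)
        y = rng.integers(0, 2, size=4000)
        s = rng.random(4000)
        rep = compute_metrics(y, y, y_score=s)
        assert rep.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_pair_statistic_exhaustively(self):
        """Brute-force Mann-Whitney oracle on all binary label patterns of
        size <= 7 with distinct scores."""
        scores = np.linspace(0.1, 0.9, 7)
        for n in range(2, 8):
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                y = np.array(labels)
                s = scores[:n]
                rep = compute_metrics(y, y, y_score=s)
                assert rep.auc == pytest.approx(brute_force_auc(y, s))

    def test_f1_identity(self):
        y_true = np.array([1, 1, 2, 2, 1])
        y_pred = np.array([1, 2, 2, 2, 1])
        rep = compute_metrics(y_true, y_pred)
        for c, m in rep.per_task.items():
            if m["precision"] + m["recall"] > 0:
                expect = (2 * m["precision"] * m["recall"]
                          / (m["precision"] + m["recall"]))
                assert m["f1"] == pytest.approx(expect)

    def test_confusion_row_sums_equal_support(self):
        y_true = np.array([0, 1, 1, 2, 2, 2])
        y_pred = np.array([1, 1, 2, 2, 0, 2])
        rep = compute_metrics(y_true, y_pred)
        for i, c in enumerate(rep.classes):
            assert rep.confusion[i].sum() == (y_true == c).sum()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.empty(0), np.empty(0))


class TestNestedCV:
    @staticmethod
    def _dataset(rng, n_trials=6):
        """Binary windows tagged by trial; classes separated by a mean offset
        (a deliberately easy cue so short training runs suffice)."""
        X, y, tags = [], [], []
        for trial in range(1, n_trials + 1):
            for cls in (0, 1):
                offset = 0.0 if cls == 0 else 3.0
                X.append(offset + rng.standard_normal((12, 24)))
                y.extend([cls] * 12)
                tags.extend([(0, 0, trial)] * 12)
        return np.vstack(X), np.array(y), np.array(tags)

    def test_single_point_grid_reduces_to_plain_cv(self):
        rng = np.random.default_rng(2)
        X, y, tags = self._dataset(rng)
        grid = [(ModelConfig(input_len=24), TrainConfig(max_epochs=3, seed=0))]
        best, folds = nested_cv_gridsearch(X, y, tags, grid, k=3, seed=1)
        assert best == grid[0]
        assert len(folds) == 3
        assert all(f["selected"] == 0 for f in folds)

    def test_broken_grid_point_never_selected(self):
        rng = np.random.default_rng(3)
        X, y, tags = self._dataset(rng)
        grid = [
            (ModelConfig(input_len=24), TrainConfig(max_epochs=3, seed=0)),
            # kernel longer than the pooled feature map: shape error on build
            (ModelConfig(input_len=24, kernel_len=23, pool_len=2),
             TrainConfig(max_epochs=3, seed=0)),
        ]
        best, folds = nested_cv_gridsearch(X, y, tags, grid, k=3, seed=1)
        assert best == grid[0]
        assert all(f["selected"] == 0 for f in folds)
        assert all(f["inner_mean_scores"][1] == -np.inf for f in folds)

    def test_honest_config_beats_label_shuffling(self):
        rng = np.random.default_rng(4)
        X, y, tags = self._dataset(rng)
        grid = [
            (ModelConfig(input_len=24), TrainConfig(max_epochs=10, seed=0,
                                                    shuffle_labels=True)),
            (ModelConfig(input_len=24), TrainConfig(max_epochs=10, seed=0)),
        ]
        best, folds = nested_cv_gridsearch(X, y, tags, grid, k=3, seed=1)
        assert best == grid[1]
        assert all(f["selected"] == 1 for f in folds)

    def test_leak_freedom_via_provenance_tags(self):
        rng = np.random.default_rng(5)
        X, y, tags = self._dataset(rng)
        grid = [(ModelConfig(input_len=24), TrainConfig(max_epochs=2, seed=0))]
        _, folds = nested_cv_gridsearch(X, y, tags, grid, k=3, seed=1)
        for f in folds:
            outer = set(map(tuple, f["outer_test_trials"]))
            inner = set(map(tuple, f["inner_train_trials"]))
            assert not outer & inner

    def test_fewer_trials_than_folds_rejected(self):
        rng = np.random.default_rng(6)
        X, y, tags = self._dataset(rng, n_trials=2)
        grid = [(ModelConfig(input_len=24), TrainConfig(max_epochs=1, seed=0))]
        with pytest.raises(ValueError, match="trials"):
            nested_cv_gridsearch(X, y, tags, grid, k=5, seed=1)
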