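"""Network architecture, training, tuning and ensembling."""

import numpy as np
import pytest

from fractomap.augment import TrainingSet
from fractomap.data_io import DataError
from fractomap.nnmodel import (LR_BOUNDS, NetworkSpec, build_network,
                               default_spec, hidden_size_range,
                               predict_ensemble, train_single,
                               tune_hyperparameters)


@pytest.mark.parametrize("F,C,expected", [
    (16, 8, (11, 13)),   # 8 + 0.4*8 = 11.2, 8 + 0.6*8 = 12.8
    (8, 8, (8, 8)),
    (6, 8, (8, 8)),      # floored at C when F < C
    (16, 12, (14, 14)),
])
def test_hidden_size_range(F, C, expected):
    assert hidden_size_range(F, C) == expected


class TestForwardPass:
    def _with_head(self, W2, b2, F=3, C=3):
        spec = NetworkSpec(F=F, C=C, hidden1=C)
        net = build_network(spec, seed=0)
        # make the hidden layer an identity pass-through
        net.W1 = np.eye(F, spec.hidden1)
        net.b1 = np.zeros(spec.hidden1)
        net.W2 = np.asarray(W2, dtype=float)
        net.b2 = np.asarray(b2, dtype=float)
        return net

    def test_output_sums_to_one_for_any_input(self, rng):
        net = build_network(NetworkSpec(F=7, C=4, hidden1=6), seed=1)
        Y = net.predict(rng.random((50, 7)))
        assert np.allclose(Y.sum(axis=1), 1.0, atol=1e-12)
        assert (Y >= 0).all()

    def test_positive_activations_normalized(self):
        net = self._with_head(np.zeros((3, 3)), [2.0, 1.0, 1.0])
        Y = net.predict(np.zeros((1, 3)))
        assert np.allclose(Y, [[0.5, 0.25, 0.25]])

    def test_negative_activations_clamped_before_normalizing(self):
        net = self._with_head(np.zeros((3, 3)), [-1.0, 3.0, 0.0])
        Y = net.predict(np.zeros((1, 3)))
        assert np.allclose(Y, [[0.0, 1.0, 0.0]])

    def test_all_nonpositive_gives_uniform(self):
        net = self._with_head(np.zeros((3, 3)), [-1.0, -2.0, 0.0])
        Y = net.predict(np.zeros((1, 3)))
        assert np.allclose(Y, [[1 / 3, 1 / 3, 1 / 3]])


def _toy_training_set(n_per_class=40, F=6, seed=0):
    """Two orthogonal one-hot compartments: trivially separable."""
    rng = np.random.default_rng(seed)
    X, Y = [], []
    for ci in range(2):
        base = np.zeros(F)
        base[3 * ci:3 * ci + 3] = 1 / 3
        for _ in range(n_per_class):
            x = base + rng.normal(0, 0.01, F)
            x = np.clip(x, 0, None)
            X.append(x / x.sum())
            t = np.zeros(2)
            t[ci] = 1.0
            Y.append(t)
    X, Y = np.asarray(X), np.asarray(Y)
    return TrainingSet(X, Y, np.asarray(["marker"] * len(X), dtype=object),
                       ["c1", "c2"])


def test_training_reaches_low_mse_on_separable_toy():
    tset = _toy_training_set()
    spec = default_spec(6, 2)
    net = build_network(spec, seed=4)
    train_single(net, tset, seed=4)
    assert net.mse(tset.X, tset.Y) < 0.01


def test_training_is_deterministic():
    tset = _toy_training_set()
    spec = default_spec(6, 2)
    a = build_network(spec, seed=4)
    va = train_single(a, tset, seed=4)
    b = build_network(spec, seed=4)
    vb = train_single(b, tset, seed=4)
    assert va == vb
    assert np.array_equal(a.W1, b.W1)


def test_early_stopping_halts_on_plateau():
    # force a validation plateau: training must stop after exactly
    # `patience` non-improving epochs, not exhaust max_epochs
    tset = _toy_training_set()
    net = build_network(default_spec(6, 2), seed=0)
    counted = {"epochs": 0}

    def plateau_mse(X, T):
        counted["epochs"] += 1
        return 1.0

    net.mse = plateau_mse
    train_single(net, tset, seed=0, max_epochs=500, patience=5)
    assert counted["epochs"] == 6  # first epoch sets best, then 5 stale


def test_training_set_too_small_rejected():
    tset = _toy_training_set(n_per_class=4)
    small = TrainingSet(tset.X[:8], tset.Y[:8], tset.origin[:8],
                        tset.compartment_order)
    net = build_network(default_spec(6, 2), seed=0)
    with pytest.raises(DataError, match="too small"):
        train_single(net, small, seed=0)


def test_tuning_returns_spec_within_search_space():
    tset = _toy_training_set()
    spec = tune_hyperparameters(tset, F=6, C=2, seed=8, max_epochs=6)
    low, high = hidden_size_range(6, 2)
    assert low <= spec.hidden1 <= high
    assert LR_BOUNDS[0] <= spec.learning_rate <= LR_BOUNDS[1]
    assert spec.optimizer in ("sgd", "rmsprop", "adam")


def test_default_spec_is_midpoint():
    spec = default_spec(16, 8)
    assert spec.hidden1 == 12
    assert spec.optimizer == "adam"
    assert spec.learning_rate == 1e-3


class TestEnsemble:
    def test_raw_vector_count_and_simplex(self, tiny_dataset, tiny_run):
        raw = tiny_run.prediction.raw
        order = tiny_run.prediction.compartment_order
        # 1 round x 2 runs -> 2 raw vectors per (species, replicate)
        counts = raw.groupby(["species", "condition", "replicate"]).size()
        assert (counts == 2).all()
        W = raw[order].to_numpy()
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-6)
        assert (W >= 0).all()

    def test_aggregated_means_renormalized(self, tiny_run):
        order = tiny_run.prediction.compartment_order
        for m in tiny_run.prediction.mean.values():
            assert np.allclose(m[order].sum(axis=1), 1.0, atol=1e-9)

    def test_single_compartment_recovery_on_markers(self, tiny_dataset,
                                                    tiny_run):
        # noise-limited check: marker argmax of the ensemble mean must
        # match the annotated compartment for >= 95% of markers
        labels = tiny_dataset.markers.labels
        m = tiny_run.prediction.mean["Cond1"]
        shared = [s for s in m.index if s in labels.index]
        hit = (m.loc[shared].idxmax(axis=1) == labels[shared]).mean()
        assert hit >= 0.95

    def test_mixed_profile_recovery(self, tiny_dataset, tiny_run):
        # 50:50 doubles: mean absolute error of the predicted weights
        # against the (0.5, 0.5) truth stays within 0.15
        ds = tiny_dataset
        truth = ds.truth_weights("Cond1")
        m = tiny_run.prediction.mean["Cond1"]
        halves = [s for s in truth.index
                  if s in m.index
                  and sorted(truth.loc[s][truth.loc[s] > 0]) == [0.5, 0.5]]
        err = (m.loc[halves, ds.compartment_order]
               - truth.loc[halves]).abs().to_numpy()
        assert err.mean() <= 0.15

    def test_invalid_ensemble_sizes_rejected(self, tiny_dataset):
        from fractomap.preprocess import (impute_fractionation,
                                          sum_normalize)
        tensor = sum_normalize(
            impute_fractionation(tiny_dataset.fractionation))
        with pytest.raises(DataError):
            predict_ensemble(tensor, tiny_dataset.markers, seed=0,
                             rounds=0, runs=1)
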