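"""Threshold computation, false-positive filtering, localization calls."""

import numpy as np
import pandas as pd
import pytest

from fractomap.ccfilter import (CCMatrix, ThresholdVector, apply_filter,
                                call_localization, compute_thresholds)
from fractomap.data_io import DataError, MarkerSet
from fractomap.nnmodel import EnsemblePrediction


def _prediction(mean_frames, raw=None):
    order = list(next(iter(mean_frames.values())).columns)
    if raw is None:
        rows = []
        for g, m in mean_frames.items():
            block = m.copy()
            block.insert(0, "run", 0)
            block.insert(0, "round", 0)
            block.insert(0, "replicate", 1)
            block.insert(0, "condition", g)
            rows.append(block.reset_index(names="species"))
        raw = pd.concat(rows, ignore_index=True)
    return EnsemblePrediction(raw=raw, mean=mean_frames, std={},
                              compartment_order=order)


class TestThresholds:
    def test_percentile_against_independent_oracle(self):
        # foreign outputs 0.001..0.100 evenly spaced: tau = 95th percentile
        vals = np.linspace(0.001, 0.100, 100)
        markers = MarkerSet(
            pd.Series({f"M{i}": "B" for i in range(100)}
                      | {f"A{i}": "A" for i in range(3)}), ["A", "B"])
        mean = pd.DataFrame(
            {"A": np.concatenate([vals, [0.9, 0.9, 0.9]]),
             "B": np.concatenate([1 - vals, [0.1, 0.1, 0.1]])},
            index=[f"M{i}" for i in range(100)] + [f"A{i}" for i in range(3)])
        pred = _prediction({"g": mean})
        tau = compute_thresholds(pred, markers, level="mean")
        k = 0.95 * 99  # linear interpolation between order statistics
        lo, hi = vals[int(k)], vals[int(k) + 1]
        expected = lo + (k - int(k)) * (hi - lo)
        assert tau.tau["g"]["A"] == pytest.approx(expected, abs=1e-12)

    def test_zero_foreign_outputs_give_zero_threshold(self):
        markers = MarkerSet(
            pd.Series({"M1": "B", "M2": "B", "M3": "A"}), ["A", "B"])
        mean = pd.DataFrame({"A": [0.0, 0.0, 1.0], "B": [1.0, 1.0, 0.0]},
                            index=["M1", "M2", "M3"])
        tau = compute_thresholds(_prediction({"g": mean}), markers,
                                 level="mean")
        assert tau.tau["g"]["A"] == 0.0

    def test_raising_foreign_output_weakly_increases_threshold(self, rng):
        markers = MarkerSet(
            pd.Series({f"M{i}": "B" for i in range(20)} | {"A0": "A"}),
            ["A", "B"])
        base = rng.random(20) * 0.1
        for bump in (0.0, 0.5):
            vals = base.copy()
            vals[7] += bump
            mean = pd.DataFrame(
                {"A": np.append(vals, 0.9), "B": np.append(1 - vals, 0.1)},
                index=[f"M{i}" for i in range(20)] + ["A0"])
            tau = compute_thresholds(_prediction({"g": mean}), markers,
                                     level="mean")
            if bump == 0.0:
                first = tau.tau["g"]["A"]
        assert tau.tau["g"]["A"] >= first

    def test_no_foreign_marker_is_an_error(self):
        markers = MarkerSet(pd.Series({"M1": "A", "M2": "A", "M3": "B"}),
                            ["A", "B", "C"])
        mean = pd.DataFrame(np.ones((3, 3)) / 3, index=["M1", "M2", "M3"],
                            columns=["A", "B", "C"])
        pred = _prediction({"g": mean})
        tau = compute_thresholds(pred, markers, level="mean")  # fine: A,B,C all have foreign
        lonely = MarkerSet(pd.Series({"M1": "A", "M2": "A", "M3": "A"}),
                           ["A", "B"])
        with pytest.raises(DataError, match="foreign"):
            compute_thresholds(pred, lonely, level="mean")


class TestFilter:
    def test_filter_and_renormalize_example(self):
        mean = pd.DataFrame([[0.50, 0.30, 0.20]], index=["P1"],
                            columns=["A", "B", "C"])
        tau = ThresholdVector({"g": pd.Series(
            {"A": 0.10, "B": 0.35, "C": 0.15})})
        ccm = apply_filter(_prediction({"g": mean}), tau)
        assert np.allclose(ccm.cc["g"].loc["P1"],
                           [0.7142857, 0.0, 0.2857143], atol=1e-6)

    def test_all_below_threshold_is_unassigned(self):
        mean = pd.DataFrame([[0.3, 0.3, 0.4]], index=["P1"],
                            columns=["A", "B", "C"])
        tau = ThresholdVector({"g": pd.Series(
            {"A": 0.5, "B": 0.5, "C": 0.5})})
        ccm = apply_filter(_prediction({"g": mean}), tau)
        assert (ccm.cc["g"].loc["P1"] == 0).all()
        assert ccm.unassigned == ["P1"]

    def test_zero_thresholds_are_identity(self):
        mean = pd.DataFrame([[0.5, 0.3, 0.2]], index=["P1"],
                            columns=["A", "B", "C"])
        tau = ThresholdVector({"g": pd.Series({"A": 0.0, "B": 0.0, "C": 0.0})})
        ccm = apply_filter(_prediction({"g": mean}), tau)
        assert np.allclose(ccm.cc["g"].loc["P1"], [0.5, 0.3, 0.2])

    def test_raising_thresholds_never_grows_support(self, rng):
        mean = pd.DataFrame(rng.dirichlet(np.ones(4), size=30),
                            columns=list("ABCD"))
        mean.index = [f"P{i}" for i in range(30)]
        pred = _prediction({"g": mean})
        lo = ThresholdVector({"g": pd.Series(dict(zip("ABCD", [0.1] * 4)))})
        hi = ThresholdVector({"g": pd.Series(dict(zip("ABCD", [0.3] * 4)))})
        sup_lo = apply_filter(pred, lo).cc["g"].to_numpy() > 0
        sup_hi = apply_filter(pred, hi).cc["g"].to_numpy() > 0
        assert not (sup_hi & ~sup_lo).any()

    def test_assigned_rows_sum_to_one_and_support_shrinks(self, tiny_run):
        for g, frame in tiny_run.cc.cc.items():
            W = frame.to_numpy()
            mean = tiny_run.prediction.mean[g].to_numpy()
            sums = W.sum(axis=1)
            assigned = sums > 0
            assert np.allclose(sums[assigned], 1.0, atol=1e-9)
            assert not ((W > 0) & ~(mean > 0)).any()


class TestCalls:
    def _ccm(self, rows, order=("A", "B", "C")):
        frame = pd.DataFrame(rows, columns=list(order),
                             index=[f"P{i}" for i in range(len(rows))])
        return CCMatrix({"g": frame}, list(order))

    def test_single_and_multiple_calls(self):
        calls = call_localization(
            self._ccm([[1, 0, 0], [0.7, 0, 0.3], [0, 0, 0]]))["g"]
        assert calls.loc["P0", "call"] == "single"
        assert calls.loc["P0", "main"] == "A"
        assert calls.loc["P1", "call"] == "multiple"
        assert calls.loc["P1", "main"] == "A"
        assert calls.loc["P1", "n_localizations"] == 2
        assert calls.loc["P2", "call"] == "unassigned"
        assert calls.loc["P2", "main"] is None

    def test_tie_broken_by_compartment_order_with_flag(self):
        calls = call_localization(self._ccm([[0.5, 0.5, 0]]))["g"]
        assert calls.loc["P0", "main"] == "A"
        assert bool(calls.loc["P0", "tie"])
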