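"""Lipid processing: mol%, KNN-TN imputation, integration, FA features."""

import numpy as np
import pandas as pd
import pytest

from fractomap.data_io import DataError, TotalOmicsTable
from fractomap.lipidomics import (LipidSpecies, integrate_lipid_profiles,
                                  knn_tn_impute, molar_fraction_normalize,
                                  parse_lipid_id,
                                  weighted_fatty_acid_feature)


class TestMolPercent:
    def test_basic_normalization(self):
        out = molar_fraction_normalize(pd.Series({"a": 1.5, "b": 4.5}))
        assert out["a"] == pytest.approx(25.0)
        assert out["b"] == pytest.approx(75.0)

    def test_sub_threshold_dropped_before_normalization(self):
        out = molar_fraction_normalize(
            pd.Series({"a": 0.8, "b": 2.0, "c": 2.0}))
        assert "a" not in out.index
        assert out.sum() == pytest.approx(100.0, abs=1e-9)

    def test_conservation(self, rng):
        amounts = pd.Series(rng.uniform(0, 50, size=200))
        out = molar_fraction_normalize(amounts)
        assert out.sum() == pytest.approx(100.0, abs=1e-9)

    def test_all_below_threshold_rejected(self):
        with pytest.raises(DataError):
            molar_fraction_normalize(pd.Series({"a": 0.5, "b": 0.9}))


class TestParse:
    def test_shorthand(self):
        lip = parse_lipid_id("PC 34:2")
        assert (lip.lipid_class, lip.n_fatty_acids) == ("PC", 2)
        assert (lip.total_carbons, lip.total_double_bonds) == (34, 2)
        assert parse_lipid_id("TAG 52:3").n_fatty_acids == 3
        assert parse_lipid_id("CL 72:8").n_fatty_acids == 4

    def test_override_and_unknown_class(self):
        assert parse_lipid_id("XYZ 30:1", n_fatty_acids=2).n_fatty_acids == 2
        with pytest.raises(DataError, match="unknown lipid class"):
            parse_lipid_id("XYZ 30:1")


class TestKnnTn:
    def _table(self, values, ids=None):
        values = np.asarray(values, dtype=float)
        samples = [f"S{j}" for j in range(values.shape[1])]
        ann = pd.DataFrame([(s, "g", j + 1) for j, s in enumerate(samples)],
                           columns=["sample", "condition", "replicate"])
        data = pd.DataFrame(values, columns=samples,
                            index=ids or [f"L{i}" for i in range(len(values))])
        return TotalOmicsTable(data, ann)

    def test_identical_neighbor_fills_exact_value(self):
        # lipid A missing in sample 3; B complete and identical elsewhere
        table = self._table([[10.0, 20.0, np.nan],
                             [10.0, 20.0, 40.0],
                             [500.0, 900.0, 700.0]])
        out = knn_tn_impute(table, seed=0)
        # imputed A3 = B3 -> mean over 3 samples matches B's mean
        assert out.means["g"]["L0"] == pytest.approx(out.means["g"]["L1"])

    def test_truncation_at_observed_minimum(self):
        # neighbor offset would push the prediction below the global
        # minimum; the truncated-normal floor prevents that
        table = self._table([[1.0, 1.0, np.nan],
                             [100.0, 100.0, 0.5],
                             [80.0, 90.0, 85.0]])
        out = knn_tn_impute(table, seed=0)
        imputed = out.means["g"]["L0"] * 3 - 2.0
        assert imputed >= 0.5 - 1e-9

    def test_determinism(self, rng):
        vals = rng.uniform(1, 100, size=(30, 4))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        table = self._table(vals)
        a = knn_tn_impute(table, seed=5)
        b = knn_tn_impute(table, seed=5)
        pd.testing.assert_series_equal(a.means["g"], b.means["g"])


class TestIntegration:
    def test_combined_table_and_kind_flags(self, tiny_dataset):
        prot = tiny_dataset.fractionation
        lipid_ids = [f"PC 3{i}:{i}" for i in range(4)]
        rng = np.random.default_rng(0)
        lip = type(prot)(
            pd.DataFrame(rng.uniform(0, 100, (4, prot.data.shape[1])),
                         index=lipid_ids, columns=prot.data.columns),
            prot.annotation)
        combined, kinds = integrate_lipid_profiles(prot, lip)
        assert combined.data.shape[0] == prot.data.shape[0] + 4
        assert (kinds[lipid_ids] == "lipid").all()
        assert (kinds[prot.species_ids] == "protein").all()

    def test_lipids_share_filtering_and_normalization(self, tiny_dataset):
        from fractomap.preprocess import (filter_by_replicates,
                                          impute_fractionation,
                                          sum_normalize)
        prot = tiny_dataset.fractionation
        ann = prot.annotation
        # a lipid present in only 1 of 3 replicates must be removed
        row = np.full(prot.data.shape[1], np.nan)
        for s in ann.samples_for("Cond1", 1):
            row[prot.data.columns.get_loc(s)] = 5.0
        lip = type(prot)(
            pd.DataFrame([row], index=["PC 34:2"], columns=prot.data.columns),
            ann)
        combined, _ = integrate_lipid_profiles(prot, lip)
        tensor = sum_normalize(impute_fractionation(
            filter_by_replicates(combined)))
        assert not tensor.present["Cond1"].get("PC 34:2", False)


class TestWeightedFeature:
    def test_printed_example(self):
        a = LipidSpecies("PC 32:0", "PC", 2, 32, 0)
        b = LipidSpecies("PC 36:0", "PC", 2, 36, 0)
        q = weighted_fatty_acid_feature([a, b], [1.0, 1.0], [10.0, 10.0])
        assert q == pytest.approx(17.0)

    def test_single_species_identity(self):
        a = LipidSpecies("TAG 54:3", "TAG", 3, 54, 3)
        assert weighted_fatty_acid_feature([a], [0.4], [7.0]) \
            == pytest.approx(54 / 3)
        assert weighted_fatty_acid_feature([a], [0.4], [7.0],
                                           feature="double_bonds") \
            == pytest.approx(1.0)

    def test_zero_cc_species_contribute_nothing(self):
        a = LipidSpecies("PC 32:0", "PC", 2, 32, 0)
        b = LipidSpecies("PC 40:0", "PC", 2, 40, 0)
        with_b = weighted_fatty_acid_feature([a, b], [1.0, 0.0], [10, 99])
        assert with_b == pytest.approx(16.0)

    def test_matches_brute_force_enumeration(self, rng):
        # oracle: expand each species into amount*CC weight on its total
        # feature and average explicitly
        for _ in range(50):
            n = int(rng.integers(1, 8))
            f_l = int(rng.integers(1, 5))
            lips = [LipidSpecies(f"X {c}:{d}", "X", f_l, int(c), int(d))
                    for c, d in zip(rng.integers(10, 80, n),
                                    rng.integers(0, 12, n))]
            cc = rng.random(n)
            amt = rng.uniform(0.1, 20, n)
            num = sum(l.total_carbons * a * c
                      for l, a, c in zip(lips, amt, cc))
            den = f_l * sum(a * c for a, c in zip(amt, cc))
            expected = num / den
            got = weighted_fatty_acid_feature(lips, cc, amt)
            assert abs(got - expected) < 1e-10

    def test_zero_denominator_is_missing(self):
        a = LipidSpecies("PC 32:0", "PC", 2, 32, 0)
        assert np.isnan(weighted_fatty_acid_feature([a], [0.0], [10.0]))
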