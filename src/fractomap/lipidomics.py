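"""Lipid-specific processing.

Shotgun lipidomics reports molar amounts per lipid species; these are
converted to molar fractions (mol%) per sample after discarding species at
or below 1 pmol. Lipid fractionation profiles are appended to the protein
table as additional species: they share the protein filtering and
normalization path and receive compartment predictions from the
protein-trained network while contributing no training markers. Missing
total-lipidome values are imputed by a nearest-neighbor scheme in log
space with truncation at the observed minimum (KNN-TN). Compartment-level
lipid chemistry is summarized by CC- and amount-weighted mean features
(carbon-chain length or double bonds) per fatty acid and lipid class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DataError, FractionationTable, TotalOmicsTable
from .preprocess import TotalAbundance

#: default number of fatty-acyl chains per lipid class
FATTY_ACIDS_PER_CLASS = {
    "TAG": 3, "TG": 3, "CL": 4, "DAG": 2, "DG": 2,
    "PC": 2, "PE": 2, "PG": 2, "PI": 2, "PS": 2, "PA": 2, "BMP": 2, "SM": 2,
    "LPC": 1, "LPE": 1, "LPG": 1, "LPI": 1, "LPS": 1, "LPA": 1,
    "CER": 1, "CE": 1, "HEXCER": 1, "MAG": 1, "MG": 1,
}

_SHORTHAND = re.compile(
    r"^\s*(?P<cls>[A-Za-z]+[A-Za-z0-9]*)[ _-]+(?P<c>\d+):(?P<db>\d+)\s*$")


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid species with its class-level structural features."""

    id: str
    lipid_class: str
    n_fatty_acids: int
    total_carbons: int
    total_double_bonds: int
    molar_amount: float = float("nan")  # pmol

    def __post_init__(self):
        if self.n_fatty_acids < 1:
            raise DataError("a lipid needs at least one fatty acid")
        if self.total_carbons < 0 or self.total_double_bonds < 0:
            raise DataError("lipid features must be nonnegative")


def parse_lipid_id(identifier: str,
                   n_fatty_acids: int | None = None,
                   class_table: dict | None = None) -> LipidSpecies:
    """Parse 'CLASS carbons:double_bonds' shorthand (e.g. 'PC 34:2')."""
    m = _SHORTHAND.match(identifier)
    if not m:
        raise DataError(f"cannot parse lipid id {identifier!r}")
    cls = m.group("cls").upper()
    table = {**FATTY_ACIDS_PER_CLASS, **(class_table or {})}
    if n_fatty_acids is None:
        if cls not in table:
            raise DataError(
                f"unknown lipid class {cls!r}; pass n_fatty_acids")
        n_fatty_acids = table[cls]
    return LipidSpecies(identifier, cls, n_fatty_acids,
                        int(m.group("c")), int(m.group("db")))


def molar_fraction_normalize(amounts: pd.Series,
                             threshold: float = 1.0) -> pd.Series:
    """Convert pmol amounts to mol% per sample.

    Species with amounts <= ``threshold`` pmol are dropped before
    normalization; the retained values sum to 100.
    """
    amounts = amounts.astype(float)
    if (amounts.dropna() < 0).any():
        raise DataError("negative molar amounts")
    kept = amounts[amounts > threshold]
    if kept.empty:
        raise DataError(f"no lipid above the {threshold} pmol threshold")
    return kept / kept.sum() * 100.0


def knn_tn_impute(table: TotalOmicsTable, k: int = 1,
                  seed: int = 0) -> TotalAbundance:
    """Nearest-neighbor imputation in log space with truncation (KNN-TN).

    For each missing cell the k=1 nearest fully observed lipid (Euclidean
    distance over shared samples in log space) predicts the value via its
    own value shifted by the mean log offset between the two lipids;
    predictions are truncated below at the table's observed log minimum
    and back-transformed. Lipids with no complete neighbor fall back to
    their own observed minimum.
    """
    if k != 1:
        raise DataError("only k=1 is supported")
    log = np.log(table.data.where(table.data > 0))
    vals = log.to_numpy(dtype=float)
    complete = np.isfinite(vals).all(axis=1)
    if complete.sum() < 1 and np.isfinite(vals).sum() < 2:
        raise DataError("need at least two observed lipids to impute")
    global_min = np.nanmin(vals)
    filled = vals.copy()
    flags = ~np.isfinite(vals)
    ref = vals[complete]
    for i in np.where(~np.isfinite(vals).all(axis=1))[0]:
        row = vals[i]
        obs = np.isfinite(row)
        if not obs.any() or ref.shape[0] == 0:
            filled[i, ~obs] = np.nanmin(row) if obs.any() else global_min
            continue
        dist = np.sqrt(((ref[:, obs] - row[obs]) ** 2).mean(axis=1))
        j = int(np.argmin(dist))
        offset = (row[obs] - ref[j, obs]).mean()
        pred = ref[j, ~obs] + offset
        filled[i, ~obs] = np.maximum(pred, global_min)
    out = pd.DataFrame(np.exp(filled), index=table.data.index,
                       columns=table.data.columns)
    means, fl = {}, {}
    for g in table.conditions:
        cols = list(table.annotation.loc[
            table.annotation["condition"] == g, "sample"])
        means[g] = out[cols].mean(axis=1)
        fl[g] = pd.DataFrame(flags, index=table.data.index,
                             columns=table.data.columns)[cols]
    return TotalAbundance(means, fl)


def integrate_lipid_profiles(protein_ds: FractionationTable,
                             lipid_ds: FractionationTable
                             ) -> tuple[FractionationTable, pd.Series]:
    """Append lipid species to the protein fractionation table.

    Both tables must share the sample annotation; returns the combined
    table plus a species-kind series ('protein' / 'lipid') so markers
    (proteins only) train the network while lipids receive predictions.
    """
    pa = protein_ds.annotation.table.reset_index(drop=True)
    la = lipid_ds.annotation.table.reset_index(drop=True)
    if not pa.sort_values("sample").reset_index(drop=True).equals(
            la.sort_values("sample").reset_index(drop=True)):
        raise DataError("protein and lipid sample annotations differ")
    overlap = set(protein_ds.species_ids) & set(lipid_ds.species_ids)
    if overlap:
        raise DataError(f"species ids shared between tables: {sorted(overlap)}")
    combined = pd.concat(
        [protein_ds.data, lipid_ds.data[protein_ds.data.columns]])
    kinds = pd.Series("protein", index=protein_ds.data.index, dtype=object)
    kinds = pd.concat(
        [kinds, pd.Series("lipid", index=lipid_ds.data.index, dtype=object)])
    return FractionationTable(combined, protein_ds.annotation), kinds


def weighted_fatty_acid_feature(lipids, cc_values, amounts,
                                feature: str = "carbons") -> float:
    """CC- and amount-weighted mean feature value per fatty acid.

    ``lipids`` is a list of :class:`LipidSpecies` of one class,
    ``cc_values`` their class contributions on one compartment and
    ``amounts`` their total molar amounts. Weighting each species' total
    feature value (carbons or double bonds) by amount x CC and dividing by
    the class's number of fatty acids gives the per-fatty-acid mean:

        q_bar = sum_k(q_k * n_k * CC_k) / (f_L * sum_k(n_k * CC_k))
    """
    if feature not in ("carbons", "double_bonds"):
        raise DataError("feature must be 'carbons' or 'double_bonds'")
    if not lipids:
        raise DataError("no lipid species given")
    f_L = {lip.n_fatty_acids for lip in lipids}
    if len(f_L) != 1:
        raise DataError("lipids span several classes (n_fatty_acids differs)")
    f_L = f_L.pop()
    q = np.array([lip.total_carbons if feature == "carbons"
                  else lip.total_double_bonds for lip in lipids], dtype=float)
    w = np.asarray(amounts, dtype=float) * np.asarray(cc_values, dtype=float)
    denom = w.sum()
    if denom <= 0:
        return float("nan")
    return float((q * w).sum() / (f_L * denom))
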