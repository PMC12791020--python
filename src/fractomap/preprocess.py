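"""Filtering, imputation and normalization of fractionation and total-omics
tables into model-ready profiles.

Fractionation data differ from expression data: a missing fraction value
usually means the species is not in that compartment, not that it is lowly
expressed. Missing fractionation values are therefore replaced by zeros,
and each profile is rescaled to sum to one so that profiles of species with
different absolute abundance become comparable. Total-omics tables instead
receive the left-shifted-Gaussian imputation conventional for
intensity-based proteomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DataError, FractionationTable, TotalOmicsTable

PROFILE_SUM_TOL = 1e-9


@dataclass
class ProfileTensor:
    """Normalized profiles per (condition, replicate).

    ``profiles[(g, r)]`` is a species x fraction matrix whose rows each sum
    to 1; species absent from that replicate (no signal) are simply not
    rows of the matrix. ``present`` records per-condition presence after
    replicate filtering.
    """

    profiles: dict  # (condition, replicate) -> DataFrame (fractions 1..F)
    present: pd.DataFrame  # species x condition booleans

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(g for g, _ in self.profiles))

    def replicates(self, condition) -> list[int]:
        return sorted(r for g, r in self.profiles if g == condition)

    def n_fractions(self, condition) -> int:
        r = self.replicates(condition)[0]
        return self.profiles[(condition, r)].shape[1]


@dataclass
class TotalAbundance:
    """Per-condition mean total intensities with imputation flags."""

    means: dict  # condition -> Series (species -> mean intensity)
    imputed: dict = field(default_factory=dict)  # condition -> DataFrame bool


def filter_by_replicates(table, min_reps: int = 2):
    """Keep species identified in >= ``min_reps`` replicates per condition.

    A species counts as identified in a replicate if it has at least one
    non-missing intensity there. Species failing the rule in a condition
    are set fully missing for that condition but kept where they pass.
    Returns a table of the same type.
    """
    if isinstance(table, FractionationTable):
        ann = table.annotation
        data = table.data.copy()
        for g in ann.conditions:
            reps = ann.replicates(g)
            if min_reps > len(reps):
                raise DataError(
                    f"min_reps={min_reps} exceeds the {len(reps)} replicate(s) "
                    f"of condition {g!r}"
                )
            ident = pd.DataFrame(
                {r: table.replicate_matrix(g, r).notna().any(axis=1)
                 for r in reps}
            )
            fail = ident.sum(axis=1) < min_reps
            cols = [s for r in reps for s in ann.samples_for(g, r)]
            data.loc[fail, cols] = np.nan
        return FractionationTable(data, ann)
    if isinstance(table, TotalOmicsTable):
        data = table.data.copy()
        for g in table.conditions:
            mat = table.condition_matrix(g)
            if min_reps > mat.shape[1]:
                raise DataError(
                    f"min_reps={min_reps} exceeds the {mat.shape[1]} "
                    f"replicate(s) of condition {g!r}"
                )
            fail = mat.notna().sum(axis=1) < min_reps
            data.loc[fail, mat.columns] = np.nan
        return TotalOmicsTable(data, table.annotation)
    raise TypeError(f"unsupported table type: {type(table).__name__}")


def impute_fractionation(table: FractionationTable) -> FractionationTable:
    """Replace missing fractionation values with zeros.

    Species fully missing in a replicate stay recognizable downstream:
    their all-zero profiles are flagged absent by :func:`sum_normalize`.
    """
    return FractionationTable(table.data.fillna(0.0), table.annotation)


def sum_normalize(table: FractionationTable) -> ProfileTensor:
    """Rescale each per-replicate profile to sum to 1.

    All-zero profiles (species absent from a replicate) are dropped from
    that replicate's matrix rather than divided by zero.
    """
    ann = table.annotation
    profiles: dict = {}
    present = {}
    for g in ann.conditions:
        any_present = pd.Series(False, index=table.data.index)
        for r in ann.replicates(g):
            mat = table.replicate_matrix(g, r).fillna(0.0)
            sums = mat.sum(axis=1)
            mat = mat.loc[sums > 0]
            profiles[(g, r)] = mat.div(mat.sum(axis=1), axis=0)
            any_present |= sums > 0
        present[g] = any_present
    return ProfileTensor(profiles, pd.DataFrame(present))


def minmax_normalize(profile) -> np.ndarray:
    """Min-max rescale one profile into [0, 1] (visualization only)."""
    p = np.asarray(profile, dtype=float)
    lo, hi = p.min(), p.max()
    if hi == lo:
        raise DataError("min-max scaling undefined for a constant profile")
    return (p - lo) / (hi - lo)


def impute_total_omics(
    table: TotalOmicsTable,
    seed: int,
    shift: float = 1.8,
    width: float = 0.3,
    per_column: bool = False,
) -> TotalAbundance:
    """Impute missing total intensities from a left-shifted Gaussian.

    Statistics are computed on log2 intensities: with mu and sigma the mean
    and s.d. of the valid log2 values, missing cells are drawn from
    N(mu - shift*sigma, (width*sigma)^2) and back-transformed. By default
    mu/sigma are global over the table; ``per_column`` computes them per
    sample column instead. Per-condition means are taken after imputation.
    """
    rng = np.random.default_rng(seed)
    log = np.log2(table.data.where(table.data > 0))
    vals = log.to_numpy(dtype=float)
    miss = ~np.isfinite(vals)
    if (~miss).sum() < 2:
        raise DataError("need >= 2 valid intensities to impute (sigma undefined)")
    filled = vals.copy()
    if per_column:
        for j in range(vals.shape[1]):
            col = vals[:, j]
            ok = np.isfinite(col)
            if ok.sum() < 2:
                raise DataError("a column has < 2 valid values")
            mu, sd = col[ok].mean(), col[ok].std(ddof=1)
            n = int((~ok).sum())
            filled[~ok, j] = rng.normal(mu - shift * sd, width * sd, size=n)
    else:
        ok = np.isfinite(vals)
        mu, sd = vals[ok].mean(), vals[ok].std(ddof=1)
        filled[miss] = rng.normal(mu - shift * sd, width * sd,
                                  size=int(miss.sum()))
    imputed_tab = pd.DataFrame(2.0 ** filled, index=table.data.index,
                               columns=table.data.columns)
    means, flags = {}, {}
    for g in table.conditions:
        cols = table.annotation.loc[
            table.annotation["condition"] == g, "sample"
        ]
        means[g] = imputed_tab[list(cols)].mean(axis=1)
        flags[g] = pd.DataFrame(
            miss, index=table.data.index, columns=table.data.columns
        )[list(cols)]
    return TotalAbundance(means, flags)
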