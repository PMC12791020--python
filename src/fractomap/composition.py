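"""Class-centric composition: combining class contributions with total
abundances into compartment-resolved protein economies.

For species s, compartment c and condition g:

    SA = CC * I_mean      compartment-weighted species abundance
    CA = sum_s SA         compartment abundance
    NA = SA / CA          normalized abundance (sums to 1 over species)
    CFC = log2 NA(g2) - log2 NA(g1)   class-centric fold change

CA defaults to the sum over all species; ``ca_mode="markers"`` restricts
the sum to marker species (the marker-intensity variant of compartment
abundance). No pseudocounts: a zero CC means "not in this compartment",
so the corresponding CFC is reported as missing, not as a large fold
change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccfilter import CCMatrix
from .data_io import DataError, MarkerSet
from .preprocess import TotalAbundance


@dataclass
class CompositionResult:
    """SA/NA per species x compartment and CA per compartment, one condition."""

    condition: object
    SA: pd.DataFrame  # species x compartments, intensity units
    NA: pd.DataFrame  # species x compartments, columns sum to 1 where CA > 0
    CA: pd.Series     # compartment -> total abundance


def compute_composition(
    ccm: CCMatrix,
    totals: TotalAbundance,
    condition,
    ca_mode: str = "all",
    markers: MarkerSet | None = None,
) -> CompositionResult:
    """SA, CA and NA for one condition.

    Species present in both the CC matrix and the totals are used; the
    rest are dropped. Compartments with CA = 0 get NA = NaN.
    """
    if ca_mode not in ("all", "markers"):
        raise DataError("ca_mode must be 'all' or 'markers'")
    if ca_mode == "markers" and markers is None:
        raise DataError("ca_mode='markers' requires a marker set")
    cc = ccm.cc[condition]
    means = totals.means[condition].dropna()
    shared = [s for s in cc.index if s in means.index]
    cc = cc.loc[shared, ccm.compartment_order]
    SA = cc.mul(means.loc[shared], axis=0)
    if ca_mode == "markers":
        msk = [s for s in shared if s in markers.labels.index]
        CA = SA.loc[msk].sum(axis=0)
    else:
        CA = SA.sum(axis=0)
    NA = SA.div(CA.where(CA > 0), axis=1)
    return CompositionResult(condition, SA, NA, CA)


def cfc(result_g1: CompositionResult, result_g2: CompositionResult) -> pd.DataFrame:
    """Class-centric log2 fold change per (species, compartment).

    Defined only where NA > 0 on both sides; elsewhere NaN.
    """
    na1, na2 = result_g1.NA, result_g2.NA
    shared = [s for s in na1.index if s in na2.index]
    a = na1.loc[shared]
    b = na2.loc[shared]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(b.to_numpy()) - np.log2(a.to_numpy())
    out = pd.DataFrame(out, index=shared, columns=na1.columns)
    return out.where((a > 0) & (b > 0))
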