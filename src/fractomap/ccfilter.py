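"""False-positive filtering of ensemble outputs into class contributions.

Raw ensemble means assign small spurious weights to compartments a species
does not occupy. Marker proteins expose the size of this effect: for each
compartment c, the mean outputs observed on markers of *other*
compartments are "false positives" by construction, and their 95th
percentile defines a compartment-specific threshold tau_c. Mean weights
below tau_c are zeroed and the remaining entries renormalized, yielding
class-contribution (CC) values that sum to 1. Species zeroed everywhere in
every condition are reported as unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DataError, MarkerSet
from .nnmodel import EnsemblePrediction


@dataclass
class ThresholdVector:
    """Per-compartment false-positive thresholds, per condition."""

    tau: dict  # condition -> Series (compartment -> threshold in [0, 1])


@dataclass
class CCMatrix:
    """Filtered, renormalized class contributions per condition."""

    cc: dict  # condition -> DataFrame (species x compartments)
    compartment_order: list
    unassigned: list = field(default_factory=list)  # all-zero everywhere

    def conditions(self) -> list:
        return list(self.cc)


def compute_thresholds(
    pred: EnsemblePrediction,
    markers: MarkerSet,
    percentile: float = 95.0,
    scope: str = "condition",
    level: str = "replicate",
) -> ThresholdVector:
    """95th percentile of foreign-marker outputs, per compartment.

    ``level`` chooses which marker outputs enter the percentile
    collection: ``"replicate"`` (default) uses one ensemble-averaged
    output vector per (marker, replicate) — the network outputs at
    replicate granularity; ``"run"`` uses every raw per-run vector;
    ``"mean"`` uses the fully aggregated per-species means. The filter
    itself always compares the across-replicate mean against tau.

    ``scope="condition"`` computes thresholds per condition from that
    condition's outputs; ``"global"`` pools conditions.
    """
    order = pred.compartment_order
    labels = markers.labels
    if level == "mean":
        frames = {g: m.reset_index(names="species")
                  for g, m in pred.mean.items()}
    elif level == "replicate":
        rep = (pred.raw.groupby(["species", "condition", "replicate"],
                                sort=False)[list(order)]
               .mean().reset_index())
        frames = {g: grp for g, grp in rep.groupby("condition", sort=False)}
    elif level == "run":
        frames = {g: grp for g, grp in
                  pred.raw.groupby("condition", sort=False)}
    else:
        raise DataError("threshold level must be replicate, run or mean")

    def _tau_from(parts: list[pd.DataFrame]) -> pd.Series:
        tau = {}
        for c in order:
            vals = []
            for frame in parts:
                mk = frame[frame["species"].isin(labels.index)]
                foreign = mk["species"].map(labels) != c
                vals.append(mk.loc[foreign, c].to_numpy(dtype=float))
            vals = np.concatenate(vals) if vals else np.array([])
            if vals.size == 0:
                raise DataError(
                    f"no foreign markers to set a threshold for {c!r}"
                )
            tau[c] = float(np.percentile(vals, percentile))
        return pd.Series(tau)

    if scope == "global":
        shared = _tau_from(list(frames.values()))
        return ThresholdVector({g: shared.copy() for g in frames})
    if scope != "condition":
        raise DataError("threshold scope must be 'condition' or 'global'")
    return ThresholdVector({g: _tau_from([f]) for g, f in frames.items()})


def apply_filter(pred: EnsemblePrediction, thresholds: ThresholdVector) -> CCMatrix:
    """Zero mean weights below tau_c, renormalize survivors to sum 1.

    Rows zeroed in one condition stay all-zero there; species all-zero in
    *every* condition are listed as unassigned.
    """
    order = pred.compartment_order
    cc = {}
    for g, m in pred.mean.items():
        tau = thresholds.tau[g].reindex(order).to_numpy(dtype=float)
        W = m[list(order)].to_numpy(dtype=float)
        W = np.where(W >= tau, W, 0.0)
        sums = W.sum(axis=1, keepdims=True)
        W = np.divide(W, sums, out=np.zeros_like(W), where=sums > 0)
        cc[g] = pd.DataFrame(W, index=m.index, columns=order)
    all_species = sorted(set().union(*(set(f.index) for f in cc.values())))
    unassigned = []
    for s in all_species:
        if all(s not in f.index or f.loc[s].sum() == 0 for f in cc.values()):
            unassigned.append(s)
    return CCMatrix(cc=cc, compartment_order=list(order), unassigned=unassigned)


def call_localization(ccm: CCMatrix) -> dict:
    """Localization calls per condition.

    Returns condition -> DataFrame with columns: main (argmax CC, ties
    broken by compartment order with a flag), n_localizations, call in
    {single, multiple, unassigned}, tie flag.
    """
    out = {}
    order = ccm.compartment_order
    for g, frame in ccm.cc.items():
        W = frame[list(order)].to_numpy(dtype=float)
        nloc = (W > 0).sum(axis=1)
        main_idx = W.argmax(axis=1)  # first max wins: compartment order
        best = W.max(axis=1)
        tie = (W == best[:, None]).sum(axis=1) > 1
        calls = np.where(nloc == 0, "unassigned",
                         np.where(nloc == 1, "single", "multiple"))
        main = np.asarray(order, dtype=object)[main_idx]
        main[nloc == 0] = None
        out[g] = pd.DataFrame(
            {"main": main, "n_localizations": nloc, "call": calls, "tie": tie},
            index=frame.index,
        )
    return out


def cc_report(ccm: CCMatrix, calls: dict) -> pd.DataFrame:
    """One tidy frame: CC per compartment + call columns, per condition."""
    pieces = []
    for g, frame in ccm.cc.items():
        piece = frame.copy()
        piece.insert(0, "condition", g)
        piece = piece.join(calls[g])
        pieces.append(piece.reset_index(names="species"))
    return pd.concat(pieces, ignore_index=True)
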