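"""Reading and writing of fractionation pivot tables, sample annotations,
marker lists, total-omics tables and result reports.

All tabular IO goes through pandas. A fractionation experiment is a pivot
table (one row per species, one intensity column per sample) plus a sample
annotation that maps every sample column to a ``(condition, replicate,
fraction)`` triple. Marker lists supply the supervision signal: species with
an accepted single-compartment localization.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("sample", "condition", "replicate", "fraction")


class DataError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_table(path) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting tab/comma/semicolon."""
    return pd.read_csv(path, sep=_sniff_delimiter(path))


@dataclass
class SampleAnnotation:
    """Maps sample columns to (condition, replicate, fraction).

    Fractions within a (condition, replicate) must be a contiguous 1..F
    range and all replicates of a condition must share the same F.
    """

    table: pd.DataFrame  # columns: sample, condition, replicate, fraction

    def __post_init__(self) -> None:
        missing = set(ANNOTATION_COLUMNS) - set(self.table.columns)
        if missing:
            raise DataError(f"annotation lacks columns: {sorted(missing)}")
        t = self.table
        if t["sample"].duplicated().any():
            dup = t.loc[t["sample"].duplicated(), "sample"].tolist()
            raise DataError(f"duplicate sample ids in annotation: {dup}")
        t = t.astype({"replicate": int, "fraction": int})
        if (t["replicate"] < 1).any() or (t["fraction"] < 1).any():
            raise DataError("replicate and fraction indices must be >= 1")
        for (g, r), grp in t.groupby(["condition", "replicate"]):
            fr = sorted(grp["fraction"])
            if fr != list(range(1, len(fr) + 1)):
                raise DataError(
                    f"fractions of condition {g!r} replicate {r} are {fr}, "
                    f"not a contiguous 1..F range"
                )
        for g, grp in t.groupby("condition"):
            fs = grp.groupby("replicate")["fraction"].max().unique()
            if len(fs) > 1:
                raise DataError(
                    f"replicates of condition {g!r} disagree on the number "
                    f"of fractions: {sorted(fs)}"
                )
        self.table = t.reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def replicates(self, condition) -> list[int]:
        sub = self.table[self.table["condition"] == condition]
        return sorted(sub["replicate"].unique())

    def n_fractions(self, condition) -> int:
        sub = self.table[self.table["condition"] == condition]
        return int(sub["fraction"].max())

    def samples_for(self, condition, replicate) -> list[str]:
        """Sample ids of one replicate, ordered by fraction index."""
        sub = self.table[
            (self.table["condition"] == condition)
            & (self.table["replicate"] == replicate)
        ]
        return list(sub.sort_values("fraction")["sample"])


@dataclass
class FractionationTable:
    """Species x sample intensity matrix with its sample annotation.

    ``data`` columns are exactly the annotated samples (bijective to
    annotation rows); intensities are nonnegative or NaN (missing).
    """

    data: pd.DataFrame  # index: species ids; columns: sample ids
    annotation: SampleAnnotation

    def __post_init__(self) -> None:
        ann_samples = list(self.annotation.table["sample"])
        if set(self.data.columns) != set(ann_samples):
            raise DataError("data columns and annotation samples differ")
        self.data = self.data[ann_samples]
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise DataError(f"duplicate species ids: {dups}")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise DataError("negative intensities in fractionation table")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    def replicate_matrix(self, condition, replicate) -> pd.DataFrame:
        """Species x fraction matrix (columns 1..F) of one replicate."""
        samples = self.annotation.samples_for(condition, replicate)
        mat = self.data[samples].copy()
        mat.columns = range(1, len(samples) + 1)
        return mat


@dataclass
class MarkerSet:
    """Single-compartment labels: species id -> compartment."""

    labels: pd.Series  # index: species ids; values: compartment labels
    compartment_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.compartment_order:
            self.compartment_order = sorted(self.labels.unique())
        extra = set(self.labels.unique()) - set(self.compartment_order)
        if extra:
            raise DataError(f"labels missing from compartment_order: {extra}")
        if len(self.compartment_order) < 2:
            raise DataError("a marker set needs at least two compartments")

    @property
    def n_compartments(self) -> int:
        return len(self.compartment_order)

    def species_of(self, compartment) -> list[str]:
        return list(self.labels.index[self.labels == compartment])


@dataclass
class TotalOmicsTable:
    """Total proteome/lipidome intensities: species x (condition, replicate)."""

    data: pd.DataFrame  # index: species; columns: sample ids
    annotation: pd.DataFrame  # columns: sample, condition, replicate

    def __post_init__(self) -> None:
        need = {"sample", "condition", "replicate"}
        if not need <= set(self.annotation.columns):
            raise DataError("total-omics annotation needs sample/condition/replicate")
        self.annotation = self.annotation.astype({"replicate": int})
        if set(self.data.columns) != set(self.annotation["sample"]):
            raise DataError("total-omics columns and annotation samples differ")
        self.data = self.data[list(self.annotation["sample"])]
        for g, grp in self.annotation.groupby("condition"):
            if len(grp) < 1:
                raise DataError(f"condition {g!r} has no replicates")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.annotation["condition"]))

    def condition_matrix(self, condition) -> pd.DataFrame:
        samples = self.annotation.loc[
            self.annotation["condition"] == condition, "sample"
        ]
        return self.data[list(samples)]


def read_annotation(path) -> SampleAnnotation:
    return SampleAnnotation(read_table(path))


def read_fractionation(pivot_path, annotation_path) -> FractionationTable:
    """Load a pivot table and its sample annotation.

    The first pivot column is taken as the species id. Sample columns not
    present in the annotation are dropped with a warning; annotation rows
    without a matching pivot column are an error.
    """
    ann = read_annotation(annotation_path)
    pivot = read_table(pivot_path)
    pivot = pivot.set_index(pivot.columns[0])
    ann_samples = list(ann.table["sample"])
    missing = [s for s in ann_samples if s not in pivot.columns]
    if missing:
        raise DataError(f"annotated samples absent from pivot table: {missing}")
    unannotated = [c for c in pivot.columns if c not in ann_samples]
    if unannotated:
        logger.warning(
            "dropping %d unannotated sample column(s): %s",
            len(unannotated), unannotated,
        )
    return FractionationTable(pivot[ann_samples].astype(float), ann)


def read_markers(path, dataset: FractionationTable | None = None,
                 min_markers: int = 3) -> MarkerSet:
    """Load a two-column (species, compartment) marker list.

    When ``dataset`` is given, markers absent from it are silently dropped
    (count logged) and every compartment must keep at least ``min_markers``
    markers quantified in every (condition, replicate) — the profile
    upsampling draws three reference profiles per artificial profile.
    """
    tab = read_table(path)
    if tab.shape[1] < 2:
        raise DataError("marker list needs (species, compartment) columns")
    species, comp = tab.columns[:2]
    dup = tab[tab.duplicated(species, keep=False)]
    if not dup.empty and dup.groupby(species)[comp].nunique().max() > 1:
        bad = dup.groupby(species)[comp].nunique()
        raise DataError(
            f"conflicting labels for species: {list(bad[bad > 1].index)}"
        )
    tab = tab.drop_duplicates(species)
    labels = pd.Series(tab[comp].values, index=tab[species].values, dtype=object)
    order = list(dict.fromkeys(tab[comp]))
    if dataset is not None:
        keep = labels.index.isin(dataset.species_ids)
        if (~keep).any():
            logger.info("%d marker species absent from dataset; excluded",
                        int((~keep).sum()))
        labels = labels[keep]
        order = [c for c in order if c in set(labels.values)]
        for g in dataset.annotation.conditions:
            for r in dataset.annotation.replicates(g):
                mat = dataset.replicate_matrix(g, r)
                present = mat.notna().any(axis=1)
                for c in order:
                    n = int(present.reindex(labels.index[labels == c],
                                            fill_value=False).sum())
                    if n < min_markers:
                        raise DataError(
                            f"compartment {c!r} has only {n} marker(s) in "
                            f"condition {g!r} replicate {r}; "
                            f"need >= {min_markers}"
                        )
    return MarkerSet(labels, order)


def read_totals(path, annotation_path) -> TotalOmicsTable:
    ann = read_table(annotation_path)
    tab = read_table(path)
    tab = tab.set_index(tab.columns[0]).astype(float)
    keep = [s for s in ann["sample"] if s in tab.columns]
    ann = ann[ann["sample"].isin(keep)]
    return TotalOmicsTable(tab[keep], ann)


def write_report(frame: pd.DataFrame, path) -> None:
    """Write a result table as TSV: one row per species, empty fields for
    missing values, 6 significant digits."""
    frame.to_csv(path, sep="\t", index=True, float_format="%.6g", na_rep="")


def read_report(path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", index_col=0)
    return out
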