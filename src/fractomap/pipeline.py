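"""End-to-end orchestration: preprocess -> augment/train/predict ->
filter -> statistics -> (optional) composition, with TSV reports and JSON
run metadata written to a run directory."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ccfilter import (CCMatrix, apply_filter, call_localization, cc_report,
                       compute_thresholds)
from .composition import cfc, compute_composition
from .data_io import (DataError, FractionationTable, MarkerSet,
                      TotalOmicsTable, read_fractionation, read_markers,
                      read_totals, write_report)
from .nnmodel import EnsemblePrediction, predict_ensemble
from .preprocess import (ProfileTensor, filter_by_replicates,
                         impute_fractionation, impute_total_omics,
                         sum_normalize)
from .relocstats import compare_conditions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs; loadable from YAML."""

    pivot: str | None = None
    annotation: str | None = None
    markers: str | None = None
    totals: str | None = None
    totals_annotation: str | None = None
    outdir: str = "fractomap_run"
    seed: int = 0
    min_replicates: int = 2
    imputation_shift: float = 1.8
    imputation_width: float = 0.3
    rounds: int = 3
    runs: int = 10
    tune: bool = True
    max_epochs: int = 100
    tune_max_epochs: int = 20
    hyperband_reduction: int = 3
    patience: int = 5
    mix_ratios: tuple = (0.25, 0.5, 0.75)
    mix_fraction: float = 0.05
    upsample_noise_factor: float = 2.0
    fp_percentile: float = 95.0
    threshold_scope: str = "condition"
    threshold_level: str = "replicate"
    stat_samples: str = "runs"
    ds_mode: str = "max"
    ca_mode: str = "all"
    condition_pairs: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    profiles: ProfileTensor
    prediction: EnsemblePrediction
    cc: CCMatrix
    calls: dict
    relocalization: dict = field(default_factory=dict)  # (g1,g2) -> result
    composition: dict = field(default_factory=dict)     # condition -> result
    cfc: dict = field(default_factory=dict)             # (g1,g2) -> DataFrame


def analyze(
    fractionation: FractionationTable,
    markers: MarkerSet,
    config: RunConfig,
    totals: TotalOmicsTable | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory tables."""
    filtered = filter_by_replicates(fractionation, config.min_replicates)
    profiles = sum_normalize(impute_fractionation(filtered))
    logger.info("profiles: %d conditions, %s species per replicate",
                len(profiles.conditions),
                {k: v.shape[0] for k, v in profiles.profiles.items()})
    pred = predict_ensemble(
        profiles, markers, seed=config.seed,
        rounds=config.rounds, runs=config.runs, tune=config.tune,
        max_epochs=config.max_epochs, tune_max_epochs=config.tune_max_epochs,
        reduction_factor=config.hyperband_reduction, patience=config.patience,
        mix_ratios=tuple(config.mix_ratios), mix_fraction=config.mix_fraction,
        noise_factor=config.upsample_noise_factor,
    )
    tau = compute_thresholds(pred, markers, percentile=config.fp_percentile,
                             scope=config.threshold_scope,
                             level=config.threshold_level)
    ccm = apply_filter(pred, tau)
    calls = call_localization(ccm)
    result = PipelineResult(profiles, pred, ccm, calls)

    conditions = profiles.conditions
    pairs = [tuple(p) for p in config.condition_pairs] or [
        (a, b) for i, a in enumerate(conditions) for b in conditions[i + 1:]]
    for g1, g2 in pairs:
        if g1 in conditions and g2 in conditions:
            result.relocalization[(g1, g2)] = compare_conditions(
                ccm, pred, g1, g2, stat_samples=config.stat_samples,
                ds_mode=config.ds_mode)

    if totals is not None:
        tot = filter_by_replicates(totals, config.min_replicates)
        abundance = impute_total_omics(
            tot, seed=config.seed, shift=config.imputation_shift,
            width=config.imputation_width)
        for g in conditions:
            if g in abundance.means:
                result.composition[g] = compute_composition(
                    ccm, abundance, g, ca_mode=config.ca_mode,
                    markers=markers)
        for g1, g2 in pairs:
            if g1 in result.composition and g2 in result.composition:
                result.cfc[(g1, g2)] = cfc(result.composition[g1],
                                           result.composition[g2])
    return result


def write_results(result: PipelineResult, config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = cc_report(result.cc, result.calls).set_index("species")
    write_report(report, outdir / "class_contributions.tsv")
    for (g1, g2), rel in result.relocalization.items():
        write_report(rel.table.rename_axis("species"),
                     outdir / f"relocalization_{g1}_vs_{g2}.tsv")
    for g, comp in result.composition.items():
        frame = comp.SA.add_prefix("SA_").join(comp.NA.add_prefix("NA_"))
        write_report(frame.rename_axis("species"),
                     outdir / f"composition_{g}.tsv")
        comp.CA.rename_axis("compartment").to_frame("CA").to_csv(
            outdir / f"compartment_abundance_{g}.tsv", sep="\t")
    for (g1, g2), table in result.cfc.items():
        write_report(table.rename_axis("species"),
                     outdir / f"cfc_{g1}_vs_{g2}.tsv")
    meta = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_unassigned": len(result.cc.unassigned),
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return outdir


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based entry point: read inputs per the config, analyze, write
    all reports into the run directory."""
    for name in ("pivot", "annotation", "markers"):
        path = getattr(config, name)
        if path is None:
            raise DataError(f"config lacks required path: {name}")
        if not Path(path).exists():
            raise DataError(f"{name} file not found: {path}")
    frac = read_fractionation(config.pivot, config.annotation)
    markers = read_markers(config.markers, frac)
    totals = None
    if config.totals:
        tot_ann = config.totals_annotation or config.annotation
        totals = read_totals(config.totals, tot_ann)
    result = analyze(frac, markers, config, totals=totals)
    write_results(result, config)
    return result
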