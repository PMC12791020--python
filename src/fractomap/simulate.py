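"""Seeded simulator of density-gradient fractionation experiments.

The generator emulates gradient centrifugation followed by MS
quantification: each compartment occupies one of C equal windows of the
gradient, and every sedimentation peak is a Gaussian whose center is drawn
uniformly within the compartment's window and whose s.d. lies between 1.5
and 2 fractions. The draw happens per species and replicate, so a
compartment is a distribution of similar profiles rather than one
canonical profile — species near a window boundary genuinely resemble the
neighboring compartment. A protein's profile is a finite-sampling
histogram of its Gaussian (about 200 draws, +/-10%), binned into the F
fractions, scaled by a per-protein intensity factor between 5,000 and
8,000 with a per-fraction fluctuation of +/-50 units on the factor.
Multi-localized proteins are additive combinations of compartment draws at
fixed ratios, mixed before scaling so the ratios refer to underlying mass.

Species inventory per dataset: 75-125 annotated markers per compartment,
100-200 unannotated single-localized proteins, 150-250 double-localized
proteins per compartment (75:25 or 50:50, partner random) and 20-80
triple-localized proteins per compartment (50:25:25, partners random).
Realistic dropout: each (protein, replicate) is completely missing with
4% probability; with two conditions each protein is absent from one
condition with 2% probability and relocalizes (its localization is
redrawn for condition 2, profiles re-simulated) with 1% probability.

Everything derives from one root seed; ground-truth weight vectors and
relocalization flags are recorded for evaluation. A simple total-proteome
table (per-species log-normal intensity, log2 mean uniform in [18, 26],
replicate s.d. 0.3) accompanies the fractionation data for
composition-style analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (DataError, FractionationTable, MarkerSet,
                      SampleAnnotation, TotalOmicsTable)


@dataclass
class SimulationConfig:
    n_compartments: int = 8
    n_fractions: int = 16
    n_conditions: int = 1
    n_replicates: int = 3
    markers_per_compartment: tuple = (75, 125)
    unannotated_singles: tuple = (100, 200)
    doubles_per_compartment: tuple = (150, 250)
    triples_per_compartment: tuple = (20, 80)
    double_ratios: tuple = ((0.75, 0.25), (0.5, 0.5))
    triple_ratio: tuple = (0.5, 0.25, 0.25)
    peak_sigma: tuple = (1.5, 2.0)
    points: int = 200
    points_deviation: float = 0.10
    scale: tuple = (5000.0, 8000.0)
    fraction_jitter: float = 50.0
    p_missing_replicate: float = 0.04
    p_missing_condition: float = 0.02
    p_relocalization: float = 0.01
    total_log2_mean: tuple = (18.0, 26.0)
    total_log2_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_fractions < self.n_compartments:
            raise DataError("need at least as many fractions as compartments")
        if self.n_conditions not in (1, 2):
            raise DataError("simulator supports 1 or 2 conditions")


@dataclass
class SimulatedDataset:
    """Generated tables plus ground truth."""

    fractionation: FractionationTable
    markers: MarkerSet
    totals: TotalOmicsTable
    truth: pd.DataFrame       # species x (condition, kind, reloc, weights...)
    compartment_order: list = field(default_factory=list)

    def truth_weights(self, condition) -> pd.DataFrame:
        """Species x compartment ground-truth weight matrix (rows sum 1)."""
        sub = self.truth[self.truth["condition"] == condition]
        return sub.set_index("species")[self.compartment_order]

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fractionation.data.rename_axis("species").to_csv(
            outdir / "fractionation.tsv", sep="\t")
        self.fractionation.annotation.table.to_csv(
            outdir / "annotation.tsv", sep="\t", index=False)
        pd.DataFrame({"species": self.markers.labels.index,
                      "compartment": self.markers.labels.values}).to_csv(
            outdir / "markers.tsv", sep="\t", index=False)
        self.totals.data.rename_axis("species").to_csv(
            outdir / "total_proteome.tsv", sep="\t")
        self.totals.annotation.to_csv(
            outdir / "total_annotation.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def compartment_windows(C: int, F: int) -> np.ndarray:
    """(C, 2) array of [start, end) peak-center windows on the [0, F] axis."""
    edges = np.linspace(0.0, float(F), C + 1)
    return np.column_stack([edges[:-1], edges[1:]])


def _compartment_counts(compartment: int, C: int, F: int, n_points: int,
                        rng: np.random.Generator,
                        sigma_range=(1.5, 2.0)) -> np.ndarray:
    """Bin ``n_points`` draws of one compartment peak into F fraction bins.

    The peak center is drawn uniformly within the compartment's window of
    the [0, F] gradient axis and the peak s.d. uniformly from
    ``sigma_range`` — per call, so every species (and replicate) realizes
    its own peak within the compartment's range, reflecting that a
    compartment spans a distribution of similar profiles rather than one
    canonical profile. Draws outside [0, F] are discarded (material lost
    off the gradient ends), so counts sum to at most ``n_points``.
    """
    lo, hi = compartment_windows(C, F)[compartment]
    mu = rng.uniform(lo, hi)
    sigma = rng.uniform(*sigma_range)
    draws = rng.normal(mu, sigma, size=n_points)
    counts, _ = np.histogram(draws, bins=F, range=(0.0, float(F)))
    return counts.astype(float)


def _draw_points(cfg: SimulationConfig, rng) -> int:
    lo = cfg.points * (1 - cfg.points_deviation)
    hi = cfg.points * (1 + cfg.points_deviation)
    return int(round(rng.uniform(lo, hi)))


def simulate_compartment_profile(compartment: int, F: int,
                                 rng: np.random.Generator,
                                 C: int | None = None,
                                 cfg: SimulationConfig | None = None
                                 ) -> np.ndarray:
    """One raw single-compartment intensity profile (F-vector).

    Peak center, peak width and point count are drawn fresh from the
    configured ranges; the binned counts are scaled by a per-species
    factor with per-fraction jitter on the factor.
    """
    cfg = cfg or SimulationConfig(n_compartments=C or 8, n_fractions=F)
    C = C or cfg.n_compartments
    counts = _compartment_counts(compartment, C, F, _draw_points(cfg, rng),
                                 rng, cfg.peak_sigma)
    factor = rng.uniform(*cfg.scale)
    jitter = rng.uniform(-cfg.fraction_jitter, cfg.fraction_jitter, size=F)
    return counts * (factor + jitter)


def _species_profile(weights: np.ndarray, cfg: SimulationConfig,
                     rng) -> np.ndarray:
    """One raw intensity profile: ratio-weighted compartment histograms
    combined before scaling, then intensity-scaled with jitter."""
    C, F = cfg.n_compartments, cfg.n_fractions
    n_pts = _draw_points(cfg, rng)
    counts = np.zeros(F)
    for c in np.nonzero(weights)[0]:
        n_c = int(round(weights[c] * n_pts))
        counts += _compartment_counts(c, C, F, n_c, rng, cfg.peak_sigma)
    factor = rng.uniform(*cfg.scale)
    jitter = rng.uniform(-cfg.fraction_jitter, cfg.fraction_jitter, size=F)
    return counts * (factor + jitter)


def _assign(kind: str, C: int, rng, cfg: SimulationConfig,
            fixed: int | None = None) -> np.ndarray:
    """Draw a ground-truth weight vector for a species of the given kind."""
    w = np.zeros(C)
    if kind in ("marker", "single"):
        c = fixed if fixed is not None else int(rng.integers(C))
        w[c] = 1.0
    elif kind == "double":
        c1 = fixed if fixed is not None else int(rng.integers(C))
        others = [k for k in range(C) if k != c1]
        c2 = int(rng.choice(others))
        ratio = cfg.double_ratios[int(rng.integers(len(cfg.double_ratios)))]
        w[c1], w[c2] = ratio
    elif kind == "triple":
        c1 = fixed if fixed is not None else int(rng.integers(C))
        others = [k for k in range(C) if k != c1]
        c2, c3 = rng.choice(others, size=2, replace=False)
        w[c1], w[int(c2)], w[int(c3)] = cfg.triple_ratio
    else:
        raise DataError(f"unknown species kind {kind!r}")
    return w


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one complete dataset with ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    C, F, R = cfg.n_compartments, cfg.n_fractions, cfg.n_replicates
    conditions = [f"Cond{g+1}" for g in range(cfg.n_conditions)]
    comp_names = [f"C{c+1:02d}" for c in range(C)]

    # species inventory with condition-1 assignments
    records = []  # (species_id, kind, weights)
    for c in range(C):
        n = int(rng.integers(*cfg.markers_per_compartment, endpoint=True))
        for i in range(n):
            records.append((f"M_{comp_names[c]}_{i:04d}", "marker",
                            _assign("marker", C, rng, cfg, fixed=c)))
    n_single = int(rng.integers(*cfg.unannotated_singles, endpoint=True))
    for i in range(n_single):
        records.append((f"S_{i:04d}", "single", _assign("single", C, rng, cfg)))
    for c in range(C):
        n = int(rng.integers(*cfg.doubles_per_compartment, endpoint=True))
        for i in range(n):
            records.append((f"D_{comp_names[c]}_{i:04d}", "double",
                            _assign("double", C, rng, cfg, fixed=c)))
    for c in range(C):
        n = int(rng.integers(*cfg.triples_per_compartment, endpoint=True))
        for i in range(n):
            records.append((f"T_{comp_names[c]}_{i:04d}", "triple",
                            _assign("triple", C, rng, cfg, fixed=c)))
    species = [r[0] for r in records]
    kinds = {r[0]: r[1] for r in records}
    weights = {(r[0], conditions[0]): r[2] for r in records}

    # condition-2 assignments: identical unless relocalized
    reloc: dict = {s: False for s in species}
    if cfg.n_conditions == 2:
        for sid, kind, w in records:
            if rng.random() < cfg.p_relocalization:
                new_w = _assign(kind if kind != "marker" else "single",
                                C, rng, cfg)
                # redraw until the localization actually changes
                while np.allclose(new_w, w):
                    new_w = _assign(kind if kind != "marker" else "single",
                                    C, rng, cfg)
                weights[(sid, conditions[1])] = new_w
                reloc[sid] = True
            else:
                weights[(sid, conditions[1])] = w.copy()

    # condition dropout
    present_in: dict = {s: set(conditions) for s in species}
    if cfg.n_conditions == 2:
        for s in species:
            if rng.random() < cfg.p_missing_condition:
                drop = conditions[int(rng.integers(2))]
                present_in[s].discard(drop)

    # intensity matrix
    ann_rows, columns = [], {}
    for g in conditions:
        for r in range(1, R + 1):
            for f in range(1, F + 1):
                sid = f"{g}_R{r}_F{f:02d}"
                ann_rows.append((sid, g, r, f))
    sample_ids = [a[0] for a in ann_rows]
    data = np.full((len(species), len(sample_ids)), np.nan)
    col_of = {sid: j for j, (sid, *_rest) in enumerate(ann_rows)}
    for i, s in enumerate(species):
        for g in conditions:
            if g not in present_in[s]:
                continue
            w = weights[(s, g)]
            for r in range(1, R + 1):
                if rng.random() < cfg.p_missing_replicate:
                    continue
                prof = _species_profile(w, cfg, rng)
                for f in range(1, F + 1):
                    data[i, col_of[f"{g}_R{r}_F{f:02d}"]] = prof[f - 1]

    annotation = SampleAnnotation(pd.DataFrame(
        ann_rows, columns=["sample", "condition", "replicate", "fraction"]))
    frac = FractionationTable(
        pd.DataFrame(data, index=species, columns=sample_ids), annotation)

    # marker list (annotated markers only)
    marker_ids = [s for s in species if kinds[s] == "marker"]
    labels = pd.Series(
        {s: comp_names[int(np.argmax(weights[(s, conditions[0])]))]
         for s in marker_ids}, dtype=object)
    markers = MarkerSet(labels, comp_names)

    # total proteome: log-normal per species, shared across conditions
    tot_rows, tot_cols = [], []
    for g in conditions:
        for r in range(1, R + 1):
            tot_cols.append((f"{g}_TR{r}", g, r))
    log2_mean = rng.uniform(*cfg.total_log2_mean, size=len(species))
    tot = np.full((len(species), len(tot_cols)), np.nan)
    for j, (sid, g, r) in enumerate(tot_cols):
        vals = 2.0 ** rng.normal(log2_mean, cfg.total_log2_sd)
        gone = np.array([g not in present_in[s] for s in species])
        vals[gone] = np.nan
        tot[:, j] = vals
    totals = TotalOmicsTable(
        pd.DataFrame(tot, index=species, columns=[c[0] for c in tot_cols]),
        pd.DataFrame([(c[0], c[1], c[2]) for c in tot_cols],
                     columns=["sample", "condition", "replicate"]))

    truth_rows = []
    for s in species:
        for g in conditions:
            if g not in present_in[s]:
                continue
            w = weights[(s, g)]
            truth_rows.append(
                {"species": s, "condition": g, "kind": kinds[s],
                 "relocalized": reloc[s],
                 **{comp_names[c]: w[c] for c in range(C)}})
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(frac, markers, totals, truth, comp_names)
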