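"""Pairwise condition comparison: relocalization vectors and scores,
Welch tests and Cohen's d on the unfiltered ensemble outputs, and a
distance score ranking relocalization candidates.

For a species assigned in both conditions, RL_c = CC_c(g2) - CC_c(g1) per
compartment (summing to zero), and the relocalization score
RLS = sum_c |RL_c| ranges from 0 (static) to 2 (completely disjoint
localization). Statistical evidence comes from the spread of the raw
ensemble outputs: Welch's unequal-variance t-test and Cohen's d per
compartment, with the distance score DS = max_c |d_c| (configurable to the
sum) ranking effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ccfilter import CCMatrix
from .data_io import DataError
from .nnmodel import EnsemblePrediction


def relocalization_vector(cc1, cc2) -> np.ndarray:
    """Element-wise CC difference (condition 2 minus condition 1)."""
    cc1 = np.asarray(cc1, dtype=float)
    cc2 = np.asarray(cc2, dtype=float)
    if cc1.sum() == 0 or cc2.sum() == 0:
        raise DataError("species unassigned in one condition; no RL defined")
    return cc2 - cc1


def rls(rl) -> float:
    """Relocalization score: sum of absolute RL values, in [0, 2]."""
    return float(np.abs(np.asarray(rl, dtype=float)).sum())


def welch_test(samples1, samples2) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns (t, df, p) with t = (mean2 - mean1) / sqrt(s1^2/n1 + s2^2/n2),
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    Zero variance in both groups: p = 1 if the means agree else p = 0.
    """
    a = np.asarray(samples1, dtype=float)
    b = np.asarray(samples2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("welch_test needs >= 2 values per group")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se1, se2 = v1 / a.size, v2 / b.size
    diff = b.mean() - a.mean()
    if se1 + se2 == 0:
        return (0.0, float(a.size + b.size - 2), 1.0) if diff == 0 \
            else (np.inf if diff > 0 else -np.inf, float(a.size + b.size - 2), 0.0)
    t = diff / np.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (
        se1 ** 2 / (a.size - 1) + se2 ** 2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def cohens_d(samples1, samples2) -> float:
    """Cohen's d with the unweighted pooled s.d. sqrt((s1^2 + s2^2)/2)."""
    a = np.asarray(samples1, dtype=float)
    b = np.asarray(samples2, dtype=float)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt((v1 + v2) / 2.0)
    if pooled == 0:
        return float("nan")
    return float((b.mean() - a.mean()) / pooled)


def distance_score(d_vector, mode: str = "max") -> float:
    """Aggregate per-compartment effect sizes into one ranking score."""
    d = np.asarray(d_vector, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return float("nan")
    if mode == "max":
        return float(np.abs(d).max())
    if mode == "sum":
        return float(np.abs(d).sum())
    raise DataError("distance score mode must be 'max' or 'sum'")


@dataclass
class RelocalizationResult:
    """Per-species relocalization table for one condition pair."""

    condition_pair: tuple
    table: pd.DataFrame  # index species; RL_*, RLS, p_*, d_*, DS, flags
    excluded: list       # species unassigned in either condition


def compare_conditions(
    ccm: CCMatrix,
    pred: EnsemblePrediction,
    g1,
    g2,
    stat_samples: str = "runs",
    ds_mode: str = "max",
) -> RelocalizationResult:
    """RL/RLS plus Welch p, Cohen's d and DS for every species assigned in
    both conditions.

    ``stat_samples="runs"`` pools the raw per-(replicate, round, run)
    outputs of a condition (R x rounds x runs values per compartment);
    ``"replicates"`` first averages within replicate, testing R values.
    A Benjamini-Hochberg adjusted column is added per compartment.
    """
    order = ccm.compartment_order
    cc1, cc2 = ccm.cc[g1], ccm.cc[g2]
    shared = [s for s in cc1.index if s in cc2.index]
    assigned = [s for s in shared
                if cc1.loc[s].sum() > 0 and cc2.loc[s].sum() > 0]
    excluded = [s for s in shared if s not in set(assigned)]

    raw = pred.raw
    if stat_samples == "replicates":
        raw = (raw.groupby(["species", "condition", "replicate"],
                           sort=False)[list(order)]
               .mean().reset_index())
    elif stat_samples != "runs":
        raise DataError("stat_samples must be 'runs' or 'replicates'")
    grp1 = {s: f for s, f in
            raw[raw["condition"] == g1].groupby("species")[list(order)]}
    grp2 = {s: f for s, f in
            raw[raw["condition"] == g2].groupby("species")[list(order)]}

    rows = {}
    for s in assigned:
        rl = relocalization_vector(cc1.loc[s, order], cc2.loc[s, order])
        row = {f"RL_{c}": rl[i] for i, c in enumerate(order)}
        row["RLS"] = rls(rl)
        ds = []
        for c in order:
            a = grp1[s][c].to_numpy(dtype=float)
            b = grp2[s][c].to_numpy(dtype=float)
            t, df, p = welch_test(a, b)
            d = cohens_d(a, b)
            row[f"t_{c}"], row[f"p_{c}"], row[f"d_{c}"] = t, p, d
            ds.append(d)
        row["DS"] = distance_score(ds, mode=ds_mode)
        rows[s] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    if not table.empty:
        for c in order:
            p = table[f"p_{c}"].to_numpy(dtype=float)
            ok = np.isfinite(p)
            adj = np.full_like(p, np.nan)
            if ok.any():
                adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            table[f"p_bh_{c}"] = adj
    return RelocalizationResult((g1, g2), table, excluded)
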