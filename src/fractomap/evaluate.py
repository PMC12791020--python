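"""Scoring predictions against ground truth.

Classification quality (precision / recall / F1 per compartment plus a
marker-count-weighted F1) scores the argmax compartment call. The
localization error LE = sum_c |true_c - pred_c| / 2 measures how far a
predicted distribution is from the truth (0 = identical, 1 = disjoint);
the halving avoids double-counting, since overestimating one compartment
necessarily underestimates another. Relocalization is scored through
transport matrices: each species' localization change is decomposed into
origin -> target flows by a conservation-preserving earth mover's plan
(0/1 ground cost by default), and the relocalization-error matrix RLE is
the element-wise mean absolute difference between true and predicted
plans over species present in both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .ccfilter import CCMatrix
from .data_io import DataError

MARGINAL_TOL = 1e-9


@dataclass
class ClassificationReport:
    per_class: pd.DataFrame   # compartment x (precision, recall, f1, n)
    weighted_f1: float


def classification_metrics(true_labels, predicted_main,
                           compartment_order) -> ClassificationReport:
    """Per-compartment precision/recall/F1 and marker-weighted F1.

    Classes absent from the truth are excluded from the weighted average.
    """
    y_true = np.asarray(true_labels, dtype=object)
    y_pred = np.asarray(predicted_main, dtype=object)
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=list(compartment_order), zero_division=0.0)
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "n": supp},
        index=list(compartment_order))
    present = per_class["n"] > 0
    weighted = float(
        (per_class.loc[present, "f1"] * per_class.loc[present, "n"]).sum()
        / per_class.loc[present, "n"].sum())
    return ClassificationReport(per_class, weighted)


def localization_error(true_w, predicted_cc) -> float:
    """LE = sum of absolute compartment differences, divided by two."""
    t = np.asarray(true_w, dtype=float)
    p = np.asarray(predicted_cc, dtype=float)
    return float(np.abs(t - p).sum() / 2.0)


def transport_matrix(P, Q, cost: np.ndarray | None = None) -> np.ndarray:
    """Minimal-cost transport plan redistributing P into Q.

    Ground cost defaults to 0/1 (0 on the diagonal, 1 elsewhere), under
    which mass stays in place wherever possible: the plan keeps
    min(P_i, Q_i) on the diagonal and distributes the residual mass
    proportionally (outer product of residual marginals over the total
    residual), a deterministic optimal plan. A custom cost matrix falls
    back to a linear program.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if abs(P.sum() - Q.sum()) > MARGINAL_TOL:
        raise DataError("transport requires equal total mass in P and Q")
    n = P.size
    if cost is None:
        m = np.minimum(P, Q)
        rp, rq = P - m, Q - m
        T = rp.sum()
        F = np.diag(m)
        if T > MARGINAL_TOL:
            F += np.outer(rp, rq) / T
        return F
    from scipy.optimize import linprog
    cost = np.asarray(cost, dtype=float)
    A_eq = np.zeros((2 * n, n * n))
    for i in range(n):
        A_eq[i, i * n:(i + 1) * n] = 1.0          # row sums = P
        A_eq[n + i, i::n] = 1.0                    # column sums = Q
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=np.concatenate([P, Q]),
                  bounds=(0, None), method="highs")
    if not res.success:
        raise DataError(f"transport LP failed: {res.message}")
    return res.x.reshape(n, n)


def relocalization_error_matrix(truth_pairs, predicted_pairs) -> np.ndarray:
    """Mean element-wise |true plan - predicted plan| over species.

    Both arguments are sequences of (P, Q) distribution pairs, aligned by
    species (one entry per species present in both conditions).
    """
    if len(truth_pairs) != len(predicted_pairs):
        raise DataError("truth and prediction pair lists differ in length")
    if not truth_pairs:
        raise DataError("no species to evaluate")
    acc = None
    for (tp, tq), (pp, pq) in zip(truth_pairs, predicted_pairs):
        diff = np.abs(transport_matrix(tp, tq) - transport_matrix(pp, pq))
        acc = diff if acc is None else acc + diff
    return acc / len(truth_pairs)


def unassigned_fraction(ccm: CCMatrix) -> float:
    """Share of species whose CC vector is all-zero in every condition."""
    n_total = len(set().union(*(set(f.index) for f in ccm.cc.values())))
    if n_total == 0:
        return 0.0
    return len(ccm.unassigned) / n_total
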