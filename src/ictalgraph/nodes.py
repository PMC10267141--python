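"""ROC analysis of normalized nodal strength as an epileptogenicity marker.

Electrodes of good-outcome patients are pooled; a contact is predicted
epileptogenic when its normalized strength is >= a grid threshold (0 to 1,
step 0.1), and the resected/non-resected flag is the ground truth.  AUC is
trapezoidal over the grid's (1-specificity, sensitivity) points with the
(0,0)/(1,1) endpoints appended; the operating threshold maximizes the
Youden index J = sensitivity + specificity - 1 (ties -> lowest threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .config import AnalysisConfig
from .pipeline import cohort_strengths

__all__ = ["RocResult", "label_nodes", "roc_curve", "classify_nodes"]


@dataclass
class RocResult:
    measure: str
    band: str
    state: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    counts: np.ndarray  # per-threshold rows (TP, FP, FN, TN)
    auc: float
    youden_j_max: float
    optimal_threshold: float

    @property
    def youden_j(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def label_nodes(data, outcome: str = "good") -> pd.DataFrame:
    """Pooled electrode-level (strength, resected) pairs of one outcome group,
    for every measure/band/state present in the strengths table."""
    table = cohort_strengths(data) if isinstance(data, Cohort) else data
    pool = table[table["outcome"] == outcome]
    if pool.empty:
        raise ValueError(f"no {outcome}-outcome patients to pool")
    if not pool["resected"].any():
        raise ValueError("pooled electrodes contain no resected contacts")
    return pool[
        ["patient_id", "channel_id", "measure", "band", "state", "strength", "resected"]
    ].reset_index(drop=True)


def roc_curve(
    strengths,
    labels,
    thresholds=None,
    measure: str = "",
    band: str = "",
    state: str = "",
) -> RocResult:
    """ROC over the epileptogenicity-threshold grid.

    ``labels`` are booleans (True = resected = epileptogenic ground truth);
    prediction at threshold t is ``strength >= t``.
    """
    s = np.asarray(strengths, float)
    y = np.asarray(labels, bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("strengths and labels must be matching 1-D arrays")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    if thresholds is None:
        thresholds = AnalysisConfig().node_threshold_grid
    thresholds = np.asarray(thresholds, float)
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    counts = np.empty((thresholds.size, 4), int)
    for k, t in enumerate(thresholds):
        pred = s >= t
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = n_pos - tp
        tn = n_neg - fp
        counts[k] = (tp, fp, fn, tn)
        sens[k] = tp / n_pos
        spec[k] = tn / n_neg
    fpr = np.concatenate([[0.0], 1.0 - spec[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (lowest) threshold on ties
    return RocResult(
        measure=measure,
        band=band,
        state=state,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        counts=counts,
        auc=auc,
        youden_j_max=float(j[best]),
        optimal_threshold=float(thresholds[best]),
    )


def classify_nodes(
    data, thresholds=None, outcome: str = "good", require=None
) -> dict[tuple[str, str, str], RocResult]:
    """RocResults for every (measure, band, state) combination in the pooled
    good-outcome electrode table, keyed by that triple.

    ``require`` is an optional iterable of (measure, band, state) triples that
    must all be present; missing combinations raise a descriptive error.
    """
    pool = label_nodes(data, outcome=outcome)
    if require is not None:
        present = set(map(tuple, pool[["measure", "band", "state"]].drop_duplicates().to_numpy()))
        missing = sorted(set(map(tuple, require)) - present)
        if missing:
            raise ValueError(f"missing measure/band/state combinations: {missing}")
    out: dict[tuple[str, str, str], RocResult] = {}
    for (measure, band, state), grp in pool.groupby(["measure", "band", "state"]):
        out[(measure, band, state)] = roc_curve(
            grp["strength"].to_numpy(),
            grp["resected"].to_numpy(),
            thresholds,
            measure=measure,
            band=band,
            state=state,
        )
    return out
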