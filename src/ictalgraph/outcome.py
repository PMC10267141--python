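"""Patient-level surgical-outcome prediction from resection of hubs.

A contact is a hub when its normalized nodal strength exceeds the
connectivity threshold (from the ROC maximum-Youden operating point).  Per
patient, the overlap is 100 x |hubs inside resection| / |resected contacts|;
the resection counts as "achieved" when the overlap is strictly above an
overlap threshold swept over 0..100% in 5% steps.  At each grid point the
patient-level 2x2 table (resected/missed x good/poor outcome) gives a
two-sided Fisher exact p, PPV, NPV and accuracy; the reported operating
point maximizes the Youden index (ties -> lowest threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .config import AnalysisConfig
from .pipeline import cohort_strengths
from .stats import TestResult, fisher_exact, wilcoxon_rank_sum

__all__ = [
    "HubSet",
    "PredictionResult",
    "hub_overlap",
    "patient_overlaps",
    "predict_outcomes",
    "predict_by_onset_type",
    "compare_overlap_by_outcome",
]


@dataclass(frozen=True)
class HubSet:
    patient_id: str
    measure: str
    band: str
    state: str
    fc_threshold: float
    channel_ids: tuple[str, ...]


@dataclass
class PredictionResult:
    measure: str
    band: str
    state: str
    fc_threshold: float
    overlap_threshold_percent: float
    contingency: np.ndarray  # [[TP, FP], [FN, TN]] at patient level
    fisher_p: float
    ppv: float
    npv: float
    accuracy: float
    youden_j: float
    per_threshold: pd.DataFrame = field(repr=False, default=None)


def hub_overlap(hub_ids, resected_ids) -> float:
    """Percent of resected contacts that are hubs inside the resection."""
    resected = set(resected_ids)
    if not resected:
        raise ValueError("patient has no resected contacts")
    return 100.0 * len(set(hub_ids) & resected) / len(resected)


def _strength_table(data) -> pd.DataFrame:
    return cohort_strengths(data) if isinstance(data, Cohort) else data


def patient_overlaps(
    data, measure: str, band: str, state: str, fc_threshold: float, target: str = "resection"
) -> pd.DataFrame:
    """Per-patient hub sets and their percent overlap with the resection
    (or, with ``target='soz'``, the seizure onset zone)."""
    flag = {"resection": "resected", "soz": "in_soz"}[target]
    table = _strength_table(data)
    sub = table[
        (table["measure"] == measure)
        & (table["band"] == band)
        & (table["state"] == state)
    ]
    rows = []
    for pid, grp in sub.groupby("patient_id"):
        hubs = grp.loc[grp["strength"] > fc_threshold, "channel_id"]
        target_ids = grp.loc[grp[flag], "channel_id"]
        if target_ids.empty:
            warnings.warn(f"{pid}: no {flag} contacts; patient excluded")
            continue
        rows.append(
            {
                "patient_id": pid,
                "outcome": grp["outcome"].iloc[0],
                "onset_type": grp["onset_type"].iloc[0],
                "n_hubs": len(hubs),
                "overlap_percent": hub_overlap(hubs, target_ids),
            }
        )
    return pd.DataFrame(rows)


def _prediction_stats(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float, float]:
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    acc = (tp + tn) / (tp + fp + fn + tn)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return ppv, npv, acc, sens + spec - 1.0


def predict_outcomes(
    data,
    measure: str,
    band: str,
    state: str,
    fc_threshold: float,
    overlap_grid=None,
) -> PredictionResult:
    """Sweep the overlap grid and report the maximum-Youden operating point.

    TP = good outcome with the hub zone resected, FP = poor outcome with it
    resected, FN = good outcome with it missed, TN = poor outcome with it
    missed ("resected" = overlap strictly above the threshold).
    """
    if overlap_grid is None:
        overlap_grid = AnalysisConfig().overlap_grid_percent
    ov = patient_overlaps(data, measure, band, state, fc_threshold)
    if ov.empty or ov["outcome"].nunique() < 2:
        raise ValueError("outcome prediction needs evaluable patients of both outcomes")
    good = (ov["outcome"] == "good").to_numpy()
    rows = []
    for t in np.asarray(overlap_grid, float):
        resected_zone = ov["overlap_percent"].to_numpy() > t
        tp = int(np.sum(resected_zone & good))
        fp = int(np.sum(resected_zone & ~good))
        fn = int(np.sum(~resected_zone & good))
        tn = int(np.sum(~resected_zone & ~good))
        ppv, npv, acc, j = _prediction_stats(tp, fp, fn, tn)
        p = fisher_exact([[tp, fp], [fn, tn]]).pvalue
        rows.append(
            dict(overlap_threshold_percent=float(t), tp=tp, fp=fp, fn=fn, tn=tn,
                 fisher_p=p, ppv=ppv, npv=npv, accuracy=acc, youden_j=j)
        )
    grid = pd.DataFrame(rows)
    best = grid.iloc[int(np.argmax(grid["youden_j"].to_numpy()))]
    return PredictionResult(
        measure=measure,
        band=band,
        state=state,
        fc_threshold=float(fc_threshold),
        overlap_threshold_percent=float(best["overlap_threshold_percent"]),
        contingency=np.array(
            [[best["tp"], best["fp"]], [best["fn"], best["tn"]]], dtype=int
        ),
        fisher_p=float(best["fisher_p"]),
        ppv=float(best["ppv"]),
        npv=float(best["npv"]),
        accuracy=float(best["accuracy"]),
        youden_j=float(best["youden_j"]),
        per_threshold=grid,
    )


def predict_by_onset_type(
    data, measure: str, band: str, fc_threshold: float, state: str = "ictal",
    overlap_grid=None,
) -> dict[str, PredictionResult]:
    """Outcome prediction run separately on the SSO and FSO patient subsets
    (ictal state); a subset with a single outcome class is skipped with a
    warning."""
    table = _strength_table(data)
    out: dict[str, PredictionResult] = {}
    for onset in ("SSO", "FSO"):
        sub = table[table["onset_type"] == onset]
        if sub.empty:
            continue
        if sub.groupby("patient_id")["outcome"].first().nunique() < 2:
            warnings.warn(f"{onset} group has a single outcome class; skipped")
            continue
        out[onset] = predict_outcomes(sub, measure, band, state, fc_threshold, overlap_grid)
    return out


def compare_overlap_by_outcome(
    data, measure: str, band: str, state: str, fc_threshold: float,
    target: str = "resection",
) -> dict:
    """Rank-sum comparison of per-patient hub overlap (with resection or SOZ)
    between good- and poor-outcome patients, with group medians."""
    ov = patient_overlaps(data, measure, band, state, fc_threshold, target=target)
    good = ov.loc[ov["outcome"] == "good", "overlap_percent"]
    poor = ov.loc[ov["outcome"] == "poor", "overlap_percent"]
    if good.empty or poor.empty:
        raise ValueError("both outcome groups must be non-empty")
    res: TestResult = wilcoxon_rank_sum(good, poor)
    return {
        "test": res,
        "median_good": float(good.median()),
        "median_poor": float(poor.median()),
        "n_good": len(good),
        "n_poor": len(poor),
    }
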