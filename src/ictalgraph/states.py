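"""Cohort-level nonparametric contrasts of nodal strength.

All operations consume the tidy strengths table produced by
:mod:`ictalgraph.pipeline` (a :class:`~ictalgraph.cohort.Cohort` is accepted
and converted on the fly).  Tests are paired Wilcoxon signed-rank within
patients or rank-sum between patient groups, with Benjamini-Hochberg FDR
correction within each test family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord, State, STATES
from .connectivity import FCMatrix
from .cohort import ElectrodeType
from .pipeline import cohort_strengths
from .stats import TestResult, fdr_bh, spearman, wilcoxon_rank_sum, wilcoxon_signed_rank

__all__ = [
    "StateComparisonResult",
    "RegionConnectivity",
    "compare_states",
    "inside_outside_contrast",
    "subgroup_contrasts",
    "between_within_connectivity",
    "age_correlation",
    "percent_difference",
]


@dataclass(frozen=True)
class StateComparisonResult:
    measure: str
    band: str
    state_a: str
    state_b: str
    p_raw: float
    p_fdr: float
    percent_difference: float
    n_patients: int


@dataclass(frozen=True)
class RegionConnectivity:
    patient_id: str
    region_label: str
    between_strength: float
    within_strength: float  # NaN when the region has < 2 contacts
    epileptogenic: bool


def _as_table(x) -> pd.DataFrame:
    if isinstance(x, Cohort):
        return cohort_strengths(x)
    return x


def percent_difference(median_a: float, median_b: float) -> float:
    """Signed percent difference of two cohort medians, second as reference."""
    if median_b == 0:
        return float("nan")
    return 100.0 * (median_a - median_b) / median_b


def _patient_medians(
    table: pd.DataFrame, measure: str, band: str, state: str, mask=None
) -> pd.Series:
    df = table[
        (table["measure"] == measure)
        & (table["band"] == band)
        & (table["state"] == state)
    ]
    if mask is not None:
        df = df[mask(df)]
    return df.groupby("patient_id")["strength"].median()


def compare_states(
    data, measure: str, band: Optional[str] = None
) -> list[StateComparisonResult]:
    """All 10 unordered state-pair contrasts of per-patient median strength.

    Paired two-sided Wilcoxon signed-rank per (state pair, band); FDR is
    applied jointly over the whole family for the measure (all pairs x all
    requested bands).  ``percent_difference`` compares the cohort medians of
    the per-patient values, with the second (earlier) state as reference.
    """
    table = _as_table(data)
    bands = [band] if band else sorted(table["band"].unique())
    pairs = list(itertools.combinations([s.value for s in STATES], 2))
    raw: list[dict] = []
    for bd in bands:
        per_state = {
            s.value: _patient_medians(table, measure, bd, s.value) for s in STATES
        }
        for sa, sb in pairs:
            a, b = per_state[sa], per_state[sb]
            joined = pd.concat([a, b], axis=1, keys=["a", "b"])
            if joined.isna().any().any():
                missing = joined[joined.isna().any(axis=1)].index.tolist()
                raise ValueError(
                    f"missing state data for patients {missing} "
                    f"({measure}/{bd}/{sa} vs {sb})"
                )
            # later (more epileptogenic) state first, earlier as reference
            res = wilcoxon_signed_rank(joined["b"], joined["a"])
            raw.append(
                {
                    "band": bd,
                    "state_a": sb,
                    "state_b": sa,
                    "p_raw": res.pvalue,
                    "pct": percent_difference(
                        float(joined["b"].median()), float(joined["a"].median())
                    ),
                    "n": len(joined),
                }
            )
    adj = fdr_bh([r["p_raw"] for r in raw])
    return [
        StateComparisonResult(
            measure=measure,
            band=r["band"],
            state_a=r["state_a"],
            state_b=r["state_b"],
            p_raw=r["p_raw"],
            p_fdr=float(q),
            percent_difference=r["pct"],
            n_patients=r["n"],
        )
        for r, q in zip(raw, adj)
    ]


def inside_outside_contrast(
    data,
    target: str,
    measure: str,
    band: str,
    state: str,
    outcome: Optional[str] = None,
) -> dict:
    """Paired contrast of median strength inside vs outside the resection
    (``target='resection'``) or the clinical SOZ (``target='soz'``).

    Patients lacking channels on either side are excluded with a warning.
    Returns the test result plus the inside/outside cohort medians.
    """
    flag = {"resection": "resected", "soz": "in_soz"}[target]
    table = _as_table(data)
    if outcome is not None:
        table = table[table["outcome"] == outcome]
    inside = _patient_medians(table, measure, band, state, lambda d: d[flag])
    outside = _patient_medians(table, measure, band, state, lambda d: ~d[flag])
    joined = pd.concat([inside, outside], axis=1, keys=["inside", "outside"])
    dropped = joined[joined.isna().any(axis=1)].index.tolist()
    if dropped:
        warnings.warn(
            f"excluding patients without channels on both sides of the "
            f"{target}: {dropped}"
        )
        joined = joined.dropna()
    if joined.empty:
        raise ValueError(f"no patient has channels inside and outside the {target}")
    res = wilcoxon_signed_rank(joined["inside"], joined["outside"])
    return {
        "test": res,
        "median_inside": float(joined["inside"].median()),
        "median_outside": float(joined["outside"].median()),
        "n_patients": len(joined),
    }


_GROUPINGS = ("intra_vs_extra_temporal", "implant_type", "propagating")


def _implant_group(df: pd.DataFrame) -> str:
    types = set(df["electrode_type"])
    if types == {"depth"}:
        return "seeg"
    if types == {"subdural"}:
        return "ecog"
    return "both"


def subgroup_contrasts(
    data,
    grouping: str,
    measure: str,
    bands=None,
    states=None,
) -> pd.DataFrame:
    """Subgroup contrasts of per-patient median strength.

    * ``intra_vs_extra_temporal`` / ``propagating``: paired signed-rank of
      within-patient group medians;
    * ``implant_type``: unpaired rank-sum between patient groups (depth-only
      vs subdural-only).

    FDR is applied within the (band x state) family.  Patients with an empty
    group are excluded with a warning; an error is raised if a group is empty
    for every patient.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {_GROUPINGS}")
    table = _as_table(data)
    bands = bands or sorted(table["band"].unique())
    states = [State(s).value for s in (states or STATES)]
    flag = {"intra_vs_extra_temporal": "temporal_lobe", "propagating": "propagating"}.get(
        grouping
    )
    rows = []
    for bd in bands:
        for st in states:
            if grouping == "implant_type":
                sub = table[
                    (table["measure"] == measure)
                    & (table["band"] == bd)
                    & (table["state"] == st)
                ]
                groups = sub.groupby("patient_id").apply(
                    _implant_group, include_groups=False
                )
                med = sub.groupby("patient_id")["strength"].median()
                a = med[groups == "seeg"]
                b = med[groups == "ecog"]
                if a.empty or b.empty:
                    raise ValueError(
                        "implant-type contrast needs both depth-only and "
                        "subdural-only patients"
                    )
                res = wilcoxon_rank_sum(a, b)
                rows.append(
                    dict(band=bd, state=st, p_raw=res.pvalue, statistic=res.statistic,
                         n=len(a) + len(b))
                )
            else:
                g1 = _patient_medians(table, measure, bd, st, lambda d: d[flag])
                g0 = _patient_medians(table, measure, bd, st, lambda d: ~d[flag])
                joined = pd.concat([g1, g0], axis=1, keys=["in", "out"])
                dropped = joined[joined.isna().any(axis=1)].index.tolist()
                if dropped:
                    warnings.warn(f"excluding patients with an empty group: {dropped}")
                joined = joined.dropna()
                if joined.empty:
                    raise ValueError(
                        f"grouping {grouping!r} empty for all patients "
                        f"({measure}/{bd}/{st})"
                    )
                res = wilcoxon_signed_rank(joined["in"], joined["out"])
                rows.append(
                    dict(band=bd, state=st, p_raw=res.pvalue, statistic=res.statistic,
                         n=len(joined))
                )
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p_raw"].to_numpy())
    out.insert(0, "grouping", grouping)
    out.insert(1, "measure", measure)
    return out


def between_within_connectivity(
    patient: PatientRecord, fc: FCMatrix
) -> list[RegionConnectivity]:
    """Between- vs within-region connectivity from depth (sEEG) contacts only.

    Per region: ``between_strength`` is the median of edges from the region's
    contacts to all depth contacts outside it; ``within_strength`` the median
    of edges among the region's contacts (NaN when it has fewer than two).
    A region counts as epileptogenic when more than half its contacts were
    resected.
    """
    depth_idx = [
        i
        for i, c in enumerate(patient.channels)
        if c.electrode_type is ElectrodeType.DEPTH
    ]
    if len(depth_idx) < 2:
        raise ValueError("between/within analysis needs >= 2 depth contacts")
    regions: dict[str, list[int]] = {}
    for i in depth_idx:
        regions.setdefault(patient.channels[i].region_label, []).append(i)
    if len(regions) < 2:
        raise ValueError("between/within analysis needs >= 2 regions")
    v = fc.values
    out = []
    for label, idx in regions.items():
        others = [i for i in depth_idx if i not in idx]
        between = float(np.nanmedian(v[np.ix_(idx, others)]))
        if len(idx) >= 2:
            sub = v[np.ix_(idx, idx)]
            within = float(np.nanmedian(sub[~np.eye(len(idx), dtype=bool)]))
        else:
            within = float("nan")
        n_res = sum(patient.channels[i].resected for i in idx)
        out.append(
            RegionConnectivity(
                patient_id=patient.patient_id,
                region_label=label,
                between_strength=between,
                within_strength=within,
                epileptogenic=n_res > len(idx) / 2,
            )
        )
    return out


def age_correlation(data, measure: str, state: str, band: str) -> TestResult:
    """Spearman correlation of age at surgery with per-patient median strength."""
    table = _as_table(data)
    sub = table[
        (table["measure"] == measure)
        & (table["band"] == band)
        & (table["state"] == State(state).value)
    ]
    per_patient = sub.groupby("patient_id").agg(
        strength=("strength", "median"), age=("age_at_surgery", "first")
    )
    if len(per_patient) < 5:
        raise ValueError("age correlation needs >= 5 patients")
    return spearman(per_patient["age"], per_patient["strength"])
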