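"""End-to-end per-patient pipeline: preprocess -> band FC -> nodal strength.

The central product is a tidy "strengths table" (one row per patient x
channel x measure x band x state) carrying the max-normalized nodal strength
together with the channel metadata flags; every cohort-level analysis
consumes this table.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .cohort import Cohort, PatientRecord, State, STATES
from .config import AnalysisConfig, Band
from .connectivity import (
    MEASURES,
    FCMatrix,
    distance_normalize,
    fc_matrices,
    nodal_strength,
)
from .preprocessing import band_filter, preprocess_epoch, segment_epoch, SegmentSet

__all__ = ["patient_fc", "patient_strengths", "cohort_strengths"]


def _normalize_states(states) -> tuple[State, ...]:
    return tuple(State(s) for s in (states or STATES))


def patient_fc(
    patient: PatientRecord,
    config: AnalysisConfig | None = None,
    measures: Sequence[str] = MEASURES,
    bands: Iterable[Band] | None = None,
    states=None,
    distance_norm: bool = True,
) -> dict[tuple[str, str, State], FCMatrix]:
    """Segment-averaged, distance-normalized FC matrices for one patient,
    keyed by (measure, band name, state)."""
    config = config or AnalysisConfig()
    bands = tuple(bands or config.bands)
    states = _normalize_states(states)
    patient.require_states(states)
    out: dict[tuple[str, str, State], FCMatrix] = {}
    for state in states:
        clean = preprocess_epoch(patient.epochs[state], config)
        for band in bands:
            filtered = band_filter(clean.data, band, clean.fs, config.filter_order)
            segset = segment_epoch(
                type(clean)(state, filtered, clean.fs), config
            )
            segset = SegmentSet(segset.segments, band.name, state, clean.fs)
            mats = fc_matrices(
                segset, measures, config.edge_trim_fraction, patient.patient_id
            )
            for m, fc in mats.items():
                if distance_norm:
                    fc = distance_normalize(fc, patient.channels)
                out[(m, band.name, state)] = fc
    return out


def patient_strengths(
    patient: PatientRecord,
    config: AnalysisConfig | None = None,
    measures: Sequence[str] = MEASURES,
    bands: Iterable[Band] | None = None,
    states=None,
    distance_norm: bool = True,
) -> pd.DataFrame:
    """Strengths table for one patient (max-normalized per state/band/measure)."""
    fcs = patient_fc(patient, config, measures, bands, states, distance_norm)
    rows = []
    flags = {
        c.channel_id: c for c in patient.channels
    }
    for (measure, band_name, state), fc in fcs.items():
        nsv = nodal_strength(fc, normalize=True)
        for ch_id, s in zip(patient.channel_ids, nsv.values):
            c = flags[ch_id]
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "channel_id": ch_id,
                    "measure": measure,
                    "band": band_name,
                    "state": state.value,
                    "strength": float(s),
                    "electrode_type": c.electrode_type.value,
                    "resected": c.resected,
                    "in_soz": c.in_soz,
                    "propagating": c.propagating,
                    "temporal_lobe": c.temporal_lobe,
                    "region_label": c.region_label,
                }
            )
    return pd.DataFrame(rows)


def cohort_strengths(
    cohort: Cohort,
    config: AnalysisConfig | None = None,
    measures: Sequence[str] = MEASURES,
    bands: Iterable[Band] | None = None,
    states=None,
    distance_norm: bool = True,
) -> pd.DataFrame:
    """Concatenated strengths table over all patients, with clinical columns."""
    frames = []
    for p in cohort:
        df = patient_strengths(p, config, measures, bands, states, distance_norm)
        df["outcome"] = p.outcome
        df["onset_type"] = p.onset_type
        df["age_at_surgery"] = p.age_at_surgery
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
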