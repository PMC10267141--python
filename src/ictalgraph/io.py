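"""Cohort file I/O.

Native interchange layout (all plain text)::

    DIR/
      patients.tsv                  one row per patient (clinical metadata, fs)
      <patient_id>/
        channels.tsv                one row per contact
        no_spikes.txt ... post_ictal.txt   channels x samples matrices (uV)

EDF signal files are accepted on read when ``mne`` is importable
(``<patient_id>/<state>.edf``); writing always uses text matrices.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    STATES,
    ChannelInfo,
    Cohort,
    ElectrodeType,
    PatientRecord,
    State,
    StateEpoch,
)

__all__ = ["read_cohort", "write_cohort"]

_PATIENT_COLS = [
    "patient_id",
    "engel_class",
    "onset_type",
    "age_at_surgery",
    "sex",
    "laterality",
    "fs",
]

_CHANNEL_COLS = [
    "channel_id",
    "electrode_type",
    "shaft_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "resected",
    "in_soz",
    "propagating",
    "temporal_lobe",
    "region_label",
]


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to ``path`` in the native text layout."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort:
        fs = next(iter(p.epochs.values())).fs if p.epochs else float("nan")
        rows.append(
            {
                "patient_id": p.patient_id,
                "engel_class": p.engel_class,
                "onset_type": p.onset_type if p.onset_type else "",
                "age_at_surgery": p.age_at_surgery,
                "sex": p.sex,
                "laterality": p.laterality,
                "fs": fs,
            }
        )
    pd.DataFrame(rows, columns=_PATIENT_COLS).to_csv(
        root / "patients.tsv", sep="\t", index=False
    )
    for p in cohort:
        pdir = root / p.patient_id
        pdir.mkdir(exist_ok=True)
        ch_rows = []
        for c in p.channels:
            x, y, z = c.coordinates
            ch_rows.append(
                {
                    "channel_id": c.channel_id,
                    "electrode_type": c.electrode_type.value,
                    "shaft_id": c.shaft_id if c.shaft_id else "",
                    "x_mm": x,
                    "y_mm": y,
                    "z_mm": z,
                    "resected": int(c.resected),
                    "in_soz": int(c.in_soz),
                    "propagating": int(c.propagating),
                    "temporal_lobe": int(c.temporal_lobe),
                    "region_label": c.region_label,
                }
            )
        pd.DataFrame(ch_rows, columns=_CHANNEL_COLS).to_csv(
            pdir / "channels.tsv", sep="\t", index=False
        )
        for state, epoch in p.epochs.items():
            np.savetxt(pdir / f"{state.value}.txt", epoch.data, fmt="%.8e")


def _read_signal(pdir: Path, state: State, fs: float, patient_id: str) -> np.ndarray:
    txt = pdir / f"{state.value}.txt"
    if txt.exists():
        return np.atleast_2d(np.loadtxt(txt))
    edf = pdir / f"{state.value}.edf"
    if edf.exists():
        try:
            import mne  # optional, only needed for EDF input
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                f"{patient_id}/{state.value}: EDF input requires the optional "
                "dependency 'mne'"
            ) from exc
        raw = mne.io.read_raw_edf(edf, preload=True, verbose="error")
        return raw.get_data() * 1e6  # volts -> microvolts
    raise FileNotFoundError(
        f"patient {patient_id}: missing signal file for state {state.value!r} "
        f"(looked for {txt.name} / {edf.name})"
    )


def read_cohort(path) -> Cohort:
    """Read and validate a cohort written by :func:`write_cohort`."""
    root = Path(path)
    meta_path = root / "patients.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no patients.tsv under {os.fspath(root)}")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"patient_id": str})
    missing_cols = set(_PATIENT_COLS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"patients.tsv is missing columns: {sorted(missing_cols)}")
    patients = []
    for _, row in meta.iterrows():
        pid = str(row["patient_id"])
        pdir = root / pid
        ch_tab = pd.read_csv(
            pdir / "channels.tsv",
            sep="\t",
            dtype={"channel_id": str, "shaft_id": str, "region_label": str},
            keep_default_na=False,
        )
        channels = [
            ChannelInfo(
                channel_id=str(r["channel_id"]),
                electrode_type=ElectrodeType(r["electrode_type"]),
                shaft_id=(str(r["shaft_id"]) or None),
                coordinates=(float(r["x_mm"]), float(r["y_mm"]), float(r["z_mm"])),
                resected=bool(int(r["resected"])),
                in_soz=bool(int(r["in_soz"])),
                propagating=bool(int(r["propagating"])),
                temporal_lobe=bool(int(r["temporal_lobe"])),
                region_label=str(r["region_label"]),
            )
            for _, r in ch_tab.iterrows()
        ]
        fs = float(row["fs"])
        epochs = {}
        for state in STATES:
            data = _read_signal(pdir, state, fs, pid)
            try:
                epochs[state] = StateEpoch(state, data, fs)
            except ValueError as exc:
                raise ValueError(f"patient {pid}: {exc}") from exc
        onset = str(row["onset_type"]) if not pd.isna(row["onset_type"]) else ""
        patients.append(
            PatientRecord(
                patient_id=pid,
                channels=channels,
                epochs=epochs,
                engel_class=str(row["engel_class"]),
                onset_type=onset or None,
                age_at_surgery=float(row["age_at_surgery"]),
                sex=str(row["sex"]),
                laterality=str(row["laterality"]),
            )
        )
    return Cohort(patients)
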