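"""Domain containers for iEEG cohorts.

A cohort bundles, per patient, the multichannel recordings of the five
epileptogenic states (interictal without spikes, interictal with spikes,
pre-ictal, ictal, post-ictal), per-contact metadata (electrode type, shaft
membership, 3-D position, resection / seizure-onset-zone / propagation /
temporal-lobe flags) and clinical labels (Engel class, onset type, age, sex,
laterality).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "State",
    "STATES",
    "ElectrodeType",
    "ChannelInfo",
    "StateEpoch",
    "PatientRecord",
    "Cohort",
    "EPOCH_DURATION_S",
    "MIN_SAMPLING_RATE",
    "parse_engel",
    "engel_outcome",
]

EPOCH_DURATION_S = 60.0
MIN_SAMPLING_RATE = 500.0


class State(str, Enum):
    """The five epileptogenic states analysed per patient."""

    NO_SPIKES = "no_spikes"
    SPIKES = "spikes"
    PRE_ICTAL = "pre_ictal"
    ICTAL = "ictal"
    POST_ICTAL = "post_ictal"


#: Canonical ordering of states (interictal -> peri-ictal).
STATES: tuple[State, ...] = (
    State.NO_SPIKES,
    State.SPIKES,
    State.PRE_ICTAL,
    State.ICTAL,
    State.POST_ICTAL,
)


class ElectrodeType(str, Enum):
    DEPTH = "depth"      # sEEG contact on a stereotactic shaft
    SUBDURAL = "subdural"  # ECoG grid/strip contact


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for a single iEEG contact."""

    channel_id: str
    electrode_type: ElectrodeType
    shaft_id: Optional[str]
    coordinates: tuple[float, float, float]  # mm
    resected: bool = False
    in_soz: bool = False
    propagating: bool = False
    temporal_lobe: bool = False
    region_label: str = ""

    def __post_init__(self) -> None:
        etype = ElectrodeType(self.electrode_type)
        object.__setattr__(self, "electrode_type", etype)
        if etype is ElectrodeType.DEPTH and not self.shaft_id:
            raise ValueError(
                f"depth channel {self.channel_id!r} must have a shaft_id"
            )
        coords = tuple(float(c) for c in self.coordinates)
        if len(coords) != 3 or not all(np.isfinite(coords)):
            raise ValueError(
                f"channel {self.channel_id!r}: coordinates must be a finite 3-vector"
            )
        object.__setattr__(self, "coordinates", coords)


@dataclass
class StateEpoch:
    """One 60-s multichannel recording of a single epileptogenic state.

    ``data`` is a (channels x samples) float array in microvolts.
    """

    state: State
    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.state = State(self.state)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"{self.state.value}: data must be 2-D (channels x samples)")
        if self.fs < MIN_SAMPLING_RATE:
            raise ValueError(
                f"{self.state.value}: sampling rate {self.fs} Hz is below the "
                f"minimum of {MIN_SAMPLING_RATE:g} Hz"
            )
        expected = int(round(EPOCH_DURATION_S * self.fs))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"{self.state.value}: epoch must be exactly {EPOCH_DURATION_S:g} s "
                f"({expected} samples at {self.fs:g} Hz), got {self.data.shape[1]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.state.value}: epoch contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


_ENGEL_GOOD_PREFIXES = ("IA", "IB", "IC", "ID")


def parse_engel(label: str) -> str:
    """Normalize an Engel class string ('ia' -> 'IA'); accepts bare 'I'..'IV'."""
    lab = str(label).strip().upper()
    if not lab or not set(lab) <= set("IVABCD"):
        raise ValueError(f"unrecognized Engel class {label!r}")
    return lab


def engel_outcome(engel: str) -> str:
    """Dichotomize Engel class: 'good' iff class I (seizure-free), else 'poor'."""
    lab = parse_engel(engel)
    if lab.startswith("IV"):
        return "poor"
    if lab.startswith(("II", "III")):
        return "poor"
    if lab.startswith("I"):
        return "good"
    raise ValueError(f"unrecognized Engel class {engel!r}")


@dataclass
class PatientRecord:
    """All data for one patient: channels, state epochs and clinical labels."""

    patient_id: str
    channels: list[ChannelInfo]
    epochs: dict[State, StateEpoch]
    engel_class: str
    onset_type: Optional[str] = None  # "SSO" | "FSO" | None
    age_at_surgery: float = float("nan")
    sex: str = "F"
    laterality: str = "L"  # "L" | "R" | "LR"

    def __post_init__(self) -> None:
        self.engel_class = parse_engel(self.engel_class)
        if self.onset_type is not None:
            ot = str(self.onset_type).upper()
            if ot not in ("SSO", "FSO"):
                raise ValueError(f"{self.patient_id}: onset_type must be SSO or FSO")
            self.onset_type = ot
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.patient_id}: duplicate channel_id")
        # canonical channel order: lexicographic by channel_id
        order = np.argsort(np.asarray(ids, dtype=object))
        if not np.array_equal(order, np.arange(len(ids))):
            self.channels = [self.channels[i] for i in order]
            self.epochs = {
                s: StateEpoch(e.state, e.data[order], e.fs)
                for s, e in self.epochs.items()
            }
        self.epochs = {State(s): e for s, e in self.epochs.items()}
        n = len(self.channels)
        for s, e in self.epochs.items():
            if e.n_channels != n:
                raise ValueError(
                    f"{self.patient_id}/{s.value}: epoch has {e.n_channels} rows "
                    f"but patient has {n} channels"
                )

    @property
    def outcome(self) -> str:
        return engel_outcome(self.engel_class)

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    def channel_mask(self, attr: str) -> np.ndarray:
        """Boolean mask over channels for a flag attribute (e.g. 'resected')."""
        return np.array([bool(getattr(c, attr)) for c in self.channels])

    def require_states(self, states=STATES) -> None:
        missing = [s.value for s in states if State(s) not in self.epochs]
        if missing:
            raise ValueError(f"{self.patient_id}: missing state epoch(s): {missing}")

    def with_channels(self, channels: list[ChannelInfo]) -> "PatientRecord":
        """Copy of the record with replaced channel metadata (same signals)."""
        out = replace(self, channels=list(channels))
        return out


@dataclass
class Cohort:
    patients: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_id in cohort")

    def __iter__(self):
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)

    def __getitem__(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def subset(self, predicate) -> "Cohort":
        return Cohort([p for p in self.patients if predicate(p)])

    def by_outcome(self, outcome: str) -> "Cohort":
        return self.subset(lambda p: p.outcome == outcome)
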