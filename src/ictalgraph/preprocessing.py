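"""Filtering, referencing and segmentation of state epochs.

Raw epochs are band-pass filtered 1-100 Hz, notch filtered at 60 Hz
(zero-phase in both cases), then common average referenced; the referenced
epoch is band-filtered per frequency band and cut into 20 non-overlapping
3-s segments for connectivity estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .cohort import State, StateEpoch
from .config import AnalysisConfig, Band

__all__ = [
    "SegmentSet",
    "common_average_reference",
    "band_filter",
    "notch_filter",
    "preprocess_epoch",
    "segment_epoch",
    "extract_state_windows",
]


@dataclass
class SegmentSet:
    """Non-overlapping analysis segments cut from one state epoch."""

    segments: list[np.ndarray]  # each channels x samples
    band: str  # band name or "broadband"
    state: State
    fs: float

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def concatenate(self) -> np.ndarray:
        return np.concatenate(self.segments, axis=1)


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the per-sample mean over channels (idempotent)."""
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("common average reference requires >= 2 channels")
    return data - data.mean(axis=0, keepdims=True)


def _padlen(fs: float) -> int:
    # 1 s of reflection padding against filter edge transients
    return int(round(fs))


def band_filter(
    data: np.ndarray, band: Band | tuple[float, float], fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if isinstance(band, Band):
        low, high = band.low, band.high
    else:
        low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz must lie strictly inside (0, fs/2={fs / 2:g})"
        )
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    data = np.asarray(data, float)
    padlen = min(_padlen(fs), data.shape[-1] - 1)
    return scipy.signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


def notch_filter(data: np.ndarray, fs: float, freq: float = 60.0, q: float = 30.0):
    """Zero-phase IIR notch along the last axis."""
    b, a = scipy.signal.iirnotch(freq, q, fs=fs)
    data = np.asarray(data, float)
    padlen = min(_padlen(fs), data.shape[-1] - 1)
    return scipy.signal.filtfilt(b, a, data, axis=-1, padlen=padlen)


def preprocess_epoch(epoch: StateEpoch, config: AnalysisConfig | None = None):
    """Broadband 1-100 Hz band-pass, 60 Hz notch, then common average reference."""
    config = config or AnalysisConfig()
    if epoch.fs < 2 * config.broadband[1] + 50:
        # need headroom above the 100 Hz passband edge
        if epoch.fs < 250:
            raise ValueError(
                f"sampling rate {epoch.fs:g} Hz too low for a "
                f"{config.broadband[1]:g} Hz passband"
            )
    data = band_filter(epoch.data, config.broadband, epoch.fs, config.filter_order)
    data = notch_filter(data, epoch.fs, config.notch_hz, config.notch_q)
    data = common_average_reference(data)
    return StateEpoch(epoch.state, data, epoch.fs)


def segment_epoch(epoch: StateEpoch, config: AnalysisConfig | None = None) -> SegmentSet:
    """Cut an epoch into ``n_segments`` contiguous non-overlapping segments."""
    config = config or AnalysisConfig()
    seg_samples = int(round(config.segment_length_s * epoch.fs))
    expected = seg_samples * config.n_segments
    if epoch.data.shape[1] != expected:
        raise ValueError(
            f"epoch of {epoch.data.shape[1]} samples cannot be cut into "
            f"{config.n_segments} segments of {seg_samples} samples"
        )
    segments = [
        epoch.data[:, i * seg_samples : (i + 1) * seg_samples]
        for i in range(config.n_segments)
    ]
    return SegmentSet(segments=segments, band="broadband", state=epoch.state, fs=epoch.fs)


def extract_state_windows(
    data: np.ndarray,
    fs: float,
    seizure_onset_s: float,
    seizure_offset_s: float,
    interictal_regions: dict | None = None,
    rng_seed: int = 0,
) -> dict[State, StateEpoch]:
    """Cut the five state epochs out of a continuous annotated recording.

    ``pre_ictal`` is the minute before onset, ``ictal`` the minute from onset,
    ``post_ictal`` the minute from seizure offset.  Interictal epochs are drawn
    by a seeded uniform choice from the annotated artifact-free regions
    (``interictal_regions``: state name -> list of (start_s, end_s)).

    A seizure shorter than 60 s yields no ictal epoch; the seizure is reported
    in the returned dict under the key ``"short_ictal"`` instead, so that
    downstream onset-type analyses can exclude the patient.
    """
    data = np.asarray(data, float)
    n = data.shape[1]
    win = int(round(60.0 * fs))
    onset = int(round(seizure_onset_s * fs))
    offset = int(round(seizure_offset_s * fs))
    if onset - win < 0:
        raise ValueError("insufficient pre-ictal data (need 60 s before onset)")
    if offset + win > n:
        raise ValueError("insufficient post-ictal data (need 60 s after offset)")
    out: dict = {
        State.PRE_ICTAL: StateEpoch(State.PRE_ICTAL, data[:, onset - win : onset], fs),
        State.POST_ICTAL: StateEpoch(State.POST_ICTAL, data[:, offset : offset + win], fs),
    }
    if offset - onset >= win:
        out[State.ICTAL] = StateEpoch(State.ICTAL, data[:, onset : onset + win], fs)
    else:
        out["short_ictal"] = (seizure_onset_s, seizure_offset_s)
    rng = np.random.default_rng(rng_seed)
    for name in ("no_spikes", "spikes"):
        regions = (interictal_regions or {}).get(name, [])
        candidates = [
            (int(round(a * fs)), int(round(b * fs)))
            for a, b in regions
            if (b - a) >= 60.0
        ]
        if not candidates:
            continue
        a, b = candidates[rng.integers(len(candidates))]
        start = int(rng.integers(a, b - win + 1))
        state = State(name)
        out[state] = StateEpoch(state, data[:, start : start + win], fs)
    return out
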