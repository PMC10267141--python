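"""Slow vs fast seizure-onset (SSO/FSO) classification.

A seizure is FSO when fast (beta/gamma) discharges dominate around the
electrographic onset and SSO when slow (theta/alpha) rhythms do.  The
quantitative surrogate used here: Welch spectra of the +/-5 s window around
onset, per channel, with each band power expressed as a log-ratio to the
same channel's 60-s interictal baseline power.  The onset channel is the one
with the largest baseline-relative power increase in either band group; the
``fast_score`` is that channel's (fast log-ratio - slow log-ratio) and the
call is FSO iff the score is positive.  Anchoring the score on the onset
channel (rather than taking a plain channel-maximum of the difference)
prevents off-focus channels whose spectra barely change from outvoting a
focal slow onset by noise alone.  Log-ratios make the classifier invariant
to global amplitude rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .cohort import Cohort, PatientRecord, State

__all__ = [
    "OnsetCall",
    "classify_onset",
    "classify_patient_record",
    "classify_patient",
    "filter_ictal_duration",
    "SLOW_BAND",
    "FAST_BAND",
]

SLOW_BAND = (5.0, 12.0)   # theta + alpha
FAST_BAND = (15.0, 90.0)  # beta + low/high gamma

_LOW_CONFIDENCE_SCORE = 0.1


@dataclass(frozen=True)
class OnsetCall:
    patient_id: str
    seizure_id: str
    call: str  # "SSO" | "FSO"
    fast_score: float
    window_s: float
    low_confidence: bool = False


def _band_power(freqs: np.ndarray, psd: np.ndarray, band) -> np.ndarray:
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    return psd[..., sel].mean(axis=-1)


def classify_onset(
    pre_onset: np.ndarray,
    post_onset: np.ndarray,
    baseline: np.ndarray,
    fs: float,
    window_s: float = 5.0,
    patient_id: str = "",
    seizure_id: str = "s1",
) -> OnsetCall:
    """Classify one seizure from the signals around its electrographic onset.

    ``pre_onset`` / ``post_onset`` are (channels x samples) arrays ending at /
    starting from the onset; the last / first ``window_s`` seconds of each are
    analysed.  ``baseline`` is an interictal epoch of the same channels.
    """
    win = int(round(window_s * fs))
    if pre_onset.shape[-1] < win or post_onset.shape[-1] < win:
        raise ValueError(f"need at least {window_s:g} s on each side of onset")
    around = np.concatenate([pre_onset[:, -win:], post_onset[:, :win]], axis=1)
    nperseg = int(round(fs))  # 1-s Hann windows, 50% overlap
    f_on, psd_on = scipy.signal.welch(
        around, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, axis=-1
    )
    f_bl, psd_bl = scipy.signal.welch(
        baseline, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, axis=-1
    )
    eps = np.finfo(float).tiny
    fast_lr = np.log(_band_power(f_on, psd_on, FAST_BAND) + eps) - np.log(
        _band_power(f_bl, psd_bl, FAST_BAND) + eps
    )
    slow_lr = np.log(_band_power(f_on, psd_on, SLOW_BAND) + eps) - np.log(
        _band_power(f_bl, psd_bl, SLOW_BAND) + eps
    )
    onset_channel = int(np.argmax(np.maximum(fast_lr, slow_lr)))
    score = float(fast_lr[onset_channel] - slow_lr[onset_channel])
    return OnsetCall(
        patient_id=patient_id,
        seizure_id=seizure_id,
        call="FSO" if score > 0 else "SSO",
        fast_score=score,
        window_s=window_s,
        low_confidence=abs(score) < _LOW_CONFIDENCE_SCORE,
    )


def classify_patient_record(
    patient: PatientRecord, window_s: float = 5.0, seizure_id: str = "s1"
) -> OnsetCall:
    """Classify a patient's recorded seizure: the ictal epoch starts at onset,
    the pre-ictal epoch ends at it, and the spike-free interictal epoch is the
    baseline."""
    patient.require_states((State.PRE_ICTAL, State.ICTAL, State.NO_SPIKES))
    fs = patient.epochs[State.ICTAL].fs
    return classify_onset(
        patient.epochs[State.PRE_ICTAL].data,
        patient.epochs[State.ICTAL].data,
        patient.epochs[State.NO_SPIKES].data,
        fs,
        window_s=window_s,
        patient_id=patient.patient_id,
        seizure_id=seizure_id,
    )


def classify_patient(calls: list[OnsetCall]) -> str:
    """Patient-level call: majority vote over seizures; ties go to the side
    with the larger mean |fast_score|."""
    if not calls:
        raise ValueError("no seizure calls to aggregate")
    fso = [c for c in calls if c.call == "FSO"]
    sso = [c for c in calls if c.call == "SSO"]
    if len(fso) != len(sso):
        return "FSO" if len(fso) > len(sso) else "SSO"
    mean_abs = lambda cs: np.mean([abs(c.fast_score) for c in cs]) if cs else 0.0
    return "FSO" if mean_abs(fso) > mean_abs(sso) else "SSO"


def filter_ictal_duration(
    cohort: Cohort, durations: dict[str, float] | None = None, min_s: float = 60.0
) -> Cohort:
    """Drop patients whose ictal recording is shorter than ``min_s`` seconds
    (``durations`` overrides the epoch durations, e.g. for truncated seizures)."""
    keep = []
    for p in cohort:
        if State.ICTAL not in p.epochs:
            continue
        d = (durations or {}).get(p.patient_id, p.epochs[State.ICTAL].duration_s)
        if d >= min_s:
            keep.append(p)
    return Cohort(keep)
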