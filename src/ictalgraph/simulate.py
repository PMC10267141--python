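"""Seeded synthetic iEEG cohorts with known ground truth.

Signal model
------------
Each channel is a sum over the six analysis bands of band-limited stochastic
oscillators (filtered white noise).  Coupling is produced by two mechanisms,
both scaled per state by ``coupling_gain[state]``:

* a *shared additive source* per band: channel ``i`` mixes the common source
  with weight ``c_i`` and keeps ``sqrt(1 - c_i^2)`` of its private noise, so
  that both amplitude envelopes and phases co-fluctuate (drives AEC and PLV);
* a *shared slow (1-6 Hz) envelope modulator* multiplying each channel's
  summed oscillatory part with weight proportional to ``c_i``, producing
  envelope co-modulation that survives both common average referencing
  (multiplicative structure) and instantaneous orthogonalization (drives
  oAEC).  The delta/theta-rate band is a deliberate choice: a sub-0.5 Hz
  modulator is nearly constant within a 3-s analysis segment and therefore
  invisible to per-segment envelope correlation.

Hub channels couple with full weight; non-hub channels with weight
``background_coupling``.  The "spikes" epoch superimposes shared biphasic
70-ms transients (5x background SD) on hub channels; the ictal epoch starts
with 10 s of onset rhythm at 3x background RMS - 6 Hz for slow-onset (SSO)
and 40 Hz for fast-onset (FSO) seizures.  Independent Gaussian sensor noise
is added everywhere.  All draws are deterministic given ``rng_seed``.

Geometries follow typical pediatric implants: 10 mm-pitch subdural grids and
depth shafts of 10 contacts with 3-5 mm pitch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .cohort import (
    STATES,
    ChannelInfo,
    Cohort,
    ElectrodeType,
    PatientRecord,
    State,
    StateEpoch,
)
from .config import DEFAULT_BANDS, BandSet

__all__ = [
    "SimulationSpec",
    "simulate_patient",
    "simulate_cohort",
    "simulate_null_cohort",
    "hub_study_spec",
    "state_study_spec",
    "spike_template",
    "DEFAULT_COUPLING_GAINS",
]

#: Default per-state coupling gains following the epileptogenic hierarchy
#: (ictal >= post-ictal >= spikes >= pre-ictal >= no-spikes).
DEFAULT_COUPLING_GAINS: dict[State, float] = {
    State.NO_SPIKES: 0.1,
    State.PRE_ICTAL: 0.2,
    State.SPIKES: 0.35,
    State.POST_ICTAL: 0.6,
    State.ICTAL: 1.0,
}

#: Band RMS amplitudes in microvolts (roughly 1/f-shaped).
_BAND_AMPLITUDE = {
    "delta": 20.0,
    "theta": 15.0,
    "alpha": 12.0,
    "beta": 8.0,
    "low_gamma": 5.0,
    "high_gamma": 3.0,
}

_ONSET_FREQ = {"SSO": 6.0, "FSO": 40.0}
_ONSET_DURATION_S = 10.0
_SPIKE_DURATION_S = 0.07
_SPIKE_AMPLITUDE_SD = 5.0
_MAX_MIX = 0.95  # cap on the shared-source mixing weight
_MOD_BAND = (1.0, 6.0)  # shared envelope-modulator band
_MOD_CLIP = 1.5


@dataclass
class SimulationSpec:
    """Ground-truth parameters of one synthetic patient."""

    n_channels: int = 20
    geometry: str = "shafts"  # "grid" | "shafts" | "mixed"
    hub_set: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    coupling_gain: dict[State, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING_GAINS)
    )
    background_coupling: float = 0.5
    spike_rate: float = 60.0  # events/min in the "spikes" state
    onset_type: str = "SSO"
    noise_sd: float = 5.0  # microvolts
    envelope_mod_depth: float = 0.6  # envelope-modulation depth per unit weight
    fs: float = 500.0
    rng_seed: int = 0
    bands: BandSet = field(default_factory=lambda: DEFAULT_BANDS)

    def __post_init__(self) -> None:
        if self.fs < 500:
            raise ValueError("simulation sampling rate must be >= 500 Hz")
        self.hub_set = tuple(sorted(int(i) for i in self.hub_set))
        if not self.hub_set:
            raise ValueError("hub_set must be non-empty")
        if min(self.hub_set) < 0 or max(self.hub_set) >= self.n_channels:
            raise ValueError("hub_set indices must lie in [0, n_channels)")
        self.coupling_gain = {State(s): float(g) for s, g in self.coupling_gain.items()}
        missing = [s.value for s in STATES if s not in self.coupling_gain]
        if missing:
            raise ValueError(f"coupling_gain missing state(s): {missing}")
        if any(g < 0 for g in self.coupling_gain.values()):
            raise ValueError("coupling gains must be nonnegative")
        if self.onset_type not in _ONSET_FREQ:
            raise ValueError("onset_type must be 'SSO' or 'FSO'")


def spike_template(fs: float) -> np.ndarray:
    """Biphasic interictal-spike waveform (unit peak, 70 ms)."""
    n = int(round(_SPIKE_DURATION_S * fs))
    t = np.arange(n) / n
    return np.sin(2 * np.pi * t) * np.hanning(n)


def _band_noise(rng, shape, low, high, fs, order=4) -> np.ndarray:
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    x = scipy.signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _make_channels(spec: SimulationSpec, rng) -> list[ChannelInfo]:
    """Electrode geometry: zero-padded ids keep lexicographic = index order."""
    n = spec.n_channels
    width = max(3, len(str(n)))
    channels: list[ChannelInfo] = []
    if spec.geometry == "grid":
        side = math.ceil(math.sqrt(n))
        for i in range(n):
            r, c = divmod(i, side)
            channels.append(
                ChannelInfo(
                    channel_id=f"G{i:0{width}d}",
                    electrode_type=ElectrodeType.SUBDURAL,
                    shaft_id=None,
                    coordinates=(10.0 * c, 10.0 * r, 0.0),
                    region_label=f"grid_q{2 * (r >= side / 2) + (c >= side / 2)}",
                )
            )
    elif spec.geometry in ("shafts", "mixed"):
        n_grid = n // 2 if spec.geometry == "mixed" else 0
        n_depth = n - n_grid
        n_shafts = math.ceil(n_depth / 10)
        idx = 0
        for s in range(n_shafts):
            pitch = float(rng.choice([3, 4, 5]))
            origin = np.array([40.0 * s, 0.0, -10.0])
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            for c in range(min(10, n_depth - 10 * s)):
                pos = origin + pitch * c * direction
                channels.append(
                    ChannelInfo(
                        channel_id=f"S{s:02d}C{idx:0{width}d}",
                        electrode_type=ElectrodeType.DEPTH,
                        shaft_id=f"shaft{s:02d}",
                        coordinates=tuple(pos),
                        region_label=f"region_{s:02d}",
                    )
                )
                idx += 1
        for i in range(n_grid):
            r, c = divmod(i, 8)
            channels.append(
                ChannelInfo(
                    channel_id=f"T{i:0{width}d}",
                    electrode_type=ElectrodeType.SUBDURAL,
                    shaft_id=None,
                    coordinates=(100.0 + 10.0 * c, 10.0 * r, 0.0),
                    region_label="lateral_grid",
                )
            )
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    return channels


def _simulate_state(spec: SimulationSpec, state: State, seed_key) -> np.ndarray:
    rng = np.random.default_rng(seed_key)
    n, fs = spec.n_channels, spec.fs
    t_samples = int(round(60.0 * fs))
    g = spec.coupling_gain[state]
    hubs = np.zeros(n, bool)
    hubs[list(spec.hub_set)] = True
    weight = g * np.where(hubs, 1.0, spec.background_coupling)
    c = np.minimum(_MAX_MIX * weight, _MAX_MIX)[:, None]

    osc = np.zeros((n, t_samples))
    for band in spec.bands:
        noise = _band_noise(rng, (n, t_samples), band.low, band.high, fs)
        shared = _band_noise(rng, (1, t_samples), band.low, band.high, fs)
        osc += _BAND_AMPLITUDE[band.name] * (np.sqrt(1 - c**2) * noise + c * shared)

    # shared slow envelope modulator
    m = _band_noise(rng, (1, t_samples), *_MOD_BAND, fs, order=2)
    m = np.clip(m, -_MOD_CLIP, _MOD_CLIP)
    osc *= 1.0 + spec.envelope_mod_depth * c * m

    background_sd = osc.std(axis=1, keepdims=True)

    if state is State.SPIKES and spec.spike_rate > 0:
        tpl = spike_template(fs)
        n_spikes = rng.poisson(spec.spike_rate)
        starts = rng.integers(0, t_samples - tpl.size, size=n_spikes)
        amp = _SPIKE_AMPLITUDE_SD * background_sd[:, 0]
        for s0 in starts:
            osc[hubs, s0 : s0 + tpl.size] += amp[hubs, None] * tpl[None, :]

    if state is State.ICTAL:
        n_on = int(round(_ONSET_DURATION_S * fs))
        tt = np.arange(n_on) / fs
        ramp = np.ones(n_on)
        fade = int(round(fs))  # 1-s fade at both ends of the onset burst
        ramp[:fade] = np.linspace(0, 1, fade)
        ramp[-fade:] = np.linspace(1, 0, fade)
        burst = np.sin(2 * np.pi * _ONSET_FREQ[spec.onset_type] * tt) * ramp
        amp = 3.0 * np.sqrt(2.0) * background_sd[:, 0]  # 3x background RMS
        osc[hubs, :n_on] += amp[hubs, None] * burst[None, :]

    return osc + spec.noise_sd * rng.standard_normal((n, t_samples))


def simulate_patient(
    spec: SimulationSpec,
    patient_id: str = "sim000",
    engel_class: str = "IA",
    resected: np.ndarray | None = None,
    soz: np.ndarray | None = None,
    age_at_surgery: float = 12.0,
    sex: str = "F",
    laterality: str = "L",
    states=STATES,
) -> PatientRecord:
    """Generate one synthetic patient from a :class:`SimulationSpec`.

    By default the resection coincides with the planted hub set (the
    good-outcome construction) and the seizure-onset zone is the first half
    of the hubs; pass explicit ``resected`` / ``soz`` masks to override.
    ``states`` restricts which epochs are synthesized (seeding is per state,
    so a subset reproduces the corresponding epochs of the full record).
    """
    rng = np.random.default_rng([int(spec.rng_seed), 0xC0FFEE])
    channels = _make_channels(spec, rng)
    hubs = np.zeros(spec.n_channels, bool)
    hubs[list(spec.hub_set)] = True
    if resected is None:
        resected = hubs.copy()
    if soz is None:
        soz = np.zeros(spec.n_channels, bool)
        soz[list(spec.hub_set[: max(1, len(spec.hub_set) // 2)])] = True
    temporal = np.arange(spec.n_channels) < spec.n_channels // 2
    channels = [
        replace(
            ch,
            resected=bool(resected[i]),
            in_soz=bool(soz[i]),
            propagating=bool(hubs[i]),
            temporal_lobe=bool(temporal[i]),
        )
        for i, ch in enumerate(channels)
    ]
    wanted = {State(s) for s in states}
    epochs = {
        state: StateEpoch(
            state, _simulate_state(spec, state, [int(spec.rng_seed), k + 1]), spec.fs
        )
        for k, state in enumerate(STATES)
        if state in wanted
    }
    return PatientRecord(
        patient_id=patient_id,
        channels=channels,
        epochs=epochs,
        engel_class=engel_class,
        onset_type=spec.onset_type,
        age_at_surgery=age_at_surgery,
        sex=sex,
        laterality=laterality,
    )


_GOOD_ENGEL = ("IA", "IB", "IC")
_POOR_ENGEL = ("IIA", "IIB", "IIIA", "IVB")


def _displaced_resection(spec: SimulationSpec, rng) -> np.ndarray:
    """Poor-outcome resection: same size as the hub set but covering at most
    25% of the hubs; the remainder falls on non-hub channels."""
    n = spec.n_channels
    hubs = list(spec.hub_set)
    non_hubs = [i for i in range(n) if i not in spec.hub_set]
    n_res = len(hubs)
    n_hub_in = min(len(hubs), int(math.floor(0.25 * len(hubs))))
    chosen = list(rng.choice(hubs, size=n_hub_in, replace=False)) if n_hub_in else []
    n_fill = min(n_res - n_hub_in, len(non_hubs))
    chosen += list(rng.choice(non_hubs, size=n_fill, replace=False))
    mask = np.zeros(n, bool)
    mask[np.asarray(chosen, int)] = True
    return mask


def simulate_cohort(
    n_good: int,
    n_poor: int,
    template: SimulationSpec | None = None,
    rng_seed: int = 0,
    onset_types: tuple[str, ...] | None = None,
    states=STATES,
) -> Cohort:
    """Cohort with planted outcome structure.

    Good-outcome patients have their hubs inside the resection; poor-outcome
    patients have the resection displaced so at most 25% of hubs are resected.
    """
    if n_good < 0 or n_poor < 0 or n_good + n_poor < 2:
        raise ValueError("need n_good + n_poor >= 2 with nonnegative counts")
    template = template or hub_study_spec()
    rng = np.random.default_rng([int(rng_seed), 0xBEEF])
    patients = []
    outcomes = ["good"] * n_good + ["poor"] * n_poor
    for k, outcome in enumerate(outcomes):
        child_seed = int(rng.integers(0, 2**31 - 1))
        onset = (
            onset_types[k % len(onset_types)] if onset_types else template.onset_type
        )
        spec = replace(template, rng_seed=child_seed, onset_type=onset)
        if outcome == "good":
            resected = None  # hubs inside resection
            engel = _GOOD_ENGEL[k % len(_GOOD_ENGEL)]
        else:
            resected = _displaced_resection(spec, rng)
            engel = _POOR_ENGEL[k % len(_POOR_ENGEL)]
        patients.append(
            simulate_patient(
                spec,
                patient_id=f"sim{k:03d}",
                engel_class=engel,
                resected=resected,
                age_at_surgery=float(np.round(rng.uniform(2, 22), 1)),
                sex="F" if rng.random() < 0.5 else "M",
                laterality=str(rng.choice(["L", "R", "LR"], p=[0.7, 0.2, 0.1])),
                states=states,
            )
        )
    return Cohort(patients)


def simulate_null_cohort(
    n_patients: int,
    n_channels: int = 20,
    rng_seed: int = 0,
    resected_fraction: float = 0.3,
    geometry: str = "grid",
    states=STATES,
) -> Cohort:
    """Cohort with no planted coupling and resection labels assigned at random
    (type-I / null-calibration conditions)."""
    rng = np.random.default_rng([int(rng_seed), 0xA0])
    gains = {s: 0.0 for s in STATES}
    patients = []
    for k in range(n_patients):
        spec = SimulationSpec(
            n_channels=n_channels,
            geometry=geometry,
            hub_set=(0,),
            coupling_gain=gains,
            background_coupling=0.0,
            spike_rate=0.0,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        n_res = max(1, int(round(resected_fraction * n_channels)))
        resected = np.zeros(n_channels, bool)
        resected[rng.choice(n_channels, size=n_res, replace=False)] = True
        patients.append(
            simulate_patient(
                spec,
                patient_id=f"null{k:03d}",
                resected=resected,
                soz=resected.copy(),
                age_at_surgery=float(np.round(rng.uniform(2, 22), 1)),
                sex="F" if rng.random() < 0.5 else "M",
                states=states,
            )
        )
    return Cohort(patients)


def hub_study_spec(
    n_channels: int = 20, n_hubs: int = 6, rng_seed: int = 0, **overrides
) -> SimulationSpec:
    """Template with a localized minority hub set (subdural grid geometry):
    the conditions for hub-recovery (ROC) and outcome-prediction studies."""
    return SimulationSpec(
        n_channels=n_channels,
        geometry="grid",
        hub_set=tuple(range(n_hubs)),
        rng_seed=rng_seed,
        **overrides,
    )


def state_study_spec(n_channels: int = 12, rng_seed: int = 0, **overrides) -> SimulationSpec:
    """Template with uniform coupling across all channels, emulating the
    global synchronization rise of peri-ictal states: the conditions for the
    state-discrimination study (every channel belongs to the coupled set, and
    deep envelope modulation saturates the wide-band edges so the
    max-normalized median strength rises with the state gain)."""
    overrides.setdefault("envelope_mod_depth", 1.5)
    return SimulationSpec(
        n_channels=n_channels,
        geometry="grid",
        hub_set=tuple(range(n_channels)),
        rng_seed=rng_seed,
        **overrides,
    )
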