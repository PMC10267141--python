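"""Undirected functional-connectivity measures and nodal strength.

Three measures are computed per 3-s segment and frequency band from the
analytic (Hilbert) representation of the band-filtered signals:

* AEC  — absolute Pearson correlation of the amplitude envelopes;
* oAEC — AEC after instantaneous pairwise orthogonalization (each signal's
  analytic representation is stripped of the component collinear with the
  other's unit phasor), averaged over both directions; suppresses zero-lag
  common-source (volume-conduction) coupling;
* PLV  — modulus of the time-averaged unit phasor of the instantaneous
  phase difference.

Per-segment matrices are arithmetically averaged across the 20 segments of a
state epoch.  Within-shaft depth-electrode edges are normalized by the edge
of the most distant contact pair of the same shaft, and each node's strength
is the median of its edges, max-normalized per patient/state/band.

The first and last 10% of each segment are discarded before computing
statistics to suppress Hilbert edge artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.signal

from .cohort import ChannelInfo, ElectrodeType, State
from .config import Band
from .preprocessing import SegmentSet, band_filter

__all__ = [
    "MEASURES",
    "FCMatrix",
    "NodalStrengthVector",
    "plv_pair",
    "aec_pair",
    "oaec_pair",
    "fc_state",
    "fc_matrices",
    "distance_normalize",
    "nodal_strength",
    "patient_median_strength",
]

MEASURES = ("AEC", "oAEC", "PLV")

DEFAULT_EDGE_TRIM = 0.1

# orthogonalized residual below this fraction of the source envelope is
# numerically indistinguishable from full collinearity
_COLLINEAR_TOL = 1e-7


@dataclass
class FCMatrix:
    """N x N symmetric connectivity matrix; diagonal stored as NaN."""

    values: np.ndarray
    measure: str
    band: str = ""
    state: Optional[State] = None
    patient_id: str = ""
    n_segments_averaged: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] < 2:
            raise ValueError("FC matrix must be square with N >= 2")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.allclose(v[off], v.T[off], atol=0, rtol=0, equal_nan=True):
            raise ValueError("FC matrix must be symmetric")
        vals = v[off]
        if np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12:
            raise ValueError("FC values must lie in [0, 1]")
        np.fill_diagonal(v, np.nan)
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class NodalStrengthVector:
    """Per-channel hub score: median of the node's edges, optionally
    max-normalized per patient/state/band."""

    values: np.ndarray
    measure: str
    band: str = ""
    state: Optional[State] = None
    patient_id: str = ""
    normalized: bool = False


def _analytic(x: np.ndarray, trim_fraction: float) -> np.ndarray:
    z = scipy.signal.hilbert(np.asarray(x, float), axis=-1)
    k = int(round(trim_fraction * z.shape[-1]))
    return z[..., k : z.shape[-1] - k] if k else z


def _maybe_filter(x, y, band, fs):
    if band is not None:
        if fs is None:
            raise ValueError("fs is required when a band is given")
        x = band_filter(x, band, fs)
        y = band_filter(y, band, fs)
    return np.asarray(x, float), np.asarray(y, float)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def plv_pair(x, y, band=None, fs=None, trim_fraction=DEFAULT_EDGE_TRIM) -> float:
    """Phase locking value: |mean phasor of the instantaneous phase difference|.

    Robust to amplitude fluctuations; 1 for a constant phase lag, ~0 for
    independent phases.  A constant input has undefined phase and returns 0
    with a warning.
    """
    x, y = _maybe_filter(x, y, band, fs)
    zx, zy = _analytic(x, trim_fraction), _analytic(y, trim_fraction)
    ax, ay = np.abs(zx), np.abs(zy)
    if np.all(ax == 0) or np.all(ay == 0):
        warnings.warn("constant signal: phase undefined, returning PLV = 0")
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(ax > 0, zx / ax, 0)
        uy = np.where(ay > 0, zy / ay, 0)
    return float(np.abs(np.mean(ux * np.conj(uy))))


def aec_pair(x, y, band=None, fs=None, trim_fraction=DEFAULT_EDGE_TRIM) -> float:
    """Amplitude envelope correlation: |Pearson r| of analytic-signal envelopes."""
    x, y = _maybe_filter(x, y, band, fs)
    ex = np.abs(_analytic(x, trim_fraction))
    ey = np.abs(_analytic(y, trim_fraction))
    r = _pearson(ex, ey)
    if np.isnan(r):
        warnings.warn("zero-variance envelope: returning AEC = 0")
        return 0.0
    return abs(r)


def oaec_pair(x, y, band=None, fs=None, trim_fraction=DEFAULT_EDGE_TRIM) -> float:
    """Orthogonalized AEC.

    Each analytic signal is orthogonalized instantaneously against the other
    (removing the component collinear with the other's unit phasor), the
    residual envelope is correlated with the other signal's envelope, the two
    directions are averaged, and the absolute value is returned.  Identical
    (or merely rescaled) inputs orthogonalize to nothing and give 0.
    """
    x, y = _maybe_filter(x, y, band, fs)
    zx, zy = _analytic(x, trim_fraction), _analytic(y, trim_fraction)
    ex, ey = np.abs(zx), np.abs(zy)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(ex > 0, zx / ex, 0)
        uy = np.where(ey > 0, zy / ey, 0)
    env_y_perp_x = np.abs(np.imag(zy * np.conj(ux)))
    env_x_perp_y = np.abs(np.imag(zx * np.conj(uy)))

    def _residual_corr(env_perp, env_own, env_other):
        # a residual at float-noise level means full collinearity: exactly 0
        if np.sqrt(np.mean(env_perp**2)) < _COLLINEAR_TOL * np.sqrt(np.mean(env_own**2)):
            return 0.0
        return _pearson(env_perp, env_other)

    r1 = _residual_corr(env_y_perp_x, ey, ex)
    r2 = _residual_corr(env_x_perp_y, ex, ey)
    rs = [r for r in (r1, r2) if not np.isnan(r)]
    if not rs:
        return 0.0
    return abs(float(np.mean(rs)))


def _segment_matrices(seg: np.ndarray, measures: Sequence[str], trim: float):
    """All-pairs FC matrices for one segment, sharing one analytic transform."""
    z = _analytic(seg, trim)
    n, t = z.shape
    env = np.abs(z)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(env > 0, z / env, 0)
    out = {}
    if "AEC" in measures:
        sd = env.std(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            c = np.corrcoef(env)
        c = np.abs(np.nan_to_num(c, nan=0.0))
        c[sd == 0, :] = 0.0
        c[:, sd == 0] = 0.0
        out["AEC"] = np.clip(c, 0, 1)
    if "PLV" in measures:
        p = np.abs(u @ u.conj().T) / t
        out["PLV"] = np.clip(p, 0, 1)
    if "oAEC" in measures:
        ec = env - env.mean(axis=1, keepdims=True)
        enorm = np.linalg.norm(ec, axis=1)
        erms = np.sqrt(np.mean(env**2, axis=1))
        r = np.zeros((n, n))
        for i in range(n):
            if enorm[i] == 0:
                continue
            b = np.abs(np.imag(z * np.conj(u[i])))  # every channel orthogonalized vs i
            collinear = np.sqrt(np.mean(b**2, axis=1)) < _COLLINEAR_TOL * erms
            bc = b - b.mean(axis=1, keepdims=True)
            bnorm = np.linalg.norm(bc, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r[i] = (bc @ ec[i]) / (bnorm * enorm[i])
            r[i, (bnorm == 0) | collinear] = 0.0
        r[np.arange(n), np.arange(n)] = 0.0
        out["oAEC"] = np.clip(np.abs((r + r.T) / 2.0), 0, 1)
    return out


def fc_matrices(
    segset: SegmentSet,
    measures: Iterable[str] = MEASURES,
    trim_fraction: float = DEFAULT_EDGE_TRIM,
    patient_id: str = "",
) -> dict[str, FCMatrix]:
    """Segment-averaged FC matrices for several measures in one pass."""
    measures = tuple(measures)
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown FC measure(s): {sorted(unknown)}")
    if segset.segments[0].shape[0] < 2:
        raise ValueError("connectivity requires >= 2 channels")
    sums = {m: None for m in measures}
    for seg in segset.segments:
        mats = _segment_matrices(seg, measures, trim_fraction)
        for m in measures:
            sums[m] = mats[m] if sums[m] is None else sums[m] + mats[m]
    n_seg = segset.n_segments
    out = {}
    for m in measures:
        v = sums[m] / n_seg
        v = (v + v.T) / 2.0  # enforce exact symmetry against float noise
        out[m] = FCMatrix(
            values=v,
            measure=m,
            band=segset.band,
            state=segset.state,
            patient_id=patient_id,
            n_segments_averaged=n_seg,
        )
    return out


def fc_state(
    segset: SegmentSet,
    measure: str,
    band: Band | None = None,
    fs: float | None = None,
    trim_fraction: float = DEFAULT_EDGE_TRIM,
    patient_id: str = "",
) -> FCMatrix:
    """Segment-averaged FC matrix for one measure.

    If ``band`` is given, each segment is band-filtered first (the pipeline
    normally filters whole epochs before segmentation instead).
    """
    if band is not None:
        segset = SegmentSet(
            segments=[band_filter(s, band, fs or segset.fs) for s in segset.segments],
            band=band.name,
            state=segset.state,
            fs=segset.fs,
        )
    return fc_matrices(segset, (measure,), trim_fraction, patient_id)[measure]


def distance_normalize(fc: FCMatrix, channels: Sequence[ChannelInfo]) -> FCMatrix:
    """Depth-electrode spatial-sampling control.

    For every depth shaft, the within-shaft edges are divided by the FC value
    of the shaft's most distant contact pair (capped at 1).  Edges involving
    subdural contacts or spanning different shafts are unchanged.
    """
    if len(channels) != fc.n_channels:
        raise ValueError("channel metadata does not match FC matrix size")
    v = fc.values.copy()
    shafts: dict[str, list[int]] = {}
    for i, c in enumerate(channels):
        if c.electrode_type is ElectrodeType.DEPTH and c.shaft_id:
            shafts.setdefault(c.shaft_id, []).append(i)
    for shaft_id, idx in shafts.items():
        if len(idx) < 2:
            continue
        coords = np.array([channels[i].coordinates for i in idx])
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        a, b = np.unravel_index(np.argmax(d), d.shape)
        ref = v[idx[a], idx[b]]
        if not np.isfinite(ref) or ref <= 0:
            warnings.warn(
                f"shaft {shaft_id!r}: reference FC value is 0, left unnormalized"
            )
            continue
        sub = np.ix_(idx, idx)
        v[sub] = np.minimum(v[sub] / ref, 1.0)
    return replace(fc, values=v)


def nodal_strength(fc: FCMatrix, normalize: bool = True) -> NodalStrengthVector:
    """Median of each node's edges; optionally divided by the max across nodes."""
    if fc.n_channels < 2:
        raise ValueError("nodal strength requires N >= 2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        raw = np.nanmedian(fc.values, axis=1)
    raw = np.nan_to_num(raw, nan=0.0)
    if normalize:
        mx = raw.max()
        if mx > 0:
            raw = raw / mx
    return NodalStrengthVector(
        values=raw,
        measure=fc.measure,
        band=fc.band,
        state=fc.state,
        patient_id=fc.patient_id,
        normalized=normalize,
    )


def patient_median_strength(
    nsv: NodalStrengthVector, subset: np.ndarray | None = None
) -> float:
    """Median strength over a channel subset (boolean mask or index array)."""
    v = np.asarray(nsv.values, float)
    if subset is not None:
        v = v[np.asarray(subset)]
    if v.size == 0:
        raise ValueError("empty channel subset")
    return float(np.median(v))
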