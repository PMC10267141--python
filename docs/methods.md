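# Methods

This note documents the models, numerical choices and limitations behind
`ictalgraph`: what the pipeline computes, what the synthetic cohorts emulate,
and what passing tests do and do not establish about real recordings.

## Pipeline

### Preprocessing

Raw 60-s state epochs (≥ 500 Hz sampling) are band-pass filtered 1–100 Hz
and notch filtered at 60 Hz, both zero-phase: a 4th-order Butterworth
band-pass (applied forward–backward, so 8th-order magnitude response) and a
2nd-order IIR notch with Q = 30, with 1 s of reflection padding against edge
transients. Common average referencing (CAR) follows the broadband filters
and precedes per-band filtering; the notch is applied before CAR. Filter
*family* and order, the padding, and the notch/CAR order are package
choices — the analysis convention only fixes the cutoffs and that CAR is
applied to filtered data. Per-band signals are cut into 20 contiguous
non-overlapping 3-s segments whose concatenation reproduces the epoch.

### Connectivity measures

All three measures work on the analytic (Hilbert) signal of the
band-filtered segment. The first and last 10 % of each segment are dropped
before any statistic to suppress Hilbert edge artifacts; the brute-force
oracles in the test suite apply the same trim, so oracle equivalence is
checked on identical samples.

* AEC: absolute Pearson correlation of the envelopes. The absolute value
  folds negative envelope correlations so values lie in [0, 1].
* oAEC: each signal's analytic representation is orthogonalized
  instantaneously against the other's unit phasor; the residual envelope of
  one signal is correlated with the raw envelope of the other, the two
  directions are averaged and the absolute value taken. A residual whose RMS
  is below 1e−7 of the source envelope is treated as exact collinearity and
  contributes a correlation of 0 — this makes oAEC(x, x) and
  oAEC(x, a·x) exactly 0 instead of float-noise junk.
* PLV: modulus of the time-averaged unit phasor of the phase difference.
  Constant signals have undefined phase; the pair value is defined as 0 with
  a warning.

Higher values mean stronger connectivity throughout. Per-segment matrices
are arithmetically averaged across the 20 segments; node reduction then uses
the median of each node's edges. Degenerate zero-variance channels yield 0
edges with a warning.

### Distance normalization

Within each depth shaft the contact pair with maximal Euclidean distance is
the reference; every within-shaft edge is divided by the reference pair's FC
and capped at 1. Cross-shaft, subdural–subdural and subdural–depth edges are
untouched, as are patients without depth electrodes. Only within-shaft edges
are normalized, and normalization precedes nodal-strength computation and
max-normalization; both orderings were open choices and are fixed here.
Note a consequence relevant to synthetic data: when within-shaft edges are
noise-dominated, most of them exceed the most-distant-pair reference and the
cap drives them to 1, erasing within-shaft contrast. Real recordings, whose
FC decays with distance, are less affected; the synthetic hub-recovery
studies therefore use grid (subdural) geometry.

### Nodal strength and cohort statistics

Node strength = median of the node's N−1 edges, divided by the maximum over
nodes per patient, state, band and measure (so each vector's max is 1).
Cross-state comparisons use per-patient medians of these normalized
strengths (paired two-sided Wilcoxon signed-rank), with Benjamini–Hochberg
FDR applied jointly over the 10 state pairs × 6 bands per measure (60
tests); the family definition is a package choice. Percent differences
compare cohort medians of the per-patient values, second state as reference;
the formula behind published percentage magnitudes for such contrasts is not
standardized, so these values are descriptive. The signed-rank test drops
zero differences (Wilcoxon's convention), uses the exact null for n ≤ 25
without ties and a continuity-corrected normal approximation otherwise;
all-zero differences define p = 1 with a warning.

Region-level "between" vs "within" connectivity is computed from depth
contacts only: per region (default grouping: the per-channel region label),
between = median of edges leaving the region, within = median of edges
inside it (undefined below 2 contacts); a region is epileptogenic when more
than half its contacts were resected.

### Node classification and outcome prediction

Electrode-level ROC pools (strength, resected) pairs across good-outcome
patients — pooling, not per-patient averaging, matches the framing of
distinguishing epileptogenic from non-epileptogenic electrodes. Prediction
at threshold t is strength ≥ t (inclusive, a package choice) over the 0–1
grid in 0.1 steps; AUC is trapezoidal over the grid's operating points with
(0,0) and (1,1) appended, and a finer grid is available via the `thresholds`
argument (with a fine grid the trapezoid converges to the Mann–Whitney rank
AUC, which is what the invariance-under-monotone-transform test checks).
Youden-tie-breaks take the lowest threshold.

Outcome prediction defines hubs as contacts with normalized strength
strictly above the connectivity threshold (taken per measure/band/state from
that combination's ROC max-J point; a single user-supplied threshold is also
accepted). Per patient, overlap = 100 × |hubs ∩ resected| / |resected|;
patients with no resected contacts are excluded, not imputed. "Resected
zone" at an overlap threshold is *strictly greater*, per the analysis
convention. The patient-level 2×2 table is tested two-sided Fisher exact;
PPV/NPV/accuracy come from the stored contingency.

### Onset classification

Welch spectra (1-s Hann windows, 50 % overlap) of the ±5 s window around
electrographic onset are compared to a 60-s interictal baseline per channel,
as log-ratios of band-group power (slow = θ+α 5–12 Hz; fast = β+γ 15–90 Hz).
The *onset channel* is the one with the largest baseline-relative increase
in either group; the seizure's fast score is that channel's fast-minus-slow
log-ratio and the call is FSO iff positive. Anchoring on the onset channel
matters: a plain channel-maximum of the difference lets off-focus channels
with near-zero spectral change outvote a focal slow onset through noise
alone (pilot simulations misclassified ~40 % of slow onsets that way).
Scores within ±0.1 carry a low-confidence flag. Patient calls are majority
votes over seizures; ties go to the side with larger mean |score|. The
window length and band groups are configurable; the procedure is a
quantitative surrogate for what is clinically a visual judgement.

## Synthetic cohorts

The generator produces per-patient 60-s epochs of the five states at 500 Hz
over realistic geometries (8×8-style subdural grids at 10 mm pitch;
10-contact depth shafts at 3–5 mm pitch). Each channel sums six band-limited
stochastic oscillators (filtered white noise, band RMS amplitudes 20, 15,
12, 8, 5, 3 µV from δ to high-γ) plus independent Gaussian sensor noise
(default 5 µV). Coupling has two planted mechanisms, both scaled per state
by the coupling gain (defaults 0.1, 0.2, 0.35, 0.6, 1.0 from
interictal-no-spikes to ictal, encoding the epileptogenic hierarchy):

* a shared additive source per band, mixed with weight c into each coupled
  channel (hub channels at full weight, others at `background_coupling`,
  default 0.5; mixing capped at 0.95), driving phase locking and envelope
  correlation;
* a shared slow envelope modulator multiplying the summed oscillation,
  weight proportional to c (depth 0.6 per unit weight by default). The
  modulator band is 1–6 Hz: a sub-0.5 Hz modulator is nearly constant within
  a 3-s segment and therefore invisible to per-segment envelope correlation,
  so slower "co-modulation" would not couple anything this pipeline
  measures. Being multiplicative, this coupling survives both CAR and
  instantaneous orthogonalization — it is what gives oAEC its planted
  structure, since the purely additive shared source is largely removed by
  orthogonalization (and, at uniform weights, by CAR).

The "spikes" epoch adds shared biphasic 70-ms transients at 5× background SD
on hub channels (default 60/min; at the fixed amplitude, lower rates add
under 2 % broadband RMS and would be undetectable). The ictal epoch opens
with 10 s of onset rhythm on hub channels at 3× background RMS — 6 Hz for
slow (SSO), 40 Hz for fast (FSO) onsets — with 1-s fades. All draws descend
from a single integer seed; epochs are bit-reproducible.

Two study templates freeze the conditions used by the verification suites:

* `hub_study_spec` — a minority hub set (6 of 20 contacts) on a subdural
  grid, for ROC hub recovery and outcome prediction. Cohorts built from it
  give good-outcome patients a resection equal to the hub set and
  poor-outcome patients a displaced resection covering ≤ 25 % of hubs, with
  the SOZ flag on half the hubs.
* `state_study_spec` — *uniform* coupling (every channel in the coupled
  set) with deeper envelope modulation (1.5), for state discrimination.
  The uniformity is deliberate: because strengths are max-normalized per
  state, a minority hub set makes the strength distribution more
  heterogeneous as coupling rises and the normalized median *falls*; the
  cross-state rise of the normalized median is a signature of global
  synchronization saturating the wide-band edges, which is what peri-ictal
  hypersynchronization looks like at the whole-implant scale. Only the
  wide bands (β, low/high-γ) can carry this effect: for narrow low bands the
  3-s envelope has too few degrees of freedom, and modulation sidebands fall
  outside the band.

What the generator does *not* emulate: 1/f-continuum spectra, nonstationary
interictal dynamics, seizure evolution/propagation beyond the onset burst,
distance-dependent FC decay, volume-conduction mixing matrices, artifacts
beyond Gaussian noise, or any biophysical (neural-mass) dynamics. Passing
recovery tests therefore shows the pipeline correctly extracts the kinds of
coupling structure it assumes — not that real iEEG satisfies those
assumptions. The interictal states differ only by spikes and gain, mirroring
how little their difference is otherwise specified.

## Verification conditions and problem sizes

The end-to-end suites run at sizes chosen to exercise the full pipeline in a
single-CPU session: hub recovery pools 12 good-outcome patients × 20
contacts (ictal state, all measures and bands; best-band AUC ≥ 0.9 per
measure); chance level uses 25 null patients × 80 contacts (2000 pooled
electrodes, AUC within [0.4, 0.6]); state discrimination runs 10 seeded
cohorts of 20 patients × 12 channels (ictal vs pre-ictal flagged with FDR
p < 0.05 and positive difference in ≥ 9/10); outcome prediction uses a
6-good/6-poor cohort (perfect alignment recovers J = 1, PPV = NPV =
accuracy = 100 % and Fisher p = 2/C(12,6)); the onset classifier is scored
on 40 seeded seizures (≥ 95 % agreement). Type-I calibration runs 200
replicates per test against continuous exchangeable nulls — for rank
statistics the rejection law is distribution-free, so these realize exactly
the same null as no-effect generator runs at a fraction of the cost — and
uses 500-per-group Fisher margins, where the discrete achievable size
(~0.046) is near-nominal; at small margins Fisher's conservatism would put
its rejection rate below any band centred on 0.05 by construction.

Null-connectivity floors are band-dependent: the envelope of 2–4 Hz noise
has ~6 effective samples per trimmed 3-s segment, so |Pearson r| of truly
independent delta envelopes averages ≈ 0.3, while β/γ floors sit below 0.15.
Tests freeze these simulated floors per band rather than a single number.

## Known limitations

* Undirected measures only; no directed/propagation analysis.
* Nodal strength is the only graph reduction; the max-normalization makes
  cross-state contrasts sensitive to distribution shape, not absolute level.
* The distance-normalization cap can saturate within-shaft edges when FC
  does not decay with distance (see above).
* EDF is read (via `mne`, if installed) but not written; the native format
  is plain text matrices + TSV metadata.
* Engel-class subtypes beyond the I/II–IV dichotomy are stored but not
  modeled.
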