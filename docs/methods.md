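# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `ecogstate`, and what the synthetic-data tests do and do
not establish about real recordings.

## Pipeline model and assumptions

The pipeline treats consciousness-level estimation as unsupervised
two-state soft clustering of windowed signal features. The working
hypotheses, inherited from the resting-state literature the feature set
comes from, are: an activated cortex shows (i) more θ and β band power,
(ii) more irregular dynamics (higher Poincaré SD1/SD2 and Lempel–Ziv
complexity), and (iii) more genuinely lagged cross-channel coupling in the
θ band (imaginary coherency, wSMI). None of these is individually
reliable; the design premise is that fusing all seven raises the
probability of catching a state change that any single feature misses.
No artefact removal beyond amplitude-based channel rejection is performed:
the target population cannot produce movement artefacts, and interpolation
would distort the connectivity measures.

Key structural assumptions:

- **Two states.** The clustering is fixed at two components. A recording
  that spans only one state makes the fitted partition arbitrary — both
  clusters then describe the same state and the membership trace hovers
  near 0.5. The pre-defined-centroid mode exists for exactly that case:
  centres fitted elsewhere (e.g. on a reference dataset via
  `fit_reference_model`, persisted with `save_reference_model`) are applied
  without refitting.
- **Offline analysis.** Min–max normalization and clustering see the whole
  recording; there is no streaming mode.
- **Windows never span files.** One-hour files are windowed independently
  (3-s windows, 1-s stride → 3598 per hour, 86,352 per 24 h); timestamps
  are absolute wall-clock times so interval summaries ("day" 08:00–20:00,
  "night" otherwise) resolve against the first file's start time.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| band-pass | 0.5–45 Hz, order 3, zero-phase | the features are defined on this band; zero-phase (forward–backward) application avoids phase distortion that would bias imaginary coherency; effective attenuation is the squared magnitude response |
| amplitude threshold | 200 (header units) | channels whose peak absolute value over the whole recording exceeds it are dropped; the criterion is peak-based because transient saturation invalidates a channel throughout |
| window / stride | 3 s / 1 s | short enough for quasi-stationarity, 2/3 overlap smooths the trace |
| θ, β, total bands | 0–4, 12–30, 0–45 Hz | θ deliberately spans the slow end (not the classical 4–8 Hz); bands are config-driven (`BandDefinition`), so the conventional definition is one edit away |
| Welch | Hamming, 1/8-segment sub-windows, 50% overlap, density scaling, no detrend | band *ratios* are scale-invariant, so density vs. power normalization is immaterial; band sums are edge-inclusive; SEF is grid-exact (first crossing bin, ties to the lower frequency, no interpolation) |
| Poincaré τ | ¼ × dominant cycle period, global per recording | a single global lag keeps ERR comparable across windows; per-window τ would conflate rhythm shifts with geometry changes |
| LZC binarization | per-window median split | parameter-free and the dominant convention; normalized form c(n)·log₂n/n removes the length dependence |
| wSMI | k = 3, τ = 8 samples at 200 Hz | 3! = 6 symbols; the (k−1)τ = 80 ms pattern span targets slow/θ-range structure; signals are resampled 500→200 Hz (polyphase, rational 2/5) before symbolization |
| wSMI weights | 0 for identical and sign-opposite patterns, 1 otherwise | discards coupling explainable by a single common source seen twice |
| clustering | N = 2, fuzzifier m = 2, tol 1e-5, ≤1000 iterations, full covariances, reg 1e-6 | FCM starts from a seeded random membership matrix; the GMM uses k-means++ seeding from the same seed; both are deterministic given the seed |

## Numerical conventions and degenerate inputs

- **Dominant period.** The PSD argmax of a noisy periodogram wanders, so
  the estimate caps the Welch sub-window at 4 s (coarse, heavily averaged
  grid) and refines the peak by the power centroid of the octave around
  the argmax. Flat or constant spectra fall back to a configured default
  period with a logged warning.
- **ERR.** A finite-sample negative SD2 radicand is clamped to zero with a
  warning; a constant window (SD2 = 0) is an error, not a silent zero.
  ERR is invariant to amplitude scaling and offset.
- **wSMI.** Joint probabilities come from raw co-occurrence counts without
  smoothing; empty cells contribute 0 (0·log 0 := 0); natural logs with
  the 1/log k! prefactor in the same base. Degenerate single-symbol
  windows return 0 with a warning rather than killing a long run.
- **iCOH.** The θ-band reduction is the unweighted mean of |Im Cxy| over
  in-band Welch bins. Note the DC bin's imaginary part is identically
  zero, so at 3-s windows (two in-band bins) the feature's ceiling is ~0.5.
- **Conscious-cluster rule.** The cluster whose centroid has the larger
  mean over normalized coordinates is "conscious"; an exact tie breaks on
  the Pβ coordinate, and a tie on both is reported as a degenerate
  clustering error.
- **Missing windows.** A feature that fails in one window (e.g. a flat
  channel) yields NaN and is imputed by carrying the previous window's
  value (leading gaps backfilled), logged.
- **Determinism.** Identical inputs, configuration and seed reproduce
  byte-identical trace CSVs; this is tested.

## The synthetic generator

`ecogstate.synthetic` emulates the acquisition geometry the pipeline
targets (64 channels, 500 Hz, consecutive one-hour files; desk-scale tests
shrink geometry but never the contrast profiles) and plants a two-state
schedule. Every channel carries unit-calibrated 1/f background noise
(RMS 0.5). Conscious epochs add, per channel, 2–3.5 Hz oscillatory noise
(gain 2.2), an 18–22 Hz β oscillation (gain 1.1), independent white noise
(gain 1.2), and a *shared* θ-band source received with a per-channel lag
of 20 ms × channel index (gain 0.8) — lagged sharing is what drives
imaginary coherency and wSMI, both of which ignore zero-lag coupling.
Unconscious epochs add shared zero-lag 0.5–1.5 Hz slow waves (gain 0.6)
and a shared broadband 4.5–11.5 Hz mid-band hump (gain 0.7).

These amplitudes were chosen once so that the construction documented
above holds: conscious windows exceed unconscious ones in expectation on
all seven features. The choice is genuinely constrained — the θ band
starts at 0 Hz, so unconscious slow waves land *inside* it, and strong
slow waves would invert the Pθ contrast, while a purely low-frequency
unconscious spectrum would invert it the other way through the spectral
edge. The broadband (rather than narrow-spindle) mid-band hump matters for
ERR: a narrowband component's autocorrelation at the calibrated Poincaré
lag swings with its phase and can make the unconscious cloud round; a
broadband hump's autocorrelation there is negligible, leaving the slow
waves to elongate it.

What the generator does **not** model: biophysical sources and volume
conduction, electrode geometry, non-stationary artefacts, sleep
architecture, medication effects, or the auditory question paradigm.
Passing the end-to-end test therefore shows that the pipeline recovers a
planted contrast of the kind its features are designed for — it does not
certify performance on clinical recordings, where state contrasts are far
weaker (clinical membership traces hover near 0.4–0.5, not 0.98/0.04 as on
the fixture) and the two-cluster assumption itself may fail.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on single windows and small matrices. The
end-to-end fixture is 2 files × 10 min × 8 channels with 120-s alternating
planted states (1196 windows); 8 channels keep the pairwise-connectivity
cost proportionate at desk scale, and no checked quantity depends on the
channel count except the rejection test, which runs at the full 64
channels. The segmentation arithmetic is verified on 24 freshly generated
one-hour single-channel files (windowed for real, cross-checked against
the closed-form count). The fuzzy-c-means implementation is the package's
own (Bezdek alternating updates); the Gaussian mixture leg delegates to
scikit-learn, and tests check both against closed-form limits
(coincident/equidistant points, posterior at a component mean, parameter
recovery within three standard errors on simulated mixtures).

## Known limitations

- The pre-defined-centroid mode ships without clinical reference centres
  (none are publicly available); `fit_reference_model` fits and persists
  centres from data the user supplies or from the synthetic reference.
- FCM on a recording without state contrast yields uninformative ~0.5
  memberships by construction; detect this via the degenerate-clustering
  error or near-constant traces before trusting interval summaries.
- No threshold is provided for declaring "conscious" vs "unconscious";
  the output is a relative membership trace, and absolute calibration is
  deliberately left to per-patient context.
- EDF reading is best-effort via mne; the canonical on-disk fixture format
  is raw float32 + JSON sidecar (`save_raw`/`load_raw`), and EDF writing
  is out of scope.
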