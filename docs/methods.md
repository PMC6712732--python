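# Methods

## The signal model

A triaxial magnetometer rigidly mounted on a neck collar measures the
projection of the local geomagnetic field vector **B** onto the sensor's
roll, pitch and yaw axes. **B** is constant in the Earth frame over a
recording session, so — unlike an accelerometer — the magnetometer
responds only to *orientation*: a perfectly still collar produces a
perfectly still signal, and with noiseless, calibrated hardware every
sample lies on a sphere of radius |**B**|.

Write δ for the dip (inclination) angle of the field and α for the
animal's heading (azimuth) from magnetic North. Three geometric facts
drive the whole method:

* roll axis pointing straight up (bipedal vigilance posture):
  `m_roll = +|B| sin δ`;
* roll axis pointing straight down (curled-up resting):
  `m_roll = −|B| sin δ`;
* roll axis horizontal (foraging, running):
  `m_roll = |B| cos δ cos α`, confounded by the arbitrary heading α and
  spanning `[−|B| cos δ, +|B| cos δ]`.

The default field model is the Kalahari study site: |**B**| = 27.3 μT,
δ = 65° pointing upward, declination 17.9° W (so ±24.74 μT for the two
vertical postures and ±11.54 μT for the horizontal band). Time
differentiation of the measured components is proportional to the rate
of change of the angles the field subtends on the sensor axes, i.e. a
magnetometer-derived angular-velocity proxy — the basis of the movement
intensity features.

## The synthetic-data generator

`magbehave.simulate` is a forward model: an orientation trajectory
(elevation of the roll axis above the horizontal, azimuth, and collar
rotation about the neck axis) is built per behaviour bout, an orthonormal
sensor frame is constructed from those angles, and the field vector is
projected onto it; white Gaussian sensor noise (default 0.3 μT SD per
channel, ≈1% of the field magnitude — visible but not
separability-destroying) is added last. Because the frame is orthonormal,
noiseless samples preserve the field norm exactly.

Behaviour archetypes:

* **vigilance** — elevation 90° + Ornstein–Uhlenbeck (OU) tremor
  (SD 6°, correlation time 0.6 s);
* **resting** — elevation −90°, slower, smaller tremor (SD 5°, τ 1.5 s);
* **foraging** — aperiodic: elevation OU wander around the horizontal
  (SD 22°, τ 0.8 s) with the heading drifting as a random walk
  (40 deg/s scale) — the azimuthal confound is therefore present in the
  synthetic data;
* **running** — periodic: sinusoidal oscillation at a 3 Hz stride
  frequency, amplitude 22°. The literature this package draws on gives
  no stride frequency or angular-velocity numbers for small-mammal
  behaviours, so these are modelling choices: 3 Hz is plausible for
  small-mammal locomotion and sits safely below the 10 Hz analysis
  cut-off. The stride oscillation engages all three rotation angles
  (neck pitch, heading sway, collar swing about the neck axis) with the
  amplitude split drawn per bout from [0.3, 1]: collars physically swing
  about the neck with each stride and gait kinematics vary, so no single
  sensor axis carries the periodicity reliably — this is what makes the
  axis-averaged periodicity feature the robust choice, as observed on
  field data.

Per-individual variability: a uniform collar-rotation offset in
[0°, 360°), a log-normal intensity scaling (SD 0.15 in log space,
≈ ±16%), and a Gaussian elevation bias (SD 4°).

`make_study_dataset` reproduces the field study's structure: eleven
~30-minute sessions on ten individuals (sessions 4 and 7 on the same
animal), behaviour time budget foraging 56.2% / vigilance 38.2% /
resting 4.6% / running 1%, and no resting at all in sessions
{3, 4, 5, 8, 9, 10} — the structure that exercises the LOIO
session-discard rule. The real data's concentration of resting in the
first session is *not* emulated; resting's share is spread evenly over
the five sessions that contain it, which changes nothing downstream
except per-session resting counts. Bout durations are drawn uniformly
from behaviour-specific ranges (vigilance 6–40 s, resting 30–120 s,
foraging 10–60 s, running 3–8 s) and capped to meet the time budget.

What the generator does **not** emulate: quadrupedal vigilance and
belly-flat resting (intermediate postures that degrade posture-based
separation on real animals), collar impacts and transient artefacts,
calibration drift within a session (available separately through
`apply_sensor_distortion`), magnetic anomalies, and label noise from
imperfect video annotation. Passing tests therefore demonstrate that the
pipeline recovers the structure this model generates — near-ideal
postures and clean archetypes — not that field data would reach the same
accuracy.

## Calibration

Hard-iron (additive offset) and soft-iron (linear gain/cross-coupling)
distortion turn the field sphere into an ellipsoid. `magbehave` fits the
general quadric `sᵀM₀s + 2bᵀs + d = 0` by the SVD null vector of the
10-column design matrix, recentres it to `(s−o)ᵀM(s−o) = 1`, and uses
`gain = target_norm · M^{1/2}` (symmetric matrix square root), so
calibrated samples `gain·(s − offset)` lie on the target sphere. This is
a deliberate substitution of a standard least-squares ellipsoid fit for
the specific published calibration procedure used in the original field
protocol: downstream processing only requires calibrated, norm-stable
signals, not a particular algorithm. The fit refuses clouds that are
coplanar/collinear (singular-value ratio < 1e-6) or whose fitted quadric
is not an ellipsoid. The symmetric square root leaves an overall
rotation unresolved — unavoidable, since a rotated sphere is the same
sphere; recovery tests therefore check axis-aligned distortions, where
the symmetric solution is unique.

Calibrated output can target the local field magnitude in μT (default)
or unit norm; all nine features are scale-covariant (amplitude features
scale linearly, the normalised spectra are scale-invariant), so this
choice moves decision thresholds but not separability.

`norm_drift_diagnostic` screens a calibrated recording in blocks
(per-block median norm, default flag threshold 5% relative deviation):
start-of-session calibrations need not stay valid for hours, and the
diagnostic flags when they stop being so. No in-run recalibration is
attempted.

## Preprocessing

Defaults mirror the acquisition protocol: generation at 50 Hz/axis,
linear-interpolation resampling to 100 Hz/axis, a 4th-order Butterworth
low-pass at 10 Hz, and 2-s windows with 50% overlap (200 samples per
window at 100 Hz).

Numerical choices:

* The filter is a single forward (causal) pass — zero-phase filtering is
  not assumed; all features are phase-insensitive, and a `zero_phase`
  flag exists for sensitivity analysis. The filter is applied **once per
  recording**, before windowing, so individual windows carry no startup
  transient (only the first ~0.3 s of each recording does).
* Time differentiation is first differences × sampling rate; the
  derivative series is used at length N−1, with no re-padding — the
  consumers (mean of absolute values, DFT) do not require equal length,
  and inventing an endpoint would bias them.
* Window spans are half-open `[start, start + 2 s)`; a sample on a label
  boundary belongs to the *later* behaviour. Any window containing two
  distinct labels (or unlabelled samples) is a transition window and is
  excluded.

## Features

Nine candidates, three per biomechanical descriptor (see the README
table). Spectral features: each series is z-normalised (mean removed,
divided by its SD — the package's reading of "normalised", which makes
peak power a pure periodicity/shape measure; a zero-variance series
short-circuits to a zero spectrum), tapered with a Blackman-Harris
window, zero-padded by 100 samples per side, and transformed on a
U = 0.01 Hz grid (L = Fs/U = 10 000 evaluation frequencies); the feature
is the maximum squared coefficient over 0 < f ≤ Fs/2 (after mean
removal the DC bin is ≈ 0 and is excluded from the search).
Axis-averaged variants average the per-axis *power* spectra before the
maximum. Tapering is applied to the 200-sample segment *before*
padding — tapering a padded signal would smear the pad boundaries into
the taper; a config-visible deviation from a literal
pad-then-window reading of the protocol description.

The sample (n−1) standard deviation convention is used for `stdRoll`.

## Feature selection

Five univariate two-sample filter criteria: |Welch t|, symmetric
Gaussian Kullback–Leibler divergence, Gaussian Bhattacharyya distance,
|AUC − 0.5|, and the rank-sum |z|. The exact list used in the original
analysis is not fully specified, so this standard filter-family set is
the documented default. Posture is `meanRoll` by default (the only
posture candidate). The intensity winner is the majority winner across
criteria on the static-vs-dynamic task — the upstream node — which also
resolves any disagreement with the foraging-vs-running task; the
periodicity winner is the majority winner on foraging-vs-running. Ties
break by earliest win in the documented criterion order, then
lexicographically. On the default synthetic study dataset the selection
is `meanRoll` / `meanAbsDiffRoll` / `avgDiffFftPeakPower`, matching the
field-data outcome.

## Classifier

Three binary linear maximum-margin separators (hinge loss, C = 1 by
default) arranged as a tree: node 1 (posture + intensity) splits static
from dynamic on all windows; node 2 (posture) splits vigilance from
resting on static windows; node 3 (intensity + periodicity) splits
foraging from running on dynamic windows. Features are z-standardised
per node on training data only (margins are scale-sensitive; the
standardisation parameters are part of the stored model). Training uses
the deterministic SMO solver behind scikit-learn's
`SVC(kernel="linear")` with tolerance 1e-6 — identical data yields
identical weights. No class reweighting by default despite the 1:56
running:foraging imbalance, matching the apparent original setup; a
class-weight study remains possible by passing `C` per call and
reweighting externally.

## Evaluation

STRAT: stratified 10-fold cross-validation, the full pipeline
(standardisation + node training) refit per fold; fold confusion
matrices are **pooled** before aggregate metrics — stable for the ~1%
running class — with per-fold reports kept alongside (whether the
original tables pooled or averaged folds is unstated; pooling is this
package's documented choice). LOIO: sessions lacking any of the four
behaviours are discarded with a logged notice (they cannot train all
three nodes), all sessions of an individual are held out together,
and metrics are computed per held-out individual then summarised as
mean ± SD (sample convention) across individuals.

Zero-denominator metrics are NaN with a warning, never silent zeros.

## Problem sizes

The end-to-end tests and the acceptance script use the study-structured
dataset at its native scale: 11 sessions × 30 min at 50 Hz
(≈ 10⁶ raw samples, ≈ 18 000 retained windows), STRAT with k = 10 and
LOIO over the 5 usable sessions. The whole pipeline runs in well under
two minutes on one CPU; the spectral features are evaluated in chunked
batched FFTs (identical to the per-window path, which is asserted in the
tests).

## Known limitations

* The generator's archetypes are cleaner than field behaviour; reported
  synthetic accuracies (≈ 99–100%) exceed what the same pipeline
  achieves on real collar data and should be read as parameter-recovery
  checks, not field performance estimates.
* The ellipsoid calibration recovers soft iron only up to rotation
  (inherent to sphere-fitting), and no temperature or in-run drift
  compensation is attempted.
* No sequence-level smoothing of predictions (e.g. an HMM over window
  labels) and no probabilistic calibration of SVM scores.
* Recordings with dropouts must be split upstream; no gap-filling.
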