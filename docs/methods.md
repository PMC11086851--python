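# Methods

This note documents the models, algorithms and numerical choices behind
`spineflex`, and what its synthetic validation does and does not establish.

## Problem setting

Non-specific low back pain (NSLBP) is commonly managed by first classifying
the patient's movement presentation. Two phenotypes dominate among cases
with movement-related pain drivers: **movement impairment (MI)** — pain with
*restricted* spinal movement — and **motor control impairment (MCI)** — pain
with *unrestricted* movement but impaired control. Expert classification is
reliable but training-intensive. `spineflex` implements an automated
pipeline that phenotypes patients from an ordinary sagittal video of
repeated forward spine flexion: a pose estimator reduces each frame to three
landmarks (ankle, hip, neck), and everything downstream of those keypoint
trajectories is this package.

## Spine-flexion angle

For each frame, the flexion angle θ is the angle at the hip between the
hip→neck and hip→ankle segments, computed by the law of cosines over the
pairwise Euclidean distances hn (hip–neck), ah (ankle–hip), an (ankle–neck):

    θ = arccos((hn² + ah² − an²) / (2·hn·ah))

θ ≈ 180° in relaxed standing and falls toward 90° or below in deep flexion.
Because only distances enter, θ is invariant under similarity transforms and
reflections of the image plane, so raw pixel coordinates need no
calibration, and image y-down conventions need no correction. The arccos
argument is clamped to [−1, 1] against floating-point drift; coincident
hip/neck or ankle/hip points raise a degenerate-geometry error naming the
offending pair and frame.

The raw waveform is smoothed with a centered 30-frame moving average (1 s at
30 fps). At the edges the window shrinks to the available frames
(`min_periods=1`), preserving length and never widening the value range.
Note one consequence used throughout validation: a 1 s average attenuates a
raised-cosine flexion dip whose period is 2.5–3.5 s by several degrees
(growing with dip amplitude and shrinking period), so the smoothed minimum
sits *above* the instantaneous latent depth. Parameter-recovery oracles
therefore compare against the latent angle processed with the same
smoothing, plus the one-sided invariant that smoothing never deepens a dip.

## Repetition segmentation and kinematic features

Full-flexion events are minima of the smoothed waveform, found by negating
the signal and applying continuous-wavelet-transform ridge-line peak
detection (`scipy.signal.find_peaks_cwt`). Wavelet widths span 0.25–1.5 s —
matched to the duration of the flexion *dip*, roughly half a repetition
cycle across physiological cadences (2–4 s periods). Widths near the full
cycle were found to merge adjacent minima on fast trials, which is why the
upper width stops at 1.5 s. Each CWT candidate is snapped to the true local
minimum within ±0.5 s; minima in the first/last 0.5 s are discarded as
partial repetitions; minima closer than 1 s are merged keeping the deeper
one. Fewer than two surviving minima is an error (repetition features are
undefined).

Nine features summarise a trial, in a fixed order that subset masks depend
on: θ variance (deg²), θ standard deviation (deg), minimum θ (full-flexion
angle, deg), range (deg), maximum θ (standing angle, deg), mean repetition
time (frames between consecutive minima), repetition-time variance
(frames²), flexion-depth variance (deg², over θ at the minima), and
movement stability (range of the waveform's second half minus range of its
first half, deg; positive when range grew across the trial). All variances
are sample variances (ddof = 1); with a single repetition interval the
repetition-time variance is reported as 0 rather than NaN.

## PROMs

Seven questionnaire totals enter as numeric features: VAS (0–100), ODI
(0–100), TSK (17–68), PCS (0–52), PSEQ (0–60), CSQ (0–70, taking the
14-item total on 0–5 anchors), SBT (0–9, the total score rather than its
low/medium/high band, since it enters the model as one numeric input).
Values outside the closed instrument range are rejected; there is no
imputation.

## Classifier

A two-stream feedforward network. Each stream (kinematic features; PROMs)
applies batch normalisation, a square linear layer (outputs = inputs), and
ReLU; the streams are concatenated into a final linear layer with a sigmoid
giving P(MI). The label is MI when the probability reaches the decision
threshold (default 0.5). Feature-subset masks select each stream's inputs;
a stream with no active features is dropped, yielding the angle-only and
PROMs-only models.

Training minimises binary cross-entropy by gradient descent. Defaults:
full-batch updates (exact and bit-reproducible at cohort sizes near 10²;
minibatch SGD available), learning rate 0.05, 500 epochs, no momentum or
weight decay. Batch normalisation sits at the input layer, so its batch
statistics depend only on the data and never on the parameters; treating
them as constants in the backward pass is exact, not an approximation.
Inference uses running statistics accumulated with momentum 0.1
(ε = 1e-5), which converge to the dataset statistics under full-batch
training. The model is a few hundred parameters and is implemented directly
in NumPy with analytic gradients.

Two training choices deserve justification:

* **Learning rate 0.05.** At 0.01 with 500 full-batch epochs the optimiser
  stalls short of separating even 6-σ-separated clusters on some seeds;
  0.05 meets that contract across seeds at identical cost.
* **Initialisation.** Stream layers start at identity plus U(−0.1, 0.1)
  noise with bias 1, so nearly every ReLU unit is initially active; the
  final layer is uniform ±1/√d. A symmetric-uniform start for the stream
  layers leaves single-feature streams prone to dead-unit collapse (the
  entire stream output stuck at zero, loss pinned at ln 2), which would
  silently corrupt the single-feature subsets of the exhaustive search.

## Evaluation protocol

Metrics use MI as the positive class: accuracy, sensitivity (MI detection),
specificity (MCI detection) as percentages, F1 in [0, 1]; reporting rounds
percentages to 2 decimals and F1 to 3. A metric with a zero denominator is
undefined (`None`), never silently 0.

Cross-validation is stratified 5-fold with a fixed seed; held-out
predictions from all folds are pooled into a single confusion matrix before
computing metrics, so counts sum exactly to n and every record is tested
once. Pooling (rather than averaging per-fold metrics) is also the only
scheme whose metric denominators are not forced to be fold-divisible.

The assessment has three stages: (1) baselines with all features of each
family and with both; (2) exhaustive evaluation of all 2⁹ = 512 kinematic
and 2⁷ = 128 PROMs subsets, the empty subset recorded as an untrained
majority-class predictor; ranking by F1, ties broken by accuracy then by
fewer features (smallest adequate model preferred); per-subset seeds are
derived from the mask bits, making the ranking independent of evaluation
order; (3) ablation of the chosen mask — for each active feature, the
pooled-CV accuracy drop when it is removed.

Whether an accuracy beats chance follows the binomial framework of
Combrisson & Jerbi (J Neurosci Methods, 2015): with n samples and c
equiprobable classes, St(α) = binoinv(1−α, n, 1/c)·100/n, where binoinv is
the binomial quantile. For a held-out fold of 16 samples, two classes and
α = 0.001 this gives 14/16 = 87.5%. The threshold decreases toward the
theoretical 100/c = 50% as n grows. The exceedance probability
P(X ≥ z) is exposed alongside; note the quantile construction guarantees
P(X ≥ z+1) ≤ α, while P(X ≥ z) itself may slightly exceed α — an inherent
quirk of the discrete quantile, preserved as defined.

A small solver reconstructs integer confusion matrices from printed rounded
(accuracy, sensitivity, specificity) triples by exhaustive enumeration of
all splits of n, flagging non-uniqueness and inconsistency. It serves the
metric-identity checks (recovering published F1 values from published
percentages) and documents that one published PROMs row admits no
consistent integer matrix at n = 83.

## Synthetic cohort

The generator defines the study conditions under which the pipeline is
validated. Defaults: 41 MI / 42 MCI participants, 30 fps video, 8–10
repetitions per trial, 1 s standing lead-in/out, standing dwell of 0.1 of a
period between repetitions. Each repetition is a raised-cosine excursion
from the standing angle to a per-repetition depth (raised cosine rather
than a pure sinusoid so standing dwell between repetitions is
representable). Per-class latents (mean/sd):

| parameter | MI | MCI | rationale |
|---|---|---|---|
| standing angle θ_max (deg) | 172 / 3 | 172 / 3 | near-vertical stance, both classes |
| full-flexion angle θ_min (deg) | 120 / 8 | 85 / 8 | restricted vs unrestricted flexion |
| repetition period (s) | 3.5 / 0.5 | 2.5 / 0.4 | guarded, slower movement in MI |
| within-trial period jitter sd (s) | 0.2 | 0.2 | natural cadence variability |
| within-trial depth jitter sd (deg) | 2 | 4 | less consistent depth in MCI |

Keypoints place the ankle at the origin, the hip fixed 450 px above it, and
the neck on a 350 px trunk segment rotated by 180° − θ from vertical,
with isotropic 1 px Gaussian noise (typical pose-estimator jitter at
768-px-scaled video). PROMs are truncated normals whose class means overlap
heavily (standardised differences ≲ 0.2) except the SBT (MI 3, MCI 6, sd
1.5) — mirroring the intended qualitative structure in which kinematics
discriminate strongly and questionnaires barely.

A mocap twin realises the same latent θ(t) at 120 Hz in 3-D: C7 on the
trunk, L4 co-located with the pelvic centroid (above floor level so the
virtual-ankle construction — L4 with its vertical coordinate zeroed — is
genuinely exercised), four pelvic markers as rigid offsets whose centroid
is the hip, zero mediolateral motion, optional isotropic marker noise.
Mocap-derived angles use 3-D distances directly (no sagittal projection
step); comparison with 30 fps pose waveforms goes through linear
time-interpolation, whose error is negligible relative to the 1 s
smoothing.

What the generator does *not* emulate: hip translation during flexion (the
hip is a fixed pivot), pelvic rotation, out-of-plane motion, pose-estimator
outliers and occlusion dropouts, correlations among PROMs, and any overlap
structure in which kinematics fail to separate the classes. Passing the
end-to-end tests therefore demonstrates that the pipeline is correct and
self-consistent under its stated assumptions — not that the published
clinical accuracies would be reproduced on real patients.

## Numerical and degenerate-input choices

* arccos argument clamped to [−1, 1]; angles in degrees throughout.
* Sample variance (ddof = 1) for all variance/std features; batch
  normalisation uses population variance for batch and running statistics.
* The probability of the sigmoid is clipped to [1e-12, 1−1e-12] inside the
  cross-entropy; a non-finite loss raises a divergence error naming the
  epoch and learning rate.
* Ties at the decision threshold go to MI (≥).
* Mocap frames with missing (non-finite) markers are rejected with the gap
  locations listed; there is no gap filling.
* Empty trajectories, single-class training sets, single-feature ablation
  masks and sub-window waveforms are rejected with specific errors.
* Mean-square error between angle waveforms is reported in deg². A
  published criterion-validity figure of "0.35 degrees" is ambiguous
  between deg and deg²; this package always states deg².

## Problem sizes in the bundled checks

The test suite and the acceptance script run entirely on synthetic data at
the study-condition scale (83 participants; ~60–90 s trials), with the
exhaustive kinematic sweep (512 subsets × 5 folds) run at a reduced
training budget of 150 epochs — the ranking is insensitive to the budget on
these well-separated cohorts. The shuffled-label null uses 10 replicates;
the Monte-Carlo significance check uses 10⁵ binomial draws.

## Known limitations

* The 1 s moving average biases depth-related features (minimum angle,
  range, depth variance) toward shallower values; all models see
  consistently processed features, so classification is unaffected, but
  the features should not be read as unbiased biomechanical estimates.
* With ~83 participants, pooled 5-fold metrics still carry binomial noise
  of several percentage points; the chance-threshold block quantifies this.
* The exhaustive search performs no multiple-comparison correction across
  the 640 subsets, by design of the protocol it implements.
* The classifier is intentionally minimal (no hidden layers); it cannot
  express feature interactions beyond what one linear map plus ReLU per
  stream provides.
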