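# Methods

This note documents the modeling choices behind `vbreath`: the detection
model, the feature definitions and their numerical conventions, the
synthetic cohort generator and its parameters, and how to read the
evaluation outputs. Units are given for every physical parameter.

## 1. Problem and detection model

The task is to decide whether a person is alcohol-intoxicated from two
short free-walking sessions recorded by body-worn motion sensors: a sober
**baseline** session and a later **suspect** session. Ground truth is the
suspect session's breath alcohol concentration (BrAC, µg/L of breath),
thresholded at one of three operating points: 220 (a common legal driving
limit), 240, or 380 µg/L. A subject is labeled *intoxicated* when
`brac >= threshold`.

Each session is reduced to a fixed 228-dimensional feature vector
(section 3), and the classifier never sees a session in isolation: its
input is the elementwise difference

```
difference[i] = f_suspect[i] − f_sober[i]
```

This before/after representation acts as per-subject normalization —
stable personal gait traits (cadence preference, device placement,
amplitude profile) cancel, leaving the *change* between sessions. Under
the null (both sessions sober) the difference fluctuates around zero;
under intoxication it shifts in the directions of the known gait effects:
reduced movement frequency, decreased average acceleration, increased
low-frequency postural sway, and more irregular (noisier) movement.

A `DetectionModel` wraps one of five classifiers over the difference
vector: AdaBoost (100 depth-1 trees), gradient boosting (500 trees,
learning rate 0.01, depth-1 stumps — "many weak learners with a low
learning rate"; depth was otherwise unconstrained and stumps keep the
LOOCV suites fast), logistic regression and a linear SVM (both behind a
standardizing scaler), and Gaussian naive Bayes. All expose a score in
[0, 1]; the binary verdict is `score > confidence_threshold` with a
default threshold of 0.5 (strict inequality).

## 2. Signal model

A session carries 12 channels: {smartphone, wrist} × {accelerometer,
gyroscope} × {x, y, z}. Sampling is at each device's native rate —
180 Hz for the smartphone, 62 Hz for the wrist — with integer nanosecond
timestamps. A `ChannelRecording` validates strictly increasing
timestamps and requires the median sampling interval to be within 20% of
the nominal one.

Features are computed on the window **[6 s, 14 s)** relative to each
channel's first timestamp (the walk's sixth through fourteenth second):
the first seconds of a walk contain gait initiation transients, and a
fixed 8 s window makes spectral estimates comparable across sessions.
The window is half-open; a recording's *covered duration* is its
timestamp span plus one median sampling interval, so that windowing a
full recording by its own covered duration is the identity and windowing
is idempotent.

## 3. Features (228 per session)

Each of the 12 channels contributes 19 features from four families, for
12 × 19 = 228. Names are `device.sensor.axis.family.index`, sorted
lexicographically by (device, sensor, axis, family, index); the family
order is alphabetical: gait, histogram, spectral, statistical.

**Spectral (4):** average one-sided periodogram power in four equal-width
bands partitioning [0, 31] Hz. The cap is the Nyquist frequency of the
slower (62 Hz) device so bands are comparable across devices. The signal
mean is removed first (the DC level is already carried by the statistical
family), no taper is applied, and the periodogram convention is
`P_k = c_k |X_k|² / N²` with `c_k = 2` except at DC and, for even N, the
Nyquist bin — so a unit-amplitude sinusoid carries total power 1/2. Each
feature is the mean of the bins whose `rfftfreq` frequency falls in the
band; the last band is right-closed so the 31 Hz bin is kept. The
band-edge bin assignment is exposed as `band_masks(n, rate)` — it is a
convention, not a computation, and the test oracle shares it while
computing the DFT independently.

**Statistical (5):** mean, population standard deviation, population
variance, minimum, maximum.

**Histogram (6):** fractions of samples in six equal-width bins spanning
[min, max] of the windowed channel; the last bin is right-closed and a
constant channel puts all mass in bin 1. Fractions sum to 1, so this
family is amplitude-invariant and captures waveform *shape*.

**Gait (4):** zero-crossing rate, mean-crossing rate, median, RMS.
Crossing rates count consecutive sample pairs with a strict sign change
about the reference (0 or the mean), divided by n − 1; samples exactly at
the reference neither create nor interrupt a crossing.

## 4. Evaluation

With one difference instance per subject, generalization is measured by
**leave-one-user-out** cross-validation: for each subject, a model is
fitted on the remaining subjects and scores the held-out one. Because
every fold holds out a single instance, per-fold AUC is undefined; the
out-of-fold scores are pooled and a single AUC is computed over them
(Mann–Whitney rank formulation, ties counted half). A training fold that
contains only one class cannot be fitted; its held-out subject receives
the indifference score 0.5.

Two deployment policies summarize the score distribution beyond AUC:

* `fpr_at_full_tpr` — the false-positive rate at the most conservative
  threshold that still catches every intoxicated subject (cost of a
  "never miss" policy);
* `tpr_at_zero_fpr` — the true-positive rate at the strictest threshold
  that never accuses a sober subject (power of a "never falsely accuse"
  policy).

Both are computed directly from the score order statistics and are
cross-checked in the tests against an exhaustive threshold sweep.

**Reading pooled-LOOCV numbers.** Pooled LOOCV has a known pessimistic
bias on small cohorts: removing a positive from the training fold shifts
the fitted model's base rate down, which depresses the held-out
positive's score relative to held-out negatives (a prior-shift artifact).
On null cohorts (no effect) this pushes the AUC slightly *below* 0.5 —
mean null AUCs around 0.40–0.49 are expected behavior, not signal — and
on weak-effect cohorts it can even invert a ranking. Strong effects
dominate the artifact.

**Ablations.** `AblationSpec` selects features by device, sensor, and/or
family, in `only` mode (keep the selection) or `all_except` mode (keep
the complement), and re-runs the same LOOCV on the reduced columns.

## 5. Synthetic cohort generator

The generator produces paired 16 s sessions per subject with a
dose-dependent intoxication transform. It claims *qualitative*, not
physiological, fidelity: its purpose is to give the pipeline a cohort
whose separability is controlled by a single knob (`effect_size`).

### Base gait signal

Each channel is a sum of a step fundamental and two harmonics, a slow
postural-sway sinusoid, and Gaussian noise, sampled at the device rate:

| Parameter | Default | Rationale |
|---|---|---|
| cadence | ~N(1.8, 0.15²) Hz per subject, shared across their two sessions | typical step frequency; jitter is the subject's individual gait style |
| harmonic amplitudes | 1.0 / 0.5 / 0.25 at 1×, 2×, 3× cadence | decaying harmonic series of a periodic gait |
| base amplitude | 2.5 m/s² (accelerometer), 1.2 rad/s (gyroscope) | realistic free-walking IMU magnitudes |
| axis anisotropy | ×1.0 / 0.8 / 0.6 for x / y / z | vertical/fore-aft axes carry more power; fixed across subjects |
| sway | 0.5 Hz sinusoid, baseline amplitude 5% of channel amplitude | slow postural component |
| noise | Gaussian, σ = 0.3 (channel units) | sensor + soft-tissue noise |

Phases and noise are redrawn per session (two independent walks);
cadence is fixed per subject. Each subject consumes an independent
random stream spawned by index from the root seed (`SeedSequence`), so a
cohort is bit-identical for a given seed and independent of generation
order.

### BrAC mixture

The suspect session's BrAC is 0 with probability 1 − 0.4325
(abstainers); drinkers draw from lognormal(µ = 5.6681, σ = 0.3703) µg/L.
The three parameters are the exact solution (found once, at design time)
of the calibration constraints P(BrAC ≥ 220) = 1/3, P(≥ 240) = 0.30,
P(≥ 380) = 0.10, so the three threshold tasks have the intended class
balances in expectation.

### Dose transform

The effect strength is

```
dose = effect_size · min(brac, 320) / 240
```

so `effect_size` is the dose at the 240 µg/L decision boundary. The
`min(·, 320)` saturation models the plateau of gait impairment at severe
intoxication; mechanically, it also keeps the feature response monotone
in BrAC — without it, rare extreme lognormal draws (500–900 µg/L) push
the amplitude damping to its floor while sway/noise variance keeps
growing, producing feature vectors outside the envelope spanned by the
near-threshold training subjects.

Per unit dose:

| Effect | Magnitude | Gait interpretation |
|---|---|---|
| cadence | −4% | reduced frequency of movement |
| harmonic amplitude | −12% | decreased average acceleration |
| sway amplitude | +12% of channel amplitude (×1.5 on wrist) | balance difficulty; arm swing couples sway into the wrist |
| noise σ | +10% | irregular gait |

The amplitude effect is sized so one dose unit shifts the signal by one
channel-noise σ at the reference accelerometer amplitude
(0.12 × 2.5 = 0.3 m/s² = σ): `effect_size` reads directly in
noise-sigma units, and `effect_size = 3` realizes a "strong" cohort
(effect ≥ 3× channel noise σ for boundary subjects). An abstainer's
suspect session takes the identical null path as the baseline.

### Expected behavior by effect size

* `effect_size = 0`: before/after differ only by session noise; LOOCV
  AUC fluctuates around (slightly below) 0.5 — see the pooled-LOOCV
  reading above.
* `effect_size = 3`: the boosting classifiers recover the signal; mean
  LOOCV AUC ≥ 0.9 across seeds at the 240 threshold.

## 6. Limitations

* The generator is stationary within a session: no turning, stopping,
  terrain, or footwear effects, and no within-session BrAC dynamics.
* One instance per subject means small-n evaluation; all the LOOCV
  caveats of section 4 apply.
* BrAC is measured, not estimated: the package detects *threshold
  exceedance*, it does not regress the concentration.
* The fixed 31 Hz spectral cap discards the smartphone's 31–90 Hz band
  by design (cross-device comparability), so high-frequency content is
  only visible to the noise-sensitive time-domain families.
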