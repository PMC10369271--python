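# Methods

This note records the models behind each pipeline stage, the parameters
that matter, the design decisions taken where the design was open, and
what the synthetic data can and cannot show.

## Signals and containers

A `Recording` holds one multichannel block: bend angles (5 finger
channels, degrees, 0–180°), contact pressure (6 region channels,
arbitrary force units), or triaxial acceleration (`ax, ay, az`, g,
acquisition range ±4 g).  All kinds default to 100 Hz sampling; time is
implicit (sample index / fs).  Tremor windows are 5 s (500 samples),
which at 100 Hz gives a DFT resolution of 0.2 Hz across the 3–8 Hz rest
tremor band.  On disk a recording is a plain CSV with `#`-prefixed
metadata lines, written at full float64 precision so read∘write is the
identity.

## Filters

* **EWA** `y[t] = α·x[t] + (1−α)·y[t−1]`, `y[0] = x[0]`.  Every output
  is a convex combination of past inputs, so the filter can never leave
  the input envelope, and a constant series is a fixed point.  The
  default α = 0.2 smooths the slow bend/pressure channels strongly
  while preserving their maxima, which is all the grading uses.
* **Median filter**, window 5, edge-replication padding.  Removes
  isolated spikes without smearing edges or injecting zeros at the
  borders.
* **Band-pass**: 4th-order Butterworth, 3–8 Hz, applied
  forward–backward (`sosfiltfilt`).  Zero phase, so tremor peaks are
  not shifted; the effective order is 8.  The pass band is the rest
  tremor band; drift, DC (including the gravity component of the fused
  signal) and powerline residue fall outside it.
* **Adaptive scalar Kalman** on a local-level (random-walk) model.
  Predict `x⁻ = x̂`, `P⁻ = P + Q`; gain `K = P⁻/(P⁻+R)`; update.  For
  the scalar local-level model, pure innovation/residual covariance
  matching is degenerate — any steady-state gain is self-consistent, so
  a filter adapting Q and R from the innovation sequence alone can
  drift into heavy attenuation.  We therefore anchor R with an
  independent noise-floor estimate: the MAD-robust variance of second
  differences over the trailing 50-sample window (second differencing
  nearly cancels in-band tremor while multiplying white measurement
  noise variance by six), and let Q follow from innovation-covariance
  consistency (`mean(d²)` estimates `P+Q+R`).  Consequences: a clean
  in-band sinusoid passes with < 2% amplitude loss after the transient;
  white noise on a weak tremor is smoothed (RMSE reduced).  Limitation:
  at very high SNR the causal filter's residual phase lag can exceed
  the noise it removes; in the full chain this is immaterial because
  the band-pass has already removed most noise.  Default initialisation
  derives R₀ from the first-window variance, which makes the whole
  chain homogeneous of degree 1 under signal scaling.  Passing an
  explicit `KalmanState` with `adaptive=False` reduces the recursion to
  the textbook constant-Q/R filter (used as a cross-check).

## Flexibility grading

Each gesture recording is EWA-smoothed per finger and min–max
normalized with the fixed sensor range (0°, 180°); the grade is the bin
of the **maximum** normalized bend over all gestures, repetitions and
fingers.  The five bins are equal-width by default (cut points 0.2,
0.4, 0.6, 0.8), configurable; bins are half-open `[a, b)` so a value
exactly on a cut point takes the upper grade, and grading is monotone.
Using the maximum favours the subject's best effort, which matches how
range-of-motion scales are administered.  Extension gestures ("Flat
hand") are processed like the rest; only flexion range is graded.

## Strength grading

`IntervalKMeans` is a 1-D Lloyd k-means with k-means++ seeding, 10
restarts (best within-cluster sum of squares kept), at most 300
iterations, convergence on stable assignments, and an explicit WCSS
path (non-increasing by construction; asserted in tests).  Interval
boundaries are midpoints of adjacent sorted centers — exactly the 1-D
Voronoi boundaries implied by nearest-center assignment, so every
training value falls inside the interval of its own cluster.  With
k = 6 the intervals map one-to-one onto Lovett grades M0–M5; a
subject's grade is the interval of the maximum EWA-smoothed force over
the four actions.  All-identical inputs with k > 1 are rejected as
degenerate.  The published interval boundaries are not available, so
the partition must be refit on a force population; the package ships a
synthetic population generator for this.

## Tremor features

The raw axes are median-filtered and fused first,
`a(k) = √(ax²+ay²+az²)`; the fused signal then runs band-pass → Kalman.
With gravity riding on one axis, the fused signal is, to first order,
the gravity magnitude plus the projected tremor oscillation, and the
band-pass removes the static 1 g component, leaving the signed
oscillation.  (Fusing zero-mean axes instead would rectify the signal
and push its energy to twice the tremor frequency, outside the band —
which is why the fusion happens before filtering.)  The feature vector
has nine entries: peak-to-peak, SD, RMS of the filtered fused signal
and their logarithms `ln(x + ε)` (ε = 1e-6 g keeps zero-tremor windows
finite), plus the dominant in-band frequency of each axis from a
Hann-windowed DFT restricted to 3–8 Hz (no interpolation; one bin is
0.2 Hz at 5 s).  The fused-signal dominant frequency is computed too
but excluded from the default vector so its length matches the
classifier's nine input nodes.

## Classifier

`BPNNClassifier` is a from-scratch single-hidden-layer network:
standardized inputs, 6 sigmoid hidden units, softmax output,
cross-entropy loss, mini-batch gradient descent (learning rate 0.05,
batch 16, 500 epochs), weights initialised N(0, 1/√fan-in) from a
seeded generator — two fits with the same seed and data are bitwise
identical, and the per-epoch loss curve is recorded.  Hyperparameter
search uses stratified 10-fold cross-validation (folds reduce with a
warning when the rarest class is smaller than the fold count); ties on
mean validation accuracy resolve to fewer hidden nodes, then lower
learning rate.  Evaluation reports the 3×3 confusion matrix (rows =
true), accuracy, per-class precision/recall/F1 from the matrix, and
one-vs-rest ROC AUC by the trapezoidal rule on the softmax scores.

## Agreement statistics

Cohen's kappa is computed from the R×R contingency table with the
large-sample Z statistic under the null of independent raters (the
form SPSS prints):
`Var₀ = [p_e + p_e² − Σᵢ p_{i+} p_{+i}(p_{i+}+p_{+i})]/(n(1−p_e)²)`,
`Z = κ/√Var₀`, two-sided p from the normal distribution.  Bands:
excellent (κ > 0.8), good (0.6, 0.8], moderate (0.4, 0.6], poor
otherwise.  The ICC defaults to the absolute-agreement
single-measurement form ICC(A,1) — whose point estimate is identical
under the two-way random and two-way mixed designs, the latter matching
a fixed device rated repeatedly on each subject — with an
F-distribution 95% CI; all six standard variants are selectable.  Bands:
excellent (> 0.9), good (0.75, 0.9], moderate (0.5, 0.75], poor
otherwise.  Constant data and single-category tables are rejected as
undefined rather than returned as NaN.

## Synthetic data

The tremor generator emulates a palm-down hold: per-axis
`gain·A·sin(2πft+φ) + noise`, axis gains (1.0, 0.7, 0.5), 1 g gravity
offset on z, Gaussian sensor noise (SD 0.02 g), frequency uniform on
3–8 Hz, 5 s at 100 Hz.  Severity classes differ only in amplitude:
class 0 none, class 1 uniform on [0.05, 0.25] g, class 2 on
[0.4, 1.2] g.  These ranges are a modelling choice — separable on
average but overlapping with noise near the class-1 floor — because no
per-severity amplitude distribution is published; they make the
three-class problem non-trivial without being hopeless.  The standard
experiment uses 120 windows, 40 per class, split 8:2.  Gesture and
pressure generators use stylized templates (per-finger flexion
fractions; per-region contact gains with "Grasp the cylinder" engaging
every region, hence the global force maximum), trapezoidal/pulse-train
envelopes and Gaussian noise.

What passing tests show: the plumbing is correct end to end —
filtering, fusion, feature extraction, training, grading and the
agreement statistics all behave as specified on data with known ground
truth.  What they do not show: clinical performance.  Real tremor is
non-sinusoidal (harmonics, waxing-waning, re-emergence), real gestures
and grips are far richer than templates, and the published clinical
accuracies depend on recordings that are not available; the synthetic
experiment's near-perfect accuracy reflects the generator's
separability, not the glove's.

## Numerical choices

Ties and boundaries are half-open everywhere (a value exactly on a
grade cut point or cluster boundary takes the upper bin).  The CSV
reader uses round-trip float parsing; writes use 17 significant digits.
Log features guard with ε = 1e-6 g.  K-means restarts accept a new
optimum only when it improves WCSS by more than 1e-12 (determinism
under ties).  All randomness flows through `numpy.random.default_rng`
with explicit seeds; dataset generation derives per-window child seeds
below 2³¹ from the master seed.

## Problem sizes

The default test suite and the acceptance script use the study-scale
experiment (120 windows, 12-subject agreement tables, 12×10
reliability matrices) and small oracle fixtures (n ≤ 8 exhaustive
k-means enumeration, 100-seed class-ordering sweeps); everything runs
in well under a minute on one CPU.
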