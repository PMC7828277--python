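# Methods

`cuffdrift` simulates chronic signal drift in multi-contact nerve-cuff
recordings of compound action potentials (CAPs) and compares strategies for
keeping a pathway classifier calibrated as the drift progresses.  This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic data does and does not emulate.

## Volume conductor

The cuffed nerve segment is a straight cylinder along z (mm).  A 7-ring x
8-contact cuff (56 channels) sits on the inner surface of a cylinder of
radius 0.8 mm and length 23 mm; rings are evenly spaced 1.5–21.5 mm (the ring
layout inside the cuff is a package choice), with 8 angular slots 45° apart.
Channels are numbered ring-major, ring 1 proximal.

Inside the epineurium (radius 0.70 mm) sit three fascicles, each a cylinder
parallel to the axis wrapped in a 0.065 mm perineurium shell:

| fascicle | center offset | center angle | outer radius | fiber class |
|----------|---------------|--------------|--------------|-------------|
| tibial   | 0.30 mm       | 90°          | 0.35 mm      | A-alpha     |
| peroneal | 0.35 mm       | 210°         | 0.25 mm      | A-alpha     |
| sural    | 0.40 mm       | 330°         | 0.15 mm      | A-beta      |

Layer conductivities (S/m): endoneurium 8.26e-2 radial / 5.71e-1
longitudinal, perineurium 2.10e-3, epineurium 8.26e-2, encapsulation
6.59e-2, saline 2.00e-1, cuff 1.00e-7.

The leadfield entry for contact i and point source j is approximated as a
point source in an effective homogeneous medium,

    L[i, j] = 1 / (4 π σ_eff(i, j) d(i, j)),

with d the Euclidean distance (m) and σ_eff the length-weighted series
(harmonic-mean) conductivity along the straight source-contact segment,
split at its crossings of the nested cylindrical boundaries (endoneurium
core, perineurium shell, epineurium, encapsulation front).  The anisotropic
endoneurium uses σ(α) = σ_long·cos²α + σ_rad·sin²α for the segment/axis
angle α.  This straight-ray approximation preserves the geometry-,
conductivity- and perturbation-dependence of the potentials at negligible
cost; it is explicitly *not* a finite-element solution — it cannot express
current redistribution (shunting along high-conductivity layers), which
matters for the encapsulation scenario (see Limitations).  The cuff is not
treated as an insulator (uniform gain factor 1): relative class
separability, not absolute amplitude, drives the study.

Two chronic perturbations:

* **Encapsulation growth** — an annulus of encapsulation tissue fills the
  epineurium-cuff gap from the inside out; fill fractions 0, 1/3, 2/3, 1
  define time points Base, ET1, ET2, ET3.  Since σ_encap < σ_saline, every
  |gain| is nondecreasing in fill (verified on a fill grid).
* **Cuff rotation** — the contact grid rotates rigidly around the nerve
  axis, 0–45° in 5° steps (time points R0…R45).  45° is one full slot pitch,
  so the 45° leadfield is exactly a ring-wise channel permutation of the 0°
  leadfield (verified to 1e-10).

## CAP simulation

Fiber classes follow the large myelinated afferents of the rat sciatic
nerve: A-alpha (tibial, peroneal) with 1.70 mm node-of-Ranvier spacing and
94.86 m/s conduction velocity; A-beta (sural) with 1.16 mm and 64.72 m/s.
Each pathway is an arc-length-parameterized cubic spline through control
points along its fascicle center (lateral wiggle 0.02 mm), spanning z =
−3.5…26.5 mm so the cuff is covered with margin of at least two node
spacings on each side.  Nodes sit every node-spacing of arc length.  A bank
of 20 laterally offset copies of the trajectory (offsets drawn uniformly in
a disk inside the endoneurium) emulates CAPs arising at different positions
within the fascicle.

All fibers of a pathway fire in perfect synchrony, so one charge-balanced
source waveform — a Ricker wavelet (second derivative of a Gaussian, σ =
0.1 ms, support ±8σ, unit amplitude) — is injected at every node with
constant-velocity delay s_k / v (s_k = node arc length).  Channel potentials
are the leadfield-weighted sums of the delayed waveforms at 30 kHz.
Charge balance makes every channel integrate to zero (verified to 1e-6
relative), and inter-ring peak lags match distance/velocity within one
sample.

Recordings are tripole-referenced: the instantaneous mean of the 16
outer-ring contacts (rings 1 and 7) is subtracted from every channel,
removing common-mode interference exactly.

**Series and noise.**  Each pathway's referenced CAP clip (100 samples,
peak at offset 49; ties broken toward the earliest sample, then the lowest
channel) is assembled into a per-pathway time series: event onsets drawn
uniformly (seeded) with minimum separation of one clip length, events
cycling through the 20 bank offsets.  The nominal series is 10,000 CAPs in
53.333 s (1.6 M samples).  White Gaussian noise is added with one standard
deviation for all channels, σ² = P_signal / 10^(SNR/10), where P_signal is
the mean squared value of the whole series (all 56 channels, silence
included), per pathway; the standard grid is −5, −10, −15 dB.  Because the
series is exactly the clips placed at non-overlapping onsets, P_signal (and
hence σ) can be computed from the bank without materializing 1.6 M samples;
datasets therefore add noise directly to the extracted windows using the
full-series σ, which is statistically identical to extracting windows from
the noisy series.  The full-series path is retained and used for fidelity
checks (measured SNR within ±0.1 dB on a 2 s, 300-event assembled series;
longer series only sharpen the estimate).

## Signature datasets

A signature is the 56 x 100 window [peak−49, peak+50] around a clean-signal
CAP peak (3.333 ms at 30 kHz); peaks are detected on the referenced clean
recording, never on noisy data.  Each time point's dataset pools the three
pathways (full-study scale: 10,000 CAPs per pathway, 30,000 total), is
normalized into [−1, 1] by the single maximum absolute amplitude across all
of its CAPs (the constant is stored so amplitude growth across time points
remains inspectable; normalization is per time point), and carries a
seeded, stratified 5-fold assignment (full-study scale: folds of 6000, 2000 per
class).  Rows can be presented ring-major ("spatial emphasis") or
slot-major ("temporal emphasis"); the two orderings are pure row
permutations of each other.

Datasets at different time points of one sequence share the generator seed,
so signatures correspond one-to-one (same event order, same noise draws,
same folds) and differ only through the leadfield.  Linear interpolation
between corresponding signatures defines intermediate time points for the
training-frequency analysis; endpoints reproduce the source datasets
exactly.

## Classifiers

Two interchangeable specs behind one state/train/predict contract:

* `linear_baseline` — multinomial softmax regression on the flattened
  signature (3·5601 parameters).  Default for desk-scale sweeps.
* `dual_cnn` — the same signature fed in spatial and temporal row order
  through two identical-topology convolutional branches (untied weights;
  per branch two 3x3-conv + 2x2-maxpool stages, 8 then 16 filters),
  concatenated into a single dense softmax(3) layer.  Convolution and
  backpropagation are implemented in numpy and gradient-checked in the
  tests.  Filter counts and schedule are config-exposed.

Training is minibatch SGD with momentum 0.9 (linear: lr 0.05, batch 128, 15
epochs; CNN: lr 0.01, batch 64, 8 epochs), seeded and warm-starting from
the passed-in parameters; zero epochs is an exact no-op.  No early stopping,
for reproducibility.  Confidence is the maximum softmax probability;
predicted label is the argmax with ties toward the lowest class index
(class order tibial, peroneal, sural).  Performance is macro F1: per-class
F1 = 2PR/(P+R) (defined as 0 when P+R = 0) averaged over the three classes;
the implementation is cross-checked against scikit-learn's in the tests.

## Update strategies

All strategies share one sequence of datasets, fold assignments and
per-fold initial models, so differences are attributable to the update rule:

* **Baseline calibration** — train once at the first time point (4 folds),
  evaluate the frozen model on the held-out fold of every time point.
* **Periodic recalibration** — at each new time point, warm-start from the
  previous weights and retrain on that time point's 4 training folds with
  true labels (full-study scale: 24,000 CAPs), test on the held-out fold.
* **Self-learning** — at each new time point, the previous model labels the
  training pool; samples with confidence ≥ 0.95 form the self-labelled set
  (true labels discarded); the model warm-start retrains on it and is
  tested on the held-out fold with true labels.  When any class's
  self-labelled count falls below 200 in any fold, the run stops: no
  retraining or evaluation from that time point on.  The rule is applied to
  the per-fold training pool.  No replay of earlier data.

**Frequency / initial-performance analysis** (encapsulation only): with
frequency m ∈ {1, 2, 4, 8}, m−1 interpolated datasets are inserted between
consecutive real time points and self-learning runs at every sub-step; F1
is reported at real time points, and m = 1 reproduces plain self-learning
bit for bit.  Two starting levels at ET1 share the Base lineage: HP (one
supervised step Base→ET1) and LP (one self-learning step).  The summary
statistic is the strategy-minus-control slope of mean F1 between ET1 and
ET2, the control being the starting model frozen at ET1; positive values
mean the strategy slowed the decline.

## Orchestration and problem sizes

A single master seed derives every stage seed as
`sha256(master/stage) mod 2^31`, making strategy comparisons paired without
bookkeeping and full runs bitwise reproducible (verified by hashing result
CSVs of two runs).  The default profile is desk-scale: 3000 CAPs per time
point (1000 per pathway), `linear_baseline`, both scenarios, SNRs −5/−10/−15
dB; `scripts/acceptance.py` uses this profile for the strategy and slope
sweeps, full-study scale (30,000 CAPs) for the dataset-arithmetic checks, and a
2 s / 300-event assembled series for the SNR fidelity check.  Paper-scale
strategy sweeps and the `dual_cnn` are config-selectable.

## What the generator does and does not emulate

Emulated: the 56-channel cuff geometry and tissue conductivities; discrete
node-of-Ranvier sources with class-specific spacing and velocity; tripole
referencing; whole-series SNR definition; per-CAP windowing, per-dataset
normalization and stratified folds; both drift scenarios; the three update
strategies and the frequency/initial-performance analysis.

Not emulated: finite-element current redistribution (the leadfield is a
series-resistance ray approximation); membrane biophysics (the CAP shape is
a fixed charge-balanced template, not a simulated action potential); firing
rates and overlapping CAPs; nerve branching; electrode impedance and
amplifier artifacts.

Consequences observed with this generator (all numbers recomputed by the
tests and `scripts/acceptance.py`):

* **Rotation drift is strong and behaves as expected**: at −5 dB the frozen
  baseline classifier falls from macro F1 1.0 at R0 to ≈0.40 at R45,
  periodic recalibration holds ≈1.0 throughout, and self-learning survives
  only part of the sweep before the <200-per-class rule halts it.
* **Encapsulation drift is weak by construction**: replacing saline with
  encapsulation tissue only changes the series resistance of the short
  annulus segment of each ray, a <2% change on the informative channels
  (the perineurium crossing dominates the path resistance), far below the
  spatial separation of the three fascicles.  The frozen baseline therefore
  does **not** measurably decline across Base→ET3 at any SNR in this
  pipeline, and the corresponding directional check in the acceptance suite
  fails honestly.  Capturing that decline requires a field solver in which
  the resistive layer reshapes the potential distribution, which is outside
  this package's scope.  The slope-difference machinery is still fully
  exercised (near-zero slopes on near-zero drift).

## Numerical choices and degenerate inputs

* Distances in mm internally; gains in ohms (distance converted to meters).
* Harmonic-mean conductivity uses midpoint classification of ray segments;
  duplicate boundary crossings produce zero-length segments and are
  harmless.  Sources must lie strictly inside the epineurium; zero
  source-contact distance is rejected.
* The Ricker template's discrete sample sum is ≤1e-13 of its peak with the
  ±8σ support, so no rebalancing is applied.
* Peak ties: earliest sample, then lowest channel.  Signatures too close to
  a series edge are skipped with a logged warning.
* Normalizing divides by the dataset's max |value|, so the post-norm global
  maximum is exactly 1.0 in floating point.
* Interpolation uses (1−α)·A + α·B, which is exact at both endpoints in
  IEEE arithmetic.
* All-zero datasets, empty training sets, missing classes, infeasible event
  packing, double referencing and out-of-range fills/rotations are rejected
  with messages rather than propagated.

## Known limitations

Beyond the generator gaps above: the linear desk-scale classifier saturates
(F1 ≈ 1.0) at −5 and −10 dB under these study conditions, so small drift
effects are invisible at desk scale; the dual-branch CNN is CPU-priced
(small filter counts) and not a reproduction of any published network's
hyperparameters; and the self-labelled stopping rule is evaluated on the
training pool rather than a separate validation set.
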