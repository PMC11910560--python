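# Methods

## Problem setting

A four-state motor-imagery BCI assigns each 5-second, three-channel EEG
trial (electrodes T3, T4, FP1; tasks forward / left / right / stop) to one
of the four task classes.  The package implements the full decision
pipeline — mains-notch preprocessing, Welch power-spectral-density (W-PSD)
band features, and a small feed-forward network trained by a cheetah
optimization algorithm (COA) — together with a synthetic cohort generator
that stands in for human recordings, which are not distributable.

## Welch spectral estimator

For a length-N channel signal, segments of length `M` start every `S`
samples; `K = floor((N − M)/S) + 1` segments fit and trailing samples are
dropped.  Each segment is tapered by a window `w[m]` and transformed:

    X_k(ν) = Σ_m x[m] w[m] exp(−j 2π ν m),   ν = i/M,  i = 0 … M/2
    P_k(ν) = |X_k(ν)|² / W,                  W = Σ_m w[m]²
    S_x(ν) = (1/K) Σ_k P_k(ν)

Conventions (all tested):

* `W = Σ w²` (window energy) is the modified-periodogram normalizer; it is
  exactly the choice that makes the rectangular-window, no-overlap estimate
  satisfy Parseval (two-sided periodogram average = mean squared amplitude).
* One-sided grid of `M/2 + 1` bins, mapped to Hz by `ν·fs`; DC and Nyquist
  bins are **not** doubled, and no `1/fs` density scaling is applied.
  The unit-test suite contains the exact conversion to `scipy.signal.welch`
  density scaling, which serves as an independent cross-check; the
  estimator itself is implemented directly from the definition above.
* Defaults `M = 256`, `S = 128` (50 % overlap), symmetric Hamming window:
  at fs = 256 Hz this gives K = 9 segments per 5-s trial and 1-Hz bin
  spacing — a conventional trade-off between variance reduction and band
  resolution for short EEG epochs.

### 22-dimensional feature vector

Each trial maps to `log(mean band PSD + ε)`, ε = 1e−12, over fixed bands:

* T3, T4: eight bands with edges 0.5, 4, 8, 13, 18, 24, 30, 38, 45 Hz
  (delta, theta, alpha, low/mid/high beta, low/high gamma-edge);
* FP1: six bands with edges 0.5, 4, 8, 13, 20, 25, 30 Hz (the frontal
  channel carries less high-frequency task information, so its coverage
  stops at 30 Hz).

8 + 8 + 6 = 22 features, channel-major, bands low→high.  The plan is
configurable (`band_plan`), but the default is the tested contract.

## Notch preprocessing

The only preprocessing applied: a second-order IIR notch
(`scipy.signal.iirnotch`) at 50 Hz with quality factor 30 (−3 dB width
≈ 1.7 Hz), run forward–backward (`filtfilt`) per channel so the output is
zero-phase and sample-count preserving.  Measured behaviour: ≥ 20 dB
rejection at 50 Hz, ≤ 5 % amplitude loss at 10 Hz.  Requires
`fs > 2 × 50 Hz`; lower rates are rejected with an explanatory error.

## Classifier network

A three-layer feed-forward network: 22 inputs, 4 tanh hidden units,
4-way softmax output; parameters live in one flat vector
(`D = (22+1)·4 + (4+1)·4 = 112`) so a derivative-free optimizer can search
them directly.  There is no backpropagation anywhere in the package.
Inputs are z-scored per feature with statistics estimated on the training
split only.

The hidden width (4) and the weight box (±1 per dimension, standardized
units) are deliberately small: the log-band-power classes are close to
linearly separable, direct search degrades with parameter count, and a
tight box acts as regularization — wider boxes and wider layers measurably
overfit (training accuracy rises while held-out accuracy falls).

## Cheetah optimization algorithm

Population metaheuristic over a box, minimization convention.  Per
iteration, **every coordinate of every cheetah independently** draws one of
three strategies (defaults: search 0.3, wait 0.3, attack 0.4):

* search: `x_j ← x_j + r̂_j · a_j`, `r̂_j ~ N(0,1)`,
  `a_j = 0.05 · (u_j − l_j) · (1 − t/T)` (bound-scaled, linearly annealed);
* wait: `x_j` unchanged (a fully waiting cheetah is not re-evaluated);
* attack: `x_j ← x_B,j + r̆_j · β_j` with prey `x_B` (best-so-far), turning
  factor `r̆ = |u|^(exp(u/2)) · sin(2πu)`, `u ~ N(0,1)`, and interaction
  `β_j = x_k,j − x_i,j` for a uniformly drawn other cheetah `k`.

A candidate replaces the cheetah's position only if it improves that
cheetah's own fitness (greedy acceptance); the global best is elitist on
top.  After `home_return_patience = 20` iterations without improvement the
worst half of the population is re-randomized in the box (leave-and-return)
while the best-so-far is retained.  All candidates are clipped to the box;
non-finite objective values are treated as +∞ and skipped.

Two design points matter in high dimension and were chosen for that
reason: per-coordinate strategy draws make an attack mix prey coordinates
with the cheetah's own (crossover-like moves that keep progress possible
when D ≳ 100), and greedy acceptance prevents the population from
forgetting good solutions.  With per-cheetah strategies and unconditional
replacement the same budget stalls far above the achievable error on the
weight-training problem.

Benchmarks (seeded, re-run by the test suite and acceptance script): on the
5-D sphere with n = 20, T = 300 the optimizer reaches < 1e−2 in 20/20
seeds (median ≈ 5e−11), and beats uniform random search at matched
evaluation budget on both sphere and Rosenbrock.

## Training objective and protocol

Fitness of a weight vector is the mean cross-entropy of the softmax scores
against the labels (clipped logs); a misclassification-rate objective is
available as an alternative.  Training defaults: population 30, T = 1000
iterations, box ±1, seed-controlled.  The split is a per-subject stratified
holdout (default 25 %): within every (subject, task) cell of ≥ 2 trials at
least one trial goes to each side, so subject-wise test tables are always
defined.

## Session scoring

Accuracy is reported two ways, both derived from the 4×4 confusion matrix
(rows = true task):

* pooled trial accuracy = correct / total — the number usually quoted for
  a session;
* one-vs-rest accuracy (TP+TN)/(TP+FP+TN+FN) per class, macro-averaged —
  the binary definition extended to four classes; it counts true negatives
  and therefore exceeds the pooled number.

Macro precision/recall/F1 are one-vs-rest with a zero-denominator class
contributing 0 (with a warning).  Session reports add per-task accuracy,
per-subject accuracy, the mean ± sd of subject accuracies, and the
wrongly-classified total; `aggregate_scoresheet` applies the same
arithmetic to per-subject × per-task correct-count tables.

The bundled reference score sheets (`cheetahbci.datasets`) reproduce their
published summary rows to the printed two decimals, with two caveats the
package does not hide: the sources occasionally round their final digit
up from a 3-decimal intermediate (85/90 printed as 94.45 rather than
94.44) or truncate (93.889 printed as 93.88), so comparisons in the
acceptance tests use ±0.02; and the female offline sheet is internally
inconsistent — its count grid implies 23 wrong trials while its
per-subject wrong-count column (consistent with its accuracy column) sums
to 22 — so subject-wise aggregates for that sheet are driven by the
wrong-count column and task-wise aggregates by the grid.

## Synthetic cohort generator

Defaults mirror the emulated study design: 18 subjects, 10 trials per task
per subject (720 trials), fs = 256 Hz (1280 samples per 5-s trial).  Each
channel is a sum of band-limited oscillations — three sinusoids with
uniform-random frequencies and phases per rhythm band (delta 1–4, theta
4–8, alpha 8–13, beta 13–30 Hz), base amplitude 10 µV-like units per
band — plus Gaussian noise (sd 4) and a 50 Hz mains sinusoid
(amplitude 20).  Task identity enters as an *excess power gain*: each task
multiplies the power of one distinct (channel, band) pair by `1 + g`
(default g = 2.0; forward→T3-alpha, left→T4-alpha, right→T3-beta,
stop→T4-beta).  `g = 0` therefore produces statistically identical classes
(a true null), and separability increases monotonically in `g`.  Subjects
differ by a small multiplicative amplitude jitter (sd 5 %); online-mode
sessions cue tasks in seeded-random order and carry 1.25× noise sd,
offline sessions use fixed task blocks.

Every trial derives from its own RNG substream keyed by
(seed, subject, label, trial index, mode), so cohorts are bit-reproducible
in any generation order.

What the generator does **not** emulate: ocular/muscular artifacts,
non-stationarity within a trial, volume-conduction correlation between
channels, 1/f background spectra, or inter-session drift.  Passing the
end-to-end tests therefore shows that the pipeline recovers class structure
of the kind it assumes (band-power differences), not that it would reach
the same numbers on human EEG.

## Problem sizes used

The end-to-end checks run the full default cohort (720 trials, 576/144
split at 25 %), COA benchmarks use 20 seeds at n = 20, T = 300, the
spectral-oracle equivalence draws 100 random configurations with N ≤ 160,
and the gain-recovery surface (medians over 5 seeds at gains 0, 0.5, 1.0,
2.0) runs on a 6-subject, 5-trials-per-task cohort with T = 300 — sizes at
which the whole suite completes in a few minutes on one CPU while still
exercising the defaults end to end.

## Known limitations

* Which 22 spectral features the emulated study actually used is not
  recoverable; the band plan here is a documented choice.
* The COA random-factor distributions (r̂, r̆, β, step rule) are not fixed
  by the algorithm's verbal description; the definitions above are this
  package's, and results for other choices may differ.
* Metaheuristic weight search is practical only for small networks; the
  D = 112 default trains in seconds, but the approach does not scale to
  deep architectures.
* Held-out accuracy at the default gain (≈ 93 % pooled) has run-to-run
  spread of a few points across seeds; single-seed numbers should be read
  with that in mind.
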