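# Methods

## Problem setting

Human activity recognition (HAR) from body-worn inertial sensors maps
windows of accelerometer/gyroscope samples to activity labels.  The
standard chain extracts a large catalogue of per-window statistics and
then selects a subset of them, because irrelevant and redundant features
degrade both accuracy and on-device cost.  This package implements a
wrapper selector: a candidate subset is a binary mask s over the N
features, scored by training a classifier on the selected columns and
measuring accuracy f(s) = (TP+TN)/(TP+FP+TN+FN) (multi-class:
#correct/#total).  Ties in f are broken toward fewer selected features.

## Preprocessing and features

Recordings are cleaned by mean imputation of missing samples, a running
median (default width 3 — the width is not fixed by convention, so it is
configurable), and a 3rd-order Butterworth low-pass with a 20 Hz corner.
The Butterworth filter is applied forward-backward (zero phase): window
statistics such as zero-crossing rate are sensitive to phase lag, and
nothing in the chain requires causal filtering.  Segmentation uses
fixed-width sliding windows (default 2.56 s, 50% overlap; at 50 Hz that
is 128-sample windows with stride 64), fully contained in the recording.
Window labels are the majority per-sample label, ties resolved toward
the label occurring earliest in the window.

The feature catalogue covers the classic time-domain statistics (mean,
variance, SD, absolute mean, square-root amplitude, median, mode,
min/max/peak-to-peak, IQR, RMS, zero-crossing rate
ZC = Σ|sgn(x_i)−sgn(x_{i−1})|/(2N), skewness, kurtosis, and the
impulse/margin/shape/crest factors), spectral statistics (energy
Σx_i², spectral entropy −Σ p_k log₂ p_k over normalized squared
magnitudes, power-weighted frequency center and RMS frequency, DC
component, top-3 peak frequencies, and the mean/SD/skewness/kurtosis of
the magnitude spectrum), and pairwise Pearson correlation and cosine
distance between axes of the same sensor.  Conventions worth noting:

* IQR uses the (n+1)-based order-statistic rule (the "weibull"
  percentile method), i.e. the (3/4)(n+1)th minus the (1/4)(n+1)th term
  with linear interpolation.
* Variance is the 1/N (population) form while SD is the 1/(N−1) sample
  form; both conventions circulate in the vibration-feature literature
  and the two are reported as separate features.
* SRA is ((1/N)Σ√|x_i|)²; the margin factor divides the absolute peak
  by it, the impulse factor by the absolute mean, the crest factor by
  the RMS.
* Any statistic with a zero denominator (zero-variance window, all-zero
  spectrum) is defined as 0, so all features are finite for finite
  input and the selector never sees NaNs.
* Spectral statistics exclude the DC bin, which is reported separately;
  this keeps the frequency center of a pure tone at the tone.

Column order is catalogue order, then sorted channel order, so the
matrix layout is independent of channel insertion order.

## The search

**Outer loop (bee swarm).**  A reference mask spawns `nb` candidates by
three flip strategies: (1) the i-th of the first min(flip, nb) masks
flips positions i, i+flip, i+2·flip, …; (2) the next masks flip
contiguous blocks of ⌈N/flip⌉ bits; (3) the remainder flip ⌈N/flip⌉
seeded-random distinct positions (the randomized strategy is uniform;
no principled skewed alternative is defined anywhere, so uniform is the
neutral choice).  Each bee runs a local search from its candidate and
posts its best find to the dance table.  The next reference is the best
dance entry; a global improvement resets the chance counter to
`max_chances`, otherwise one chance is consumed, and when the counter
reaches zero the search diversifies to the spawned candidate furthest
in Hamming distance from the best global mask that is not in the tabu
list (seeded random fallback if none).  Reference masks are recorded in
a tabu list and never reused; if a branch would reuse one, the
diversification choice is substituted.  The chance counter persists
across iterations — resetting it every iteration would make
diversification unreachable — and diversification fires on the
iteration that would drain it to zero.  Defaults: nb=10, flip=5,
max_chances=3.

**Local search (the hybrid's core).**  Every feature owns an agent.
Agent u observes a 2N-bit vector: a one-hot block (entry u set iff
feature u is selected; all other entries zero) followed by the full
mask.  Its actions are keep/flip its own bit.  Flips are restricted to
the XOR of the current mask with the best global mask, which funnels
each bee monotonically toward the incumbent — the Hamming distance to
the best global mask never increases while the restriction is active.
A search that starts at (or reaches) the incumbent has nothing to
funnel toward; under a literal per-step reading it would be confined to
the incumbent's Hamming-1 ball (each flip's only legal successor is its
own reversal), so the implementation treats the restriction as spent at
that point and the remainder of the run is unrestricted.

The reward for a step from accuracy acc_{t−1} to acc_t is:

* acc_t if accuracy rose;
* 0.5·(acc_t − acc_{t−1}) (negative) if it fell;
* ±acc_t·δ if it is unchanged, positive exactly when the selected-count
  fell (δ = 0.1 by default; only the sign structure matters, and 0.1
  keeps the nudge an order below typical accuracy changes).

One value function is shared by all agents — the one-hot block is what
distinguishes them.  In tabular mode it is a lookup table updated by
Q_new = Q + α(r + γ·max_a' Q(s',a') − Q); in deep mode a single-hidden-
layer network (2N → hid_num ReLU → 2 linear) trained by squared error
against targets r + γ·max_a' Q_target(s') from uniform replay batches,
with the target network copied from the live one every
`target_copy_every` steps.  The value function, replay buffer and
exploration schedule persist across bees and outer iterations, so all
bees learn from the accumulated experience.

Agents step sequentially, cycling in index order over the positions the
restriction allows; sequential stepping makes the environment
well-defined even though the reward depends on the joint mask.  When a
feature is unselected its one-hot block is all zeros, which makes those
observations agent-anonymous; this is retained as designed, and the
tabular convergence guarantee is stated only for settings where each
observation identifies the actor.

**Exploration schedule.**  ε-greedy with ε: 1.0 → 0.1 at ×0.999 per
step; tabular greedy ties break toward flipping (optimistic
initialization — an untried flip is preferred over staying put); deep
training starts after 64 stored experiences (two mini-batches of 32).
These values were chosen so that a single local search of a few hundred
steps is actually capable of traversing a small mask space; a schedule
that decays to near-zero within one search freezes the searcher at its
start.

**Degenerate masks.**  The empty mask is unscorable (no columns to
train on), so spawning repairs all-zero candidates by setting one
random bit and an agent whose flip would empty the mask is forced to
no-op.

## Evaluation

Fitness uses a pluggable classifier: k-nearest-neighbours (default
k=2), an RBF-kernel SVM (default γ=0.001), or a small 1-D convnet (two
conv/ReLU/max-pool blocks — 32 filters of width 5, then 64 of width 3,
pooling kernel 2 stride 2 — followed by fully-connected layers sized
flat → flat → 256 → 64 → n_classes with softmax), which treats the
selected feature vector as a 1-D sequence and needs at least 8
features.  The default protocol is a single stratified 70/30 holdout
with a per-run seed; k-fold is available.  Results are memoized by the
exact mask bit pattern — metaheuristics revisit masks constantly, and
the cache changes cost, never values.  Both the Q-network and the
convnet are trained with hand-derived backpropagation and Adam in
numpy.

## Comparators

GA (real genomes decoded at 0.5; tournament size 2; uniform crossover
0.8; per-gene mutation 0.01; elitism 1), binary PSO (global-best;
inertia 0.9; acceleration 2/2; velocity clamp ±4; positions re-sampled
through the sigmoid transfer — select where sigmoid(v) ≥ u, u uniform,
with the exact boundary resolving as select), and an ant system
(inclusion probability τ_j/(τ_j + τ̄); retention 0.95 per iteration;
deposit 0.1 by the iteration-best ant).  A purely deterministic
sigmoid-vs-0.5 transfer was measured to collapse the swarm onto a few
dozen masks and is not used.  Population sizes and iteration counts are
not fixed by convention; defaults are 20 individuals/particles and 50
iterations, and 10 ants.  "Evaporation 0.95" is read as the retained
fraction.

## Synthetic data

`gen_feature_table` plants: informative columns (per-feature class
means on an effect_size-spaced grid permuted across classes, plus unit
noise), redundant columns (ρ·standardized parent + √(1−ρ²)·noise, so
the parent correlation is the redundancy_corr knob), and
label-independent noise columns; labels are balanced block-wise and
shuffled with the seed, and column order is shuffled so the truth set
is not positional.  Defaults (600 samples, 4 classes, 10 informative,
5 redundant at ρ=0.8, 85 noise, effect 1.5) give a table whose
informative block separates classes strongly.  `gen_recording` emits
6-channel IMU-like signals: accelerometer = 9.81·orientation + a
band-limited sinusoid + Gaussian noise, gyroscope = sinusoid + noise;
stationary activities are zero-amplitude and differ only through the
gravity orientation.  The generators reproduce the *statistical
structure* the selector exploits — class-conditional mean shifts,
controlled redundancy, band-limited oscillation — not human
kinematics; passing tests therefore demonstrate the search and
evaluation machinery, not field performance on real recordings.

## Known limitations

* With the default planted conditions the table is perfectly
  classifiable: k-NN accuracy saturates at 1.0 for many subsets, and
  backward elimination shows minimal perfect subsets containing only
  6–7 of the 10 informative features.  Once fitness saturates, the
  fewer-features tie-break can only shed features, so the number of
  informative features the selector retains is bounded by the size of
  those minimal subsets.  Full recovery of a planted truth set should
  only be expected when the evaluator does not saturate (weaker
  separation, fewer samples, or a harder protocol).
* The observation design is agent-anonymous for unselected features
  (see above).
* Wall-clock fields in run reports are hardware-dependent and excluded
  from determinism guarantees.

## Problem sizes used in the shipped checks

Search-mechanics examples run on 5–16-bit masks; oracle-equivalence
checks enumerate all 256 masks of an 8-feature landscape; planted
recovery runs the full selector (10 bees, 50 iterations, 20 local steps
per bee — roughly 8–9 thousand distinct mask evaluations per seed) on
600×100 tables for five seeds; the hybrid-vs-components comparison uses
a 1000-evaluation budget per algorithm on the same tables.
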