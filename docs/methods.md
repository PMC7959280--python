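# Methods

This note records the models, estimators, numerical choices and known
limitations behind `gesturenet`, at the level of detail a maintainer or
reviewer needs to judge what the package's tests do and do not establish.

## Signal model and preprocessing

Recordings are channels × samples voltage blocks (µV) at a nominal 500 Hz.
The conditioning chain is: per-channel DC-offset subtraction; a zero-phase
60 Hz IIR notch (quality factor Q = 30 — unspecified in the source
protocol, chosen as the standard line-noise setting and recorded in the
config); a zero-phase Butterworth band-pass 0.2–250 Hz at 24 dB/octave.
24 dB/octave corresponds to a 4th-order Butterworth; since a 250 Hz edge
equals Nyquist at 500 Hz, the filter is implemented as the 0.2 Hz
high-pass (a band edge at Nyquist is a no-op; hardware anti-aliasing is
assumed to have happened at acquisition). Forward–backward application
doubles the effective order; the 0.2 Hz pole's multi-second transient is
absorbed by an explicit pad of 3·fs/f_low samples so the zero-phase
property holds away from the record edges.

Artifact correction implements the documented subset of topographic-PCA
projection: spatial principal components are fitted on user-marked
artifact intervals; the artifact topography is estimated from the channel
vectors at the intervals' highest-amplitude samples; components whose
spatial correlation with that topography exceeds a threshold (default
0.9), or whose RMS amplitude exceeds the highest permitted brain-signal
amplitude (default 100 µV), are projected out of the whole recording, up
to a configured maximum (default 3). Each removed component reduces
signal rank by one. Interval marking is file-based (CSV of start/end
seconds); there is no GUI, because visual inspection is inherently manual
and out of scope. No ICA, bad-channel interpolation, or re-referencing
beyond the surface Laplacian is attempted.

The surface Laplacian is the k-nearest-neighbor ("small") variant, k = 4:
each channel minus the mean of its 4 nearest montage neighbors. The
technique's named variants differ mainly in neighborhood construction;
the nearest-neighbor form is deterministic and robust to montage details.

## Montage

The default montage models a 128-electrode headset: 119 analysis channels
partitioned into motor (70), cognition (37) and perception (12) cortices,
7 excluded channels (I1, Iz, I2, CPz, PO5, PO6, Oz) and 2 mastoid
references. Electrode coordinates are generated on an upper unit
hemisphere (Fibonacci lattice) with the sign of x made consistent with
each channel's hemisphere label; positions feed only the Laplacian
neighborhoods and artifact topographies, where relative distance — not
scalp-accurate geometry — is what matters. The assignment of individual
electrodes to cortices is an approximation constrained only by the group
sizes; published per-region channel counts are internally inconsistent
(they sum to 100, not 119), so no per-electrode mapping can be
reconstructed. Odd cortex sizes place one channel on the midline; midline
channels belong to whole-cortex scopes but to neither hemisphere scope.

## Coherence networks

Each epoch is cut into non-overlapping 1 s windows (trailing remainder
discarded; epochs under 2 s are rejected — two layers are the minimum for
any dynamic measure). Within a window, cross-spectra are Welch-averaged
over 125-sample Hann-tapered sub-segments at 50 % overlap (7 per window at
500 Hz), each sub-segment mean-removed; magnitude-squared coherence is
band-averaged over 1–50 Hz (configurable). The window length fixes the
estimator's resolution/variance trade-off: one segment per window would
make coherence identically 1, and longer sub-segments (e.g. 250 samples,
3 per window) leave an estimator bias floor around 0.34 for independent
channels, which would compress the usable dynamic range; 125-sample
segments put the floor near 0.15 while still resolving the physiological
bands at 4 Hz resolution. The estimator's bias depends on the signal's
coherence bandwidth, so the honest noise-floor comparison for a planted
effect is against independent channels with the same spectral content —
the simulator tests do exactly that. Zero-variance channels make
coherence undefined; their rows are set to 0 and logged. The diagonal is
fixed at 1 by convention; every graph feature that sums over neighbors
excludes self-loops explicitly, and community detection zeroes the
diagonal before building the modularity matrix, so the convention never
leaks into a statistic.

## Multilayer community detection

The per-epoch tensor is treated as a multilayer network with categorical
(all layer pairs) inter-layer coupling by default; ordinal coupling
(consecutive layers) is available, matching the reading of flexibility as
change across successive windows. Resolution γ = 1 and coupling ω = 1 are
the canonical defaults of the multilayer-modularity literature (the
source protocol does not print them) and are provenance-stamped into
every output. Optimization is a generalized Louvain: greedy single-node
moves on the dense supra-modularity matrix until no move improves the
quality, then community aggregation, repeated to a local optimum. Sweep
order is randomized from a seeded generator, so a run is deterministic
given its seed; the ensemble default is 100 independent runs.

Consensus: the runs' co-assignment matrix over supra-nodes is thresholded
at the maximum off-diagonal co-assignment observed across permuted
surrogate ensembles (each run's assignment vector shuffled across
supra-nodes, preserving community sizes; default 100 surrogates), then
re-clustered with the same Louvain on the thresholded matrix, iterating
until all re-clustering runs agree (or a cap of 20 iterations, after
which the modal partition is returned with `converged=False`). Community
labels are canonicalized by first appearance, making partitions
comparable across runs.

The module-allegiance matrix averages co-assignment over **both** runs and
layers (the aggregation is not pinned down in the source description;
run-only or layer-only averaging can be had by passing single-layer or
single-run partition lists).

## Features

Per-scope features are means over the scope's member channels (or ordered
member pairs): 6 families × 3 cortices × {left, right, whole} = 54, plus
3 whole-brain scalars and 3 cortex powers = 60. Per-layer graph
quantities are averaged over the epoch's T layers (median available);
a time-averaged-adjacency mode computes them once on the layer mean
instead, since the source description is ambiguous between the two.

* **Flexibility** needs T ≥ 2; bounded in [0, 1].
* **Integration / recruitment** read the allegiance matrix; "outside" means
  outside the cortex (not outside the hemisphere scope); recruitment of a
  hemispheric scope runs over the whole cortex's other members.
* **Search information** follows the shortest path under lengths 1/w; each
  step u→v costs −log₂(w_uv/s_u). Among tied shortest paths the
  predecessor tree's path is used. Unreachable pairs contribute +∞ and are
  excluded from scope means with a logged count.
* **Diffusion efficiency** is 1/MFPT with MFPT from the fundamental matrix
  of the within-component random walk (one matrix inverse per layer,
  rather than one absorbing-chain solve per pair); cross-component pairs
  get efficiency 0 (1/∞). The scoped family averages ordered pairs inside
  each scope; the global feature averages all ordered pairs.
* **Transitivity** uses geometric-mean triplet weights normalized by the
  layer's maximum weight, keeping it in [0, 1]; degree counts nonzero
  neighbors.
* **Global efficiency** averages 1/d over ordered pairs with d from
  Dijkstra on lengths 1/w; unreachable pairs contribute 0.
* **Power** integrates the Welch PSD (1 s Kaiser windows, β = 14 — chosen
  for strong sidelobe suppression, configurable — 50 % overlap) over
  frequency, recovering band-limited variance in µV²; by default the full
  passband is used (a band limit is configurable). Cortex features pool
  member channels across hemispheres.

Scaling behaviour (verified by tests): strength and global efficiency
scale linearly with a global edge-weight factor; transitivity (by its
normalization) and search information (step probabilities are scale-free)
are invariant, as is diffusion efficiency.

## Synthetic data

The simulator stands in for unavailable operating-room recordings. Each
gesture class plants: coupling groups whose channels share a band-limited
latent oscillator (band-pass-filtered unit-variance Gaussian noise — not a
sinusoid, so in-band coherence is high but below 1), mixed as
√c·latent + √(1−c)·own-band-noise plus broadband background; and a
class-specific amplitude gain. Epochs of 2–3.5 s (uniform) are shuffled
across classes and laid end-to-end with 0.5–1.5 s noise gaps; class counts
follow the config exactly, including imbalanced inventories. Idle is an
ordinary class with no coupling. All randomness flows from one seed
through per-epoch substreams, so datasets are bit-reproducible and epoch
order does not leak randomness between epochs.

The ready-made scenarios couple a distinct pair of cortex-hemisphere
blocks per class, shift the latent band by 3 Hz per class and step the
amplitude gain by 15 % — strong class-conditional structure in both
connectivity and power. What passing tests show: the pipeline detects
planted coherence communities and class structure far above chance, and
degrades to exactly chance when no structure is planted. What they do not
show: performance on real EEG, whose artifacts, nonstationarity, volume
conduction and inter-subject variability the simulator deliberately does
not model (no forward head model, no 1/f background beyond band-pass
shaping).

## Classification protocol

SMOTE (synthetic rows x + u(x_nn − x), u ~ U(0,1), k = 5 same-class
neighbors, k reduced with a warning for classes of ≤ k + 1 samples)
balances every class to the majority count — strictly inside each
training fold, as are the ANOVA F-scores and the classifier fit; the test
fold is never touched by any fitted object. Folds are stratified (the
protocol says only "10-fold"; without stratification rare classes vanish
from folds). Precision and sensitivity are reported macro-averaged —
with imbalanced classes micro-averaging would collapse onto accuracy —
and support-weighted variants are also emitted since the source reporting
is ambiguous. The confusion matrix is accumulated over folds and
row-normalized. Classifier hyperparameters are fixed: KNN (5 neighbors,
uniform weights); BAG = bagged unpruned Gini trees on bootstrap replicas;
RF; ET (whole sample, random split points) — all at 350 trees, min-split
2, min-leaf 1. A tree-count sweep utility (100–1000 step 20) exists but
is not part of the default protocol. Subject-grouped CV is available as
an option but not default.

Classifier pairs are compared with a paired t-test over matched accuracy
vectors (per fold, or per fold × feature-count from the accuracy-vs-n
curve), reporting the mean improvement in percentage points, its 95 %
confidence interval, and Bonferroni-adjusted p (default m = 6: three
ensemble pairs × two hands). Zero-variance differences are flagged
degenerate.

One statistical subtlety: the chance-level check on null data compares
mean accuracy to 1/n_classes within 3 standard errors, with the SE taken
**across independent null datasets** (3 seeded replicates). The per-fold
SE within a single dataset understates the sampling variability of a
cross-validated mean — folds share the dataset, and no unbiased
single-dataset estimator of CV variance exists — enough that a nominal
3 SE band on fold SEs rejects a substantial fraction of genuinely null
datasets in both directions.

## Problem sizes and defaults used in the shipped experiments

End-to-end benchmarks run on an 18-channel montage with the same
three-cortex structure (8 motor / 6 cognition / 4 perception), 60 epochs
per class, community ensembles of 20 runs with 20 permutation surrogates
(tests use 10–20; the closed-form and oracle tests are exact and
size-independent). These sizes were chosen so a full benchmark runs in
minutes on one core while keeping every per-class count large enough for
stratified 10-fold CV; the statistical behaviour of every estimator is
size-checked by the oracle tests rather than by scale. The 119-channel
default montage exercises the I/O and preprocessing paths in tests;
feature extraction at 119 channels is supported but not exercised in the
benchmark loop.

## Known limitations

* Coherence only — no phase-based or directed connectivity measures.
* No per-frequency-band feature variants; the aggregation band is a
  single configurable interval.
* The electrode-to-cortex mapping is size-faithful but not
  electrode-faithful (see Montage).
* The artifact-projection step is a documented approximation of a
  proprietary pipeline and is validated only on synthetic rank-1
  artifacts.
* Consensus convergence is not guaranteed; non-convergence is flagged,
  not raised.
* Search information assumes the reconstructed shortest path; with ties
  the value depends on deterministic tie-breaking of the predecessor
  tree.
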