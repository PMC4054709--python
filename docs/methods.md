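# Methods

## The problem and the model

An operator performing long, monotonous supervisory tasks (the motivating
case is remote piloting of uncrewed combat aircraft) can slip into
*hypovigilance* — a sustained-attention level below what the task demands.
`vigilhmm` implements a detector that decides, from a multichannel EEG-like
observation sequence, whether the operator was in normal vigilance ("+") or
hypovigilance ("−") while the sequence was recorded.

Direct vigilance labels are essentially unobtainable (probing the operator
destroys the state being measured). The method therefore adopts the
*difficulty-as-label* hypothesis: demanding tasks force normal vigilance,
undemanding ones admit hypovigilance, so sequences recorded during
difficult tasks are labelled "+" and sequences from easy tasks "−". In the
simulated-cockpit task set shipped with the package, landing, emergency
landing and air-to-air combat form the difficult group; taking off, missile
launch and navigation the easy group.

Each sequence `E = e_1 … e_L` is modelled by a continuous hidden Markov
model `Λ = (S, X, A, B, Π)` with `G` hidden states, transition matrix
`A = [a_ij]`, initial vector `Π`, and per-state multivariate Gaussian
emission densities `b_j(x) = N(x; μ_j, Σ_j)` on `X = R^k`. Two complementary
uses are provided:

* **Model-based detection** (`detector.train_detector` / `classify`): for
  each operator `m` a pair of HMMs is fitted — `Λ_m^+` on that operator's
  "+" sequences, `Λ_m^−` on the "−" sequences — and a new sequence is
  assigned `argmax_ν f(E | Λ_m^ν)`. Training is strictly per operator:
  EEG patterns are individual-specific, and the package's own experiments
  (below) show a pooled model is measurably worse.
* **State-based trend analysis** (`detector.state_occupancy` /
  `difficulty_correlation`): a single HMM pooled over all of an operator's
  sequences regardless of label; the posterior state-occupancy profile per
  task-difficulty level is correlated with difficulty rank. A positive,
  significant correlation for the designated vigilance state supports the
  difficulty-as-label hypothesis.

## Inference and training

All recursions run in log space with log-sum-exp (sequences of hundreds of
frames underflow linear-space probabilities). The forward and backward
recursions give `log f(E | Λ)`; both are exposed and agree to 1e-8, and both
are verified in the test suite against exhaustive enumeration over all
`G^L` state paths on small instances. Viterbi decoding returns the most
probable path with ties broken toward the lowest state index, so decoding is
deterministic.

Parameters are estimated by k-means initialisation followed by Baum–Welch
(EM) refinement:

* **k-means init** (`hmm_core.kmeans_init`): centroids start uniformly at
  random inside the per-dimension [min, max] envelope of the pooled frames;
  after convergence `μ_j` is centroid `j`, `Σ_j` the within-cluster
  covariance, and `A`, `Π` come from cluster-label transition/initial counts
  with additive smoothing (pseudocount 1). The clustering itself is
  delegated to scikit-learn's `KMeans` with this custom init and `n_init=1`;
  its empty-cluster relocation (to the highest-inertia points) covers the
  degenerate case.
* **Baum–Welch** (`hmm_core.fit_em`): E-step statistics are summed across
  all training sequences before each M-step. Stopping: absolute
  log-likelihood gain below `tol = 1e-4` or `max_iter = 100`. The
  log-likelihood trace is recorded and asserted non-decreasing (to 1e-6)
  throughout the test suite. A state that loses all posterior mass keeps its
  previous parameters with a floored covariance and a logged warning —
  never a silent NaN.
* Whether the original procedure refined the k-means estimate with EM is
  ambiguous; both are available (`refine=False` gives init-only) and the
  detector defaults to k-means + EM.

Covariances are full by default with a diagonal floor (`cov_floor = 1e-6`,
escalating jitter if a factorization still fails); a diagonal-only mode
exists for very short sequences. Transition matrices are unconstrained
(fully connected). State indices are 0-based internally and 1-based in
reports. Every source of randomness is an explicit seed argument; composite
operations derive independent sub-seeds via `numpy.random.SeedSequence`.

## Preprocessing

Raw input is a channels × time matrix in µV with a sampling rate (default
128 Hz, typical of consumer EEG headsets). The chain:

1. **`band_limit`** — zero-phase low-pass at 30 Hz (the "0–30 Hz band" of
   scalp EEG; DC is retained since the lower edge is 0). The default
   implementation applies the squared-magnitude Butterworth response
   `1/(1 + (f/30)^{2·order})`, order 8, in the frequency domain — the exact
   amplitude response of a forward–backward Butterworth pass with no edge
   transient. The implied circular convolution can ring near record edges
   for non-periodic signals; the pipeline truncates edges downstream, and a
   conventional time-domain `sosfiltfilt` pass is available as
   `method="sos"`.
2. **`decompose_bands`** — wavelet-packet decomposition (Daubechies-4,
   periodization mode) to the level whose frequency-ordered terminal bins
   are ≤ 2 Hz wide (level 5 at 128 Hz). Bins are assigned to delta
   (0–3 Hz), theta (4–7), alpha (8–12) or beta (13–30) by bin midpoint,
   with boundaries at 3.5/7.5/12.5/30 Hz (midpoints between the printed
   band edges); bins above 30 Hz are dropped. Frames are non-overlapping
   1 s windows; the per-frame band amplitude is the root of the summed
   squared coefficients of the band's bins, so summing squared amplitudes
   over the four bands recovers the frame's signal energy (checked to 20%,
   the slack covering filter roll-off between 30 Hz and the low bin edges
   and wavelet boundary effects). Channels are averaged by default
   (`obs_dim = 4`, matching the four-band view of the signal);
   `channel_mode="concat"` keeps `4 × n_channels` features. Whether the
   original observation vectors were band features or per-channel power
   spectra is ambiguous; band features averaged over channels are the
   default because the published signal views show four band series.
3. **`normalize`** — per-column z-score (default) or min–max; zero-variance
   columns are left at zero with a warning. Z-scoring is idempotent.
4. **`truncate_edges`** — removes the first and last 5 s (settling and
   tear-down artifacts).
5. **`split_train_test`** — stratified by vigilance label, seeded.

Artifact rejection by visual inspection is replaced by an optional
amplitude-threshold frame rejection (off by default) — a declared stand-in,
not an equivalent.

## Evaluation protocol

Accuracy is `(TP + TN) / (TP + FP + FN + TN)` with hypovigilance — the
event the detector exists to catch — as the positive class, although its
class symbol is "−". The configuration sweep crosses the number of states
(2, 3) with the training ratio (50%, 67%): DM1 = (2, 50%), DM2 = (2, 67%),
DM3 = (3, 50%), DM4 = (3, 67%). The "All" baseline trains one detector on
the training splits pooled across operators and is evaluated per operator
on the same test splits. Improvement over "All" is reported as relative
percent, `mean over operators of (acc − acc_All)/acc_All × 100`
(an absolute-difference mode exists; every report names the convention).
A one-sided one-sample t-test (n−1 variance) checks whether mean accuracy
exceeds 0.7 at α = 0.05; with zero variance the mean is compared directly
and no statistic is reported. Likelihood ties in classification resolve to
"+" with a warning: falsely declaring hypovigilance would trigger an
unnecessary intervention.

## The synthetic data generator

No public corpus of difficulty-labelled operator EEG exists, so the package
ships a generator that embodies the statistical premises the method relies
on, making every claim testable end to end.

Each simulated operator has a seed-derived baseline: `G = 2` state means
(scale 2 in feature units), a sticky transition matrix (self-transitions
0.80–0.95), an initial vector, and identity emission covariances. The two
vigilance classes share this baseline entirely and differ *only* in their
emission means, displaced by ±separation/2 along an operator-specific
random unit direction. Consequences, each load-bearing for the validation:

* the centroid distance between class mean sets equals the requested
  `separation` exactly, in pooled-sd units (covariances are identity);
* at `separation = 0` the class generators are identical, so held-out
  accuracy must sit at chance — a calibration check on the whole pipeline;
* the displacement *direction* varies across operators, so pooling
  sequences across operators mixes the classes and a pooled detector is
  genuinely handicapped — the premise behind per-operator modelling,
  which the package verifies directionally rather than assumes.

The default experiment shape mirrors a five-operator simulated-cockpit
study: 10 repetitions × (3 difficult + 3 easy) tasks per operator, one
observation vector per second, ~360 frames per task (about six minutes).
Nonstationarity can be added as a slow sinusoidal drift of the emission
means (one cycle per sequence; amplitude = `drift`) — a declared stand-in
for real EEG nonstationarity, which is asserted in the literature but not
given a model. Features can be rendered back into raw multichannel signal
(`render_raw`): per 1 s frame, a sum over bands of sinusoids at the band
centre frequencies with amplitudes √power from the generating state's band
profile, plus white noise (sd 0.1 by default), padded with 5 s of noise on
each side so edge truncation recovers exactly the original frames.

What the generator does **not** emulate: 1/f background spectra,
event-related potentials, ocular/muscular artifacts, inter-channel
correlation structure, or any physiological link between band power and
vigilance. Passing tests therefore demonstrate that the pipeline recovers
the structure the model assumes when it is present — not that real EEG
contains that structure.

## Validation scale and numerical choices

The acceptance-style checks run at deliberately desk-sized problem scales,
chosen once as the package's defaults:

* oracle equivalence: 50 random models, `G ≤ 3`, `k ≤ 2`, `L ≤ 6`
  (enumeration is `G^L`);
* parameter recovery: 2 states, means ±3, unit variance,
  `A = [[0.9, 0.1], [0.1, 0.9]]`, 20 sequences × 200 frames;
* detector discrimination: separations {0, 1, 2, 3}, 20 training and 100
  test sequences per class, L = 200, medians over 10 seeds;
* configuration sweep: 5 operators × 9 sequences per class, L = 60,
  DM1–DM4 each against a pooled baseline matched in states and ratio (so
  the test split is identical), 10 seeds;
* trend analysis: 6 difficulty levels × 3 sequences × 60 frames; the null
  calibration uses 100 replicates and probes a *fixed* state index —
  selecting the state by its occupancy at the hardest level (the shipped
  mapping rule) would bias the null significance rate upward.

Other numerical choices: Cholesky factorization for emission densities and
sampling; `log 0 = −inf` handled explicitly in the recursions; k-means and
EM seeds below 2³¹; JSON model serialization round-trips bit-exactly
(floats via `repr`).

## Known limitations

* Two vigilance levels only; no streaming/online decision rule with latency
  guarantees (whole sequences are classified after the fact).
* The difficulty-as-label hypothesis is assumed, not tested on humans here;
  the state-trend analysis shows only internal consistency on synthetic
  data.
* Gaussian emissions with a shared full covariance per state; no mixture
  emissions.
* Hardware EEG formats (EDF/BDF) and electrode-montage handling are out of
  scope; raw input is CSV plus a JSON manifest.
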