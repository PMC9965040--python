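# Methods

## Signal model

Each simulated epoch is a sum of Gaussian ERP components plus noise.
For trial *i* of participant *p*, the voltage on cluster *c* at time *t*
(ms relative to stimulus onset) is

    v(t) = Σ_k a_ik · exp( −(t − μ_k − δ_pk − ε_ik)² / (2 σ_k²) ) + η(t)

where the sum runs over the components assigned to cluster *c* for the
trial's stimulus type, `a_ik ~ N(mean_amplitude_k, amplitude_sd_k)` is a
signed per-trial amplitude, `δ_pk ~ N(0, latency_sd_between_k)` is drawn
once per participant and component name (shared between stimulus types),
`ε_ik ~ N(0, latency_jitter_within_k)` is trial-level jitter, and `σ_k`
is the component width.  The noise η is the sum of white Gaussian noise
and pink noise obtained by shaping white noise with a 1/√f spectral gain
and rescaling to a target standard deviation.  Optional artifact epochs
receive a single-sample spike whose sign follows the underlying sample,
guaranteeing the epoch's absolute peak reaches the artifact amplitude.

### Default generative profiles

Amplitudes are in µV, latencies in ms.  Rare (face) trials carry a
larger N170 and P3 than frequent (square) trials; the strongest
rare/frequent contrast sits at the N170, which is what makes the
early-component band the best decoding window.  Older adults have
delayed P2/P3 latencies and reduced posterior amplitudes, while the P2
contrast is identical in both groups — an age-invariant discriminative
feature.

| component | cluster  | young freq/rare | older freq/rare | latency y/o | width σ |
|-----------|----------|-----------------|-----------------|-------------|---------|
| P1        | occipital| 3.0 / 3.0       | 2.1 / 2.1       | 100 / 110   | 20      |
| N170      | occipital| −1.5 / −5.5     | −1.0 / −3.0     | 170 / 180   | 22      |
| P2        | occipital| 2.0 / 5.0       | 2.0 / 5.0       | 235 / 300   | 30      |
| P3        | central  | 1.5 / 4.0       | 1.5 / 3.5       | 340 / 400   | 45      |

Between-participant latency sd 10 ms, trial jitter 15 ms (12 for the
narrow N170), per-trial amplitude sd 0.8 µV, pink noise sd 3 µV, white
noise sd 2 µV.  These magnitudes are conventional for visual ERPs and
were chosen so that per-participant single-trial AUROC lands in the
0.6–0.85 range reported for this kind of task; they are a model of the
*statistical structure* the analysis assumes, not of any individual
recording.  What the generator deliberately omits: volume conduction and
realistic topography (clusters are simulated directly, not as 32
channels), eye/muscle artifacts (the artifact model is a bare amplitude
spike), non-Gaussian trial-to-trial variability, and any correlation
between components within a trial.  Passing tests therefore demonstrate
that the pipeline recovers known structure under these idealized
conditions — not that it would behave identically on recorded EEG.

## Preprocessing

Averaging to the four standard clusters (O1/Oz/O2, P3/Pz/P4, C3/Cz/C4,
F3/Fz/F4) happens before amplitude rejection, because the rejection
criterion guards the traces the classifiers actually consume.  Both
thresholds are strict: an epoch is dropped when its absolute peak
*exceeds* 100 µV, and a recording is excluded when *more than* 25% of
epochs are dropped.  Rejection is idempotent.

## Temporal features

Per time point: 4 cluster voltages + 36 power values (9 frequencies ×
4 clusters).  The sliding window is 32 samples, centered (16 samples per
side), so 16 samples are trimmed from each epoch end; a 256-sample epoch
yields 224 feature time points.  Each window has its mean removed (so a
DC offset cannot leak through the taper into the low-frequency bins), is
Hann-tapered, and zero-padded to 64 samples before the DFT — at 256 Hz
this makes the bin grid exactly 4 Hz so the requested 4–36 Hz
frequencies align with bins; at other sampling rates the nearest bin is
used.  Power is reported as absolute dB, `10·log10(P + ε)` with
ε = 1e−12 µV², with no per-trial baseline normalization: dividing by a
short pre-stimulus baseline at the single-trial level mostly injects
baseline noise into every feature, and the classifiers are scale-free
after min-max normalization anyway.

## Time-independent ERP features

Four measures per component within fixed windows (P1 50–150, N170
100–200, P2 200–325, P3 250–500 ms; samples nearest the endpoints
included).  Measures for the negative N170 are computed on the negated
trace and the sign restored for amplitudes.  The fractional 50% peak
latency is defined on the leading edge: starting at the in-window peak
and walking backward, the first sample below half the (polarity-aligned)
peak is found and the crossing time is linearly interpolated; if the
trace never falls below the threshold the window start is returned, and
if the aligned peak is itself negative (pure-noise windows) the peak
time is returned.  Parameterization is per trial — the classifiers
consume single-trial rows — rather than measure-on-average.

A collapsed-localizer diagnostic derives candidate windows from the
zero-crossings of the all-trials grand average: each component is
located by the absolute extremum inside its default window (making the
boundaries invariant to a global sign flip), the surrounding
zero-crossing interval is intersected with the default window's ±50 ms
neighborhood, and the fixed windows are used as a fallback (with a
warning) when a trace never crosses zero.  The pipeline always measures
in the fixed windows; the localizer output is a check, not an input.

## Feature selection

Mutual information between each continuous feature and the binary label
is estimated with the k-nearest-neighbour continuous–discrete estimator
(k = 3) as implemented in scikit-learn, clipped at zero, on trials
pooled across participants (one global selected set).  Temporal
features: MI per time point, aggregated by the mean over time, top 8
kept, ties broken by the fixed feature order.  ERP features: the two
amplitude measures are compared by MI summed over components, likewise
the two latency measures; the winning measure of each kind is kept for
all four components.  Ties prefer the peak amplitude and the fractional
latency.  Both the neighbour count and the aggregation are exposed as
parameters.

## Decoding protocol

Stratified 10-fold CV per participant (and independently per time point
for the temporal dataset).  Within each fold, in order: (1) the majority
class is randomly undersampled without replacement and the minority
class SMOTE-oversampled — synthetic points `x + u(z − x)` with `z` one
of the point's min(5, n−1) nearest minority neighbours in the raw
feature space and `u ~ U(0,1)` — both to ⌊(n₀+n₁)/2⌋ (66 for the modal
124/23 fold geometry); (2) the balanced training set is shuffled;
(3) min-max scaling is fitted on the balanced training set and applied
to train and test, with zero-range features mapped to 0 and test values
left unclipped; (4) the classifier is fitted and evaluated on the
untouched, imbalanced test split with rare as the positive class.
AUROC uses the rank-based Mann–Whitney identity on continuous scores
(decision function where available, otherwise the positive-class
probability).  A fold whose test split contains one class is skipped
with a warning; a fold whose scaled training features are all constant
yields the majority-class chance record.

Classifier suite: LDA, logistic regression, linear-kernel SVC, RBF SVC,
3-NN, decision tree (library defaults), and random forest, AdaBoost
(depth-4 base trees) and XGBoost at 100 estimators and maximum depth 4.

Every random decision derives from a master seed through
`derive_seed(*keys)` (a SeedSequence over an integer key tuple), keyed
by participant index, time point and fold — results are bit-reproducible
and independent of execution order, and decoding one time point of the
temporal tensor equals a static run on that slice with the derived seed.

## Comparison statistics

The Friedman test uses within-participant average ranks with the
standard tie correction (a fully tied matrix reports statistic 0,
p = 1).  Post-hoc pairwise Wilcoxon signed-rank tests over all k(k−1)/2
pairs are Holm-adjusted; an all-zero-difference pair records p = 1.  The
Nemenyi critical distance is `q_α(k)/√2 · √(k(k+1)/(6N))` with `q_α`
the studentized-range quantile at infinite degrees of freedom, supported
at the conventional α ∈ {0.01, 0.05, 0.10}; at k = 9, N = 70, α = 0.05
it evaluates to 1.436.  The CD diagram joins maximal runs of rank-sorted
classifiers whose pairwise adjusted p all exceed α.  The time-resolved
extension repeats the machinery per time point: no marker where the
Friedman test is non-significant; elsewhere a classifier joins a
representative's cluster when its Holm-adjusted p against that
representative exceeds 0.05.  Holm correction is applied within each
time point only, with no across-time correction — a deliberate
faithful-reproduction choice of the analysis being re-implemented, not a
statistical endorsement.  Age comparisons use one-way ANOVA across
group×dataset cells followed by pairwise equal-variance two-sided
t-tests (Welch is available via a flag); per-time group tests are
summarized as maximal contiguous runs of p < α in ms.

## Permutation importance

For a fitted model and its (scaled, imbalanced) test fold, each feature
column is shuffled `n_repeats = 10` times with the others fixed;
importance is baseline AUROC minus mean permuted AUROC (negative values
are possible).  Test-fold permutation was chosen over train-fold (the
standard convention); group profiles average participant-level
importances unweighted because group sizes differ.

## Problem sizes used by the test suite

The qualitative checks run at sizes chosen to finish in minutes while
keeping every feature well defined: time-resolved decoding uses 10+10
participants at 96 Hz with 96-sample epochs — the full −200 to +790 ms
window, exactly 64 trimmed time points, and a Nyquist (48 Hz) above the
36 Hz feature grid.  The age-group comparison runs at the full 27/43
cohort geometry, where the static protocol is cheap and the two-sample
t-test has adequate power for AUROC gaps of ~0.06; at 10 participants
per group such gaps are undetectable more often than not.  In that test
the "age-invariant classifier" is implemented literally as a linear
discriminant restricted to the P2 peak amplitude and fractional latency
— the features whose class contrast is identical in both groups — which
shows no group difference, while random forest and 3-NN on the full
selected set lose significant performance in the older group.  A
classifier given the full feature set always absorbs the young group's
extra N170/P3 signal at this sample size, so age-invariance of
*features*, not of a particular model family, is the mechanism the suite
asserts.

## Known limitations

- The generator's clusters are independent noise tracks; real volume
  conduction correlates them strongly.
- SMOTE neighbours are found in the raw feature space before scaling;
  with features of very different ranges the neighbourhood structure is
  dominated by the widest-range feature (harmless here, where features
  within a dataset share units, but worth revisiting for mixed-unit
  inputs).
- The 3-NN classifier produces only four distinct score levels, which
  depresses and coarsens its AUROC relative to margin-based models.
- `select_temporal` computes MI at every time point; on paper-scale
  inputs (224 time points × 40 features × 10k trials) this is the
  slowest selection step by far.
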