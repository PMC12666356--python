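# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limitations of the `rfgr` package.

## Problem and data model

The unit of analysis is a single-channel EEG *segment*: 178 consecutive
amplitude samples (~1 s at the dialect's nominal 178 Hz) labeled with
one of five brain-activity classes — epileptic seizure (1), tumor brain
area (2), healthy brain area (3), eyes closed (4), eyes open (5).
Segments arise by tiling a subject's 4,097-sample recording into 23
non-overlapping windows anchored at sample 0; the trailing 3 samples
are discarded. 500 recordings (100 per class) therefore yield 11,500
segments, 2,300 per class. The recording type accepts any trace of at
least 23·178 = 4,094 samples so that exactly-tiling traces can be
constructed in tests; the generator always emits the canonical 4,097.

The CSV dialect is `X1..X178,y` with an optional leading unnamed
identifier column (retained as per-row provenance). Reading uses
round-trip float parsing so that write→read reproduces every amplitude
bit-exactly.

## The fusion method

Two extractors are fitted on the training split only:

* **Forest probabilities.** A random forest (T = 100 trees, depth ≤ 100,
  bootstrap resampling per tree) produces per-segment class
  probabilities as the average over trees of the leaf class
  frequencies. Column order is ascending label code.
* **Recurrent features.** A single-layer GRU (64 units) reads the
  segment as a univariate sequence, followed by dropout (0.2) and a
  K-way softmax head, trained 10 epochs with softmax cross-entropy and
  Adam. Either the K-dim probability head (default) or the 64-dim final
  hidden state can be fused.

The fused set concatenates the two blocks (`fused`: K + K = 10 columns;
`fused_hidden`: K + 64). Feature names are `f1..fd` with per-column
provenance tags.

**Cross-fitting.** Scoring training rows with the forest that memorized
them would make the training-side features near-one-hot and useless for
stacking. Training-side forest probabilities are therefore out-of-fold:
the training split is partitioned into 5 stratified folds and each fold
is scored by a forest refitted on its complement. The recurrent head is
applied directly to the training rows — a 10-epoch, 13k-parameter
network does not memorize the way deep trees do, and its training-side
optimism is correspondingly mild. Held-out rows are always scored by
direct application of extractors that never saw them; their labels are
not consulted at any point, which the tests verify bitwise.

**Recurrent cell conventions.** The GRU uses separate input-side and
recurrent-side bias vectors per gate and applies the reset gate after
the recurrent matrix product — the convention under which a 64-unit
univariate cell has 3·(64·65 + 2·64) = 12,864 parameters. With zero
recurrent bias this coincides with the textbook single-bias equations,
which is what the unit-level hand oracles exercise. The state update is
`h_t = (1−z)⊙h_{t−1} + z⊙h̃` (the update gate weights the *candidate*).
The LSTM uses a single bias per gate: 4·(64·65 + 64) = 16,896
parameters. The dense head adds 64·5 + 5 = 325; totals 13,189 (GRU) and
17,221 (LSTM). Parameter accounting is exposed as a standalone function
and checked against the instantiated networks.

## Synthetic study conditions

The generator emulates the class-conditional amplitude structure of the
real dataset rather than its physiology. Each recording is a sum of 2–4
class-band sinusoids with random phases, scaled to a per-recording peak
target, plus Gaussian broadband noise; seizure recordings additionally
carry 1+ Hann-windowed spike bursts (peaks up to ~1,950), and tumor
recordings carry rare excursion bursts (probability 0.3 per recording).
Final amplitudes are clipped to the class envelope.

| class | envelope | peak target | band (Hz) |
|---|---|---|---|
| epileptic seizure | ±2000 | 500–800 + bursts | 2–8 |
| tumor brain area | ±500 (excursions to ±1200) | 350–480 | 4–10 |
| healthy brain area | +300/−400 | 140–260 | 8–13 (alpha) |
| eyes closed | +300/−400 | 150–280 | 1–5 (delta) |
| eyes open | +300/−400 | 130–250 | 14–30 (beta) |

Two deliberate design choices shape what the pipeline can demonstrate:

* The three low-amplitude classes have *overlapping* amplitude ranges
  and *disjoint* frequency bands. Single time samples then carry mostly
  amplitude information, so a forest on raw samples confuses those
  classes — matching the weak raw-feature baseline of the real data —
  while a temporal model can read frequency. This is what gives the
  recurrent half of the fusion its measurable value.
* The noise floor sits at half the oscillation amplitude
  (`noise_scale = 0.5`). Real EEG rhythms ride on strong broadband
  background; a near-noiseless generator lets trees read clean
  adjacent-sample structure and trivializes the raw baseline.

Determinism: every recording is a pure function of (master seed, label
code, stream id) via seeded substreams, so datasets of different sizes
share common prefixes and the whole dataset is reproducible bit-for-bit.

What the generator does **not** model: multi-channel montages, artifact
classes (eye blinks, EMG), 1/f spectra, nonstationarity within a
recording, and inter-subject variability. Passing tests therefore show
that the machinery is correct and that the fusion helps when classes
are separable temporally but not pointwise — they do not certify
performance on clinical EEG.

## Downstream classifiers

Defaults are pinned: LR (max_iter = 100, C = 1.0), SVM (max_iter = 500,
RBF kernel, margin-only unless probability output is requested), GNB
(var_smoothing = 1e−9), RF (100 trees, depth ≤ 100), GRU/LSTM (64
units, dropout 0.2, 10 epochs, batch 64, cross-entropy + Adam). The
recurrent classifiers treat a d-wide feature row as a length-d
univariate sequence, mirroring the 178-step treatment of raw segments.
The SVM's iteration cap is honored even though it may truncate
convergence. Predictions are the argmax of the probability output where
available, with ties broken toward the lowest class code.

Inputs to the recurrent models are z-scored per time-step column using
training statistics only; raw amplitudes up to ±2000 would otherwise
saturate the gate nonlinearities. The Adam step size is 3e−3: within
the fixed 10-epoch budget the default 1e−3 leaves the network badly
underfitted (held-out accuracy 0.63 vs 0.96 on the synthetic fixture at
design time).

## Evaluation harness

Splits and folds are stratified by class (the dataset is balanced, so
stratification is the faithful reading of an 80/20 protocol). Metrics
use the standard definitions with macro averages as unweighted means
over classes; a class absent from the test truth scores 0 with a
warning. The confusion matrix has true classes in rows. k-fold reports
per-fold accuracies with their mean and population standard deviation
(ddof = 0). In transfer mode, the fusion extractors are refit inside
every fold. The PCA baseline (20 components) is fitted on the training
portion only. Wall-clock profiling is provided for orientation and is
never a tested quantity. Displayed tables round to 2 decimals; stored
values keep full precision, and serialized metric files exclude
runtimes so that seeded runs are byte-identical.

## Explanation

For the narrow fused set, Shapley values of the model's probability
output are computed *exactly* under the interventional value function
by enumerating all 2^d feature subsets against a seeded background
sample (d ≤ 16 enforced; default 50 explained rows, 20 background
rows). The implementation satisfies the efficiency identity
(base + Σφ = prediction) to 1e−9, which the tests assert. Importance is
the mean |attribution| over rows and classes, ranked descending.
Permutation importance (20 seeded repeats, mean accuracy drop) is the
model-agnostic fallback for wide inputs. Tree export emits a
node/threshold/class-count outline from which any sample's leaf — and
hence the forest's probability feature — can be re-derived by hand.

## Sizes used in the shipped checks

The end-to-end directional check runs at 30 recordings per class
(3,450 segments; 5 seeded repetitions of split + refit + ablation), and
the 10-fold transfer-mode cross-validation at 10 recordings per class —
sizes chosen so the full pipeline, including ten per-fold GRU refits,
runs comfortably on a laptop-class single core while leaving the
directional conclusion stable across seeds. Unit tests use further
scaled-down extractor configs (fewer trees/units/epochs); the defaults
above are exercised by the architecture and determinism checks.

## Known limitations

* The recurrent networks are plain-numpy and single-threaded; they are
  sized for 178-step univariate sequences, not GPU-scale training.
* Fusion is concatenation; no learned weighting of the two blocks.
* The SVM kernel choice in the reference configuration is unknowable;
  RBF is the documented default and is configurable.
* Exact Shapley enumeration is exponential in d and intentionally
  refuses wide inputs.
* Accuracy figures obtained on synthetic data characterize the method's
  mechanics, not clinical performance.
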