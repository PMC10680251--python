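# Methods

## Problem and model

The task is binary classification of fixed-length DNA windows (by
convention 41 nt with the candidate adenine at position 21, 1-based):
label 1 if the centre carries N6-methyladenine (6mA), 0 otherwise.

The predictor is a two-layer stacking ensemble whose meta-features come
from K-fold cross validation rather than from refitting base learners on
the full training set:

1. The training set is partitioned once into K stratified folds of equal
   or near-equal size (per-fold class counts differ by at most one).
   The single shared partition keeps every base learner's out-of-fold
   (OOF) vector aligned row-by-row.
2. Each base learner b is fitted K times, each time on the complement of
   one fold. The OOF value of a training sample is the positive-class
   probability assigned by the one fold model that excluded it, so no
   meta-feature entry is ever produced by a model that saw its sample.
3. The final classifier is trained on the n × N matrix of OOF
   probabilities against the true labels.
4. At prediction time, base learner b's meta-feature for a new sample is
   the arithmetic mean of its K fold models' probabilities; the final
   classifier maps the N meta-features to the 6mA probability. Fold
   models are stored in the serialized model for exactly this reason —
   nothing is refitted at prediction time.

Base learners must emit positive-class probabilities (averaging hard
labels would discard the information the second layer learns from). The
SVM therefore runs in its probability-emitting mode — a sigmoid
(Platt)-calibrated SVC.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| window length | 41 nt | length of every input window; models reject other lengths at prediction time |
| encoders | one-hot + EIIP | 205 features for 41 nt; any of the seven encoders can be combined |
| ENAC window S | 5 nt | sliding-window width, step 1 |
| k-mer k | 3 | 64 lexicographic columns (A<C<G<T) |
| K (folds) | 5 | CV fold count for meta-feature construction; configurable ≥ 2 |
| first layer | XGBoost, gradient boosting, LightGBM | the configuration selected by backward elimination |
| second layer | SVM (calibrated) | near-tied with LightGBM/logistic regression in the sweep; all are selectable |
| hold-out ratio / repeats | 0.8 / 5 | repeated stratified 8:2 splits for all selection protocols |
| screening cutoff | 0.81 mean ACC | single-encoder threshold below which forward search discards a candidate |
| decision threshold | 0.5 | label = 1 iff probability ≥ threshold; used for SN/SP/ACC/MCC, never for AUC |
| learner hyperparameters | library defaults + fixed seed | no tuning is performed anywhere |

## Encoding conventions

Positional blocks always use base order A, C, G, T. Feature names are
`<prefix>_<i>` with a 1-based index restarting per encoder block
(`one-hot_96`, `EIIP_19`, ...), so one-hot index j addresses position
⌈j/4⌉ and base (j−1) mod 4. EIIP constants are stored exactly as the
4-decimal literature values (A 0.1260, C 0.1340, G 0.0806, T 0.1335).
ANF at position i is the frequency of that position's own residue within
the prefix 1..i (hence always 1 at position 1). The k-mer denominator is
the window count L−k+1, the standard overlapping-k-mer frequency. Under
the opt-in `mask` alphabet policy, non-ACGT residues contribute zeros to
positional encoders and are excluded from composition counts; the default
policy rejects them outright, and U is never silently mapped to T.

## Selection protocols

All three searches use mean hold-out ACC as the criterion (AUC is
recorded in the trace but never selects) and are deterministic given the
base seed, hence replayable from their traces.

* Forward feature search: screen each encoder alone with a single
  screening learner; discard those under the ACC cutoff; seed with the
  best survivor; accept an addition only on strict improvement.
* Backward classifier search: from the full first layer, evaluate every
  single-learner removal per round; accept the best removal when its ACC
  is ≥ the current set's (a learner whose removal does not hurt
  contributed nothing). Exact ties between removals are broken toward
  removing the later learner in list order; the search stops when no
  removal qualifies or one learner remains.
* Second-layer sweep: evaluate each candidate final classifier over the
  fixed first layer; highest mean ACC wins, first seen wins exact ties.

Confidence intervals over hold-out repeats are Student-t:
mean ± t((1+c)/2, m−1)·sd/√m. With a single repeat the interval is
undefined and reported as absent rather than degenerate.

## Metrics

SN/SP/ACC/MCC come from the exact ratio formulas on integer counts; any
metric whose denominator is zero is reported as `None`, never zero-filled
(zero-filling would silently bias the greedy searches). AUC is the
normalized rank-sum with average ranks, which equals both the fraction of
correctly ordered positive/negative pairs (ties ½) and the trapezoidal
area under the tie-aware ROC curve; tests verify the pairwise equivalence
directly.

## Synthetic data generator

The generator emulates the *shape* of 6mA benchmarks: fixed odd length
(default 41), both classes centred on A with probability 1 (negatives are
adenine-centred too — the harder and more realistic discrimination), and
class-dependent position-specific composition. Each class samples
positions independently from its own position weight matrix (PWM); a PWM
of signal strength s blends a uniform background with a seeded random
preferred base per position, `(1−s)·0.25 + s·indicator`. Strength 0.8
versus a uniform negative PWM gives a strongly separable dataset used for
recovery tests; an identical PWM for both classes gives the null dataset
used for calibration tests.

What the generator does **not** model: dinucleotide or longer-range
correlation, genome-specific base composition, and motif realism. Passing
the recovery and null tests therefore demonstrates that the pipeline is
mechanically correct and well calibrated, not that it attains any
particular accuracy on real Rosaceae/Rice/Arabidopsis data — that check
is the optional, download-dependent `scripts/rosaceae_benchmark.py`.

## Numerical and design choices

* Fold assignment is stratified and seeded; a training complement with a
  single class raises an error rather than being silently imputed.
* Fold partitioning is delegated to scikit-learn's (Stratified)KFold;
  learners are the scikit-learn / XGBoost / LightGBM implementations with
  their defaults and a fixed `random_state`; everything is single-threaded
  for bit-reproducibility.
* The label threshold is inclusive (probability ≥ threshold ⇒ 1) and must
  lie strictly inside (0, 1).
* Serialized models are format-versioned joblib archives containing the
  encoder specs, all K×N fold models, the final model and the fold seed;
  loading anything else raises a serialization error, and a reloaded
  model still enforces the training window length.
* Test problem sizes: recovery and null calibration use 500 sequences per
  class with an 80/20 split; the search-protocol tests use 120 per class
  with 2 hold-out repeats — the smallest sizes at which the signal
  encoders sit comfortably above the 0.81 screening cutoff while noise
  components sit far below it.

## Known limitations

* Two layers only; no heterogeneous per-base-learner encodings; no neural
  base learners.
* No hyperparameter tuning or nested cross-validation — the selection
  protocols compare default-parameter learners, as the design intends.
* The probability calibration of the final SVM inherits the sigmoid
  assumption of Platt scaling; AUC is unaffected (rank-invariant) but
  absolute probabilities near 0/1 should not be over-interpreted.
* The single-file `|1`/`|0` FASTA dialect and the `mask` alphabet policy
  are conveniences; the canonical input remains the validated two-file
  convention.
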