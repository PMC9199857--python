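# Methods

This note documents the model, the synthetic-data generator, the numerical
choices, and the limitations of `mamlp`.

## The classification problem

Input is a samples × features table of morphometric measurements —
gray-matter volume and mean cortical thickness per region of interest
(ROI) — extracted from structural MRI under many brain parcellation
atlases and concatenated column-wise, one block per atlas version.  The
target is the ordered three-stage label NC (normal control), MCI (mild
cognitive impairment), AD (Alzheimer's disease), coded 0/1/2 throughout.
The class order is fixed everywhere (confusion-matrix axes, tie-breaking,
softmax heads).

## Atlas registry and filtering

The atlas layout is a *registry*: an ordered list of atlas versions, each
with a family key, an ROI count, and a half-open column span.  Spans must
be pairwise disjoint; a manifest with overlapping spans or duplicate names
is rejected at load time.

Filtering keeps exactly one version per family — the one with the maximal
ROI count, ROI count being the only detail measure the catalogue provides.
Ties (which never occur in the packaged catalogue) break to the
first-listed version so the operation is deterministic.  Filtering does
not touch column indices; `select_columns` then slices the matrix to the
retained spans and re-packs the registry contiguously.  Applying the pair
(filter, select) twice is a no-op, which the tests assert.

The packaged catalogue holds 30 versions in 13 families.  (The catalogue's
version tokens would enumerate a few more; the packaged fixture keeps the
stated total of 30 by omitting the three coarsest MIST resolutions, which
no filtering outcome depends on.)  The packaged column layout is synthetic:
2 features per ROI (one volume, one thickness), laid out in catalogue
order; the retained 13 atlases then span 6,072 columns.  The feature
composition of the original cohort is not public, so the layout is an
emulation convention, not a claim about the real table.

## Preprocessing

Order is fixed: filter → repair → standardize.  Standardization statistics
are therefore computed on the filtered, repaired matrix only; a test
verifies that an extreme value in a dropped column cannot shift them.

**Repair.**  Missing cells become 0.  Infinite cells become the mean of
their feature column's *finite* entries, computed before any replacement —
a feature-level average is the only scale-meaningful choice when adjacent
atlas blocks differ by four orders of magnitude.  A column with no finite
entries at all is zeroed with a warning rather than aborting a batch run,
mirroring the missing→0 rule.

**Standardization.**  One global scalar mean and one global *population*
standard deviation over all N × M entries; every entry maps through
(x − mean)/std.  A per-feature mode exists behind `per_feature=True` for
experimentation but is not the default behaviour.  A constant matrix
(std = 0) raises a degenerate-scale error.  In supervised use the
statistics are fitted on the training split and reused on the test split,
which keeps the test data out of every fitted quantity.

## The ensemble model

One subnetwork per retained atlas, seeing only that atlas's column slice:

* ROIs > 100 → three linear layers: linear → ReLU, linear → dropout,
  linear → softmax.  Exactly 100 ROIs falls in the two-layer branch
  (strict inequality; the case does not arise among the retained
  atlases).
* ROIs ≤ 100 → two linear layers: linear → dropout, linear → softmax.

Hidden widths are (128, 32) for three-layer and (32,) for two-layer
subnets — small capacities suited to the small-sample regime; both are
constructor parameters.  The hidden rectifier is noisy during training,
h(z) = max(0, z + ε) with ε ~ N(0, 1) drawn independently per element, and
plain ReLU at evaluation: stochastic inference would make the argmax
prediction rule ill-defined, and the noise is applied at hidden
activations only (the output layer carries softmax, not h).  Dropout is
inverted (surviving units scaled by 1/(1−p)), so evaluation needs no
rescaling.

**Voting.**  The ensemble score vector is the elementwise sum of the N
subnet softmax vectors (it sums to N); the prediction is its argmax, ties
breaking to the lowest class index.  The sum is deliberately not
renormalized — dividing by N cannot change the argmax — though
`predict_proba` divides by N to return a proper probability vector for
scikit-learn interoperability.  Binary-task scores use the positive
class's summed-softmax entry divided by N.

**Training.**  Each subnet is trained independently on its own
cross-entropy loss −log p_y (probability clipped to [1e−12, 1]) against
the shared labels, by plain mini-batch SGD — learning rate 0.001, dropout
0.5, batch size 32, epochs 100 by default, no momentum or weight decay.
Independent training matches a two-step design in which the combination
rule is applied to finished subnet outputs; a joint mode that
backpropagates the averaged vote's cross-entropy through every subnet is
available behind `joint_training=True`.  Weights are initialised
U(−1/√fan_in, +1/√fan_in) from the run seed.  All randomness — split,
initialisation, batch order, dropout masks, activation noise — fans out
from a single seed via `numpy` seed sequences, so a run is bit-reproducible.
The backward pass is hand-derived and checked against central finite
differences (relative error < 1e−5) in the suite.

**Protocol split.**  The evaluation split draws a fixed number of test
samples per class uniformly at random (default 100, giving a 300-sample
label-balanced test set and 2,300 training samples on the emulated
2,600-subject cohort); the remainder trains.

## Metrics

Per-class precision, recall and F1 come from the 3 × 3 confusion matrix
(rows true, columns predicted); 0/0 cases resolve to 0 with a warning.
Macro F1 is the unweighted mean of the three class F1 scores; table-level
precision/recall are macro-averaged, with per-class values always
reported alongside.  The binary AUC is the rank-count form: the number of
(positive, negative) pairs with the positive scored strictly higher, plus
half credit for ties, over |pos|·|neg| pairs.  Half-credit ties follow the
Mann–Whitney convention — under strict counting a constant classifier
would score 0 rather than 0.5, contradicting AUC's meaning; a strict mode
remains available (`ties="strict"`).  The positive class of each binary
task is the later-listed, more progressed stage (MCI in NC/MCI; AD in
NC/AD and MCI/AD).  The tests cross-check these implementations against
scikit-learn's macro F1 and ROC-AUC and scipy's Mann–Whitney U on random
instances.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline must
survive, with defaults chosen as the study conditions:

* **Cohort.**  781 NC / 1,148 MCI / 671 AD (2,600 samples), shuffled.
* **Signal.**  On a random `affected_fraction` (default 0.2) of each
  atlas's features, class means shift by `effect_size` within-class SDs
  per stage in a per-feature random direction, so NC < MCI < AD along
  that direction — a monotone progression mimicking progressive atrophy.
  Unaffected features carry no class information.
* **Magnitudes.**  Per-atlas multiplicative scales are log-spaced over
  (5, 15,000) (defaults), so block mean magnitudes span from below 10 to
  above 10,000.  Base feature values are log-normal (σ = 0.5), keeping
  volumes positive and right-skewed; within-class noise is standard
  normal before scaling.
* **Contamination.**  After signal generation, each cell independently
  becomes missing with probability `nan_rate` or ±∞ with `inf_rate`
  (defaults 0.001 each — sporadic, as registration failures are); exact
  positions are recorded in the truth record, and `contamination_report`
  reconciles matrix counts against it.

What the generator does **not** model: inter-ROI correlation (features
are independent given class), site/scanner effects, age and sex
covariates, and any real anatomical structure.  Independent noise makes
classification *easier* than real data, so passing learnability tests
demonstrates that the pipeline works mechanically, not that it would
reach any particular accuracy on a real cohort; accuracies measured on
synthetic cohorts are properties of the generator's settings.

## Problem sizes used in tests and the acceptance script

Structural checks (filtering, depth rule, split) run on the full packaged
registry and the full 2,600-sample cohort.  The strong-signal (effect
size 2) and null (effect size 0) training checks run on the full cohort
with the default configuration (the null run uses 20 epochs — with no
signal there is nothing further to learn).  The effect-size sweep
(δ ∈ {0, 0.5, 1, 2} × 3 seeds) runs on 600-sample cohorts with 150-sample
balanced test sets and 15 epochs: the monotone trend being tested is a
property of the signal model, not of cohort size, and the smaller runs
keep the sweep proportionate to the rest of the suite.  Unit-test
fixtures use a two-atlas registry (400 features) with a milder scale
range, sized so training tests converge in seconds.

## Numerical choices

* Softmax is computed with max-subtraction; outputs are valid probability
  vectors for arbitrary finite inputs.
* Cross-entropy clips probabilities at 1e−12, so a confidently wrong
  subnet yields a large finite loss, never ∞.
* CSV round-trips are exact: floats are written with 17 significant
  digits and parsed with correctly-rounded conversion.
* Model persistence stores the registry and layer shapes as JSON and the
  weight arrays as NPZ; save → load round-trips bit-exactly.
* A non-finite training loss raises a divergence error naming the epoch
  rather than silently producing NaN parameters.

## Known limitations

* The global (scalar) standardization leaves low-magnitude atlas blocks
  with small post-transform variance, which slows their subnets' SGD
  convergence at lr 0.001; this is faithful to the design rather than a
  defect, and the per-feature mode exists for comparison.
* Subnet training is sequential on one CPU; wall time scales with the
  widest atlas (1,000-ROI Schaefer dominates).
* The generator's independence assumptions overstate separability (see
  above); no attempt is made to reproduce published accuracies from the
  original, non-redistributable cohort.
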