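# Methods

## The classification problem

Human skin-sensitization evidence is graded on a 6-level potency scale:
categories 1–4 are sensitizers (extreme to weak), 5–6 non-sensitizers. The
package collapses this to the two decisions a defined approach must make:
hazard (sensitizer vs non-sensitizer) and, for sensitizers, potency
(strong 1A = categories 1–2 vs weak 1B = categories 3–4). Inputs per
substance are five assay features — C- and K-peptide DPRA depletion (%,
continuous), KeratinoSens EC1.5 (continuous concentration, right-censored
at 2000 because larger values are not measured precisely), the binary
h-CLAT call, and SENS-IS binarized so any sensitizer call (extreme…weak) is
positive — plus an open block of named physicochemical descriptors and one
scalar distilled from a SMILES sequence-embedding model.

## Preprocessing

Rows with missing required assay values are removed (no imputation; the
modelled tables are complete by construction). Descriptors are
redundancy-pruned: a greedy scan in column order keeps a feature iff its
absolute Pearson correlation with every already-kept feature is below 0.75,
and maps each dropped feature to the kept representative that triggered the
drop. Absolute correlation is used because a negatively duplicated feature
is equally redundant; zero-variance columns are dropped with an explicit
reason since their correlation is undefined. Pruning applies to descriptors
only — the five assays and the embedding scalar are domain-chosen inputs,
not a redundant pool. Kept descriptors and the embedding are standardized
to mean 0, variance 1 using population variance (so the training sample has
variance exactly 1), with the scaler fitted on training rows only.

The train/test split is stratified by the 6-level potency category at an
8:2 ratio. The total test size is `ceil(0.2 n)` — 122 substances give
97 train / 25 test — allocated across strata by largest remainder on each
stratum's exact quota; singleton strata go to the training side with a
warning.

## The bagged stage model

`BaggedXGBClassifier` draws five bootstrap subsets (80% of the training
set, round-half-up, sampled with replacement; draws are keyed to the sorted
id list so results do not depend on row order). Each subset gets an
exhaustive grid search over learning rate {0.01, 0.1, 0.2}, boosting rounds
{50, 100, 200, 300, 500}, depth {3, 5, 7, 9}, subsample {0.6, 0.8, 1.0}
and `scale_pos_weight` ({0.5, 1} for the hazard stage, {1, 2} for the
potency stage, reflecting the flipped imbalance), scored by stratified
5-fold cross-validated balanced accuracy. Ties take the first grid point in
enumeration order (keys in the order listed above, last key fastest), so
tuning is deterministic. Folds are stratified because an unstratified fold
at n≈78 can lose the minority class entirely; when the minority class has
fewer members than folds, the fold count drops to that class count with a
warning. The winning point is refitted on the whole subset. Prediction is a
majority vote of the five hard labels — five voters cannot tie — and the
positive vote fraction (0, 0.2, …, 1.0) is kept as a continuous score.

The two-stage cascade trains stage 2 on the *true* sensitizers rather than
stage-1 positives, which lets it be evaluated independently on every true
test sensitizer as well as in cascaded mode (stage 2 runs only on stage-1
positives; a stage-1 negative is final). Each stage draws its own derived
seed from the master seed; per-subset searches likewise use independently
derived seeds.

## Feature selection and explanation

Importance is per-feature gain (training-loss reduction) averaged over the
five learners, with features unused by a learner contributing zero. Top-k
selection includes every feature tied with the k-th value, so a tie at the
cutoff can return more than k features. The assay-substitution step swaps
the least-important selected assay for the best excluded feature —
trading an expensive in vitro test for a free computed descriptor at equal
accuracy. Candidate feature sets are compared by refitting the full bagged
pipeline per candidate on identical rows and seeds and scoring held-out
balanced accuracy; selecting on the test set mirrors the study protocol
and carries an optimistic-bias risk, so all candidate scores are reported
for audit. Ties favour fewer features, then the substituted variant.

Explanations are exact TreeSHAP attributions on the margin (log-odds)
scale, where additivity (base value + Σ attributions = raw margin) is exact
per learner; the ensemble explanation is the unweighted mean over the five
learners. Because the final call is a vote of hard labels, the sign of the
summed average attribution can disagree with the voted label on close
votes; such substances are flagged as discordant, which is expected
behaviour, not an error. Summary rankings use mean |attribution|
(configurable to signed means), ties broken by feature name.

Two ROC-AUC variants are reported: `auc_hard` scores the hard majority
labels (a two-point ROC, identically equal to balanced accuracy — the
package's default reading) and `auc_score` is the Mann–Whitney area on vote
fractions with ties counted ½.

## Numerical choices and degenerate inputs

* Metrics with zero denominators are reported as undefined (`None`), never
  as 0.
* Report percentages are rounded half-up to one decimal; internal values
  stay exact.
* TreeSHAP outputs are single precision. Additivity is asserted at 1e-6
  wherever float32 can express it, and at the float32 summation
  forward-error bound `n_terms · eps32 · (|base| + Σ|φ|)` beyond that
  (observed residuals are a few ULP).
* The embedding scalar is the grand mean over token positions and hidden
  dimensions of the last-hidden-layer matrix; pooling over tokens first is
  numerically identical to a flat grand mean. The built-in backend hashes
  character trigrams through BLAKE2b into unit-interval reals — fully
  deterministic, offline and platform-independent; a pretrained SMILES
  language model (hidden size 768) can be plugged in through the
  `EmbeddingProvider` contract, with the backend id recorded in the feature
  cache since embeddings are checkpoint-dependent. Inference uses no
  dropout.
* Applicability-domain flags mark features outside the training min/max
  and an EC1.5 sitting exactly at the 2000 cap (censored readouts carry an
  elevated false-negative risk).

## The synthetic generator

`generate()` emulates the statistical structure of a Cosmetics-Europe-style
battery, not its chemistry. Each substance draws a potency category from an
imbalanced 6-vector (default (0.10, 0.10, 0.24, 0.24, 0.16, 0.16),
extrapolated from the 5/12/8 1A/1B/NC test composition) and a latent score
`u = (7 − category)/6 + N(0, noise_sd)`. All readouts are monotone, noisy
functions of `β·u`, where `β` (`effect`, default 1) is a global effect-size
multiplier:

| feature | model | direction |
|---|---|---|
| EC1.5 | `min(2000, exp(8 − 4βu + ε))` | lower when potent; censoring grows toward weak categories |
| C/K depletion | `100·logistic(−3 (−3.5) + 6βu + ε)` | higher when potent |
| h-CLAT | `Bernoulli(logistic(−1 + 3βu))` | more positives when potent |
| SENS-IS | 5-level threshold of `β(u − ½) + ε` | ordinal in potency |
| descriptors | block-correlated Gaussians (4 blocks, within-block r = 0.85); first block shifted by `βu` | carries signal + redundancy |
| embedding | `0.5βu + N(0, 1)` | weakly informative |

At `β = 0` every feature is exact noise, giving a null condition for
calibration checks. The free noise scales (`noise_sd = 0.05`,
`assay_noise_sd = 0.5`) were fixed once so that the generator's defining
conditions hold with margin: a strong-effect battery (`β = 2`, n = 400) is
reliably separable (stage-1 balanced accuracy ≥ 0.85 across seeds) while
the null stays in the chance band. SMILES strings come from a bundled pool
of 150 valid structures; they feed the deterministic embedding backend but
carry no generated signal (the embedding column does). Missing assay values
are injected by independent per-assay Bernoulli masking; the default rate
is 0 because the emulated modelling table is complete after row removal.

What passing tests on this generator do **not** show: real assay error
structure (the generator's noise is homoscedastic and independent across
assays), real descriptor distributions or their relation to structure, or
transferability of the embedding feature — on real data the embedding
scalar's value depends entirely on the pretrained checkpoint.

## Problem sizes and grids used in checks

End-to-end synthetic runs in the test suite and the acceptance script use a
single-point hyperparameter grid (learning rate 0.1, 100 rounds, depth 3,
subsample 0.8, weight 1) rather than the full 360-point search: with five
bootstrap subsets and 5-fold CV the full grid costs ~9000 model fits per
stage, which adds nothing to a synthetic-recovery check. The full grid
remains the default for `BaggedXGBClassifier` and the `train` CLI command.
Recovery runs use n = 400 (320 train / 80 test) and 20 null seeds.

## Known limitations

* The real study's trained model is not reproducible here: its substance
  table lives in a journal appendix and its embedding feature is
  checkpoint-dependent. The package reproduces the *method* and the metric
  arithmetic of its published confusion counts.
* Test-set-based candidate selection (as in the study protocol) is
  optimistically biased; use nested validation for honest generalization
  estimates.
* EC1.5 units are treated as unitless magnitudes with the 2000 cap.
* No probability calibration, alternative base learners, multi-class AUC
  or confidence intervals.
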