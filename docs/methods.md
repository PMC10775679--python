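# Methods

## The problem and the pipeline

A rare disease leaves traces in the EHR — comorbidity codes, abnormal
laboratory values — even when the diagnosis code itself was never
recorded. The pipeline has three stages: (1) learn, from diagnosed cases
and eligible controls, what a patient with disease *q* looks like given
every diagnosis *except* *q* and its exclusions; (2) score all
participants and binarize at a high-confidence threshold; (3) among
participants whose case/control status is unknown, estimate how many are
undiagnosed cases by correcting the positive-prediction rate for the
classifier's measured error rates.

## Case/control/unknown semantics

For query phecode *q* and a participant with recorded code set *C*:
case iff *q* ∈ *C*; unknown iff *q* ∉ *C* but an exclusion phecode of *q*
is in *C*, or the participant's sex does not match a sex-restricted *q*;
control otherwise. Exclusions mark related conditions that make a
non-case untrustworthy as a control. Codes are binary present/absent
indicators; dates and recurrence are ignored.

**Masking scope.** The query and its exclusions are hidden from the input
in *every* example — cases, controls, unknowns, and inference inputs —
not only in cases. Masking only cases would leak label information at
inference time (an unknown's exclusion code would be visible exactly when
the label is contested); a `mask_all_statuses=False` switch restores
case-only masking for comparison.

## Architecture

The many-hot diagnosis vector is treated as a single sequence position:
projected once into the embedding dimension, then passed through decoder
blocks of self-attention (no causal mask — the code ordering is
alphabetic, not temporal), cross-attention to the embedded query, and a
feed-forward sublayer, each wrapped in residual + layer norm. With one
position, softmax attention weights are identically 1, so both attention
sublayers reduce algebraically to value+output projections; the query/key
projections would receive zero gradient and are not materialized
(`n_heads` is validated but has no numerical effect at sequence length 1).
Cross-attention therefore injects a learned per-query vector into the
stream and the feed-forward sublayer supplies diagnosis-by-query
interactions. Demographics (z-scored age with training-split statistics
persisted in the checkpoint, and a sex indicator) map through one dense
layer to vocabulary dimension, are added to the output projection, and the
sum is layer-normalized over the vocabulary axis — the only dimension
assignment under which the stated addition and the final dot product with
the one-hot query type-check. The scalar logit passes through a logistic
transform (equivalently a two-logit softmax against a zero reference),
giving a probability score.

A set-of-tokens encoding (one position per recorded code) is a coherent
alternative reading of the architecture; it is deliberately not
implemented — the single-position design is the primary semantics here,
and every learnability and negative-control study below validates it
directly.

## Training

Binary cross-entropy on case/control labels; Adam (β₁=0.9, β₂=0.999,
ε=1e-8); Glorot-uniform initialization; gradients hand-derived and checked
against central finite differences to ~1e-6 relative error in the test
suite. Default small configuration: embedding 32, 1 block, feed-forward
64, batch 64, learning rate 1e-2, dropout 0 — sized so a 20,000-example
corpus trains in seconds on one CPU; all fields are exposed. A 20%
validation split is drawn by example inside the training corpus (never
overlapping a held-out CV fold — passing a corpus that still contains the
test fold is an error); early stopping triggers after 5 epochs without
validation improvement, capped at 54 epochs (18 during tuning), and the
best epoch's weights are restored. Optionally the model is re-initialized
and retrained on the full corpus for the selected epoch count.
Hyperparameter search is successive halving: all candidates train briefly,
the top third by validation loss survive on a tripled budget, until one
remains; per-candidate seeds derive from a stable hash of the candidate's
configuration so the selection cannot depend on listing order.

## Corpus construction

k cases and k controls per eligible query (default k=100; studies here use
k=50), sampled uniformly without replacement within each (query, label)
stratum; a participant may recur across queries. Phecodes with fewer than
k cases or k eligible controls are never queried but remain as features.
Folds partition participants: greedy longest-processing-time assignment
(participants sorted by example count, ties by id) into the fold
minimizing the summed squared (case, control) tallies after the addition —
a two-dimensional balance criterion, since balancing totals alone lets the
case share drift. Per-fold case and control counts are verified against a
±10% tolerance (plus half an example of rounding slack) and violations
raise an error naming the heaviest participants. The assignment is
deterministic; the `seed` argument exists for interface symmetry.

## Metrics

Predicted case iff score > threshold (strictly; a score exactly at the
threshold is a predicted control). The diagnostic OR uses a 0.5
continuity correction on all four cells, making it finite and positive for
every table — including degenerate ones: with *no* predicted positives
the corrected OR collapses to (TN+0.5)/(FN+0.5), which is large for a rare
phenotype despite the classifier asserting nothing. Summaries in the
negative-control study therefore restrict the OR band check to queries
with a nonempty positive margin. PPV is reported as precision TP/(TP+FP)
("as worded") with the sensitivity-form TP/(TP+FN) ("as printed")
available; neither is asserted as the canonical intent. Evaluation drops
unknowns, sex-mismatched non-cases, and training-set members (rows are
flagged, not removed, so downstream stages choose). The cross-phecode
matrix restricts to diagnosed cases of phecodes A and B, queries A
treating B's cases as controls, reports the median OR across the supplied
models, blanks the diagonal and exclusion pairs, and counts cases of both
A and B as cases of A (switchable to dropping them).

## Undiagnosed-case estimation

Strata per phecode: diagnosed cases; confirmed controls (status control,
every associated test inside the sex-specific reference range *and*
within 1 population SD of the sex-specific mean — means/SDs over the full
cohort per sex, per the "population" reading); unknowns (everyone else,
including exclusion-code holders and unconfirmed controls). The estimator
assumes the positive rate among unknowns is the mixture of the rate on
true cases (TPR, from diagnosed cases) and true controls (FPR, from
confirmed controls): Pu = (UP − FPR·U)/(TPR − FPR). TPR ≤ FPR raises a
non-identifiability error before any clamping; afterwards Pu is clamped
to [0, U]. The estimand is undiagnosed cases *within the unknown group*:
a true case whose biomarkers happen to fall within 1 SD is absorbed into
the confirmed controls and is outside Pu's reach (it also slightly
inflates FPR — the dominant small-sample bias, downward). The bootstrap
resamples participants with replacement within each stratum (keeping all
three rates estimable per replicate), recomputes TPR/FPR/UP/Pu, takes
percentile 2.5/97.5 bounds, drops and counts TPR ≤ FPR replicates, and
aborts if more than half degenerate. Fraction undiagnosed is
Pu/(Pu + diagnosed cases).

## Biomarker association scans

Per phecode–test relationship (direction above/below/outside): a logistic
regression of the abnormal-in-expected-direction indicator, and a linear
regression of the quantitative value z-scored per sex on in-range
statistics and sign-aligned (above unchanged, below negated, outside
absolute value), both on the binary prediction with age, sex, and
ethnicity-indicator covariates (largest category as reference). Reference
range boundaries count as normal (strict inequalities). Control-only
variants drop cases and exclusion holders (and, for the linear model,
abnormal results). Separation or non-convergence flags a result
unestimable rather than dropping it. The permutation null permutes the
phecode column of the relationship table uniformly at random, reruns the
scan, and reports (1 + #permutations ≥ observed)/(n_perm + 1) over
Bonferroni-significant expected-direction counts (family = number of
relationships).

## The synthetic-cohort generator

Per participant: sex Bernoulli(0.5); age Uniform(40, 70) (a typical
mid-life biobank recruitment window); ethnicity categorical with no
effect, present so covariate adjustment is exercised. Per disease: latent
truth Bernoulli(prevalence) among sex-eligible participants; the
disease's own code recorded iff true *and* Bernoulli(1 − underdiagnosis
rate) succeeds — underdiagnosis is Bernoulli thinning, a modeling choice
(the real process is the estimand, not observed); no false diagnoses by
default (a miscoding rate exists for robustness studies). Signature
comorbidity codes are emitted independently given truth (conditional vs
background probability); correlated signatures are out of scope. Test
values are sex-specific unit normals shifted by the effect size (in SD
units) in true cases, with reference ranges at mean ± 1.5 SD per sex, so
~87% of unaffected values are in-range and the 1-SD confirmation rule is
the binding constraint. Every participant has every test, emulating
recruitment-time assays.

What the generator does *not* emulate: longitudinal visit structure, code
timestamps, ICD hierarchy noise, correlated comorbidity structure beyond
the planted signatures, care-utilization differences, or miscoded
diagnoses (by default). Passing studies therefore demonstrate the
pipeline's internal correctness and calibration under a known generative
model — not performance on real EHR data, where coding noise and
confounding are richer.

## Validation studies and problem sizes

The standard conditions: 10 diseases at 2% prevalence in a 200-phecode
vocabulary, each marked by a 5-code signature (0.9 conditional vs 0.05
background); half the diseases carry an exclusion phecode so unknown
handling and masking are exercised. Studies run at n = 5,000 participants
(learnability, negative control), n = 10,000 × 100 replicates
(estimator calibration, one disease, underdiagnosis 50%, 2-SD biomarker
effect, with a transparent signature-count-≥3 rule as the classifier so
the study isolates the estimator), and n = 2,000 × 50 replicates
(permutation null with zero planted effects). These sizes are scaled-down
analogues of a biobank analysis chosen so the whole battery completes in
minutes on one CPU; the spirit of each check — oracle equivalence, known
ground truth recovery, chance-level negative controls, super-uniform null
p-values, bitwise reproducibility — is size-independent.

## Numerical choices and conventions

Layer-norm ε = 1e-5; BCE clipped at 1e-12; float64 throughout (exact
same-seed reproducibility across runs on one platform); score ties at the
threshold go to control; undefined PPV (zero denominator) is NaN, never
0; the OR of the all-zero table is exactly 1 by symmetry of the
correction; zero-variance in-range strata make quantitative normalization
an error, not a silent NaN; all randomness flows from explicit integer
seeds through `numpy.random.default_rng`.

## Known limitations

The single-position encoding cannot express attention *between*
individual diagnoses; with hundreds of codes and planted additive
signatures this does not bind, but richer code-interaction structure may
favor the token-sequence variant. The underdiagnosis estimator inherits
the paper-level assumptions — unknowns behave as a two-component mixture
of case-like and control-like prediction behavior, and confirmed controls
are uncontaminated; both fail gracefully (non-identifiability errors,
documented downward bias) rather than silently. Survival and
disease-burden regressions on external reference data are out of scope.
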