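# Methods

`pdmci` implements a screening analysis of picture-description responses for
mild cognitive impairment (MCI) subtypes. Participants describe a pictured
scene (a Cookie Theft–style stimulus); acoustic features are extracted from the
recording by an external tool and language features are computed from a
verified, POS-tagged transcript. The analysis asks which individual features,
which pairwise feature contrasts, and which penalized combinations of features
separate healthy controls (HC) from amnestic MCI (aMCI) and non-amnestic MCI
(naMCI).

## Feature model and preparation

The default feature registry names 44 acoustic features (pitch, perturbation,
intensity, pausing, formant, and vocal-tremor measures) and 47 language
features (content-unit counts, lexical-category counts, and response-length
measures), 91 in total. Exactly six acoustic vocal-tremor measures (ATrP, FTrP,
ATrI, FTrI, ATrF, FTrF) are permitted to be missing, reflecting that tremor
estimation can fail on some recordings.

Every feature is **quantile normalized** before analysis: within a column, the
non-missing values are replaced by Φ⁻¹(rank/(n+1)), ties receiving the mean of
their rank positions. The target distribution is standard normal so that
contrasts read in standard-deviation units; the tie rule makes the transform
invariant to permutation of equal values. Any strictly monotone transform of a
column produces the identical normalized column, which is why the synthetic
generator's native-scale links are immaterial downstream.

Missing tremor values are completed by **SoftImpute** — iterative
soft-thresholded SVD with maximum rank 5, a shrinkage target of 1% of the
leading singular value annealed along a geometric continuation path, tolerance
1e-4, at most 200 iterations per level. The continuation path matters: a single
small shrinkage level can stall at a poor fixed point, while warm-starting from
strong shrinkage recovers planted low-rank structure to high accuracy (the test
suite plants a rank-1 matrix with 10% masked entries and requires RMSE < 0.1).
Imputation is always fitted separately on the train and test sides of a split,
so completed values never leak across; a column entirely missing within a split
falls back to 0, the post-normalization column median. Imputed values feed only
the penalized risk-score models — the per-feature screen and the contrasts drop
incomplete rows instead.

**Contrasts** are the differences A − B of quantile-normalized same-modality
feature pairs, A preceding B in registry order: C(47,2) = 1081 language pairs
plus C(44,2) = 946 acoustic pairs, 2,027 in all, and no cross-modality pairs.
Differences are used rather than ratios to avoid scale mismatch and division by
values near zero.

## Transcript scoring

Content units are predefined objects, actions, and locations in the stimulus,
stored in an editable JSON lexicon with relatedness (related/unrelated to the
depicted scenario) and side-of-picture (left/right/both) attributes. Matching
is case-insensitive, longest-match-first over multi-token spans, left-to-right
and non-overlapping, so "cookie jar" counts once as the jar unit rather than as
"cookie" plus "jar". Counts are reported under RELATED/ALL, DISTINCT (repeats
counted once), and per-side filters. The shipped Cookie Theft lexicon is a
documented default, not a reproduction of any study's scoring rubric; all
analyses parameterize over the lexicon.

Lexical categories use Penn Treebank tags (nouns NN*, prepositions IN, modals
MD, ...) with closed-class word lists for indefinite articles ({a, an}),
function words, pro-sentences ({yes, okay, ...}), negations, and fillers. POS
tagging is an input, not a stage: the scorer consumes pre-tagged CoNLL-like
TSV, which keeps the package deterministic and self-contained.

Several length measures lack canonical definitions and are implemented as
documented, pluggable defaults: a *complete sentence* contains at least one
finite verb tag (VBD/VBP/VBZ/MD) and one nominal; a *phrase* is a chunk opened
at the sentence start or at a coordinator/preposition/wh-word/infinitival
marker; *syllables* use a vowel-group heuristic with a silent-final-e rule
(hand-checked at ≥90% exact agreement on a fixture list). These are explicit
design choices, not claims about any external scoring implementation.

## Association screen

For each feature or contrast the screen fits an unpenalized logistic regression
of case status (case = 1) on age, gender, and the target, and reports the Wald
p-value and the sign of the target's coefficient (positive: cases higher after
adjustment). Wald rather than likelihood-ratio p-values follow the convention
of standard GLM summaries. Complete or quasi-complete separation is detected by
a diverging coefficient norm and flagged rather than silently reported.

P-values are adjusted by the **Benjamini–Yekutieli** step-up procedure,
adj₍ᵢ₎ = min over j ≥ i of p₍ⱼ₎ · m · c(m)/j with c(m) = Σ 1/k, valid under
arbitrary dependence — appropriate because all features derive from the same
response. Features and contrasts form separate FDR families, mirroring their
separate result tables.

## Per-feature classifiers and threshold rule

Each target's practical value is measured by an L2-penalized logistic
classifier on (age, gender, target). The ridge penalty is chosen to minimize
binomial deviance under stratified 5-fold cross-validation (folds are
stratified because the case groups are small); out-of-sample log-odds from
5-fold CV are averaged over 10 repetitions with fresh fold splits, and AUROC is
computed on the averaged scores with the Mann–Whitney convention (ties count
one half). A baseline age+gender-only classifier provides the reference AUROC.

Thresholds for confusion-matrix metrics maximize F1 subject to specificity
≥ 0.85 — the operating regime of a screening tool that must keep false
positives low. Candidates are midpoints between adjacent sorted unique scores
plus ±∞; ties break toward higher specificity, then higher threshold. A
feasible candidate always exists because +∞ gives specificity 1.

## Penalized risk scores

The **PD risk score** for a cohort pair is an elastic-net logistic regression
over all 91 features plus *unpenalized* age and gender (penalty factor 0, so
they are never shrunk away). The solver is written in this package: IRLS with
cyclic coordinate descent on the penalized weighted least-squares subproblem,
warm-started along a geometric lambda path (30 values down to 1e-3 of the
smallest lambda that zeroes all penalized coefficients), with per-feature
penalty factors. It reproduces R glmnet coefficient-for-coefficient at matched
penalties (a cross-check test runs glmnet through Rscript as the independent
oracle; glmnet rescales penalty factors to sum to the number of variables, and
the test applies the same rescaling).

Alpha (L1:L2 mixing, grid 0.0–1.0 in steps of 0.1) and lambda are chosen
jointly by 5-fold cross-validated deviance at the minimum (the lambda.min rule,
not 1-SE), with tremor features imputed separately on each side of every split.
The final model refits on all data at the chosen penalties; each participant's
risk score is the mean out-of-sample prediction over 10 further replications of
5-fold CV, and AUROC is computed on those averaged scores. No participant's
score ever comes from a model trained on a fold containing that participant
(asserted in code). Features are not re-standardized inside the penalized fit —
they are already quantile normalized, and internal standardization would
distort the unpenalized covariates' scale. The three two-class tasks use
independent seeded fold splits.

The **multinomial alternative** fits one penalized softmax model over
HC/aMCI/naMCI (partial-Newton coordinate descent over classes, same penalty
factors). Cross-validated class liabilities, averaged over 10 CV rounds, yield
pairwise liability differences — estimates of the pairwise log-odds — used as
risk scores for aMCI-vs-HC, naMCI-vs-HC, and aMCI-vs-naMCI. The symmetric
softmax parameterization is unidentified up to a per-feature constant on
unpenalized rows; liability differences are invariant to it.

## Synthetic cohort generator

No participant-level data ship with this package; the generator emulates the
cohort structure the analysis assumes so every stage is testable.

* Groups: 62 HC / 18 aMCI / 15 naMCI by default; ages truncated-normal within
  64–85 with group-specific means/SDs (HC 70.3 ± 4.5, aMCI 70.2 ± 7.4, naMCI
  71.5 ± 5.8) and female fractions (35/62, 6/18, 6/15); gender coded female = 0,
  male = 1 throughout.
* Features are generated on a latent standard-normal scale plus group-specific
  mean shifts from an effect map. Count-type language features load 0.6 on a
  shared "verbosity" factor, inducing the correlation among response-length
  counts that the contrast analysis presumes; the within-group covariance is
  otherwise an artifact choice, since no external estimate exists.
* Default effects: −1.2 SD on count-type features and +0.8 SD on F0 variability
  in aMCI, and exactly zero effects in naMCI. The magnitudes were set from the
  binormal AUROC scale — a per-feature shift d gives population AUROC
  Φ(d/√2), so d = 1.2 corresponds to per-feature AUROCs near 0.8 and d = 0.8
  near 0.71, the regime of interest for a usable screening feature. The
  direction pattern (count features depressed, pitch variability elevated in
  aMCI; naMCI null) is what the package's qualitative acceptance checks assert.
* Count-type features optionally map through a monotone rounded link
  (20 + 8·z, floored at 0) to nonnegative counts; quantile normalization makes
  the native scale irrelevant, and the latent scale can be kept for effect-size
  checks.
* Missingness is MCAR at rate 0.05, confined to the six tremor features.
* Toy transcripts mention Poisson(rate)-many related units per participant
  (group-specific rates) in short template sentences, and emit exact
  content-unit ground truth, closing the loop with the scorer.

What the generator does **not** emulate: realistic discourse (transcripts are
templated), non-Gaussian feature marginals beyond the count link, informative
missingness, covariance beyond one shared factor, and any association of age or
gender with diagnosis beyond the group demographics. Passing tests therefore
demonstrate correctness and calibration of the machinery under the assumed
structure, not clinical performance on real cohorts.

## Numerical choices

* Coordinate-descent tolerance 1e-7 on maximum coefficient change; IRLS weights
  floored at 1e-5; numba-compiled inner loops; fully deterministic.
* Quantile normalization of a constant column yields all zeros (every value
  ties at the mean rank, Φ⁻¹(0.5) = 0). An all-missing column is an error.
* Fewer than 5 cases or controls reduces CV folds (minimum 3) with a warning.
* AUROC ties count 1/2; negating scores complements the AUROC.
* A single global seed expands into per-stage seeds via SHA-256 of
  "seed:stage"; identical configuration and seed reproduce every output file
  bitwise (content hashes recorded in the run manifest).

## Problem sizes in the shipped checks

The test suite and acceptance script run at the cohort's own scale (95
participants, 91 features, 2,027 contrasts). Monte-Carlo checks use 200 null
cohorts for screen calibration, 50 seeds for planted-signal recovery at
n = 60/20 with five planted |d| = 1.0 features, and 20 seeds for the subtype
asymmetry check; these sizes give the binomial margins the assertions need
while keeping a full run in minutes on one CPU.

## Known limitations

* The content-unit lexicon and several feature definitions (phrases, complete
  sentences, pro-sentences, syllables-per-word minimum) are documented defaults
  for slots whose external definitions are unavailable; results depend on them
  only through the named feature columns.
* The elastic-net CV selects lambda.min; a 1-SE rule is not implemented.
* Risk scores are log-odds predictions, not calibrated probabilities.
* naMCI analyses at n = 15 are intrinsically noisy; the generator's null naMCI
  effects encode the qualitative finding that the package is built around, not
  a biological claim.
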