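# Methods

This note records the modelling choices, parameters, and numerical
conventions of the `enzdis` pipeline, plus the scope and limitations of the
synthetic benchmark generator.

## Text units and segmentation

A *reference* is (ID, title, abstract). It is segmented into *text units*:
the title is unit 0; abstract sentences follow in order. Sentence boundaries
are `[.!?]` followed by whitespace and an uppercase letter or digit, with an
exception list of ~30 common abbreviations (e.g. "e.g.", "fig.", "al.") and
single-letter initials. Spans are 0-based half-open code-point offsets into
the source field, and concatenating unit texts (with the stripped whitespace)
reconstructs the source exactly — the invariant is enforced by the
`TextUnit` dataclass and tested with property-based tests.

## Dictionary matching

Tokens are maximal alphanumeric runs (hyphens join compound tokens).
Normalization lower-cases everything except short all-caps acronyms
(1–4 letters), which are preserved and match case-sensitively — this is
the policy that keeps an acronym like "AAA" from matching "aaa" in prose.
Matching is longest-leftmost over normalized token sequences: at each token
position the longest dictionary entry anchored there wins, and its tokens
are consumed. An ambiguous surface mapped to several concepts yields one
mention per concept at the same span. A homonym blacklist (normalized
surface forms) removes ambiguous entries before matching; applying it is
idempotent.

A *co-occurrence unit* is a text unit with at least one enzyme and one
disease mention. Enzymes are identified by four-field EC numbers, whose
first field (1–6) is the enzyme class used in the summaries.

## Features

Two preprocessing modes: **removal** drops every token overlapping an entity
mention; **replacement** emits one generic token per mention (`@ENZYME@` /
`@DISEASE@`) at the mention position. Term weights are raw term frequency
times idf = ln(D/dₜ) with no smoothing, so a term in every document carries
exactly zero weight. Vectors are Euclidean-normalized; an all-zero vector is
kept as zero. No stop-word removal and no stemming, by design. The
vectorizer is a scikit-learn `TransformerMixin` (`fit`/`transform`, fitted
attributes `vocabulary_`, `idf_`, `n_docs_`), so the per-category model is a
standard `Pipeline([("tfidf", ...), ("svm", SVC(...))])`.

## Classification

One binary soft-margin SVM per category (categories are non-exclusive).
Training uses *balanced sets*: all positive units for the category plus an
equal-size uniform sample (seeded, without replacement) of negative
co-occurrence units. Kernels: linear, polynomial, radial basis, sigmoid
(scikit-learn `SVC` underneath). The grid is ranked by mean cross-validated
F1 over the four categories; the selection filter keeps parameter sets with
precision ≥ 0.7 and F1 ≥ 0.5 in at least one category. An empty survivor
set is a warning, not an error.

The ensemble's per-unit vote fraction (share of models with a positive
decision value) maps to confidence levels through inclusive thresholds
0.90 / 0.70 / 0.50 / 0.25 for levels 4 / 3 / 2 / 1; below 0.25 the unit is
unassigned (level 0). Semantics are cumulative: "at level ℓ" means
level ≥ ℓ, so the level sets nest and precision/specificity descend from
level 4 to level 1 by construction of the vote ordering.

## Evaluation

`compute_metrics` derives precision, recall, accuracy, specificity, F1,
MCC and FPR from an explicit confusion matrix; every 0/0 is reported as 0.0
and flagged in `MetricSet.degenerate`. `confusion_from_rates` reconstructs a
(possibly fractional) confusion matrix from recall, specificity, and
prevalence — with prevalence 0.5 it reproduces the accuracy and MCC columns
of published per-level result tables from their printed recall/specificity.

Stratified k-fold splitting shuffles each class, concatenates, and deals
round-robin, so per-class and overall fold sizes each differ by at most one.
ROC curves are averaged *vertically*: each fold's step curve (tied scores
collapse to the upper envelope) is linearly interpolated onto a fixed
101-point false-positive-rate grid, true-positive rates are averaged, and
AUC is the trapezoidal integral of the averaged curve.

## Representation quotient

For EC class c with a_c distinct EC–disease combinations and b_c known EC
numbers, the quotient is (a_c / Σa) / (b_c / Σb). This share-normalized
form (not the raw column ratio) is what reproduces the published values;
a class with b_c = 0 is reported as undefined. The acceptance targets t1–t4
recompute the quotients for hydrolases, oxidoreductases, isomerases and
ligases from the published marginals (Σa = 112,805 distinct combinations,
Σb = 5,126 EC numbers) and match the printed 1.64 / 0.76 / 0.86 / 0.45 at
two decimals.

## Synthetic generator

Since the original expert-annotated corpus and dictionaries are not
redistributable, `enzdis.synth` builds a seeded benchmark:

- **Lexicons** — pronounceable nonsense names (1–3 synonyms per concept,
  one- or two-token surfaces), unique synthetic EC numbers spanning classes
  1–6, unique disease IDs. A configurable fraction of enzyme concepts
  additionally receives a short all-caps acronym synonym that is *also*
  planted in filler text — these are the homonyms listed in the manifest
  and used to exercise the blacklist.
- **Corpus strata** (defaults are the study conditions) — 2,500 units with
  an enzyme only, 2,000 with an enzyme and a disease, 500 random filler
  units; units are packed three per reference (title + two abstract
  sentences). Category labels on co-occurrence units follow prevalences
  1382 : 587 : 477 : 366 over 5,031.
- **Signal** — each category has a family of cue phrases. With cue strength
  s ∈ [0, 1], a cue appears with probability (1 + 3s)/4 in units positive
  for the category and (1 − s)/4 in negative units: s = 1 is perfectly
  separable, s = 0 is an exact null (equal rates), and the default s = 0.8
  is a hard-but-learnable regime. Filler words are Zipf-distributed from a
  2,000-word vocabulary disjoint from all lexicon tokens.
- **Gold** — exact mention spans per unit; planted surfaces never reuse a
  homonym acronym, so after blacklisting the matcher output equals the gold
  exactly (tested end to end).

### Generator scope and limitations

The generator validates the *machinery* — matching, feature extraction,
learning dynamics, confidence calibration — not biomedical performance.
Its text is nonsense with planted signal: it has no real syntax, no
morphological variation, no nested real-world terminology beyond what is
planted, and cue phrases are a much cleaner signal than real rhetorical
cues. Published F1/MCC values from the original annotated corpus are
therefore *not* reproduction targets; the acceptance suite instead checks
in-table arithmetic, oracle equivalence, and qualitative learning behavior
(separable corpus → F1 ≥ 0.9; null corpus → chance accuracy and AUC ≈ 0.5;
confidence tiers monotone on held-out data).

## Numerical conventions

- idf uses the natural logarithm with no smoothing; 0/0 metric cases are
  0.0 with an explicit degenerate flag.
- All randomness flows through `numpy.random.default_rng(seed)`; seeds are
  plain integers below 2³¹. Corpus generation, balanced sampling, k-fold
  splitting, and training are each deterministic given their seed.
- Published-value consistency checks tolerate half a unit in the last
  printed place for accuracy (inclusive, since one cell sits exactly on the
  0.0005 boundary) and one unit for MCC, because MCC is recomputed from
  inputs that are themselves rounded to three decimals and the propagated
  input-rounding error exceeds half a unit in two cells.
- ROC interpolation collapses tied false-positive rates to the maximum
  true-positive rate first, so a perfect ranking integrates to AUC = 1.0
  exactly.
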