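# enzdis — enzyme–disease relation mining from titles and abstracts

`enzdis` implements a classical text-mining pipeline that extracts and
categorizes enzyme–disease relations from the titles and abstracts of
biomedical literature records. It is built around sentence-level
co-occurrence of dictionary terms, per-category support-vector-machine
classification of those sentences, and a tiered confidence system.

## Scientific problem

Disease-related knowledge about enzymes is scattered across millions of
abstracts. The pipeline answers, for each enzyme (identified by its EC
number) and each disease (identified by a controlled-vocabulary concept ID):
*does the literature connect them, and in what way?* Four non-exclusive
relation categories are distinguished:

- **causal interaction** — enzyme malfunction induces the disease,
- **ongoing research** — a relation is presumed but not proven,
- **diagnostic usage** — the enzyme is measured to diagnose the disease,
- **therapeutic application** — the enzyme is a drug target or drug agent.

## Model

The pipeline is a five-stage chain:

1. **Corpus I/O** (`enzdis.corpus_io`) — records are read from TSV, JSON
   Lines, or MEDLINE-style XML and segmented into *text units*: the title
   (unit 0) plus individual abstract sentences, with abbreviation-aware
   boundary detection and exact character spans.
2. **Dictionary matching** (`enzdis.lexicon`, `enzdis.cooccur`) —
   longest-leftmost token-anchored matching of enzyme and disease
   dictionaries. Matching is case-insensitive except for short all-caps
   acronyms (≤ 4 letters), which match case-sensitively; a curated homonym
   blacklist removes ambiguous surface forms. A unit containing at least one
   enzyme and one disease mention is a *co-occurrence unit*, the basic
   classification unit.
3. **Features** (`enzdis.features`) — each unit is tokenized with the
   entity mentions either *removed* or *replaced* by generic tokens, then
   vectorized as tf·idf with idf = ln(D/dₜ) (no smoothing; ubiquitous terms
   get zero weight) and Euclidean unit normalization. No stop-word removal,
   no stemming. `TfidfUnitVectorizer` is a scikit-learn transformer, so it
   composes with standard `Pipeline` objects.
4. **Classification** (`enzdis.classifier`) — one binary soft-margin SVM
   per category, trained on balanced sets (all positive units plus an
   equal-size seeded sample of negative co-occurrence units). A kernel/cost
   grid is ranked by cross-validated F1; survivors (precision ≥ 0.7 and
   F1 ≥ 0.5 in at least one category) form a per-category ensemble. The
   fraction of models voting positive maps to confidence levels 4 (most
   precise) down to 1, with 0 meaning unassigned; "at level ℓ" always means
   level ≥ ℓ.
5. **Relation table and summaries** (`enzdis.pipeline`) — co-occurrence
   units expand into (EC number, disease, reference, category, level) rows,
   deduplicated at the maximum level per reference. Summaries include the
   per-EC-class **representation quotient** — a class's share of distinct
   EC–disease combinations divided by its share of known EC numbers
   (> 1 = over-represented in disease literature) — and the intersection
   counts of the four categories at each confidence level.

Evaluation utilities (`enzdis.evaluation`) provide exact confusion-matrix
metrics (precision, recall, accuracy, specificity, F1, MCC, FPR with
explicit 0/0 handling), stratified k-fold splitting, and vertically averaged
ROC curves with trapezoidal AUC.

Because the original annotated corpus and dictionaries are not
redistributable, the package ships a seeded synthetic-corpus generator
(`enzdis.synth`) that plants dictionary terms, per-category cue phrases and
acronym homonyms into nonsense filler text, with an exact gold standard for
end-to-end testing. Generator defaults mirror the study conditions
(2,500 enzyme-only / 2,000 enzyme+disease / 500 random units; category
prevalences 1382 : 587 : 477 : 366 over 5,031 units).

## Running the tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests, hypothesis property tests, and
`tests/test_acceptance.py`, which checks the published-number targets and
the learning-sanity/confidence-structure criteria end to end.

## Worked example

Generate a small synthetic gold corpus, match, train, classify and
summarize (all commands are deterministic given `--seed`):

```console
$ enzdis synth --seed 42 --out gold --n-enzymes 40 --n-diseases 30 \
    --n-enzyme-only 250 --n-both 400 --n-random 50 \
    --cue-strength 0.9 --homonym-fraction 0.1
wrote 700 units in 234 references to gold

$ enzdis match --corpus gold/corpus.tsv --enzymes gold/enzymes.tsv \
    --diseases gold/diseases.tsv --blacklist gold/blacklist.txt --out cooc.tsv
400 co-occurrence units -> cooc.tsv

$ head -3 cooc.tsv
ref_id	unit_index	text	enzyme_ecs	disease_ids	mention_spans
R000001	0	Fipu nicise tepasoha cofamuro fizi suba bekufe.	3.5.3.2	D000001	12:20,30:34
R000001	1	Zileniga rilake zahahu zogo mugu tebahu zubeta siduliha haduteni.	1.16.22.8	D000006	16:22,28:39

$ enzdis train --gold-dir gold --seed 0 --out bundle
ensemble of 7 models/category -> bundle

$ enzdis classify --corpus gold/corpus.tsv --enzymes gold/enzymes.tsv \
    --diseases gold/diseases.tsv --blacklist gold/blacklist.txt \
    --bundle bundle --out relations.tsv
635 relation rows -> relations.tsv

$ head -4 relations.tsv
ec_number	disease_id	ref_id	unit_index	category	confidence_level
1.12.6.19	D000001	R000228	1	ongoing_research	4
1.12.6.19	D000001	R000228	1	therapeutic_application	4
1.12.6.19	D000003	R000103	1	causal_interaction	4

$ enzdis evaluate --gold-dir gold --k 5 --out cv.tsv
cross-validation report -> cv.tsv
```

Mean 5-fold cross-validation scores from `cv.tsv` for this run:

```text
               category  precision  recall    f1   mcc
     causal_interaction      0.908   0.889 0.895 0.798
       ongoing_research      0.772   0.893 0.823 0.635
       diagnostic_usage      0.808   0.846 0.825 0.640
therapeutic_application      0.772   0.889 0.821 0.631
```

And the EC-class summary with representation quotients:

```console
$ enzdis summarize --relations relations.tsv --enzymes gold/enzymes.tsv \
    --level 2 --out summaries
summaries -> summaries

$ cat summaries/ec_class_summary.tsv
ec_class	combos_a	ec_count_b	quotient
1	77	9	1.1
2	50	7	0.92
3	52	7	0.96
4	36	5	0.93
5	59	7	1.08
6	37	5	0.95
```

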