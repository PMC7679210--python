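# triage-lda

Topic modeling of musculoskeletal referral letters for triage support, as a
tested, reusable pipeline:

- **textprep** — clinical-text regularization (lowercasing, enclitic
  expansion, abbreviation/variant normalization, punctuation rules) and
  honorific-driven personal-name masking that preserves clinical eponyms
  (McMurray test, Baker cyst, ...); Porter stemming or lightweight
  lemmatization.
- **enrichment** — dictionary-lookup concept recognition with word-order
  insensitive, stem-tolerant matching against a term → concept-id →
  semantic-type lexicon; injects concept/semantic-type tokens to build the
  four feature variants D1 (words), D2 (+concepts), D3 (+semantic types),
  D4 (+both); bag-of-words construction.
- **topic_model** — latent Dirichlet allocation by collapsed Gibbs sampling
  (numba-accelerated, bit-reproducible from the seed), fold-in inference,
  perplexity, probability/lift/λ-relevance word ranking, perplexity-elbow
  K selection.
- **coherence** — PMI / NPMI / log-conditional-probability over Boolean
  virtual documents (whole letter, sentence, or sliding window) and the
  topic-level aggregates C_UCI, C_NPMI, C_UMass, C_cos, C_V; coherence-based
  selection of the number of topics.
- **triage** — per-treatment binary k-nearest-neighbour classification
  (k=5) on the document-topic matrix with stratified 10-fold
  cross-validation, accuracy (TP+TN)/N, and the prevalence-matched random
  baseline p² + (1−p)².
- **interpretability** — Likert encoding of paired-rater confidence (0–4)
  and similarity (−3..−1, 1..3) ratings, linearly weighted Cohen kappa with
  Fleiss–Cohen standard errors, shipped two-rater ratings fixture.
- **synthetic** — referral-letter-like corpus generator with planted
  topics, synonym clusters, abbreviations, honorific-prefixed names, and
  logistic-link multi-label treatment outcomes calibrated to target
  prevalences — the ground-truth engine behind the test suite.
- **pipeline** — orchestrates the full grid (variants × coherence measures
  × triage CV) with a manifest that reproduces every report cell
  bit-identically.

## CLI

```bash
triage-lda simulate --seed 7 --d 500 --k-true 11 --out corpus.jsonl --truth truth.json
triage-lda prep     --corpus corpus.jsonl --lexicon variants.tsv --mode stem --out streams.jsonl
triage-lda enrich   --in streams.jsonl --lexicon concepts.tsv --variant D2 --out enriched.jsonl
triage-lda fit      --streams enriched.jsonl --k 11 --seed 7 --out modeldir
triage-lda rank     --model modeldir --topic 3 --lambda 0.6 --n 30
triage-lda coherence --model modeldir --streams enriched.jsonl --measure c_v --top-n 10
triage-lda select-k --streams enriched.jsonl --grid 2:20 --measure c_v --seeds 3
triage-lda triage   --model modeldir --streams enriched.jsonl --labels corpus.jsonl --k 5 --folds 10 --seed 7 --out results.csv
triage-lda kappa    --ratings ratings.csv
triage-lda run      --config experiment.yaml
```

Corpus input is a directory of UTF-8 `.txt` files or a JSON-lines file with
`{"id", "text", "treatments": [...]}` records. Lexica are tab-separated:
2 columns (surface → canonical) for the variant lexicon, 3 columns
(term → concept id → semantic type) for the concept lexicon; `#` starts a
comment. A toy concept lexicon and abbreviation table ship under
`triage_lda/data/`.

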