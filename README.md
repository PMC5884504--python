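# lexepi

County-level language epidemiology in Python: score geographic units on
lexicon-defined topics from raw token counts, predict a health-outcome
rate from those scores with and without socio-demographic controls,
identify topics differentially associated with the outcome, and screen
every topic as a mediator of the socioeconomics → outcome relationship.
A synthetic-data generator with planted effects stands in for
non-redistributable social-media and survey data, so the entire pipeline
is testable offline.

## What it does

- **`lexepi.language_features`** — social-media-aware tokenizer
  (hashtags, @-mentions, URLs, and a frozen emoticon list survive as
  single tokens), county-level token aggregation, a minimum-word-count
  filter (default 40,000), and topic scoring
  `P(topic|county) = Σ_tok P(topic|tok) · P(tok|county)` against a
  `term,topic,weight` lexicon CSV.
- **`lexepi.covariates`** — z-scoring with sample SD, the composite
  socioeconomic index (mean of standardized log income and high-school
  graduation rate), age-bin collapsing, county-set restriction with
  logging, and a Pearson cross-correlation matrix with BH-corrected
  p-values.
- **`lexepi.prediction`** — OLS with classical standard errors, ridge
  regression `β = (XᵀX + λI)⁻¹Xᵀy` (λ defaults to 1000, intercept
  unpenalized, columns standardized), univariate feature screening
  (variance floor + permissive Bonferroni-style correlation sieve,
  alpha default 60), train-fold-only PCA, 10-fold cross-validated
  prediction (language-only, controls-only, or residualized combined),
  Pearson r / MAE evaluation, and a paired t-test for model comparison.
- **`lexepi.dla`** — differential language analysis: one standardized
  OLS per topic (optionally covariate-adjusted), Benjamini–Hochberg
  step-up correction, and ranked topic reports with top-weighted words.
- **`lexepi.mediation`** — mass mediation screening: per topic, the
  three standardized regressions give paths a, b, c, c′; mediation size
  c − c′ (= a·b), Sobel z/p, BH correction, and ranking by mediation
  size within b-sign groups.
- **`lexepi.synthetic`** — seeded generator of Dirichlet topic–word
  lexicons, multinomial county corpora with SES-shifted topic mixtures,
  census-like covariates, and outcomes with known control effects,
  direct topic effects, and mediator paths, all recorded as ground
  truth.

## CLI

All commands are subcommands of `lexepi` (add `-v` for restriction and
fold logging):

```sh
# generate a synthetic dataset with a planted mediator
lexepi simulate --config sim.json --out-dir fixtures/

# county x topic scores from token counts
lexepi score --lexicon fixtures/lexicon.csv --corpus fixtures/corpus.csv \
    --min-words 40000 --out scores.csv

# cross-validated prediction (controls optional; --no-language for OLS-only)
lexepi predict --scores scores.csv --outcome fixtures/outcome.csv \
    --controls fixtures/covariates.csv --lambda 1000 --folds 10 --seed 42 \
    --out eval.json

# per-topic association with the outcome, BH-corrected
lexepi dla --scores scores.csv --outcome fixtures/outcome.csv \
    --covariates fixtures/covariates.csv --cols ses_index --q 0.05 --out dla.csv

# mediation screen of ses_index -> topic -> outcome
lexepi mediate --scores scores.csv --outcome fixtures/outcome.csv \
    --covariates fixtures/covariates.csv --x-col ses_index --q 0.05 \
    --out mediation.csv
```

Corpus input is either a `county_id,term,count` CSV or plain text lines
`county_id<TAB>text`. The simulate config is a JSON object of
`SimulationConfig` fields; `--paper-scale` switches to the study-scale
preset (1,384 counties, 2,000 topics, 40,000 words per county — slow).

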