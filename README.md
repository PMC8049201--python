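# gpcomplexity

Measurement of general-practice consultation complexity from routine
electronic records. The package implements the full measure-development
pipeline end to end:

* **`gpcomplexity.delphi`** — two-round expert-panel (Delphi) consensus
  aggregation: per-factor endorsement classification (scores 3–5 endorse,
  score 1 rejects; accepted when >70% endorse and <20% reject, strict
  inequalities), carry-forward of uncertain factors, participant-suggested
  additions, and individualised feedback reports.
* **`gpcomplexity.codesets`** — flat-CSV clinical code sets mapping codes to
  complexity factors, with factor level (consultation vs patient), trigger
  rule (code match, distinct-count, first-consultation-after-diagnosis) and
  lookback window ("ever" or days).
* **`gpcomplexity.factors`** — per-consultation boolean factor flagging with
  half-open lookback windows `(date − L, date]`, within-consultation count
  rules, and the binary complexity classification (complex ⇔ ≥1 retained
  factor; deliberately no cumulative score).
* **`gpcomplexity.develop`** — the development pipeline: prevalence
  screening (strict <0.05%), percentile threshold re-specification,
  consultation→patient reclassification, mixed-effects duration regressions
  with random intercepts for practice and for patient nested within
  practice (REML, Wald intervals), one-pass negative-coefficient exclusion,
  and backward stepwise elimination at P < 0.05.
* **`gpcomplexity.report`** — applied-measure summaries: proportion
  complex, complex vs non-complex mean durations with a Welch-style CI on
  the difference, and age–sex stratified proportions (optional bar chart).
* **`gpcomplexity.synthetic`** — a ground-truthed synthetic primary-care
  generator (patients, consultations, coded events, prescriptions, panel
  votes) so every stage is testable without licensed data.
* **`gpcomplexity.reference`** — the bundled bookkeeping of the released
  17-factor measure (candidate factors, per-round statuses, regression
  table, final coefficients) plus a toy code-set registry and replay
  helpers.

The nested two-level random-intercept model is fitted by an in-package
profiled REML routine (`gpcomplexity.nested_lmm`) that exploits the
closed-form block structure; it matches `statsmodels` MixedLM to four
decimals at small n (cross-checked in the test suite) and fits 100 000
consultations in about a second.

## Command-line usage

```bash
# write the bundled toy code-set template
gpcomplexity codesets template --out cs.csv

# generate synthetic data (TOML config; see tests/test_cli.py for an example)
gpcomplexity simulate --config sim.toml --out data/ --seed 7

# classify a two-round vote table / build panelist feedback
gpcomplexity delphi classify --votes votes.csv --out statuses.csv
gpcomplexity delphi report --votes votes.csv --panelist p003

# flag consultations and apply the binary measure
gpcomplexity score --data data/ --codesets cs.csv --retained retained.txt --out flags.csv

# run the full development pipeline (prevalence screen, mixed models,
# stepwise selection) and write its reports
gpcomplexity develop --data data/ --codesets cs.csv --out report/

# summarise an applied measure
gpcomplexity report --scored flags.csv --out report/ --plot
```

## Conventions worth knowing

* Lookback windows are half-open: an event exactly `L` days before the
  consultation is outside; an event on the consultation date is inside.
* Score 2 counts toward neither endorsement nor rejection but stays in the
  denominator; abstentions are excluded from it.
* The frequent-attender count excludes the index consultation (configurable).
* Percentile thresholds use the nearest-rank (inverted-CDF) convention.
* The generator is bit-reproducible: identical config ⇒ identical CSV bytes.
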