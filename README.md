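# aquanrf

Nutrient profiling and affordability analysis for aquatic foods.

`aquanrf` implements a Nutrient Rich Food (NRF) scoring pipeline for fish and
shellfish composition tables: hierarchical lookup imputation of missing
values, per-100 g NRFn.2 scoring with percent-daily-value capping, group
summary statistics with one-way ANOVA / Tukey HSD compact-letter displays,
edible-portion price processing, and an NRF Affordability Index that ranks
species by nutrient density per unit cost. A synthetic-data generator
reproduces the group structure of a 515-item fish/shellfish composition
database from published group moments, so the entire pipeline runs with no
external data.

## Scoring model

Two profiles are shipped:

- **NRF6.2** — six priority micronutrients (iron, zinc, calcium, vitamin A,
  vitamin B12, folate) minus two nutrients to limit (saturated fat, sodium);
- **NRF9.2** (aquatic variant, the default) — protein, selenium, calcium,
  iron, potassium, magnesium, vitamin A, vitamin D and omega-3 fatty acids,
  minus the same two limit nutrients.

For each item, `%DV = 100 × amount / daily value` is computed per 100 g
edible portion and capped at 100 %; `NRFn.2 = NRn − LIM`. Daily values
default to the FDA reference set (ages ≥ 4); omega-3, which has no FDA DV,
defaults to 1.6 g and is config-overridable. Scores are averaged per group
(mean of scores, never score of means).

The Affordability Index divides a group's mean NRF score by its
edible-portion price per kg (whole-product price / edible yield, EUR
converted to USD at the October-2024 rate of 1.09).

## CLI

```bash
aquanrf simulate --seed 1 --out out/            # synthetic composition + prices
aquanrf impute out/composition.csv --out out/   # fill gaps from fallback tables
aquanrf score out/composition_imputed.csv --profile NRF6.2 --profile NRF9.2 \
    --group-by taxon_group --out out/
aquanrf compare out/composition_imputed.csv --metric iron --out out/
aquanrf afford out/group_summaries.csv out/prices.csv --out out/
aquanrf report --seed 1 --out out/              # the whole pipeline end to end
```

Every stage writes CSV outputs plus a JSON manifest (seed, config hash,
package version, row counts) that makes stochastic stages reproducible
bit-for-bit.

## Layout

- `src/aquanrf/model.py` — domain types, units, taxonomy, DV table, profiles
- `src/aquanrf/io.py` — composition/price CSV readers-writers, config loading
- `src/aquanrf/scoring.py` — %DV, NRn/LIM subscores, NRFn.2, group summaries
- `src/aquanrf/impute.py` — fallback-cascade lookup imputation with provenance
- `src/aquanrf/afford.py` — currency/yield corrections, affordability table
- `src/aquanrf/stats.py` — ANOVA, Tukey HSD, compact letters, wild-vs-farmed
- `src/aquanrf/synthetic.py` — group-moment synthetic generator
- `src/aquanrf/reference.py` — shipped published group summary statistics
- `src/aquanrf/cli.py` — `aquanrf` command-line entry point
- `src/aquanrf/data/` — default group-moment config, farmed/wild config,
  published group-score reference table
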