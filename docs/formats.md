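# File formats

## Song table (input to `test` and `summarize`, output of `simulate`)

Delimited text (comma or tab; sniffed) with a header row. Default columns:

| column        | meaning                                      |
|---------------|----------------------------------------------|
| `population`  | population label                             |
| `species`     | species label                                |
| `bird`        | bird / annotation identifier                 |
| `phrase_type` | phrase-type label (non-empty string)         |
| `duration_s`  | duration in seconds (> 0)                    |

With `--unit start_end`, columns `start_s` and `end_s` replace `duration_s`
and the duration is `end − start`. Column names are remappable with
`--schema logical=actual` (logical names: `population`, `species`, `bird`,
`phrase_type`, `duration`, `start`, `end`). Rows with missing or
non-positive durations are rejected and reported to stderr.

## Test report (output of `test`)

JSON object with `tau_bar`, `p_individual`, `tau_pop`, `p_pop`,
`detection_threshold`, `settings` (n_perm, seed, weights, center, scale,
alpha, p_correction), `per_bird` (bird_id, n_k, tau_k, v_k; tau_k is null
when undefined), `excluded_birds`, and `n_flagged_replicates`. With
`--null-csv`, the null sample is written as a single-column CSV
(`tau_bar_p`).

## Per-population table (output of `summarize`, input to `meta`)

CSV, one row per population: `population`, `species`, `n_records`,
`total_phrase_types`, `phrases_per_record`, `types_per_record`, `shannon`.
`meta` additionally requires `tau_bar` and, for the planning regression,
`detection_threshold` (negative) and `total_phrase_types` — i.e. the output
of `summarize` joined with the results of `test` per population, or a
hand-entered table of the same shape (see
`brevity.load_population_table()`).

## Meta report (output of `meta`)

JSON with `meta_tau` (intercept, se, one-tailed p, df, variance components)
and, when `--predict-at` is given, `detection_regression` (predicted
repertoire size with 95% CI and the fitted log–log coefficients).

## Text report (output of `text`)

JSON with one entry per document (`document`, `n_word_types`, `tau`; `tau`
null when undefined) and, for multiple documents, the pooled `tau_bar`.

## Simulation truth (optional output of `simulate`)

JSON with `a_bar_true` (log-scale type centers), `lineage_of`,
`lineage_repertoires`, `lineage_gamma`, `usage_weights` (types × birds
multinomial probabilities), and the full parameter set including the seed.
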