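# ehrpheno

Visit-level EHR phenotyping toolkit: generate synthetic clinic cohorts
with known latent-class structure, extract clinical-topic flags from
note text by exact token matching with windowed negation, build a
categorical feature matrix, label care-retention and viral-load
outcomes, fit latent class models by EM with information-criterion
model selection, and compare the resulting phenotypes with
contingency statistics.

## Modules

| module | purpose |
|---|---|
| `ehrpheno.synth` | synthetic cohort generator (visits, labs, notes, ground truth) |
| `ehrpheno.notes` | rule-based topic annotation: exact matching, ±k-word exclusion window |
| `ehrpheno.features` | age bins, retention history, indicator columns → LCA input matrix |
| `ehrpheno.outcomes` | per-visit loss-to-follow-up (>365-day gap), NHAS retention, high viral load (≥200 copies/ml in following 365 d) |
| `ehrpheno.lca` | EM fitting, AIC/BIC/SABIC/CAIC, model selection over a class range, max-posterior assignment, label alignment |
| `ehrpheno.stats` | 2×2 odds ratios with Wald CIs, chi-squared, Kruskal–Wallis, class profile / outcome tables |
| `ehrpheno.pipeline` | YAML-configured end-to-end run with SHA-256 provenance manifest |
| `ehrpheno.fixtures` | packaged published contingency counts and toy notes |

## CLI

One root command with a subcommand per stage:

```sh
ehrpheno simulate --n-patients 200 --seed 1 --outdir run/
ehrpheno annotate-notes --notes run/notes.jsonl --out run/flags.csv
ehrpheno build-features --visits run/visits.csv --topic-flags run/flags.csv --out run/fm.csv
ehrpheno label-outcomes --visits run/visits.csv --labs run/labs.csv --study-end 2020-12-31 --out run/outcomes.csv
ehrpheno select-model --features run/fm.csv --c-min 1 --c-max 10 --criterion bic --out run/selection.csv
ehrpheno fit-lca --features run/fm.csv --classes 6 --model-out run/model.json --assignments-out run/asg.csv
ehrpheno compare-classes --features run/fm.csv --assignments run/asg.csv --outcomes run/outcomes.csv --outdir run/cmp
ehrpheno reproduce-table4          # OR engine on the packaged published counts
ehrpheno run-all --demo --outdir run/   # full deterministic demo pipeline
```

`run-all --config config.yaml` accepts a YAML file mirroring
`ehrpheno.pipeline.PipelineConfig`.

## Notes on conventions

- The note annotator lowercases and splits on any non-alphanumeric
  character; exclusion terms (default `no`, `neg`) suppress a match when
  they fall within the entry's window (default ±3 words) of the matched
  span. The shipped 12-topic lexicon is illustrative and fully
  user-replaceable via `--lexicon lex.json`.
- Visits too close to the study end to observe a 365-day follow-up gap
  are marked non-evaluable; by default they are excluded from outcome
  denominators (`boundary_rule: count_as_not_ltfu` restores
  full-denominator behaviour).
- LCA classes are relabelled by descending mixing weight; posterior ties
  break toward the lower class index; SABIC uses the (n+2)/24
  sample-size adjustment.
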