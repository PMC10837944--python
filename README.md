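# akicomorbid

A pipeline for mining comorbidities of acute kidney injury (AKI) from
ICU-style tabular data:

1. **KDIGO staging** (`kdigo_staging`) — detect and stage AKI (0–3) from
   serum-creatinine and urine-output streams, using a 7-day rolling-minimum
   creatinine baseline, the ≥ 0.3 mg/dl / 48 h absolute-rise rule, fold-change
   bands, and sustained urine-output rate episodes.
2. **ICD-10 processing** (`icd_processing`) — canonicalize diagnosis codes,
   map ICD-9 → ICD-10 through a two-column equivalence table, drop external
   cause (V01–Y98) and health-status (Z00–Z99) categories, truncate to
   category (ID-3) level, and build per-patient itemsets with an AKI
   pseudo-item derived from the staging labels.
3. **Rule mining** (`rule_mining`) — Apriori frequent 1-/2-itemset mining
   with support, Kulczynski and lift; AKI-centered pairs filtered at
   configurable thresholds (defaults: sup ≥ 0.08, kulc > 0, lift > 1).
4. **Validation** (`pair_validation`) — confirm pairs by membership in a
   reference pair set, by chi-square on local 2×2 co-occurrence tables, and
   by the ID-3 → ID-4 → ID-5 fallback-replacement re-mining algorithm for
   codes that fail concept mapping.
5. **Disease network** (`disease_network`) — AKI-centered star graph with
   sup·kulc node importance, kulc/lift/verification edge attributes;
   GraphML and node-link JSON export.
6. **Crosstalk & risk factors** (`crosstalk_risk`) — stage-stratified mining
   for codes unique to stage 3, and per-organ crosstalk scores
   `score_u = Σ sup·kulc` over a user-overridable category→organ range table.
7. **Synthetic cohorts** (`synthetic_cohort`) — generate MIMIC-shaped CSV
   tables with planted AKI stages (recovered exactly by the staging module)
   and planted pair associations of known lift, for fully offline testing.

## CLI

Every stage is a subcommand of `akicomorbid`:

```sh
akicomorbid simulate --config sim.json --out cohort/
akicomorbid stage --cohort cohort/ --out labels.csv
akicomorbid transactions --cohort cohort/ --labels labels.csv --out tx.json
akicomorbid mine --transactions tx.json --min-sup 0.08 --out comorbidities.csv
akicomorbid validate --pairs comorbidities.csv --ref eicu_pairs.csv \
    --cooc cohd_counts.csv --map concept_map.csv --out verdicts.csv
akicomorbid network --pairs comorbidities.csv --top-k 284 --out dn.graphml
akicomorbid crosstalk --pairs comorbidities.csv --out crosstalk.json
akicomorbid risk-factors --cohort cohort/ --labels labels.csv --out risk.csv
```

An end-to-end run with a single JSON config (simulate → stage → transactions
→ mine → [validate] → network → crosstalk → risk factors) writes every
intermediate artifact plus a reproducibility manifest:

```sh
akicomorbid run --config run.json
```

Minimal `run.json`:

```json
{
  "out_dir": "out",
  "seed": 42,
  "simulate": {
    "n_patients": 500,
    "code_catalog": [["I10", 0.45], ["E78", 0.4], ["J96", 0.3], ["K21", 0.3]],
    "planted_pairs": [["AKI", "E78", 1.8]]
  }
}
```

## File formats

All inputs and outputs are plain text: cohort directories hold
`patients.csv`, `scr_events.csv`, `uo_events.csv`, `diagnoses.csv`;
reference tables are `reference_pairs.csv` (source, code_a, code_b),
`cooccurrence.csv` (code_a, code_b, n_ab, n_a_only, n_b_only, n_neither),
`concept_map.csv` (icd10, concept_id), and `organ_map.csv`
(range_start, range_end, organ). Bundled defaults for the ICD-10 chapter
ranges and the organ classification live in `src/akicomorbid/data/` and can
be overridden per run.
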