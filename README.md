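# cohortpheno

Biobank EHR phenotyping: parse machine-actionable phenotype definition
tables, harmonize a main cohort dataset plus record-level hospital /
primary-care / death files into one clinical-episode schema, and ascertain
case/control status with prevalent, incident and time-to-event semantics.
Ships a synthetic cohort generator so the whole pipeline is testable without
restricted data.

## What it does

1. **Code maps** (`cohortpheno.codemaps`) — load per-classification code
   lists (ICD-9/10, OPCS-4, READ2, CTV3, drug codes), expand parent codes by
   prefix (READ dot-padding handled), extract flat maps from record-level
   data.
2. **Definitions** (`cohortpheno.definitions`) — one trait per row; code
   columns with comma-separated lists and `(annotations)`, self-report field
   specs like `20002(1471, 1483)`, touchscreen conditions like
   `6177=3(insulin)` or `4041=1[2976]`, and composite columns
   (`Study_population`, `Include_definitions`, `Exclude_from_cases`,
   `Exclude_from_controls`). Codes are expanded at parse time and
   non-matching codes are dropped with a validation report.
3. **I/O** (`cohortpheno.ukb_io`) — main dataset (`f.<field>.<inst>.<arr>`
   TSV), field metadata (html or TSV fallback), record-level tables,
   withdrawal lists.
4. **Harmonization** (`cohortpheno.harmonize`) — everything becomes episodes
   with columns `.id, identifier, code, classification, eventdate, event,
   epidur`. The `event` flag records date provenance (1 = true date from
   linked data or self-reported operation, 2 = other self-reported date,
   0 = imputed from the assessment-centre visit). Returns a three-part
   container: episode tables by source, the participant subset, the full
   identifier vector. Withdrawn participants are removed everywhere.
5. **Ascertainment** (`cohortpheno.ascertain`) — per-trait case/control
   status relative to a reference date, with a 16-column per-participant
   summary (counts, hospitalization days, death, Hx/Fu/Ref/Any indicators,
   first-diagnosis offset). Included case/control read 2/1; excluded read
   −2/−1. Batch mode prefixes columns `<trait>_0_<col>`. Exploration
   helpers: per-code frequencies, source-overlap matrix, yearly timeline,
   individual timelines.
6. **Follow-up** (`cohortpheno.followup`) — censoring-aware observed time:
   event time for incident cases, otherwise the earlier of death and the
   region-specific secondary-care censoring date (configurable).
7. **Synthetic cohorts** (`cohortpheno.synth`) — seeded generator emitting
   every input format plus a ground-truth table; same seed gives
   byte-identical files.

## CLI

```sh
# generate a synthetic cohort with ground truth
cohortpheno synth --n 500 --seed 1 --out fixtures/

# harmonize all sources into the episode container
cohortpheno harmonize \
    --config fixtures/data_settings.tsv \
    --definitions fixtures/definitions.tsv --codemaps fixtures/codemaps \
    --main fixtures/main.tab --metadata fixtures/metadata.tsv \
    --hesin fixtures/hesin.txt --hesin-diag fixtures/hesin_diag.txt \
    --hesin-oper fixtures/hesin_oper.txt \
    --gp-clinical fixtures/gp_clinical.txt --gp-scripts fixtures/gp_scripts.txt \
    --death fixtures/death.txt --death-cause fixtures/death_cause.txt \
    --withdrawals fixtures/withdrawals.txt \
    --out harmonized/

# ascertain one trait (or --traits a,b,c for a wide batch table)
cohortpheno phenotype --trait DmT2 \
    --definitions fixtures/definitions.tsv --codemaps fixtures/codemaps \
    --harmonized harmonized/ --reference-field f.53.0.0 --out pheno/

# censoring-aware follow-up time
cohortpheno followup --pheno pheno/ --harmonized harmonized/ --out followup.tsv

# exploration tables/figures
cohortpheno report --trait DmT2 --definitions fixtures/definitions.tsv \
    --codemaps fixtures/codemaps --harmonized harmonized/ \
    --formats tsv,png --out figs/

# extract flat code maps from record-level data
cohortpheno codes extract --records fixtures/gp_clinical.txt \
    --columns read_2,read_3 --out maps/
```

## File formats

All inputs and outputs are plain TSV/text. The data-settings file declares,
per source, the definition-table column, classification system, hierarchy
and case flags, the date rule (`record`, `year:<field>`, `age:<field>`,
`condition`, `none`), the event flag used when a date exists, and the
minimum instance count. Code maps are 1–2 column TSVs without headers (a
converter from spreadsheet code maps is a one-liner and out of scope).
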