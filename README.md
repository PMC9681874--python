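# ciaspipe

Analysis pipeline for a randomised-trial cognitive endpoint built from a
five-subtest computerised battery:

- **normative scoring** — raw subtest scores are converted to sign-corrected
  Z-scores against age-band norms (18–34, 35–49, 50–59, 60–69) and averaged
  into a composite (no partial composites);
- **cohort filters** — completer selection (valid baseline and week-5 symptom
  totals plus complete five-subtest panels at both visits), impairment
  stratification at a baseline composite of −1, per-administration
  intraindividual variability (IIV = sample SD across the five subtest
  Z-scores), and Q3 + 1.5·IQR fence exclusion of high-IIV administrations
  (a patient flagged at one or both timepoints is excluded everywhere);
- **effect models** — ANCOVA of composite change on arm + age + sex + site +
  baseline composite, with least-squares means (continuous covariates at
  their means, categorical levels equally weighted), between-arm contrasts,
  model-derived Cohen's *d* = estimate / √MSE, ANOVA / chi-squared baseline
  comparisons, and simple linear regression of cognitive change on symptom
  change;
- **synthetic trials** — a seeded generator producing two-arm datasets with a
  controllable impaired fraction (two-component latent mixture truncated at
  the −1 cutoff), subgroup-specific treatment effects, site intercepts,
  symptom–cognition coupling, dropout/missingness, and injectable IIV
  contamination with recorded ground truth;
- **reporting** — a deterministic end-to-end runner writing paper-style CSV
  tables, an exclusion ledger, and a manifest sufficient to reproduce any
  synthetic run bit-for-bit.

## CLI

```sh
ciaspipe simulate --seed 7 --out sim/            # data.csv, norms.csv, truth, config echo
ciaspipe score    --data sim/data.csv --norms sim/norms.csv --out scored.csv
ciaspipe report   --data sim/data.csv --norms sim/norms.csv --out report/
ciaspipe analyze  --cohort sim/data.csv --norms sim/norms.csv \
                  --subgroup impaired --exclude-iiv-outliers --out report/
ciaspipe run      --seed 7 --out report/         # synthetic end-to-end run
```

`simulate` and `run` accept `--config <yaml>`; `run` configs may specify
either a `synth:` block or `data_csv`/`norms_csv` paths, plus the
`stratify` / `iiv_exclusion` toggles. A run that filters out every patient
writes header-only tables and exits with status 3.

Report bundles contain `effects_<variant>.csv` (variants: all / impaired /
minimal, each with and without IIV exclusion) with columns
`Treatment, Estimate (SE), CI lower, CI upper, p value, Cohen's d`,
baseline-characteristic tables, a regression summary, `exclusions.csv`,
`summary.txt`, and `manifest.json`.

## Layout

```
src/ciaspipe/
  norms.py      normative bands, sign-corrected Z-scoring, composites
  panss.py      symptom-scale validator (30 items x 1-7)
  simulate.py   synthetic trial generator + IIV contamination injector
  cohort.py     completer selection, impairment split, IIV, fences, flags
  effects.py    ANCOVA, LS means, Cohen's d, baseline tests, regression
  pipeline.py   orchestration, report bundles, manifest
  cli.py        click CLI
```
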