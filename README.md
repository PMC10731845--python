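# metamwas

A metabolome-wide association study (MWAS) pipeline for untargeted LC-HRMS
serum feature tables, with a synthetic cohort generator for end-to-end
testing.

The pipeline covers:

- **`metamwas.synthetic`** — a two-wave, two-run case-control cohort
  generator (batches, triplicate injections, pooled-QC samples, batch/run/
  drift effects, planted case-control, medication-dose and age effects) with
  a ground-truth table, a matching reference metabolite library, GMT pathway
  sets, and an external-study summary table.
- **`metamwas.processing`** — cross-run feature alignment, replicate-quality
  filters (median replicate CV < 30%, replicate Pearson r > 0.9, detection
  in > 50% of subjects), median replicate collapse, zero replacement by the
  per-feature minimum detected value, log2, column quantile normalization,
  parametric empirical-Bayes batch correction, technical PC-cluster
  detection/re-correction, and QC CV reporting.
- **`metamwas.mwas`** — moderated per-feature linear models (empirical-Bayes
  variance shrinkage), per-wave logistic fits pooled by fixed-effects
  inverse-variance meta-analysis, Benjamini-Hochberg FDR, a replication
  tier rubric, patient-phenotype (LEDD / HY / UPDRS-III) associations, and
  the correlation network of hits.
- **`metamwas.annotation`** — adduct-based m/z (and RT) matching against a
  reference library at 5/10 ppm with two confidence tiers.
- **`metamwas.pathways`** — permutation-based weighted pathway enrichment,
  joint across ion modes, down-weighting ambiguous matches.
- **`metamwas.crossstudy`** — cross-study meta-analysis of (fold change, p,
  n) summaries: size-weighted FC combination, Lancaster-style weighted
  p-value combination, pseudo t-score, and a three-criteria validation
  rubric. `metamwas.datasets` bundles a 20-metabolite worked example.
- **`metamwas.cli` / `metamwas.pipeline`** — a `metamwas` command with
  `simulate`, `preprocess`, `mwas`, `annotate`, `pathways`, `network`,
  `validate-external`, `report` and `run-all` subcommands; deterministic
  outputs plus a JSON run manifest.

## CLI

Run the whole pipeline on a synthetic cohort:

```bash
metamwas run-all --seed 7 --out-dir results/demo --scale test
```

Or stage by stage (each stage reads the previous stage's files from
`--out-dir`):

```bash
metamwas simulate   --seed 7 --out-dir results/demo
metamwas preprocess --seed 7 --out-dir results/demo
metamwas mwas       --seed 7 --out-dir results/demo
metamwas annotate   --seed 7 --out-dir results/demo
metamwas pathways   --seed 7 --out-dir results/demo
metamwas network    --seed 7 --out-dir results/demo
metamwas validate-external --seed 7 --out-dir results/demo
metamwas report     --seed 7 --out-dir results/demo
```

A YAML config (`--config`) can override any module parameter; CLI flags
(`--seed`, `--out-dir`, `--scale {test,full}`) take precedence. All outputs
are plain TSV/JSON/GMT/GraphML; reruns with the same config and seed are
byte-identical.

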