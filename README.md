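# mciconvert

Tools for studying 3-year MCI-to-AD conversion prediction. The package
compares two approaches on a synthetic ADNI-like cohort:

1. **Dichotomized prodromal-AD research criteria** — the RAVLT
   hippocampal-memory core criterion (delayed recall < 3 and delayed
   recognition < 10), visual medial temporal atrophy (Scheltens >= 3),
   and CSF markers (Tau > 93 pg/ml, Abeta1-42 < 192 pg/ml) combined into
   eight prediction rules and a four-way likelihood-of-AD category.
2. **A disease state index (DSI)** — a 0-1 composite score aggregating
   per-feature evidence (empirical-distribution *fitness* weighted by
   Youden-index *relevance*) up a modality tree, tolerant of missing
   modalities, with a six-level category scale and a 0.50 binary cutoff.

Because the underlying clinical cohort is restricted-access, a seeded
synthetic cohort generator reproduces its statistical structure
(group-conditional feature distributions, exact modality-availability
counts, outcome mix) so that every stage runs offline.

## Layout

| Module | Contents |
| --- | --- |
| `mciconvert.cohort` | `CohortSpec`, `SubjectRecord`, `generate_cohort`, `simulate_rater`, CSV I/O |
| `mciconvert.criteria` | cutoffs, tri-state marker status, likelihood categories, rule predictions |
| `mciconvert.dsi` | feature references (fitness/relevance), `DsiModel`, composite scoring, fingerprint export |
| `mciconvert.evaluation` | confusion summaries with Clopper-Pearson CIs, conversion rates, McNemar, Cohen's kappa, six-category accuracy tables |
| `mciconvert.reference_tables` | published count-table fixtures and target verification |
| `mciconvert.pipeline` / `mciconvert.cli` | end-to-end comparison runs and the CLI |

## CLI

```sh
mciconvert simulate --seed 1 --out cohort.csv           # synthetic cohort
mciconvert criteria --cohort cohort.csv --out crit.csv  # markers, likelihood, rules
mciconvert dsi fit --cohort cohort.csv --model-out model.json
mciconvert dsi score --cohort cohort.csv --model model.json --out dsi.csv
mciconvert dsi fingerprint --cohort cohort.csv --model model.json \
    --subject mci_001 --out fp.json
mciconvert evaluate --predictions crit.csv --labels cohort.csv --report report/
mciconvert run --config run.yaml                        # full comparison bundle
mciconvert verify-paper-tables                          # recompute fixture targets
```

A run config (YAML) names one cohort source (`spec_path` + `seed`, or
`cohort_csv`), the DSI options (`split_seed`, `dsi_cutoff`,
`dsi_in_sample`), the evaluation denominator mode, and `out_dir`. Reruns
with the same config are bit-identical; `manifest.json` records seeds,
the config hash, and SHA-256 of every output.

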