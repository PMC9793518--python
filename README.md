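# germtrace

Evaluation pipeline for germline genotyping from low-coverage WGS of archival
tissue, with a ductal-carcinoma-in-situ (DCIS) survival use case. The package
scores blood-vs-tissue genotype dosage concordance, computes polygenic risk
scores (PRS), scores HLA-typing concordance, derives copy-number burden, and
fits an incidence-reweighted Cox proportional-hazards model of PRS versus
subsequent breast-cancer events — together with a synthetic-data generator
that emulates the statistical structure of the restricted study data so every
stage is testable offline.

## Modules

| module | purpose |
| --- | --- |
| `germtrace.types` | shared domain types (variant keys, dosage panels, segments, cohort and HLA records) |
| `germtrace.formats` | readers/writers: dosage VCF, PGS-Catalog scoring files, segment tables, cohort CSV, HLA TSV; sample QC filter |
| `germtrace.simulate` | synthetic inputs: HWE genotypes over a truncated-Beta MAF spectrum, noisy dosage panels (error grows with rarity, low coverage and copy loss), CN profiles, HLA truth/call pairs, proportional-hazards cohorts |
| `germtrace.concordance` | MAF-binned aggregate r² with percentile-bootstrap CIs, quality/CN stratification, Spearman score comparison |
| `germtrace.cnv` | segment classification (gain > 0.3, loss < −0.3, artifact < −15 on log2 scale), genomic burden, burden-tertile grade imputation |
| `germtrace.prs` | effect-allele orientation, weighted-sum scoring, cohort z-scoring, site-coverage reporting |
| `germtrace.hla` | allele-string parsing, 2-/4-field truncation, unordered-pair maximum matching, per-class summaries, posterior comparison |
| `germtrace.survival` | weighted Breslow Cox partial likelihood (Newton–Raphson, sandwich robust variance), baseline survival and PRS-percentile curves, Harrell's C, Schoenfeld PH checks, exact Fisher test, Li–Ji effective number of tests, 1/p control weights |

## CLI

All subcommands share `--seed`, `--log-level` and `--config` (a key=value
file). A typical round trip:

```bash
germtrace --seed 7 simulate --n-variants 20000 --n-samples 10 --out-dir simdata
germtrace concordance --blood-vcf simdata/blood.vcf --tissue-vcf simdata/tissue.vcf \
    --segments simdata/segments.tsv --quality-threshold 0.8 --min-snps 1000 \
    --n-boot 1000 --out concordance.tsv
germtrace prs --vcf simdata/tissue.vcf --model scoring_file.txt --out prs.tsv
germtrace hla --pred simdata/hla_pred.tsv --gold simdata/hla_gold.tsv --fields 4 --out hla.tsv
germtrace survival --cohort simdata/cohort.csv --prs PRS --incidence 0.15 --out fit.tsv
```

Outputs are tab-delimited report tables plus JSON run summaries.

## Notes

- Variants use 1-based VCF coordinates; segments use 0-based half-open BED
  coordinates; a variant at position p lies in segment [start, end) iff
  start ≤ p − 1 < end.
- The dosage FORMAT tag (default `DS`), quality INFO tag (default
  `INFO_SCORE`) and MAF INFO tag (default `MAF`) are configurable, since
  imputation tools differ in dialect.
- `germtrace/data/dcis_cohort.csv` is the transcribed clinical cohort table
  used by the survival stage and tests; `data/hla_allele_freqs.tsv` is the
  small allele-frequency table backing the HLA simulator.
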