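# grsvol

Polygenic risk scoring and subcortical-volume association, as a tested,
reusable pipeline:

* **io_formats** (`grsvol.io`) — read/validate GWAS summary statistics
  (whitespace/TSV, log-OR weights), genotype dosages (VCF with GT/DS,
  PLINK `.bed/.bim/.fam`, plain TSV dosage matrix) and phenotype/covariate
  tables (TSV with hemisphere averaging); allele harmonization with strand
  flips and strand-ambiguous dropping; MAF filtering (strict `< 0.01`
  default).
* **clump** (`grsvol.clump`) — greedy P-value-ordered LD clumping in the
  target cohort (`r² > 0.25` within ±500 kb removed, both configurable).
* **prs** (`grsvol.prs`) — per-sample risk scores at the six default
  P-value ceilings (1e-5, 1e-4, 0.01, 0.1, 0.3, 0.5), strict `P < P_T`,
  sum or average mode, scoring-time mean imputation of missing dosages,
  z-standardization.
* **assoc** (`grsvol.assoc`) — per-ROI OLS of z-scored volume on covariates
  (sex + ICV always, age only for configured ROIs) plus the z-scored score:
  standardized β, two-sided nominal P, incremental R², and permutation P
  (score vector permuted; `k/n_perm` estimator; Freedman–Lane and
  `(k+1)/(n+1)` variants available).
* **power** (`grsvol.power`) — Fisher-z sample-size/power for a Pearson
  correlation; `sample_size(r=0.1, alpha=0.05, power=0.85, one-sided) == 717`.
* **synthetic_data** (`grsvol.simulate`) — LD-blocked genotypes (AR(1)
  latent haplotypes), four coupled summary-statistics sets with shared and
  disorder-specific causal effects (combined, case-case, and two
  single-disorder contrasts), and volumes with a designed ΔR² plus
  sex/ICV/age effects.
* **cli** (`grsvol.cli`, `grsvol.pipeline`) — end-to-end orchestration from
  a YAML config with per-stage logs and seed-reproducible outputs.

## CLI

```bash
grsvol make-demo demo --seed 1        # synthetic inputs + config.yaml
grsvol run demo/config.yaml           # full pipeline -> demo/results/
grsvol power --r 0.1 --alpha 0.05 --power 0.85 --sided one   # -> 717
grsvol clump --sumstats ss.tsv --genotypes geno.tsv --out clumps.tsv
grsvol score --sumstats ss.tsv --genotypes geno.tsv --out scores.tsv
grsvol assoc --scores scores.tsv --phenotypes pheno.tsv \
             --rois globus_pallidus,amygdala --out assoc.tsv
```

`run` writes `report.tsv` (one row per training set × threshold, per-ROI
β/p/ΔR²/permuted-p column groups), `associations.tsv`/`.json` (long format),
`stages.log` (variant counts surviving each stage) and `provenance.json`
(config hash, seed, version). Identical config + seed ⇒ byte-identical
outputs.

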