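# hdscan

Genome-wide homozygosity-disequilibrium (HD) analysis for treatment-response
studies in family cohorts:

1. **Homozygosity intensity profiles** — per-individual, per-SNP-anchored
   sliding windows (5% of a chromosome's SNPs, nearest-neighbor members);
   a double-weight local polynomial smoother (tricube kernel in scaled
   distance × capped-linear minor-allele-frequency locus weight) estimates
   the local homozygosity intensity in [0, 1]. Runs of intensity ≥ 0.9
   spanning ≥ 5 Mb are reported as HD regions (BED6 export).
2. **Association scan** — Gaussian GEE of each window's intensity against
   the triglyceride response (mean of visits 3–4 minus mean of visits 1–2)
   with exchangeable working correlation within pedigree, robust sandwich
   covariance, and covariates sex, age, field center, smoking, one
   metabolic-syndrome index (ATP or IDF), and 10 PCs from an LD-pruned
   (r² < 0.2) SNP set.
3. **Multiplicity** — per-chromosome effective number of independent tests
   n_e = n − Σ_{λ>1}(λ − 1) from the eigenvalues of the window-intensity
   correlation matrix; genome-wide threshold α / Σ n_e.
4. **Methylation arm** — per-sample BMIQ-style beta-mixture quantile
   normalization of Infinium type-II probes onto the type-I distribution,
   M-value transform, methylation response (visit-4 M − visit-2 M), and
   cis/trans meQTL GEE scans of HD windows against CpG responses.
5. **Synthetic data** — pedigree gene-dropping genotype simulator with
   planted homozygous segments, a TG-response model with a planted
   window-level effect, and two-probe-type three-state methylation with a
   compression bias and planted cis links, so the whole pipeline is testable
   without external data.

## CLI

```sh
hdscan simulate --out-dir data --seed 1            # synthetic cohort
hdscan scan     --config run.yaml                  # profile -> PCs -> GEE -> multiplicity
hdscan profile  --config run.yaml                  # intensities + HD regions only
hdscan meqtl    --config run.yaml                  # BMIQ -> responses -> cis/trans scans
hdscan report   --config run.yaml                  # summarize an existing run
```

`run.yaml` holds input paths and parameters; every default matches the
analysis constants above (window fraction 0.05, MAF threshold 0.05,
HD thresholds 0.9 / 5 Mb, prune r² 0.2, 10 PCs, α 0.05):

```yaml
genotypes: data/genotypes.vcf       # VCF or PLINK .bed
phenotypes: data/phenotypes.tsv
methylation: data/methylation.tsv
methylation_annot: data/probe_annot.tsv
out_dir: results
metabolic_index: atp                # or idf (the dual-run design)
```

## Layout

```
src/hdscan/
  io_formats.py            VCF/PLINK/TSV/BED readers and writers, data model
  synthetic_data.py        cohort simulator + planted truth
  homozygosity.py          windows, smoother, HD regions, summaries
  population_structure.py  LD pruning, PCA
  association.py           GEE scan, effective tests, Manhattan
  methylation.py           beta-mixture EM, BMIQ, M values, responses
  meqtl.py                 cis/trans scans
  cli.py                   orchestration + click CLI
```
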