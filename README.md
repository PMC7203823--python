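# vegwas

A GWAS toolkit for the **environmental variance** of a repeated count trait
(litter size), mapping variance QTL (vQTL) rather than mean effects. It
implements the full analysis chain:

1. **Phenotype** — litter-size records are pre-corrected for year-season and
   parity-lactation factors by OLS; the per-female phenotype is the
   within-doe variance of the corrected records with divisor *n* + 1, with
   precision weight (*n* + 1)² / (2(*n* − 1)).
2. **Genotype QC** — call-rate / MAF / missingness filters, binomial
   frequency imputation, VanRaden genomic relationship matrix (GRM), PCA.
3. **Single-marker regression (SMR)** — mixed-model association with a
   leave-one-chromosome-out GRM (REML variance components estimated once per
   chromosome), plus a weighted least-squares variant with 5 principal
   components; significance at p < 1e-4 (with a configurable "near" tier).
4. **BayesB multiple-marker regression** — Gibbs sampler with prior
   exclusion probability π = 0.999, per-SNP Bayes factors
   BF = (p̂/(1−p̂))/((1−π)/π) with BF > 10 significance, and 1-Mb window
   variance partitioning.
5. **Validation** — permutation empirical p-values (EMP1 = (b+1)/N, minimum
   1/N) and within-population effect comparison via ±2 SE CI overlap.
6. **Regions** — significant SNPs grouped within 0.5 Mb, padded ±1 Mb, and
   extended to LD blocks at r² > 0.7 (connected-component rule; isolated
   SNPs yield point regions).
7. **Variant screen** — pooled-line VCF sites are hard-filtered
   (SNV: QD < 2, FS > 60, MQ < 40, MQRankSum < −12.5, ReadPosRankSum < −8;
   INDEL: QD < 2, FS > 200, ReadPosRankSum < −20), restricted to regions,
   selected for protein/UTR/splicing consequences, classified as
   absent / fixed / segregating per line from pooled allele depths, and
   intersected with GFF3 gene models.
8. **Synthetic data** — a first-class generator for litter tables, SNP
   panels with copying-process LD and line-divergent frequencies, pooled
   two-sample VCFs with designated filter fates and consequence annotations,
   gene grids, and a machine-readable truth file, so the whole pipeline is
   testable without external data.

## CLI

Each stage is a subcommand; `run-all` chains them from a YAML config (or
pure simulation mode) and writes a `manifest.json` with SHA-256 hashes of
every output. Runs are deterministic under `--seed`.

```bash
vegwas simulate --seed 1 --outdir out/sim
vegwas phenotype --litters out/sim/litters.tsv --out out/phenotypes.tsv
vegwas qc --plink-prefix out/sim/genotypes --out-prefix out/qc
vegwas gwas-smr --phenotypes out/phenotypes.tsv --plink-prefix out/qc --out out/smr.tsv
vegwas gwas-bayesb --phenotypes out/phenotypes.tsv --plink-prefix out/qc --out out/bmmr.tsv
vegwas validate --phenotypes out/phenotypes.tsv --plink-prefix out/qc \
    --snps snp_1_5000000 --out out/validation.tsv
vegwas regions --validated out/validated.tsv --plink-prefix out/qc --out out/regions.tsv
vegwas screen --vcf out/sim/pools.vcf --gff3 out/sim/genes.gff3 \
    --regions out/regions.tsv --out-prefix out/screen
vegwas run-all --seed 1 --outdir out/full        # everything, simulation mode
```

## Layout

```
src/vegwas/
  simulate.py       synthetic litters / genotypes / pooled VCF / GFF3 / truth
  phenotype.py      pre-correction, V_E phenotype, weights
  genotype_qc.py    GenotypeSet, QC, imputation, GRM, PCA, PLINK text I/O
  gwas_smr.py       REML + LOCO mixed-model scan, weighted PC regression
  gwas_bmmr.py      BayesB Gibbs sampler (numba), Bayes factors, windows
  validation.py     permutation EMP1, within-population CI overlap
  regions.py        SNP grouping, LD r², vQTL region definition
  variant_screen.py hard filters, consequence selection, segregation, genes
  pipeline.py       run-all orchestration with manifest
  cli.py            click CLI
```
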