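# logoscan

Scan-statistic detection of small genome segments harboring **local genetic
correlation** between two complex traits, from GWAS summary statistics and a
reference LD panel.

For a SNP window `R` the scan statistic is

```
Q(R) = sum_{i in R} z1_i * z2_i / (sum_{i in R} l_i)^theta
```

where `z1`, `z2` are the two studies' association z-scores, `l_i` is the LD
score of SNP `i` (1 Mb window), and `theta` tunes the LD penalty.  Within
each approximately LD-independent block the maximal `|Q|` over variable-size
windows is compared against a Monte-Carlo null: pseudo z-score pairs are
drawn from the plug-in null covariance (heritabilities and a sample-overlap
term estimated by LD-score regression; LD from the reference panel;
block-tridiagonal conditional Gaussian sampling with TSVD-regularized
inverses), significant windows are peeled off iteratively, candidates are
pooled genome-wide and BH-corrected at FDR 0.05, nearby regions are merged
(<= 100 kb), and `theta` is chosen adaptively to maximize the proportion of
genetic covariance captured by the detected regions.

## Layout

| module | contents |
| --- | --- |
| `logoscan.gwas_io` | `.sumstats` / PLINK / dosage-TSV / BED readers, allele harmonization, region output |
| `logoscan.ld_core` | genotype standardization, LD matrices and scores, bias-corrected squared-LD estimator, TSVD pseudo-inverse |
| `logoscan.covariance_regression` | LDSC-style heritability, cross-trait covariance + overlap intercept, two-annotation stratified covariance, liability/observed scale conversion |
| `logoscan.null_sampler` | null covariance assembly (with overlap splitting) and pseudo z-score sampling |
| `logoscan.scan_engine` | scan statistic, window enumeration, peel-off scan, BH FDR, merging, adaptive theta, full pipeline |
| `logoscan.synthetic_data` | mosaic genotype simulator, effect-size models, GWAS z-score simulation, fixture bundles |
| `logoscan.evaluation` | point/segment detection rates, G-score, size-matched permutation enrichment, conditional annotations |
| `logoscan.cli` | `logoscan` command-line entry point |

## CLI

```bash
# generate a synthetic input bundle (panel TSV, two .sumstats, blocks BED, truth BED)
logoscan simulate --scenario power_grid --out demo/ --seed 1 --m-snps 2000 --n-ref 500 --n 2000

# run the detection pipeline
logoscan run --sumstats1 demo/trait1.sumstats --sumstats2 demo/trait2.sumstats \
             --panel demo/panel.tsv --blocks demo/blocks.bed --out results/ \
             --n-mc 5000 --seed 1 [--overlap auto|none|VALUE] [--theta-grid 0.4,...,0.7]

# score detections against ground truth
logoscan evaluate --truth demo/truth.bed --detected results/regions.tsv

# LD scores / enrichment permutation test
logoscan ldscore --panel demo/panel.tsv --out l2.tsv
logoscan enrich --detected det.bed --annotation ann.bed --genome genome.tsv --n-perm 100000
```

`run` writes `regions.tsv` (chrom, start, end, block_id, n_snps, q_stat, p,
q_fdr; BED-style half-open coordinates), `theta.json` (the theta grid and the
selected value) and `manifest.json` (input hashes, config, seed) for exact
reruns.  Reference panels may be PLINK `.bed/.bim/.fam` or a plain dosage
TSV.  Sample overlap between the two GWAS is absorbed through the cross-trait
regression intercept (`--overlap auto`), can be disabled (`none`), or set
explicitly to a known `rho_e * n_s` value.  For binary traits,
`logoscan.covariance_regression.observed_scale` converts liability-scale
heritability/covariance to the observed scale.

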