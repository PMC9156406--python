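# File formats

All tabular files are tab-separated with a header row; coordinates are
1-based inclusive (GRCh37/VCF convention).  Rows violating per-row
invariants are diverted to a sidecar reject report with a `reason`
column rather than aborting the run.

## Genotypes

- **PLINK BED/BIM/FAM** (`read_plink` / `write_plink`): SNP-major v1
  `.bed`.  The BIM allele1 (`a1`) column is the dosage-counted effect
  allele.  Hard calls only (0/1/2, missing).
- **VCF** (`read_vcf` / `write_vcf`): ALT is the counted allele; dosage
  taken from the `DS` FORMAT field when present, else derived from
  `GT`.  Reading uses cyvcf2 when installed, with a plain-text fallback.

## Tables (`read_table(path, schema)`)

| schema | mandatory columns | row invariants |
|---|---|---|
| `eqtl` | gene_id, variant_id, chrom, pos, effect_allele, other_allele, slope, pval_nominal | single-base ACGT alleles, effect ≠ other, p ∈ (0, 1] |
| `gwas` | variant_id, effect_allele, other_allele, beta, p | effect ≠ other, p ∈ (0, 1] |
| `annotation` | gene_id, chrom, start, end | start ≤ end, autosomal chrom |
| `phenotype` | individual_id (+ outcome/covariate columns) | — |
| `sample_meta` | sample_id, region, stage | stage ∈ {early, adult} |

Header matching is order-insensitive; a missing mandatory column raises
a schema error naming it.

## Expression

`write_expression` / `read_expression`: a genes × samples TSV (index
column `gene_id`) plus a sample-metadata TSV (`sample_id`, `region`,
`stage`).

## Outputs

- network TSV: `gene_id`, `r`, `sign`, `fold_change`
- weights TSV: `variant_id`, `region`, `weight`, `gene_id`, `slope`,
  `network_sign`, `flip`
- scores TSV: `individual_id`, `score_<region>` per region,
  `score_combined`
- `manifest.json`: config snapshot plus per-region record counts
  (`genes_network`, `pairs_in`, `pairs_harmonized`,
  `pairs_deduplicated`, `pairs_clumped`, `snps_scored`); counts are
  checked to be non-increasing along the filter stages.
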