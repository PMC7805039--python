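# gwasvcf-kit

Convert, harmonise, index and query GWAS summary statistics stored as
**GWAS-VCF**.

GWAS analysis tools emit summary statistics (variant, effect size β,
standard error, P value) in dozens of incompatible tabular layouts, with
chronic ambiguity about which allele the effect size refers to, little or
no embedded study metadata, and no index — so secondary analyses
(Mendelian randomisation, colocalization, polygenic scores, LD-score
regression) inherit slow, error-prone preprocessing. This toolkit stores
summary statistics in an adapted VCF 4.2: one variant per row, the
**alternative allele is always the effect allele**, per-trait statistics
live in sample columns (FORMAT fields `ES`, `SE`, `LP` = −log₁₀ P, and
optionally `AF`, `SS`), study/trait metadata in structured `##SAMPLE`
header lines, and the dbSNP locus identifier in `INFO/RSID` (an rsid names
a locus, not an allelic substitution, so it cannot serve as the unique
per-row ID). Files are BGZF-compressed, karyotypically sorted, and dually
indexed: tabix for positional queries and an rsidx-layout SQLite database
for rsid→coordinate lookup.

The core guarantees the converter enforces:

- **Harmonisation** — the REF (non-effect) allele of every record matches
  the reference genome. If the input's *effect* allele matches instead,
  the alleles are swapped, β := −β and every allele frequency f := 1 − f.
  Records matching neither allele (including reverse-complement-only
  matches — no strand flipping is ever attempted) are excluded or flagged
  `HARMONISATION_FAILED`.
- **Normalisation** — indels are rewritten to the unique leftmost,
  trimmed spelling, so equivalent representations of one edit compare
  equal.
- **Validity by construction** — 1-based coordinates, explicit A/C/G/T
  haplotypes, unique non-null IDs, karyotypic sort order and declared
  FORMAT/INFO fields are checked at every write; files parse under any
  htslib-family tool (bcftools, tabix, pysam, cyvcf2, ...).

A deterministic synthetic-data generator (`gwasvcfkit.synthdata`) emulates
a Neale-lab-style dense sumstats table with injected allele swaps,
non-left-aligned indel spellings, multiallelic sites, incompatible and
malformed rows — each recorded in a ground-truth ledger — so the whole
pipeline is testable without downloading anything.

## Worked example

```bash
# 1. synthesize a reference genome + summary statistics + column schema
gwasvcfkit simulate --seed 4 --variants 800 --traits 1 --out-dir demo/

# 2. convert to harmonised, sorted, indexed GWAS-VCF
gwasvcfkit convert --sumstats demo/sumstats_trait_1.tsv \
    --schema demo/schema.json --ref demo/reference.fa \
    --out demo/trait.vcf.gz --trait-id bmi
```

which reports (stderr):

```
INFO convert: read=832 written=824 rejected_parse=8 rejected_validation=0 excluded=0 flagged=0
  harmonisation={'unchanged': 666, 'swapped': 158, 'incompatible': 0, 'not_in_reference': 0}
written 824 records to demo/trait.vcf.gz (read 832, rejected 8, excluded 0, flagged 0)
```

832 input rows were read (800 sites, 32 of them multiallelic siblings
sharing a locus); 8 deliberately malformed rows were rejected with
per-row reasons; 158 rows arrived with the effect/other alleles swapped
and were repaired (β negated, frequencies complemented), giving 824
harmonised records. `demo/trait.vcf.gz.tbi` (tabix) and
`demo/trait.vcf.gz.rsidx` (rsid index) are built automatically. Then:

```bash
gwasvcfkit query demo/trait.vcf.gz --region 1:40000-60000   # interval
gwasvcfkit query demo/trait.vcf.gz --rsid rs433375064       # by locus id
gwasvcfkit query demo/trait.vcf.gz --pval 5e-8              # P < 5e-8 scan
gwasvcfkit validate demo/trait.vcf.gz                       # 4 x PASS
gwasvcfkit export demo/trait.vcf.gz                         # GWAS-Catalog TSV
```

A query prints GWAS-Catalog-style columns, e.g.

```
chromosome  base_pair_location  effect_allele  other_allele  beta           standard_error  p_value       ...
1           42297               T              A             0.02529920079  0.02085510083   0.2250950634
```

where `beta` is the effect of one dose of `effect_allele` and `p_value`
is recomputed from the stored `LP` on the fly. The same operations are
available as library functions (`convert_sumstats`, `query_interval`,
`query_rsid`, `query_pvalue`, `merge_traits`, `export_tsv`, ...).

Multiple single-trait files over the same assembly merge into one
multi-trait file (`gwasvcfkit merge a.vcf.gz b.vcf.gz --out ab.vcf.gz`),
one sample column per trait.

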