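# panelforge

Construction and quality control of cohort **allele-frequency reference
panels** from per-sample genotype evidence — the kind of panel a national
genome project distributes as a sites-only VCF with `AC`/`AN`/`AF` per
alternative allele.

It is written for groups who run joint genotyping over hundreds to thousands
of whole genomes and need the orchestration around the caller to be correct
and testable:

- **Chunked joint genotyping with overlap reconciliation.** Contigs are split
  into fixed-size chunks (default 3 Mb) sharing a short overlap (default
  1 kb). Adjacent chunks are cross-checked over the shared zone and any
  disagreement — including a call present in only one chunk — is removed from
  the panel and reported, so chunking can never silently change the result.
- **Sex-aware X-chromosome ploidy under two pseudoautosomal conventions.**
  Females are diploid across the X; males are diploid only in PAR1/PAR2
  (TWO_PAR mode) or additionally in the X-transposed region XTR (THREE_PAR
  mode). `AN` at each site is the sum of per-sample ploidies over called
  samples: `AN = 2·females + males` in male-hemizygous regions.
- **Circular mitochondrial calling via dual linearizations.** The circular
  genome is cut at two breakpoints 10,000 bases apart; variants near the
  primary breakpoint are taken from the shifted linearization, where they sit
  far from any edge. The merge is rotation-invariant.
- **Sample QC**: sex inference from the X inbreeding coefficient F with a
  Y-depth consistency check (so XO-like karyotypes come out ambiguous rather
  than male), and relatedness pruning from method-of-moments IBD
  (PIHAT = Z2 + Z1/2 with finite-sample frequency corrections).
- **Panel QC**: WGS-vs-array genotype concordance matrices, cross-panel
  allele-frequency comparison with Pearson r and mask-annotated outliers,
  Ts/Tv ratios, and accessibility tracks from depth under two MAPQ policies.
- **Population structure**: MAF / Hardy-Weinberg-exact / missing-rate
  filters, `--indep-pairwise`-style LD pruning, frequency-standardized PCA,
  and a maximum-pairwise-PIHAT check for PCA outlier clusters.

Real cohort genotypes are access-controlled, so the package ships a fully
seeded synthetic-cohort generator (`panelforge.synthetic`) producing
per-sample VCFs, array genotype tables and depth tracks with the statistical
structure the pipeline assumes: Beta-distributed allele frequencies,
Hardy-Weinberg genotypes, sex-linked ploidy, Mendelian relatives and
duplicates, genotyping error, and a MAPQ-0 depth mixture. Every analysis is
testable end to end from a single seed.

## Worked example

Simulate a small cohort, write one VCF per sample, and build the panel with
the chunked pipeline:

```python
from panelforge.synthetic import CohortSpec, simulate_truth, emit_sample_vcfs

spec = CohortSpec(n_samples=8, contig_plan=(("autosome", 5_000_000),),
                  n_sites=120, genotype_error=0.001, seed=7)
truth = simulate_truth(spec)
emit_sample_vcfs(truth, "vcfs")
```

```bash
$ cat > genome.yaml <<EOF
contigs:
  - {name: '1', length: 5000000}
EOF
$ panelforge build --config genome.yaml --vcf-dir vcfs \
      --chunk-size 3000000 --overlap 1000 --out out
panel: 102 sites -> out/panel.vcf (0 overlap-discordant sites removed)
$ grep -v '^#' out/panel.vcf | head -3
1	18671	.	C	A	.	PASS	AC=15;AN=16;AF=0.9375
1	58970	.	A	T	.	PASS	AC=12;AN=16;AF=0.75
1	210569	.	T	C	.	PASS	AC=5;AN=16;AF=0.3125
```

102 of the 120 simulated sites carried an alternative allele in at least one
of the 8 samples; every `AN` is 16 because all samples are diploid and called
at every site, and `AF = AC/AN` per alternative allele. The two 3 Mb chunks
agreed on every call in their 1 kb overlap, so nothing was removed.

For population structure from a dosage table:

```bash
$ panelforge structure --genotypes genotypes.tsv \
      --maf 0.05 --hwe 0.05 --missing 0.01 --indep-pairwise 200 4 0.1 \
      --pcs 4 --out struct
400 variants -> 379 after filters -> 177 after LD pruning; 4 PCs written to struct
```

`struct/pca_coordinates.tsv` then holds one row per sample with its
principal-component coordinates; on a two-subpopulation simulation PC1
separates the groups completely.

The X-chromosome and mitochondrial pipelines are library calls
(`panelforge.sex_chrom_mito.build_x_panels`, `call_mt_panel`); see
`docs/methods.md` for the model behind each stage.

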