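# Methods

This note documents the models, conventions and numerical choices behind
each stage of the panel pipeline, what the synthetic cohorts do and do not
emulate, and the known limitations.

## Coordinates and genome model

All coordinates are 1-based inclusive (VCF convention); BED input is
converted at the boundary. Contig order is the order declared in the genome
configuration, never lexicographic, so chunking and merging are
deterministic. A contig carries a category (autosome, chrX, chrY, mito) and
a circularity flag; only the mitochondrial genome may be circular.

The X region map records PAR1, XTR and PAR2 as closed intervals. The
GRCh37 preset uses 60,001–2,699,520 (PAR1), 88,456,802–92,375,509 (XTR) and
154,931,044–155,260,560 (PAR2). Desk-scale simulations use the same layout
at 1/100 of those coordinates (an X contig of ~1.55 Mb), so the relative
geometry of the named regions is preserved while runs finish in seconds.

## Joint genotyping

The joint caller is a **likelihood-argmax aggregation**: at every position
where at least one sample's most likely genotype carries an alternative
allele, allele lists are merged across samples (ordered by pooled allele
depth, descending, ties broken by allele string) and each sample's genotype
is re-expressed in the merged indexing. Ties in the phred likelihood vector
break toward the lower genotype index; a sample with no record at a position
is a no-call. The caller does not realign or reassemble reads — input
records are taken as the per-sample evidence.

The site quality proxy is the sum, over alt-carrying samples, of the gap
between their smallest and second-smallest phred likelihood, capped at 99
per sample. It is monotone in genotype evidence and fully specified, but it
is a stand-in for a likelihood-model QUAL and is only used relatively (in
the QD annotation).

### Chunked execution

Contigs are processed in chunks of `chunk_size` bases (default 3,000,000)
with consecutive chunks sharing exactly `overlap` bases (default 1,000); the
last chunk may be shorter. Within each shared zone the two adjacent chunks'
call sets are compared site by site on (reference, alt set, full genotype
vector expressed as allele strings — so allele reordering cannot masquerade
as discordance). Agreement keeps one copy; any difference, including a site
called by only one chunk, removes the site from the panel and logs it in
the discordance report. For a deterministic caller the chunked run is
provably identical to a single pass, and the test suite asserts this
bit-for-bit at the 200-sample / 5,000-site / 10 Mb scale.

### Annotations and hard filters

- **DP**: summed sample depth.
- **QD**: site quality proxy divided by the summed depth of alt-carrying
  samples.
- **FS**: −10·log10 of the two-sided Fisher exact p-value on the pooled
  ref-vs-alt × forward-vs-reverse strand table, floored at 0. The p-value
  sums hypergeometric probabilities of tables no more likely than the
  observed one, with the customary 1+1e-7 relative slack at the inclusion
  boundary (the same convention as R's fisher.test); it is computed from
  vectorized log-gamma terms and matches an exact integer-arithmetic
  enumeration to ~1e-12 on all tables with margins ≤ 30.
- **SOR**: symmetric odds-ratio strand test with +1 pseudocounts,
  ln(R + 1/R) + ln(refRatio) − ln(altRatio) where R is the strand odds ratio
  and each ratio is min/max of that allele's strand counts. A fully
  balanced table gives ln 2.
- **InbreedingCoeff**: 1 − observed/expected heterozygotes among diploid
  called samples, expected = 2p(1−p)·n. Undefined (absent, not 0) when no
  diploid sample is called.
- **MQ / MQRankSum / ReadPosRankSum** need read alignments and are accepted
  only as pass-through annotations if supplied from outside; they are never
  computed here. This is a documented limitation.

Hard filters are per-annotation thresholds with conventional directions
(QD/DP/InbreedingCoeff fail below, FS/SOR fail above), independent sets for
SNVs and indels, and named FILTER values for every violated annotation.
They default to off: the panel records filter status rather than dropping
sites.

### Frequencies

`AN` at a site is the sum of resolved ploidies over called samples; no-calls
contribute nothing. `AC` counts occurrences per alternative allele and
`AF = AC/AN`. Multiallelic sites are retained as single entries with per-ALT
vectors — their absence is a known weakness of earlier frequency panels.

## X chromosome and mitochondria

The ploidy map resolves (sex, contig category, position, PAR mode) to 1 or 2:
females diploid everywhere on X, males diploid only in regions the mode
treats as pseudoautosomal, everyone haploid on the mitochondrial genome. At
full scale the TWO_PAR/THREE_PAR contrast is produced by remapping X/Y reads
to an XTR-masked reference; at the record level this package realises the
same contrast by reclassifying XTR positions in the ploidy map and, under
TWO_PAR, collapsing male diploid XTR records to haploid (keeping the allele
with the higher allele depth; ties toward the lower allele index). A male
heterozygote at a position that is non-PAR under both modes is invalid input
and raises a ploidy conflict.

The XTR heterozygosity scan computes, in non-overlapping windows of array
markers, the fraction of male genotype calls that are heterozygous. Windows
are labelled with every named region they overlap, so windows purely inside
PAR1/XTR/PAR2 are distinguishable from boundary windows that mix non-PAR
markers. With diploid-behaving male truth the three named regions are
elevated and non-PAR windows are exactly zero at zero error.

The circular mitochondrial genome (length 16,569, rCRS) is linearized at
two breakpoints 10,000 bases apart. The coordinate remap from the shifted to
the primary linearization is pos → ((pos + shift − 1) mod L) + 1, a bijection
verified exhaustively. After haploid joint genotyping on both linearizations,
positions within an edge margin E of either end of the primary linearization
(default E = 300 bases, roughly read-length scale; the choice is not
critical and is configurable) are taken from the shifted call set, which is
breakpoint-distant there; all other positions come from the primary set, so
away from the edges the primary linearization wins any disagreement.
Heteroplasmy is deliberately ignored: calls are haploid major-allele calls.

## Sample QC

**Sex inference** uses the method-of-moments inbreeding coefficient on
non-PAR X markers, F = (O_hom − E_hom)/(M − E_hom) with
E_hom = Σ(1 − 2p(1−p)) over informative markers (≥ 50 required). F ≥ 0.8
suggests male, F ≤ 0.2 female, between is ambiguous. When depth is
available, the Y/autosome mean-depth ratio must agree (≥ 0.3 for male,
≤ 0.1 for female); a contradiction — e.g. a homozygous X with no Y coverage,
the XO signature — demotes the call to ambiguous so irregular karyotypes are
excluded rather than mis-sexed. The F thresholds are the conventional
screening defaults; the Y-ratio cutoffs were chosen once as generous margins
around the simulated male (≈0.5) and female (≈0.01) ratios.

**Relatedness** uses the method-of-moments IBD decomposition on
identity-by-state counts over LD-pruned autosomal markers. Expected IBS
compositions given allele frequencies use falling-factorial (finite-sample)
corrections parameterised by the number of alleles the frequencies were
estimated from, as in the classic PLINK `--genome` estimator; Z0/Z1/Z2 are
solved sequentially, clipped to [0, 1] and renormalised, and
PIHAT = Z2 + Z1/2. A duplicate pair yields PIHAT = 1 exactly; at 10,000
markers parent-offspring pairs land within [0.45, 0.55] and unrelated pairs
below 0.05.

**Pruning** removes samples greedily: repeatedly drop the sample with the
most over-threshold pairs (ties: lower call rate, then the lexicographically
later id), until no kept pair reaches the threshold. The default cutoff
0.1875 is the midpoint between expected second-degree (0.25) and
third-degree (0.125) sharing, so third-degree relatives are kept and closer
ones removed. This greedy rule is deterministic and minimises removals on
small graphs; it differs from the pairwise drop-one behaviour of the
original tooling. Every run re-audits the kept set against the threshold.

## Concordance and panel comparison

Concordance cross-tabulates WGS against array states over five categories
(NotObserved, NoCall, HomRef, Het, HomAlt) for every marker × sample
observation; hemizygous calls are expressed in the array's diploid
vocabulary. The (NotObserved, NotObserved) cell is undefined and never
populated. The concordance ratio is the diagonal fraction of the
jointly-called 3×3 genotype block — no-calls and unobserved markers are
excluded from the denominator (one of several defensible denominators; this
one isolates genotype disagreement from missingness).

Panel comparison matches per-ALT keys (contig, pos, ref, alt), attempting a
ref/alt swap with frequency complementation before declaring a key
one-sided. Pearson r is computed on shared frequency pairs; pairs differing
by at least a threshold (default |ΔAF| ≥ 0.3, configurable — chosen because
published outlier examples differ by 0.3–0.5) are reported with the names of
overlapping region masks (e.g. a low-complexity BED) or "Unknown". Strand
flips are not attempted: the synthetic data never generates strand
ambiguity, and real-data harmonization would need allele-frequency-aware
flip detection.

## Population structure

The Hardy-Weinberg test is the exact conditional test: given the allele
counts, the heterozygote count follows a hypergeometric-type distribution
over counts of matching parity; the p-value sums the probabilities of all
counts no more probable than the observed one (standard exact p, not mid-p).
It is computed by the stable mode-anchored recurrence and agrees with an
exact rational-arithmetic enumeration to ~1e-15 for all totals ≤ 25.

Variant filtering applies MAF ≥ threshold, HWE p ≥ threshold and missing
rate ≤ threshold in that order, logging the first failing criterion; it is
idempotent. LD pruning slides a window measured in variant counts (the
`--indep-pairwise 200 4 0.1` convention: window 200, step 4, r² 0.1) and
within each window repeatedly removes, from the currently worst pair, the
member with the lower MAF (ties: later position) until no kept pair exceeds
the r² threshold; the kept set is re-audited before returning. Missing
dosages are mean-imputed for correlation purposes only.

PCA standardizes each variant to (d − 2p̂)/√(2p̂(1−p̂)) and
eigendecomposes the sample × sample covariance. Missing dosages are
mean-imputed (run the filters first; at missing ≤ 0.01 the choice is
immaterial). Components are reported as eigenvector × √eigenvalue with a
deterministic sign convention: the largest-magnitude coordinate of each
component is positive. The outlier-cluster check runs the IBD estimator over
all pairs of a designated sample subset and reports the maximum PIHAT.

## The synthetic cohorts

`CohortSpec` fixes the study conditions: cohort size, sex ratio, contig
plan, sites per contig, a Beta(a, b) prior on alternative allele frequencies
(default a = b = 0.8, a U-shaped spectrum with mean 0.5 that exercises both
rare and common variants), genotype error rate (default 0.001, a typical
high-confidence call error scale; analyses that need a specific rate set it
explicitly), array marker fraction and no-call rate, a relative plan
(duplicates, parent-offspring trios, full-sibling quartets), a
negative-binomial depth model (mean 30×, like production short-read
coverage), and MAPQ-0 fractions with a designated repeat interval.

Founder genotypes are independent Hardy-Weinberg draws from each site's
frequency — two draws in diploid contexts, one in haploid. Children receive
one allele from each parent (sex-aware on X: fathers transmit X only to
daughters outside pseudoautosomal context; mitochondria are maternal);
duplicates are exact copies. X sites are allocated 20% each to PAR1, XTR and
PAR2 and 40% to non-PAR so every ploidy context is exercised at small site
counts — a testability choice, not a realistic density. A fraction of sites
can be made triallelic to exercise multiallelic handling.

Observation flips the true genotype with the error rate using symmetric
single-step flips (hom↔het; haploid flips to a uniformly different allele) —
one parameter, sufficient to exercise the concordance machinery, rather than
a full confusion matrix. Phred likelihood vectors place 0 at the observed
genotype and a jittered scale (default 60) elsewhere; a recalibration-like
toggle adds further jitter to the non-minimal entries without ever moving
the argmax, so genotype-level results are provably invariant under it. Depth
is negative-binomial, allele depths split binomially for heterozygotes, and
strand counts split binomially per allele. Genotype errors, depths,
likelihood jitter, the recalibration toggle and array errors draw from
independent seeded streams, so toggling one subsystem never perturbs
another; identical specs produce byte-identical output files.

What the generator does **not** emulate: read-level data (no FASTQ/BAM, so
alignment-dependent annotations are out of reach), linkage disequilibrium
beyond optional duplicated variants (r² = 1 pairs for pruning tests),
strand-ambiguous alleles, reference errors, indels, and heteroplasmy.
Passing tests therefore demonstrate the correctness of the aggregation,
accounting and statistical machinery under the stated model — not robustness
to alignment artefacts or haplotype structure in real cohorts.

## Problem sizes

The test suite and the acceptance script use cohorts chosen to exercise each
property at meaningful scale while staying desk-sized: 200 samples × 5,000
sites on 10 Mb for chunking transparency; 100 samples × 400 X sites for
ploidy accounting; 40 samples × 400 mitochondrial sites for rotation
invariance; 60 samples × 11,000 markers (pruned to 10,000) for relatedness;
1,000 samples split into two 500-sample panels for cross-panel correlation;
200 samples × 2,000 variants at frequency divergence δ = 0.1 for structure
recovery; and exhaustive enumeration for the exact tests (all genotype
configurations with ≤ 25 samples; all 2×2 tables with margins ≤ 30).

## Known limitations

- The caller aggregates supplied records; it cannot rescue sites absent from
  a sample's input or model reference-block (GVCF) compression.
- QUAL is a proxy; filters depending on a calibrated QUAL scale should not
  be transplanted from other pipelines.
- Alignment-derived annotations (MQ and rank-sum statistics) are
  pass-through only.
- The Y chromosome carries depth evidence for sex inference only; no Y
  variant panel is produced.
- Indels pass through the machinery as alleles but the generator never
  emits them, so indel-specific behaviour (normalisation, left-alignment)
  is untested and out of scope.
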