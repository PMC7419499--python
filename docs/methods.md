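# Methods

## Scope and model of the data

`tailvar` operates strictly downstream of variant calling. Its inputs are
the artifacts a caller-based RNA-seq pipeline produces for a two-breed
cohort: per-sample or merged VCFs with site annotations (DP, QD, MQ,
MQRankSum, ReadPosRankSum) and GT:AD:DP genotypes, a reference FASTA, a
gene annotation (GTF, Ensembl dialect), a known-SNP database VCF, QTL
intervals (TSV, 1-based inclusive), gene-set definitions and optionally a
differential-expression table. Alignment, duplicate handling,
recalibration and the calling itself are consumed as already done, as is
any DE estimation. Indels are out of scope throughout: the first cascade
stage restricts the callset to biallelic single-base substitutions.

Internal coordinates are 0-based half-open everywhere; VCF/GTF (1-based
inclusive) and BED (0-based half-open) convert exactly once at file I/O.

## The confidence cascade

Stage order is fixed: biallelic SNP → hard filter → per-sample read
support → positional masks → known-SNP restriction. Per-stage survivor
counts are recorded in a trace together with the stage and rule labels of
every removed variant, which is what the planted-truth tests key on.

Numerical and semantic choices:

- **Strict inequalities.** Every hard-filter cut-off eliminates only when
  strictly violated (DP < 10 removes DP = 9, keeps DP = 10, etc.).
- **Missing annotations pass.** A rule whose INFO key is absent cannot
  fire; what cannot be evaluated cannot eliminate. This mirrors common
  hard-filtering practice and keeps the cascade total on sparse VCFs.
- **Homopolymer run is recomputed**, never read from INFO: the run of the
  *alternate* base through the substituted position
  (1 + left-run + right-run of the alt base around the site). This makes
  the cascade reproducible on any VCF and pins down a definition the
  upstream annotation leaves loose. An INFO HRun, if present, is ignored.
- **Read support is per sample by default**: a variant call with alt-AD
  < 3 (or without AD) is invalidated and set to a missing genotype rather
  than dropping the site for everyone; the site dies only when no valid
  supported call remains. A pooled reading (summed alt reads across
  samples ≥ 3) is available as `pooled_support=True`; it is a switch, not
  a claim about which reading the upstream pipelines used.
- **Known-SNP matching requires allele identity** (chrom, pos, ref, alt),
  not position alone: a different substitution at a catalogued position is
  still novel.

The cascade is a pure function of its inputs: permuting the input order
leaves the surviving set unchanged, and running it on its own output is a
no-op. Both properties are tested, as is equivalence with a brute-force
re-evaluation of all predicates.

## Context masks

- **SSR (microsatellite) tracts**: perfect tandem repeats of primitive
  1–6 bp motifs meeting per-length copy minima — mono 10, di 6, tri–hexa 5
  (the MISA convention; the upstream pipelines state the ±3 bp flank but
  no copy thresholds, so these are configurable defaults). Detection uses
  the period-m self-match profile of the sequence; a tract is the maximal
  stretch with period m, attributed to its primitive motif only, so an
  (AT)n tract is one interval, never (AT) plus (TA) plus (ATAT). Reported
  intervals carry the 3 bp flank, clipped and merged.
- **Splice-junction flanks**: the first and last 5 bp of every intron
  (clipped for introns shorter than 10 bp); single-exon transcripts
  contribute nothing.
- **Bidirectional transcription**: intersection of the union of '+'-strand
  gene bodies with the union of '−'-strand gene bodies. Same-strand
  overlap does not count. The alternative reading — expressed antisense
  signal rather than annotation overlap — would need the read data this
  package deliberately does not consume; annotation overlap is the
  implemented definition.

Point membership uses binary search over merged, disjoint intervals.

## Breed comparison

"Common to at least two animals" is read as *presence of the alternate
allele* (het or hom-alt) in ≥ 2 valid calls — not as two animals sharing
the same genotype class, which the source description leaves open.
Breed-specificity requires the focal common-SNP plus uniform homozygosity
for the non-focal allele in every genotyped animal of the other breed
(operationally hom-ref at focal-alt sites, which is what "segregating only
in one breed" amounts to). Sites absent from the other breed's calls count
as hom-ref, and missing genotypes do not veto specificity; a strict mode
(`require_complete=True`) makes them veto. By construction the two
specific sets are disjoint, each a subset of its breed's common set, and
relabelling the breeds swaps them exactly.

Ts/Tv is computed on site sets (transitions A↔G, C↔T over everything
else), matching per-breed reporting; zero transversions yields NaN rather
than an exception. The het/hom ratio is per sample over its valid variant
calls (het / hom-alt; NaN when no hom-alt call exists). The published
figure this mirrors is printed with a percent sign ("0.54%") although it
is a plain ratio; the ratio is what is implemented.

**Genotype PCA** follows the EIGENSTRAT/smartpca normalization: missing
dosages are imputed to the site mean, each site is centred and scaled by
√(p(1−p)) with the shrunk allele frequency p = (1 + Σg)/(2 + 2n),
zero-variance sites are dropped, and the sample coordinates are the top
eigenvectors of the sample-sample covariance, with eigenvalue fractions as
explained variance. Mean imputation is chosen for determinism; no
missingness thresholds are applied because the cascade leaves a
near-complete matrix.

## Consequence annotation

Each SNP is classified against every overlapping transcript plus
transcripts within a 5,000 bp flank (the conventional up/downstream
window; configurable). Coding calls extract the affected codon via the
spliced CDS coordinates, substitute the transcript-strand allele
(complemented on '−' transcripts) and translate both codons with the
standard genetic code. Stop codons are modelled as their own feature
(Ensembl GTF keeps them out of the CDS), giving stop_lost/stop_retained;
a non-ATG substitution in the first codon is start_lost. The per-variant
summary is the most severe call under a fixed order (stop_gained >
stop_lost > start_lost > missense > stop_retained > synonymous > UTRs >
other > intron > upstream > downstream > intergenic), so term counts and
impact counts (HIGH/MODERATE/LOW/MODIFIER) each partition the callset.
Ties across transcripts keep the first transcript's call. Homology-based
deleteriousness scores (SIFT-like) are not reimplemented. One visible
consequence of the severity tie-break: a site that is upstream of one gene
and downstream of another is reported as upstream.

## QTL colocalization and enrichment

QTL intervals are 1-based inclusive at both ends; a SNP at an end
coordinate is inside. A SNP inside N QTLs of one trait counts once in that
trait's distinct tally but N times in the SNP×QTL pair tally — this dual
counting is what reconciles "X SNPs in Y QTL positions" style reporting.
Malformed QTL rows are skipped with the file line number; duplicate QTL
ids are kept because overlapping records of one QTL are real in curated
databases. Reported percentages round half-up to integers while full
precision is retained.

Enrichment is the one-sided hypergeometric tail P(X ≥ k) (identical to a
one-sided Fisher test; implemented once via the exact survival function),
with Benjamini–Hochberg adjustment across terms and two reporting tiers:
FDR < 0.05 significant, p < 0.05 and FDR < 0.3 suggestive. The default
background is caller-supplied; the cohort pipeline uses all annotated
genes, and the choice is an explicit argument rather than a hidden
default, because web-service defaults differ.

## The synthetic cohort

The generator's defaults are the emulated study design: two breeds of
four samples, two 100 kb chromosomes, 16 genes, 50 + 50 breed-specific
sites, 100 shared sites, 10 sites for each of seven artifact classes, and
a known-SNP database covering ~94% of the sites that reach the database
stage. The number of `novel` sites is derived from that coverage target
(n_novel = round(n_good · (1−f)/f), 13 at the defaults) unless set
explicitly.

Construction guarantees rather than hopes for the planted properties:

- Homopolymer runs (6–8 bp) and SSR tracts are planted at recorded
  coordinates in a reserved head region of each chromosome, with
  periodicity-breaking bases at both boundaries so tract lengths are
  exact; the gene layout starts after the reserved region.
- `generate_annotation` writes transcript sequence into the (mutable)
  reference, so every CDS genuinely starts with ATG, contains no internal
  stop and ends at a stop codon; the first gene of each chromosome hosts a
  nested antisense gene inside an enlarged intron, creating the
  opposite-strand overlap the bidirectional mask needs without sequence
  conflicts.
- Site positions are rejection-sampled against the *recomputed* masks and
  homopolymer rule, with ≥ 4 bp spacing, so good sites pass every filter
  by construction and each artifact class violates exactly one rule
  (multiallelic: two ALTs; low_depth: DP = 9; low_support: every carrier
  at exactly 2 alt reads; high_hrun: the base adjacent to a planted run,
  alt extending it past 5; mask classes: inside exactly their own mask;
  novel: absent from the database).
- INFO fields draw from passing envelopes (DP 15–60, QD 5–30, MQ 50–60,
  rank sums ±2) so artifact classes are the only filter casualties.
- Alternate alleles are drawn transition-biased (p = 0.75) so the
  cohort's Ts/Tv lands in the high-2s, the regime of coding-region SNP
  sets, rather than the 0.5 of uniform substitution.
- A configurable number of shared sites are planted at chosen codon
  positions with known consequences (10 missense, 5 synonymous,
  3 stop_gained by default), and a configurable number of genes
  (7 by default) are guaranteed to both contain breed-specific sites and
  appear as significant rows of the simulated DEG table.

The truth table records every planted site, its class, its expected
coding consequence where planted, and all per-sample genotypes; identical
configurations produce byte-identical output files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level error processes (the INFO values are
drawn, not derived from reads), linkage and allele-frequency spectra,
RNA-editing artifacts, incomplete or wrong annotation, cross-contamination
between filter rules (real artifacts often violate several), and genome
scale. The planted-truth results are a correctness check of the
implemented rules, not an estimate of real-data sensitivity/specificity.

## Problem sizes and determinism

The test and acceptance runs use the default cohort (2 × 100 kb, 283
planted sites, 8 samples), which exercises every stage in a few seconds;
all randomness flows from a single integer seed through
`numpy.random.default_rng`, and the acceptance script derives its
simulation seed from its `--seed` argument. Published-table arithmetic in
`tailvar.study` involves no randomness at all.

## Known limitations

- Per-transcript consequence calls are exhaustive but the summary
  collapse is order-fixed; alternative collapsing rules (e.g. canonical
  transcript) are not implemented.
- The bidirectional mask is annotation-derived; expressed antisense
  transcription without annotation is invisible to it.
- `hard_filter` evaluates only the five named INFO keys plus the
  recomputed homopolymer run; caller-specific extras (FS, SOR, …) pass
  through untouched.
- The enrichment stand-in is the plain hypergeometric tail; rank-combined
  statistics of web enrichment services are not reproduced.
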