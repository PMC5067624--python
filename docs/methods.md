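# Methods

## Study system and model

The package models a deletion-mapping experiment in a hemizygous radiation
hybrid (RH) panel. A diploid-like "survey" reference carries planted gene
models; one gene is causal: five exons and four introns, two in-frame ATG
start codons 156 nt apart (proteins of 326 and 274 aa), and a single
diagnostic exonic position whose functional state G encodes arginine (AGG,
residue 173 from the first start) and whose nonfunctional state A encodes
lysine (AAG). Every other property of the analysis — bulk contrast,
centiRay map, landing interval, HSV diagnosis, expression round trips — is
measured against this planted truth.

### Radiation deletions

Per line and scaffold, breakpoints are a homogeneous Poisson process
(`breaks_per_Mb`); each resulting segment is lost independently with
probability `1 − retention_prob`. A line with no breakpoints keeps its
chromosome intact (a fully deleted genome would not regenerate a viable
line). Deletions are stored merged as 0-based half-open intervals; the
phenotype truth is whether any deletion overlaps the causal gene body.

### Test cross

The tester is hemizygous for a functional homoeoallele; the RH line
contributes a functional gamete with probability ½ when it retains the
locus, never when deleted. Enumerating gametes, the probability of a
shrivelled seed (zero functional copies) is ¼ (retained, a 1:3 ratio) or ½
(deleted, 1:1). Counts are binomial draws; classification is by the exact
binomial log₁₀ likelihood ratio between p = ½ and p = ¼ on the shrivelled
count, calling the better model at ≥ 1.0 (10:1 odds) and "ambiguous"
otherwise. Ambiguous calls are treated as missing downstream.

### Restriction-reduced bulk reads

Each bulk pools six lines (retaining vs deleting the causal locus). Every
retained segment of a line is digested per enzyme independently; deletions
are treated as gaps rather than excised-and-rejoined, because radiation
deletions are orders of magnitude larger than fragments and junction
fragments would contribute negligibly. Only internal fragments (cut at both
ends) within the 100–600 bp size-selection window emit read pairs, anchored
at the fragment ends (mate 1 forward off the left cut, mate 2 reverse off
the right cut), with substitution errors at `error_rate` and an optional
contaminant. The contaminant genome is drawn so its canonical 31-mer
spectrum is disjoint from the reference, making the foreign-read filter
well-posed; spiked reads are a fixed fraction of the emitted total.

Enzyme sites are planted with inter-site gaps alternating between a short,
size-selectable gap (150–550 bp) and a long complementary gap, so the mean
gap equals `enzyme_site_spacing` (site count ≈ length/spacing) while about
half the fragments fall inside the size window — mimicking the subset of a
natural site distribution that survives size selection.

## Analysis choices

- **Contigs of reads.** Reads are collapsed by canonical (strand-folded)
  identity and chained by exact suffix/prefix overlap (≥ `min_overlap`,
  seeded by a shared k-mer). There is deliberately no error-tolerant
  consensus: a read with an error becomes its own low-coverage contig and
  drops out at the presence threshold. Coverage per bulk is read bases over
  consensus length.
- **Presence calls.** POS-only requires coverage ≥ 5× in the POS bulk and
  ≤ 0× in the NEG bulk (both configurable); the symmetric rule gives
  NEG-only, both-covered gives "both", anything else "neither".
- **Extension.** Anchoring is exact canonical-31-mer seeding followed by
  maximal exact-match growth; a read whose best placements tie is left
  unextended (repeats must not chimerize the locus), and reverse-strand
  anchors are reverse-complemented so output is always on the survey
  forward strand. Growth is 1 kb per side per iteration to a 70 kb cap,
  clipped at scaffold ends; the cap binds exactly (the last growth is
  truncated). With simulated errors, anchoring uses any error-free seed and
  mismatches are tolerated only inside the original read span (≤ 10%).
- **Assembly statistics** follow the count/length convention: N50 is the
  number of largest contigs whose cumulative length first reaches half the
  assembly; L50 is the length of the contig at that point.
- **Marker model.** A marker assays an amplicon interval and is scored
  deleted when any deletion overlaps it; gene-derived markers assay the
  gene body, so the causal gene's marker matches the phenotype truth by
  construction (its discordance is zero whenever phenotyping is
  error-free), while neighbouring markers decay with distance.
- **Map construction.** Loci with identical retention vectors (missing
  breaks identity; no imputation) collapse into one "unique locus". Unique
  loci are ordered by minimum total obligate breaks over adjacent pairs —
  exhaustively up to 8 loci; beyond that by greedy insertion from the best
  exhaustive triple refined by a descent over single-locus relocations and
  segment reversals (2-opt). Ties settle toward the lexicographically
  smallest order, and orientation is normalized the same way. Positions are
  cumulative two-point distances, cR = −100·ln(1−θ) with θ the fraction of
  pairwise-complete lines whose states differ; θ = 1 is flagged unlinked.
- **Landing.** The refined interval is the open span between the anchored
  loci flanking the cosegregating locus in map order; the flank-tagged
  ORFs straddle the interval boundaries and are thereby excluded, so
  candidates are ORFs strictly inside. The ORF caller is a naive ATG→stop
  scanner over six frames recording downstream in-frame ATGs as
  alternative starts; planted genes carry introns, so candidate
  confirmation runs it on spliced CDS (`orfs_from_genes`) while gene
  density uses whole-scaffold arithmetic (Kb per ORF, 3 significant
  figures).
- **Haplotype alignment** projects each sequence onto the first via global
  pairwise alignment (match +1, mismatch −1, gap open −4, extend −0.5) and
  requires ≥ 90% identity — homoeologues are near-identical, and anything
  below that threshold deserves manual alignment rather than automatic
  projection. Diagnostic columns must partition the functional group from
  the rest with zero exceptions. Indel placement follows the aligner's
  highest-scoring path; substitution columns are unaffected by gap-shift
  ambiguity.
- **Expression.** Pyrosequencing normalizes each variant peak by the mean
  of the two flanking reference-base peaks and reports percent of the
  reference sample's G value (100% by definition); the four qualitative
  expression classes are left to the caller — the continuous G:A pair is
  reported. ΔΔCt uses per-sample mean Ct differences against a named
  calibrator, RQ = 2^−ΔΔCt, with the replicate SD taken over per-replicate
  RQ values.

## Default study conditions

The default synthetic study is one 5 Mb scaffold with 10 genes (the causal
gene central), a 64-line panel, and 6+6 bulks — a deliberate scale-down of
a 644-line experiment to desk scale. Parameters, with units and rationale:

| parameter | default | rationale |
|---|---|---|
| `breaks_per_Mb` | 1.0 | adjacent 500 kb markers resolve clearly (θ ≈ 0.14 per interval at 64 lines) while long-range breakage stays below the 2q(1−q) = 0.375 independence ceiling, so minimum-break ordering is not misled by saturation |
| `retention_prob` | 0.75 | typical RH segment retention |
| `depth` | 8× per line | matches ~49× coverage over a six-line bulk; also makes "every read of the sole retaining line is errored" (p ≈ 0.18^n_reads) negligible, which matters because the contig builder is deliberately not error-tolerant |
| `read_length` | 100 bp | consistent with tens of millions of pairs per ~10 Gb library |
| size selection | 100–600 bp | standard reduced-representation window |
| `error_rate` | 2×10⁻³ /base | Illumina-like substitution rate |
| `contam_frac` | 0.01 | a mild foreign-DNA contamination |
| `enzyme_site_spacing` | 2 kb | ~2500 sites per enzyme on 5 Mb; half the fragments size-selectable |
| test-cross seeds | 160 | drives the per-line miscall probability of the 10:1 LR classifier to ~10⁻⁴, reproducing the error-free-phenotyping regime in which one marker can cosegregate across every line |
| `k` | 31 | one uint64 per k-mer; unique in a 5 Mb background |
| `max_len` | 70 kb | observed ceiling for reference-guided extension |

The ordering simulation study (10 markers at 10 kb spacing, 64 lines) uses
6 breaks/Mb — the same expected breaks per marker interval as the default
map, rescaled to the tighter spacing.

## What the generator does and does not emulate

It emulates the statistical structure the analysis relies on: deletion
haplotypes shared within bulks, restriction-anchored read clusters,
coverage presence/absence, Mendelian seed ratios, diagnostic-variant
haplotype structure, and planted pyrosequencing/qPCR signals. It does not
emulate base-quality error profiles, indel errors, PCR duplicates,
repeat-induced multi-mapping (the background is random sequence, so
k-mer anchors are essentially unique), polyploid homoeologous
cross-mapping, or chromosome flow-sorting. Passing recovery tests
therefore shows the algorithms are correct under the stated model, not
that they are robust to every artifact of real wheat libraries —
repeat-rich genomes in particular would stress the unique-anchor
assumption, which is why ambiguous anchors are left unextended.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open throughout; strands are "+"/"−"; FASTQ
qualities Phred+33. Zero seeds → ambiguous typing; zero informative lines →
error in two-point distance; an all-identical retention matrix yields a
single unique locus at 0 cR; empty contig sets are rejected by
`assembly_stats`; flanking anchors at equal cR raise (division by zero);
fragments shorter than the read length emit no reads; contigs whose
overlapping placements disagree in sequence are kept separate and logged.

## Known limitations

The contig-forming and extension procedures are declared reconstructions of
a published analysis whose exact algorithmic details are not public; all
their parameters are exposed in `RunConfig`. Multipoint maximum-likelihood
RH mapping is out of scope (two-point distances plus minimum-break ordering
only), as are diploid retention models and interference. The landing step
assumes the cosegregating locus is flanked by two anchored loci in map
order; when a misordered map leaves it at a map end, the study reports no
candidate rather than guessing — this accounts for the rare misses in the
20-replicate landing study.
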