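# rhbulkseq

Gene landing by radiation-hybrid BulkSeq deletion mapping.

## The problem

Some traits segregate with the **presence or absence** of a locus rather
than with allelic variation — for example a nuclear gene restoring
nucleus–cytoplasm compatibility in alloplasmic wheat, whose deletion makes
seeds shrivel and die. In a radiation hybrid (RH) panel, each hemizygous
line carries random radiation-induced deletions, so marker **co-retention**
frequency measures physical proximity, and pooled sequencing of
phenotypically contrasting lines turns the trait into a coverage contrast:
restriction-site-anchored read clusters ("contigs of reads") present in the
bulk of locus-retaining lines (bulk POS) but absent from the bulk of
locus-deleting lines (bulk NEG) must lie inside the region all NEG lines
co-deleted.

`rhbulkseq` implements that analysis end to end, together with a
ground-truthed synthetic-data generator, for geneticists who want to study,
teach or stress-test the approach at desk scale:

- **in-silico restriction reduction** (PstI `CTGCAG`, AatII `GACGTC`, cut
  after base 5) and presence/absence calling per contig;
- **foreign-read filtering** by shared canonical k-mers with the reference
  spectrum;
- **iterative reference-guided read extension**: anchor a 100 bp read by an
  exact 31-mer, grow it by 1 kb of survey context per side and iteration up
  to 70 kb, merge overlapping placements, and summarize with the
  N50-as-count / L50-as-length convention;
- **RH genetics**: deletion typing from test-cross seed ratios
  (shrivelled:plump of 1:1 when the locus is deleted vs 1:3 when retained,
  called by a binomial likelihood ratio), marker ordering by minimum
  obligate breaks, centiRay distances `cR = -100·ln(1-θ)`, cosegregation
  scanning, and physical anchoring into a Kb-per-cR resolution;
- **gene landing**: the open interval between the anchored markers flanking
  the cosegregating marker, intersected with predicted ORFs;
- **homoeologous sequence variants and expression**: haplotype alignment,
  diagnostic-column calling, codon-level effect annotation (e.g. AGG→AAG,
  Arg→Lys), pyrosequencing peak normalization (variant peak over the mean
  of the two flanking reference peaks) and qPCR relative quantification by
  `2^-ΔΔCt`.

## Worked example

`python examples/03_rh_mapping.py` simulates a 5 Mb genome with ten planted
genes and a 64-line RH panel, deletion-types every line from a 160-seed test
cross, and maps ten gene-derived markers:

```
RH000: 85 shrivelled / 75 plump -> deleted (truth: deleted)

cosegregation scan (top 3):
  locus  discordance  n_informative  cosegregating
Xgene05            0             64           True
Xgene06           11             64          False
Xgene04           14             64          False

cosegregating marker: Xgene05 (marker in the causal gene: Xgene05)
map resolution: 23 Kb/cR
```

The 85:75 seed ratio is ~1:1, so the line lost the locus. `Xgene05` — the
marker inside the planted causal gene — is the only marker that never
disagrees with the phenotype across all 64 lines. `examples/04_gene_landing.py`
then intersects the interval between its anchored flanking markers with the
ORF set and reports the planted gene as the only candidate, plus the
gene-density arithmetic (1.83 Mb / 15 ORFs = 122 Kb per ORF).
`examples/01_bulk_contrast.py` runs the sequencing side: all POS-only
contigs fall inside the NEG-shared deletion and tile 100% of its
size-selected restriction fragments.

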