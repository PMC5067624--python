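"""Ground-truthed synthetic inputs for the deletion-mapping pipeline.

The generator emulates, at desk scale, the study system of a radiation
hybrid (RH) BulkSeq experiment in wheat:

* a "survey" reference of scaffolds carrying planted gene models, one of
  which is the causal locus — a five-exon gene with two in-frame start
  codons and a single diagnostic G/A variant whose G (functional) vs A
  (nonfunctional) states change one arginine to a lysine;
* an RH panel of hemizygous lines whose radiation-induced deletion
  haplotypes follow a Poisson-breakpoint / independent-segment-loss model;
* test-cross seed counts (1:1 shrivelled:plump when the causal locus is
  deleted, 1:3 when retained — from Mendelian enumeration of the
  hemizygous tester x hemizygous/null donor cross);
* restriction-reduced paired-end bulk reads with substitution errors and an
  optional prokaryote-like contaminant whose k-mer spectrum is disjoint
  from the reference;
* pyrosequencing peak heights and qPCR threshold cycles with planted
  allele fractions and fold changes.

Every artifact carries the planted truth needed by recovery tests, and all
generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kmers
from .bulkseq import CUT_OFFSET, ENZYMES, digest, find_sites, reference_spectrum
from .io import ReadPair, SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Filler codons for planted coding sequence are drawn from the T-free codon
# alphabet: without T no stop codon, no ATG and no PstI/AatII site can arise
# anywhere in or across the filler, so the only starts/stops are the planted
# ones.
_FILLER_CODONS = [
    a + b + c
    for a in "CG"
    for b in "ACG"
    for c in "ACG"
    if a + b + c not in ("ATG",)
]


@dataclass
class GeneModel:
    """A planted gene: exon structure plus (for the causal gene) the
    diagnostic variant and the two in-frame translation starts."""

    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, sorted
    start_offsets: tuple[int, ...] = (0,)  # CDS offsets of in-frame ATGs
    variant_cds_offset: int | None = None
    functional_base: str = "G"
    nonfunctional_base: str = "A"

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not s1 < e1 <= s2 < e2:
                raise ValueError(f"{self.gene_id}: exons must be sorted, non-overlapping")
        cds_len = self.cds_length
        for off in self.start_offsets:
            if (cds_len - off) % 3 != 0:
                raise ValueError(f"{self.gene_id}: CDS not divisible by 3 from offset {off}")
        if self.variant_cds_offset is not None and not (
            0 <= self.variant_cds_offset < cds_len
        ):
            raise ValueError(f"{self.gene_id}: variant offset outside CDS")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_cds(self, scaffold_seq: str) -> str:
        return "".join(scaffold_seq[s:e] for s, e in self.exons)

    def cds_to_genomic(self, offset: int) -> int:
        """Map a CDS offset to the genomic coordinate on the scaffold."""
        for s, e in self.exons:
            if offset < e - s:
                return s + offset
            offset -= e - s
        raise ValueError("CDS offset beyond gene")

    def genomic_to_cds(self, pos: int) -> int:
        """Map a genomic position to its CDS offset; error inside introns."""
        acc = 0
        for s, e in self.exons:
            if s <= pos < e:
                return acc + (pos - s)
            acc += e - s
        raise ValueError(f"position {pos} is noncoding (intron or outside gene)")


@dataclass
class ReferenceSet:
    """Survey scaffolds plus the planted gene models (ground truth)."""

    scaffolds: list[SeqRecord]
    genes: list[GeneModel]
    causal_gene_id: str
    site_density: dict[str, float] = field(default_factory=dict)  # sites/Mb

    @property
    def causal_gene(self) -> GeneModel:
        (g,) = [g for g in self.genes if g.gene_id == self.causal_gene_id]
        return g

    def scaffold(self, scaffold_id: str) -> SeqRecord:
        (s,) = [s for s in self.scaffolds if s.id == scaffold_id]
        return s


def _random_bases(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, n)].tobytes())


def _scrub_sites(seq: bytearray, rng: np.random.Generator) -> None:
    """Destroy every accidental enzyme site by mutating its middle base."""
    for site in ENZYMES.values():
        text = bytes(seq).decode()
        for p in find_sites(text, site):
            old = seq[p + 3]
            choices = [b for b in b"ACGT" if b != old]
            seq[p + 3] = choices[rng.integers(0, 3)]


def _causal_cds(rng: np.random.Generator) -> tuple[str, tuple[int, int], int]:
    """Build the causal CDS: 327 codons (326 aa + stop), in-frame ATGs at
    codons 0 and 52 (156 nt apart -> proteins of 326 and 274 aa), and the
    diagnostic AGG (Arg) codon at residue 173 whose middle G -> A makes AAG
    (Lys). Returns (cds, start_offsets, variant_cds_offset)."""
    n_codons = 327
    codons = [
        _FILLER_CODONS[i] for i in rng.integers(0, len(_FILLER_CODONS), n_codons)
    ]
    codons[0] = "ATG"
    codons[52] = "ATG"
    codons[172] = "AGG"  # residue 173 from the first start
    codons[-1] = "TAA"
    return "".join(codons), (0, 156), 517


def _simple_cds(rng: np.random.Generator, n_aa: int = 180) -> str:
    codons = ["ATG"] + [
        _FILLER_CODONS[i] for i in rng.integers(0, len(_FILLER_CODONS), n_aa)
    ] + ["TAA"]
    return "".join(codons)


_EXON_SPLIT = (200, 180, 220, 181, 200)  # sums to 981 = 327 codons
_INTRON_LENGTHS = (87, 110, 130, 150)


def _build_causal_gene(
    rng: np.random.Generator, gene_id: str, scaffold: str, at: int
) -> tuple[str, GeneModel]:
    cds, starts, var_off = _causal_cds(rng)
    pieces = []
    exons = []
    pos = at
    cds_pos = 0
    for i, exon_len in enumerate(_EXON_SPLIT):
        pieces.append(cds[cds_pos : cds_pos + exon_len])
        exons.append((pos, pos + exon_len))
        pos += exon_len
        cds_pos += exon_len
        if i < len(_INTRON_LENGTHS):
            intron = _random_bases(rng, _INTRON_LENGTHS[i])
            _scrub_sites(intron, rng)
            pieces.append(bytes(intron).decode())
            pos += _INTRON_LENGTHS[i]
    model = GeneModel(
        gene_id=gene_id,
        scaffold=scaffold,
        strand="+",
        exons=exons,
        start_offsets=starts,
        variant_cds_offset=var_off,
    )
    return "".join(pieces), model


def simulate_genome(
    n_scaffolds: int = 1,
    scaffold_len: int = 5_000_000,
    n_genes: int = 10,
    enzyme_site_spacing: int = 2000,
    seed: int = 0,
    paralog_free: bool = True,
) -> ReferenceSet:
    """Generate the survey reference with planted genes and enzyme sites.

    All genes are planted on the first scaffold (the "causal" scaffold,
    mimicking one chromosome arm region); remaining scaffolds are gene-free
    background. Enzyme sites are planted with inter-site gaps alternating
    between a short size-selectable gap (150-550 bp) and a long gap, so the
    mean gap equals `enzyme_site_spacing` and the per-enzyme site count is
    ~scaffold_len / spacing.
    """
    if scaffold_len < 10_000:
        raise ValueError("scaffold_len must be >= 10 kb")
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if enzyme_site_spacing < 700:
        raise ValueError("enzyme_site_spacing must be >= 700 bp")
    if n_genes * 3000 > scaffold_len // 2:
        raise ValueError("requested gene density impossible for this scaffold length")

    rng = np.random.default_rng(seed)
    scaffolds: list[SeqRecord] = []
    genes: list[GeneModel] = []
    causal_idx = n_genes // 2
    causal_id = f"gene{causal_idx:02d}"
    site_counts = {name: 0 for name in ENZYMES}

    for si in range(n_scaffolds):
        name = f"scaffold{si}"
        seq = _random_bases(rng, scaffold_len)
        _scrub_sites(seq, rng)

        # plant restriction sites, each enzyme independently
        for ename, site in ENZYMES.items():
            pos = int(rng.integers(200, enzyme_site_spacing))
            short_next = True
            while pos + len(site) < scaffold_len:
                seq[pos : pos + len(site)] = site.encode()
                site_counts[ename] += 1
                if short_next:
                    gap = int(rng.integers(150, 551))
                else:
                    gap = 2 * enzyme_site_spacing - int(rng.integers(150, 551))
                short_next = not short_next
                pos += gap

        if si == 0:
            slot = scaffold_len / n_genes
            for gi in range(n_genes):
                gid = f"gene{gi:02d}"
                at = int(slot * gi + slot / 2)
                if gi == causal_idx:
                    gseq, model = _build_causal_gene(rng, gid, name, at)
                else:
                    cds = _simple_cds(rng)
                    gseq = cds
                    model = GeneModel(gid, name, "+", [(at, at + len(cds))])
                seq[at : at + len(gseq)] = gseq.encode()
                genes.append(model)
        scaffolds.append(SeqRecord(id=name, sequence=bytes(seq).decode()))

    ref = ReferenceSet(
        scaffolds=scaffolds,
        genes=genes,
        causal_gene_id=causal_id,
        site_density={
            name: site_counts[name] / (n_scaffolds * scaffold_len / 1e6)
            for name in ENZYMES
        },
    )
    if paralog_free:
        _check_variant_unique(ref)
    return ref


def _check_variant_unique(ref: ReferenceSet) -> None:
    gene = ref.causal_gene
    pos = gene.cds_to_genomic(gene.variant_cds_offset)
    seq = ref.scaffold(gene.scaffold).sequence
    context = seq[pos - 15 : pos + 16]
    hits = 0
    for s in ref.scaffolds:
        hits += s.sequence.count(context) + s.sequence.count(_kmers.revcomp(context))
    if hits != 1:
        raise RuntimeError("diagnostic variant context is not unique in the reference")


@dataclass
class RHLine:
    """One radiation hybrid line: merged deletion intervals per scaffold."""

    line_id: str
    deletions: dict[str, list[tuple[int, int]]]
    retains_causal: bool

    def retains_interval(self, scaffold: str, start: int, end: int) -> bool:
        """True iff no deletion overlaps [start, end) on the scaffold."""
        return not any(s < end and start < e for s, e in self.deletions.get(scaffold, []))


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def simulate_rh_panel(
    ref: ReferenceSet,
    n_lines: int = 64,
    breaks_per_Mb: float = 1.0,
    retention_prob: float = 0.75,
    seed: int = 0,
) -> list[RHLine]:
    """Simulate hemizygous deletion haplotypes.

    Per line and scaffold, breakpoints are a Poisson process at
    `breaks_per_Mb`; each resulting segment is independently deleted with
    probability 1 - retention_prob. Deletions are merged and sorted, and
    `retains_causal` records whether any deletion overlaps the causal gene
    body.
    """
    if breaks_per_Mb < 0:
        raise ValueError("breaks_per_Mb must be >= 0")
    if not 0 <= retention_prob <= 1:
        raise ValueError("retention_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    causal = ref.causal_gene
    lines = []
    for li in range(n_lines):
        deletions: dict[str, list[tuple[int, int]]] = {}
        for scf in ref.scaffolds:
            L = len(scf.sequence)
            n_breaks = rng.poisson(breaks_per_Mb * L / 1e6)
            if n_breaks == 0:
                continue  # unbroken chromosome: nothing to lose
            cuts = np.sort(rng.integers(1, L, n_breaks))
            bounds = [0, *map(int, cuts), L]
            lost = [
                (s, e)
                for s, e in zip(bounds[:-1], bounds[1:])
                if e > s and rng.random() > retention_prob
            ]
            if lost:
                deletions[scf.id] = _merge_intervals(lost)
        line = RHLine(f"RH{li:03d}", deletions, True)
        line.retains_causal = line.retains_interval(
            causal.scaffold, causal.start, causal.end
        )
        lines.append(line)
    return lines


def mendelian_shrivelled_probability(deleted: bool) -> float:
    """Probability a test-cross seed is shrivelled, by gamete enumeration.

    The tester is hemizygous for a functional homoeoallele (gametes carry 1
    or 0 functional copies, equally). The RH pollen donor is hemizygous for
    the causal locus when it retains it, null when deleted. A seed is
    shrivelled iff it inherits zero functional copies.
    """
    tester_gametes = [1, 0]
    donor_gametes = [0, 0] if deleted else [1, 0]
    outcomes = [
        t + d for t, d in itertools.product(tester_gametes, donor_gametes)
    ]
    return sum(1 for o in outcomes if o == 0) / len(outcomes)


@dataclass
class DeletionTyping:
    """Test-cross seed counts for one RH line, plus the planted truth."""

    line_id: str
    plump: int
    shrivelled: int
    truth_call: str  # deleted | retained

    def __post_init__(self) -> None:
        if self.plump < 0 or self.shrivelled < 0:
            raise ValueError("seed counts must be non-negative")


def simulate_testcross(line: RHLine, n_seeds: int = 160, seed: int = 0) -> DeletionTyping:
    """Draw shrivelled/plump counts from the Mendelian expectation."""
    if n_seeds < 0:
        raise ValueError("n_seeds must be >= 0")
    deleted = not line.retains_causal
    p = mendelian_shrivelled_probability(deleted)
    rng = np.random.default_rng(seed)
    shrivelled = int(rng.binomial(n_seeds, p)) if n_seeds else 0
    return DeletionTyping(
        line_id=line.line_id,
        plump=n_seeds - shrivelled,
        shrivelled=shrivelled,
        truth_call="deleted" if deleted else "retained",
    )


@dataclass
class BulkReads:
    """Paired reads per bulk plus everything needed to score recovery."""

    pairs_pos: list[ReadPair]
    pairs_neg: list[ReadPair]
    pos_line_ids: list[str]
    neg_line_ids: list[str]
    contaminant: SeqRecord | None = None
    n_contaminant: int = 0


def select_bulks(lines: list[RHLine], n_per_bulk: int = 6) -> tuple[list[RHLine], list[RHLine]]:
    """First n lines retaining / deleting the causal locus, in panel order."""
    pos = [l for l in lines if l.retains_causal][:n_per_bulk]
    neg = [l for l in lines if not l.retains_causal][:n_per_bulk]
    if len(pos) < n_per_bulk or len(neg) < n_per_bulk:
        raise ValueError(
            f"panel has too few informative lines for {n_per_bulk}+{n_per_bulk} bulks"
        )
    return pos, neg


def size_selected_fragments(
    ref: ReferenceSet,
    enzymes=("PstI", "AatII"),
    size_min: int = 100,
    size_max: int = 600,
) -> list:
    """Internal (both-ends-cut) reference fragments inside the size window."""
    out = []
    for scf in ref.scaffolds:
        for enzyme in enzymes:
            frags = digest(scf.sequence, enzyme, scaffold=scf.id)
            for f in frags[1:-1]:
                if size_min <= len(f) <= size_max:
                    out.append(f)
    return out


def _retained_segments(line: RHLine, scaffold: SeqRecord) -> list[tuple[int, int]]:
    dels = line.deletions.get(scaffold.id, [])
    bounds = [0]
    for s, e in dels:
        bounds.extend((s, e))
    bounds.append(len(scaffold.sequence))
    return [(s, e) for s, e in zip(bounds[::2], bounds[1::2]) if e > s]


def simulate_bulk_reads(
    ref: ReferenceSet,
    lines: list[RHLine],
    enzymes=("PstI", "AatII"),
    read_len: int = 100,
    depth: float = 8.0,
    error_rate: float = 0.002,
    contam_frac: float = 0.01,
    seed: int = 0,
    n_per_bulk: int = 6,
    size_min: int = 100,
    size_max: int = 600,
) -> BulkReads:
    """Restriction-reduced paired-end reads for the POS and NEG bulks.

    For each bulk line, every retained (non-deleted) genome segment is
    digested per enzyme; internal fragments inside the size window emit read
    pairs anchored at the fragment ends (mate 1 forward off the left cut,
    mate 2 reverse off the right cut) at `depth` mean per-line coverage.
    Substitution errors are applied at `error_rate`; a `contam_frac` fraction
    of reads is spiked in from a contaminant with a disjoint 31-mer spectrum.
    """
    if depth <= 0 or read_len <= 0:
        raise ValueError("depth and read_len must be positive")
    rng = np.random.default_rng(seed)
    pos_lines, neg_lines = select_bulks(lines, n_per_bulk)

    def _emit(bulk_lines: list[RHLine]) -> list[ReadPair]:
        pairs = []
        for line in bulk_lines:
            for scf in ref.scaffolds:
                for seg_start, seg_end in _retained_segments(line, scf):
                    segment = scf.sequence[seg_start:seg_end]
                    for enzyme in enzymes:
                        frags = digest(segment, enzyme, scaffold=scf.id, offset=seg_start)
                        for f in frags[1:-1]:
                            L = len(f)
                            if not (size_min <= L <= size_max) or L < read_len:
                                continue
                            covered = min(2 * read_len, L)
                            n_pairs = max(1, round(depth * L / covered))
                            m1 = f.sequence[:read_len]
                            m2 = _kmers.revcomp(f.sequence[-read_len:])
                            for i in range(n_pairs):
                                pid = (
                                    f"{line.line_id}:{f.scaffold}:{f.start}-{f.end}"
                                    f":{enzyme}:{i}"
                                )
                                pairs.append(ReadPair(pid, m1, m2))
        return pairs

    pairs_pos = _emit(pos_lines)
    pairs_neg = _emit(neg_lines)

    if error_rate > 0:
        for pairs in (pairs_pos, pairs_neg):
            _apply_substitutions(pairs, error_rate, rng)

    contaminant = None
    n_contam = 0
    if contam_frac > 0:
        contaminant = _make_contaminant(ref, rng)
        for pairs in (pairs_pos, pairs_neg):
            n = round(contam_frac / (1 - contam_frac) * len(pairs))
            n_contam += n
            pairs.extend(_contaminant_pairs(contaminant, n, read_len, rng))

    return BulkReads(
        pairs_pos=pairs_pos,
        pairs_neg=pairs_neg,
        pos_line_ids=[l.line_id for l in pos_lines],
        neg_line_ids=[l.line_id for l in neg_lines],
        contaminant=contaminant,
        n_contaminant=n_contam,
    )


def _apply_substitutions(pairs: list[ReadPair], rate: float, rng: np.random.Generator) -> None:
    if not pairs:
        return
    for mate_attr in ("mate1", "mate2"):
        lengths = np.array([len(getattr(p, mate_attr)) for p in pairs])
        n_err = rng.binomial(lengths, rate)
        for idx in np.nonzero(n_err)[0]:
            seq = bytearray(getattr(pairs[idx], mate_attr).encode())
            for pos in rng.integers(0, len(seq), n_err[idx]):
                old = seq[pos]
                choices = [b for b in b"ACGT" if b != old]
                seq[pos] = choices[rng.integers(0, 3)]
            setattr(pairs[idx], mate_attr, bytes(seq).decode())


def _make_contaminant(
    ref: ReferenceSet, rng: np.random.Generator, length: int = 50_000, k: int = 31
) -> SeqRecord:
    spectrum = reference_spectrum(ref.scaffolds, k)
    for _ in range(10):
        seq = bytes(_random_bases(rng, length)).decode()
        if _kmers.shared_count(_kmers.canonical_kmers(seq, k), spectrum) == 0:
            return SeqRecord(id="contaminant", sequence=seq)
    raise RuntimeError("failed to draw a contaminant with a disjoint k-mer spectrum")


def _contaminant_pairs(
    contaminant: SeqRecord, n: int, read_len: int, rng: np.random.Generator
) -> list[ReadPair]:
    pairs = []
    L = len(contaminant.sequence)
    for i in range(n):
        p = int(rng.integers(0, L - 3 * read_len))
        frag = contaminant.sequence[p : p + 3 * read_len]
        pairs.append(
            ReadPair(
                f"contam:{p}:{i}",
                frag[:read_len],
                _kmers.revcomp(frag[-read_len:]),
            )
        )
    return pairs


@dataclass
class PyroSample:
    """Pyrosequencing peak heights around and at the diagnostic position."""

    sample_id: str
    flank_heights: tuple[float, float]  # the two surrounding reference peaks
    peak_g: float
    peak_a: float

    def __post_init__(self) -> None:
        if min(*self.flank_heights, self.peak_g, self.peak_a) < 0:
            raise ValueError("peak heights must be >= 0")
        if max(self.flank_heights) <= 0:
            raise ValueError("at least one flanking peak must be positive")


def simulate_pyro(
    g_fraction: float,
    total_signal: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "sample",
) -> PyroSample:
    """Peak heights with G carrying `g_fraction` of the variant signal."""
    if not 0 <= g_fraction <= 1:
        raise ValueError("g_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def noisy(mean: float) -> float:
        return float(max(0.0, mean + (rng.normal(0, noise_sd) if noise_sd else 0.0)))

    return PyroSample(
        sample_id=sample_id,
        flank_heights=(noisy(total_signal), noisy(total_signal)),
        peak_g=noisy(g_fraction * total_signal),
        peak_a=noisy((1 - g_fraction) * total_signal),
    )


@dataclass
class CtTable:
    """qPCR threshold cycles: per sample/replicate target and reference Ct."""

    data: pd.DataFrame  # columns: sample, replicate, ct_target, ct_reference
    calibrator: str


def simulate_ct(
    true_fold_changes: dict[str, float],
    calibrator: str,
    seed: int = 0,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    base_ct_target: float = 24.0,
    ct_reference: float = 18.0,
) -> CtTable:
    """Ct values constructed so ddCt analysis recovers the planted folds.

    Ct_target(sample) = base - log2(fold): a 2-fold change lowers Ct by one
    cycle. With the calibrator's fold at 1 and zero noise, downstream RQ
    equals the planted fold change exactly.
    """
    if calibrator not in true_fold_changes:
        raise ValueError(f"calibrator {calibrator!r} missing from fold-change table")
    if any(f <= 0 for f in true_fold_changes.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, fold in true_fold_changes.items():
        ct_t = base_ct_target - np.log2(fold)
        for rep in range(1, n_replicates + 1):
            jt = rng.normal(0, noise_sd) if noise_sd else 0.0
            jr = rng.normal(0, noise_sd) if noise_sd else 0.0
            rows.append(
                {
                    "sample": sample,
                    "replicate": rep,
                    "ct_target": ct_t + jt,
                    "ct_reference": ct_reference + jr,
                }
            )
    return CtTable(data=pd.DataFrame(rows), calibrator=calibrator)


@dataclass
class Marker:
    """A PCR marker assaying an amplicon interval; scored deleted when any
    deletion overlaps the interval. Gene-derived markers assay the gene body
    (a marker "tags" its gene)."""

    marker_id: str
    scaffold: str
    start: int
    end: int

    @property
    def position_kb(self) -> float:
        return (self.start + self.end) / 2 / 1000


def markers_from_genes(ref: ReferenceSet) -> list[Marker]:
    """One marker per planted gene, assaying the gene body."""
    return [
        Marker(f"X{g.gene_id}", g.scaffold, g.start, g.end) for g in ref.genes
    ]
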