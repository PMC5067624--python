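"""Physical interval refinement and gene landing.

Once a cosegregating marker and its anchored flanks are known, the physical
interval between the flanking markers (open: the flank-tagged genes are
excluded) is intersected with predicted open reading frames. "Landing"
succeeds when exactly one ORF remains — the candidate gene.

The ORF caller is a naive ATG->stop scanner over all six frames; planted
genes carry introns, so candidate confirmation runs it on spliced CDS while
gene-density statistics run it on genomic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from ._kmers import revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class ORF:
    """A stop-terminated open reading frame, coordinates on forward strand."""

    scaffold: str
    strand: str
    start: int  # 0-based half-open, forward-strand coordinates
    end: int
    frame: int
    protein_length: int  # aa, excluding the stop
    alt_start_offsets: list[int] = field(default_factory=list)  # nt from ORF start
    name: str = ""

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.protein_length != (self.end - self.start) // 3 - 1:
            raise ValueError("protein length inconsistent with ORF span")


def find_orfs(sequence: str, min_aa: int = 10, scaffold: str = "seq") -> list[ORF]:
    """Scan both strands, all frames, for ATG->stop ORFs.

    Within each stop-bounded frame segment, the ORF runs from the first ATG
    to the stop; downstream in-frame ATGs are recorded as alternative start
    offsets. Only stop-terminated ORFs of >= min_aa residues are reported.
    """
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    sequence = sequence.upper()
    L = len(sequence)
    orfs: list[ORF] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for frame in range(3):
            seg_start_atg = None
            alt_starts: list[int] = []
            for pos in range(frame, L - 2, 3):
                codon = seq[pos : pos + 3]
                if codon == "ATG":
                    if seg_start_atg is None:
                        seg_start_atg = pos
                    else:
                        alt_starts.append(pos - seg_start_atg)
                elif codon in STOP_CODONS:
                    if seg_start_atg is not None:
                        s, e = seg_start_atg, pos + 3
                        n_aa = (e - s) // 3 - 1
                        if n_aa >= min_aa:
                            if strand == "+":
                                fs, fe = s, e
                            else:
                                fs, fe = L - e, L - s
                            orfs.append(
                                ORF(scaffold, strand, fs, fe, frame, n_aa, alt_starts)
                            )
                    seg_start_atg = None
                    alt_starts = []
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


@dataclass
class ContigPlacement:
    scaffold: str
    start: int
    end: int
    strand: str
    identity: float


def place_contig(
    contig: str,
    scaffold_seq: str,
    k: int = 31,
    min_identity: float = 0.98,
    scaffold: str = "scaffold",
) -> ContigPlacement | None:
    """Best exact/near-exact placement of a contig on a physical scaffold.

    Seeds with exact k-mer string search on both strands, then scores the
    full-length alignment implied by the seed; returns None (unplaced) when
    no seed yields identity >= min_identity.
    """
    if not contig or not scaffold_seq:
        raise ValueError("contig and scaffold must be non-empty")
    k = min(k, len(contig))
    best: ContigPlacement | None = None
    for strand in ("+", "-"):
        query = contig if strand == "+" else revcomp(contig)
        for off in range(0, len(query) - k + 1, k):
            seed = query[off : off + k]
            hit = scaffold_seq.find(seed)
            while hit != -1:
                start = hit - off
                end = start + len(query)
                if start >= 0 and end <= len(scaffold_seq):
                    window = scaffold_seq[start:end]
                    matches = sum(a == b for a, b in zip(window, query))
                    identity = matches / len(query)
                    if identity >= min_identity and (
                        best is None or identity > best.identity
                    ):
                        best = ContigPlacement(scaffold, start, end, strand, identity)
                hit = scaffold_seq.find(seed, hit + 1)
            if best is not None and best.identity == 1.0:
                return best
    return best


@dataclass
class CandidateReport:
    """The refined interval, the ORFs landing inside it, and gene density."""

    scaffold: str
    start: int  # bp, open interval between the flanking marker positions
    end: int
    candidates: list[ORF]
    flank_markers: tuple[str, str]
    flank_positions_kb: tuple[float, float]
    kb_per_orf: float


def gene_density(total_bp: int, n_orfs: int) -> float:
    """Kb of sequence per ORF, to 3 significant figures."""
    if n_orfs < 1:
        raise ValueError("n_orfs must be >= 1")
    return float(f"{total_bp / n_orfs / 1000:.3g}")


def refine_interval(
    map_result,
    anchors,
    orfs: list[ORF],
    cosegregating_locus: str,
    placements: list[ContigPlacement] | None = None,
    scaffold_len: int | None = None,
) -> CandidateReport:
    """Intersect the marker-pinned interval with predicted ORFs.

    The interval is the open span between the anchored loci flanking the
    cosegregating locus in map order; the flank-tagged ORFs themselves cross
    the boundary positions and are thereby excluded, matching the logic that
    flanking markers exclude the genes they tag. Density is computed over
    the whole scaffold (`scaffold_len` or the ORF span when not given).
    """
    from .rhmap import anchor_and_resolution  # local import avoids cycle at import time

    order = map_result.locus_ids
    rep = next(r for r in order if cosegregating_locus in map_result.groups[r])
    idx = order.index(rep)

    def _nearest_anchor(direction: int) -> tuple[str, float]:
        i = idx + direction
        while 0 <= i < len(order):
            for m in map_result.groups[order[i]]:
                if m in anchors.positions_kb:
                    return m, anchors.positions_kb[m]
            i += direction
        raise ValueError(
            f"cosegregating locus {cosegregating_locus!r} lacks an anchored flank"
        )

    left_id, left_kb = _nearest_anchor(-1)
    right_id, right_kb = _nearest_anchor(+1)
    lo_kb, hi_kb = sorted((left_kb, right_kb))
    start, end = round(lo_kb * 1000), round(hi_kb * 1000)

    scaffold_orfs = [o for o in orfs if o.scaffold == anchors.scaffold]
    candidates = [o for o in scaffold_orfs if o.start > start and o.end < end]
    total = scaffold_len if scaffold_len is not None else max(
        (o.end for o in scaffold_orfs), default=end
    )
    density = gene_density(total, max(1, len(scaffold_orfs)))
    return CandidateReport(
        scaffold=anchors.scaffold,
        start=start,
        end=end,
        candidates=candidates,
        flank_markers=(left_id, right_id),
        flank_positions_kb=(lo_kb, hi_kb),
        kb_per_orf=density,
    )


def orfs_from_genes(ref) -> list[ORF]:
    """Confirmed ORFs for planted gene models (spliced-CDS mode).

    Each gene's spliced CDS is scanned with find_orfs to confirm it encodes
    a stop-terminated ORF starting at its first codon; the record is placed
    at the gene's genomic start with the intron-free CDS extent.
    """
    out = []
    for gene in ref.genes:
        cds = gene.spliced_cds(ref.scaffold(gene.scaffold).sequence)
        hits = [o for o in find_orfs(cds, min_aa=10) if o.strand == "+" and o.start == 0]
        if not hits:
            continue
        confirmed = hits[0]
        out.append(
            ORF(
                scaffold=gene.scaffold,
                strand=gene.strand,
                start=gene.start,
                end=gene.start + (confirmed.end - confirmed.start),
                frame=gene.start % 3,
                protein_length=confirmed.protein_length,
                alt_start_offsets=confirmed.alt_start_offsets,
                name=gene.gene_id,
            )
        )
    return out


def translate_cds(cds: str) -> str:
    """Standard-table translation, stop-trimmed."""
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot
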