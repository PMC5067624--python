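"""Iterative reference-guided read extension.

Short restriction-anchored reads are placed on a survey reference by exact
k-mer seeding, then grown by a fixed flank of survey context per iteration,
re-anchoring each round, until a fixed point, a length cap, or the scaffold
ends. Extended sequences whose survey placements overlap are merged into
"contigs of extended reads", and assembly statistics follow the convention
in which N50 is a contig COUNT (number of largest contigs reaching half the
assembly) and L50 a LENGTH (the length of the contig at that point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kmers
from .io import SeqRecord

log = logging.getLogger("rhbulkseq")


@dataclass
class Placement:
    """A maximal exact match of (part of) a read on the survey."""

    scaffold: str
    start: int
    end: int
    strand: str  # strand of the read relative to the survey forward strand
    read_start: int  # matched span, in survey-forward-oriented read coords
    read_end: int

    @property
    def length(self) -> int:
        return self.end - self.start


class SurveyIndex:
    """Canonical k-mer index over survey scaffolds for exact anchoring."""

    def __init__(self, scaffolds: list[SeqRecord], k: int = 31):
        if not 11 <= k <= 31:
            raise ValueError("k must be in [11, 31]")
        self.k = k
        self.scaffold_ids = [s.id for s in scaffolds]
        self.sequences = {s.id: s.sequence for s in scaffolds}
        kmer_parts, meta_parts = [], []
        for si, s in enumerate(scaffolds):
            fwd = _kmers.kmer_ints(s.sequence, k)
            good = np.nonzero(fwd != np.uint64(2**63))[0]
            fwd = fwd[good]
            canon = _kmers.canonical_ints(fwd, k)
            is_fwd = canon == fwd
            # pack scaffold index, position and orientation into one uint64
            meta = (
                (np.uint64(si) << np.uint64(40))
                | (good.astype(np.uint64) << np.uint64(1))
                | is_fwd.astype(np.uint64)
            )
            kmer_parts.append(canon)
            meta_parts.append(meta)
        kmers = np.concatenate(kmer_parts) if kmer_parts else np.empty(0, np.uint64)
        meta = np.concatenate(meta_parts) if meta_parts else np.empty(0, np.uint64)
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._meta = meta[order]

    def lookup(self, kmer_int: int) -> list[tuple[str, int, bool]]:
        """(scaffold_id, position, survey_kmer_is_canonical) for each hit."""
        key = np.uint64(kmer_int)
        lo = int(np.searchsorted(self._kmers, key, side="left"))
        hi = int(np.searchsorted(self._kmers, key, side="right"))
        hits = []
        for m in self._meta[lo:hi]:
            m = int(m)
            hits.append(
                (self.scaffold_ids[m >> 40], (m >> 1) & ((1 << 39) - 1), bool(m & 1))
            )
        return hits


def _as_index(survey, k: int) -> SurveyIndex:
    if isinstance(survey, SurveyIndex):
        return survey
    return SurveyIndex(list(survey), k)


def anchor_read(read: str, survey, k: int = 31) -> list[Placement]:
    """Maximal exact matches of a read, seeded by its first matching k-mer.

    Seeds are scanned 5'->3'; the first seed with survey hits determines the
    placements (one per distinct hit), each grown to a maximal exact match
    around the seed. Returns [] when no seed matches.
    """
    index = _as_index(survey, k)
    k = index.k
    if k > len(read):
        raise ValueError("k must not exceed read length")
    fwd = _kmers.kmer_ints(read, k)
    placements: list[Placement] = []
    for off in range(len(read) - k + 1):
        if fwd[off] == np.uint64(2**63):
            continue
        canon = int(_kmers.canonical_ints(fwd[off : off + 1], k)[0])
        hits = index.lookup(canon)
        if not hits:
            continue
        read_is_fwd = int(fwd[off]) == canon
        for scaffold_id, pos, survey_is_fwd in hits:
            same_strand = read_is_fwd == survey_is_fwd
            oriented = read if same_strand else _kmers.revcomp(read)
            ooff = off if same_strand else len(read) - off - k
            seq = index.sequences[scaffold_id]
            s, e = pos, pos + k
            rs, re_ = ooff, ooff + k
            while rs > 0 and s > 0 and seq[s - 1] == oriented[rs - 1]:
                s -= 1
                rs -= 1
            while re_ < len(oriented) and e < len(seq) and seq[e] == oriented[re_]:
                e += 1
                re_ += 1
            p = Placement(scaffold_id, s, e, "+" if same_strand else "-", rs, re_)
            if not any(
                q.scaffold == p.scaffold and q.start == p.start and q.end == p.end
                for q in placements
            ):
                placements.append(p)
        break
    return placements


@dataclass
class ExtendedContig:
    """A read grown with survey context, or a merge of such sequences."""

    contig_id: str
    sequence: str
    source_read_ids: list[str] = field(default_factory=list)
    placements: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    iterations: int = 0
    anchored: bool = True
    ambiguous: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def extend_iteratively(
    read: str,
    survey,
    k: int = 31,
    flank: int = 1000,
    max_len: int = 70_000,
    max_iter: int = 100,
    read_id: str = "read",
    max_mismatch_frac: float = 0.1,
) -> ExtendedContig:
    """Grow a read with up to `flank` bases of survey context per side and
    iteration, re-anchoring each round, until fixed point, `max_len` or
    `max_iter`.

    A read with no anchor is returned unchanged and flagged unanchored; a
    read with several equally long best placements is returned unextended
    and flagged ambiguous (repeats must not chimerize the locus). Reads on
    the reverse strand are reverse-complemented first; output is on the
    survey forward strand.
    """
    index = _as_index(survey, k)
    placements = anchor_read(read, index, k)
    if not placements:
        return ExtendedContig(read_id, read, [read_id], anchored=False)
    best_len = max(p.length for p in placements)
    best = [p for p in placements if p.length == best_len]
    if len(best) > 1:
        return ExtendedContig(read_id, read, [read_id], ambiguous=True)
    p = best[0]
    oriented = read if p.strand == "+" else _kmers.revcomp(read)
    seq = index.sequences[p.scaffold]
    L = len(seq)
    # implied full-read span on the survey, clipped at scaffold ends
    s = max(0, p.start - p.read_start)
    e = min(L, p.end + (len(oriented) - p.read_end))
    span = seq[s:e]
    mismatches = sum(a != b for a, b in zip(span, oriented[: e - s]))
    if mismatches > max_mismatch_frac * len(oriented):
        return ExtendedContig(read_id, read, [read_id], anchored=False)

    iterations = 0
    while iterations < max_iter:
        allow = max_len - (e - s)
        if allow <= 0:
            break
        grow_left = min(flank, s, allow)
        grow_right = min(flank, L - e, allow - grow_left)
        if grow_left == 0 and grow_right == 0:
            break
        s -= grow_left
        e += grow_right
        iterations += 1

    return ExtendedContig(
        contig_id=read_id,
        sequence=seq[s:e],
        source_read_ids=[read_id],
        placements=[(p.scaffold, (s, e))],
        iterations=iterations,
    )


def merge_extended(
    contigs: list[ExtendedContig], min_overlap: int = 1
) -> list[ExtendedContig]:
    """Merge contigs whose survey placements overlap by >= min_overlap.

    Merged sequences are spliced through the shared interval after checking
    the overlapping sequence agrees; disagreeing overlaps are logged and
    both contigs kept. Idempotent: merging a merged set changes nothing.
    """
    placed = [c for c in contigs if c.anchored and not c.ambiguous and c.placements]
    passthrough = [c for c in contigs if c not in placed]
    by_scaffold: dict[str, list[ExtendedContig]] = {}
    for c in placed:
        by_scaffold.setdefault(c.placements[0][0], []).append(c)

    merged_all: list[ExtendedContig] = []
    for scaffold in sorted(by_scaffold):
        group = sorted(by_scaffold[scaffold], key=lambda c: c.placements[0][1])
        current: ExtendedContig | None = None
        for c in group:
            if current is None:
                current = c
                continue
            (s1, e1) = current.placements[0][1]
            (s2, e2) = c.placements[0][1]
            ov = min(e1, e2) - s2
            if ov >= min_overlap:
                if e2 <= e1:  # contained
                    expected = current.sequence[s2 - s1 : s2 - s1 + len(c.sequence)]
                    if expected != c.sequence:
                        log.warning(
                            "conflicting contained contig %s on %s", c.contig_id, scaffold
                        )
                        merged_all.append(c)
                        continue
                    new_seq, new_span = current.sequence, (s1, e1)
                else:
                    if current.sequence[s2 - s1 :] != c.sequence[:ov]:
                        log.warning(
                            "conflicting overlap %s/%s on %s",
                            current.contig_id,
                            c.contig_id,
                            scaffold,
                        )
                        merged_all.append(current)
                        current = c
                        continue
                    new_seq = current.sequence + c.sequence[ov:]
                    new_span = (s1, e2)
                current = ExtendedContig(
                    contig_id=current.contig_id,
                    sequence=new_seq,
                    source_read_ids=current.source_read_ids + c.source_read_ids,
                    placements=[(scaffold, new_span)],
                    iterations=max(current.iterations, c.iterations),
                )
            else:
                merged_all.append(current)
                current = c
        if current is not None:
            merged_all.append(current)

    out = merged_all + passthrough
    for n, c in enumerate(out):
        c.contig_id = f"ec{n:04d}"
    return out


@dataclass
class AssemblyStats:
    """Length summary of an assembly; N50 is a count, L50 a length."""

    l50_bp: int
    n50_count: int
    total_bp: int
    mean_bp: float
    max_bp: int
    min_bp: int
    count: int


def assembly_stats(contigs) -> AssemblyStats:
    """Compute the length summary over contigs (or raw lengths)."""
    lengths = sorted(
        (len(c) if not isinstance(c, int) else c for c in contigs), reverse=True
    )
    if not lengths:
        raise ValueError("assembly_stats requires at least one contig")
    total = sum(lengths)
    acc = 0
    for i, length in enumerate(lengths):
        acc += length
        if 2 * acc >= total:
            return AssemblyStats(
                l50_bp=length,
                n50_count=i + 1,
                total_bp=total,
                mean_bp=total / len(lengths),
                max_bp=lengths[0],
                min_bp=lengths[-1],
                count=len(lengths),
            )
    raise AssertionError("unreachable")


def stats_table(stats: AssemblyStats) -> pd.DataFrame:
    """Assembly summary as a two-column table with conventional row names."""
    rows = [
        ("L50 (bp)", stats.l50_bp),
        ("N50 (#)", stats.n50_count),
        ("Total length (bp)", stats.total_bp),
        ("Average length (bp)", round(stats.mean_bp, 1)),
        ("Max length (bp)", stats.max_bp),
        ("Min length (bp)", stats.min_bp),
        ("Contigs (#)", stats.count),
    ]
    return pd.DataFrame(rows, columns=["Data (unit)", "Value"])
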