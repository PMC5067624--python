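"""Deletion-based bulk contrast.

A radiation-hybrid BulkSeq experiment pools DNA of lines that retain the
target locus (bulk POS) and lines that deleted it (bulk NEG), reduces genome
complexity by restriction digestion, and sequences fragment ends. Because RH
lines are hemizygous, the contrast is presence/absence of coverage rather
than allele frequency: restriction-anchored read clusters ("contigs of
reads") covered in bulk POS but absent from bulk NEG are expected to sit
inside the region all NEG lines co-deleted, i.e. around the target locus.

This module provides the in-silico digestion, the foreign-read filter, the
read grouping into contigs and the presence/absence caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kmers
from .io import ReadPair

#: Recognition sites; both enzymes are modelled as cutting after base 5 of
#: the site on the forward strand (blunt-cut simplification: the 3' overhang
#: chemistry is irrelevant to locus presence/absence).
ENZYMES = {"PstI": "CTGCAG", "AatII": "GACGTC"}
CUT_OFFSET = 5


@dataclass
class Fragment:
    """A restriction fragment: interval on its scaffold plus sequence."""

    scaffold: str
    start: int
    end: int
    sequence: str
    enzyme: str

    def __len__(self) -> int:
        return self.end - self.start


def find_sites(sequence: str, site: str) -> list[int]:
    """Start positions of every (possibly overlapping) site occurrence."""
    positions = []
    i = sequence.find(site)
    while i != -1:
        positions.append(i)
        i = sequence.find(site, i + 1)
    return positions


def digest(sequence: str, enzyme: str, scaffold: str = "seq", offset: int = 0) -> list[Fragment]:
    """Cut a sequence with one enzyme; fragments partition the input.

    `offset` shifts reported coordinates (useful when digesting a slice of a
    larger scaffold).
    """
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}; known: {sorted(ENZYMES)}")
    site = ENZYMES[enzyme]
    cuts = [p + CUT_OFFSET for p in find_sites(sequence, site)]
    bounds = [0] + cuts + [len(sequence)]
    frags = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e > s:
            frags.append(Fragment(scaffold, offset + s, offset + e, sequence[s:e], enzyme))
    return frags


def reference_spectrum(scaffolds, k: int = 31) -> np.ndarray:
    """Sorted canonical k-mer spectrum of the reference scaffolds."""
    return _kmers.canonical_spectrum([s.sequence for s in scaffolds], k)


def filter_foreign_reads(
    reads: list[ReadPair],
    ref_kmer_set: np.ndarray,
    k: int = 31,
    min_shared: int = 1,
) -> tuple[list[ReadPair], list[ReadPair]]:
    """Split read pairs into (kept, removed) by shared reference k-mers.

    A pair is kept iff its two mates together share at least `min_shared`
    canonical k-mers with the reference spectrum. This removes reads from a
    contaminating genome with a disjoint k-mer spectrum.
    """
    if k < 11:
        raise ValueError("k must be >= 11 for a discriminative spectrum")
    if ref_kmer_set.size == 0:
        raise ValueError("empty reference k-mer spectrum")
    kept, removed = [], []
    for pair in reads:
        shared = _kmers.shared_count(_kmers.canonical_kmers(pair.mate1, k), ref_kmer_set)
        if shared < min_shared:
            shared += _kmers.shared_count(
                _kmers.canonical_kmers(pair.mate2, k), ref_kmer_set
            )
        (kept if shared >= min_shared else removed).append(pair)
    return kept, removed


@dataclass
class ReadContig:
    """A restriction-anchored read cluster with per-bulk coverage."""

    contig_id: str
    consensus: str
    reads_pos: list[str] = field(default_factory=list)
    reads_neg: list[str] = field(default_factory=list)
    coverage_pos: float = 0.0
    coverage_neg: float = 0.0


def _canonical_orient(seq: str) -> str:
    rc = _kmers.revcomp(seq)
    return seq if seq <= rc else rc


def build_read_contigs(
    reads_pos: list[ReadPair],
    reads_neg: list[ReadPair],
    k: int = 31,
    min_overlap: int = 30,
) -> list[ReadContig]:
    """Group reads into "contigs of reads" and merge by exact overlap.

    Reads are first collapsed by canonical (strand-folded) identity — reads
    sequenced off the same restriction fragment end are identical in the
    error-free case — then distinct sequences are chained whenever the suffix
    of one exactly matches the prefix of another over >= min_overlap bases
    (seeded by a shared k-mer). Mismatching reads stay in separate contigs:
    there is deliberately no error-tolerant consensus.
    """
    # unique oriented sequence -> [pos read ids, neg read ids]
    members: dict[str, tuple[list[str], list[str]]] = {}

    def _add(pair: ReadPair, bulk: int) -> None:
        for suffix, mate in (("/1", pair.mate1), ("/2", pair.mate2)):
            key = _canonical_orient(mate)
            members.setdefault(key, ([], []))[bulk].append(pair.id + suffix)

    for p in reads_pos:
        _add(p, 0)
    for p in reads_neg:
        _add(p, 1)

    seqs = sorted(members)  # deterministic order
    merged_into: dict[int, int] = {}
    chains: dict[int, list[int]] = {i: [i] for i in range(len(seqs))}
    sequences: dict[int, str] = dict(enumerate(seqs))

    # index: prefix k-mer (exact string, both orientations) -> seq indices
    prefix_index: dict[str, list[int]] = {}
    for i, s in enumerate(seqs):
        if len(s) >= k:
            prefix_index.setdefault(s[:k], []).append(i)

    def _root(i: int) -> int:
        while i in merged_into:
            i = merged_into[i]
        return i

    changed = True
    while changed:
        changed = False
        for i in list(sequences):
            i = _root(i)
            a = sequences.get(i)
            if a is None or len(a) < k:
                continue
            for cand in prefix_index.get(a[-k:], []):
                j = _root(cand)
                if j == i or j not in sequences:
                    continue
                b = sequences[j]
                # find exact suffix(a)/prefix(b) overlap anchored at a's last k-mer
                pos = a.rfind(b[:k]) if len(b) >= k else -1
                if pos < 0:
                    continue
                ov = len(a) - pos
                if ov < min_overlap or ov > len(b):
                    continue
                if a[pos:] != b[:ov]:
                    continue
                sequences[i] = a + b[ov:]
                chains[i].extend(chains.pop(j))
                del sequences[j]
                merged_into[j] = i
                changed = True
                break

    contigs = []
    for n, i in enumerate(sorted(sequences)):
        consensus = sequences[i]
        rp: list[str] = []
        rn: list[str] = []
        for m in chains[i]:
            rp.extend(members[seqs[m]][0])
            rn.extend(members[seqs[m]][1])
        read_len_sum_pos = sum(len(seqs[m]) * len(members[seqs[m]][0]) for m in chains[i])
        read_len_sum_neg = sum(len(seqs[m]) * len(members[seqs[m]][1]) for m in chains[i])
        contigs.append(
            ReadContig(
                contig_id=f"rc{n:06d}",
                consensus=consensus,
                reads_pos=rp,
                reads_neg=rn,
                coverage_pos=read_len_sum_pos / len(consensus),
                coverage_neg=read_len_sum_neg / len(consensus),
            )
        )
    return contigs


@dataclass
class PresenceCall:
    contig_id: str
    status: str  # POS_only | NEG_only | both | neither


def call_presence(
    contigs: list[ReadContig],
    min_present_cov: float = 5.0,
    max_absent_cov: float = 0.0,
) -> list[PresenceCall]:
    """Classify contigs by per-bulk coverage.

    POS_only: covered in bulk POS (>= min_present_cov) and absent from bulk
    NEG (<= max_absent_cov); NEG_only symmetric; both when covered in both;
    neither otherwise. POS_only contigs are the deletion-mapping signal.
    """
    if not min_present_cov > max_absent_cov >= 0:
        raise ValueError("require min_present_cov > max_absent_cov >= 0")
    calls = []
    for c in contigs:
        pos_present = c.coverage_pos >= min_present_cov
        neg_present = c.coverage_neg >= min_present_cov
        pos_absent = c.coverage_pos <= max_absent_cov
        neg_absent = c.coverage_neg <= max_absent_cov
        if pos_present and neg_absent:
            status = "POS_only"
        elif neg_present and pos_absent:
            status = "NEG_only"
        elif pos_present and neg_present:
            status = "both"
        else:
            status = "neither"
        calls.append(PresenceCall(c.contig_id, status))
    return calls


def library_yield_gb(n_pairs: float, read_length: int) -> float:
    """Total gigabases from `n_pairs` mate pairs of `read_length` bp each."""
    return n_pairs * 2 * read_length / 1e9
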