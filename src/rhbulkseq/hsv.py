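"""Homoeologous sequence variants and homoeoallele expression.

In a polyploid, the copies of a gene on homoeologous chromosomes are fixed
for small sequence differences (homoeologous sequence variants, HSVs). This
module aligns near-identical haplotype sequences of one gene, reports
variant columns, flags diagnostic columns that perfectly separate a
functional from a nonfunctional haplotype group, annotates coding effects
(e.g. an exonic G->A turning an AGG arginine codon into AAG lysine), and
quantifies homoeoallele expression two ways: pyrosequencing peak
normalization (variant peak over the mean of the two flanking reference
peaks) and qPCR relative quantification by 2^-ddCt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .simulate import CtTable, GeneModel, PyroSample


@dataclass
class HaplotypeAlignment:
    """Multiple alignment of haplotypes projected onto the first sequence.

    Column coordinates are positions in the reference (first) haplotype;
    insertion columns relative to the reference carry an insertion index
    > 0 at the reference position they precede.
    """

    ids: list[str]
    # rows: position, insertion_index, one column of bases per haplotype
    table: pd.DataFrame

    def variant_columns(self) -> pd.DataFrame:
        bases = self.table[self.ids]
        keep = bases.nunique(axis=1) >= 2
        return self.table[keep].reset_index(drop=True)


def _pairwise(ref: str, alt: str):
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-4,
        extend_gap_score=-0.5,
    )
    return aligner.align(ref, alt)[0]


def align_haplotypes(seqs, min_identity: float = 0.9) -> HaplotypeAlignment:
    """Globally align near-identical haplotypes against the first one.

    Homoeologues are expected to be >= 90% identical; anything less raises
    (such sequences need manual alignment, not an automatic projection).
    """
    records = list(seqs)
    if len(records) < 2:
        raise ValueError("need at least two haplotypes")
    ids = [r.id for r in records]
    ref = records[0].sequence
    per_hap_ref_base: dict[str, list[str]] = {ids[0]: list(ref)}
    insertions: dict[tuple[int, int], dict[str, str]] = {}

    for rec in records[1:]:
        aln = _pairwise(ref, rec.sequence)
        blocks_ref, blocks_alt = aln.aligned
        matches = sum(
            1
            for (rs, re_), (qs, qe) in zip(blocks_ref, blocks_alt)
            for i in range(re_ - rs)
            if ref[rs + i] == rec.sequence[qs + i]
        )
        identity = matches / max(len(ref), len(rec.sequence))
        if identity < min_identity:
            raise ValueError(
                f"haplotype {rec.id!r} is only {identity:.2%} identical to "
                f"{ids[0]!r}; below {min_identity:.0%} — align manually"
            )
        mapped = ["-"] * len(ref)
        prev_re, prev_qe = 0, 0
        for (rs, re_), (qs, qe) in zip(blocks_ref, blocks_alt):
            if rs > prev_re and qs > prev_qe:
                raise AssertionError("global alignment cannot gap both sequences")
            if qs > prev_qe:  # insertion in alt before ref position rs
                ins = rec.sequence[prev_qe:qs]
                for j, base in enumerate(ins):
                    insertions.setdefault((rs, j + 1), {})[rec.id] = base
            for i in range(re_ - rs):
                mapped[rs + i] = rec.sequence[qs + i]
            prev_re, prev_qe = re_, qe
        per_hap_ref_base[rec.id] = mapped

    rows = []
    for pos in range(len(ref)):
        for key in sorted(k for k in insertions if k[0] == pos):
            row = {"position": pos, "insertion_index": key[1]}
            for hid in ids:
                row[hid] = insertions[key].get(hid, "-")
            rows.append(row)
        row = {"position": pos, "insertion_index": 0}
        for hid in ids:
            row[hid] = per_hap_ref_base[hid][pos]
        rows.append(row)
    return HaplotypeAlignment(ids=ids, table=pd.DataFrame(rows))


@dataclass
class HSVTable:
    """Variant columns across haplotypes, with diagnostic flags.

    A column is diagnostic when its base partitions the designated
    functional haplotypes from all others with zero exceptions.
    """

    data: pd.DataFrame  # position, insertion_index, per-haplotype bases, diagnostic
    haplotype_ids: list[str]
    functional_ids: list[str]

    @property
    def diagnostic_positions(self) -> list[int]:
        return self.data.loc[self.data["diagnostic"], "position"].tolist()


def call_hsv(alignment: HaplotypeAlignment, functional_group_ids) -> HSVTable:
    """Report all variant columns; flag the ones that perfectly separate
    the functional group from the rest."""
    functional = [h for h in alignment.ids if h in set(functional_group_ids)]
    others = [h for h in alignment.ids if h not in set(functional_group_ids)]
    var = alignment.variant_columns().copy()
    flags = []
    for _, row in var.iterrows():
        f_bases = {row[h] for h in functional}
        o_bases = {row[h] for h in others}
        flags.append(len(f_bases) == 1 and len(o_bases) == 1 and f_bases != o_bases)
    var["diagnostic"] = flags
    return HSVTable(data=var, haplotype_ids=alignment.ids, functional_ids=functional)


@dataclass
class EffectCall:
    """Coding consequence of one exonic variant."""

    position: int  # genomic position in the haplotype
    cds_offset: int
    codon_before: str
    codon_after: str
    residue_index: int  # 1-based in the protein from the first start
    residue_before: str
    residue_after: str
    synonymous: bool


def annotate_effect(
    gene: GeneModel, haplotype_seq: str, position: int, alt_base: str
) -> EffectCall:
    """Map a genomic variant position through the exon structure to its
    codon and residue change under the standard codon table.

    Raises for intronic positions ("noncoding").
    """
    cds_offset = gene.genomic_to_cds(position)  # raises inside introns
    cds = gene.spliced_cds(haplotype_seq)
    s0 = gene.start_offsets[0]
    codon_index = (cds_offset - s0) // 3
    codon_start = s0 + 3 * codon_index
    codon_before = cds[codon_start : codon_start + 3]
    within = cds_offset - codon_start
    codon_after = codon_before[:within] + alt_base + codon_before[within + 1 :]
    aa_before = str(Seq(codon_before).translate())
    aa_after = str(Seq(codon_after).translate())
    return EffectCall(
        position=position,
        cds_offset=cds_offset,
        codon_before=codon_before,
        codon_after=codon_after,
        residue_index=codon_index + 1,
        residue_before=aa_before,
        residue_after=aa_after,
        synonymous=aa_before == aa_after,
    )


@dataclass
class AlleleQuant:
    """Normalized pyrosequencing peak values and percent-of-reference."""

    sample_id: str
    normalized_g: float
    normalized_a: float
    percent_g: float
    percent_a: float

    @property
    def g_fraction(self) -> float:
        total = self.normalized_g + self.normalized_a
        return self.normalized_g / total if total > 0 else math.nan


def pyro_quantify(
    samples: list[PyroSample], reference_sample_id: str
) -> list[AlleleQuant]:
    """Normalize variant peaks by the mean of the two flanking reference
    peaks; express each allele relative to the reference sample's G value
    (which is 100% by definition)."""
    by_id = {s.sample_id: s for s in samples}
    if reference_sample_id not in by_id:
        raise ValueError(f"reference sample {reference_sample_id!r} missing")

    def _normalized(s: PyroSample) -> tuple[float, float]:
        flank_mean = (s.flank_heights[0] + s.flank_heights[1]) / 2
        if flank_mean == 0:
            raise ValueError(f"sample {s.sample_id!r}: both flanking peaks are zero")
        return s.peak_g / flank_mean, s.peak_a / flank_mean

    ref_g, _ = _normalized(by_id[reference_sample_id])
    if ref_g == 0:
        raise ValueError("reference sample has zero normalized G peak")
    out = []
    for s in samples:
        ng, na = _normalized(s)
        out.append(
            AlleleQuant(
                sample_id=s.sample_id,
                normalized_g=ng,
                normalized_a=na,
                percent_g=100.0 * ng / ref_g,
                percent_a=100.0 * na / ref_g,
            )
        )
    return out


@dataclass
class RQResult:
    """Relative quantification of one sample by 2^-ddCt."""

    sample_id: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    rq_sd: float


def compute_rq(ct_table: CtTable) -> list[RQResult]:
    """2^-ddCt relative quantification against the calibrator sample.

    dCt = mean(Ct_target) - mean(Ct_reference) per sample; ddCt subtracts
    the calibrator's dCt; RQ = 2^-ddCt (calibrator RQ is exactly 1). The
    replicate SD is the SD of per-replicate RQ values.
    """
    df = ct_table.data
    if ct_table.calibrator not in set(df["sample"]):
        raise ValueError(f"calibrator {ct_table.calibrator!r} missing from Ct table")
    if not np.isfinite(df[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    dct = (
        df.groupby("sample", sort=False)
        .apply(
            lambda g: g["ct_target"].mean() - g["ct_reference"].mean(),
            include_groups=False,
        )
        .to_dict()
    )
    dct_cal = dct[ct_table.calibrator]
    out = []
    for sample, group in df.groupby("sample", sort=False):
        ddct = dct[sample] - dct_cal
        rq_reps = 2.0 ** -(
            (group["ct_target"] - group["ct_reference"]) - dct_cal
        )
        out.append(
            RQResult(
                sample_id=str(sample),
                delta_ct=float(dct[sample]),
                delta_delta_ct=float(ddct),
                rq=float(2.0**-ddct),
                rq_sd=float(rq_reps.std(ddof=1)) if len(rq_reps) > 1 else 0.0,
            )
        )
    return out


def implied_intron_length(gdna_amplicon_bp: int, cdna_amplicon_bp: int) -> int:
    """Intron span implied by a genomic vs spliced amplicon size difference."""
    if gdna_amplicon_bp < cdna_amplicon_bp:
        raise ValueError("genomic amplicon cannot be shorter than the cDNA amplicon")
    return gdna_amplicon_bp - cdna_amplicon_bp
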