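"""End-to-end synthetic studies.

Two composed workflows mirror the two halves of an RH BulkSeq experiment:

* `bulk_contrast_study` — simulate the genome, panel and restriction-reduced
  bulk reads; filter foreign reads; group reads into contigs; call
  presence/absence; and score how well the POS-only contigs recover the
  region co-deleted by the NEG bulk.
* `mapping_study` — deletion-type the panel from test-cross seed counts,
  build the marker retention matrix, order the markers into a centiRay map,
  scan for cosegregation, anchor the map physically and land on the
  candidate gene.

Both return result objects carrying the planted truth next to the computed
answers, so recovery is a comparison, not a re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bulkseq import (
    PresenceCall,
    ReadContig,
    build_read_contigs,
    call_presence,
    filter_foreign_reads,
    reference_spectrum,
)
from .extension import SurveyIndex, anchor_read
from .landing import CandidateReport, ORF, orfs_from_genes, refine_interval
from .rhmap import (
    PhysicalAnchorSet,
    RetentionMatrix,
    RHMapResult,
    anchor_and_resolution,
    build_retention_matrix,
    classify_deletion_typing,
    cosegregation_scan,
    order_markers,
)
from .simulate import (
    BulkReads,
    Marker,
    ReferenceSet,
    RHLine,
    markers_from_genes,
    simulate_bulk_reads,
    simulate_genome,
    simulate_rh_panel,
    simulate_testcross,
)

DEFAULT_SCAFFOLD_LEN = 5_000_000
DEFAULT_N_GENES = 10
DEFAULT_N_LINES = 64


def default_reference(seed: int, scaffold_len: int = DEFAULT_SCAFFOLD_LEN,
                      n_genes: int = DEFAULT_N_GENES) -> ReferenceSet:
    return simulate_genome(
        n_scaffolds=1, scaffold_len=scaffold_len, n_genes=n_genes, seed=seed
    )


def _intersect_deletions(lines: list[RHLine], scaffold_ids) -> dict[str, list[tuple[int, int]]]:
    """Genome-wide intersection of the lines' deleted-region sets."""
    shared: dict[str, list[tuple[int, int]]] = {}
    for scf in scaffold_ids:
        current = lines[0].deletions.get(scf, [])
        for line in lines[1:]:
            nxt = []
            for s1, e1 in current:
                for s2, e2 in line.deletions.get(scf, []):
                    s, e = max(s1, s2), min(e1, e2)
                    if e > s:
                        nxt.append((s, e))
            current = nxt
        if current:
            shared[scf] = sorted(current)
    return shared


@dataclass
class BulkContrastResult:
    ref: ReferenceSet
    lines: list[RHLine]
    bulk: BulkReads
    contigs: list[ReadContig]
    calls: list[PresenceCall]
    pos_only_ids: list[str]
    footprints: dict[str, list[tuple[str, int, int]]]  # contig -> placements
    shared_deletions: dict[str, list[tuple[int, int]]]
    removed_fraction: float
    footprints_within_fraction: float
    tiling_fraction: float


def _within_padded(
    scaffold: str, start: int, end: int,
    intervals: dict[str, list[tuple[int, int]]], pad: int,
) -> bool:
    return any(
        s - pad <= start and end <= e + pad
        for s, e in intervals.get(scaffold, [])
    )


def bulk_contrast_study(
    seed: int,
    ref: ReferenceSet | None = None,
    lines: list[RHLine] | None = None,
    n_lines: int = DEFAULT_N_LINES,
    size_max: int = 600,
    **read_kwargs,
) -> BulkContrastResult:
    """Run the full bulk presence/absence contrast on a synthetic panel."""
    if ref is None:
        ref = default_reference(seed)
    if lines is None:
        lines = simulate_rh_panel(ref, n_lines=n_lines, seed=seed + 1)
    bulk = simulate_bulk_reads(ref, lines, seed=seed + 2, **read_kwargs)

    spectrum = reference_spectrum(ref.scaffolds, k=31)
    kept_pos, removed_pos = filter_foreign_reads(bulk.pairs_pos, spectrum)
    kept_neg, removed_neg = filter_foreign_reads(bulk.pairs_neg, spectrum)
    n_total = len(bulk.pairs_pos) + len(bulk.pairs_neg)
    removed_fraction = (len(removed_pos) + len(removed_neg)) / max(1, n_total)

    contigs = build_read_contigs(kept_pos, kept_neg)
    calls = call_presence(contigs)
    pos_only = {c.contig_id for c, k in zip(contigs, calls) if k.status == "POS_only"}

    neg_lines = [l for l in lines if l.line_id in bulk.neg_line_ids]
    shared = _intersect_deletions(neg_lines, [s.id for s in ref.scaffolds])

    index = SurveyIndex(ref.scaffolds, k=31)
    footprints: dict[str, list[tuple[str, int, int]]] = {}
    n_within = 0
    for c in contigs:
        if c.contig_id not in pos_only:
            continue
        placements = anchor_read(c.consensus, index, k=31)
        spans = [(p.scaffold, p.start, p.end) for p in placements]
        footprints[c.contig_id] = spans
        if spans and all(
            _within_padded(scf, s, e, shared, pad=size_max) for scf, s, e in spans
        ):
            n_within += 1
    footprints_within = n_within / max(1, len(footprints))

    # which size-selected reference fragments inside the shared deletion are
    # tiled by a POS-only contig footprint?
    from .simulate import size_selected_fragments

    frags = [
        f
        for f in size_selected_fragments(ref)
        if any(s <= f.start and f.end <= e for s, e in shared.get(f.scaffold, []))
    ]
    all_spans = [sp for spans in footprints.values() for sp in spans]
    n_tiled = sum(
        any(
            scf == f.scaffold and s < f.end and f.start < e
            for scf, s, e in all_spans
        )
        for f in frags
    )
    tiling = n_tiled / max(1, len(frags))

    return BulkContrastResult(
        ref=ref,
        lines=lines,
        bulk=bulk,
        contigs=contigs,
        calls=calls,
        pos_only_ids=sorted(pos_only),
        footprints=footprints,
        shared_deletions=shared,
        removed_fraction=removed_fraction,
        footprints_within_fraction=footprints_within,
        tiling_fraction=tiling,
    )


@dataclass
class MappingStudyResult:
    ref: ReferenceSet
    lines: list[RHLine]
    markers: list[Marker]
    matrix: RetentionMatrix
    phenotype_calls: dict[str, str]
    map_result: RHMapResult
    scan: object  # DataFrame from cosegregation_scan
    cosegregating_locus: str
    anchors: PhysicalAnchorSet
    orfs: list[ORF] = field(default_factory=list)
    report: CandidateReport | None = None
    resolution_kb_per_cR: float = float("nan")
    causal_marker_id: str = ""

    @property
    def causal_is_unique_candidate(self) -> bool:
        return (
            self.report is not None
            and len(self.report.candidates) == 1
            and self.report.candidates[0].name == self.ref.causal_gene_id
        )


def mapping_study(
    seed: int,
    ref: ReferenceSet | None = None,
    lines: list[RHLine] | None = None,
    n_lines: int = DEFAULT_N_LINES,
    n_seeds_per_cross: int = 160,
) -> MappingStudyResult:
    """Deletion-type, map, scan and land on the candidate gene."""
    if ref is None:
        ref = default_reference(seed)
    if lines is None:
        lines = simulate_rh_panel(ref, n_lines=n_lines, seed=seed + 1)

    markers = markers_from_genes(ref)
    matrix = build_retention_matrix(lines, markers)

    cross_rng = np.random.default_rng([seed, 3])
    phenotype_calls = {}
    for line in lines:
        typing = simulate_testcross(
            line, n_seeds=n_seeds_per_cross, seed=int(cross_rng.integers(2**31))
        )
        phenotype_calls[line.line_id] = classify_deletion_typing(
            typing.plump, typing.shrivelled
        )

    map_result = order_markers(matrix)
    scan = cosegregation_scan(matrix, phenotype_calls)
    coseg_locus = str(scan.iloc[0]["locus"])

    causal_scaffold = ref.causal_gene.scaffold
    anchors = PhysicalAnchorSet(
        scaffold=causal_scaffold,
        positions_kb={
            m.marker_id: m.position_kb for m in markers if m.scaffold == causal_scaffold
        },
    )
    orfs = orfs_from_genes(ref)
    causal_marker = f"X{ref.causal_gene_id}"

    result = MappingStudyResult(
        ref=ref,
        lines=lines,
        markers=markers,
        matrix=matrix,
        phenotype_calls=phenotype_calls,
        map_result=map_result,
        scan=scan,
        cosegregating_locus=coseg_locus,
        anchors=anchors,
        orfs=orfs,
        causal_marker_id=causal_marker,
    )
    try:
        result.report = refine_interval(
            map_result,
            anchors,
            orfs,
            coseg_locus,
            scaffold_len=len(ref.scaffold(causal_scaffold).sequence),
        )
        result.resolution_kb_per_cR, _ = anchor_and_resolution(
            map_result, anchors, coseg_locus
        )
    except ValueError:
        result.report = None  # e.g. cosegregating locus landed at a map end
    return result
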